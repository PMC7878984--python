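"""Tau-leaping birth–death simulator for tagged subpopulations.

k tagged subpopulations evolve independently under a linear birth–death
process; per fixed step dt each tag draws Poisson(beta*n*dt) births and
Poisson(delta*n*dt) deaths (capped at the current count, so extinction is
absorbing). Multinomial sampling events model technical bottlenecks
(pipetting, sequencing depth), and the in-silico experiment harness wires
simulation, sampling and founder-size estimation together to validate the
bottleneck correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    corrected_founder_population_size,
    founder_population_size,
    mean_founder_theoretical,
)
from .types import (
    BirthDeathParams,
    BottleneckLedger,
    ReferenceProfile,
    TagFrequencyProfile,
)

__all__ = [
    "TagLibraryState",
    "SimulationPlan",
    "InSilicoExperimentResult",
    "geometric_library",
    "simulate_tau_leap",
    "simulate_heterogeneous",
    "multinomial_bottleneck",
    "run_insilico_experiment",
]


@dataclass(frozen=True)
class TagLibraryState:
    """Cell counts per tag at one moment of a simulation."""

    counts: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=np.int64)
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def census(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            raise ValueError("population is extinct")
        return self.counts / total


@dataclass(frozen=True)
class SimulationPlan:
    """Settings for a tau-leap run.

    rate_sd, when positive, draws per-tag (beta_i, delta_i) once at t=0 from
    normal distributions centred on the plan rates (truncated at 0), modeling
    inheritable rate heterogeneity.
    """

    params: BirthDeathParams
    dt: float = 0.01
    n_iterations: int = 100
    seed: int = 0
    record_times: tuple = ()
    rate_sd: float = 0.0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.rate_sd < 0:
            raise ValueError("rate_sd must be non-negative")
        rec = tuple(float(x) for x in self.record_times) or (self.params.t,)
        if any(x < 0 or x > self.params.t + 1e-12 for x in rec):
            raise ValueError("record_times must lie within [0, t]")
        object.__setattr__(self, "record_times", rec)


@dataclass
class InSilicoExperimentResult:
    """Ensemble founder-size and census outcomes of a simulated experiment.

    Arrays are per-iteration; *ideal* compares true end frequencies with true
    initial frequencies, *uncorrected* uses the sampled (bottlenecked)
    profiles without correction, *corrected* additionally subtracts the
    bottleneck ledger.
    """

    nb_ideal: np.ndarray
    nb_uncorrected: np.ndarray
    nb_corrected: np.ndarray
    census_start: np.ndarray
    census_end: np.ndarray
    theory_nb: float
    ledger: BottleneckLedger

    def summary(self) -> dict:
        def stat(a):
            a = np.asarray(a, dtype=float)
            finite = a[np.isfinite(a)]
            return {
                "mean": float(finite.mean()),
                "sd": float(finite.std(ddof=1)) if finite.size > 1 else 0.0,
                "n": int(finite.size),
            }

        return {
            "nb_ideal": stat(self.nb_ideal),
            "nb_uncorrected": stat(self.nb_uncorrected),
            "nb_corrected": stat(self.nb_corrected),
            "census_start": stat(self.census_start),
            "census_end": stat(self.census_end),
            "theory_nb": self.theory_nb,
        }


def geometric_library(k: int, prob: float, seed=None) -> TagLibraryState:
    """Initial library with geometric tag abundances on support {1, 2, ...}.

    Every tag exists (no zero counts); the per-tag mean is 1/prob, so
    k=1000, prob=1/1000 gives a census near 10^6.
    """
    if not (0 < prob < 1):
        raise ValueError("prob must lie in (0, 1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    counts = rng.geometric(prob, size=k)
    return TagLibraryState(counts=counts, time=0.0)


def _tau_leap(counts, beta, delta, t_grid, dt, rng):
    """Advance counts (any shape) through the tau-leap, snapshotting at t_grid.

    beta/delta may be scalars or arrays broadcastable to counts. Returns an
    array of shape (len(t_grid),) + counts.shape.
    """
    counts = counts.astype(np.int64)
    snapshots = np.empty((len(t_grid),) + counts.shape, dtype=np.int64)
    now = 0.0
    gi = 0
    while gi < len(t_grid) and t_grid[gi] <= now + 1e-12:
        snapshots[gi] = counts
        gi += 1
    while gi < len(t_grid):
        # step with dt, shortening the last step to land on the grid time
        step = min(dt, t_grid[gi] - now)
        births = rng.poisson(beta * counts * step)
        deaths = rng.poisson(delta * counts * step)
        np.minimum(deaths, counts, out=deaths)
        counts = counts + births - deaths
        now += step
        if t_grid[gi] <= now + 1e-12:
            snapshots[gi] = counts
            gi += 1
    return snapshots


def simulate_tau_leap(plan: SimulationPlan, initial: TagLibraryState):
    """Run the tau-leap for all iterations of a plan.

    Returns (record_times, trajectories) with trajectories of shape
    (n_record, n_iterations, k). Iterations share the initial state and are
    advanced in lockstep on one seeded generator, so a given (seed, plan)
    reproduces bit-identically.
    """
    rng = np.random.default_rng(plan.seed)
    t_grid = np.asarray(sorted(set(plan.record_times)), dtype=float)
    counts = np.broadcast_to(
        initial.counts, (plan.n_iterations, initial.counts.size)
    ).copy()
    if plan.rate_sd > 0:
        beta = np.clip(
            rng.normal(plan.params.beta, plan.rate_sd, size=counts.shape), 0, None
        )
        delta = np.clip(
            rng.normal(plan.params.delta, plan.rate_sd, size=counts.shape), 0, None
        )
    else:
        beta, delta = plan.params.beta, plan.params.delta
    traj = _tau_leap(counts, beta, delta, t_grid, plan.dt, rng)
    return t_grid, traj


def simulate_heterogeneous(plan: SimulationPlan, initial: TagLibraryState):
    """Tau-leap with per-tag rates drawn once at t=0 (requires rate_sd set)."""
    if plan.rate_sd <= 0:
        raise ValueError("plan.rate_sd must be positive for heterogeneous runs")
    return simulate_tau_leap(plan, initial)


def multinomial_bottleneck(state, sample_size: int, seed=None) -> np.ndarray:
    """One multinomial draw of sample_size cells/reads over current frequencies.

    ``state`` may be a TagLibraryState, a count vector, or a frequency vector
    (sums to 1). Models pipetting or sequencing-depth subsampling.
    """
    if sample_size < 1:
        raise ValueError("sample_size must be >= 1")
    rng = np.random.default_rng(seed)
    if isinstance(state, TagLibraryState):
        weights = state.counts.astype(float)
    else:
        weights = np.asarray(state, dtype=float)
    total = weights.sum()
    if total <= 0:
        raise ValueError("cannot sample from an empty population")
    return rng.multinomial(sample_size, weights / total)


def run_insilico_experiment(
    plan: SimulationPlan,
    inoculum_sizes=(),
    sample_sizes=(),
    initial: TagLibraryState | None = None,
    library_prob: float = 1e-3,
    library_k: int = 1000,
) -> InSilicoExperimentResult:
    """Simulate birth–death + technical bottlenecks and estimate N_B three ways.

    Per iteration: evolve the library to t; push the inoculum through the
    I_1..I_mI sampling chain and the endpoint through S_1..S_mS; then compute
    the founder size (i) ideally from true pre-sampling frequencies,
    (ii) uncorrected from the sampled profiles, and (iii) with the ledger
    correction subtracted. With no bottlenecks configured all three coincide.
    """
    rng = np.random.default_rng(plan.seed)
    if initial is None:
        initial = geometric_library(library_k, library_prob, seed=rng)
    k = initial.counts.size
    tag_ids = tuple(f"tag{i:05d}" for i in range(k))
    ledger = BottleneckLedger.from_sizes(inoculum_sizes, sample_sizes)

    t_grid, traj = simulate_tau_leap(
        SimulationPlan(
            params=plan.params,
            dt=plan.dt,
            n_iterations=plan.n_iterations,
            seed=int(rng.integers(2**31)),
            record_times=(plan.params.t,),
            rate_sd=plan.rate_sd,
        ),
        initial,
    )
    end_counts = traj[-1]  # (n_iter, k)

    f0_true = initial.counts / initial.counts.sum()
    nb_ideal = np.empty(plan.n_iterations)
    nb_unc = np.empty(plan.n_iterations)
    nb_cor = np.empty(plan.n_iterations)
    census_end = end_counts.sum(axis=1).astype(float)

    ref_true = ReferenceProfile(tag_ids, f0_true)
    for it in range(plan.n_iterations):
        endc = end_counts[it]
        if endc.sum() == 0:
            nb_ideal[it] = nb_unc[it] = nb_cor[it] = np.nan
            continue
        prof_true = TagFrequencyProfile.from_counts(tag_ids, endc)
        nb_ideal[it] = founder_population_size(prof_true, ref_true).value

        # reference chain: sequential sampling of the inoculum
        ref_counts = initial.counts
        for size in inoculum_sizes:
            ref_counts = multinomial_bottleneck(ref_counts, int(size), seed=rng)
        # timepoint chain
        smp_counts = endc
        for size in sample_sizes:
            smp_counts = multinomial_bottleneck(smp_counts, int(size), seed=rng)

        if inoculum_sizes or sample_sizes:
            ref = ReferenceProfile(tag_ids, ref_counts / ref_counts.sum())
            prof = TagFrequencyProfile.from_counts(tag_ids, smp_counts)
        else:
            ref, prof = ref_true, prof_true
        nb_unc[it] = founder_population_size(prof, ref).value
        est = corrected_founder_population_size(prof, ref, ledger)
        nb_cor[it] = est.value if not est.negative_flag else np.nan

    return InSilicoExperimentResult(
        nb_ideal=nb_ideal,
        nb_uncorrected=nb_unc,
        nb_corrected=nb_cor,
        census_start=np.full(plan.n_iterations, float(initial.census)),
        census_end=census_end,
        theory_nb=mean_founder_theoretical(plan.params),
        ledger=ledger,
    )
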