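"""Synthetic barcode libraries, FASTQ read sets and experiment tables.

Everything the estimators and the read pipeline consume can be generated here
with known ground truth: barcode libraries with a pairwise Hamming-distance
floor, reads with i.i.d. per-base substitution errors and a fixed strain
barcode, and complete in-silico experiment bundles (reference + timepoint
count tables, CFU series, bottleneck ledger) driven by the tau-leap
simulator. All outputs are deterministic given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import (
    SimulationPlan,
    TagLibraryState,
    geometric_library,
    multinomial_bottleneck,
    simulate_tau_leap,
)
from .types import BottleneckLedger, CfuSeries

__all__ = [
    "GeneratorSpec",
    "BarcodeLibrary",
    "generate_library",
    "generate_reads",
    "write_fastq",
    "generate_experiment_tables",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class GeneratorSpec:
    """Settings for synthetic read generation.

    abundance is "uniform", ("geometric", prob) or an explicit weight vector.
    q is the per-base substitution probability (uniform over the three
    alternative bases, no indels, position-independent).
    """

    k: int = 50
    random_len: int = 30
    strain_len: int = 21
    strain_sequence: str | None = None
    abundance: object = "uniform"
    depth: int = 10_000
    q: float = 0.0
    n_contaminants: int = 0
    contaminant_fraction: float = 0.0
    seed: int = 0
    min_distance: int = 5

    def __post_init__(self):
        if not (0 <= self.q < 0.5):
            raise ValueError("q must lie in [0, 0.5)")
        if self.k < 1 or self.depth < 1:
            raise ValueError("k and depth must be positive")


@dataclass(frozen=True)
class BarcodeLibrary:
    """The set of true tag sequences plus the layout constants."""

    sequences: tuple
    strain_sequence: str

    @property
    def k(self) -> int:
        return len(self.sequences)

    @property
    def random_len(self) -> int:
        return len(self.sequences[0])


def _random_seqs(rng, n: int, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=(n, length), dtype=np.uint8)


def _to_strings(mat: np.ndarray) -> list[str]:
    return [_BASES[row].tobytes().decode() for row in mat]


def generate_library(spec: GeneratorSpec) -> BarcodeLibrary:
    """k distinct random barcodes with pairwise Hamming distance >= floor.

    The floor (default 5) keeps sequencing-error classes up to m_max from
    colliding between barcodes. Drawn by rejection; random 30-mers almost
    never fall below it, so the loop terminates quickly whenever
    4^random_len >> k.
    """
    rng = np.random.default_rng(spec.seed)
    if 4.0 ** spec.random_len < 100 * spec.k:
        raise ValueError("sequence space too small for k distinct barcodes")
    accepted = np.empty((0, spec.random_len), dtype=np.uint8)
    attempts = 0
    while accepted.shape[0] < spec.k:
        attempts += 1
        if attempts > 200 * spec.k:
            raise ValueError("could not satisfy the pairwise distance floor")
        cand = _random_seqs(rng, 1, spec.random_len)
        if accepted.shape[0]:
            d = (accepted != cand).sum(axis=1)
            if d.min() < spec.min_distance:
                continue
        accepted = np.vstack([accepted, cand])
    strain = spec.strain_sequence or _to_strings(
        _random_seqs(rng, 1, spec.strain_len)
    )[0]
    return BarcodeLibrary(tuple(_to_strings(accepted)), strain)


def _abundance_weights(spec: GeneratorSpec, rng) -> np.ndarray:
    ab = spec.abundance
    if isinstance(ab, str) and ab == "uniform":
        w = np.ones(spec.k)
    elif isinstance(ab, tuple) and ab[0] == "geometric":
        w = rng.geometric(ab[1], size=spec.k).astype(float)
    else:
        w = np.asarray(ab, dtype=float)
        if w.size != spec.k:
            raise ValueError("explicit weights must have length k")
    return w / w.sum()


def _mutate(mat: np.ndarray, q: float, rng) -> np.ndarray:
    """Apply i.i.d. substitutions at rate q, uniform over the 3 other bases."""
    if q == 0:
        return mat
    hit = rng.random(mat.shape) < q
    shift = rng.integers(1, 4, size=mat.shape, dtype=np.uint8)
    out = mat.copy()
    out[hit] = (out[hit] + shift[hit]) % 4
    return out


def generate_reads(library: BarcodeLibrary, spec: GeneratorSpec):
    """Synthetic reads with ground truth.

    Returns (records, truth) where records is a list of
    (read_id, sequence, source) — source is the error-free source barcode or
    "contaminant" — and truth is the per-barcode Series of error-free read
    counts. Contaminant reads carry a random barcode region and a random
    (non-matching) strain region.
    """
    rng = np.random.default_rng(spec.seed + 1)
    weights = _abundance_weights(spec, rng)
    n_cont = spec.n_contaminants or int(round(spec.depth * spec.contaminant_fraction))
    n_real = spec.depth - n_cont
    if n_real < 0:
        raise ValueError("contaminants exceed total depth")

    src = rng.choice(library.k, size=n_real, p=weights)
    lib_mat = np.array(
        [np.frombuffer(s.encode(), dtype=np.uint8) for s in library.sequences]
    )
    lib_codes = np.searchsorted(_BASES, lib_mat)  # ACGT bytes -> 0..3 codes
    strain_codes = np.searchsorted(
        _BASES, np.frombuffer(library.strain_sequence.encode(), dtype=np.uint8)
    )

    barcodes = lib_codes[src]
    strains = np.broadcast_to(strain_codes, (n_real, strain_codes.size))
    full = np.hstack([barcodes, strains])
    mutated = _mutate(full, spec.q, rng)

    records = []
    for i, row in enumerate(mutated):
        records.append(
            (f"read{i:07d}", _BASES[row].tobytes().decode(), library.sequences[src[i]])
        )
    # contaminants: random full-length sequences (strain region almost surely
    # mismatching, so they exercise both the filter and the spurious removal)
    cont = _random_seqs(rng, n_cont, full.shape[1] if n_real else spec.random_len + len(library.strain_sequence))
    for j, row in enumerate(cont):
        records.append((f"cont{j:07d}", _BASES[row].tobytes().decode(), "contaminant"))

    truth = pd.Series(
        np.bincount(src, minlength=library.k), index=list(library.sequences)
    )
    return records, truth


def write_fastq(records, path):
    """Write (id, sequence, source) records as plain 4-line FASTQ.

    Quality is a constant dummy character; the error model is quality-blind.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for rid, seq, _src in records:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
    return path


def generate_experiment_tables(
    plan: SimulationPlan,
    inoculum_sizes=(),
    sample_sizes=(),
    library_k: int = 1000,
    library_prob: float = 1e-3,
    n_reference_replicates: int = 3,
):
    """One simulated experiment ready for the estimation workflow.

    Simulates a single birth–death realization from a geometric library,
    pushes the inoculum through the I-chain (per reference replicate) and the
    endpoint through the S-chain, and returns a dict with the reference
    count tables, the timepoint count table, a noiseless CFU series, the
    bottleneck ledger, and the ground-truth parameters.
    """
    rng = np.random.default_rng(plan.seed)
    initial = geometric_library(library_k, library_prob, seed=rng)
    tag_ids = [f"tag{i:05d}" for i in range(library_k)]

    one = SimulationPlan(
        params=plan.params,
        dt=plan.dt,
        n_iterations=1,
        seed=int(rng.integers(2**31)),
        record_times=plan.record_times,
        rate_sd=plan.rate_sd,
    )
    t_grid, traj = simulate_tau_leap(one, initial)
    end_counts = traj[-1][0]

    refs = []
    for _ in range(n_reference_replicates):
        ref_counts = initial.counts
        for size in inoculum_sizes:
            ref_counts = multinomial_bottleneck(ref_counts, int(size), seed=rng)
        refs.append(pd.Series(ref_counts, index=tag_ids, name="count"))

    smp = end_counts
    for size in sample_sizes:
        smp = multinomial_bottleneck(smp, int(size), seed=rng)
    sample_table = pd.Series(smp, index=tag_ids, name="count")

    times = np.asarray(sorted({0.0, *t_grid}))
    cfu = CfuSeries(
        times=times,
        cfu_per_ml=initial.census * np.exp(plan.params.r * times),
    )
    return {
        "reference_tables": refs,
        "sample_table": sample_table,
        "cfu": cfu,
        "ledger": BottleneckLedger.from_sizes(inoculum_sizes, sample_sizes),
        "truth": {
            "beta": plan.params.beta,
            "delta": plan.params.delta,
            "t": plan.params.t,
            "n0": initial.census,
            "end_counts": pd.Series(end_counts, index=tag_ids),
        },
    }
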