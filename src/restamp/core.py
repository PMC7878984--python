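"""Closed-form estimators for barcode-based division/death rate inference.

The central quantity is the founder population size N_B(t): the size of a
hypothetical population whose multinomial sampling drift matches the observed
change in tag frequencies between t=0 and t. For a neutral birth–death process
with division rate beta and death rate delta its expectation is

    <N_B(t)> = (beta - delta) N(0) / [(beta + delta) (1 - exp(-(beta-delta) t))]

which, combined with the census trajectory N(t) = N(0) exp(r t), inverts to
closed-form estimates of both rates. Technical bottlenecks (pipetting,
sequencing depth) add drift of their own; their contribution is additive on
the inverse founder-size scale and is subtracted via a ledger of mean inverse
sample sizes.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    BirthDeathParams,
    BottleneckLedger,
    CfuSeries,
    FounderEstimate,
    PlasmidObservation,
    RateEstimate,
    ReferenceProfile,
    SensitivityQuery,
    TagFrequencyProfile,
)

__all__ = [
    "SENSITIVITY_THRESHOLD",
    "founder_population_size",
    "corrected_founder_population_size",
    "mean_founder_theoretical",
    "estimate_rates",
    "net_growth_rate",
    "bd_frequency_variance",
    "bottleneck_sensitivity",
    "sensitivity_grid",
    "death_emulation_volume",
    "death_emulation_schedule",
    "death_emulation_scale",
    "volume_rescale",
    "plasmid_segregation_rates",
    "expected_surviving_tags",
    "rate_from_doubling_time",
    "doubling_time_from_rate",
]

#: Empirically calibrated robustness cut-off for the bottleneck sensitivity:
#: sampling-induced frequency variance should stay below 0.17 of the
#: birth–death-induced variance for rate estimates to tolerate errors in the
#: bottleneck correction terms.
SENSITIVITY_THRESHOLD = 0.17

# |r|*t below this uses the r->0 series limit of the closed forms (avoids 0/0).
_R_T_EPS = 1e-8


def _drift_denominator(
    profile_t: TagFrequencyProfile, reference: ReferenceProfile
) -> tuple[float, int, int]:
    """Mean chi-square-like drift term of the founder-size estimator.

    Returns (mean drift term, tags used, tags excluded). Tags whose reference
    frequency is 0 or 1 carry no drift information and are excluded.
    """
    if profile_t.tag_ids != reference.tag_ids:
        raise ValueError("profile and reference must share the same tag set")
    keep = ~reference.zero_mask
    k_used = int(keep.sum())
    if k_used < 2:
        raise ValueError("fewer than 2 informative tags in the reference")
    f0 = reference.mean_freqs[keep]
    ft = profile_t.freqs[keep]
    terms = (ft - f0) ** 2 / (f0 * (1.0 - f0))
    return float(terms.mean()), k_used, int((~keep).sum())


def founder_population_size(
    profile_t: TagFrequencyProfile, reference: ReferenceProfile
) -> FounderEstimate:
    """Founder population size from tag-frequency drift (no corrections).

    N_B(t) = 1 / [ (1/k') sum_i (f_i(t) - <f_i(0)>)^2 / (<f_i(0)>(1-<f_i(0)>)) ]

    over the k' tags with informative reference frequencies. Identical
    profiles give infinite N_B (zero drift), returned flagged so callers can
    tell it apart from a genuine estimate.
    """
    denom, k_used, k_excl = _drift_denominator(profile_t, reference)
    if denom == 0.0:
        return FounderEstimate(
            value=math.inf,
            corrected=False,
            negative_flag=True,
            n_tags_used=k_used,
            n_tags_excluded=k_excl,
        )
    return FounderEstimate(
        value=1.0 / denom,
        corrected=False,
        n_tags_used=k_used,
        n_tags_excluded=k_excl,
    )


def corrected_founder_population_size(
    profile_t: TagFrequencyProfile,
    reference: ReferenceProfile,
    ledger: BottleneckLedger,
) -> FounderEstimate:
    """Founder size with technical-bottleneck drift subtracted.

    Subtracts the mean inverse sample size of every bottleneck on both the
    reference and timepoint side from the inverse founder size:

    <N_B(t)> = 1 / [ drift - sum_j <S_j^-1> - sum_j <I_j^-1> ]

    A non-positive corrected denominator is returned flagged (value <= 0 or
    inf) rather than raised: it diagnoses bottlenecks stringent enough to
    drown the biological signal.
    """
    denom, k_used, k_excl = _drift_denominator(profile_t, reference)
    corrected = denom - ledger.total_inverse
    if corrected > 0:
        return FounderEstimate(
            value=1.0 / corrected,
            corrected=True,
            n_tags_used=k_used,
            n_tags_excluded=k_excl,
        )
    value = math.inf if corrected == 0 else 1.0 / corrected
    return FounderEstimate(
        value=value,
        corrected=True,
        negative_flag=True,
        n_tags_used=k_used,
        n_tags_excluded=k_excl,
    )


def mean_founder_theoretical(params: BirthDeathParams) -> float:
    """Expected founder population size of a neutral birth–death process.

    <N_B(t)> = r N(0) / [(beta+delta)(1 - e^{-r t})], with the series limit
    N(0)/((beta+delta) t) as r -> 0. Independent of the tag distribution.
    """
    if params.t <= 0:
        raise ValueError("t must be positive (N_B(0) is undefined)")
    bpd = params.beta + params.delta
    if bpd <= 0:
        raise ValueError("beta + delta must be positive")
    r = params.r
    if abs(r) * params.t < _R_T_EPS:
        return params.n0 / (bpd * params.t)
    return r * params.n0 / (bpd * (1.0 - math.exp(-r * params.t)))


def estimate_rates(
    r: float,
    n0: float,
    nt: float,
    nb: float | FounderEstimate,
    t: float | None = None,
) -> RateEstimate:
    """Invert the founder-size relation for the division and death rates.

    delta = (r/2) [ N(0) / (N_B (1 - N(0)/N(t))) - 1 ],   beta = r + delta.

    All of N(0), N(t), N_B must refer to the same reference volume. When
    N(0) = N(t) (r = 0) the limit form delta = N(0)/(2 N_B t) - r/2 is used,
    which requires ``t``.
    """
    if isinstance(nb, FounderEstimate):
        if nb.negative_flag:
            raise ValueError(
                "founder size is flagged (non-positive after correction); "
                "rates cannot be estimated — redesign the bottlenecks"
            )
        nb = nb.value
    if nb <= 0:
        raise ValueError("founder size must be positive")
    if n0 <= 0 or nt <= 0:
        raise ValueError("census sizes must be positive")
    if n0 == nt or (t is not None and abs(r) * t < _R_T_EPS):
        if t is None or t <= 0:
            raise ValueError("the r≈0 limit requires a positive elapsed time t")
        delta = n0 / (2.0 * nb * t) - r / 2.0
    else:
        delta = (r / 2.0) * (n0 / (nb * (1.0 - n0 / nt)) - 1.0)
    return RateEstimate(
        beta_hat=r + delta, delta_hat=delta, r_hat=r, t=t, n0=n0, nt=nt, nb=nb
    )


def net_growth_rate(series: CfuSeries, conf_level: float = 0.95):
    """Net growth rate r as the OLS slope of ln(CFU/ml) on time.

    Returns a dict with slope, intercept, and confidence intervals for both
    (two-sided, Student-t on n-2 df).
    """
    t = np.asarray(series.times, dtype=float)
    y = np.log(np.asarray(series.cfu_per_ml, dtype=float))
    if t.size < 2:
        raise ValueError("need at least two timepoints")
    if np.ptp(t) == 0:
        raise ValueError("times are all identical")
    res = stats.linregress(t, y)
    df = t.size - 2
    if df > 0:
        tcrit = stats.t.ppf(0.5 + conf_level / 2.0, df)
        slope_ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
        intercept_ci = (
            res.intercept - tcrit * res.intercept_stderr,
            res.intercept + tcrit * res.intercept_stderr,
        )
    else:  # two points: the fit is exact, no CI
        slope_ci = (res.slope, res.slope)
        intercept_ci = (res.intercept, res.intercept)
    return {
        "r": float(res.slope),
        "r_ci": slope_ci,
        "intercept": float(res.intercept),
        "intercept_ci": intercept_ci,
        "rvalue": float(res.rvalue),
        "n": int(t.size),
    }


def bd_frequency_variance(params: BirthDeathParams, f0: float) -> float:
    """Variance of a tag's frequency after time t of a birth–death process.

    Var(f_i(t)) = (beta+delta)(1 - e^{-r t}) / (r N(0)) * f0 (1 - f0),
    with the limit (beta+delta) t / N(0) * f0 (1-f0) as r -> 0.
    """
    if not (0 < f0 < 1):
        raise ValueError("f0 must lie in (0, 1)")
    if params.t == 0:
        return 0.0
    bpd = params.beta + params.delta
    r = params.r
    if abs(r) * params.t < _R_T_EPS:
        factor = bpd * params.t / params.n0
    else:
        factor = bpd * (1.0 - math.exp(-r * params.t)) / (r * params.n0)
    return factor * f0 * (1.0 - f0)


def bottleneck_sensitivity(q: SensitivityQuery) -> float:
    """Ratio of sampling-induced to birth–death-induced frequency variance.

    s_B(t) = r N(0) / [(beta+delta)(1 - e^{-r t}) N_B], with the r -> 0 limit
    N(0) / ((beta+delta) t N_B). N(0) must be the CFU count per ml. Estimates
    with s_B above ``q.threshold`` are fragile against errors in the
    bottleneck correction terms.
    """
    p = q.params
    if p.t <= 0:
        raise ValueError("t must be positive")
    bpd = p.beta + p.delta
    if bpd <= 0:
        raise ValueError("beta + delta must be positive")
    r = p.r
    if abs(r) * p.t < _R_T_EPS:
        return p.n0 / (bpd * p.t * q.nb)
    return r * p.n0 / (bpd * (1.0 - math.exp(-r * p.t)) * q.nb)


def sensitivity_grid(
    beta_range: tuple[float, float],
    delta_range: tuple[float, float],
    step: float,
    t: float,
    n0: float,
    nb: float,
    threshold: float = SENSITIVITY_THRESHOLD,
) -> pd.DataFrame:
    """Bottleneck sensitivity over a (beta, delta) grid.

    One row per grid cell with columns beta, delta, s_b, exceeds (s_b above
    the threshold). Used to pre-screen experimental designs: cells where both
    rates approach 0 show sharply rising sensitivity.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    betas = np.arange(beta_range[0], beta_range[1] + step / 2, step)
    deltas = np.arange(delta_range[0], delta_range[1] + step / 2, step)
    rows = []
    for b in betas:
        for d in deltas:
            if b == 0 and d == 0:
                s = math.inf  # no events: sampling variance dominates totally
            else:
                s = bottleneck_sensitivity(
                    SensitivityQuery(
                        BirthDeathParams(beta=b, delta=d, t=t, n0=n0),
                        nb=nb,
                        threshold=threshold,
                    )
                )
            rows.append((b, d, s, s > threshold))
    return pd.DataFrame(rows, columns=["beta", "delta", "s_b", "exceeds"])


def death_emulation_volume(v0: float, delta: float, t: float) -> float:
    """Volume to sample so the cell count mimics a death process at time t.

    dv_t = dv_0 e^{-delta t}: sampling this volume from a well-mixed culture
    draws as many cells as would remain after dying at rate delta for t.
    """
    if v0 <= 0:
        raise ValueError("v0 must be positive")
    if delta < 0 or t < 0:
        raise ValueError("delta and t must be non-negative")
    return v0 * math.exp(-delta * t)


def death_emulation_schedule(v0: float, delta: float, times) -> list[float]:
    """Volume schedule for a list of emulated timepoints."""
    return [death_emulation_volume(v0, delta, t) for t in times]


def death_emulation_scale(
    nb: FounderEstimate, delta: float, t: float
) -> FounderEstimate:
    """Scale a sampling-derived founder size to match a true death process.

    A multinomial volume-sampling experiment reproduces the mean, but not the
    variance, of per-tag survivor counts under death at rate delta; matching
    variances multiplies N_B by 1/(1-p) with p = e^{-delta t}.
    """
    if delta * t <= 0:
        raise ValueError("delta * t must be positive (scale factor diverges)")
    factor = 1.0 / (1.0 - math.exp(-delta * t))
    return replace(
        nb,
        value=nb.value * factor,
        emulation_scale=nb.emulation_scale * factor,
    )


def volume_rescale(
    nb: FounderEstimate, measured_volume: float, reference_volume: float
) -> FounderEstimate:
    """Rescale a founder size to the CFU reference volume.

    Founder sizes are per-volume quantities: an N_B measured in 200 µl must be
    multiplied by 5 before entering rate equations parameterized per ml.
    """
    if measured_volume <= 0 or reference_volume <= 0:
        raise ValueError("volumes must be positive")
    factor = reference_volume / measured_volume
    return replace(
        nb, value=nb.value * factor, volume_scale=nb.volume_scale * factor
    )


def plasmid_segregation_rates(obs: PlasmidObservation) -> RateEstimate:
    """Division and death rates from conditionally non-replicative plasmid loss.

    The plasmid-positive fraction dilutes with every division,
    <F(t)> = F(0) e^{-beta t}, so

        beta  = (1/t) ln(F(0)/F(t))
        delta = (1/t) ln(F(0) N(0) / (F(t) N(t)))
    """
    if obs.ft <= 0:
        raise ValueError("plasmid marker fully diluted (F(t) = 0)")
    beta = math.log(obs.f0 / obs.ft) / obs.t
    delta = math.log((obs.f0 * obs.n0) / (obs.ft * obs.nt)) / obs.t
    return RateEstimate(
        beta_hat=beta,
        delta_hat=delta,
        r_hat=beta - delta,
        t=obs.t,
        n0=obs.n0,
        nt=obs.nt,
    )


def expected_surviving_tags(
    initial_counts, beta: float, delta: float, t: float
) -> tuple[float, float]:
    """Expected fraction and number of tags with at least one surviving cell.

    For a linear birth–death process a lineage founded by one cell goes
    extinct by time t with probability

        p1 = delta (e^{r t} - 1) / (beta e^{r t} - delta)     (beta != delta)
        p1 = delta t / (1 + delta t)                          (beta == delta)

    and a tag with n0 independent founder cells with probability p1^n0.
    Returns (mean over tags of 1 - p1^n0, k times that mean).
    """
    if beta < 0 or delta < 0 or t < 0:
        raise ValueError("beta, delta, t must be non-negative")
    n0 = np.asarray(initial_counts, dtype=float)
    if np.any(n0 < 0):
        raise ValueError("initial counts must be non-negative")
    if delta == 0 or t == 0:
        p1 = 0.0
    elif beta == delta:
        p1 = delta * t / (1.0 + delta * t)
    else:
        r = beta - delta
        ert = math.exp(r * t)
        p1 = delta * (ert - 1.0) / (beta * ert - delta)
        p1 = min(max(p1, 0.0), 1.0)
    surv = 1.0 - p1 ** n0
    frac = float(surv.mean())
    return frac, frac * n0.size


def rate_from_doubling_time(t_double: float) -> float:
    """Rate (min^-1) from the time for the population to double (or halve)."""
    if t_double <= 0:
        raise ValueError("doubling time must be positive")
    return math.log(2.0) / t_double


def doubling_time_from_rate(rate: float) -> float:
    """Doubling (or halving) time in minutes from a rate in min^-1."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    return math.log(2.0) / rate
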