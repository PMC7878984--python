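"""Domain containers for barcode-based rate estimation.

All rates are per minute, times in minutes, census sizes per ml unless a
volume scale is recorded alongside. Frequencies are dimensionless proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TagFrequencyProfile",
    "ReferenceProfile",
    "BottleneckLedger",
    "BirthDeathParams",
    "FounderEstimate",
    "RateEstimate",
    "CfuSeries",
    "SensitivityQuery",
    "PlasmidObservation",
]

_FREQ_SUM_TOL = 1e-9


@dataclass(frozen=True)
class TagFrequencyProfile:
    """Per-tag frequencies of a single sample.

    Parameters
    ----------
    tag_ids : sequence of str
        Ordered tag identifiers (length k >= 2).
    freqs : array-like of float
        Proportion of each tag; must sum to 1.
    total_count : int
        Number of cells or reads the profile was computed from.
    """

    tag_ids: tuple
    freqs: np.ndarray
    total_count: int

    def __post_init__(self):
        object.__setattr__(self, "tag_ids", tuple(self.tag_ids))
        freqs = np.asarray(self.freqs, dtype=float)
        object.__setattr__(self, "freqs", freqs)
        if len(self.tag_ids) != freqs.size:
            raise ValueError("tag_ids and freqs must have equal length")
        if freqs.size < 2:
            raise ValueError("a profile needs at least 2 tags")
        if np.any(freqs < 0) or np.any(freqs > 1):
            raise ValueError("frequencies must lie in [0, 1]")
        if abs(freqs.sum() - 1.0) > _FREQ_SUM_TOL:
            raise ValueError(f"frequencies must sum to 1 (got {freqs.sum()!r})")

    @classmethod
    def from_counts(cls, tag_ids, counts) -> "TagFrequencyProfile":
        counts = np.asarray(counts, dtype=float)
        total = counts.sum()
        if total <= 0:
            raise ValueError("counts must sum to a positive total")
        return cls(tuple(tag_ids), counts / total, int(round(total)))


@dataclass(frozen=True)
class ReferenceProfile:
    """Mean initial tag proportions <f_i(0)> over replicate t=0 samples."""

    tag_ids: tuple
    mean_freqs: np.ndarray
    n_replicates: int = 1

    def __post_init__(self):
        object.__setattr__(self, "tag_ids", tuple(self.tag_ids))
        freqs = np.asarray(self.mean_freqs, dtype=float)
        object.__setattr__(self, "mean_freqs", freqs)
        if len(self.tag_ids) != freqs.size:
            raise ValueError("tag_ids and mean_freqs must have equal length")
        if abs(freqs.sum() - 1.0) > _FREQ_SUM_TOL:
            raise ValueError("mean frequencies must sum to 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @classmethod
    def from_profiles(cls, profiles) -> "ReferenceProfile":
        """Average replicate t=0 profiles (tag sets must agree)."""
        profiles = list(profiles)
        ids = profiles[0].tag_ids
        for p in profiles[1:]:
            if p.tag_ids != ids:
                raise ValueError("replicate profiles must share tag_ids")
        mean = np.mean([p.freqs for p in profiles], axis=0)
        return cls(ids, mean, len(profiles))

    @property
    def zero_mask(self) -> np.ndarray:
        """Tags absent (or fixed) in the reference; excluded from drift sums."""
        return (self.mean_freqs <= 0) | (self.mean_freqs >= 1)


@dataclass(frozen=True)
class BottleneckLedger:
    """Ordered mean inverse sample sizes of the technical bottlenecks.

    ``inoculum_inverse_means`` holds <I_j^-1> for the t=0 (reference) side and
    ``sample_inverse_means`` holds <S_j^-1> for the timepoint side. Empty lists
    mean no correction.
    """

    inoculum_inverse_means: tuple = ()
    sample_inverse_means: tuple = ()

    def __post_init__(self):
        inoc = tuple(float(x) for x in self.inoculum_inverse_means)
        samp = tuple(float(x) for x in self.sample_inverse_means)
        if any(x <= 0 for x in inoc + samp):
            raise ValueError("inverse sample sizes must be positive")
        object.__setattr__(self, "inoculum_inverse_means", inoc)
        object.__setattr__(self, "sample_inverse_means", samp)

    @classmethod
    def from_sizes(cls, inoculum_sizes=(), sample_sizes=()) -> "BottleneckLedger":
        """Build from bottleneck sizes I_j / S_j.

        Each entry may be a scalar or a sequence of replicate sizes; replicate
        sizes are averaged as the mean of inverses (<S_j^-1>), not the inverse
        of the mean.
        """

        def inv_mean(entry):
            arr = np.atleast_1d(np.asarray(entry, dtype=float))
            if np.any(arr <= 0):
                raise ValueError("bottleneck sizes must be positive")
            return float(np.mean(1.0 / arr))

        return cls(
            tuple(inv_mean(e) for e in inoculum_sizes),
            tuple(inv_mean(e) for e in sample_sizes),
        )

    @property
    def total_inverse(self) -> float:
        return sum(self.inoculum_inverse_means) + sum(self.sample_inverse_means)


@dataclass(frozen=True)
class BirthDeathParams:
    """Birth–death process parameters: division rate beta, death rate delta
    (both min^-1), elapsed time t (min) and initial census n0 (cells/ml)."""

    beta: float
    delta: float
    t: float
    n0: float

    def __post_init__(self):
        if self.beta < 0 or self.delta < 0:
            raise ValueError("rates must be non-negative")
        if self.t < 0:
            raise ValueError("t must be non-negative")
        if self.n0 <= 0:
            raise ValueError("n0 must be positive")

    @property
    def r(self) -> float:
        """Net growth rate beta - delta."""
        return self.beta - self.delta


@dataclass(frozen=True)
class FounderEstimate:
    """A founder population size N_B with its correction/scaling provenance."""

    value: float
    corrected: bool = False
    volume_scale: float = 1.0
    emulation_scale: float = 1.0
    negative_flag: bool = False
    n_tags_used: int = 0
    n_tags_excluded: int = 0

    def __post_init__(self):
        if self.volume_scale <= 0:
            raise ValueError("volume_scale must be positive")
        if not self.negative_flag and not self.value > 0:
            raise ValueError("unflagged founder sizes must be positive")


@dataclass(frozen=True)
class RateEstimate:
    """Estimated (beta, delta, r) triple with the inputs it came from."""

    beta_hat: float
    delta_hat: float
    r_hat: float
    t: float | None = None
    n0: float | None = None
    nt: float | None = None
    nb: float | None = None

    def __post_init__(self):
        if abs((self.beta_hat - self.delta_hat) - self.r_hat) > 1e-12 * max(
            1.0, abs(self.r_hat)
        ):
            raise ValueError("beta_hat - delta_hat must equal r_hat")


@dataclass(frozen=True)
class CfuSeries:
    """CFU/ml measurements over time; replicate column optional."""

    times: np.ndarray
    cfu_per_ml: np.ndarray
    replicate: np.ndarray | None = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.cfu_per_ml, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "cfu_per_ml", c)
        if t.size != c.size:
            raise ValueError("times and cfu_per_ml must have equal length")
        if np.any(c <= 0):
            raise ValueError("CFU counts must be positive")
        if self.replicate is None:
            if np.any(np.diff(t) <= 0):
                raise ValueError("times must be strictly increasing")
        else:
            object.__setattr__(
                self, "replicate", np.asarray(self.replicate)
            )


@dataclass(frozen=True)
class SensitivityQuery:
    """Inputs for a bottleneck-sensitivity evaluation.

    ``nb`` is the technical bottleneck size (cells sampled or reads obtained);
    ``threshold`` is the empirically calibrated robustness cut-off.
    """

    params: BirthDeathParams
    nb: float
    threshold: float = 0.17

    def __post_init__(self):
        if self.nb <= 0:
            raise ValueError("nb must be positive")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")


@dataclass(frozen=True)
class PlasmidObservation:
    """Plasmid-positive fractions and census sizes at t=0 and t."""

    f0: float
    ft: float
    n0: float
    nt: float
    t: float

    def __post_init__(self):
        for name, f in (("f0", self.f0), ("ft", self.ft)):
            if not (0 < f <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.n0 <= 0 or self.nt <= 0:
            raise ValueError("census sizes must be positive")
        if self.t <= 0:
            raise ValueError("t must be positive")
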