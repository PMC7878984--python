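"""Independent brute-force oracles for the test suite.

These deliberately avoid the package's tau-leap/closed-form code paths: the
birth–death oracle is an exact event-driven (Gillespie) simulation and the
sampling oracles are direct numpy draws.
"""

from __future__ import annotations

import numpy as np


def gillespie_lineage(n0: int, beta: float, delta: float, t_end: float, rng) -> int:
    """Exact simulation of one linear birth–death lineage; returns n(t_end)."""
    n = int(n0)
    t = 0.0
    rate_per_cell = beta + delta
    if rate_per_cell == 0:
        return n
    p_birth = beta / rate_per_cell
    while n > 0:
        total = rate_per_cell * n
        t += rng.exponential(1.0 / total)
        if t > t_end:
            break
        if rng.random() < p_birth:
            n += 1
        else:
            n -= 1
    return n


def gillespie_population(counts, beta, delta, t_end, rng) -> np.ndarray:
    """Exact simulation of independent tagged lineages."""
    return np.array(
        [gillespie_lineage(n, beta, delta, t_end, rng) for n in counts],
        dtype=np.int64,
    )


def inverse_founder_of_multinomial(freqs, sample_size, n_reps, rng) -> np.ndarray:
    """1/N_B values of pure multinomial draws against the true frequencies.

    Direct evaluation of the drift statistic, independent of the package.
    """
    freqs = np.asarray(freqs, dtype=float)
    out = np.empty(n_reps)
    denom = freqs * (1 - freqs)
    for i in range(n_reps):
        f_hat = rng.multinomial(sample_size, freqs) / sample_size
        out[i] = np.mean((f_hat - freqs) ** 2 / denom)
    return out
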