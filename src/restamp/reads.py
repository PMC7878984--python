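"""Barcode read processing: strain-barcode filtering, error-rate estimation,
and abundance-ranked removal of spurious sequences.

Reads carry a random barcode region (default 30 bp) followed by a fixed
strain barcode (default 21 bp). Filtering keeps reads whose strain region
matches exactly; the pass rate p^{N_S} yields the per-base correct-call
probability p. A binomial mismatch model then predicts how many distinct
error sequences each mismatch class m should contribute, and sequences in
excess of that budget — or farther than any plausible error from a true
barcode — are discarded as spurious.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from Bio import SeqIO

__all__ = [
    "ReadLayout",
    "ErrorModel",
    "MismatchBudget",
    "TagCountTable",
    "iter_fastq",
    "filter_strain_barcode",
    "estimate_error_rate",
    "mismatch_expectations",
    "despurify",
    "count_tags",
]

_BASE_TO_INT = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class ReadLayout:
    """Geometry of a barcode read: random region then strain barcode."""

    strain_sequence: str
    random_len: int = 30
    random_offset: int = 0

    def __post_init__(self):
        if self.random_len <= 0:
            raise ValueError("random_len must be positive")
        if not self.strain_sequence:
            raise ValueError("strain_sequence must be non-empty")
        object.__setattr__(self, "strain_sequence", self.strain_sequence.upper())

    @property
    def strain_len(self) -> int:
        return len(self.strain_sequence)

    @property
    def read_len(self) -> int:
        return self.random_offset + self.random_len + self.strain_len

    def random_region(self, read: str) -> str:
        return read[self.random_offset : self.random_offset + self.random_len]

    def strain_region(self, read: str) -> str:
        start = self.random_offset + self.random_len
        return read[start : start + self.strain_len]


@dataclass(frozen=True)
class ErrorModel:
    """Per-base sequencing error model from the strain-barcode pass rate."""

    p: float
    n_total: int
    n_filtered: int

    def __post_init__(self):
        if not (0 < self.p <= 1):
            raise ValueError("p must lie in (0, 1]")
        if self.n_filtered > self.n_total:
            raise ValueError("n_filtered cannot exceed n_total")

    @property
    def q(self) -> float:
        return 1.0 - self.p


@dataclass(frozen=True)
class MismatchBudget:
    """Expected distinct-sequence counts per mismatch class.

    expected[m] is the expected number of filtered reads carrying exactly m
    substitutions in the random barcode region; m_max is the largest class
    expected to contribute at least one read.
    """

    expected: np.ndarray
    m_max: int

    def __post_init__(self):
        object.__setattr__(self, "expected", np.asarray(self.expected, dtype=float))


@dataclass
class TagCountTable:
    """Final per-barcode read counts with pipeline provenance counters."""

    counts: pd.Series  # index: barcode sequence, values: int counts
    n_total: int = 0
    n_filtered: int = 0
    n_spurious_discarded: int = 0
    n_error_merged: int = 0

    def to_frame(self) -> pd.DataFrame:
        df = self.counts.rename("count").rename_axis("tag_sequence").reset_index()
        return df

    def frequencies(self) -> pd.Series:
        return self.counts / self.counts.sum()


def iter_fastq(path):
    """Yield (read_id, sequence) from a FASTQ file, gzipped or plain."""
    path = Path(path)
    if path.suffix == ".gz":
        handle = gzip.open(path, "rt")
    else:
        handle = open(path)
    try:
        for rec in SeqIO.parse(handle, "fastq"):
            yield rec.id, str(rec.seq).upper()
    finally:
        handle.close()


def filter_strain_barcode(reads, layout: ReadLayout):
    """Keep reads whose strain region matches the layout exactly.

    ``reads`` is an iterable of sequences or of (id, sequence) pairs (as from
    :func:`iter_fastq`). Returns (list of random-region sequences of passing
    reads, ErrorModel). Reads shorter than the layout raise, with the
    offending record index.
    """
    kept = []
    n_total = 0
    for i, item in enumerate(reads):
        seq = item[1] if isinstance(item, tuple) else item
        if len(seq) < layout.read_len:
            raise ValueError(
                f"record {i}: read of length {len(seq)} shorter than the "
                f"layout ({layout.read_len} bp)"
            )
        n_total += 1
        if layout.strain_region(seq) == layout.strain_sequence:
            kept.append(layout.random_region(seq))
    n_f = len(kept)
    if n_f == 0:
        model = ErrorModel(p=1.0, n_total=n_total, n_filtered=0)
    else:
        model = ErrorModel(
            p=estimate_error_rate(n_total, n_f, layout),
            n_total=n_total,
            n_filtered=n_f,
        )
    return kept, model


def estimate_error_rate(n: int, n_f: int, layout: ReadLayout) -> float:
    """Per-base correct-call probability p = (n_F / N)^{1/N_S}.

    Follows from the pass rate of exact strain-barcode filtering being
    p^{N_S} under position-independent substitution errors.
    """
    if n_f <= 0:
        raise ValueError("no reads passed the filter; p is undefined")
    if n_f > n:
        raise ValueError("n_f cannot exceed n")
    return float((n_f / n) ** (1.0 / layout.strain_len))


def mismatch_expectations(model: ErrorModel, layout: ReadLayout) -> MismatchBudget:
    """Expected filtered-read counts per mismatch class in the random region.

    P(m) = C(N_R, m) q^m (1-q)^{N_R - m}; expected[m] = n_F * P(m); m_max is
    the largest m with expected[m] >= 1 (0 when even the zero-mismatch class
    is empty).
    """
    m = np.arange(layout.random_len + 1)
    pmf = stats.binom.pmf(m, layout.random_len, model.q)
    expected = model.n_filtered * pmf
    above = np.nonzero(expected >= 1.0)[0]
    m_max = int(above.max()) if above.size else 0
    return MismatchBudget(expected=expected, m_max=m_max)


def _encode(seqs, length: int) -> np.ndarray:
    """Encode equal-length sequences as a (n, length) uint8 matrix."""
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
    return arr.reshape(len(seqs), length)


def _nearest_distances(queries, anchors, length: int, chunk: int = 2048):
    """Hamming distance from each query to its nearest anchor.

    Returns (distances, nearest anchor index); ties resolve to the first
    (most abundant, given anchors sorted by abundance) anchor.
    """
    qa = _encode(queries, length)
    aa = _encode(anchors, length)
    dists = np.empty(len(queries), dtype=np.int64)
    nearest = np.empty(len(queries), dtype=np.int64)
    for start in range(0, len(queries), chunk):
        block = qa[start : start + chunk]
        d = (block[:, None, :] != aa[None, :, :]).sum(axis=2)
        nearest[start : start + chunk] = d.argmin(axis=1)
        dists[start : start + chunk] = d.min(axis=1)
    return dists, nearest


def _abundance_order(counts: pd.Series) -> pd.Series:
    """Sort by count descending, ties broken lexicographically by sequence."""
    df = counts.rename("count").rename_axis("seq").reset_index()
    df = df.sort_values(["count", "seq"], ascending=[False, True])
    return pd.Series(df["count"].values, index=df["seq"].values)


def despurify(
    counts: pd.Series,
    k: int,
    budget: MismatchBudget,
    merge: bool = True,
):
    """Split exact-clustered sequences into true barcodes, error reads, spurious.

    The k most abundant distinct sequences are the true barcodes. Every other
    sequence is assigned the Hamming distance m to its nearest true barcode;
    sequences with m > m_max are spurious, and within each class m <= m_max
    only the round(expected[m]) most abundant are retained as plausible error
    reads (the rest are spurious). Retained error reads are merged into their
    nearest barcode's count unless ``merge`` is False.

    Returns (TagCountTable, diagnostics DataFrame of extraneous sequences).
    """
    counts = _abundance_order(counts.astype(np.int64))
    if len(counts) < k:
        warnings.warn(
            f"only {len(counts)} distinct sequences for k={k} expected "
            "barcodes; treating all as true",
            stacklevel=2,
        )
    if len(counts) <= k:
        table = TagCountTable(
            counts=counts.copy(),
            n_filtered=int(counts.sum()),
        )
        diag = pd.DataFrame(
            columns=["seq", "count", "mismatches", "nearest", "kept"]
        )
        return table, diag

    true_seqs = list(counts.index[:k])
    extra = counts.iloc[k:]
    length = len(true_seqs[0])
    dists, nearest_idx = _nearest_distances(list(extra.index), true_seqs, length)

    kept_mask = np.zeros(len(extra), dtype=bool)
    for m in range(budget.m_max + 1):
        in_class = np.nonzero(dists == m)[0]  # already in abundance order
        cap = int(round(budget.expected[m])) if m < budget.expected.size else 0
        kept_mask[in_class[:cap]] = True

    final = counts.iloc[:k].copy()
    n_merged = 0
    if merge:
        for pos in np.nonzero(kept_mask)[0]:
            parent = true_seqs[nearest_idx[pos]]
            final[parent] += int(extra.iloc[pos])
            n_merged += int(extra.iloc[pos])
    else:
        kept = extra[kept_mask]
        final = pd.concat([final, kept])

    discarded = int(extra[~kept_mask].sum())
    diag = pd.DataFrame(
        {
            "seq": extra.index,
            "count": extra.values,
            "mismatches": dists,
            "nearest": [true_seqs[i] for i in nearest_idx],
            "kept": kept_mask,
        }
    )
    table = TagCountTable(
        counts=_abundance_order(final),
        n_filtered=int(counts.sum()),
        n_spurious_discarded=discarded,
        n_error_merged=n_merged,
    )
    return table, diag


def count_tags(filtered_reads, layout: ReadLayout, k: int, model: ErrorModel = None):
    """Exact-identity clustering of random regions followed by despurification.

    ``filtered_reads`` are the random-region sequences of reads that passed
    the strain filter (as returned by :func:`filter_strain_barcode`). When no
    error model is given a perfect-call model (q=0) is assumed.

    Returns a TagCountTable whose counts conserve reads:
    sum(final counts) + discarded == n_F.
    """
    clustered = pd.Series(filtered_reads).value_counts()
    if model is None:
        model = ErrorModel(p=1.0, n_total=len(filtered_reads), n_filtered=len(filtered_reads))
    budget = mismatch_expectations(model, layout)
    table, _ = despurify(clustered.astype(np.int64), k, budget)
    table.n_total = model.n_total
    table.n_filtered = len(filtered_reads)
    return table
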