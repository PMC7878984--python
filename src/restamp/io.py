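"""Delimited-text and config glue for the estimation workflow.

Tag counts travel as two-column TSV/CSV (tag_id, count); CFU series as
(time_min, cfu_per_ml[, replicate]); experiment parameters and bottleneck
ledgers as YAML. Results are written as TSV plus a JSON summary.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import (
    BottleneckLedger,
    CfuSeries,
    ReferenceProfile,
    TagFrequencyProfile,
)

__all__ = [
    "read_tag_counts",
    "write_tag_counts",
    "read_cfu_series",
    "write_cfu_series",
    "load_config",
    "ledger_from_config",
    "profile_from_file",
    "reference_from_files",
    "write_results",
]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_tag_counts(path) -> pd.Series:
    """Read a (tag_id, count) table; returns counts indexed by tag id."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    id_col = next((c for c in cols if c in ("tag_id", "tag_sequence", "tag")), cols[0])
    count_col = next((c for c in cols if c == "count"), cols[1])
    counts = df.set_index(id_col)[count_col].astype(np.int64)
    if counts.index.has_duplicates:
        raise ValueError(f"{path}: duplicate tag ids")
    if (counts < 0).any():
        raise ValueError(f"{path}: negative counts")
    return counts


def write_tag_counts(counts: pd.Series, path):
    path = Path(path)
    df = counts.rename("count").rename_axis("tag_id").reset_index()
    df.to_csv(path, sep=_sep_for(path), index=False)
    return path


def read_cfu_series(path) -> CfuSeries:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    df.columns = [c.lower() for c in df.columns]
    rep = df["replicate"].values if "replicate" in df.columns else None
    return CfuSeries(
        times=df["time_min"].values,
        cfu_per_ml=df["cfu_per_ml"].values,
        replicate=rep,
    )


def write_cfu_series(series: CfuSeries, path):
    path = Path(path)
    data = {"time_min": series.times, "cfu_per_ml": series.cfu_per_ml}
    if series.replicate is not None:
        data["replicate"] = series.replicate
    pd.DataFrame(data).to_csv(path, sep=_sep_for(path), index=False)
    return path


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def ledger_from_config(cfg: dict) -> BottleneckLedger:
    """Ledger from a config mapping with inoculum_sizes / sample_sizes lists.

    Each entry may be a scalar size or a list of replicate sizes (averaged as
    mean inverse).
    """
    return BottleneckLedger.from_sizes(
        cfg.get("inoculum_sizes", ()), cfg.get("sample_sizes", ())
    )


def profile_from_file(path) -> TagFrequencyProfile:
    counts = read_tag_counts(path)
    return TagFrequencyProfile.from_counts(counts.index, counts.values)


def reference_from_files(paths) -> ReferenceProfile:
    """Mean reference profile from one or more replicate t=0 count tables."""
    profiles = [profile_from_file(p) for p in paths]
    return ReferenceProfile.from_profiles(profiles)


def write_results(rows, json_summary: dict, tsv_path, json_path):
    """Write per-timepoint result rows as TSV and a machine-readable summary."""
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    with open(json_path, "w") as fh:
        json.dump(json_summary, fh, indent=2, default=_jsonify)
    return tsv_path, json_path


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
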