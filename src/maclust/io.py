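"""Readers, writers, run configuration and provenance.

Scan files are GenePix-style tab-separated tables with the columns Block,
Row, Column, ID, F635, B635, F532, B532, Flags (F635/B635 = red/sample
channel, F532/B532 = green/reference channel); any nonzero flag marks the
spot as flagged.  A ``column_map`` supports other dialects.  Labels files
are two-column TSV (sample_id, class).  Result tables round-trip as TSV in
long format, with an optional wide (one aRand column per dataset) variant.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from .structures import ArrayScan

__all__ = [
    "GPR_COLUMNS",
    "read_gpr",
    "read_labels",
    "write_results",
    "read_results",
    "write_results_wide",
    "RunConfig",
    "load_config",
    "provenance_record",
]

GPR_COLUMNS = ("Block", "Row", "Column", "ID", "F635", "B635", "F532",
               "B532", "Flags")
_NUMERIC = ("Block", "Row", "Column", "F635", "B635", "F532", "B532", "Flags")

RESULT_COLUMNS = ("dataset", "normalization", "imputation", "standardization",
                  "selection", "clustering", "arand", "error")


def read_gpr(
    path,
    sample_id: Optional[str] = None,
    column_map: Optional[Dict[str, str]] = None,
) -> ArrayScan:
    """Parse one scan file into an :class:`ArrayScan`.

    Tolerant of extra columns, strict on missing required ones (error names
    the column); non-numeric intensities raise with the offending line
    number.  ``column_map`` maps required names to the file's own header
    names for non-GenePix dialects.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    column_map = column_map or {}
    rename = {v: k for k, v in column_map.items()}
    df = df.rename(columns=rename)
    for col in GPR_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path.name}: missing required column {col!r}")
    num = {}
    for col in _NUMERIC:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            line = int(np.argmax(bad.to_numpy())) + 2  # 1-based + header
            raise ValueError(
                f"{path.name}: non-numeric value {df[col][bad].iloc[0]!r} "
                f"in column {col!r} at line {line}")
        if vals.isna().any():
            line = int(np.argmax(vals.isna().to_numpy())) + 2
            raise ValueError(f"{path.name}: empty value in column {col!r} "
                             f"at line {line}")
        # re-parse with correctly-rounded float() so writes round-trip exactly
        num[col] = np.array([float(v) for v in df[col]])
    return ArrayScan(
        sample_id=sample_id or path.stem,
        gene_ids=df["ID"].to_numpy(dtype=object),
        block=num["Block"].astype(int),
        row=num["Row"].astype(int),
        column=num["Column"].astype(int),
        fg_red=num["F635"].astype(float),
        bg_red=num["B635"].astype(float),
        fg_green=num["F532"].astype(float),
        bg_green=num["B532"].astype(float),
        flagged=num["Flags"] != 0,
    )


def read_labels(path) -> Dict[str, str]:
    """Read a two-column TSV mapping sample_id -> class label."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path.name}: labels file needs two columns")
    sid, cls = df.columns[:2]
    dup = df[sid][df[sid].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path.name}: duplicate sample_id {dup.iloc[0]!r}")
    mapping = {}
    for _, row_ in df.iterrows():
        if pd.isna(row_[cls]) or str(row_[cls]).strip() == "":
            continue  # unlabeled samples are simply absent from the mapping
        mapping[str(row_[sid])] = str(row_[cls])
    return mapping


def write_results(rt: pd.DataFrame, path) -> Path:
    """Write a long-format result table as TSV at full float precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = rt.copy()
    for col in RESULT_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan if col == "arand" else ""
    out = out[list(RESULT_COLUMNS)]
    out.to_csv(path, sep="\t", index=False)
    return path


def read_results(path) -> pd.DataFrame:
    """Read back a result table written by :func:`write_results`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t",
                     dtype={"standardization": "boolean"})
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: malformed result table, missing "
                         f"column(s) {missing}")
    df["standardization"] = df["standardization"].astype(bool)
    df["error"] = df["error"].fillna("").astype(str)
    bad = df["arand"].isna() & (df["error"] == "")
    if bad.any():
        line = int(np.argmax(bad.to_numpy())) + 2
        raise ValueError(f"{path.name}: malformed row at line {line}: "
                         "no aRand and no recorded error")
    return df


def write_results_wide(rt: pd.DataFrame, path) -> Path:
    """Write the wide shape: one row per parameter combination, one aRand
    column per dataset."""
    path = Path(path)
    wide = rt.pivot_table(
        index=["normalization", "imputation", "standardization",
               "selection", "clustering"],
        columns="dataset", values="arand", aggfunc="first")
    wide.reset_index().to_csv(path, sep="\t", index=False)
    return path


@dataclass
class RunConfig:
    """Declarative description of a benchmark run."""

    datasets: dict = field(default_factory=dict)  # name -> path or SimConfig kwargs
    include_supervised: bool = False
    reduced: bool = False
    extra_std_sizes: tuple = ()
    n_clusters: int = 10
    null_reps: int = 1000
    seed: int = 0
    output_dir: str = "results"


def load_config(path) -> RunConfig:
    """Load a RunConfig from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "extra_std_sizes" in raw:
        raw["extra_std_sizes"] = tuple(raw["extra_std_sizes"])
    return RunConfig(**raw)


def provenance_record(config, seed: int) -> dict:
    """Config hash + seed + versions: enough to reproduce a run bit-identically."""
    import sklearn
    import scipy

    from . import __version__

    blob = json.dumps(config, default=str, sort_keys=True)
    return {
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": int(seed),
        "versions": {
            "maclust": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "sklearn": sklearn.__version__,
        },
    }
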