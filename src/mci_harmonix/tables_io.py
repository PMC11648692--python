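"""Reading, writing and assembly of the tabular formats the pipeline touches.

Stats tables follow the layout emitted by FreeSurfer's ``asegstats2table`` /
``aparcstats2table`` scripts: tab-separated, UTF-8, first row a header whose
first column is the subject identifier and whose remaining columns are
numeric volumes in mm^3. Demographics tables are CSV (or TSV) with one row
per subject. Results tables are plain CSV.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .schema import GROUP_LABELS, METADATA_COLS, SEX_LABELS

logger = logging.getLogger(__name__)

__all__ = [
    "read_stats_table",
    "merge_hemispheres",
    "assemble_feature_table",
    "read_demographics",
    "write_feature_table",
    "read_feature_table",
    "write_results",
    "read_results",
    "validate_feature_table",
]

#: fixed column schema of the long-format results table
RESULTS_COLUMNS = [
    "replication",
    "dataset",
    "harmonization",
    "subset",
    "classifier",
    "mode",
    "estimate_type",
    "metric",
    "value",
]


def read_stats_table(path, kind: str = "aseg") -> pd.DataFrame:
    """Parse a FreeSurfer-style stats TSV into a subject x measure table.

    The first column (whatever its header name) is treated as the subject
    identifier and becomes the index; all remaining columns must be numeric.
    """
    if kind not in ("aseg", "aparc"):
        raise ValueError(f"kind must be 'aseg' or 'aparc', got {kind!r}")
    raw = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if raw.columns[0].startswith("Unnamed") or raw.shape[1] < 2:
        raise ValueError(f"{path}: missing or malformed header")
    if raw.isna().any().any():
        raise ValueError(f"{path}: ragged rows or missing cells")
    subj = raw.iloc[:, 0]
    dup = subj[subj.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate subject id(s): {sorted(set(dup))}")
    table = raw.iloc[:, 1:].copy()
    for col in table.columns:
        try:
            table[col] = pd.to_numeric(table[col])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: non-numeric cell in column {col!r}") from exc
    table.index = pd.Index(subj, name="subject_id")
    return table


def merge_hemispheres(raw: pd.DataFrame) -> pd.DataFrame:
    """Sum paired left/right columns into total per-region volumes.

    Recognizes the ``Left-*``/``Right-*`` convention of aseg tables and the
    ``lh_*``/``rh_*`` convention of aparc tables. Unpaired bilateral or
    midline measures (e.g. ``BrainSegVolNotVent``) pass through unchanged.
    A left column without its right partner (or vice versa) is an error.
    """
    merged: dict[str, pd.Series] = {}
    consumed: set[str] = set()
    orphans: list[str] = []
    for col in raw.columns:
        if col in consumed:
            continue
        partner = base = None
        if col.startswith("Left-"):
            base = col[len("Left-"):]
            partner = f"Right-{base}"
        elif col.startswith("Right-"):
            base = col[len("Right-"):]
            partner = f"Left-{base}"
        elif col.startswith("lh_"):
            base = col[len("lh_"):]
            partner = f"rh_{base}"
        elif col.startswith("rh_"):
            base = col[len("rh_"):]
            partner = f"lh_{base}"
        if partner is None:
            merged[col] = raw[col]
            consumed.add(col)
        elif partner in raw.columns:
            # strip trailing aparc suffixes like "_volume"
            name = base.removesuffix("_volume")
            merged[name] = raw[col] + raw[partner]
            consumed.update({col, partner})
        else:
            orphans.append(col)
    if orphans:
        raise ValueError(f"hemisphere columns without a partner: {orphans}")
    return pd.DataFrame(merged, index=raw.index)


def read_demographics(path) -> pd.DataFrame:
    """Read a demographics table (CSV; TSV accepted) with one row per subject."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    demo = pd.read_csv(path, sep=sep)
    required = set(METADATA_COLS)
    missing = required - set(demo.columns)
    if missing:
        raise ValueError(f"demographics table missing columns: {sorted(missing)}")
    return demo


def assemble_feature_table(volumes: pd.DataFrame, demographics: pd.DataFrame) -> pd.DataFrame:
    """Inner-join merged volumes with demographics into an analysis-ready table.

    Subjects present in only one input are dropped and logged.
    """
    demo = demographics.set_index("subject_id") if "subject_id" in demographics.columns else demographics
    common = volumes.index.intersection(demo.index)
    if len(common) == 0:
        raise ValueError("empty join: no subject present in both inputs")
    dropped = sorted(set(volumes.index).symmetric_difference(demo.index))
    if dropped:
        logger.warning("assemble_feature_table: dropped %d unmatched subject(s): %s",
                       len(dropped), dropped[:10])
    table = pd.concat([demo.loc[common, [c for c in METADATA_COLS if c != "subject_id"]],
                       volumes.loc[common]], axis=1)
    table = table.reset_index().rename(columns={"index": "subject_id"})
    validate_feature_table(table)
    return table


def validate_feature_table(table: pd.DataFrame) -> None:
    """Enforce the feature-table invariants; raise ValueError on breach."""
    if table["subject_id"].duplicated().any():
        dups = table.loc[table["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject id(s): {dups}")
    bad_groups = set(table["group"]) - set(GROUP_LABELS)
    if bad_groups:
        raise ValueError(f"unknown group label(s): {sorted(bad_groups)}")
    bad_sex = set(table["sex"]) - set(SEX_LABELS)
    if bad_sex:
        raise ValueError(f"unknown sex label(s): {sorted(bad_sex)}")
    vol_cols = [c for c in table.columns if c not in METADATA_COLS]
    values = table[vol_cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite volume values")
    if np.any(values <= 0):
        raise ValueError("volumes must be strictly positive")
    if np.any(table["icv"].to_numpy(dtype=float) <= 0):
        raise ValueError("icv must be strictly positive")


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a feature table as TSV, preserving 12 significant digits."""
    table.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_feature_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    validate_feature_table(table)
    return table


def write_results(table: pd.DataFrame, path) -> None:
    """Write a long-format results table as CSV (fixed column schema)."""
    missing = [c for c in RESULTS_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"results table missing columns: {missing}")
    table[RESULTS_COLUMNS].to_csv(path, index=False, float_format="%.12g")


def read_results(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in RESULTS_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"results file schema mismatch; missing: {missing}")
    return table
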