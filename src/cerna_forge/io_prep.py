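"""Expression-matrix IO, cohort merging and batch-effect removal.

Expression matrices are plain :class:`pandas.DataFrame` objects with
features (genes or miRNAs) in rows and samples in columns, holding
normalised log2 intensities.  Sample metadata travels in a sample table,
a DataFrame with columns ``sample_id``, ``group`` (``control``/``case``),
``batch``, ``excluded`` (bool) and ``exclusion_reason``.

Inputs are assumed already normalised to the log2 scale; platform-level
background correction is out of scope.  Missing values are rejected at
parse time rather than imputed, because no downstream stage defines an
imputation rule.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SAMPLE_COLUMNS = ["sample_id", "group", "batch", "excluded", "exclusion_reason"]

__all__ = [
    "read_expression",
    "write_expression",
    "read_sample_table",
    "write_sample_table",
    "make_sample_table",
    "merge_cohorts",
    "remove_batch_effect",
    "validate_expression",
    "ParseError",
    "MergeError",
]


class ParseError(ValueError):
    """Raised when an input file violates the TSV expression dialect."""


class MergeError(ValueError):
    """Raised when cohorts cannot be merged (e.g. empty feature overlap)."""


def validate_expression(x: pd.DataFrame) -> None:
    """Check expression-matrix invariants: unique ids, finite values."""
    if x.index.has_duplicates:
        dups = x.index[x.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature ids: {dups[:5]}")
    if x.columns.has_duplicates:
        dups = x.columns[x.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dups[:5]}")
    if not np.isfinite(x.to_numpy(dtype=float)).all():
        raise ValueError("expression matrix contains non-finite values")


def read_expression(path) -> pd.DataFrame:
    """Read a features-in-rows TSV expression matrix.

    The first column holds feature ids, the header row holds sample ids.
    Duplicate feature ids are collapsed by keeping the row with the
    highest mean expression (the standard array convention when several
    probes map to one gene symbol).  Ragged rows, non-numeric cells and
    empty files raise :class:`ParseError` naming the offending line.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln != ""]
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    sample_ids = header[1:]
    if not sample_ids:
        raise ParseError(f"{path}: header row has no sample columns")
    n_cols = len(header)
    feature_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != n_cols:
            raise ParseError(
                f"{path}: line {lineno}: expected {n_cols} fields, got {len(parts)}"
            )
        vals = []
        for col, cell in enumerate(parts[1:], start=2):
            try:
                v = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}, column {col}: non-numeric cell {cell!r}"
                ) from None
            if not np.isfinite(v):
                raise ParseError(
                    f"{path}: line {lineno}, column {col}: non-finite cell {cell!r}"
                )
            vals.append(v)
        feature_ids.append(parts[0])
        rows.append(vals)
    x = pd.DataFrame(rows, index=feature_ids, columns=sample_ids, dtype=float)
    if x.index.has_duplicates:
        # keep-max-mean collapse; ties broken toward the first occurrence
        means = x.mean(axis=1)
        order = np.argsort(-means.to_numpy(), kind="stable")
        x = x.iloc[order]
        x = x[~x.index.duplicated(keep="first")]
        x = x.sort_index()
    validate_expression(x)
    return x


def write_expression(x: pd.DataFrame, path) -> None:
    """Write a matrix in the dialect :func:`read_expression` parses.

    Floats are printed with 17 significant digits so a write/read
    round-trip reproduces the values bit-exactly.
    """
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("feature_id\t" + "\t".join(map(str, x.columns)) + "\n")
        arr = x.to_numpy(dtype=float)
        for fid, row in zip(x.index, arr):
            fh.write(str(fid) + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


def make_sample_table(sample_ids, groups, batches=None, excluded=None, reasons=None) -> pd.DataFrame:
    """Assemble a sample table from parallel sequences."""
    n = len(sample_ids)
    t = pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "group": list(groups),
            "batch": list(batches) if batches is not None else ["batch1"] * n,
            "excluded": list(excluded) if excluded is not None else [False] * n,
            "exclusion_reason": list(reasons) if reasons is not None else [""] * n,
        }
    )
    validate_sample_table(t)
    return t


def validate_sample_table(t: pd.DataFrame) -> None:
    missing = [c for c in SAMPLE_COLUMNS if c not in t.columns]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    if t["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in sample table")
    bad = set(t["group"]) - {"control", "case"}
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")


def read_sample_table(path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    t["excluded"] = t["excluded"].map(
        {"True": True, "False": False, "true": True, "false": False, "1": True, "0": False}
    )
    if t["excluded"].isna().any():
        raise ParseError(f"{path}: unparseable 'excluded' column")
    validate_sample_table(t)
    return t


def write_sample_table(t: pd.DataFrame, path) -> None:
    t.to_csv(path, sep="\t", index=False)


def merge_cohorts(matrices, tables) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge >=2 cohorts on the intersection of their feature symbols.

    Samples are concatenated (ids must be disjoint across cohorts);
    each sample keeps the batch label of its source cohort.  Samples
    flagged ``excluded`` in the incoming tables (e.g. patients under
    CPAP treatment) are dropped from both outputs.
    """
    if len(matrices) < 2:
        raise MergeError("need at least two cohorts to merge")
    if len(matrices) != len(tables):
        raise MergeError("matrices and sample tables must pair up")
    common = matrices[0].index
    for x in matrices[1:]:
        common = common.intersection(x.index)
    if len(common) == 0:
        raise MergeError("empty feature intersection across cohorts")
    common = common.sort_values()

    kept_parts, table_parts = [], []
    all_ids: set[str] = set()
    for i, (x, t) in enumerate(zip(matrices, tables), start=1):
        validate_sample_table(t)
        overlap = all_ids.intersection(t["sample_id"])
        if overlap:
            raise MergeError(f"sample ids shared across cohorts: {sorted(overlap)[:5]}")
        all_ids.update(t["sample_id"])
        keep = t.loc[~t["excluded"].astype(bool)].copy()
        if keep.empty:
            raise MergeError(f"cohort {i}: no usable samples (all excluded)")
        missing = set(keep["sample_id"]) - set(x.columns)
        if missing:
            raise MergeError(f"cohort {i}: samples missing from matrix: {sorted(missing)[:5]}")
        keep["batch"] = f"cohort{i}"
        kept_parts.append(x.loc[common, keep["sample_id"].tolist()])
        table_parts.append(keep)
    merged = pd.concat(kept_parts, axis=1)
    table = pd.concat(table_parts, ignore_index=True)
    validate_expression(merged)
    return merged, table


def remove_batch_effect(x: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Remove additive batch effects while preserving group structure.

    Per feature, fits the two-way linear model

        y = mu + group + batch + error

    by least squares and subtracts only the fitted batch component, so
    the control/case contrast is untouched.  With a single batch the
    input is returned unchanged.  Raises if batch is perfectly
    confounded with group (the batch coefficients would then absorb the
    group effect).
    """
    validate_sample_table(samples)
    t = samples.set_index("sample_id").loc[list(x.columns)]
    batches = pd.Categorical(t["batch"])
    if len(batches.categories) < 2:
        return x.copy()
    group = (t["group"] == "case").to_numpy(dtype=float)
    # full-rank check: batch dummies must not be collinear with [1, group]
    batch_dummies = pd.get_dummies(batches, drop_first=True).to_numpy(dtype=float)
    base = np.column_stack([np.ones(len(t)), group])
    design = np.column_stack([base, batch_dummies])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("batch confounded with group")
    y = x.to_numpy(dtype=float)  # features x samples
    coef, *_ = np.linalg.lstsq(design, y.T, rcond=None)  # (2+B-1) x features
    batch_component = batch_dummies @ coef[2:, :]  # samples x features
    corrected = y - batch_component.T
    return pd.DataFrame(corrected, index=x.index, columns=x.columns)
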