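"""Readers and writers for the pipeline's plain-text artifact formats.

Expression-type matrices travel as TSV with a ``feature_id`` first column
and sample ids in the header; numbers are written with 6 significant digits
and the decimal-point dialect only.  Raw cohorts additionally write a
replicate-level wide TSV, a label table, and the synthetic truth table.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import yaml

from .preprocess import CalibrationParams, ExpressionMatrix, SummarizedMatrix
from .synthetic import QPCRTable, RawCohort

_FLOAT_FMT = "%.6g"


def read_expression_tsv(path: str) -> pd.DataFrame:
    """Read a feature-by-sample matrix TSV; strict about shape and content.

    Duplicate feature ids, ragged rows and non-numeric cells are rejected
    with the offending position named.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "feature_id":
        raise ValueError(
            f"{path}: first column must be 'feature_id', got {df.columns[0]!r}"
        )
    ids = df["feature_id"]
    dup = ids[ids.duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate feature ids: {sorted(set(dup))}")
    if ids.isna().any() or df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax())
        raise ValueError(f"{path}: ragged or missing values near data row {row + 1}")
    out = df.set_index("feature_id")
    for col in out.columns:
        converted = pd.to_numeric(out[col], errors="coerce")
        bad = converted.isna() & out[col].notna()
        if bad.any():
            feat = bad.idxmax()
            raise ValueError(
                f"{path}: non-numeric cell at feature {feat!r}, column {col!r}: "
                f"{out.loc[feat, col]!r}"
            )
        out[col] = converted
    out.index.name = "feature_id"
    return out


def write_expression_tsv(values: pd.DataFrame, path: str) -> None:
    values.to_csv(path, sep="\t", index_label="feature_id", float_format=_FLOAT_FMT)


def write_labels_tsv(labels: pd.Series, path: str) -> None:
    labels.rename("group").to_csv(path, sep="\t", index_label="sample_id")


def read_labels_tsv(path: str) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return df.set_index("sample_id")["group"]


def write_raw_cohort(raw: RawCohort, outdir: str) -> dict[str, str]:
    """Write a cohort as intensities/labels/truth TSV (+ spec YAML).

    The intensity TSV has one row per feature x replicate (columns:
    feature_id, replicate, then samples).
    """
    os.makedirs(outdir, exist_ok=True)
    n, p, r = raw.intensities.shape
    wide = pd.DataFrame(
        raw.intensities.transpose(1, 2, 0).reshape(p * r, n),
        columns=raw.sample_ids,
    )
    wide.insert(0, "replicate", np.tile(np.arange(1, r + 1), p))
    wide.insert(0, "feature_id", np.repeat(raw.feature_ids, r))
    paths = {
        "intensities": os.path.join(outdir, "intensities.tsv"),
        "labels": os.path.join(outdir, "labels.tsv"),
    }
    wide.to_csv(paths["intensities"], sep="\t", index=False, float_format=_FLOAT_FMT)
    write_labels_tsv(raw.labels, paths["labels"])
    if raw.truth is not None:
        paths["truth"] = os.path.join(outdir, "truth.tsv")
        raw.truth.to_csv(paths["truth"], sep="\t", float_format=_FLOAT_FMT)
    if raw.spec is not None:
        paths["spec"] = os.path.join(outdir, "cohort_spec.yaml")
        spec_dict = {
            k: (list(map(float, v)) if isinstance(v, (tuple, np.ndarray)) else v)
            for k, v in vars(raw.spec).items()
        }
        with open(paths["spec"], "w") as fh:
            yaml.safe_dump(spec_dict, fh, sort_keys=False)
    return paths


def read_raw_cohort(outdir: str, background: float) -> RawCohort:
    wide = pd.read_csv(os.path.join(outdir, "intensities.tsv"), sep="\t")
    labels = read_labels_tsv(os.path.join(outdir, "labels.tsv"))
    feature_ids = wide["feature_id"].drop_duplicates().tolist()
    sample_ids = [c for c in wide.columns if c not in ("feature_id", "replicate")]
    reps = wide.groupby("feature_id", sort=False).size()
    if reps.nunique() != 1:
        raise ValueError("unequal replicate counts per feature")
    r = int(reps.iloc[0])
    tensor = (
        wide[sample_ids].to_numpy(dtype=float).reshape(len(feature_ids), r, len(sample_ids))
        .transpose(2, 0, 1)
    )
    truth_path = os.path.join(outdir, "truth.tsv")
    truth = pd.read_csv(truth_path, sep="\t", index_col=0) if os.path.exists(truth_path) else None
    return RawCohort(
        intensities=tensor,
        background=background,
        labels=labels.reindex(sample_ids),
        sample_ids=sample_ids,
        feature_ids=feature_ids,
        truth=truth,
    )


def write_calibration_tsv(params: CalibrationParams, path: str) -> None:
    params.params.to_csv(path, sep="\t", index_label="sample_id", float_format=_FLOAT_FMT)


def write_diffexp_tsv(table: pd.DataFrame, path: str) -> None:
    """Report table in the discovery-table column order, fold change at 2 dp."""
    out = table.copy()
    out["fold_change"] = out["fold_change"].round(2)
    cols = [
        "median_control",
        "median_case",
        "fold_change",
        "direction",
        "p_raw",
        "p_adjusted",
        "auc",
        "significant",
    ]
    out[cols].to_csv(path, sep="\t", index_label="feature_id", float_format=_FLOAT_FMT)


def read_qpcr_table(path: str, reference_mirna: str = "miR-16") -> QPCRTable:
    sep = "," if path.endswith(".csv") else "\t"
    rec = pd.read_csv(path, sep=sep)
    required = {"sample_id", "group", "mirna_id", "replicate", "ct"}
    missing = required - set(rec.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "pair_id" not in rec.columns:
        rec["pair_id"] = pd.NA
    return QPCRTable(records=rec, reference_mirna=reference_mirna)


def write_qpcr_table(table: QPCRTable, path: str) -> None:
    sep = "," if path.endswith(".csv") else "\t"
    table.records.to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT)
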