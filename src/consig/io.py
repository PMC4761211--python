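"""Tab-separated file formats for expression matrices, clinical tables, and manifests.

Expression files are probes x samples with a header row of sample ids and
the probe id in the first column, optionally preceded by a
``#scale=log2|linear`` comment line (default log2).  Clinical files need
``sample_id, time, event`` and may carry ``stage, age, gender,
treatment_start, treated`` plus arbitrary extra columns, which are
preserved.  All floats are written at full precision so that reruns are
byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .matrix import ExpressionMatrix

REQUIRED_CLINICAL = ("sample_id", "time", "event")
_NUMERIC_CLINICAL = ("time", "age", "treatment_start")


def write_expression(expression: ExpressionMatrix, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"#scale={expression.scale}\n")
        expression.values.to_csv(fh, sep="\t", index_label="probe_id", lineterminator="\n")


def read_expression(path) -> ExpressionMatrix:
    """Read a probes x samples TSV; see the module docstring for the format."""
    path = Path(path)
    scale = "log2"
    skip = 0
    with open(path) as fh:
        first = fh.readline().strip()
    if first.startswith("#"):
        skip = 1
        if first.startswith("#scale="):
            scale = first.split("=", 1)[1].strip()
    df = pd.read_csv(path, sep="\t", skiprows=skip, index_col=0, dtype={0: str})
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate probe ids in {path}: {dups[:5]}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise ValueError(f"non-numeric cell in {path} at probe {row!r}, sample {col!r}")
        df[col] = coerced
    return ExpressionMatrix(df, scale=scale)


def validate_clinical(df: pd.DataFrame) -> pd.DataFrame:
    """Type and validate a clinical table; unknown columns pass through."""
    missing = [c for c in REQUIRED_CLINICAL if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing required column(s): {missing}")
    out = df.copy()
    out["sample_id"] = out["sample_id"].astype(str)
    if out["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in clinical table")
    for col in _NUMERIC_CLINICAL:
        if col in out.columns:
            out[col] = pd.to_numeric(out[col], errors="raise")
    if (out["time"] < 0).any():
        raise ValueError("negative survival time in clinical table")
    ev = pd.to_numeric(out["event"], errors="raise")
    if not ev.isin([0, 1]).all():
        bad = ev[~ev.isin([0, 1])].unique()
        raise ValueError(f"event must be 0/1, found {bad[:5]}")
    out["event"] = ev.astype(np.int64)
    if "treatment_start" in out.columns and (out["treatment_start"].dropna() < 0).any():
        raise ValueError("negative treatment_start in clinical table")
    return out


def read_clinical(path) -> pd.DataFrame:
    return validate_clinical(pd.read_csv(path, sep="\t"))


def write_clinical(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_manifest(path) -> list[dict]:
    """Cohort manifest: YAML list of {cohort_id, expression, clinical, endpoint?}.

    Relative paths are resolved against the manifest's directory.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    cohorts = doc.get("cohorts", doc) if isinstance(doc, dict) else doc
    if not isinstance(cohorts, list) or not cohorts:
        raise ValueError(f"manifest {path} must list at least one cohort")
    seen = set()
    out = []
    for entry in cohorts:
        cid = str(entry["cohort_id"])
        if cid in seen:
            raise ValueError(f"duplicate cohort_id {cid!r} in manifest")
        seen.add(cid)
        expr = (path.parent / entry["expression"]).resolve()
        clin = (path.parent / entry["clinical"]).resolve()
        for p in (expr, clin):
            if not p.exists():
                raise FileNotFoundError(f"manifest path does not exist: {p}")
        out.append(
            {
                "cohort_id": cid,
                "expression": expr,
                "clinical": clin,
                "endpoint": entry.get("endpoint", "OS"),
                "platform": entry.get("platform", ""),
            }
        )
    return out


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg
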