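"""Area-to-cell-number regression.

The number of nuclei N in an organoid is modelled as a log-log linear
function of its image area A (pixels) with two binary covariates — tissue
origin S (healthy = 0, tumor = 1) and morphology M (cystic = 0,
budded = 1):

    log N = b0 + bA * log A + bS * S + bM * M + eps

fitted by ordinary least squares on (area, covariates, nuclei-count)
training rows.  An extended variant adds the raw perimeter P and the
area-to-perimeter ratio A/P as predictors.  Predictions are
N_hat = exp(...) on the original count scale; well totals sum the
unrounded per-organoid estimates (rounding before summation injects up to
0.5 per organoid of bias), with the rounded sum reported alongside.

Logs are natural internally; the base is recorded in the model file and
fitting is equivariant under a base change, so this is presentation only.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import DetectionSet, OrgquantError

MODEL_SCHEMA_VERSION = 1

SAMPLE_TYPES = {"healthy": 0, "tumor": 1}
MORPHOLOGIES = {"cystic": 0, "budded": 1}


def _encode(value, table: dict[str, int], what: str) -> int:
    if isinstance(value, str):
        try:
            return table[value]
        except KeyError:
            raise OrgquantError(
                f"unknown {what} {value!r}; expected one of {sorted(table)}"
            ) from None
    v = int(value)
    if v not in (0, 1):
        raise OrgquantError(f"{what} must be binary, got {value}")
    return v


@dataclass
class CountRecord:
    """One training/validation row: a detected organoid with a reference
    nuclei count (from confocal nuclear staining in real data, or from the
    generator's law in synthetic data)."""

    area: float
    sample_type: int  # healthy = 0, tumor = 1
    morphology: int  # cystic = 0, budded = 1
    real_nuclei: Optional[int] = None
    perimeter: Optional[float] = None
    well_id: str = ""
    organoid_id: int = 0

    def __post_init__(self) -> None:
        if self.area < 1:
            raise OrgquantError(f"organoid area must be >= 1 px, got {self.area}")
        self.sample_type = _encode(self.sample_type, SAMPLE_TYPES, "sample_type")
        self.morphology = _encode(self.morphology, MORPHOLOGIES, "morphology")
        if self.real_nuclei is not None and self.real_nuclei < 1:
            raise OrgquantError("real_nuclei must be >= 1 when present")


_BASE_TERMS = ("intercept", "log_area", "sample_type", "morphology")
_EXTENDED_TERMS = _BASE_TERMS + ("perimeter", "area_perimeter_ratio")


@dataclass
class CountModel:
    """Fitted coefficients of the cell-count regression."""

    formula: str  # "base" or "extended"
    coefficients: dict[str, float]
    stderr: dict[str, float]
    log_base: float  # e recorded as math.e
    fit_n: int
    residual_sd: float
    schema_version: int = MODEL_SCHEMA_VERSION

    @property
    def terms(self) -> tuple[str, ...]:
        return _EXTENDED_TERMS if self.formula == "extended" else _BASE_TERMS


def _design_matrix(
    records: Sequence[CountRecord], formula: str, log_base: float
) -> tuple[np.ndarray, list[str]]:
    names = list(_EXTENDED_TERMS if formula == "extended" else _BASE_TERMS)
    cols = {
        "intercept": np.ones(len(records)),
        "log_area": np.array([math.log(r.area, log_base) for r in records]),
        "sample_type": np.array([float(r.sample_type) for r in records]),
        "morphology": np.array([float(r.morphology) for r in records]),
    }
    if formula == "extended":
        for r in records:
            if r.perimeter is None or r.perimeter <= 0:
                raise OrgquantError(
                    "extended formula requires a positive perimeter on every record"
                )
        cols["perimeter"] = np.array([float(r.perimeter) for r in records])
        cols["area_perimeter_ratio"] = np.array(
            [r.area / r.perimeter for r in records]
        )
    return np.column_stack([cols[n] for n in names]), names


def fit(
    records: Sequence[CountRecord],
    formula: str = "base",
    log_base: float = math.e,
) -> CountModel:
    """Ordinary least squares of log(real_nuclei) on the chosen predictors.

    Requires at least p + 2 rows with a reference count, where p is the
    number of predictors including the intercept.  A rank-deficient design
    (e.g. a constant covariate column) raises an error naming the column.
    """
    if formula not in ("base", "extended"):
        raise OrgquantError(f"unknown formula {formula!r}")
    rows = [r for r in records if r.real_nuclei is not None]
    X, names = _design_matrix(rows, formula, log_base)
    if len(rows) < X.shape[1] + 2:
        raise OrgquantError(
            f"need at least {X.shape[1] + 2} records with real_nuclei, got {len(rows)}"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        degenerate = [
            n for j, n in enumerate(names)
            if n != "intercept" and np.ptp(X[:, j]) == 0
        ]
        label = ", ".join(degenerate) if degenerate else "collinear predictors"
        raise OrgquantError(f"rank-deficient design: degenerate column(s): {label}")
    y = np.array([math.log(r.real_nuclei, log_base) for r in rows])
    res = sm.OLS(y, X).fit()
    dof = max(1, len(rows) - X.shape[1])
    return CountModel(
        formula=formula,
        coefficients=dict(zip(names, map(float, res.params))),
        stderr=dict(zip(names, map(float, res.bse))),
        log_base=float(log_base),
        fit_n=len(rows),
        residual_sd=float(np.sqrt(res.ssr / dof)),
    )


def predict_cells(
    model: CountModel,
    area,
    sample_type,
    morphology,
    perimeter=None,
    rounded: bool = False,
):
    """Predicted nuclei count(s) for given area(s) and covariates.

    Scalar or array inputs; the rounded variant is max(1, nearest int).
    """
    A = np.asarray(area, dtype=float)
    if np.any(A < 1):
        raise OrgquantError("area must be >= 1 px")
    S = float(_encode(sample_type, SAMPLE_TYPES, "sample_type"))
    M = float(_encode(morphology, MORPHOLOGIES, "morphology"))
    b = model.coefficients
    log_n = (
        b["intercept"]
        + b["log_area"] * np.log(A) / math.log(model.log_base)
        + b["sample_type"] * S
        + b["morphology"] * M
    )
    if model.formula == "extended":
        if perimeter is None:
            raise OrgquantError("extended model requires a perimeter")
        P = np.asarray(perimeter, dtype=float)
        if np.any(P <= 0):
            raise OrgquantError("perimeter must be positive")
        log_n = log_n + b["perimeter"] * P + b["area_perimeter_ratio"] * (A / P)
    elif perimeter is not None:
        raise OrgquantError("base model takes no perimeter argument")
    n_hat = np.power(model.log_base, log_n)
    if rounded:
        n_hat = np.maximum(1, np.round(n_hat)).astype(int)
    return n_hat if n_hat.ndim else n_hat.item()


@dataclass
class WellEstimate:
    """Per-organoid estimates and the well total for one detection set."""

    table: pd.DataFrame
    total: float  # sum of unrounded per-organoid estimates
    total_rounded: int  # sum of rounded per-organoid estimates


def estimate_well(
    dets: DetectionSet, model: CountModel, sample_type, morphology
) -> WellEstimate:
    """Estimate cells per organoid and in total for a deduplicated well."""
    if not dets.deduplicated:
        raise OrgquantError(
            "estimate_well requires a deduplicated detection set "
            "(duplicates would be double-counted)"
        )
    rows = []
    for inst in dets.instances:
        kwargs = {}
        if model.formula == "extended":
            kwargs["perimeter"] = inst.perimeter
        est = predict_cells(model, inst.area, sample_type, morphology, **kwargs)
        rows.append(
            {
                "id": inst.id,
                "centroid_x": inst.centroid[0],
                "centroid_y": inst.centroid[1],
                "area_px": inst.area,
                "perimeter_px": inst.perimeter,
                "confidence": inst.confidence,
                "est_cells": est,
                "est_cells_rounded": max(1, int(round(est))),
            }
        )
    cols = [
        "id", "centroid_x", "centroid_y", "area_px", "perimeter_px",
        "confidence", "est_cells", "est_cells_rounded",
    ]
    table = pd.DataFrame(rows, columns=cols)
    return WellEstimate(
        table=table,
        total=float(table["est_cells"].sum()) if rows else 0.0,
        total_rounded=int(table["est_cells_rounded"].sum()) if rows else 0,
    )


# ---------------------------------------------------------------------------
# Serialization

def save_model(model: CountModel, path) -> None:
    """Write the model as versioned JSON; round-trips exactly."""
    doc = {
        "schema_version": model.schema_version,
        "formula": model.formula,
        "coefficients": model.coefficients,
        "stderr": model.stderr,
        "log_base": model.log_base,
        "fit_n": model.fit_n,
        "residual_sd": model.residual_sd,
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def load_model(path) -> CountModel:
    """Read a model written by :func:`save_model`."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise OrgquantError(f"corrupt model file {path}: {exc}") from exc
    version = doc.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise OrgquantError(
            f"model schema version mismatch: file has {version}, "
            f"this build reads {MODEL_SCHEMA_VERSION}"
        )
    return CountModel(
        formula=doc["formula"],
        coefficients={k: float(v) for k, v in doc["coefficients"].items()},
        stderr={k: float(v) for k, v in doc["stderr"].items()},
        log_base=float(doc["log_base"]),
        fit_n=int(doc["fit_n"]),
        residual_sd=float(doc["residual_sd"]),
    )


# ---------------------------------------------------------------------------
# Training-table CSV I/O

CSV_COLUMNS = [
    "well_id", "organoid_id", "area_px", "perimeter_px",
    "sample_type", "morphology", "real_nuclei",
]


def records_to_frame(records: Sequence[CountRecord]) -> pd.DataFrame:
    inv_s = {v: k for k, v in SAMPLE_TYPES.items()}
    inv_m = {v: k for k, v in MORPHOLOGIES.items()}
    return pd.DataFrame(
        [
            {
                "well_id": r.well_id,
                "organoid_id": r.organoid_id,
                "area_px": r.area,
                "perimeter_px": r.perimeter if r.perimeter is not None else np.nan,
                "sample_type": inv_s[r.sample_type],
                "morphology": inv_m[r.morphology],
                "real_nuclei": r.real_nuclei,
            }
            for r in records
        ],
        columns=CSV_COLUMNS,
    )


def frame_to_records(frame: pd.DataFrame) -> list[CountRecord]:
    records = []
    for _, row in frame.iterrows():
        perim = row.get("perimeter_px")
        records.append(
            CountRecord(
                area=float(row["area_px"]),
                perimeter=None if pd.isna(perim) else float(perim),
                sample_type=row["sample_type"],
                morphology=row["morphology"],
                real_nuclei=None if pd.isna(row["real_nuclei"]) else int(row["real_nuclei"]),
                well_id=str(row.get("well_id", "")),
                organoid_id=int(row.get("organoid_id", 0)),
            )
        )
    return records


def read_records_csv(path) -> list[CountRecord]:
    return frame_to_records(pd.read_csv(path))


def write_records_csv(records: Sequence[CountRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)
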