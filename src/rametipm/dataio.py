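"""Reading/writing ramet tables and results; ground-truth size calibration.

Ramet tables are plain CSV with the header
``ramet_id,size_t,survived,size_t1,flowered,n_flowers,is_recruit``;
sizes are stored in natural-log m² and absent values as empty fields.
Results are serialized to JSON at full float precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import COLUMNS, RametDataset
from .errors import DegenerateDataError, InvalidParameterError, SchemaError

__all__ = [
    "CalibrationResult",
    "read_ramet_table",
    "write_ramet_table",
    "calibrate_sizes",
    "apply_size_correction",
    "write_results",
    "read_results",
]


@dataclass(frozen=True)
class CalibrationResult:
    """Multiplicative size-correction factor (true/measured) from ground targets."""

    ratio: float
    n_targets: int

    def __post_init__(self):
        if self.ratio <= 0:
            raise InvalidParameterError("calibration ratio must be > 0")


def write_ramet_table(dataset: RametDataset, path) -> None:
    dataset.data.to_csv(path, index=False, na_rep="")


def read_ramet_table(path) -> RametDataset:
    """Read a ramet CSV, validating schema, dtypes and record invariants."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"ramet_id": str})
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file with no header") from exc
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    for col in COLUMNS[1:]:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            raise SchemaError(
                f"{path}: non-numeric values in column {col!r} at rows {list(bad)}"
            ) from exc
    return RametDataset(df).validate()


def calibrate_sizes(measured_areas, known_areas, method: str = "mean_of_ratios") -> CalibrationResult:
    """Correction factor mapping measured areas onto ground-truth areas.

    ``method="mean_of_ratios"`` (default) averages per-target known/measured
    ratios; ``"pooled"`` uses Σknown/Σmeasured.  Both are scale-equivariant:
    scaling every measurement by c scales the ratio by 1/c.
    """
    measured = np.asarray(measured_areas, dtype=float)
    known = np.asarray(known_areas, dtype=float)
    if measured.size == 0 or measured.shape != known.shape:
        raise DegenerateDataError("measured and known areas must be equal-length, non-empty")
    if np.any(measured <= 0) or np.any(known <= 0):
        raise InvalidParameterError("areas must be strictly positive")
    if method == "mean_of_ratios":
        ratio = float(np.mean(known / measured))
    elif method == "pooled":
        ratio = float(known.sum() / measured.sum())
    else:
        raise ValueError(f"unknown method {method!r}")
    return CalibrationResult(ratio=ratio, n_targets=int(measured.size))


def apply_size_correction(dataset: RametDataset, calibration: CalibrationResult) -> RametDataset:
    """Rescale raw areas (m²) by the calibration ratio, then log-transform.

    The input dataset must carry raw surface areas in ``size_t``/``size_t1``;
    the returned dataset has them replaced by ln(area·ratio), with IDs and
    row order preserved.
    """
    df = dataset.data.copy()
    for col in ("size_t", "size_t1"):
        areas = df[col]
        bad = df.index[areas.notna() & (areas <= 0)]
        if len(bad):
            ids = df.loc[bad, "ramet_id"].tolist()
            raise InvalidParameterError(
                f"nonpositive area in {col} for ramet_id(s) {ids}"
            )
        df[col] = np.log(areas * calibration.ratio)
    return RametDataset(df, year_t=dataset.year_t, year_t1=dataset.year_t1)


# ---------------------------------------------------------------------------
# results file
# ---------------------------------------------------------------------------


def write_results(result, path) -> None:
    """Serialize an :class:`~rametipm.ipm.IPMResult` summary to JSON.

    Floats are written at round-trip precision; two writes of the same
    result are byte-identical.
    """
    payload = result.to_dict()
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")


def read_results(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
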