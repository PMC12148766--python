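"""Dose-function metrics over functional contours.

Two metrics per contour: the functional mean lung dose (fMLD, Gy) — the
average dose within the contour — and fV20 (%) — the fraction of contour
voxels receiving at least 20 Gy.  With four imaging methods, three
percentile thresholds and two metrics, the default per-patient table holds
24 records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contours import FunctionContour, threshold_contour, to_percentile
from .core import FunctionImage, LungMask
from .phantom import DoseGrid

log = logging.getLogger(__name__)

__all__ = ["DoseFunctionRecord", "fmld", "fv20", "dose_function_table", "table_to_frame"]

DEFAULT_LEVELS = (25, 50, 75)
V_THRESHOLD_GY = 20.0


@dataclass
class DoseFunctionRecord:
    patient: str
    method: str
    level: int
    metric: str  # "fMLD" (Gy) or "fV20" (%)
    value: float

    def __post_init__(self):
        if self.metric not in ("fMLD", "fV20"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if np.isfinite(self.value):
            if self.metric == "fV20" and not 0 <= self.value <= 100:
                raise ValueError("fV20 must lie in [0, 100]")
            if self.metric == "fMLD" and self.value < 0:
                raise ValueError("fMLD must be >= 0")


def fmld(dose: DoseGrid, contour: FunctionContour) -> float:
    """Functional mean lung dose: arithmetic mean dose over contour voxels."""
    if dose.values.shape != contour.values.shape:
        raise ValueError("dose and contour grids differ")
    if contour.n_voxels == 0:
        raise ValueError("empty functional contour")
    return float(dose.values[contour.values].mean())


def fv20(dose: DoseGrid, contour: FunctionContour, threshold_gy: float = V_THRESHOLD_GY) -> float:
    """Percent of contour voxels receiving >= 20 Gy (inclusive)."""
    if dose.values.shape != contour.values.shape:
        raise ValueError("dose and contour grids differ")
    if contour.n_voxels == 0:
        raise ValueError("empty functional contour")
    d = dose.values[contour.values]
    return float(100.0 * (d >= threshold_gy).sum() / d.size)


def dose_function_table(
    patient: str,
    images: dict,
    dose: DoseGrid,
    mask: LungMask,
    levels=DEFAULT_LEVELS,
):
    """Per-patient dose-function records for every (method, level, metric).

    ``images`` maps method labels to :class:`FunctionImage`; a missing or
    ``None`` entry yields NaN-valued records flagged by their value, and an
    empty contour likewise produces an undefined record while the rest of
    the table is still computed.
    """
    records = []
    for method, img in images.items():
        if img is None:
            for level in levels:
                for metric in ("fMLD", "fV20"):
                    records.append(DoseFunctionRecord(patient, method, level, metric, np.nan))
            log.warning("dose_function_table: method %s absent for %s", method, patient)
            continue
        pct = to_percentile(img, mask)
        for level in levels:
            contour = threshold_contour(pct, level, method=method)
            for metric, fn in (("fMLD", fmld), ("fV20", fv20)):
                try:
                    value = fn(dose, contour)
                except ValueError as exc:
                    log.warning(
                        "dose_function_table: %s/%s/%d undefined (%s)",
                        patient, method, level, exc,
                    )
                    value = np.nan
                records.append(DoseFunctionRecord(patient, method, level, metric, value))
    return records


def table_to_frame(records) -> pd.DataFrame:
    """Long-format DataFrame of dose-function records."""
    return pd.DataFrame(
        [
            {
                "patient": r.patient,
                "method": r.method,
                "level": r.level,
                "metric": r.metric,
                "value": r.value,
            }
            for r in records
        ]
    )
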