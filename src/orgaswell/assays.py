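"""CFTR-function readouts from tracked organoid areas.

Three assays are computed from instance areas:

* **DIS** (drug-induced swelling): per organoid,
  ``swelling = area(t24) / area(t0)``; records are screened by an
  explicit outlier rule (minimum t0 area, then a Tukey fence per
  condition per plate) and summarized as mean +- SD per
  (plate, condition).
* **FIS** (forskolin-induced swelling): the total organoid area per
  frame, normalized to t=0 as a percentage, summarized as the
  baseline-subtracted trapezoidal area under the curve in %*min, so a
  non-swelling well scores 0 and shrinkage is negative.
* **SLA** (steady-state lumen area): ``100 * luminal_area /
  total_area`` per organoid, in percent.

A bin-size stabilization analysis estimates how many organoids a
condition needs: mean swelling of randomly drawn bins of 2..256 records,
10 repeats each, reported as the SD of the repeat-means per bin size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .masks_io import LabelMask, ValidityError
from .tracking import OrganoidTrajectory

logger = logging.getLogger("orgaswell")

DEFAULT_MIN_AREA_T0 = 300.0  # px^2, at the generator's default organoid scale
DEFAULT_FENCE_K = 1.5  # Tukey fence multiplier
DEFAULT_BIN_SIZES = (2, 4, 8, 16, 32, 64, 128, 256)
DEFAULT_BIN_REPEATS = 10

__all__ = [
    "SwellingRecord",
    "ConditionSummary",
    "FISCurve",
    "SLARecord",
    "StabilityTable",
    "PlateLayout",
    "swelling_per_organoid",
    "exclude_outliers",
    "condition_summary",
    "sla",
    "fis_auc",
    "total_area_series",
    "bin_stability",
    "records_to_frame",
]


@dataclass
class SwellingRecord:
    """Per-organoid swelling between the two DIS timepoints."""

    well_id: str
    condition: str
    track_id: int
    area_t0: float
    area_t24: float
    swelling: float
    excluded: bool = False
    exclusion_reason: str = ""
    border_flagged: bool = False


@dataclass(frozen=True)
class ConditionSummary:
    """Mean swelling per (plate, condition) over included records."""

    plate_id: str
    condition: str
    mean_swelling: float | None
    sd_swelling: float | None
    n_included: int
    n_excluded: int


@dataclass(frozen=True)
class FISCurve:
    timepoints: tuple[float, ...]  # minutes
    total_area: tuple[float, ...]  # px^2
    relative_area: tuple[float, ...]  # % of t0
    auc: float  # %*min, baseline-subtracted


@dataclass(frozen=True)
class SLARecord:
    organoid_id: int
    luminal_area: float
    total_area: float
    sla: float


@dataclass(frozen=True)
class StabilityTable:
    bin_sizes: tuple[int, ...]
    means: pd.DataFrame  # rows = repeats, cols = bin sizes
    sd_of_means: pd.Series  # per bin size


@dataclass(frozen=True)
class PlateLayout:
    """well_id -> (condition, compounds, plate_id)."""

    wells: Mapping[str, tuple[str, str, str]]

    def condition_of(self, well_id: str) -> str:
        return self.wells[well_id][0]

    def plate_of(self, well_id: str) -> str:
        return self.wells[well_id][2]


# ---------------------------------------------------------------------------
# DIS
# ---------------------------------------------------------------------------

def swelling_per_organoid(
    traj: OrganoidTrajectory,
    t0: float = 0.0,
    t1: float = 24.0,
    well_id: str = "",
    condition: str = "",
) -> SwellingRecord:
    """Area ratio of one tracked organoid between two nominal timepoints."""
    a0 = traj.area_at(t0)
    a1 = traj.area_at(t1)
    if a0 is None or a1 is None:
        raise ValueError(
            f"track {traj.track_id} lacks an endpoint: t={t0} -> {a0}, t={t1} -> {a1}"
        )
    return SwellingRecord(
        well_id=well_id,
        condition=condition,
        track_id=traj.track_id,
        area_t0=float(a0),
        area_t24=float(a1),
        swelling=float(a1) / float(a0),
    )


def exclude_outliers(
    records: Sequence[SwellingRecord],
    min_area_t0: float = DEFAULT_MIN_AREA_T0,
    fence_k: float = DEFAULT_FENCE_K,
    layout: "PlateLayout | None" = None,
) -> list[SwellingRecord]:
    """Flag outlier records; original values are retained.

    Rule (a): ``area_t0 < min_area_t0`` -> reason ``min_area``.
    Rule (b): swelling outside the Tukey fence
    ``[Q1 - k*IQR, Q3 + k*IQR]`` computed per (plate, condition) group
    over the records passing (a) -> reason ``tukey_fence``. Groups with
    fewer than 4 surviving records get only the area filter. Border-
    flagged records are excluded with reason ``border``.
    """
    out = [replace(r) for r in records]
    groups: dict[tuple[str, str], list[SwellingRecord]] = {}
    for r in out:
        if r.border_flagged:
            r.excluded = True
            r.exclusion_reason = "border"
            continue
        if r.area_t0 < min_area_t0:
            r.excluded = True
            r.exclusion_reason = "min_area"
            continue
        plate = layout.plate_of(r.well_id) if layout and r.well_id in getattr(layout, "wells", {}) else ""
        groups.setdefault((plate, r.condition), []).append(r)
    for (plate, cond), grp in groups.items():
        if len(grp) < 4:
            continue
        sw = np.array([r.swelling for r in grp])
        q1, q3 = np.percentile(sw, [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - fence_k * iqr, q3 + fence_k * iqr
        n_fenced = 0
        for r in grp:
            if not lo <= r.swelling <= hi:
                r.excluded = True
                r.exclusion_reason = "tukey_fence"
                n_fenced += 1
        if n_fenced:
            logger.info(
                "condition %s%s: fenced %d/%d records outside [%.3f, %.3f]",
                cond, f" (plate {plate})" if plate else "", n_fenced, len(grp), lo, hi,
            )
    return out


def condition_summary(
    records: Sequence[SwellingRecord], layout: PlateLayout
) -> list[ConditionSummary]:
    """Mean and sample SD of included swellings per (plate, condition).

    A condition whose records are all excluded is still reported, with
    ``n_included`` 0 and missing mean/SD.
    """
    for r in records:
        if r.well_id not in layout.wells:
            raise KeyError(f"record well {r.well_id!r} not present in the plate layout")
    groups: dict[tuple[str, str], list[SwellingRecord]] = {}
    for r in records:
        key = (layout.plate_of(r.well_id), layout.condition_of(r.well_id))
        groups.setdefault(key, []).append(r)
    summaries = []
    for (plate, cond) in sorted(groups):
        grp = groups[(plate, cond)]
        incl = [r.swelling for r in grp if not r.excluded]
        n_ex = sum(r.excluded for r in grp)
        if incl:
            mean = float(np.mean(incl))
            sd = float(np.std(incl, ddof=1)) if len(incl) > 1 else 0.0
        else:
            mean = sd = None
        summaries.append(
            ConditionSummary(
                plate_id=plate,
                condition=cond,
                mean_swelling=mean,
                sd_swelling=sd,
                n_included=len(incl),
                n_excluded=n_ex,
            )
        )
    return summaries


def records_to_frame(records: Sequence[SwellingRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "well_id": r.well_id,
                "condition": r.condition,
                "track_id": r.track_id,
                "area_t0_px2": r.area_t0,
                "area_t24_px2": r.area_t24,
                "swelling": r.swelling,
                "excluded": r.excluded,
                "exclusion_reason": r.exclusion_reason,
            }
            for r in records
        ]
    )


# ---------------------------------------------------------------------------
# SLA
# ---------------------------------------------------------------------------

def sla(luminal_area: float, total_area: float) -> float:
    """Steady-state lumen area: luminal area as % of total organoid area."""
    if total_area < 1:
        raise ValidityError(f"total_area must be >= 1 px, got {total_area}")
    if not 0 <= luminal_area <= total_area:
        raise ValidityError(
            f"luminal_area {luminal_area} must lie in [0, total_area={total_area}]"
        )
    return 100.0 * luminal_area / total_area


# ---------------------------------------------------------------------------
# FIS
# ---------------------------------------------------------------------------

def fis_auc(timepoints: Sequence[float], total_areas: Sequence[float]) -> FISCurve:
    """Baseline-subtracted AUC of relative total area over a time-lapse.

    ``relative_area(t) = 100 * area(t)/area(0)``; the integrand is
    ``relative_area - 100`` so a flat series scores exactly 0 and
    shrinkage contributes negatively. Trapezoidal integration is exact
    for piecewise-linear area growth, so refining the frame grid of a
    linear ramp does not change the AUC.
    """
    t = np.asarray(timepoints, dtype=float)
    a = np.asarray(total_areas, dtype=float)
    if t.size < 2:
        raise ValueError("FIS needs at least 2 timepoints")
    if t[0] != 0:
        raise ValueError(f"FIS series must start at t=0, got t[0]={t[0]}")
    if np.any(np.diff(t) <= 0):
        raise ValueError("FIS timepoints must be strictly increasing")
    if a[0] == 0:
        raise ZeroDivisionError("total area at t=0 is zero; cannot normalize")
    rel = 100.0 * a / a[0]
    auc = float(np.trapezoid(rel - 100.0, t))
    return FISCurve(
        timepoints=tuple(float(x) for x in t),
        total_area=tuple(float(x) for x in a),
        relative_area=tuple(float(x) for x in rel),
        auc=auc,
    )


def total_area_series(masks: Sequence[LabelMask]) -> np.ndarray:
    """Summed instance area per frame, normalized to the first frame.

    The first frame's value is 1 by construction (or 0 when it is
    empty, in which case normalization is skipped).
    """
    if not masks:
        raise ValueError("total_area_series needs at least 1 mask")
    totals = np.array([float(np.count_nonzero(m.labels)) for m in masks])
    if totals[0] > 0:
        return totals / totals[0]
    return totals


# ---------------------------------------------------------------------------
# bin-size stabilization
# ---------------------------------------------------------------------------

def bin_stability(
    records: Sequence[SwellingRecord] | Sequence[float],
    bin_sizes: Sequence[int] = DEFAULT_BIN_SIZES,
    repeats: int = DEFAULT_BIN_REPEATS,
    rng_seed: int = 0,
) -> StabilityTable:
    """Mean swelling of random organoid bins, to find the stable bin size.

    For each bin size, ``repeats`` independent draws without replacement
    are taken (seeded) and the mean swelling of each draw is recorded;
    the SD of those repeat-means per bin size indicates when the assay
    readout stabilizes. Excluded records are ignored.
    """
    seq = list(records)
    if seq and isinstance(seq[0], SwellingRecord):
        values = np.array([r.swelling for r in seq if not r.excluded])
    else:
        values = np.array([float(v) for v in seq])
    bin_sizes = tuple(int(b) for b in bin_sizes)
    for b in bin_sizes:
        if b > values.size:
            raise ValueError(
                f"bin size {b} exceeds the {values.size} available records"
            )
        if b < 1:
            raise ValueError("bin sizes must be >= 1")
    rng = np.random.default_rng(rng_seed)
    table = np.zeros((repeats, len(bin_sizes)))
    for j, b in enumerate(bin_sizes):
        for i in range(repeats):
            draw = rng.choice(values, size=b, replace=False)
            table[i, j] = draw.mean()
    means = pd.DataFrame(table, columns=list(bin_sizes))
    sd = means.std(axis=0, ddof=1)
    return StabilityTable(bin_sizes=bin_sizes, means=means, sd_of_means=sd)
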