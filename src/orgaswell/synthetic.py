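"""Synthetic bright-field organoid scenes with known ground truth.

Real drug-induced-swelling experiments image the same well before and
~24 h after treatment; each organoid's projected area grows by a
condition-dependent ratio. This module fabricates such data: stylized
bright-field scenes (mid-gray background, dark organoid rim, brighter
interior, optional bright lumen, Gaussian noise, optional illumination
tilt) together with exact instance label masks and, for evolved scenes,
a truth table of the per-organoid area ratios that were applied.

Shapes are radial-harmonic blobs,

    r(theta) = R * (1 + sum_k a_k cos(k*theta + phi_k)),   sum|a_k| <= irregularity,

so ``irregularity = 0`` gives a disk and larger values give the
lobed, irregular outlines typical of CF organoids.  Swelling by an area
ratio ``s`` multiplies the linear scale by ``sqrt(s)``, so the measured
quantity (area) scales by ``s`` up to rasterization error.

Everything is deterministic under a fixed seed, at shape, scene and
plate level.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage import draw as skdraw
from skimage import morphology

from .masks_io import GrayImage, LabelMask, write_image, write_label_mask

logger = logging.getLogger("orgaswell")

_N_CONTOUR_POINTS = 720
_MAX_PLACEMENT_TRIES = 400

__all__ = [
    "ShapeParams",
    "OrganoidShape",
    "SceneSpec",
    "OrganoidRecord",
    "SyntheticScene",
    "SwellingModel",
    "make_shape",
    "render_scene",
    "evolve_scene",
    "make_plate",
    "PlateResult",
    "interpolate_masks",
]


@dataclass(frozen=True)
class ShapeParams:
    """Distributional parameters for organoid outlines.

    ``irregularity`` bounds the summed harmonic amplitude (0 = disk);
    ``lumen_fraction`` is the lumen's linear scale relative to the
    organoid, so the luminal area fraction is ``lumen_fraction**2``.
    """

    mean_radius: float = 16.0  # px
    irregularity: float = 0.0  # in [0, 1)
    n_harmonics: int = 4
    lumen_fraction: float = 0.0  # in [0, 1)

    def __post_init__(self) -> None:
        if self.mean_radius < 3:
            raise ValueError(f"mean_radius must be >= 3 px, got {self.mean_radius}")
        if not 0 <= self.irregularity < 1:
            raise ValueError("irregularity must lie in [0, 1)")
        if not 0 <= self.lumen_fraction < 1:
            raise ValueError("lumen_fraction must lie in [0, 1)")
        if self.n_harmonics < 0:
            raise ValueError("n_harmonics must be >= 0")


@dataclass(frozen=True)
class OrganoidShape:
    """One realized outline: fixed harmonics, scalable radius."""

    mean_radius: float
    amplitudes: tuple[float, ...]
    phases: tuple[float, ...]
    lumen_fraction: float = 0.0
    rim_width: int = 2

    def radii(self, thetas: np.ndarray, scale: float = 1.0) -> np.ndarray:
        r = np.ones_like(thetas)
        for k, (a, phi) in enumerate(zip(self.amplitudes, self.phases), start=1):
            r += a * np.cos(k * thetas + phi)
        return self.mean_radius * scale * r

    def max_radius(self, scale: float = 1.0) -> float:
        return self.mean_radius * scale * (1.0 + sum(abs(a) for a in self.amplitudes))

    def scaled(self, linear_scale: float) -> "OrganoidShape":
        return replace(self, mean_radius=self.mean_radius * linear_scale)


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one synthetic scene.

    Intensity levels are 8-bit by default (background 120, dark rim 60,
    interior 150, lumen 200). ``clustering`` is the probability that an
    organoid is deliberately placed touching an already-placed one.
    ``illumination_tilt`` adds a linear left-to-right ramp of the given
    fraction of the background level.
    """

    image_size: tuple[int, int] = (512, 512)
    n_organoids: int = 10
    shape_params: ShapeParams = field(default_factory=ShapeParams)
    clustering: float = 0.0
    background_level: float = 120.0
    interior_level: float = 150.0
    rim_level: float = 60.0
    lumen_level: float = 200.0
    noise_sd: float = 2.0
    illumination_tilt: float = 0.0
    rng_seed: int = 0
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if self.n_organoids < 0:
            raise ValueError("n_organoids must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.clustering <= 1:
            raise ValueError("clustering must lie in [0, 1]")
        lim = 255 if self.bit_depth == 8 else 65535
        for name in ("background_level", "interior_level", "rim_level", "lumen_level"):
            v = getattr(self, name)
            if not 0 <= v <= lim:
                raise ValueError(f"{name}={v} outside the {self.bit_depth}-bit range")


@dataclass(frozen=True)
class OrganoidRecord:
    label_id: int
    shape: OrganoidShape
    center: tuple[float, float]  # (row, col)
    area_px2: int


@dataclass
class SyntheticScene:
    image: GrayImage
    truth: LabelMask
    per_organoid: list[OrganoidRecord]
    timepoint: float = 0.0  # hours
    spec: SceneSpec | None = None


@dataclass(frozen=True)
class SwellingModel:
    """Condition-dependent swelling distribution for scene evolution.

    Per-organoid area ratios are drawn ``Normal(swelling_mean,
    swelling_sd)`` (clipped to stay positive); with probability
    ``outlier_rate`` the ratio is instead drawn uniformly from
    ``outlier_ratio_range``, emulating small/nonviable structures that
    shrink rather than swell.
    """

    condition_name: str
    swelling_mean: float = 1.0
    swelling_sd: float = 0.0
    centroid_jitter_sd: float = 0.0  # px
    outlier_rate: float = 0.0
    outlier_ratio_range: tuple[float, float] = (0.2, 0.6)

    def __post_init__(self) -> None:
        if self.swelling_mean <= 0:
            raise ValueError("swelling_mean must be > 0")
        if self.swelling_sd < 0:
            raise ValueError("swelling_sd must be >= 0")
        if not 0 <= self.outlier_rate <= 1:
            raise ValueError("outlier_rate must lie in [0, 1]")

    def draw_ratio(self, rng: np.random.Generator) -> tuple[float, bool]:
        """Draw one area ratio; returns (ratio, is_outlier)."""
        if self.outlier_rate and rng.random() < self.outlier_rate:
            lo, hi = self.outlier_ratio_range
            return float(rng.uniform(lo, hi)), True
        s = float(rng.normal(self.swelling_mean, self.swelling_sd))
        return max(s, 0.05), False


# ---------------------------------------------------------------------------
# shape synthesis
# ---------------------------------------------------------------------------

def make_shape(params: ShapeParams, rng: np.random.Generator) -> tuple[OrganoidShape, np.ndarray]:
    """Realize one outline and rasterize it on a tight local canvas.

    Harmonic amplitudes are drawn and rescaled so their absolute sum
    equals ``params.irregularity`` (guaranteeing a positive radius at
    every angle); phases are uniform. Returns the shape and a boolean
    mask whose canvas is square with the shape centred.
    """
    n = params.n_harmonics
    if n == 0 or params.irregularity == 0:
        amplitudes = tuple(0.0 for _ in range(n))
        phases = tuple(0.0 for _ in range(n))
        # keep the stream aligned regardless of irregularity
        rng.uniform(size=n)
        rng.uniform(size=n)
    else:
        raw = rng.uniform(0.3, 1.0, size=n)
        amps = raw / raw.sum() * params.irregularity
        phases = tuple(float(p) for p in rng.uniform(0, 2 * np.pi, size=n))
        amplitudes = tuple(float(a) for a in amps)
    rim_width = int(rng.integers(2, 4))
    shape = OrganoidShape(
        mean_radius=params.mean_radius,
        amplitudes=amplitudes,
        phases=phases,
        lumen_fraction=params.lumen_fraction,
        rim_width=rim_width,
    )
    mask = rasterize_shape(shape)
    return shape, mask


def rasterize_shape(shape: OrganoidShape, scale: float = 1.0) -> np.ndarray:
    """Fill the radial contour on a square canvas centred on the shape."""
    half = int(np.ceil(shape.max_radius(scale))) + 2
    size = 2 * half + 1
    thetas = np.linspace(0, 2 * np.pi, _N_CONTOUR_POINTS, endpoint=False)
    r = np.clip(shape.radii(thetas, scale), 0.5, None)
    rows = half + r * np.sin(thetas)
    cols = half + r * np.cos(thetas)
    mask = np.zeros((size, size), dtype=bool)
    rr, cc = skdraw.polygon(rows, cols, shape=mask.shape)
    mask[rr, cc] = True
    return mask


# ---------------------------------------------------------------------------
# scene rendering
# ---------------------------------------------------------------------------

def _paste_window(center: tuple[int, int], local: np.ndarray, shape: tuple[int, int]):
    """Slices mapping a local canvas centred at ``center`` into the scene."""
    half = local.shape[0] // 2
    r0, c0 = center[0] - half, center[1] - half
    r1, c1 = r0 + local.shape[0], c0 + local.shape[1]
    lr0 = max(0, -r0)
    lc0 = max(0, -c0)
    lr1 = local.shape[0] - max(0, r1 - shape[0])
    lc1 = local.shape[1] - max(0, c1 - shape[1])
    return (
        (slice(max(0, r0), min(r1, shape[0])), slice(max(0, c0), min(c1, shape[1]))),
        (slice(lr0, lr1), slice(lc0, lc1)),
    )


def _fits_inside(center: tuple[int, int], local: np.ndarray, shape: tuple[int, int]) -> bool:
    half = local.shape[0] // 2
    return (
        center[0] - half >= 0
        and center[1] - half >= 0
        and center[0] + half + 1 <= shape[0]
        and center[1] + half + 1 <= shape[1]
    )


def _overlaps(occupancy: np.ndarray, center, local: np.ndarray, *, pad: bool) -> bool:
    """True if the candidate footprint intersects occupied pixels.

    With ``pad`` the footprint is dilated by one pixel so accepted
    placements cannot even be 8-adjacent to an existing organoid.
    """
    cand = morphology.dilation(local, footprint=np.ones((3, 3))) if pad else local
    win, lwin = _paste_window(center, cand, occupancy.shape)
    return bool(np.any(occupancy[win] & cand[lwin]))


def _compose_image(
    spec: SceneSpec, labels: np.ndarray, records: Sequence[OrganoidRecord], rng: np.random.Generator
) -> GrayImage:
    """Background + tilt, per-organoid rim/interior/lumen, then noise."""
    h, w = spec.image_size
    cols = np.linspace(-0.5, 0.5, w)
    img = spec.background_level * (1.0 + spec.illumination_tilt * cols)[None, :] * np.ones((h, 1))
    for rec in records:
        body = labels == rec.label_id
        interior = morphology.erosion(body, footprint=morphology.disk(rec.shape.rim_width))
        rim = body & ~interior
        img[rim] = spec.rim_level
        img[interior] = spec.interior_level
        if rec.shape.lumen_fraction > 0:
            lum_local = rasterize_shape(rec.shape, scale=rec.shape.lumen_fraction)
            ic = (int(round(rec.center[0])), int(round(rec.center[1])))
            win, lwin = _paste_window(ic, lum_local, labels.shape)
            sel = np.zeros_like(body)
            sel[win] = lum_local[lwin]
            img[sel & interior] = spec.lumen_level
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    lim = 255 if spec.bit_depth == 8 else 65535
    img = np.clip(img, 0, lim)
    return GrayImage(pixels=img, bit_depth=spec.bit_depth)


def render_scene(spec: SceneSpec, timepoint: float = 0.0) -> SyntheticScene:
    """Place organoids by rejection sampling and compose the image.

    Overlap is always forbidden (each pixel belongs to one label).  With
    probability ``clustering`` an organoid is walked in along a random
    direction until it touches an existing one, producing
    touching-but-label-distinct clusters; otherwise accepted placements
    keep at least one background pixel between instances.  If a bounded
    number of rejections is exhausted the scene is returned with however
    many organoids could be placed.
    """
    rng = np.random.default_rng(spec.rng_seed)
    h, w = spec.image_size
    labels = np.zeros((h, w), dtype=np.int64)
    occupancy = np.zeros((h, w), dtype=bool)
    records: list[OrganoidRecord] = []

    for i in range(spec.n_organoids):
        shape, local = make_shape(spec.shape_params, rng)
        half = local.shape[0] // 2
        placed = False
        cluster_this = bool(records) and rng.random() < spec.clustering
        for _ in range(_MAX_PLACEMENT_TRIES):
            if cluster_this:
                anchor = records[int(rng.integers(len(records)))]
                ang = rng.uniform(0, 2 * np.pi)
                d_far = anchor.shape.max_radius() + shape.max_radius() + 3
                center = None
                prev = None
                # walk inward until the footprints collide; settle one step out
                for d in np.arange(d_far, 0, -1.0):
                    cand = (
                        int(round(anchor.center[0] + d * np.sin(ang))),
                        int(round(anchor.center[1] + d * np.cos(ang))),
                    )
                    if not _fits_inside(cand, local, (h, w)):
                        continue
                    if _overlaps(occupancy, cand, local, pad=False):
                        center = prev
                        break
                    prev = cand
                if center is None:
                    continue
            else:
                center = (
                    int(rng.integers(half, h - half)) if h > 2 * half else None,
                    int(rng.integers(half, w - half)) if w > 2 * half else None,
                )
                if center[0] is None or center[1] is None:
                    break
                if _overlaps(occupancy, center, local, pad=True):
                    continue
            if center is None or not _fits_inside(center, local, (h, w)):
                continue
            if _overlaps(occupancy, center, local, pad=False):
                continue
            win, lwin = _paste_window(center, local, (h, w))
            labels[win][local[lwin]] = i + 1
            occupancy[win] |= local[lwin]
            records.append(
                OrganoidRecord(
                    label_id=i + 1,
                    shape=shape,
                    center=(float(center[0]), float(center[1])),
                    area_px2=int(local.sum()),
                )
            )
            placed = True
            break
        if not placed:
            logger.warning(
                "placed %d of %d organoids before exhausting rejections", len(records), spec.n_organoids
            )
            break

    # recompute areas from the final label image (clipping-safe)
    records = [
        replace(rec, area_px2=int(np.count_nonzero(labels == rec.label_id))) for rec in records
    ]
    image = _compose_image(spec, labels, records, rng)
    return SyntheticScene(
        image=image, truth=LabelMask(labels=labels), per_organoid=records, timepoint=timepoint, spec=spec
    )


# ---------------------------------------------------------------------------
# temporal evolution (swelling)
# ---------------------------------------------------------------------------

_SPIRAL_MAX_RADIUS = 48  # px; beyond this an organoid is dropped


def _nearest_free_position(
    target: tuple[float, float], local: np.ndarray, occupancy: np.ndarray
) -> tuple[int, int] | None:
    """Deterministic spiral search for the closest in-frame,
    non-overlapping placement of ``local`` around ``target``."""
    tr, tc = target
    for d in range(0, _SPIRAL_MAX_RADIUS + 1):
        if d == 0:
            offsets = [(0.0, 0.0)]
        else:
            n_ang = max(8, 4 * d)
            angles = 2 * np.pi * np.arange(n_ang) / n_ang
            offsets = [(d * np.sin(a), d * np.cos(a)) for a in angles]
        for dr, dc in offsets:
            center = (int(round(tr + dr)), int(round(tc + dc)))
            if not _fits_inside(center, local, occupancy.shape):
                continue
            if not _overlaps(occupancy, center, local, pad=False):
                return center
    return None

def evolve_scene(
    scene: SyntheticScene,
    model: SwellingModel,
    rng: np.random.Generator,
    delta_hours: float = 24.0,
) -> tuple[SyntheticScene, pd.DataFrame]:
    """Swell every organoid by a drawn area ratio and re-render at t+delta.

    Each organoid keeps its harmonics; its linear scale is multiplied by
    ``sqrt(s)`` so its area scales by the drawn ratio ``s``.  Centroids
    are jittered by ``model.centroid_jitter_sd``; a collision or
    out-of-frame placement is resolved by a spiral search for the
    nearest free position, so displacements stay minimal (swelling
    organoids nudge their neighbours rather than teleport).  Larger
    organoids are placed first to keep the nudges small.  Returns the
    evolved scene and a truth table with columns label_id,
    applied_ratio, is_outlier, area_t0_px2, area_t1_px2 (area_t1 is 0
    for an organoid that could not be re-placed, which only happens in
    pathologically dense scenes).
    """
    spec = scene.spec
    if spec is None:
        raise ValueError("scene must carry its SceneSpec to be evolved")
    h, w = spec.image_size
    labels = np.zeros((h, w), dtype=np.int64)
    occupancy = np.zeros((h, w), dtype=bool)
    new_records: list[OrganoidRecord] = []
    rows_by_label: dict[int, dict] = {}

    # draw ratios and jitters in label order so the random stream is
    # independent of placement order
    draws = []
    for rec in scene.per_organoid:
        s, is_outlier = model.draw_ratio(rng)
        jr = rng.normal(0.0, model.centroid_jitter_sd) if model.centroid_jitter_sd else 0.0
        jc = rng.normal(0.0, model.centroid_jitter_sd) if model.centroid_jitter_sd else 0.0
        draws.append((rec, s, is_outlier, jr, jc))

    for rec, s, is_outlier, jr, jc in sorted(
        draws, key=lambda d: (-d[0].area_px2 * d[1], d[0].label_id)
    ):
        shape1 = rec.shape.scaled(np.sqrt(s))
        local = rasterize_shape(shape1)
        target = (rec.center[0] + jr, rec.center[1] + jc)
        center = _nearest_free_position(target, local, occupancy)
        placed = center is not None
        if placed:
            win, lwin = _paste_window(center, local, (h, w))
            labels[win][local[lwin]] = rec.label_id
            occupancy[win] |= local[lwin]
            new_records.append(
                OrganoidRecord(
                    label_id=rec.label_id,
                    shape=shape1,
                    center=(float(center[0]), float(center[1])),
                    area_px2=int(local.sum()),
                )
            )
        else:
            logger.warning("organoid %d could not be re-placed after swelling", rec.label_id)
        rows_by_label[rec.label_id] = {
            "label_id": rec.label_id,
            "applied_ratio": s,
            "is_outlier": is_outlier,
            "area_t0_px2": rec.area_px2,
            "area_t1_px2": int(local.sum()) if placed else 0,
        }
    new_records.sort(key=lambda r: r.label_id)
    rows = [rows_by_label[rec.label_id] for rec in scene.per_organoid]

    image = _compose_image(spec, labels, new_records, rng)
    evolved = SyntheticScene(
        image=image,
        truth=LabelMask(labels=labels),
        per_organoid=new_records,
        timepoint=scene.timepoint + delta_hours,
        spec=spec,
    )
    return evolved, pd.DataFrame(rows)


def interpolate_masks(
    scene0: SyntheticScene, ratios: Mapping[int, float], n_frames: int
) -> list[LabelMask]:
    """Emit ``n_frames`` masks with per-organoid areas linearly
    interpolated from 1x to the given final ratios (frame 0 is the
    original truth mask). Centres are held fixed; this is the stylized
    time-lapse used for fluid-secretion time-course tests, not a
    physical motion model."""
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    h, w = scene0.truth.shape
    frames = [scene0.truth]
    for j in range(1, n_frames):
        f = j / (n_frames - 1)
        labels = np.zeros((h, w), dtype=np.int64)
        for rec in scene0.per_organoid:
            s = 1.0 + f * (ratios.get(rec.label_id, 1.0) - 1.0)
            local = rasterize_shape(rec.shape.scaled(np.sqrt(s)))
            center = (int(round(rec.center[0])), int(round(rec.center[1])))
            win, lwin = _paste_window(center, local, (h, w))
            region = labels[win]
            sel = local[lwin] & (region == 0)
            region[sel] = rec.label_id
        frames.append(LabelMask(labels=labels))
    return frames


# ---------------------------------------------------------------------------
# plates
# ---------------------------------------------------------------------------

@dataclass
class WellResult:
    well_id: str
    condition: str
    scene_t0: SyntheticScene
    scene_t1: SyntheticScene
    truth: pd.DataFrame  # per-organoid applied ratios


@dataclass
class PlateResult:
    wells: dict[str, WellResult]
    truth: pd.DataFrame  # all wells concatenated

    def well_ids(self) -> list[str]:
        return list(self.wells)


def _well_seed(rng_seed: int, well_id: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(rng_seed), zlib.crc32(well_id.encode("utf-8"))])


def make_plate(
    wells: Sequence[tuple[str, str]],
    scene_spec: SceneSpec,
    models: Mapping[str, SwellingModel],
    rng_seed: int,
    out_dir: str | Path | None = None,
    delta_hours: float = 24.0,
) -> PlateResult:
    """Generate an independent t0/t1 scene pair for every well.

    Each well's randomness is seeded deterministically from
    ``(rng_seed, well_id)``, so regenerating a plate (or a single well)
    is byte-identical. When ``out_dir`` is given, per-well images and
    truth masks are written as TIFF along with a ``truth.csv``.
    """
    results: dict[str, WellResult] = {}
    all_rows = []
    for well_id, condition in wells:
        if condition not in models:
            raise KeyError(f"well {well_id!r}: no swelling model for condition {condition!r}")
        ss = _well_seed(rng_seed, well_id)
        seeds = ss.generate_state(2)
        spec = replace(scene_spec, rng_seed=int(seeds[0]))
        scene0 = render_scene(spec, timepoint=0.0)
        rng1 = np.random.default_rng(int(seeds[1]))
        scene1, truth = evolve_scene(scene0, models[condition], rng1, delta_hours=delta_hours)
        truth.insert(0, "condition", condition)
        truth.insert(0, "well_id", well_id)
        results[well_id] = WellResult(well_id, condition, scene0, scene1, truth)
        all_rows.append(truth)
        logger.info(
            "well %s (%s): %d organoids at t0, %d at t1",
            well_id,
            condition,
            len(scene0.per_organoid),
            len(scene1.per_organoid),
        )
    plate_truth = (
        pd.concat(all_rows, ignore_index=True)
        if all_rows
        else pd.DataFrame(
            columns=["well_id", "condition", "label_id", "applied_ratio", "is_outlier", "area_t0_px2", "area_t1_px2"]
        )
    )
    plate = PlateResult(wells=results, truth=plate_truth)
    if out_dir is not None:
        write_plate(plate, out_dir)
    return plate


def write_plate(plate: PlateResult, out_dir: str | Path) -> Path:
    """Write per-well images + truth masks (TIFF) and truth.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for well in plate.wells.values():
        write_image(well.scene_t0.image, out / f"{well.well_id}_t0.tiff")
        write_image(well.scene_t1.image, out / f"{well.well_id}_t1.tiff")
        write_label_mask(well.scene_t0.truth, out / f"{well.well_id}_t0_mask.tiff")
        write_label_mask(well.scene_t1.truth, out / f"{well.well_id}_t1_mask.tiff")
    df = plate.truth.copy()
    df["applied_ratio"] = df["applied_ratio"].map(lambda v: f"{v:.6g}")
    df.to_csv(out / "truth.csv", index=False, lineterminator="\n")
    return out
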