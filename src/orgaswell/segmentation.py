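"""Classical bright-field instance segmentation.

Organoids in bright-field appear as dark-rimmed blobs on a mid-gray
background, so a gradient-based pipeline recovers them without any
learned model:

1. flatten illumination by subtracting a coarse Gaussian background
   estimate;
2. smooth at ``smooth_sigma``;
3. threshold the gradient magnitude at the ``edge_threshold`` quantile;
4. close small gaps in the edge map and fill holes, yielding solid
   candidate blobs;
5. split touching blobs by a distance-transform watershed seeded at
   interior maxima at least ``split_min_distance`` apart;
6. discard components smaller than ``min_area``;
7. apply the border policy to instances touching the image frame.

Masks from any external model (e.g. a trained network) can be imported
through :mod:`orgaswell.masks_io` and validated with
:func:`validate_mask_pair`; downstream tracking and assays do not care
where the mask came from.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import feature, filters, morphology, segmentation as skseg

from .masks_io import GrayImage, LabelMask, PairingError, ValidityError

logger = logging.getLogger("orgaswell")

__all__ = ["SegmentationParams", "segment_brightfield", "validate_mask_pair"]


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables of the classical pipeline.

    ``edge_threshold`` is the gradient-magnitude quantile above which a
    pixel counts as edge; ``split_min_distance`` is the minimum
    separation (px) of watershed seeds, and should be below the typical
    organoid radius to split touching pairs. ``border_policy`` governs
    frame-touching instances: ``keep`` them, ``flag`` them (kept in the
    mask, reported for exclusion from swelling statistics), or ``drop``
    them.
    """

    smooth_sigma: float = 1.0  # px
    edge_threshold: float = 0.96  # quantile in (0, 1)
    min_area: int = 120  # px^2
    close_radius: int = 2  # px
    split_min_distance: int = 12  # px
    border_policy: str = "flag"  # keep | flag | drop

    def __post_init__(self) -> None:
        if not 0 < self.edge_threshold < 1:
            raise ValueError("edge_threshold must lie in (0, 1)")
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")
        if self.border_policy not in ("keep", "flag", "drop"):
            raise ValueError(f"unknown border_policy {self.border_policy!r}")


def segment_brightfield(
    image: GrayImage,
    params: SegmentationParams | None = None,
    return_border_labels: bool = False,
) -> LabelMask | tuple[LabelMask, set[int]]:
    """Segment organoid instances from a bright-field image.

    Output labels are 1..n in decreasing area order. A constant image
    yields an empty mask. With ``return_border_labels`` the (relabelled)
    ids of frame-touching instances are returned too (empty set unless
    ``border_policy`` is ``flag`` or ``keep``).
    """
    if params is None:
        params = SegmentationParams()
    px = image.pixels.astype(float)

    # 1. illumination flattening against a coarse background estimate
    bg_sigma = max(px.shape) / 8.0
    background = ndi.gaussian_filter(px, sigma=bg_sigma)
    flat = px - background

    # 2-3. smooth, then edge map from the gradient-magnitude quantile
    smooth = ndi.gaussian_filter(flat, sigma=params.smooth_sigma)
    grad = filters.sobel(smooth)
    if grad.max() <= 0:
        empty = LabelMask(labels=np.zeros(px.shape, dtype=np.int64))
        return (empty, set()) if return_border_labels else empty
    thr = np.quantile(grad, params.edge_threshold)
    edges = grad > thr

    # 4. close gaps and fill to solid blobs
    if params.close_radius > 0:
        edges = morphology.closing(edges, footprint=morphology.disk(params.close_radius))
    solid = ndi.binary_fill_holes(edges)
    # peel the closing + edge-smear halo back off the blob boundary
    if params.close_radius > 0:
        solid = morphology.erosion(solid, footprint=morphology.disk(params.close_radius))
    solid = morphology.remove_small_objects(solid, max_size=max(8, params.min_area // 4) - 1)

    # 5. distance-transform watershed to split touching blobs
    distance = ndi.distance_transform_edt(solid)
    peak_coords = feature.peak_local_max(
        distance,
        min_distance=max(1, params.split_min_distance),
        labels=ndi.label(solid)[0],
        exclude_border=False,
    )
    markers = np.zeros(px.shape, dtype=np.int64)
    for i, (r, c) in enumerate(peak_coords, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        labels = np.zeros(px.shape, dtype=np.int64)
    else:
        labels = skseg.watershed(-distance, markers=markers, mask=solid)

    # 6. area filter
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    for lid, cnt in zip(ids, counts):
        if cnt < params.min_area:
            labels[labels == lid] = 0

    # 7. border policy
    border_ids = set(np.unique(np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])))
    border_ids.discard(0)
    if params.border_policy == "drop":
        for lid in border_ids:
            labels[labels == lid] = 0
        border_ids = set()

    # relabel 1..n by decreasing area, deterministic tie-break on old label
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    order = sorted(zip(ids, counts), key=lambda t: (-t[1], t[0]))
    out = np.zeros(px.shape, dtype=np.int64)
    border_out: set[int] = set()
    for new_id, (old_id, _) in enumerate(order, start=1):
        out[labels == old_id] = new_id
        if old_id in border_ids and params.border_policy in ("flag", "keep"):
            border_out.add(new_id)
    if params.border_policy == "keep":
        border_out = set()
    logger.info("segmented %d instances (%d touching border)", len(order), len(border_out))
    mask = LabelMask(labels=out)
    return (mask, border_out) if return_border_labels else mask


def validate_mask_pair(image: GrayImage, mask: LabelMask) -> tuple[GrayImage, LabelMask]:
    """Check an externally produced mask against its image and pass both through."""
    if image.shape != mask.shape:
        raise PairingError(f"image shape {image.shape} does not match mask shape {mask.shape}")
    if mask.labels.size and mask.labels.min() < 0:
        raise ValidityError("mask contains negative labels")
    return image, mask
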