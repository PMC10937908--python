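"""Associate organoid instances across timepoints.

Adherent organoids barely translate between acquisitions, so mask
overlap is the strongest association cue; a centroid-distance fallback
covers large swelling that destroys overlap. For a candidate pair the
cost is ``1 - IoU`` when the masks overlap, otherwise
``centroid_distance / max_displacement`` when the distance is within
the gate, otherwise the pair is forbidden. Linking is the optimal
one-to-one assignment that maximizes the number of links first and
minimizes total cost second. Two-timepoint links chain into
trajectories for time-lapse series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .masks_io import InstanceSet, LabelMask, PairingError
from .evaluation import iou_matrix

_FORBIDDEN = 1e9

__all__ = ["TrackLink", "OrganoidTrajectory", "link_timepoints", "build_trajectories"]


@dataclass(frozen=True)
class TrackLink:
    label_t0: int
    label_t1: int
    cost: float
    method: str  # "overlap" | "centroid"


@dataclass
class OrganoidTrajectory:
    """One organoid followed through time: (timepoint_h, label_id, area, centroid)."""

    track_id: int
    points: list[tuple[float, int, int, tuple[float, float]]] = field(default_factory=list)
    complete: bool = False

    def timepoints(self) -> list[float]:
        return [p[0] for p in self.points]

    def area_at(self, timepoint: float) -> int | None:
        for t, _, area, _ in self.points:
            if t == timepoint:
                return area
        return None


def link_timepoints(
    a: InstanceSet,
    b: InstanceSet,
    masks: tuple[LabelMask, LabelMask],
    max_displacement: float = 50.0,
) -> list[TrackLink]:
    """Optimal one-to-one links between two timepoints of the same field.

    Unmatched instances at either timepoint simply remain unlinked.
    """
    mask_a, mask_b = masks
    if mask_a.shape != mask_b.shape:
        raise PairingError(f"mask shapes differ: {mask_a.shape} vs {mask_b.shape}")
    insts_a = sorted(a.instances, key=lambda i: i.label_id)
    insts_b = sorted(b.instances, key=lambda i: i.label_id)
    if not insts_a or not insts_b:
        return []

    iou = iou_matrix(mask_a, mask_b)
    iou_lookup = {}
    for r, la in enumerate(iou.pred_labels):
        for c, lb in enumerate(iou.gt_labels):
            iou_lookup[(la, lb)] = iou.values[r, c]

    n_a, n_b = len(insts_a), len(insts_b)
    cost = np.full((n_a, n_b), _FORBIDDEN)
    method = np.zeros((n_a, n_b), dtype=object)
    for i, ia in enumerate(insts_a):
        for j, ib in enumerate(insts_b):
            ov = iou_lookup.get((ia.label_id, ib.label_id), 0.0)
            if ov > 0:
                cost[i, j] = 1.0 - ov
                method[i, j] = "overlap"
            else:
                d = float(np.hypot(ia.centroid[0] - ib.centroid[0], ia.centroid[1] - ib.centroid[1]))
                if d <= max_displacement:
                    cost[i, j] = d / max_displacement
                    method[i, j] = "centroid"
    # _FORBIDDEN dwarfs any admissible total, so minimizing the sum
    # maximizes the number of sub-forbidden links first, then total cost
    rows, cols = linear_sum_assignment(cost)
    links = []
    for r, c in zip(rows, cols):
        if cost[r, c] < _FORBIDDEN:
            links.append(
                TrackLink(
                    label_t0=insts_a[r].label_id,
                    label_t1=insts_b[c].label_id,
                    cost=float(cost[r, c]),
                    method=str(method[r, c]),
                )
            )
    links.sort(key=lambda l: l.label_t0)
    return links


def build_trajectories(
    sets: Sequence[InstanceSet],
    masks: Sequence[LabelMask],
    max_displacement: float = 50.0,
) -> list[OrganoidTrajectory]:
    """Chain pairwise links over an ordered series into trajectories.

    A trajectory is ``complete`` iff it has a point at every timepoint.
    Instances appearing mid-series start new (incomplete) trajectories;
    disappearing ones end theirs.
    """
    if len(sets) < 2:
        raise ValueError("build_trajectories requires at least 2 timepoints")
    if len(sets) != len(masks):
        raise ValueError("sets and masks must have equal length")
    times = [s.timepoint for s in sets]
    if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
        raise ValueError(f"timepoints must be strictly increasing, got {times}")

    trajectories: list[OrganoidTrajectory] = []
    # open trajectories keyed by their label at the previous frame
    open_by_label: dict[int, OrganoidTrajectory] = {}
    next_id = 0
    for inst in sets[0].instances:
        traj = OrganoidTrajectory(track_id=next_id)
        traj.points.append((sets[0].timepoint, inst.label_id, inst.area, inst.centroid))
        trajectories.append(traj)
        open_by_label[inst.label_id] = traj
        next_id += 1

    for k in range(1, len(sets)):
        links = link_timepoints(sets[k - 1], sets[k], (masks[k - 1], masks[k]), max_displacement)
        linked_next: dict[int, OrganoidTrajectory] = {}
        by_label = sets[k].by_label()
        for link in links:
            traj = open_by_label.get(link.label_t0)
            if traj is None:
                continue
            inst = by_label[link.label_t1]
            traj.points.append((sets[k].timepoint, inst.label_id, inst.area, inst.centroid))
            linked_next[inst.label_id] = traj
        for inst in sets[k].instances:
            if inst.label_id not in linked_next:
                traj = OrganoidTrajectory(track_id=next_id)
                traj.points.append((sets[k].timepoint, inst.label_id, inst.area, inst.centroid))
                trajectories.append(traj)
                linked_next[inst.label_id] = traj
                next_id += 1
        open_by_label = linked_next

    n_frames = len(sets)
    for traj in trajectories:
        traj.complete = len(traj.points) == n_frames
    return trajectories
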