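"""Zone assignment, zone-delimited path segmentation and the artefact filter.

A trajectory is split into maximal runs of points sharing a zone (light or
dark).  Brief single-frame zone flickers produced as the larva skims the
divider are removed by discarding segments whose point count falls strictly
below a low percentile (default 1st) of the per-recording segment-size
distribution.  Light/dark transitions are counted on the unfiltered label
sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import Trajectory, WellGeometry

__all__ = [
    "PathSegment",
    "assign_zone",
    "segment_by_zone",
    "filter_short_segments",
    "count_transitions",
]

log = logging.getLogger(__name__)

LIGHT = "light"
DARK = "dark"


@dataclass(frozen=True)
class PathSegment:
    """Maximal run of consecutive trajectory points within one zone.

    ``start`` and ``end`` are inclusive indices into the parent trajectory.
    """

    zone: str
    start: int
    end: int
    duration: float

    @property
    def n_points(self) -> int:
        return self.end - self.start + 1


def assign_zone(traj: Trajectory, well: WellGeometry) -> np.ndarray:
    """Label every trajectory point ``'light'`` or ``'dark'``.

    The label follows the signed distance to the divider; points exactly on
    the divider are labelled light (deterministic tie-break on a measure-zero
    set).
    """
    s = well.signed_dark_distance(traj.x, traj.y)
    return np.where(s > 0, DARK, LIGHT)


def segment_by_zone(traj: Trajectory, labels: np.ndarray) -> list[PathSegment]:
    """Split a trajectory into maximal constant-zone runs, in temporal order.

    The returned segments partition the index range: every point belongs to
    exactly one segment and consecutive segments alternate zones.
    """
    labels = np.asarray(labels)
    if len(labels) != len(traj):
        raise ValueError("labels must align with the trajectory")
    change = np.nonzero(labels[1:] != labels[:-1])[0]
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change, [len(labels) - 1]])
    return [
        PathSegment(
            zone=str(labels[s]),
            start=int(s),
            end=int(e),
            duration=float(traj.t[e] - traj.t[s]),
        )
        for s, e in zip(starts, ends)
    ]


def filter_short_segments(
    segments: Sequence[PathSegment],
    percentile: float = 1.0,
    larva_id: str | None = None,
) -> tuple[list[PathSegment], list[PathSegment]]:
    """Drop artefact segments whose point count is strictly below the percentile.

    The threshold is the linear-interpolation empirical percentile of the
    ``n_points`` distribution of *these* segments (per recording, not pooled
    across a cohort).  Strict ``<`` comparison means a uniform-length input
    loses nothing.  Returns ``(kept, removed)``.
    """
    if not segments:
        raise ValueError("no segments to filter")
    sizes = np.array([seg.n_points for seg in segments], dtype=float)
    threshold = float(np.percentile(sizes, percentile))
    kept = [seg for seg in segments if seg.n_points >= threshold]
    removed = [seg for seg in segments if seg.n_points < threshold]
    if removed:
        log.info(
            "artefact filter (%s): removed %d of %d segments below %.3g points",
            larva_id or "?",
            len(removed),
            len(segments),
            threshold,
        )
    return kept, removed


def count_transitions(labels: np.ndarray) -> int:
    """Number of adjacent light<->dark changes in the unfiltered label sequence."""
    labels = np.asarray(labels)
    if len(labels) < 1:
        raise ValueError("need at least one label")
    return int(np.sum(labels[1:] != labels[:-1]))
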