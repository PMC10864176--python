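"""Supervised pseudotime on a 2-D (or higher) embedding.

A candidate trajectory path is a piecewise-linear curve through ordered
waypoints — either given explicitly or taken as per-group coordinate medians
in a stated cluster order. Each nucleus is orthogonally projected onto its
nearest path segment and gets pseudotime t = normalized arc length at the
projection, with the perpendicular distance reported for QC. Bifurcations are
handled by a shared root path plus per-branch continuations.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TrajectoryPath", "fit_path", "assign_pseudotime", "branch_pseudotime"]


@dataclass
class TrajectoryPath:
    waypoints: np.ndarray  # ordered, (k, dim)
    branch_id: str = "path"
    shared_root: bool = False

    def __post_init__(self):
        self.waypoints = np.asarray(self.waypoints, dtype=float)
        if self.waypoints.ndim != 2 or len(self.waypoints) < 2:
            raise ValueError("a path needs >= 2 waypoints of equal dimension")
        seg = np.diff(self.waypoints, axis=0)
        self.seg_len = np.linalg.norm(seg, axis=1)
        if np.any(self.seg_len == 0):
            raise ValueError("consecutive waypoints must be distinct")
        self.cum_len = np.concatenate([[0.0], np.cumsum(self.seg_len)])

    @property
    def total_length(self) -> float:
        return float(self.cum_len[-1])


def _moving_average(points: np.ndarray, window: int) -> np.ndarray:
    """Endpoint-preserving moving average over waypoint coordinates."""
    if window <= 1 or len(points) <= 2:
        return points
    out = points.copy()
    half = window // 2
    for i in range(1, len(points) - 1):
        lo, hi = max(0, i - half), min(len(points), i + half + 1)
        out[i] = points[lo:hi].mean(axis=0)
    return out


def fit_path(embedding: pd.DataFrame | np.ndarray, ordered_groups: list | None = None,
             labels: pd.Series | None = None, waypoints: np.ndarray | None = None,
             smooth_window: int = 0, branch_id: str = "path") -> TrajectoryPath:
    """Fit a piecewise-linear path through waypoints.

    Either pass explicit ``waypoints``, or ``labels`` (nucleus -> group) plus
    ``ordered_groups`` giving the biological order; waypoints are then the
    per-group coordinate medians. ``smooth_window`` > 1 applies an
    endpoint-preserving moving average.
    """
    if waypoints is None:
        if labels is None or ordered_groups is None:
            raise ValueError("need explicit waypoints, or labels + ordered_groups")
        coords = embedding.to_numpy() if isinstance(embedding, pd.DataFrame) else np.asarray(embedding)
        idx = embedding.index if isinstance(embedding, pd.DataFrame) else pd.RangeIndex(len(coords))
        labels = pd.Series(labels).loc[idx]
        pts = []
        for g in ordered_groups:
            mask = (labels == g).to_numpy()
            if not mask.any():
                raise ValueError(f"no nuclei labeled {g!r}")
            pts.append(np.median(coords[mask], axis=0))
        waypoints = np.asarray(pts)
    waypoints = _moving_average(np.asarray(waypoints, dtype=float), smooth_window)
    return TrajectoryPath(waypoints, branch_id=branch_id)


def _project(points: np.ndarray, path: TrajectoryPath):
    """Nearest-segment orthogonal projection: arc lengths and distances."""
    a = path.waypoints[:-1]  # (k, d)
    d = np.diff(path.waypoints, axis=0)
    len2 = (d**2).sum(axis=1)
    # u[i, j]: position of point i along segment j, clipped to the segment
    u = np.clip(((points[:, None, :] - a[None]) * d[None]).sum(-1) / len2[None], 0.0, 1.0)
    proj = a[None] + u[..., None] * d[None]
    dist = np.linalg.norm(points[:, None, :] - proj, axis=-1)
    seg = np.argmin(dist, axis=1)  # first minimum on ties
    rows = np.arange(len(points))
    arc = path.cum_len[seg] + u[rows, seg] * path.seg_len[seg]
    return arc, dist[rows, seg]


def assign_pseudotime(embedding: pd.DataFrame | np.ndarray,
                      path: TrajectoryPath) -> pd.DataFrame:
    """Per-nucleus pseudotime in [0, 1] plus perpendicular distance."""
    coords = embedding.to_numpy() if isinstance(embedding, pd.DataFrame) else np.asarray(embedding)
    idx = embedding.index if isinstance(embedding, pd.DataFrame) else pd.RangeIndex(len(coords))
    arc, dist = _project(coords.astype(float), path)
    return pd.DataFrame(
        {
            "branch": path.branch_id,
            "pseudotime": arc / path.total_length,
            "arc_length": arc,
            "distance": dist,
        },
        index=idx,
    )


def branch_pseudotime(embedding: pd.DataFrame | np.ndarray, root_path: TrajectoryPath,
                      branch_paths: list[TrajectoryPath]) -> pd.DataFrame:
    """Assign each nucleus a branch and a pseudotime on root + branch.

    Every branch path must start at the root path's terminal waypoint. The
    nucleus goes to the branch whose concatenated path it is closest to
    (ties: the first branch, flagged in the ``tied`` column).
    """
    if not branch_paths:
        raise ValueError("need >= 1 branch path")
    for bp in branch_paths:
        if not np.allclose(bp.waypoints[0], root_path.waypoints[-1]):
            raise ValueError(
                f"branch {bp.branch_id!r} does not start at the root path terminus"
            )
    full = [
        TrajectoryPath(np.vstack([root_path.waypoints, bp.waypoints[1:]]),
                       branch_id=bp.branch_id)
        for bp in branch_paths
    ]
    results = [assign_pseudotime(embedding, p) for p in full]
    dists = np.stack([r.distance.to_numpy() for r in results], axis=1)
    best = np.argmin(dists, axis=1)  # first branch wins ties
    tied = (dists == dists.min(axis=1, keepdims=True)).sum(axis=1) > 1
    rows = np.arange(len(best))
    out = pd.DataFrame(
        {
            "branch": [full[b].branch_id for b in best],
            "pseudotime": np.stack([r.pseudotime.to_numpy() for r in results], 1)[rows, best],
            "arc_length": np.stack([r.arc_length.to_numpy() for r in results], 1)[rows, best],
            "distance": dists[rows, best],
            "tied": tied,
        },
        index=results[0].index,
    )
    return out
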