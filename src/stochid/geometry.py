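"""Mean-path construction and orthogonal-plane crossings.

The average trajectory ``t̄`` is formed by resampling every trial to a common
number of points by *normalised arc length* and averaging pointwise; this
makes the mean path independent of speed fluctuations, which is what the
purely spatial difficulty integral needs.  At each arc-length position ``s``
the plane ``P(s)`` orthogonal to the mean path collects one crossing point
``q_k(s)`` per trial — the raw material of the per-section dispersion
ellipses.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CrossingError, ValidationError
from .io import Trajectory, TrialEnsemble, resample

DEFAULT_GRID_M = 200


@dataclass(frozen=True)
class MeanPath:
    """Resampled average trajectory with arc-length grid and unit tangents."""

    points: np.ndarray   # (M, 3) mm
    s: np.ndarray        # (M,) arc length, mm, s[0] = 0
    tangents: np.ndarray  # (M, 3) unit vectors

    @property
    def total_length(self) -> float:
        return float(self.s[-1])

    def __len__(self) -> int:
        return len(self.s)


@dataclass(frozen=True)
class PlaneCrossing:
    """Trial intersections with the plane orthogonal to the mean path at one
    grid index; trials that never cross are listed in ``missing``."""

    s_index: int
    q: np.ndarray               # (k, 3) crossing points on P(s)
    trial_ids: tuple[str, ...]  # ids of the k trials that cross
    missing: tuple[str, ...]    # ids of trials with no crossing

    @property
    def n_used(self) -> int:
        return len(self.q)


def path_from_points(points: np.ndarray) -> MeanPath:
    """Build a MeanPath (arc lengths + normalised central-difference tangents)
    from an ordered point sequence."""
    points = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    if np.any(seg <= 0):
        raise ValidationError("path has repeated consecutive points")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    tangents = np.gradient(points, s, axis=0)
    norms = np.linalg.norm(tangents, axis=1, keepdims=True)
    return MeanPath(points, s, tangents / norms)


def mean_path(ensemble: TrialEnsemble, M: int = DEFAULT_GRID_M) -> MeanPath:
    """Average trajectory: each trial resampled to M points by normalised arc
    length, then averaged pointwise; tangents by central differences
    (one-sided at the endpoints)."""
    if M < 2:
        raise ValueError(f"M must be >= 2, got {M}")
    stack = []
    for tr in ensemble:
        if tr.total_length <= 0:
            raise ValidationError(f"trial {tr.trial_id!r} is degenerate (zero arc length)")
        stack.append(resample(tr, M, mode="arclength").points)
    return path_from_points(np.mean(stack, axis=0))


def _segment_crossings(points: np.ndarray, p: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """All intersection points of one polyline with the plane through p with
    the given normal, ordered along the polyline.  Returns (k, 3)."""
    d = (points - p) @ normal
    hits = []
    on_plane = np.where(d == 0.0)[0]
    sign_change = np.where(d[:-1] * d[1:] < 0.0)[0]
    events = sorted([(float(i), points[i]) for i in on_plane]
                    + [(i + 0.5, None) for i in sign_change], key=lambda e: e[0])
    for pos, pt in events:
        if pt is None:
            i = int(pos)
            w = d[i] / (d[i] - d[i + 1])
            pt = points[i] + w * (points[i + 1] - points[i])
        hits.append(pt)
    return np.array(hits) if hits else np.empty((0, 3))


def plane_crossings(ensemble: TrialEnsemble, path: MeanPath, s_index: int) -> PlaneCrossing:
    """Intersect every trial with P(s): each polyline segment whose endpoints
    sit on opposite sides of the plane contributes a candidate (linear
    interpolation); the candidate nearest the plane centre p(s) is kept
    (earliest along the trial on ties).  Trials with no crossing go to
    ``missing``; if no trial crosses at all, a CrossingError is raised."""
    p = path.points[s_index]
    normal = path.tangents[s_index]
    q, used, missing = [], [], []
    for tr in ensemble:
        hits = _segment_crossings(tr.points, p, normal)
        if len(hits) == 0:
            missing.append(tr.trial_id)
            continue
        dist = np.linalg.norm(hits - p, axis=1)
        q.append(hits[int(np.argmin(dist))])  # argmin returns the earliest on ties
        used.append(tr.trial_id)
    if not q:
        raise CrossingError(f"no trial crosses the plane at s index {s_index}")
    return PlaneCrossing(s_index, np.array(q), tuple(used), tuple(missing))


def write_crossings(ensemble: TrialEnsemble, path: MeanPath, out: str | Path) -> None:
    """Diagnostic dump of all plane crossings as CSV (s, trial, qx, qy, qz)."""
    rows = []
    for i in range(len(path)):
        try:
            cr = plane_crossings(ensemble, path, i)
        except CrossingError:
            continue
        for tid, pt in zip(cr.trial_ids, cr.q):
            rows.append((path.s[i], tid, *pt))
    pd.DataFrame(rows, columns=["s", "trial", "qx", "qy", "qz"]).to_csv(out, index=False)
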