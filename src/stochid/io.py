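"""Reading, validating, resampling and writing trial trajectories.

A trial is an ordered sequence of time-stamped 3D end-effector positions.
Internally everything is millimetres and seconds.  The on-disk dialect is a
plain CSV with header ``trial,t,x,y,z`` — either one long file with a
``trial`` column, or one file per trial (in which case the ``trial`` column
is optional and the file stem names the trial).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EnsembleError, SchemaError, ValidationError

DEFAULT_SCHEMA: Mapping[str, str] = {"trial": "trial", "t": "t", "x": "x", "y": "y", "z": "z"}


@dataclass(frozen=True)
class Trajectory:
    """One trial: strictly increasing time stamps (s) and 3D points (mm)."""

    trial_id: str
    t: np.ndarray
    points: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "points", pts)
        if t.ndim != 1 or pts.ndim != 2 or pts.shape[1] != 3:
            raise ValidationError(f"trial {self.trial_id!r}: expected t (m,) and points (m,3)")
        if len(t) < 2:
            raise ValidationError(f"trial {self.trial_id!r}: needs at least 2 samples")
        if len(t) != len(pts):
            raise ValidationError(f"trial {self.trial_id!r}: {len(t)} time stamps vs {len(pts)} points")
        if not (np.isfinite(t).all() and np.isfinite(pts).all()):
            raise ValidationError(f"trial {self.trial_id!r}: non-finite values")
        bad = np.where(np.diff(t) <= 0)[0]
        if bad.size:
            raise ValidationError(
                f"trial {self.trial_id!r}: time not strictly increasing at row {bad[0] + 1}"
            )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def arc_length(self) -> np.ndarray:
        """Cumulative polyline arc length (mm), starting at 0."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def total_length(self) -> float:
        return float(self.arc_length[-1])


@dataclass(frozen=True)
class TrialEnsemble:
    """The unit of analysis: n repeated trials of one subject x condition."""

    subject: str
    condition: str
    trials: Sequence[Trajectory] = field(default_factory=list)

    def __post_init__(self) -> None:
        object.__setattr__(self, "trials", list(self.trials))
        if len(self.trials) < 2:
            raise EnsembleError(
                f"ensemble {self.subject}/{self.condition}: needs >= 2 trials, got {len(self.trials)}"
            )

    @property
    def n(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)


def _trials_from_frame(df: pd.DataFrame, schema: Mapping[str, str], where: str,
                       default_trial: str | None = None) -> list[Trajectory]:
    cols = {k: schema.get(k, k) for k in ("t", "x", "y", "z")}
    for k, c in cols.items():
        if c not in df.columns:
            raise SchemaError(f"{where}: column {c!r} (for {k!r}) not found; have {list(df.columns)}")
    trial_col = schema.get("trial", "trial")
    if trial_col in df.columns:
        groups = [(str(g), sub) for g, sub in df.groupby(trial_col, sort=False)]
    elif default_trial is not None:
        groups = [(default_trial, df)]
    else:
        raise SchemaError(f"{where}: column {trial_col!r} (for 'trial') not found")
    out = []
    for trial_id, sub in groups:
        pts = sub[[cols["x"], cols["y"], cols["z"]]].to_numpy(dtype=float)
        out.append(Trajectory(trial_id, sub[cols["t"]].to_numpy(dtype=float), pts))
    return out


def read_trials(source: str | Path, schema: Mapping[str, str] | None = None,
                subject: str = "subject", condition: str = "condition",
                unit_scale: float = 1.0) -> TrialEnsemble:
    """Read a trial ensemble from a long-format CSV file or a directory of
    per-trial CSV files.

    Parameters
    ----------
    source
        A CSV file (columns ``trial,t,x,y,z``) or a directory whose ``*.csv``
        files each hold one trial (``t,x,y,z``; file stem = trial id).
    schema
        Optional column remapping, e.g. ``{"x": "px"}``.
    unit_scale
        Multiplier applied to coordinates to bring them to millimetres.
    """
    schema = dict(DEFAULT_SCHEMA, **(schema or {}))
    source = Path(source)
    if not source.exists():
        raise FileNotFoundError(source)
    trials: list[Trajectory] = []
    if source.is_dir():
        files = sorted(source.glob("*.csv"))
        if not files:
            raise EnsembleError(f"{source}: no CSV files found")
        for f in files:
            trials.extend(_trials_from_frame(pd.read_csv(f), schema, str(f), default_trial=f.stem))
    else:
        trials = _trials_from_frame(pd.read_csv(source), schema, str(source))
    if unit_scale != 1.0:
        trials = [Trajectory(tr.trial_id, tr.t, tr.points * unit_scale) for tr in trials]
    if len(trials) < 2:
        raise EnsembleError(f"{source}: found {len(trials)} trial(s), need >= 2")
    return TrialEnsemble(subject, condition, trials)


def write_trials(ensemble: TrialEnsemble, path: str | Path) -> None:
    """Write an ensemble as one long CSV with header ``trial,t,x,y,z``."""
    frames = []
    for tr in ensemble:
        frames.append(pd.DataFrame({
            "trial": tr.trial_id, "t": tr.t,
            "x": tr.points[:, 0], "y": tr.points[:, 1], "z": tr.points[:, 2],
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def resample(traj: Trajectory, M: int, mode: str = "arclength") -> Trajectory:
    """Resample a trial at M equispaced parameters.

    ``mode="arclength"`` places the M samples at equal increments of
    cumulative polyline arc length; ``mode="time"`` at equal time steps.
    Interior points are linearly interpolated; both endpoints are kept
    exactly.
    """
    if M < 2:
        raise ValueError(f"M must be >= 2, got {M}")
    if mode == "arclength":
        param = traj.arc_length
        if param[-1] <= 0:
            raise ValidationError(f"trial {traj.trial_id!r}: zero total arc length")
    elif mode == "time":
        param = traj.t
    else:
        raise ValueError(f"unknown resampling mode {mode!r}")
    grid = np.linspace(param[0], param[-1], M)
    pts = np.column_stack([np.interp(grid, param, traj.points[:, i]) for i in range(3)])
    t = np.interp(grid, param, traj.t)
    # exact endpoint preservation (interp is exact there, but be explicit)
    pts[0], pts[-1] = traj.points[0], traj.points[-1]
    t[0], t[-1] = traj.t[0], traj.t[-1]
    t = _strictify(t)
    return Trajectory(traj.trial_id, t, pts)


def smooth(traj: Trajectory, window: int) -> Trajectory:
    """Optional centred moving-average smoothing of the points (odd window).

    Off by default everywhere; provided for noisy recordings.  Endpoints are
    kept exact.
    """
    if window <= 1:
        return traj
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    kernel = np.ones(window) / window
    half = window // 2
    padded = np.pad(traj.points, ((half, half), (0, 0)), mode="edge")
    pts = np.column_stack(
        [np.convolve(padded[:, i], kernel, mode="valid") for i in range(3)]
    )
    pts[0], pts[-1] = traj.points[0], traj.points[-1]
    return Trajectory(traj.trial_id, traj.t, pts)


def _strictify(t: np.ndarray) -> np.ndarray:
    """Nudge repeated interpolated time stamps so time stays strictly increasing."""
    if np.all(np.diff(t) > 0):
        return t
    eps = max(1e-12, float(t[-1] - t[0]) * 1e-12)
    out = t.copy()
    for i in range(1, len(out)):
        if out[i] <= out[i - 1]:
            out[i] = out[i - 1] + eps
    return out
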