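"""Speed profiles along the movement and per-phase peak extraction.

Speeds are computed per trial by central differences of position over time,
mapped onto a common normalised-arc-length grid u ∈ [0, 1], and averaged
across trials.  Phase peaks (e.g. reach / transport / return) are maxima of
the mean profile within caller-supplied u intervals; a helper detects
candidate phase boundaries as local speed minima.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import argrelmin

from .errors import ValidationError
from .io import TrialEnsemble


@dataclass(frozen=True)
class SpeedProfile:
    u: np.ndarray             # (M,) normalised arc length
    mean_speed: np.ndarray    # (M,) mm/s, averaged across trials
    trial_speeds: np.ndarray  # (n, M) mm/s

    def write(self, out: str | Path) -> None:
        pd.DataFrame({"u": self.u, "speed_mm_s": self.mean_speed}).to_csv(out, index=False)


@dataclass(frozen=True)
class PhasePeak:
    u: float        # location of the maximum (earliest on ties)
    speed: float    # mm/s


def speed_profile(ensemble: TrialEnsemble, M: int = 200) -> SpeedProfile:
    """Mean speed vs normalised arc length across the ensemble's trials."""
    if M < 2:
        raise ValueError(f"M must be >= 2, got {M}")
    u = np.linspace(0.0, 1.0, M)
    rows = []
    for tr in ensemble:
        if len(tr) < 3:
            raise ValidationError(f"trial {tr.trial_id!r}: needs >= 3 samples for speed")
        vel = np.gradient(tr.points, tr.t, axis=0)
        speed = np.linalg.norm(vel, axis=1)
        arc = tr.arc_length
        if arc[-1] <= 0:
            raise ValidationError(f"trial {tr.trial_id!r} is degenerate (zero arc length)")
        rows.append(np.interp(u, arc / arc[-1], speed))
    trial_speeds = np.array(rows)
    return SpeedProfile(u, trial_speeds.mean(axis=0), trial_speeds)


def phase_peaks(profile: SpeedProfile,
                phase_bounds: Sequence[tuple[float, float]]) -> list[PhasePeak]:
    """Maximum of the mean profile within each [a, b] ⊆ [0, 1] interval.

    Intervals must be non-empty; on a tie the earliest u wins (np.argmax).
    """
    peaks = []
    for a, b in phase_bounds:
        if not (0.0 <= a < b <= 1.0):
            raise ValueError(f"invalid phase interval [{a}, {b}]")
        mask = (profile.u >= a) & (profile.u <= b)
        if not mask.any():
            raise ValueError(f"phase interval [{a}, {b}] contains no grid points")
        seg = profile.mean_speed[mask]
        i = int(np.argmax(seg))
        peaks.append(PhasePeak(float(profile.u[mask][i]), float(seg[i])))
    return peaks


def speed_minima(profile: SpeedProfile, order: int = 5) -> np.ndarray:
    """Helper: u locations of local minima of the mean speed — candidate
    phase boundaries.  Not part of the phase-peak contract; segmentation
    is ultimately the caller's choice."""
    idx = argrelmin(profile.mean_speed, order=order)[0]
    return profile.u[idx]


def minimum_jerk_positions(L: float, T: float, t: np.ndarray,
                           direction: np.ndarray = (1.0, 0.0, 0.0),
                           origin: np.ndarray = (0.0, 0.0, 0.0)) -> np.ndarray:
    """Straight-line minimum-jerk displacement profile: the classic quintic
    x(τ) = L·(10τ³ − 15τ⁴ + 6τ⁵), τ = t/T, with peak speed 15L/(8T) at τ=½."""
    tau = np.clip(np.asarray(t, dtype=float) / T, 0.0, 1.0)
    disp = L * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    return np.asarray(origin, dtype=float) + disp[:, None] * direction
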