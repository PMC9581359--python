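"""Difficulty indices: the cumulative stochastic ID and classical baselines.

The stochastic Index of Difficulty accumulates the reciprocal stochastic
width along the average trajectory,

    ID_obs(s*, φ) = ∫₀^{s*} ds / W_obs(s, φ),

a dimensionless, non-decreasing measure of the difficulty *experienced* over
a repetitive movement: narrow dispersion (low flexibility) and long paths
both raise it.  No logarithm is applied — unlike the classical Fitts (bits)
formulations, it is a pure ratio integral.

Classical deterministic baselines are provided for comparison:

* Fitts:      ID = log2(2D / W)
* MacKenzie:  ID = log2(D / W + 1)
* trajectory: ID_t = ∫ ds / W_t(s)  for a prescribed target-width profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .errors import ProfileError
from .width import WidthProfile

DEFAULT_W_MIN = 1e-6  # mm; below this the integral is treated as divergent


@dataclass(frozen=True)
class DifficultyProfile:
    """Cumulative ID_obs(s*, φ) on the arc-length grid; ID[0] = 0."""

    s: np.ndarray
    ID: np.ndarray
    phi: float | None

    @property
    def total(self) -> float:
        """ID_obs at s* = |t̄| (the full movement)."""
        return float(self.ID[-1])

    def write(self, out: str | Path, W: np.ndarray | None = None) -> None:
        cols = {"s_mm": self.s}
        if W is not None:
            cols["W_mm"] = W
        cols["ID"] = self.ID
        pd.DataFrame(cols).to_csv(out, index=False)


def _cumulative_inverse_width(s: np.ndarray, W: np.ndarray, w_min: float) -> np.ndarray:
    bad = np.where(~(W > w_min))[0]
    if bad.size:
        raise ProfileError(
            f"width {W[bad[0]]:.3g} mm <= w_min={w_min:g} mm at s={s[bad[0]]:.3g} mm: "
            "difficulty integral diverges")
    return cumulative_trapezoid(1.0 / W, s, initial=0.0)


def id_obs(width: WidthProfile, w_min: float = DEFAULT_W_MIN) -> DifficultyProfile:
    """Cumulative trapezoid of 1/W_obs over the shared arc-length grid."""
    ID = _cumulative_inverse_width(width.s, width.W, w_min)
    return DifficultyProfile(width.s.copy(), ID, width.phi)


def id_t(s: np.ndarray, widths: np.ndarray, w_min: float = DEFAULT_W_MIN) -> DifficultyProfile:
    """Deterministic trajectory ID for a user-supplied target-width profile
    W_t(s) on a grid; same integral contract as :func:`id_obs`."""
    s = np.asarray(s, dtype=float)
    widths = np.asarray(widths, dtype=float)
    if s.shape != widths.shape or s.ndim != 1:
        raise ValueError("s and widths must be 1D arrays of equal length")
    ID = _cumulative_inverse_width(s, widths, w_min)
    return DifficultyProfile(s.copy(), ID, None)


def fitts_id(D: float, W: float, variant: str = "fitts") -> float:
    """Classical point-to-point Index of Difficulty, in bits."""
    if W <= 0:
        raise ValueError(f"target width must be > 0, got {W}")
    if D < 0:
        raise ValueError(f"distance must be >= 0, got {D}")
    if variant == "fitts":
        if D <= 0:
            raise ValueError("Fitts variant requires D > 0")
        return float(np.log2(2.0 * D / W))
    if variant == "mackenzie":
        return float(np.log2(D / W + 1.0))
    raise ValueError(f"unknown variant {variant!r}")
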