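"""Stochastic width: per-section PCA ellipses, confidence scaling, mean
radius, and the width profile W_obs(s, φ).

At each arc length ``s`` the n crossing points on the orthogonal plane are
summarised by a 2D PCA: standard deviations σϵ ≥ ση along the in-plane
principal axes (the third axis, along the tangent, carries no dispersion by
construction).  Under a bivariate-normal model the φ-level dispersion region
is the ellipse with semi-axes ``√c²·σϵ`` and ``√c²·ση``, where the squared
scale c² depends on the sampling regime:

* population known (or large sample): c² is the squared Mahalanobis distance,
  the χ² quantile with ν1 = 2 degrees of freedom at φ;
* small sample of n trials (Hotelling regime):
  ``c² = T² = ((n−1)·ν1) / (n·(n−ν1)) · F(ν1, n−ν1, φ)``.

The ellipse is converted to an equivalent circle through the mean radius

    r_mean(s, φ) = (1/2π) ∫₀^{2π} √(c²σϵ²cos²θ + c²ση²sin²θ) dθ

and the stochastic width is its diameter, W_obs(s, φ) = 2·r_mean(s, φ).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import CrossingError, InsufficientSamplesError, ProfileError
from .geometry import MeanPath, PlaneCrossing, plane_crossings
from .io import TrialEnsemble

NU1 = 2  # in-plane dimensionality of the dispersion
DEFAULT_PHI = 0.95
DEFAULT_QUADRATURE_POINTS = 256


@dataclass(frozen=True)
class SectionStats:
    """PCA summary of one plane's crossing points."""

    s: float              # arc length, mm
    sigma_eps: float      # SD along first principal axis, mm
    sigma_eta: float      # SD along second principal axis, mm
    axes: np.ndarray      # (2, 3) orthonormal in-plane axes for ϵ, η
    n_used: int


@dataclass(frozen=True)
class ConfidenceScale:
    """Squared scale c² turning sample SDs into φ-level ellipse semi-axes."""

    phi: float
    nu1: int
    nu2: int
    c2: float
    regime: str  # "hotelling" | "chi2"

    @property
    def c(self) -> float:
        return float(np.sqrt(self.c2))


@dataclass(frozen=True)
class WidthProfile:
    """W_obs(s, φ) on the mean-path grid; invalid planes were interpolated."""

    s: np.ndarray
    W: np.ndarray
    phi: float
    valid: np.ndarray            # bool per grid point
    sections: tuple = ()         # SectionStats or None per grid point

    def write(self, out: str | Path) -> None:
        pd.DataFrame({"s_mm": self.s, "W_mm": self.W,
                      "valid": self.valid.astype(int)}).to_csv(out, index=False)


def c_squared(n: int, phi: float, population_known: bool = False) -> ConfidenceScale:
    """Squared confidence scale c² at probability level φ for n trials.

    ``population_known=True`` selects the Mahalanobis/χ² regime; otherwise the
    small-sample Hotelling T² formula is used, which requires n > 2.
    """
    if not 0.0 < phi < 1.0:
        raise ValueError(f"phi must be in (0, 1), got {phi}")
    if population_known:
        c2 = float(sps.chi2.ppf(phi, NU1))
        return ConfidenceScale(phi, NU1, max(int(n) - NU1, 0), c2, "chi2")
    n = int(n)
    if n <= NU1:
        raise ValueError(f"Hotelling regime needs n > {NU1} trials, got {n}")
    nu2 = n - NU1
    f_crit = float(sps.f.ppf(phi, NU1, nu2))
    c2 = (n - 1) * NU1 / (n * nu2) * f_crit
    return ConfidenceScale(phi, NU1, nu2, c2, "hotelling")


def _in_plane_basis(tangent: np.ndarray) -> np.ndarray:
    """Two orthonormal vectors spanning the plane orthogonal to the tangent."""
    ref = np.zeros(3)
    ref[int(np.argmin(np.abs(tangent)))] = 1.0
    e1 = ref - (ref @ tangent) * tangent
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(tangent, e1)
    return np.vstack([e1, e2])


def plane_pca(crossing: PlaneCrossing, tangent: np.ndarray,
              center_mode: str = "centroid", center: np.ndarray | None = None,
              s: float = 0.0) -> SectionStats:
    """2D PCA of the crossing points in the plane orthogonal to ``tangent``.

    ``center_mode="centroid"`` (default) centres on the crossings' own mean;
    ``"mean_path_point"`` takes second moments about the supplied mean-path
    point ``center``.  Covariance uses the n−1 denominator.
    """
    pts = np.asarray(crossing.q, dtype=float)
    if len(pts) < 2:
        raise InsufficientSamplesError(
            f"plane at index {crossing.s_index}: {len(pts)} crossing(s), need >= 2")
    tangent = np.asarray(tangent, dtype=float)
    basis = _in_plane_basis(tangent)
    if center_mode == "centroid":
        c3 = pts.mean(axis=0)
    elif center_mode == "mean_path_point":
        if center is None:
            raise ValueError("center_mode='mean_path_point' requires the center point")
        c3 = np.asarray(center, dtype=float)
    else:
        raise ValueError(f"unknown center_mode {center_mode!r}")
    coords = (pts - c3) @ basis.T                       # (n, 2)
    cov = coords.T @ coords / (len(pts) - 1)
    evals, evecs = np.linalg.eigh(cov)                  # ascending
    order = [1, 0]
    sig = np.sqrt(np.clip(evals[order], 0.0, None))
    axes = (evecs[:, order].T @ basis)                  # rows: ϵ, η in 3D
    return SectionStats(float(s), float(sig[0]), float(sig[1]), axes, len(pts))


def mean_radius(sigma_eps: float, sigma_eta: float, c2: float,
                n_theta: int = DEFAULT_QUADRATURE_POINTS) -> float:
    """Mean radius of the φ-level ellipse with semi-axes √c²·σϵ, √c²·ση.

    The periodic integrand is handled by an n_theta-point trapezoid rule
    (spectrally accurate for a smooth ellipse); the circular and fully
    degenerate limits use their closed forms:

    * σϵ = ση = σ   →  r_mean = √c²·σ
    * ση = 0        →  r_mean = (2/π)·√c²·σϵ   (the |cos| integral)
    """
    if sigma_eps < 0 or sigma_eta < 0 or c2 <= 0:
        raise ValueError("sigma_eps, sigma_eta must be >= 0 and c2 > 0")
    if sigma_eta > sigma_eps:
        sigma_eps, sigma_eta = sigma_eta, sigma_eps
    c = float(np.sqrt(c2))
    if sigma_eps == sigma_eta:
        return c * sigma_eps
    if sigma_eta == 0.0:
        return (2.0 / np.pi) * c * sigma_eps
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    r = c * np.sqrt((sigma_eps * np.cos(theta)) ** 2 + (sigma_eta * np.sin(theta)) ** 2)
    return float(r.mean())


def width_profile(ensemble: TrialEnsemble, path: MeanPath, phi: float = DEFAULT_PHI,
                  regime: str = "hotelling", center_mode: str = "centroid",
                  quadrature_points: int = DEFAULT_QUADRATURE_POINTS,
                  max_invalid_frac: float = 0.5) -> WidthProfile:
    """W_obs(s, φ) = 2·r_mean(s, φ) on every plane of the mean-path grid.

    A plane is *valid* when at least ν1+1 trials cross it and the resulting
    width is positive; invalid planes are filled by linear interpolation from
    their valid neighbours and flagged.  More than ``max_invalid_frac``
    invalid planes aborts with a ProfileError (ensemble too degenerate).
    The confidence scale uses each plane's own crossing count.
    """
    if regime not in ("hotelling", "chi2"):
        raise ValueError(f"unknown regime {regime!r}")
    M = len(path)
    W = np.full(M, np.nan)
    valid = np.zeros(M, dtype=bool)
    sections: list[SectionStats | None] = [None] * M
    scale_cache: dict[int, ConfidenceScale] = {}
    for i in range(M):
        try:
            cr = plane_crossings(ensemble, path, i)
        except CrossingError:
            continue
        if cr.n_used < NU1 + 1:
            continue
        st = plane_pca(cr, path.tangents[i], center_mode=center_mode,
                       center=path.points[i], s=float(path.s[i]))
        sections[i] = st
        if cr.n_used not in scale_cache:
            scale_cache[cr.n_used] = c_squared(cr.n_used, phi,
                                               population_known=(regime == "chi2"))
        w = 2.0 * mean_radius(st.sigma_eps, st.sigma_eta,
                              scale_cache[cr.n_used].c2, quadrature_points)
        if w > 0.0:
            W[i] = w
            valid[i] = True
    n_invalid = int((~valid).sum())
    if n_invalid > max_invalid_frac * M:
        raise ProfileError(
            f"{n_invalid}/{M} planes invalid (need <= {max_invalid_frac:.0%}): "
            "ensemble too degenerate for a width profile")
    if n_invalid:
        W[~valid] = np.interp(path.s[~valid], path.s[valid], W[valid])
    return WidthProfile(path.s.copy(), W, phi, valid, tuple(sections))
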