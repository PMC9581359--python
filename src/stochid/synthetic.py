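"""Synthetic trial-ensemble generator.

Emulates the statistical structure the width model assumes: a known smooth
three-phase mean path (reach → transport → return over a table-top task:
grasp point 300 mm from the table edge, release point 500 mm symmetrically
opposite) with prescribed anisotropic in-plane Gaussian dispersion.  Within
each phase the dispersion is bell-shaped with minima at the task events
(grasp, release, final placement), where end-effector accuracy is required;
bell amplitudes scale with relative phase length (longer travel, more
explored configurations).  Because the dispersion profile is known exactly,
every downstream stage — crossings, PCA, confidence scaling, width,
difficulty — can be checked against closed-form predictions.

Noise drawn along the path is smoothed with a Gaussian kernel (correlation
length a fixed fraction of the path) and renormalised so that at every
sample the across-trial distribution is exactly N(0, σ(u)²) along each
in-plane principal axis; uncorrelated noise would produce non-physical
jagged trials and break crossing continuity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import ValidationError
from .geometry import MeanPath, path_from_points
from .io import Trajectory, TrialEnsemble

# Task layout (mm): table edge along x at y=0, grasp/release on the object
# line y=300 (300 mm beyond the edge), 500 mm apart; the hand rest sits
# 200 mm in front of that line so the three phases are not collinear.
DEFAULT_WAYPOINTS = np.array([
    [0.0, 100.0, 0.0],     # start (hand rest)
    [250.0, 300.0, 0.0],   # grasp
    [-250.0, 300.0, 0.0],  # release (500 mm from grasp)
    [0.0, 100.0, 0.0],     # final placement = start
])

SigmaProfile = Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]]


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for one simulated subject x condition.

    ``sigma_profile``, if given, maps normalised arc length u ∈ [0,1] to
    (σϵ(u), ση(u)) in mm and overrides the default per-phase bells.
    """

    waypoints: np.ndarray = field(default_factory=lambda: DEFAULT_WAYPOINTS.copy())
    n: int = 7                    # trials per condition
    m_samples: int = 400          # samples per trial
    lift: float = 60.0            # mid-phase hand lift, mm
    sigma_eps_max: float = 8.0    # peak SD along the major in-plane axis, mm
    sigma_eta_max: float = 5.0    # peak SD along the minor in-plane axis, mm
    sigma_min: float = 1.0        # SD floor at accuracy events, mm
    amplitude: float = 1.0        # overall dispersion scale (condition knob)
    sigma_profile: SigmaProfile | None = None
    speed_model: str = "minjerk"  # "minjerk" | "constant"
    mean_speed: float = 450.0     # phase mean speed, mm/s
    noise_corr: float = 0.1       # noise correlation length, fraction of path
    seed: int = 0

    def __post_init__(self) -> None:
        wp = np.asarray(self.waypoints, dtype=float)
        object.__setattr__(self, "waypoints", wp)
        if wp.ndim != 2 or wp.shape[1] != 3 or len(wp) < 2:
            raise ValidationError("waypoints must be a (K>=2, 3) array")
        if self.n < 2:
            raise ValidationError(f"n must be >= 2, got {self.n}")
        for name in ("sigma_eps_max", "sigma_eta_max", "sigma_min", "amplitude"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.speed_model not in ("minjerk", "constant"):
            raise ValidationError(f"unknown speed_model {self.speed_model!r}")


# Named condition presets emulating manipulated objects: they differ only
# in overall dispersion amplitude (grasp types limiting flexibility);
# no claim of physical fidelity.
OBJECT_PRESETS: dict[str, float] = {
    "tennis_ball": 1.00,
    "ellipsoid_soft": 1.18,
    "ellipsoid_stiff": 1.15,
    "bottle_half": 0.62,
    "bottle_full": 0.60,
}


def object_preset(name: str, **overrides) -> GeneratorSpec:
    """GeneratorSpec for a named condition preset (see OBJECT_PRESETS)."""
    if name not in OBJECT_PRESETS:
        raise KeyError(f"unknown preset {name!r}; options: {sorted(OBJECT_PRESETS)}")
    return GeneratorSpec(amplitude=OBJECT_PRESETS[name], **overrides)


def make_mean_path(spec: GeneratorSpec, density: int = 2000) -> MeanPath:
    """Smooth path through the spec's waypoints, arc-length parametrised.

    A natural cubic spline is fit through the waypoints plus one lifted
    midpoint per segment (hand raised ``lift`` mm in z mid-phase), over a
    chord-length parameter; it is sampled on a dense grid that includes the
    exact waypoint parameters, so the returned polyline passes through every
    waypoint exactly.
    """
    wp = spec.waypoints
    gaps = np.linalg.norm(np.diff(wp, axis=0), axis=1)
    if np.any(gaps <= 0):
        raise ValidationError("coincident consecutive waypoints")
    knots = [wp[0]]
    for i in range(len(wp) - 1):
        mid = 0.5 * (wp[i] + wp[i + 1]) + np.array([0.0, 0.0, spec.lift])
        knots.extend([mid, wp[i + 1]])
    knots = np.array(knots)
    chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(knots, axis=0), axis=1))])
    spline = CubicSpline(chord, knots, axis=0)
    params = np.union1d(np.linspace(0.0, chord[-1], density), chord)
    return path_from_points(spline(params))


def event_positions(path: MeanPath, spec: GeneratorSpec) -> np.ndarray:
    """Normalised arc-length positions u of the spec's waypoints on the path
    (nearest path sample; first and last pinned to 0 and 1)."""
    u = np.empty(len(spec.waypoints))
    for i, w in enumerate(spec.waypoints):
        j = int(np.argmin(np.linalg.norm(path.points - w, axis=1)))
        u[i] = path.s[j] / path.total_length
    u[0], u[-1] = 0.0, 1.0
    return np.maximum.accumulate(u)


def bell_sigma_profile(events: np.ndarray, spec: GeneratorSpec) -> SigmaProfile:
    """Default dispersion profile: within each phase [u_i, u_{i+1}] a
    half-sine bell rising from the floor ``sigma_min`` at the events to a
    peak scaled by the phase's relative length (longest phase reaches
    ``amplitude * sigma_*_max``)."""
    events = np.asarray(events, dtype=float)
    spans = np.diff(events)
    rel = spans / spans.max() if spans.max() > 0 else np.ones_like(spans)

    def profile(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        u = np.clip(np.asarray(u, dtype=float), 0.0, 1.0)
        idx = np.clip(np.searchsorted(events, u, side="right") - 1, 0, len(spans) - 1)
        x = (u - events[idx]) / np.where(spans[idx] > 0, spans[idx], 1.0)
        bell = np.sin(np.pi * np.clip(x, 0.0, 1.0)) * rel[idx]
        a = spec.amplitude
        s_eps = a * (spec.sigma_min + (spec.sigma_eps_max - spec.sigma_min) * bell)
        s_eta = a * (spec.sigma_min + (spec.sigma_eta_max - spec.sigma_min) * bell)
        return s_eps, s_eta

    return profile


def _rotation_minimizing_frame(points: np.ndarray, tangents: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """In-plane frame (e1, e2) transported along the path by the
    double-reflection method — no sudden axis flips between samples."""
    m = len(points)
    e1 = np.empty((m, 3))
    ref = np.zeros(3)
    ref[int(np.argmin(np.abs(tangents[0])))] = 1.0
    v = ref - (ref @ tangents[0]) * tangents[0]
    e1[0] = v / np.linalg.norm(v)
    for i in range(m - 1):
        v1 = points[i + 1] - points[i]
        c1 = v1 @ v1
        if c1 == 0.0:
            e1[i + 1] = e1[i]
            continue
        rL = e1[i] - (2.0 / c1) * (v1 @ e1[i]) * v1
        tL = tangents[i] - (2.0 / c1) * (v1 @ tangents[i]) * v1
        v2 = tangents[i + 1] - tL
        c2 = v2 @ v2
        r = rL if c2 == 0.0 else rL - (2.0 / c2) * (v2 @ rL) * v2
        r = r - (r @ tangents[i + 1]) * tangents[i + 1]
        e1[i + 1] = r / np.linalg.norm(r)
    e2 = np.cross(tangents, e1)
    return e1, e2


def _smooth_unit_noise(rng: np.random.Generator, m: int, corr_samples: float) -> np.ndarray:
    """White Gaussian noise smoothed with a Gaussian kernel and pointwise
    renormalised so each sample is exactly N(0, 1) across realisations."""
    white = rng.standard_normal(m)
    if corr_samples <= 0:
        return white
    half = min(int(np.ceil(4 * corr_samples)), (m - 1) // 2)
    x = np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (x / corr_samples) ** 2)
    num = np.convolve(white, kernel, mode="same")
    var = np.convolve(np.ones(m), kernel**2, mode="same")
    return num / np.sqrt(var)


def _minjerk_tau(x: np.ndarray) -> np.ndarray:
    """Invert the minimum-jerk displacement fraction x(τ)=10τ³−15τ⁴+6τ⁵."""
    tau_grid = np.linspace(0.0, 1.0, 2001)
    x_grid = 10 * tau_grid**3 - 15 * tau_grid**4 + 6 * tau_grid**5
    return np.interp(np.clip(x, 0.0, 1.0), x_grid, tau_grid)


def _timestamps(path_s: np.ndarray, events: np.ndarray, spec: GeneratorSpec) -> np.ndarray:
    total = path_s[-1]
    u = path_s / total
    if spec.speed_model == "constant":
        return path_s / spec.mean_speed
    t = np.empty_like(u)
    t0 = 0.0
    spans = np.diff(events)
    L_max = spans.max() * total
    for i in range(len(events) - 1):
        span = spans[i]
        L = span * total
        # sublinear duration growth with distance: longer phases are faster
        # on average, so their speed bells peak higher (peak = 15L/8T)
        T = np.sqrt(L * L_max) / spec.mean_speed
        mask = (u >= events[i]) & (u <= events[i + 1])
        x = (u[mask] - events[i]) / span
        t[mask] = t0 + _minjerk_tau(x) * T
        t0 += T
    return t


def simulate_trials(path: MeanPath, spec: GeneratorSpec,
                    subject: str = "sim", condition: str = "default") -> TrialEnsemble:
    """Draw n trials around the mean path with the spec's dispersion.

    Each trial adds to every path sample an offset in the local orthogonal
    plane: smooth unit-variance noise along the transported in-plane axes,
    scaled by (σϵ(u), ση(u)).  Time stamps follow the speed model per phase.
    Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    # resample the (dense) path to the trial sampling density
    s_grid = np.linspace(0.0, path.total_length, spec.m_samples)
    pts = np.column_stack([np.interp(s_grid, path.s, path.points[:, i]) for i in range(3)])
    base = path_from_points(pts)
    u = base.s / base.total_length
    events = event_positions(path, spec)
    profile = spec.sigma_profile or bell_sigma_profile(events, spec)
    s_eps, s_eta = profile(u)
    e1, e2 = _rotation_minimizing_frame(base.points, base.tangents)
    t = _timestamps(base.s, events, spec)
    corr = spec.noise_corr * spec.m_samples
    trials = []
    for k in range(spec.n):
        a = _smooth_unit_noise(rng, spec.m_samples, corr) * s_eps
        b = _smooth_unit_noise(rng, spec.m_samples, corr) * s_eta
        trial_pts = base.points + a[:, None] * e1 + b[:, None] * e2
        trials.append(Trajectory(f"trial{k + 1:02d}", t, trial_pts))
    return TrialEnsemble(subject, condition, trials)


def simulate_ensemble(spec: GeneratorSpec, subject: str = "sim",
                      condition: str = "default") -> TrialEnsemble:
    """Convenience: build the mean path and simulate in one call."""
    return simulate_trials(make_mean_path(spec), spec, subject, condition)


def predicted_width(path: MeanPath, spec: GeneratorSpec, c2: float) -> np.ndarray:
    """Closed-form W_obs the generator implies on the path grid: twice the
    mean ellipse radius of the prescribed (σϵ(u), ση(u)) at scale c²."""
    from .width import mean_radius

    u = path.s / path.total_length
    profile = spec.sigma_profile or bell_sigma_profile(event_positions(path, spec), spec)
    s_eps, s_eta = profile(u)
    return np.array([2.0 * mean_radius(a, b, c2) for a, b in zip(s_eps, s_eta)])
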