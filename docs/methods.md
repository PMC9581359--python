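# Methods

This note documents the model implemented by `stochid`, the numerical and
design choices that were genuinely open, what the synthetic generator does
and does not emulate, and known limitations.

## Model

The unit of analysis is a *trial ensemble*: n repeated 3D end-effector
trajectories of one subject under one condition, in millimetres and seconds.

**Average trajectory.** Each trial is resampled to M points at equal
increments of its own normalised arc length (linear interpolation, endpoints
exact), and t̄ is the pointwise mean.  Arc-length correspondence — rather
than time correspondence — makes t̄ independent of trial-to-trial speed
fluctuations, which is the right invariance for a purely spatial difficulty
integral.  Tangents are central differences on the resampled mean (one-sided
at the endpoints), normalised to unit length.

**Plane crossings.** At each grid point s the plane P(s) passes through the
mean-path point p(s) with the tangent as normal.  For every trial, each
polyline segment whose endpoints have opposite signs of (x − p(s))·t̂(s) is a
candidate crossing, located by linear interpolation; when a trial crosses
several times (a curved path folding back within noise range of the plane),
the crossing nearest p(s) *within the plane* is kept, because the dispersion
model describes scatter about the local path, not distant branches.  Ties
break to the earliest crossing along the trial.  Trials that never change
sign are recorded as missing for that plane, not errors.

**Section PCA.** The crossings are expressed in an orthonormal in-plane
basis and summarised by a 2×2 covariance (n−1 denominator) and its
eigen-decomposition: σϵ ≥ ση, with the eigenvectors mapped back to 3D.  By
construction the third direction (along the tangent) carries no dispersion.
Centering defaults to the centroid of the crossings — standard PCA practice,
and the estimator of the local mean position that does not assume the
estimated mean path is exact.  Taking second moments about the mean-path
point p(s) instead is available (`center_mode="mean_path_point"`); the two
coincide asymptotically in n.

**Confidence scaling.** The φ-level ellipse semi-axes are √c²·σϵ and √c²·ση.
With the population known, c² is the χ² quantile at φ with ν1 = 2 degrees of
freedom (c² = 5.992 at φ = 0.95).  For a small sample of n trials the
Hotelling form is used:

    c² = T² = ((n−1)·ν1) / (n·(n−ν1)) · F(ν1, n−ν1, φ),

which for n = 7, φ = 0.95 gives F(2,5,0.95) = 5.786 and c² = 1.984.  Note
this T² *decreases* with n and does not approach the χ² value in the large-n
limit; the two regimes are therefore genuinely different models, not
asymptotic variants of one another.  The package implements both exactly as
defined and leaves the choice to the caller: `regime="hotelling"` is the
default (appropriate for the small per-condition trial counts the method
targets), `regime="chi2"` is selected explicitly.  Within a width profile
the scale is computed per plane from that plane's own crossing count.

**Mean radius and width.** The ellipse is converted to an equivalent circle
via the mean of its polar radius over θ ∈ [0, 2π].  The integrand is smooth
and periodic for any genuine ellipse, so a 256-point trapezoid rule is
spectrally accurate there; the two non-smooth limits are special-cased with
their closed forms (σϵ = ση: r = √c²σ; ση = 0: r = (2/π)√c²σϵ), keeping the
operation accurate to ~1e-9 everywhere relevant.  For extremely eccentric
ellipses (ση/σϵ below ~1e-3 but nonzero) the trapezoid rule degrades toward
O(h²); raise `quadrature_points` if that regime matters.  W_obs = 2·r_mean.

**Profile validity.** A plane is valid when at least ν1 + 1 = 3 trials cross
it and the resulting width is positive.  Invalid planes (typically the first
/ last planes, where trials may start past the plane, or degenerate sections)
are filled by linear interpolation between valid neighbours and flagged, so
the difficulty integrand stays defined without fabricating dispersion.  More
than 50% invalid planes aborts: the ensemble cannot support a width profile
(e.g. identical trials have zero dispersion everywhere).

**Difficulty.** ID_obs(s*, φ) is the cumulative trapezoid of 1/W_obs on the
plane grid — no resampling inside the integral, since W is only known at the
planes.  Any width at or below `w_min` (default 1e-6 mm) is an error: the
integral diverges.  No logarithm is applied; the index is a pure ratio
integral, dimensionless and invariant under spatial rescaling (length and
width scale together), which is what makes it comparable across tasks.  The
classical Fitts (`log2(2D/W)`), MacKenzie (`log2(D/W+1)`) and deterministic
trajectory (`∫ds/W_t`) indices are provided as baselines.

**Kinematics.** Speeds are central differences of position over time per
trial, mapped to normalised arc length and averaged.  Phase peaks are maxima
of the mean profile over caller-supplied u intervals (ties to the earliest
u).  Arc length, not time, indexes the profile, for consistency with the
width grid.  A helper reports local speed minima as candidate phase
boundaries, but segmentation is deliberately left to the caller (for
synthetic data the generator's event positions are the natural bounds).

**Statistics.** The comparison stage is a one-way repeated-measures ANOVA
(computed from its sums-of-squares decomposition; sphericity assumed, no
correction) on a complete subjects × conditions matrix, followed by all
pairwise two-sided paired t tests at the Bonferroni-corrected critical level
alpha / npairs (0.05/10 = 0.005 for five conditions, 0.05/3 ≈ 0.016 for
three).  Normality and sphericity checks are assumption diagnostics, not
part of this package; use standard tools on the matrix directly.  Exact-tie
degeneracies are handled explicitly: identical condition columns give F = 0
(p = 1), and a constant nonzero pairwise difference is flagged rather than
assigned a fabricated p.

## Synthetic generator

The generator emulates the structure of a seated table-top manipulation
task: grasp point 300 mm beyond the table edge, release point 500 mm away
symmetrically, three phases (reach, transport, return), n = 7 trials per
condition by default.  The hand-rest start is placed 200 mm in front of the
object line — a realistic seated rest position that also keeps the three
phases non-collinear (a start on the object line would fold all three phases
onto one line and make the orthogonal-plane construction degenerate).  The
mean path is a cubic spline through the waypoints plus one mid-phase point
lifted 60 mm in z (the hand arches over the table), giving reach ≈ 360 mm
and transport ≈ 500 mm, preserving the reach-shorter-than-transport ordering
of the task.

Dispersion: within each phase, (σϵ, ση) follow half-sine bells from a 1 mm
floor at the events (grasp / release / placement require accuracy) to peaks
of 8 mm / 5 mm scaled by relative phase length (longer travel, more explored
configurations) and by a per-condition `amplitude` — the single knob that
distinguishes the object presets standing in for grasp types.  Noise is
drawn along transported in-plane axes (rotation-minimising frame, so the
axes never flip between samples), smoothed with a Gaussian kernel of
correlation length 10% of the path, and renormalised so the *across-trial*
distribution at every sample is exactly N(0, σ(u)²); uncorrelated noise
would produce jagged, non-physical trials and discontinuous crossings.
Timestamps follow a per-phase minimum-jerk law with durations growing as
√(L·L_max)/mean-speed — sublinear in distance, so longer phases reach higher
speed peaks, matching the "greater peaks for greater distances" regularity
of reaching movements (a constant-speed model is also available).

What the generator does **not** emulate: anatomical constraints (the noise
is an abstract in-plane Gaussian field, not an arm model), grasp mechanics,
along-path timing variability (all trials share the time base), marker noise
and dropouts, or any between-subject structure.  Passing recovery tests
therefore validates the *estimator chain* — given data that satisfy the
model's assumptions, the pipeline returns the dispersion that generated
them — not the model's fidelity to any specific recorded dataset.

## Verification problem sizes and statistics

Sampled per-plane dispersion estimates carry intrinsic noise: SD(σ̂)/σ ≈
1/√(2(n−1)) per plane (≈ 5% at n = 200, ≈ 29% at n = 7), and the smooth
noise field correlates neighbouring planes, so pointwise maxima over a
profile conflate estimation quality with extreme-value statistics.  Recovery
checks therefore compare profiles by RMS relative deviation over interior
planes (outer 10% excluded, where trial starts/ends interact with the
planes): simulated ensembles of n = 200 trials reproduce the generator's
closed-form width within 7% RMS, and the experimental-scale n = 7 within
25% RMS, each averaged over three seeds.  The null calibration of the ANOVA
stage uses 2000 simulated 10 × 3 datasets.  These sizes are the package's
validation conditions; all are seeded and reproducible.

## Known limitations

* Trial correspondence is normalised arc length; movements with genuinely
  different path topologies across trials (extra loops, aborted reaches)
  violate the construction and will surface as multiple/missing crossings.
* The bivariate-normal ellipse is the dispersion model; heavy-tailed or
  multimodal in-plane scatter is summarised, not modelled.
* The mean path is estimated from the same n trials whose dispersion is
  measured; at very small n its own error inflates apparent width near
  high-curvature sections.
* Widths below `w_min` are treated as divergent difficulty rather than
  floored — a deliberate refusal to fabricate a finite answer for a
  deterministic ensemble.
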