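# stochid — stochastic Index of Difficulty for repetitive 3D movements

`stochid` quantifies the motor difficulty *experienced* by an agent (human or
robot end-effector) performing a repetitive three-dimensional movement, from
the variability of its repeated trajectories.  It is aimed at movement
scientists, ergonomists and rehabilitation researchers who record repeated
reach / pick-and-place trajectories (e.g. a hand marker from motion capture)
and want a single, task-comparable difficulty number per subject and
condition.

## The model

Classical Fitts-style indices of difficulty are deterministic functions of
task geometry (target distance D and width W, `ID = log2(2D/W)`).  They say
nothing about how a *particular* agent behaves in the task.  The stochastic
index instead reads difficulty off the agent's own motor variability: where
the movement must be accurate, trial-to-trial dispersion collapses; where the
agent is free, dispersion (motor flexibility) is large.  Low flexibility
sustained over a long path means high experienced difficulty.

Given n repeated trajectories t_k with average t̄ (arc length s ∈ [0, |t̄|]):

1. at each s, intersect every trial with the plane P(s) orthogonal to t̄,
   giving crossing points q_k(s);
2. a 2D PCA of the q_k(s) yields in-plane standard deviations σϵ(s) ≥ ση(s);
3. the φ-level dispersion ellipse has semi-axes √c²·σϵ and √c²·ση, where
   c² = χ²(2, φ) when the population is known, and otherwise the
   small-sample Hotelling scale
   `c² = T² = ((n−1)·ν1)/(n·(n−ν1)) · F(ν1, n−ν1, φ)` with ν1 = 2
   (for n = 7, φ = 0.95: F(2,5,0.95) = 5.786 and c² = 1.984);
4. the ellipse is converted to an equivalent circle through its mean radius
   r_mean(s, φ) = (1/2π) ∫₀^{2π} √(c²σϵ²cos²θ + c²ση²sin²θ) dθ, and the
   **stochastic width** is W_obs(s, φ) = 2·r_mean(s, φ);
5. the **stochastic Index of Difficulty** accumulates the reciprocal width
   along the mean path:

   ID_obs(s*, φ) = ∫₀^{s*} ds / W_obs(s, φ).

ID_obs is dimensionless, zero at the start, non-decreasing in s*, invariant
under rigid motions and spatial rescaling, and grows fastest where the
movement is most constrained.

The package also ships a synthetic trial generator (a three-phase
reach / transport / return table-top task with prescribed dispersion, so
every stage can be validated against closed forms), speed-profile analysis
with per-phase velocity peaks, and a within-subject comparison stage
(one-way repeated-measures ANOVA with Bonferroni-corrected paired post hocs).

## Worked example

```python
import stochid as st

spec = st.object_preset("tennis_ball", n=7, seed=42)   # 7 trials, seeded
path = st.make_mean_path(spec)
ens  = st.simulate_trials(path, spec, condition="tennis_ball")

grid = st.mean_path(ens, 200)                # average trajectory, 200 planes
wp   = st.width_profile(ens, grid, phi=0.95) # W_obs(s, 0.95)
prof = st.id_obs(wp)                         # cumulative difficulty

print(f"|t̄| = {grid.total_length:.1f} mm")
print(f"c²(0.95) = {st.c_squared(ens.n, 0.95).c2:.3f}  (Hotelling, n = {ens.n})")
print(f"W_obs range: {wp.W.min():.2f}–{wp.W.max():.2f} mm "
      f"({int(wp.valid.sum())}/{len(wp.s)} valid planes)")
print(f"total ID_obs(|t̄|, 0.95) = {prof.total:.2f}")
```

prints

```
|t̄| = 1266.9 mm
c²(0.95) = 1.984  (Hotelling, n = 7)
W_obs range: 2.27–22.39 mm (200/200 valid planes)
total ID_obs(|t̄|, 0.95) = 136.72
```

Reading: over a 1.27 m three-phase movement the trial dispersion (at 95%
confidence, small-sample scaling for n = 7) narrows to ~2 mm at the grasp /
release / placement events and opens to ~22 mm mid-phase; integrating 1/W_obs
over the whole path accumulates a total experienced difficulty of ≈ 137.
Narrower dispersion (less flexibility) or a longer path would raise it.

The same pipeline is available from the shell:

```
stochid simulate --seed 42 --out trials.csv
stochid difficulty trials.csv --out profile.csv
stochid velocity trials.csv --out speed.csv
stochid compare id_matrix.csv            # subjects x conditions CSV
```

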