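# Methods

This note records the mathematical model behind each stage, every
parameter default with its rationale, and the known limitations.

## 1. Centerline tracing (`filotrace.centerline`)

### Model

A filopodium in a single frame is a bright ridge between a tracked base
anchor and tip anchor. The centerline is the unit-speed curve
`r(s) = (x(s), y(s))`, `s ∈ [0, L]`, whose tangent direction equals the
local intensity-weighted ridge orientation

    θ = ½ · atan2(2 μ11, μ20 − μ02),

where `μ20, μ02, μ11` are central second moments of the image inside a
square window centered on the evaluation point (window pixels falling
outside the frame carry zero weight). Since `r'(s) = (cos θ, sin θ)`,

    x''(s) = −sin θ(s) · θ'(s),   y''(s) = cos θ(s) · θ'(s),

with both endpoints pinned at the anchors — a two-point boundary-value
problem solved by relaxation:

1. initialize with the straight chord, `N = max(16, ceil(2·chord_px))`
   nodes;
2. sample θ at each node; windows whose orientation deviates more than
   π/3 from the local chord direction are rejected as degenerate (they
   are dominated by a crossing structure, typically the dendrite shaft)
   and interpolated from their neighbors;
3. lift the mod-π angles to a continuous branch anchored at the chord
   direction (`θi ← θi + π·round((θprev − θi)/π)`), then smooth the
   branch over an arc scale of half the window size — the moment window
   cannot resolve orientation variation below its own footprint, so
   retaining higher-frequency θ structure only injects noise into the
   ODE;
4. build `θ'(s)` by central differences and solve the two tridiagonal
   linear systems (`scipy.linalg.solve_banded`) for the interior nodes;
5. re-parameterize the curve to uniform arc length;
6. under-relax: the new curve is `old + α·(new − old)`; α starts at 1 and
   is halved (floor 0.1) whenever the raw displacement grows, which
   suppresses the limit cycles that pixel-quantized window centers
   otherwise cause;
7. stop when `α · max node displacement < 0.05 px` (well below the
   tracking noise of real anchors) or after `max_iter` iterations — in
   the latter case a `ConvergenceError` carrying the last iterate is
   raised; the pipeline logs it and keeps the last iterate.

### Parameters

| parameter | default | rationale |
|---|---|---|
| `window_px` | 15 | ~1 µm at 0.064 µm/px: wide enough to average over shot noise, narrow enough to follow curvature of real filopodia |
| `tol_px` | 0.05 | an order of magnitude below anchor-tracking noise |
| nodes `N` | `max(16, ceil(2·chord_px))` | ≈0.5 px node spacing; denser brings no information (θ is window-band-limited) |
| perpendicular rejection | π/3 | tangent samples nearly orthogonal to the local chord are ridge crossings, not the ridge itself |
| branch smoothing | window/2 arc scale | matches the resolution of the moment estimator |

### Accuracy

On analytic ridges with zero noise: a straight ridge returns the chord to
machine precision (the constant-θ limit of the ODE is exact); a
quarter-circle arc of radius 20 px is recovered with 1.4% length error
and 0.52 px maximum perpendicular deviation. The moment orientation
itself carries a small bias on oblique ridges because the square window
clips the ridge band asymmetrically; the bias grows with ridge width and
is ≈0.02 rad at σ = 0.8 px for a 15-px window.

## 2. Motility metrics (`filotrace.metrics`)

All rates are per-interval differences divided by the frame interval.
The motility threshold is one pixel per frame interval,
`pixel_size/interval` = 0.064 µm / 5 s = **0.0128 µm/s** at the default
calibration: displacements below one pixel per interval are not
distinguishable from tracking noise.

- `instantaneous_speeds`: tip displacement per valid consecutive frame
  pair; pairs spanning a tracking gap are omitted, never zero-filled.
- `summarize_motility`: mean tip speed; motile flag (mean speed strictly
  above threshold); % time motile (fraction of intervals with speed
  strictly above threshold); median protrusion rate (median of dL/dt
  over intervals with dL/dt > threshold) and median retraction rate
  (dL/dt < −threshold) — `NaN`, never 0, when no interval qualifies.
- Tip fluorescence: mean intensity in a fixed disc of radius 384 nm
  (6 px at default calibration) around the tip, restricted to the cell
  mask (pixel centers decide membership); normalized by the per-DF
  minimum over valid frames, so 1.0 is each DF's own dimmest state.
- `fluorescence_variance` uses the n−1 (unbiased) denominator.
- `fold_change_bins`: time-binned means normalized by the first bin,
  for event-aligned fold-change summaries.

Distinction kept deliberately: **tip speed** (magnitude of tip
displacement) and **DCTM** (signed rate of length change) are different
quantities — a buckling filopodium can move its tip quickly while its
length barely changes.

## 3. Lead–lag analysis (`filotrace.correlation`)

- FTIP and DCTM are 3-point moving-averaged (endpoints use the 2-point
  mean; NaN gaps split the series into independently smoothed runs).
- `CCF(τ) = Pearson(FTIP(t+τ), DCTM(t))`, τ ∈ [−K, +K] (default
  K = 10 frames = 50 s); negative peak offset ⇒ fluorescence precedes
  motility. Peak ties break toward the smallest |τ|, negative first.
- Per-offset significance bound: `2/√(n − |τ|)` (large-sample 95% bound
  for a correlation of `n − |τ|` overlapping points).
- TCS: Ward hierarchical clustering of the CCF-vs-offset vectors, tree
  cut at k ∈ {2, 3, 4} chosen by silhouette; the cluster with the highest
  mean peak CCF is the top-correlating subcluster.
- Block bootstrap: per randomization, every DF's DCTM series is cut into
  consecutive 8-frame blocks (the final partial block kept intact) and
  the block order permuted, fluorescence fixed. Eight frames (40 s)
  exceeds the correlation time of the smoothed motility series, so
  within-block autocorrelation is preserved while fluorescence–motility
  registration is destroyed. The TCS statistic (mean peak CCF of the
  TCS) is recomputed on each randomized dataset by re-running the
  identical clustering; `p = max(count(null ≥ observed), 1) / N` with
  N = 1,000 by default — p is never reported as 0, the floor is 1/N.

**Null construction choice.** A variant that constrains the randomized
TCS to the observed cardinality (clusters ranked by mean peak, filled
greedily to size) is available via `match_size=True` but is *not* the
default: measured under independence (50 experiments × 100
randomizations) it is badly miscalibrated (mean p ≈ 0.73,
KS-against-uniform p ≈ 1e-6), because the fill/trim statistic is
stochastically larger than a natural Ward TCS. Free re-clustering applies
the identical procedure to real and randomized data, making the
statistics exchangeable under independence; measured calibration: KS
p = 0.66, p > 0.05 in 98% of independent experiments.

## 4. Synthetic movies (`filotrace.simulate`)

What the generator emulates: the acquisition regime of TIRF filopodium
time-lapses — 0.064 µm pixels, 5 s interval, 60 frames; a dendrite shaft
(uniform band) with filopodia as constant-curvature arcs rooted on its
edge; ridge rendering with Gaussian cross-section via exact
distance-to-polyline on a 3× supersampled grid, box-downsampled;
a second channel with a diffuse structural fill plus a tip-localized
Gaussian blob whose brightness is `baseline + gain·M(t+k) + ε` for
motility `M` and programmable lead `k` (the kinematics are simulated
`k+1` frames past the movie end so the tip factor is defined at every
rendered frame); Gaussian read noise and optional Poisson shot noise
added last; a cell mask thresholded on the noise-free image; optional
Gaussian tracking jitter on the exported anchor tracks.

What it does **not** emulate: photobleaching, stage drift, filopodia
crossing each other, out-of-focus light, non-uniform illumination, or
anisotropic PSFs. Length dynamics models: constant, sinusoid,
Ornstein–Uhlenbeck (exact discretization; default mean 2.5 µm,
τ = 30 s, σ = 0.1 µm/√s giving stationary SD ≈ 0.39 µm), and a two-state
protrusion/retraction switcher; excursions below 0.2 µm are clipped with
a warning.

`psf_sigma_px = 1.2`: the in-plane Gaussian PSF approximation
σ ≈ 0.21·λ/NA gives ≈ 73 nm for λ = 520 nm (GFP emission) at NA 1.49,
i.e. ≈ 1.15 px at 64 nm pixels, rounded to 1.2.

Determinism: one `numpy.random.SeedSequence` is spawned into independent
streams per filopodium, per frame, and per channel; identical scene and
seed produce byte-identical output files.

## 5. Validation problem sizes

The validation suite (tests and `scripts/acceptance.py`) uses sizes
chosen to give tight statistical power on one CPU in minutes: 50 rendered
scenes for end-to-end lag recovery at SNR 5 (ridge amplitude 100, camera
noise σ 20), 20 coupled + 20 independent DFs for planted-subcluster
recovery, and 200 independent experiments × 200 randomizations for
bootstrap calibration.

## 6. Limitations

- The moment-window orientation is band-limited at the window scale, so
  centerline curvature sharper than ~0.5 µm is smoothed over, and
  oblique wide ridges carry a small orientation bias (see §1).
- On very noisy frames the relaxation may not converge within the
  iteration cap; the pipeline then keeps the last iterate and logs a
  warning rather than dropping the frame.
- Filopodia closer together than roughly one window width contaminate
  each other's tangent fields.
- The bootstrap p-value is a plain frequency with floor 1/N; resolving
  smaller p requires raising `n_randomizations`.
- The CCF assumes a single dominant lag per DF; oscillatory coupling
  produces multimodal profiles that the peak statistic summarizes only
  crudely.
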