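# filotrace

Quantification of dendritic filopodium dynamics from two-channel
fluorescence time-lapse movies: sub-pixel centerline tracing, motility
metrics, and lead–lag analysis of tip fluorescence against tip movement.

## Scientific problem

Dendritic filopodia (DFs) are thin, dynamic protrusions from neuronal
dendrites — precursors of dendritic spines. A central question about any
candidate regulator is temporal order: does enrichment of the tagged
protein at the filopodium tip *precede* protrusion, or merely follow it?
Answering this requires

1. an accurate per-frame **length** for each filopodium, even when the
   protrusion is curved (tip-to-base straight-line distance
   underestimates length and corrupts rate estimates);
2. a consistent **motility metric suite** (protrusion/retraction rates,
   time motile, tip speed) with an explicit noise threshold;
3. a **lead–lag statistic** relating tip fluorescence (FTIP) to
   direction-corrected tip movement (DCTM, the signed rate of length
   change), with population-level significance that respects the strong
   autocorrelation of both series.

### Centerline model

Given a movie frame `I`, a tracked base point and tip point, the
centerline is modeled as a unit-speed curve `(x(s), y(s))`, `s ∈ [0, L]`,
whose tangent follows the local ridge orientation of the image. The
orientation field is measured by intensity-weighted image moments over a
15×15-pixel window centered on the current curve estimate:

    θ(x, y) = ½ · atan2(2 μ11, μ20 − μ02)

with `μpq` the central second moments of `I` inside the window. Writing
the unit tangent as `(cos θ(s), sin θ(s))`, differentiating gives the
two-point boundary-value problem

    x''(s) = −sin θ(s) · θ'(s)
    y''(s) =  cos θ(s) · θ'(s)
    (x, y)(0) = base,   (x, y)(L) = tip

which is solved by damped fixed-point relaxation: sample θ along the
current curve, lift the mod-π angles to a continuous branch, solve the
resulting tridiagonal linear systems for `x` and `y`, re-parameterize to
uniform arc length, repeat until the update falls below 0.05 px.

### Lead–lag statistic

For each DF, `CCF(τ) = corr(FTIP(t+τ), DCTM(t))` over integer frame
offsets τ ∈ [−K, K], both series 3-point smoothed, so a peak at negative
τ means fluorescence change precedes motility. DFs are grouped by Ward
hierarchical clustering of their CCF profiles; the cluster with the
highest mean peak is the top-correlating subcluster (TCS). Population
significance comes from a block bootstrap: each DF's motility series is
permuted in 8-frame blocks (fluorescence fixed), the TCS statistic is
recomputed per randomization, and p is the fraction of null statistics at
least as large as observed (floored at 1/N).

### Synthetic movies

Because raw movies of this kind are rarely shareable, the simulator is a
first-class component: filopodia are constant-curvature arcs rooted on a
dendrite shaft, rendered as ridges of Gaussian cross-section with camera
noise, and the tip-factor channel is programmed to lead motility by a
chosen number of frames — so every stage of the analysis can be validated
against known ground truth.

## Worked example

```bash
filotrace simulate --seed 7 --out sim --n-filopodia 3 --lag-frames 2 \
    --n-frames 60 --noise-sigma 10
filotrace centerline --movie sim/movie.tif --tracks sim/tracks.csv --out cl
filotrace metrics --movie sim/movie.tif --fluor sim/fluor.tif \
    --mask sim/mask.tif --tracks sim/tracks.csv --out met
filotrace ccf --series met/series.csv --out ccf
```

The simulated dataset programs the tip factor to lead motility by
2 frames. On this exact run the metrics stage prints
`3 filopodia, 100.0% motile`, with per-DF summaries (`met/metrics.csv`):

| df_id | avg length (µm) | tip speed (µm/s) | % time motile | median protrusion rate (µm/s) |
|-------|-----------------|------------------|---------------|-------------------------------|
| df000 | 2.20            | 0.0310           | 66.1          | 0.062                         |
| df001 | 2.63            | 0.0336           | 78.0          | 0.043                         |
| df002 | 2.51            | 0.0295           | 72.9          | 0.034                         |

and the ccf stage recovers the programmed lag for every filopodium —
all three CCF profiles peak at offset −2 (values 0.952–0.964) — printing
`TCS size 1, mean peak 0.964, bootstrap p = 0.001` (the reporting floor
at the default 1,000 randomizations).

The same pipeline is driven from Python via `filotrace.simulate`,
`filotrace.pipeline.extract_series`, `filotrace.metrics`, and
`filotrace.correlation`; see `docs/methods.md` for the model, parameter
defaults, and their rationale.

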