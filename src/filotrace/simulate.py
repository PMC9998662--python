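"""Synthetic time-lapse movies of dendritic filopodia with known kinematics.

The generator emulates the acquisition regime of TIRF filopodium movies:
0.064 µm pixels, a 5 s frame interval, 60 frames.  A filopodium is a
constant-curvature arc rooted on the edge of a dendrite shaft, rendered as
a ridge of Gaussian cross-section (the in-plane point-spread width); its
length follows a prescribed stochastic model.  A second, tip-factor channel
carries a diffuse structural fill plus a tip-localized blob whose
brightness follows future motility with a programmable lag, so that the
fluorescence-precedes-motility structure the correlation analysis is
designed to detect is present by construction.  Camera noise (Gaussian
read noise, optional Poisson shot noise) is added last.

Everything is deterministic given the scene parameters and a seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy.spatial import cKDTree

from .io import Movie, TipTrack, write_tracks

LENGTH_FLOOR_UM = 0.2
SUPERSAMPLE = 3


# ---------------------------------------------------------------------------
# Length dynamics models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConstantLength:
    L0_um: float = 2.0


@dataclass(frozen=True)
class SinusoidLength:
    L0_um: float = 2.0
    amplitude_um: float = 0.5
    period_s: float = 60.0
    phase: float = 0.0


@dataclass(frozen=True)
class OULength:
    """Mean-reverting (Ornstein–Uhlenbeck) length dynamics.

    ``sigma`` is the diffusion coefficient in µm/√s; the stationary
    standard deviation is sigma·√(tau/2).
    """
    mean_um: float = 2.5
    tau_s: float = 30.0
    sigma: float = 0.1


@dataclass(frozen=True)
class TwoStateLength:
    """Alternating protrusion/retraction epochs with exponential dwells."""
    L0_um: float = 2.0
    protrude_rate_um_s: float = 0.04
    retract_rate_um_s: float = 0.04
    mean_dwell_s: float = 40.0


def simulate_length_series(model, n_frames: int, interval_s: float,
                           rng) -> np.ndarray:
    """Length trajectory (µm) for one filopodium under the given model.

    Non-positive excursions are clipped at a small positive floor with a
    warning, so downstream geometry stays valid.
    """
    rng = np.random.default_rng(rng)
    t = np.arange(n_frames) * interval_s
    if isinstance(model, ConstantLength):
        L = np.full(n_frames, model.L0_um)
    elif isinstance(model, SinusoidLength):
        w = 2 * np.pi / model.period_s
        L = model.L0_um + model.amplitude_um * np.sin(w * t + model.phase)
    elif isinstance(model, OULength):
        a = np.exp(-interval_s / model.tau_s)
        sd_step = model.sigma * np.sqrt((1 - a * a) * model.tau_s / 2)
        sd_stat = model.sigma * np.sqrt(model.tau_s / 2)
        L = np.empty(n_frames)
        L[0] = model.mean_um + sd_stat * rng.standard_normal()
        for i in range(1, n_frames):
            L[i] = (model.mean_um + a * (L[i - 1] - model.mean_um)
                    + sd_step * rng.standard_normal())
    elif isinstance(model, TwoStateLength):
        L = np.empty(n_frames)
        L[0] = model.L0_um
        state = 1 if rng.random() < 0.5 else -1
        t_switch = rng.exponential(model.mean_dwell_s)
        clock = 0.0
        for i in range(1, n_frames):
            clock += interval_s
            while clock >= t_switch:
                state = -state
                t_switch += rng.exponential(model.mean_dwell_s)
            rate = model.protrude_rate_um_s if state > 0 else -model.retract_rate_um_s
            L[i] = L[i - 1] + rate * interval_s
    else:
        raise ValueError(f"unknown length model: {model!r}")
    if np.any(L < LENGTH_FLOOR_UM):
        warnings.warn("length series clipped at positive floor")
        L = np.maximum(L, LENGTH_FLOOR_UM)
    return L


# ---------------------------------------------------------------------------
# Scene description
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FiloParams:
    """One synthetic filopodium: geometry, dynamics, and tip-factor coupling."""
    base_xy: tuple[float, float]          # pixels; on the dendrite edge
    orientation: float = -np.pi / 2        # radians; -π/2 points away from shaft
    length_model: object = field(default_factory=OULength)
    kappa_um: float = 0.0                  # curvature, 1/µm (arc-shaped DF)
    lag_frames: int = 0                    # tip factor leads motility by k frames
    gain: float = 10.0                     # fluorescence units per (µm/s)
    fluor_baseline: float = 1.0
    fluor_noise_sigma: float = 0.0         # on the tip-factor time series


@dataclass(frozen=True)
class SceneParams:
    """Scene geometry and acquisition parameters (defaults mirror the
    0.064 µm / 5 s / 60-frame regime the motility thresholds assume)."""
    filopodia: tuple[FiloParams, ...]
    pixel_size_um: float = 0.064
    interval_s: float = 5.0
    n_frames: int = 60
    shape_rc: tuple[int, int] = (112, 80)
    dendrite_row: int = 96                 # top edge of the shaft band
    dendrite_width_px: int = 12
    dendrite_intensity: float = 100.0
    ridge_amplitude: float = 100.0
    psf_sigma_px: float = 1.2       # ≈0.21·λ/NA at 520 nm, NA 1.49, 64 nm px
    background: float = 10.0
    noise_sigma: float = 0.0               # Gaussian camera noise, geometry channel
    poisson_scale: float = 0.0             # >0 enables shot noise at this gain
    mask_fraction: float = 0.05            # of noise-free peak
    fluor_fill_amplitude: float = 30.0
    fluor_tip_amplitude: float = 80.0      # blob amplitude per unit tip factor
    tracking_jitter_px: float = 0.0


@dataclass(frozen=True)
class GroundTruth:
    """Everything the renderer knew: the oracle for parameter recovery."""
    lengths_um: dict           # df_id -> (n_frames,) list
    tip_xy_px: dict            # df_id -> (n_frames, 2) list
    base_xy_px: dict
    tip_factor: dict           # df_id -> (n_frames,) list, noise included
    lag_frames: dict
    pixel_size_um: float
    interval_s: float


def arc_centerline(base_xy_px, orientation: float, kappa_px: float,
                   length_px: float, n_pts: int = 64) -> np.ndarray:
    """Constant-curvature arc of given length from the base, in pixels."""
    s = np.linspace(0.0, length_px, n_pts)
    if abs(kappa_px) < 1e-12:
        d = np.array([np.cos(orientation), np.sin(orientation)])
        return np.asarray(base_xy_px, float)[None] + s[:, None] * d[None]
    phi = orientation + kappa_px * s
    x = (np.sin(phi) - np.sin(orientation)) / kappa_px
    y = (-np.cos(phi) + np.cos(orientation)) / kappa_px
    return np.asarray(base_xy_px, float)[None] + np.column_stack([x, y])


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _supergrid(shape_rc):
    rows, cols = shape_rc
    n = SUPERSAMPLE
    # subpixel centers in pixel coordinates
    r = (np.arange(rows * n) + 0.5) / n - 0.5
    c = (np.arange(cols * n) + 0.5) / n - 0.5
    return r, c


def _add_ridge(canvas: np.ndarray, grid_rc, polyline_px: np.ndarray,
               amplitude: float, sigma_px: float) -> None:
    """Accumulate a Gaussian-cross-section ridge along a polyline onto the
    supersampled canvas (distance-to-curve evaluation)."""
    r, c = grid_rc
    seg = np.linalg.norm(np.diff(polyline_px, axis=0), axis=1).sum()
    n_dense = max(2, int(np.ceil(seg / 0.2)))
    t = np.linspace(0, 1, len(polyline_px))
    td = np.linspace(0, 1, n_dense)
    dense = np.column_stack([np.interp(td, t, polyline_px[:, 0]),
                             np.interp(td, t, polyline_px[:, 1])])
    tree = cKDTree(dense)
    margin = 4 * sigma_px
    rmin = max(0, np.searchsorted(r, polyline_px[:, 1].min() - margin))
    rmax = min(len(r), np.searchsorted(r, polyline_px[:, 1].max() + margin) + 1)
    cmin = max(0, np.searchsorted(c, polyline_px[:, 0].min() - margin))
    cmax = min(len(c), np.searchsorted(c, polyline_px[:, 0].max() + margin) + 1)
    if rmin >= rmax or cmin >= cmax:
        raise ValueError("centerline lies outside the frame")
    cc, rr = np.meshgrid(c[cmin:cmax], r[rmin:rmax])
    pts = np.column_stack([cc.ravel(), rr.ravel()])
    d, _ = tree.query(pts, workers=-1)
    canvas[rmin:rmax, cmin:cmax] += (
        amplitude * np.exp(-d * d / (2 * sigma_px ** 2))
    ).reshape(rmax - rmin, cmax - cmin)


def _add_blob(canvas: np.ndarray, grid_rc, center_xy, amplitude: float,
              sigma_px: float) -> None:
    r, c = grid_rc
    cx, cy = center_xy
    margin = 4 * sigma_px
    rmin = max(0, np.searchsorted(r, cy - margin))
    rmax = min(len(r), np.searchsorted(r, cy + margin) + 1)
    cmin = max(0, np.searchsorted(c, cx - margin))
    cmax = min(len(c), np.searchsorted(c, cx + margin) + 1)
    cc, rr = np.meshgrid(c[cmin:cmax], r[rmin:rmax])
    d2 = (cc - cx) ** 2 + (rr - cy) ** 2
    canvas[rmin:rmax, cmin:cmax] += amplitude * np.exp(-d2 / (2 * sigma_px ** 2))


def _downsample(canvas: np.ndarray) -> np.ndarray:
    n = SUPERSAMPLE
    rows, cols = canvas.shape[0] // n, canvas.shape[1] // n
    return canvas.reshape(rows, n, cols, n).mean(axis=(1, 3))


def render_frame(scene: SceneParams, centerlines_px: list[np.ndarray],
                 tip_blob: list[tuple[tuple[float, float], float]] | None = None,
                 *, fill_amplitude: float | None = None,
                 rng=None) -> tuple[np.ndarray, np.ndarray]:
    """Render one frame: dendrite shaft + filopodium ridges (+ tip blobs).

    Returns (intensity frame, boolean cell mask).  The mask thresholds the
    noise-free image at ``scene.mask_fraction`` of its peak; noise is added
    after the mask is taken.
    """
    grid = _supergrid(scene.shape_rc)
    canvas = np.zeros((scene.shape_rc[0] * SUPERSAMPLE,
                       scene.shape_rc[1] * SUPERSAMPLE))
    amp = scene.ridge_amplitude if fill_amplitude is None else fill_amplitude
    rows, cols = scene.shape_rc
    for line in centerlines_px:
        if (np.any(line[:, 0] < 0) or np.any(line[:, 0] > cols - 1)
                or np.any(line[:, 1] < 0) or np.any(line[:, 1] > rows - 1)):
            raise ValueError("centerline exits the frame")
        _add_ridge(canvas, grid, line, amp, scene.psf_sigma_px)
    # dendrite shaft: uniform band
    r = grid[0]
    band = (r >= scene.dendrite_row) & (r < scene.dendrite_row + scene.dendrite_width_px)
    shaft_amp = (scene.dendrite_intensity if fill_amplitude is None
                 else fill_amplitude)
    canvas[band, :] += shaft_amp
    for (center, blob_amp) in (tip_blob or []):
        _add_blob(canvas, grid, center, blob_amp, scene.psf_sigma_px)
    clean = _downsample(canvas)
    peak = clean.max()
    mask = clean > scene.mask_fraction * peak if peak > 0 else np.zeros_like(clean, bool)
    frame = clean + scene.background
    if rng is not None:
        rng = np.random.default_rng(rng)
        if scene.poisson_scale > 0:
            frame = rng.poisson(np.maximum(frame, 0) * scene.poisson_scale
                                ) / scene.poisson_scale
        if scene.noise_sigma > 0:
            frame = frame + scene.noise_sigma * rng.standard_normal(frame.shape)
    return frame, mask


# ---------------------------------------------------------------------------
# Tip-factor coupling
# ---------------------------------------------------------------------------

def simulate_tip_factor(motility_series, lag_frames: int, gain: float,
                        noise_sigma: float, rng, baseline: float = 1.0) -> np.ndarray:
    """Tip-factor series F(t) = baseline + gain·M(t+k) + ε.

    A positive lag k makes fluorescence enrichment precede motility by k
    frames, so the CCF of F against M peaks at offset −k.  Entries whose
    future motility is beyond the series end are NaN.
    """
    M = np.asarray(motility_series, dtype=float)
    if lag_frames < 0:
        raise ValueError("lag must be non-negative")
    if lag_frames >= len(M):
        raise ValueError("lag exceeds series length")
    rng = np.random.default_rng(rng)
    F = np.full(len(M), np.nan)
    F[: len(M) - lag_frames] = baseline + gain * M[lag_frames:]
    if noise_sigma > 0:
        F[: len(M) - lag_frames] += noise_sigma * rng.standard_normal(len(M) - lag_frames)
    return F


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------

def simulate_scene(scene: SceneParams, seed: int):
    """Simulate a scene in memory.

    Returns (geometry Movie, tip-factor Movie, list of TipTrack, GroundTruth).
    Both movies share the cell mask derived from the geometry channel.
    """
    ss = np.random.SeedSequence(seed)
    n = scene.n_frames
    dt = scene.interval_s
    px = scene.pixel_size_um
    max_lag = max((f.lag_frames for f in scene.filopodia), default=0)

    # per-DF kinematics, simulated past the movie end so the tip factor is
    # defined at every rendered frame
    per_df = []
    filo_seeds = ss.spawn(len(scene.filopodia) + 1)
    noise_ss = filo_seeds[-1]
    for fp, child in zip(scene.filopodia, filo_seeds):
        s_len, s_fluor = child.spawn(2)
        L_ext = simulate_length_series(fp.length_model, n + fp.lag_frames + 1,
                                       dt, np.random.default_rng(s_len))
        M_ext = np.diff(L_ext) / dt                       # n + lag entries
        F_ext = simulate_tip_factor(M_ext, fp.lag_frames, fp.gain,
                                    fp.fluor_noise_sigma,
                                    np.random.default_rng(s_fluor),
                                    baseline=fp.fluor_baseline)
        per_df.append((fp, L_ext[:n], F_ext[:n]))

    geo_frames = np.empty((n, *scene.shape_rc))
    flu_frames = np.empty((n, *scene.shape_rc))
    masks = np.empty((n, *scene.shape_rc), dtype=bool)
    tips = {i: np.empty((n, 2)) for i in range(len(per_df))}
    noise_children = noise_ss.spawn(n)
    for t in range(n):
        lines, blobs = [], []
        for i, (fp, L, F) in enumerate(per_df):
            kappa_px = fp.kappa_um * px   # 1/µm -> 1/px
            line = arc_centerline(fp.base_xy, fp.orientation, kappa_px,
                                  L[t] / px)
            lines.append(line)
            tips[i][t] = line[-1]
            blobs.append((tuple(line[-1]), scene.fluor_tip_amplitude * F[t]))
        g_rng, f_rng = (np.random.default_rng(s)
                        for s in noise_children[t].spawn(2))
        geo_frames[t], masks[t] = render_frame(scene, lines, rng=g_rng)
        flu_frames[t], _ = render_frame(scene, lines, tip_blob=blobs,
                                        fill_amplitude=scene.fluor_fill_amplitude,
                                        rng=f_rng)

    jitter_rng = np.random.default_rng(noise_ss.spawn(n + 1)[-1])
    tracks = []
    for i, (fp, L, F) in enumerate(per_df):
        base = np.tile(np.asarray(fp.base_xy, float), (n, 1))
        tip = tips[i].copy()
        if scene.tracking_jitter_px > 0:
            tip = tip + scene.tracking_jitter_px * jitter_rng.standard_normal((n, 2))
            base = base + scene.tracking_jitter_px * jitter_rng.standard_normal((n, 2))
        tracks.append(TipTrack(df_id=f"df{i:03d}", frames=np.arange(n),
                               base_xy=base, tip_xy=tip))

    truth = GroundTruth(
        lengths_um={f"df{i:03d}": per_df[i][1].tolist() for i in range(len(per_df))},
        tip_xy_px={f"df{i:03d}": tips[i].tolist() for i in range(len(per_df))},
        base_xy_px={f"df{i:03d}": list(per_df[i][0].base_xy) for i in range(len(per_df))},
        tip_factor={f"df{i:03d}": per_df[i][2].tolist() for i in range(len(per_df))},
        lag_frames={f"df{i:03d}": per_df[i][0].lag_frames for i in range(len(per_df))},
        pixel_size_um=px, interval_s=dt,
    )
    geo = Movie(frames=geo_frames, pixel_size_um=px, interval_s=dt, mask=masks)
    flu = Movie(frames=flu_frames, pixel_size_um=px, interval_s=dt, mask=masks)
    return geo, flu, tracks, truth


def make_dataset(scene: SceneParams, seed: int, out_dir) -> dict:
    """Simulate a scene and write it in the ingestion formats.

    Writes movie.tif (geometry channel), fluor.tif (tip-factor channel),
    mask.tif, tracks.csv, and truth.json; returns the path map.  Identical
    scene + seed produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geo, flu, tracks, truth = simulate_scene(scene, seed)
    paths = {
        "movie": out / "movie.tif",
        "fluor": out / "fluor.tif",
        "mask": out / "mask.tif",
        "tracks": out / "tracks.csv",
        "truth": out / "truth.json",
    }
    kw = dict(photometric="minisblack")
    tifffile.imwrite(paths["movie"], geo.frames.astype(np.float32), **kw)
    tifffile.imwrite(paths["fluor"], flu.frames.astype(np.float32), **kw)
    tifffile.imwrite(paths["mask"], geo.mask.astype(np.uint8), **kw)
    write_tracks(tracks, paths["tracks"])
    doc = {
        "lengths_um": truth.lengths_um,
        "tip_xy_px": truth.tip_xy_px,
        "base_xy_px": truth.base_xy_px,
        "tip_factor": truth.tip_factor,
        "lag_frames": truth.lag_frames,
        "pixel_size_um": truth.pixel_size_um,
        "interval_s": truth.interval_s,
        "seed": seed,
    }
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
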