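"""End-to-end orchestration: movies + tracks in, per-DF series and metrics out."""

from __future__ import annotations

import logging

import numpy as np

from .centerline import ConvergenceError, solve_centerline
from .io import Movie, PipelineConfig, TipTrack
from .metrics import DFSeries, normalize_tip_fluorescence, tip_roi_intensity

logger = logging.getLogger("filotrace")


def trace_track(movie: Movie, track: TipTrack, config: PipelineConfig) -> dict:
    """Solve the centerline for every tracked frame of one filopodium.

    Returns {frame_index: CenterlineCurve}.  Frames whose relaxation does
    not converge keep the last iterate (logged); frames with coincident
    anchors are skipped.
    """
    curves = {}
    for i, f in enumerate(track.frames):
        frame = movie.frames[f]
        try:
            curve = solve_centerline(frame, track.base_xy[i], track.tip_xy[i],
                                     pixel_size_um=movie.pixel_size_um,
                                     window_px=config.angle_window_px)
        except ConvergenceError as err:
            logger.warning("centerline for %s frame %d not converged; "
                           "using last iterate", track.df_id, f)
            curve = err.last_curve
        except ValueError as err:
            logger.warning("centerline for %s frame %d skipped: %s",
                           track.df_id, f, err)
            continue
        curves[int(f)] = curve
    return curves


def extract_series(geometry: Movie, fluorescence: Movie, track: TipTrack,
                   config: PipelineConfig) -> DFSeries:
    """Build the aligned per-frame series for one filopodium.

    Lengths come from centerlines traced on the geometry (space-filler)
    channel; tip fluorescence is the mean over the fixed-radius ROI on the
    fluorescence channel with non-cell background masked out, normalized by
    its minimum over valid frames.
    """
    curves = trace_track(geometry, track, config)
    f0, f1 = int(track.frames.min()), int(track.frames.max())
    n = f1 - f0 + 1
    times = (f0 + np.arange(n)) * geometry.interval_s
    length = np.full(n, np.nan)
    tip_xy = np.full((n, 2), np.nan)
    fluor = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    tracked = {int(f): i for i, f in enumerate(track.frames)}
    for f in range(f0, f1 + 1):
        if f not in tracked or f not in curves:
            continue
        i = f - f0
        curve = curves[f]
        length[i] = curve.length_um
        tip = track.tip_xy[tracked[f]]
        tip_xy[i] = tip * geometry.pixel_size_um
        mask = fluorescence.mask[f] if fluorescence.mask is not None else None
        fluor[i] = tip_roi_intensity(fluorescence.frames[f], tip,
                                     config.roi_radius_nm,
                                     fluorescence.pixel_size_um, mask)
        valid[i] = np.isfinite(length[i]) and np.isfinite(fluor[i])
    norm = normalize_tip_fluorescence(fluor)
    return DFSeries(df_id=track.df_id, times_s=times, length_um=length,
                    tip_xy_um=tip_xy, tip_fluor=fluor, tip_fluor_norm=norm,
                    valid=valid)
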