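"""Data model, calibrated readers/writers, and pipeline configuration.

Coordinates are 0-based pixel indices with x = column (rightward) and
y = row (downward).  Physical units (µm, s) are attached exactly once,
at ingestion; every downstream module consumes the in-memory model and
never touches file paths.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger("filotrace")

METRICS_COLUMNS = [
    "df_id",
    "avg_tip_speed_um_s",
    "is_motile",
    "pct_time_motile",
    "avg_length_um",
    "max_length_um",
    "median_protrusion_rate_um_s",
    "median_retraction_rate_um_s",
    "fluor_variance",
]


@dataclass(frozen=True)
class Movie:
    """Calibrated time-lapse stack: frames are (time, row, col) intensities."""

    frames: np.ndarray
    pixel_size_um: float
    interval_s: float
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        if frames.ndim != 3:
            raise ValueError(f"frames must be 3-D (t, row, col), got ndim={frames.ndim}")
        if self.pixel_size_um <= 0 or self.interval_s <= 0:
            raise ValueError("pixel_size_um and interval_s must be positive")
        object.__setattr__(self, "frames", frames)
        if self.mask is not None:
            mask = np.asarray(self.mask, dtype=bool)
            if mask.shape != frames.shape:
                raise ValueError(
                    f"mask shape {mask.shape} does not match frames {frames.shape}"
                )
            object.__setattr__(self, "mask", mask)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape_rc(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass(frozen=True)
class TipTrack:
    """Manually tracked base and tip anchors for one filopodium.

    ``frames`` are strictly increasing integer frame indices; interior gaps
    are tolerated (the filopodium was untrackable at those timepoints) and
    recorded so that metric code never differences across them.
    """

    df_id: str
    frames: np.ndarray          # (n,) int
    base_xy: np.ndarray         # (n, 2) float pixels
    tip_xy: np.ndarray          # (n, 2) float pixels

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=int)
        base = np.asarray(self.base_xy, dtype=float)
        tip = np.asarray(self.tip_xy, dtype=float)
        if frames.ndim != 1 or base.shape != (len(frames), 2) or tip.shape != (len(frames), 2):
            raise ValueError("inconsistent track array shapes")
        if len(frames) and np.any(np.diff(frames) <= 0):
            raise ValueError(f"frame indices not strictly increasing for {self.df_id}")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "base_xy", base)
        object.__setattr__(self, "tip_xy", tip)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def has_gaps(self) -> bool:
        return len(self.frames) > 1 and bool(np.any(np.diff(self.frames) > 1))

    def contiguous_runs(self) -> list[np.ndarray]:
        """Index arrays of maximal runs of consecutive frame indices."""
        if len(self.frames) == 0:
            return []
        breaks = np.flatnonzero(np.diff(self.frames) > 1) + 1
        return np.split(np.arange(len(self.frames)), breaks)


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable analysis constants.

    Defaults reproduce the acquisition regime the thresholds were designed
    for: 0.064 µm pixels on a 5 s interval, a 15×15 px orientation window,
    a 384 nm tip ROI, 8-timepoint bootstrap blocks, 1,000 randomizations.
    """

    pixel_size_um: float = 0.064
    interval_s: float = 5.0
    motility_threshold_um_s: float | None = None  # None -> pixel_size/interval
    roi_radius_nm: float = 384.0
    angle_window_px: int = 15
    ccf_max_offset_frames: int = 10
    block_len_frames: int = 8
    n_randomizations: int = 1000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.angle_window_px < 3 or self.angle_window_px % 2 == 0:
            raise ValueError("angle_window_px must be odd and >= 3")
        if self.block_len_frames < 2:
            raise ValueError("block_len_frames must be >= 2")
        if self.n_randomizations < 1:
            raise ValueError("n_randomizations must be >= 1")
        if self.pixel_size_um <= 0 or self.interval_s <= 0:
            raise ValueError("calibration values must be positive")

    @property
    def threshold_um_s(self) -> float:
        if self.motility_threshold_um_s is not None:
            return self.motility_threshold_um_s
        return self.pixel_size_um / self.interval_s

    @property
    def roi_radius_px(self) -> float:
        return self.roi_radius_nm / 1000.0 / self.pixel_size_um

    # -- key=value serialization (echoed into outputs for provenance) ------

    def to_kv(self) -> str:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            lines.append(f"{f.name}={'' if v is None else v}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_kv(cls, text: str) -> "PipelineConfig":
        kwargs: dict = {}
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in {f.name for f in fields(cls)}:
                raise ValueError(f"unknown config key: {key}")
            if val == "":
                kwargs[key] = None
            elif key in ("angle_window_px", "ccf_max_offset_frames",
                         "block_len_frames", "n_randomizations", "rng_seed"):
                kwargs[key] = int(val)
            else:
                kwargs[key] = float(val)
        return cls(**kwargs)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_kv(fh.read())

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_kv())

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, rng_seed=seed)

    def digest(self) -> str:
        return hashlib.sha256(self.to_kv().encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_movie(path, pixel_size_um: float, interval_s: float,
               mask_path=None) -> Movie:
    """Read a single-channel multi-frame TIFF as a calibrated :class:`Movie`."""
    frames = tifffile.imread(path)
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise ValueError(f"expected a single-channel movie, got shape {frames.shape}")
    mask = None
    if mask_path is not None:
        mask = np.asarray(tifffile.imread(mask_path))
        if mask.ndim == 2:
            mask = mask[None]
        if mask.shape != frames.shape:
            raise ValueError(
                f"mask frames {mask.shape} do not match movie {frames.shape}"
            )
        mask = mask > 0
    return Movie(frames=frames, pixel_size_um=pixel_size_um,
                 interval_s=interval_s, mask=mask)


TRACK_COLUMNS = ["df_id", "frame", "base_x", "base_y", "tip_x", "tip_y"]


def read_tracks(path, bounds_rc: tuple[int, int] | None = None) -> list[TipTrack]:
    """Read a manual-tracking CSV into one :class:`TipTrack` per df_id.

    The CSV has columns df_id, frame, base_x, base_y, tip_x, tip_y; rows may
    arrive unordered.  Duplicate (df_id, frame) pairs are rejected.  If
    ``bounds_rc`` (rows, cols) is given, coordinates outside the image are
    rejected too.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"track table missing columns: {missing}")
    numeric = df[TRACK_COLUMNS[1:]].apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = numeric.columns[numeric.isna().any()].tolist()
        raise ValueError(f"non-numeric values in columns: {bad}")
    df = df.assign(**{c: numeric[c] for c in numeric.columns})
    dup = df.duplicated(subset=["df_id", "frame"])
    if dup.any():
        first = df.loc[dup, ["df_id", "frame"]].iloc[0]
        raise ValueError(
            f"duplicate track row for df_id={first['df_id']} frame={int(first['frame'])}"
        )
    tracks = []
    for df_id, grp in df.groupby("df_id", sort=True):
        grp = grp.sort_values("frame")
        base = grp[["base_x", "base_y"]].to_numpy(float)
        tip = grp[["tip_x", "tip_y"]].to_numpy(float)
        if bounds_rc is not None:
            nrow, ncol = bounds_rc
            xy = np.vstack([base, tip])
            if (np.any(xy[:, 0] < 0) or np.any(xy[:, 0] > ncol - 1)
                    or np.any(xy[:, 1] < 0) or np.any(xy[:, 1] > nrow - 1)):
                raise ValueError(f"coordinates outside image bounds for {df_id}")
        track = TipTrack(df_id=str(df_id), frames=grp["frame"].to_numpy(int),
                         base_xy=base, tip_xy=tip)
        if track.has_gaps:
            logger.info("track %s has interior frame gaps; runs analyzed separately",
                        df_id)
        tracks.append(track)
    return tracks


def write_tracks(tracks: list[TipTrack], path) -> None:
    rows = []
    for t in tracks:
        for i in range(len(t)):
            rows.append((t.df_id, int(t.frames[i]), t.base_xy[i, 0], t.base_xy[i, 1],
                         t.tip_xy[i, 0], t.tip_xy[i, 1]))
    pd.DataFrame(rows, columns=TRACK_COLUMNS).to_csv(path, index=False)


def write_metrics_table(results: list[dict], path) -> None:
    """Write per-DF motility summaries as CSV with a stable column order."""
    df = pd.DataFrame(results, columns=METRICS_COLUMNS)
    df.to_csv(path, index=False)


def read_metrics_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]
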