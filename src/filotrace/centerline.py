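"""Ridge centerline extraction between tracked base and tip anchors.

The local orientation of the filopodium is estimated at any pixel from the
intensity-weighted second central moments of coordinates in a square window
(default 15×15): θ = ½·atan2(2·μ11, μ20 − μ02), the principal-axis
direction of the local intensity distribution, defined modulo π.

The centerline (x(s), y(s)) is the solution of the unit-speed curve
equations

    d²x/ds² = −sin θ · dθ/ds,      d²y/ds² = cos θ · dθ/ds,

with Dirichlet boundary conditions at the tracked base and tip.  The system
is the derivative of (dx/ds, dy/ds) = (cos θ, sin θ), so for a tangent
field consistent with a smooth ridge its solution is the ridge centerline.
We solve it by relaxation: initialize with the straight chord, sample the
tangent field at the current nodes, continue the mod-π angles to a smooth
signed branch, solve the discretized boundary-value problem, re-parameterize
to uniform arc length, and repeat until the nodes stop moving.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded


class CenterlineError(Exception):
    """Base class for centerline failures."""


class ConvergenceError(CenterlineError):
    """Relaxation did not converge; carries the last iterate."""

    def __init__(self, message: str, last_curve: "CenterlineCurve"):
        super().__init__(message)
        self.last_curve = last_curve


@dataclass(frozen=True)
class CenterlineCurve:
    """Arc-length parameterized base→tip path for one filopodium, one frame."""

    s: np.ndarray          # (N,) arc length, µm, 0 at base
    points: np.ndarray     # (N, 2) x, y in µm
    theta_s: np.ndarray    # (N,) continued tangent angle, radians
    length_um: float
    converged: bool = True
    n_iterations: int = 0
    disp_history_px: tuple = ()   # max raw node displacement per iteration

    def __len__(self) -> int:
        return len(self.s)


def local_tangent_angle(frame: np.ndarray, center, window_px: int = 15) -> float:
    """Principal-axis orientation of the intensity patch around ``center``.

    Returns the orientation in radians in [−π/2, π/2), defined modulo π.
    Out-of-bounds window pixels are excluded (no padding).  Returns NaN for
    a degenerate (isotropic) patch so the caller can fall back to a chord
    direction; raises for zero total intensity or a window mostly outside
    the frame.
    """
    frame = np.asarray(frame, dtype=float)
    if window_px < 3 or window_px % 2 == 0:
        raise ValueError("window_px must be odd and >= 3")
    half = window_px // 2
    cx, cy = float(center[0]), float(center[1])
    row_c, col_c = int(round(cy)), int(round(cx))
    r0, r1 = max(0, row_c - half), min(frame.shape[0], row_c + half + 1)
    c0, c1 = max(0, col_c - half), min(frame.shape[1], col_c + half + 1)
    n_in = (r1 - r0) * (c1 - c0)
    if n_in < (window_px * window_px) / 2:
        raise ValueError("window lies mostly outside the frame")
    patch = frame[r0:r1, c0:c1]
    total = patch.sum()
    if total <= 0:
        raise ValueError("zero total intensity in orientation window")
    ys, xs = np.mgrid[r0:r1, c0:c1]
    xbar = (patch * xs).sum() / total
    ybar = (patch * ys).sum() / total
    dx = xs - xbar
    dy = ys - ybar
    mu20 = (patch * dx * dx).sum() / total
    mu02 = (patch * dy * dy).sum() / total
    mu11 = (patch * dx * dy).sum() / total
    # isotropic patch: no principal axis
    scale = mu20 + mu02
    if scale <= 0 or (abs(2 * mu11) < 1e-9 * scale and abs(mu20 - mu02) < 1e-9 * scale):
        return float("nan")
    theta = 0.5 * math.atan2(2 * mu11, mu20 - mu02)
    if theta >= math.pi / 2:
        theta -= math.pi
    return theta


def continue_branch(theta_sequence, anchor: float | None = None) -> np.ndarray:
    """Lift mod-π orientations to a continuous signed-angle branch.

    Each angle is shifted by the multiple of π that minimizes the jump to
    its predecessor; the first is anchored to ``anchor`` (typically the
    base→tip chord direction) when given.
    """
    thetas = np.asarray(theta_sequence, dtype=float)
    if thetas.size == 0:
        raise ValueError("empty orientation sequence")
    out = thetas.copy()
    prev = anchor
    for i, th in enumerate(out):
        if prev is not None:
            out[i] = th + math.pi * round((prev - th) / math.pi)
        prev = out[i]
    return out


def _resample_uniform(points: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline to n nodes equally spaced in cumulative chord length."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    c = np.concatenate([[0.0], np.cumsum(seg)])
    total = c[-1]
    if total <= 0:
        return points.copy(), c
    t = np.linspace(0.0, total, n)
    x = np.interp(t, c, points[:, 0])
    y = np.interp(t, c, points[:, 1])
    return np.column_stack([x, y]), t


def _local_chord_angles(points: np.ndarray) -> np.ndarray:
    """Mod-π direction of the local chord at each node of a polyline."""
    n = len(points)
    d = np.empty((n, 2))
    d[1:-1] = points[2:] - points[:-2]
    d[0] = points[1] - points[0]
    d[-1] = points[-1] - points[-2]
    ang = np.arctan2(d[:, 1], d[:, 0])
    ang = np.mod(ang + math.pi / 2, math.pi) - math.pi / 2
    return ang


def _tangent_angles_batch(frame: np.ndarray, points: np.ndarray,
                          window_px: int) -> np.ndarray:
    """Vectorized moment orientation at many window centers.

    Out-of-bounds pixels enter with zero weight, which is identical to
    excluding them from the intensity-weighted moments.  Degenerate
    (zero-weight or isotropic) windows yield NaN.
    """
    half = window_px // 2
    row_c = np.rint(points[:, 1]).astype(int)
    col_c = np.rint(points[:, 0]).astype(int)
    offs = np.arange(-half, half + 1)
    rows = row_c[:, None, None] + offs[None, :, None]
    cols = col_c[:, None, None] + offs[None, None, :]
    inb = ((rows >= 0) & (rows < frame.shape[0])
           & (cols >= 0) & (cols < frame.shape[1]))
    w = frame[rows.clip(0, frame.shape[0] - 1),
              cols.clip(0, frame.shape[1] - 1)] * inb
    total = w.sum(axis=(1, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        xbar = (w * cols).sum(axis=(1, 2)) / total
        ybar = (w * rows).sum(axis=(1, 2)) / total
        dx = cols - xbar[:, None, None]
        dy = rows - ybar[:, None, None]
        mu20 = (w * dx * dx).sum(axis=(1, 2)) / total
        mu02 = (w * dy * dy).sum(axis=(1, 2)) / total
        mu11 = (w * dx * dy).sum(axis=(1, 2)) / total
    scale = mu20 + mu02
    degenerate = ((total <= 0) | (scale <= 0)
                  | ((np.abs(2 * mu11) < 1e-9 * scale)
                     & (np.abs(mu20 - mu02) < 1e-9 * scale)))
    theta = 0.5 * np.arctan2(2 * mu11, mu20 - mu02)
    theta = np.where(theta >= np.pi / 2, theta - np.pi, theta)
    return np.where(degenerate, np.nan, theta)


def _sample_branch(frame: np.ndarray, points: np.ndarray, window_px: int,
                   chord_angle: float) -> np.ndarray:
    """Sample the tangent field at the nodes, fall back to the local chord
    at degenerate patches, continue the branch, and lightly smooth the
    continued angles (3-node running mean) to suppress pixel-quantization
    jitter of the window centers."""
    n = len(points)
    theta_mod = _tangent_angles_batch(frame, points, window_px)
    fallback = _local_chord_angles(points)
    # A sample nearly perpendicular to the current curve direction cannot be
    # the tangent of the traced ridge — it is contamination from adjacent
    # structure (typically the shaft near the base).  Treat it, like
    # isotropic patches, as degenerate.
    dev = np.abs(np.mod(theta_mod - fallback + np.pi / 2, np.pi) - np.pi / 2)
    bad = ~np.isfinite(theta_mod) | (dev > np.pi / 3)
    if bad.any():
        theta_mod[bad] = fallback[bad]
    theta = continue_branch(theta_mod, anchor=chord_angle)
    # The orientation field is a window_px-scale average, so it carries no
    # information below roughly half that scale; smooth the branch over
    # ~window_px/2 pixels of arc to keep dθ/ds well conditioned.
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    h = max(seg.mean(), 1e-9)
    half_w = int(round(window_px / 2.0 / h / 2.0))
    k = min(2 * half_w + 1, n if n % 2 else n - 1)
    if k >= 3:
        kernel = np.ones(k) / k
        padded = np.concatenate([np.full(k // 2, theta[0]), theta,
                                 np.full(k // 2, theta[-1])])
        theta = np.convolve(padded, kernel, mode="valid")
    return theta


def solve_centerline(frame: np.ndarray, base_xy, tip_xy, *,
                     pixel_size_um: float = 1.0, window_px: int = 15,
                     tol_px: float = 0.05, max_iter: int = 50) -> CenterlineCurve:
    """Relax the chord between base and tip onto the intensity ridge.

    All geometry is solved in pixel units and converted to µm on return.
    Raises :class:`ConvergenceError` (carrying the last iterate) if the
    maximal node displacement does not fall below ``tol_px`` within
    ``max_iter`` relaxation sweeps.
    """
    frame = np.asarray(frame, dtype=float)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite values")
    base = np.asarray(base_xy, dtype=float)
    tip = np.asarray(tip_xy, dtype=float)
    chord = tip - base
    chord_len = float(np.linalg.norm(chord))
    if chord_len <= 1.0:
        raise ValueError("base and tip coincide (separation <= 1 pixel)")
    chord_angle = math.atan2(chord[1], chord[0])

    n_nodes = max(16, math.ceil(2 * chord_len))
    points = base[None] + np.linspace(0.0, 1.0, n_nodes)[:, None] * chord[None]

    last_disp = math.inf
    alpha = 1.0   # under-relaxation factor; halved when displacement grows
    history: list[float] = []
    for iteration in range(1, max_iter + 1):
        theta = _sample_branch(frame, points, window_px, chord_angle)

        seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
        length = float(seg.sum())
        h = length / (n_nodes - 1)

        dtheta = np.empty(n_nodes)
        dtheta[1:-1] = (theta[2:] - theta[:-2]) / (2 * h)
        dtheta[0] = (theta[1] - theta[0]) / h
        dtheta[-1] = (theta[-1] - theta[-2]) / h
        fx = -np.sin(theta) * dtheta
        fy = np.cos(theta) * dtheta

        new_points = np.empty_like(points)
        new_points[0], new_points[-1] = base, tip
        m = n_nodes - 2
        ab = np.zeros((3, m))
        ab[0, 1:] = 1.0
        ab[1, :] = -2.0
        ab[2, :-1] = 1.0
        for dim, f in ((0, fx), (1, fy)):
            rhs = h * h * f[1:-1]
            rhs[0] -= new_points[0, dim]
            rhs[-1] -= new_points[-1, dim]
            new_points[1:-1, dim] = solve_banded((1, 1), ab, rhs)

        resampled, _ = _resample_uniform(new_points, n_nodes)
        raw = float(np.max(np.linalg.norm(resampled - points, axis=1)))
        history.append(raw)
        if raw > last_disp:
            # oscillation around the (noise-fuzzy) fixed point: damp
            alpha = max(alpha * 0.5, 0.1)
        points, _ = _resample_uniform(points + alpha * (resampled - points),
                                      n_nodes)
        if alpha * raw < tol_px:
            return _finalize(frame, points, chord_angle, window_px,
                             pixel_size_um, iteration, history=history)
        last_disp = raw

    curve = _finalize(frame, points, chord_angle, window_px, pixel_size_um,
                      max_iter, converged=False, history=history)
    raise ConvergenceError(
        f"centerline relaxation did not converge in {max_iter} iterations "
        f"(last max displacement {last_disp:.3g} px)", curve)


def _finalize(frame, points_px, chord_angle, window_px, pixel_size_um,
              n_iter, converged=True, history=()) -> CenterlineCurve:
    theta = _sample_branch(frame, points_px, window_px, chord_angle)
    seg = np.linalg.norm(np.diff(points_px, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)]) * pixel_size_um
    return CenterlineCurve(s=s, points=points_px * pixel_size_um,
                           theta_s=theta, length_um=float(s[-1]),
                           converged=converged, n_iterations=n_iter,
                           disp_history_px=tuple(history))


def curve_length(curve: CenterlineCurve) -> float:
    """Base→tip distance along the centerline, in µm."""
    if len(curve) < 2:
        raise ValueError("curve needs at least 2 nodes")
    seg = np.linalg.norm(np.diff(curve.points, axis=0), axis=1)
    return float(seg.sum())
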