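"""Body/global motion features: corner detection and sparse pyramidal
Lucas-Kanade tracking.

Corners are scored by the minimum eigenvalue of the local structure tensor
(Shi-Tomasi) with the detector contract: at most ``max_corners`` points,
pairwise separation at least ``min_distance`` px, score at least ``quality``
times the best score.  Defaults (100, 0.3, 7, 7) and the tracker defaults
(window 15, 4 pyramid levels) follow the pipeline's stated operating point.

Tracking is iterative coarse-to-fine Lucas-Kanade on Gaussian image
pyramids, solved per point from the 2x2 structure tensor; points that leave
the frame or sit in untextured regions are flagged invalid and carry zero
displacement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max

from .io_formats import VideoClip
from .keyframes import LUMA, KeyframeResult

log = logging.getLogger(__name__)

MOTION_FEATURE_NAMES = ("of_mean_mag", "of_median_mag", "of_max_mag",
                        "of_mean_cos", "of_mean_sin", "of_valid_frac")


def to_gray(frame: np.ndarray) -> np.ndarray:
    """RGB (or already-gray) frame to float grayscale via luma weights."""
    frame = np.asarray(frame, dtype=float)
    if frame.ndim == 3:
        return frame @ LUMA
    return frame


@dataclass
class MotionField:
    """Tracked points and their frame-to-frame displacements."""

    points: np.ndarray         # (N, 2) positions (row, col) at frame t
    displacements: np.ndarray  # (N, 2) vectors t -> t+1; zero when invalid
    valid: np.ndarray          # (N,) bool

    def __post_init__(self) -> None:
        if len(self.points) != len(self.displacements) != len(self.valid):
            raise ValueError("points, displacements and flags must align")

    @property
    def new_points(self) -> np.ndarray:
        return self.points + self.displacements


# ---------------------------------------------------------------------------
# corner detection
# ---------------------------------------------------------------------------

def detect_corners(frame: np.ndarray, max_corners: int = 100,
                   quality: float = 0.3, min_distance: int = 7,
                   block_size: int = 7) -> np.ndarray:
    """Shi-Tomasi corners as an (N, 2) array of (row, col) positions.

    Returns an empty array on textureless input — not an error.
    """
    gray = to_gray(frame)
    gy, gx = np.gradient(gray)
    # structure tensor under a Gaussian window matched to block_size
    # (central differences + Gaussian weighting localise an ideal corner
    # to well under a pixel of bias)
    sigma = block_size / 6.0
    sxx = ndimage.gaussian_filter(gx * gx, sigma, mode="nearest")
    syy = ndimage.gaussian_filter(gy * gy, sigma, mode="nearest")
    sxy = ndimage.gaussian_filter(gx * gy, sigma, mode="nearest")
    # smaller eigenvalue of [[sxx, sxy], [sxy, syy]]
    tr = 0.5 * (sxx + syy)
    det = np.sqrt(np.maximum(0.25 * (sxx - syy) ** 2 + sxy ** 2, 0.0))
    response = tr - det
    if response.max() <= 0:
        return np.empty((0, 2))
    peaks = peak_local_max(response, min_distance=min_distance,
                           threshold_rel=quality, num_peaks=max_corners,
                           exclude_border=False)
    return peaks.astype(float)


# ---------------------------------------------------------------------------
# pyramidal Lucas-Kanade
# ---------------------------------------------------------------------------

def _build_pyramid(img: np.ndarray, max_level: int, window: int) -> list[np.ndarray]:
    levels = [img]
    for _ in range(max_level):
        cur = levels[-1]
        if min(cur.shape) < 2 * window:  # window must fit at the level
            break
        smooth = ndimage.gaussian_filter(cur, 1.0, mode="nearest")
        levels.append(smooth[::2, ::2])
    return levels


def _sample(img: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    return ndimage.map_coordinates(img, [rows, cols], order=1, mode="nearest")


def track_flow(prev_frame: np.ndarray, next_frame: np.ndarray,
               points: np.ndarray, window: int = 15, max_level: int = 4,
               max_iters: int = 10, eps: float = 0.01,
               min_eig: float = 1e-4) -> MotionField:
    """Track sparse points from ``prev_frame`` to ``next_frame``.

    Iterative Lucas-Kanade within a ``window`` x ``window`` patch, refined
    coarse-to-fine over up to ``max_level`` extra pyramid levels.  Points
    whose structure tensor is near-singular (aperture problem) or whose
    tracked position leaves the frame are flagged invalid with zero
    displacement.
    """
    prev = to_gray(prev_frame)
    nxt = to_gray(next_frame)
    if prev.shape != nxt.shape:
        raise ValueError("frames must share a common size")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        return MotionField(points=np.empty((0, 2)),
                           displacements=np.empty((0, 2)),
                           valid=np.empty(0, dtype=bool))
    n = len(pts)

    pyr_prev = _build_pyramid(prev, max_level, window)
    pyr_next = _build_pyramid(nxt, max_level, window)
    n_levels = len(pyr_prev)

    half = window // 2
    offs = np.arange(-half, half + 1, dtype=float)
    win_r, win_c = np.meshgrid(offs, offs, indexing="ij")
    win_r = win_r.ravel()
    win_c = win_c.ravel()

    flow = np.zeros((n, 2))
    valid = np.ones(n, dtype=bool)

    for level in range(n_levels - 1, -1, -1):
        scale = 2.0 ** level
        ip = pyr_prev[level]
        inx = pyr_next[level]
        gy = ndimage.sobel(ip, axis=0, mode="nearest") / 8.0
        gx = ndimage.sobel(ip, axis=1, mode="nearest") / 8.0

        p_lvl = pts / scale
        rows = p_lvl[:, 0:1] + win_r[None, :]   # (n, w*w)
        cols = p_lvl[:, 1:2] + win_c[None, :]
        templ = _sample(ip, rows, cols)
        ix = _sample(gx, rows, cols)
        iy = _sample(gy, rows, cols)
        g_rr = (iy * iy).sum(axis=1)
        g_cc = (ix * ix).sum(axis=1)
        g_rc = (iy * ix).sum(axis=1)
        det = g_rr * g_cc - g_rc ** 2
        tr = g_rr + g_cc
        lam_min = 0.5 * (tr - np.sqrt(np.maximum(tr ** 2 - 4 * det, 0.0)))
        solvable = lam_min / (window * window) > min_eig
        valid &= solvable
        det_safe = np.where(det == 0, 1.0, det)

        d = flow / scale
        for _ in range(max_iters):
            cur = _sample(inx, rows + d[:, 0:1], cols + d[:, 1:2])
            err = cur - templ
            b_r = -(err * iy).sum(axis=1)
            b_c = -(err * ix).sum(axis=1)
            step_r = (g_cc * b_r - g_rc * b_c) / det_safe
            step_c = (g_rr * b_c - g_rc * b_r) / det_safe
            step = np.column_stack([step_r, step_c])
            step[~solvable] = 0.0
            d += step
            if np.max(np.abs(step)) < eps:
                break
        flow = d * scale

    new_pts = pts + flow
    h, w = prev.shape
    inside = ((new_pts[:, 0] >= 0) & (new_pts[:, 0] <= h - 1)
              & (new_pts[:, 1] >= 0) & (new_pts[:, 1] <= w - 1))
    valid &= inside
    flow[~valid] = 0.0
    return MotionField(points=pts, displacements=flow, valid=valid)


# ---------------------------------------------------------------------------
# per-keyframe motion features
# ---------------------------------------------------------------------------

def field_summary(field: MotionField) -> np.ndarray:
    """Six-value summary of a motion field (see MOTION_FEATURE_NAMES)."""
    if len(field.points) == 0 or not field.valid.any():
        return np.zeros(len(MOTION_FEATURE_NAMES))
    d = field.displacements[field.valid]
    mags = np.linalg.norm(d, axis=1)
    nonzero = mags > 0
    if nonzero.any():
        units = d[nonzero] / mags[nonzero, None]
        mean_dir = units.mean(axis=0)
    else:
        mean_dir = np.zeros(2)
    return np.array([mags.mean(), np.median(mags), mags.max(),
                     mean_dir[1], mean_dir[0],       # (cos, sin) = (x, y)
                     field.valid.mean()])


def motion_features(clip: VideoClip, keyframes: KeyframeResult,
                    max_corners: int = 100, quality: float = 0.3,
                    min_distance: int = 7, block_size: int = 7,
                    window: int = 15, max_level: int = 4,
                    redetect_below: float = 0.5) -> np.ndarray:
    """Per-keyframe optical-flow summaries: (n_kept, 6) array.

    Corners are detected on the first keyframe and re-tracked across
    successive keyframes; when the valid-point fraction falls below
    ``redetect_below`` the corner set is re-detected (long clips would
    otherwise lose every point).  The final row is zero padding so the
    output aligns with the kept list.
    """
    kept = keyframes.kept
    if len(kept) < 2:
        raise ValueError("need at least two keyframes to measure motion")
    gray = [to_gray(clip.frames[i]) for i in kept]
    pts = detect_corners(gray[0], max_corners, quality, min_distance, block_size)
    if len(pts) == 0:
        log.warning("clip %s: no trackable corners; motion features zeroed",
                    clip.clip_id)
        return np.zeros((len(kept), len(MOTION_FEATURE_NAMES)))
    rows = []
    for a in range(len(kept) - 1):
        if len(pts) == 0:
            rows.append(np.zeros(len(MOTION_FEATURE_NAMES)))
            continue
        field = track_flow(gray[a], gray[a + 1], pts, window, max_level)
        rows.append(field_summary(field))
        pts = field.new_points[field.valid]
        if (len(field.valid) and field.valid.mean() < redetect_below):
            log.info("clip %s: re-detecting corners at keyframe %d "
                     "(valid fraction %.2f)", clip.clip_id, a + 1,
                     field.valid.mean())
            pts = detect_corners(gray[a + 1], max_corners, quality,
                                 min_distance, block_size)
    rows.append(np.zeros(len(MOTION_FEATURE_NAMES)))  # pad to kept length
    return np.stack(rows)
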