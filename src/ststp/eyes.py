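"""Eye-blink (EAR) features, iris localisation, eyebrow offsets, and the
landmark-error / R-squared confidence statistics.

The eye aspect ratio is computed from the six eye-contour landmarks
l1..l6 (l1/l4 the horizontal corners, l2/l3 upper lid, l5/l6 lower lid):

    EAR = (||l2 - l6|| + ||l3 - l5||) / (2 ||l1 - l4||)

EAR is scale-, rotation- and translation-invariant and collapses toward 0
when the lids close, so blinks appear as short runs of sub-threshold EAR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.exposure import equalize_adapthist
from skimage.transform import hough_circle, hough_circle_peaks


class DegenerateGeometryError(ValueError):
    """Eye landmarks with zero width cannot yield an aspect ratio."""


# ---------------------------------------------------------------------------
# eye aspect ratio
# ---------------------------------------------------------------------------

def compute_ear(landmarks: np.ndarray) -> float:
    """EAR from a (6, 2) array of eye-contour points l1..l6."""
    pts = np.asarray(landmarks, dtype=float)
    if pts.shape != (6, 2):
        raise ValueError("expected six 2-D eye landmarks")
    l1, l2, l3, l4, l5, l6 = pts
    width = np.linalg.norm(l1 - l4)
    if width == 0:
        raise DegenerateGeometryError("eye corners coincide (zero width)")
    return float((np.linalg.norm(l2 - l6) + np.linalg.norm(l3 - l5)) / (2 * width))


def ear_series(eye_points: np.ndarray) -> np.ndarray:
    """Vectorised EAR over a (T, 6, 2) landmark stack."""
    pts = np.asarray(eye_points, dtype=float)
    width = np.linalg.norm(pts[:, 0] - pts[:, 3], axis=1)
    if np.any(width == 0):
        raise DegenerateGeometryError("zero eye width at some frame")
    v1 = np.linalg.norm(pts[:, 1] - pts[:, 5], axis=1)
    v2 = np.linalg.norm(pts[:, 2] - pts[:, 4], axis=1)
    return (v1 + v2) / (2 * width)


# ---------------------------------------------------------------------------
# blink events
# ---------------------------------------------------------------------------

@dataclass
class BlinkEvent:
    start: int   # first frame index below threshold
    end: int     # last frame index below threshold (inclusive)
    depth: float  # minimum EAR inside the event

    @property
    def duration(self) -> int:
        return self.end - self.start + 1


def detect_blinks(ear: np.ndarray, threshold: float = 0.2,
                  min_frames: int = 2) -> list[BlinkEvent]:
    """Maximal runs of EAR < threshold lasting at least ``min_frames``."""
    ear = np.asarray(ear, dtype=float)
    if len(ear) < min_frames:
        raise ValueError(f"series shorter than min_frames={min_frames}")
    below = ear < threshold
    events: list[BlinkEvent] = []
    start = None
    for i, b in enumerate(below):
        if b and start is None:
            start = i
        elif not b and start is not None:
            if i - start >= min_frames:
                events.append(BlinkEvent(start, i - 1, float(ear[start:i].min())))
            start = None
    if start is not None and len(ear) - start >= min_frames:
        events.append(BlinkEvent(start, len(ear) - 1, float(ear[start:].min())))
    return events


# ---------------------------------------------------------------------------
# iris localisation
# ---------------------------------------------------------------------------

def locate_iris(patch: np.ndarray, radius_range: tuple[int, int] = (3, 12),
                min_accum: float = 0.65, clahe: bool = False):
    """Strongest Hough circle in a grayscale eye patch, or None.

    Returns ``(cy, cx, radius)`` for the best circle whose normalised
    accumulator peak reaches ``min_accum``; otherwise None.  A closed eye
    (no dark disc) yields a weak accumulator and hence None — absence of a
    circle is the blink signal, not an error.
    """
    patch = np.asarray(patch, dtype=float)
    if patch.ndim != 2 or min(patch.shape) < 8:
        raise ValueError("patch must be a grayscale array of at least 8x8")
    rng_span = patch.max() - patch.min()
    if rng_span == 0:
        return None
    img = (patch - patch.min()) / rng_span
    if clahe:
        img = equalize_adapthist(img)
    # iris is dark on a bright sclera: edges of the inverted image
    gy, gx = np.gradient(img)
    edges = np.hypot(gx, gy)
    edges = edges > (0.5 * edges.max())
    radii = np.arange(radius_range[0], radius_range[1] + 1)
    # hough_circle normalises each radius's accumulator: a complete circle
    # of edge pixels scores ~1.0
    accum = hough_circle(edges, radii)
    accums, cxs, cys, rads = hough_circle_peaks(
        accum, radii, total_num_peaks=1, normalize=False)
    if len(accums) == 0 or accums[0] < min_accum:
        return None
    return int(cys[0]), int(cxs[0]), int(rads[0])


# ---------------------------------------------------------------------------
# eyebrow offsets
# ---------------------------------------------------------------------------

def eyebrow_offsets(brows: np.ndarray, left_eye: np.ndarray,
                    right_eye: np.ndarray) -> np.ndarray:
    """Vertical offset of each eyebrow point V1..V3 from the eye-corner line.

    Offsets are measured per frame against the line through the two outer
    eye corners (positive = above the line in image coordinates), so the
    feature is invariant to global translation.
    Input stacks are (T, 3, 2) and (T, 6, 2); output is (T, 3).
    """
    brows = np.asarray(brows, dtype=float)
    a = np.asarray(left_eye, dtype=float)[:, 0]   # outer corner, left eye
    b = np.asarray(right_eye, dtype=float)[:, 0]  # outer corner, right eye
    d = b - a
    norm = np.linalg.norm(d, axis=1)
    norm[norm == 0] = 1.0
    # signed perpendicular distance of each brow point from the corner line
    rel = brows - a[:, None, :]
    cross = d[:, None, 0] * rel[..., 1] - d[:, None, 1] * rel[..., 0]
    return -cross / norm[:, None]  # minus: y grows downward, "above" positive


# ---------------------------------------------------------------------------
# confidence statistics
# ---------------------------------------------------------------------------

def landmark_error(predicted: np.ndarray, template: np.ndarray,
                   inter_ocular: float) -> float:
    """Average relative landmark localisation error, in percent.

    ``100 / (S * U) * sum_i ||O_i - O_i'||`` with S landmarks and U the
    inter-ocular distance; 0 for a perfect detection, 100 when every
    landmark is displaced by exactly U.
    """
    predicted = np.asarray(predicted, dtype=float)
    template = np.asarray(template, dtype=float)
    if predicted.shape != template.shape or predicted.ndim != 2:
        raise ValueError("predicted and template must be equal-shape point lists")
    if inter_ocular <= 0:
        raise ValueError("inter-ocular distance must be positive")
    S = len(template)
    dev = np.linalg.norm(predicted - template, axis=1).sum()
    return float(100.0 / (S * inter_ocular) * dev)


def r_squared(observed: np.ndarray, fitted: np.ndarray) -> float:
    """Coefficient of determination R^2 = 1 - SSE/SST."""
    observed = np.asarray(observed, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if observed.shape != fitted.shape or observed.ndim != 1 or len(observed) < 2:
        raise ValueError("need two equal-length series of at least 2 points")
    sst = np.sum((observed - observed.mean()) ** 2)
    if sst == 0:
        raise ValueError("observed series is constant (SST = 0)")
    sse = np.sum((observed - fitted) ** 2)
    return float(1.0 - sse / sst)


def confidence_matrix(series: dict[str, np.ndarray]) -> "pd.DataFrame":
    """Pairwise R^2 confidence table between named feature series.

    Entry (i, j), j <= i, is the R^2 of the least-squares straight-line fit
    of series j onto series i (the diagonal is the self-fit, identically 1).
    Mirrors the lower-triangle-plus-diagonal layout of printed confidence
    tables.
    """
    import pandas as pd

    names = list(series)
    if len(names) < 2:
        raise ValueError("need at least two series")
    arrs = {}
    n = None
    for name in names:
        a = np.asarray(series[name], dtype=float)
        if n is None:
            n = len(a)
        if len(a) != n:
            raise ValueError("series must share a common length")
        if np.ptp(a) == 0:
            raise ValueError(f"series {name!r} is constant")
        arrs[name] = a
    out = pd.DataFrame(np.nan, index=names, columns=names)
    for i, ni in enumerate(names):
        for j, nj in enumerate(names[: i + 1]):
            slope, intercept = np.polyfit(arrs[nj], arrs[ni], 1)
            fitted = slope * arrs[nj] + intercept
            out.loc[ni, nj] = r_squared(arrs[ni], fitted)
    return out


# ---------------------------------------------------------------------------
# per-keyframe EAR feature block
# ---------------------------------------------------------------------------

EAR_FEATURE_NAMES = ("ear_left", "ear_right", "brow_v1", "brow_v2", "brow_v3")


def ear_feature_block(stream, kept: np.ndarray) -> np.ndarray:
    """Per-keyframe EAR/eyebrow features: (n_kept, 5) array.

    Columns: left EAR, right EAR, V1..V3 eyebrow offsets.  An absent eye
    modality yields exact zeros (the zero-padding convention).
    """
    kept = np.asarray(kept, dtype=int)
    if not stream.has_eyes:
        return np.zeros((len(kept), len(EAR_FEATURE_NAMES)))
    le = ear_series(stream.left_eye[kept])
    re = ear_series(stream.right_eye[kept])
    brows = eyebrow_offsets(stream.brows[kept], stream.left_eye[kept],
                            stream.right_eye[kept])
    return np.column_stack([le, re, brows])
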