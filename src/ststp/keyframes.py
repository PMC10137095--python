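"""Keyframe selection by the frame-difference threshold rule.

Each frame gets a scalar signature K_i (its grayscale pixel sum).  The
data-derived threshold is

    T = (P / V) * sum_{i=1..V-1} |K_i - K_{i+1}|

with V the frame count and P a scale parameter.  Frame i (i < V) is kept
iff |K_i - K_{i+1}| > T; the first frame is always kept so the result is
never empty.  Larger P can only shrink the kept set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import VideoClip

#: luma weights for RGB -> grayscale conversion
LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class KeyframeResult:
    signatures: np.ndarray   # per-frame K_i
    threshold: float         # T
    scale_param: float       # P
    kept: np.ndarray         # strictly increasing frame indices, 0-based

    def __post_init__(self) -> None:
        self.signatures = np.asarray(self.signatures, dtype=float)
        self.kept = np.asarray(self.kept, dtype=int)
        if len(self.kept) == 0:
            raise ValueError("kept set must be non-empty (first frame forced)")
        if np.any(np.diff(self.kept) <= 0):
            raise ValueError("kept indices must be strictly increasing")

    @property
    def n_kept(self) -> int:
        return len(self.kept)


def frame_signatures(clip: VideoClip) -> np.ndarray:
    """Grayscale intensity sum per frame (channel-order independent)."""
    gray = clip.frames.astype(float) @ LUMA
    return gray.sum(axis=(1, 2))


def compute_threshold(signatures: np.ndarray, scale_param: float = 1.0) -> float:
    """Data-derived keyframe threshold T from the signature series."""
    signatures = np.asarray(signatures, dtype=float)
    if signatures.ndim != 1 or len(signatures) < 2:
        raise ValueError("need at least two frame signatures to form differences")
    if scale_param < 0:
        raise ValueError("scale parameter P must be non-negative")
    V = len(signatures)
    return float(scale_param / V * np.abs(np.diff(signatures)).sum())


def select_from_signatures(signatures: np.ndarray,
                           scale_param: float = 1.0) -> KeyframeResult:
    """Apply the threshold rule to a precomputed signature series."""
    signatures = np.asarray(signatures, dtype=float)
    T = compute_threshold(signatures, scale_param)
    diffs = np.abs(np.diff(signatures))
    kept = np.flatnonzero(diffs > T)
    if len(kept) == 0 or kept[0] != 0:
        kept = np.concatenate([[0], kept])
    return KeyframeResult(signatures=signatures, threshold=T,
                          scale_param=scale_param, kept=kept)


def select_keyframes(clip: VideoClip, scale_param: float = 1.0) -> KeyframeResult:
    """Select salient frames of a clip by the signature-difference rule."""
    if len(clip) < 2:
        # single frame: no differences; the lone frame is the key set
        return KeyframeResult(signatures=frame_signatures(clip), threshold=0.0,
                              scale_param=scale_param, kept=np.array([0]))
    return select_from_signatures(frame_signatures(clip), scale_param)
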