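"""Hand-pose vectors and their Karhunen-Loeve (PCA) projection.

A detected hand contributes 20 retained joints (thumb t1-t3, index i1-i3,
middle m1-m4, ring r1-r4, little p1-p4 and the wrist w; the extracted palm
centre is dropped as uninformative for these gestures).  Two-hand frames
additionally carry the wrist-wrist distance sigma.  Every frame is embedded
in the two-hand superset layout (2 x 40 coordinates + sigma = 81 values)
with missing hands zeroed, so all clips share one column schema.

The pose matrix is reduced by a mean-centred eigendecomposition of its
covariance (the Karhunen-Loeve transform): g = B (f - mean(f)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import HAND_JOINT_LABELS, LandmarkStream, N_HAND_JOINTS

#: length of the uniform (two-hand superset) pose vector
POSE_VECTOR_LEN = 2 * N_HAND_JOINTS * 2 + 1  # 81
WRIST_INDEX = HAND_JOINT_LABELS.index("w")


def hand_pose_vector(stream: LandmarkStream, frame_idx: int) -> np.ndarray:
    """Flat pose vector for one frame in the uniform two-hand layout.

    Layout: hand-1 joints (40), hand-2 joints (40), sigma (1).  A single
    detected hand leaves the second slice and sigma at zero; an absent hand
    modality yields the all-zero vector.
    """
    if not 0 <= frame_idx < len(stream):
        raise IndexError(f"frame index {frame_idx} out of range")
    if not stream.has_hands:
        return np.zeros(POSE_VECTOR_LEN)
    joints = np.asarray(stream.hands[frame_idx], dtype=float)
    if joints.shape != (2, N_HAND_JOINTS, 2) or not np.all(np.isfinite(joints)):
        raise ValueError(f"malformed hand joint record at frame {frame_idx}")
    present = [h for h in range(2) if np.any(joints[h] != 0)]
    vec = np.zeros(POSE_VECTOR_LEN)
    for h in present:
        off = h * N_HAND_JOINTS * 2
        vec[off:off + N_HAND_JOINTS * 2] = joints[h].ravel()
    if len(present) == 2:
        vec[-1] = inter_hand_distance(joints[0], joints[1])
    return vec


def inter_hand_distance(hand1: np.ndarray, hand2: np.ndarray) -> float:
    """sigma: Euclidean distance between the two wrists."""
    return float(np.linalg.norm(np.asarray(hand1, float)[WRIST_INDEX]
                                - np.asarray(hand2, float)[WRIST_INDEX]))


def pose_matrix(stream: LandmarkStream, kept: np.ndarray) -> np.ndarray:
    """Stack of pose vectors for the kept keyframes: (n_kept, 81)."""
    kept = np.asarray(kept, dtype=int)
    return np.stack([hand_pose_vector(stream, i) for i in kept])


# ---------------------------------------------------------------------------
# Karhunen-Loeve transform
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    mean: np.ndarray                # per-coordinate mean(f)
    basis: np.ndarray               # B, rows orthonormal, (k, dim)
    explained_variance: np.ndarray  # eigenvalues, non-increasing

    def __post_init__(self) -> None:
        if not np.allclose(self.basis @ self.basis.T,
                           np.eye(len(self.basis)), atol=1e-8):
            raise ValueError("basis rows are not orthonormal")
        if np.any(np.diff(self.explained_variance) > 1e-10):
            raise ValueError("explained variances must be non-increasing")

    @property
    def n_components(self) -> int:
        return len(self.basis)


def pca_fit(poses: np.ndarray, n_components: int = 10) -> PCAModel:
    """Fit the KL transform by eigendecomposition of the pose covariance.

    Component signs are fixed deterministically: the largest-magnitude
    loading of each basis row is made positive.
    """
    X = np.asarray(poses, dtype=float)
    if X.ndim != 2 or len(X) < 2:
        raise ValueError("need a 2-D pose matrix with at least 2 rows")
    if not 1 <= n_components <= min(X.shape):
        raise ValueError("n_components must be in [1, min(rows, dim)]")
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = Xc.T @ Xc / (len(X) - 1)
    if np.allclose(cov, 0):
        raise ValueError("constant pose matrix: zero covariance")
    evals, evecs = np.linalg.eigh(cov)           # ascending
    order = np.argsort(evals)[::-1][:n_components]
    basis = evecs[:, order].T.copy()
    evals = np.maximum(evals[order], 0.0)
    for row in basis:                            # deterministic sign
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1
    return PCAModel(mean=mean, basis=basis, explained_variance=evals)


def pca_project(model: PCAModel, poses: np.ndarray) -> np.ndarray:
    """g = B (f - mean(f)); accepts a single pose or a stack."""
    X = np.asarray(poses, dtype=float)
    single = X.ndim == 1
    if single:
        X = X[None]
    if X.shape[1] != model.mean.shape[0]:
        raise ValueError(
            f"pose dimension {X.shape[1]} does not match model "
            f"dimension {model.mean.shape[0]}")
    g = (X - model.mean) @ model.basis.T
    return g[0] if single else g


def pca_reconstruct(model: PCAModel, g: np.ndarray) -> np.ndarray:
    """Inverse transform: f = B^T g + mean(f)."""
    g = np.asarray(g, dtype=float)
    return g @ model.basis + model.mean
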