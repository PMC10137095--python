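"""Multi-modal feature fusion and guided (floating add/drop) selection.

The fused per-keyframe vector concatenates the modality blocks in the fixed
order CNN, OF, PCA, EAR, with recorded slice offsets so the concatenation is
exactly invertible; an absent modality contributes an all-zero slice.

Selection scores a candidate column subset S by the relevance-vs-redundancy
merit

    J(S) = sum_{x in S} rel(x) / sqrt(|S| + sum_{l != u in S} red(l, u))

where rel(x) is the R^2 of a straight-line fit of the class label on the
column and red(l, u) the pairwise column R^2 (the "confidence score":
columns that predict each other well are redundant and penalised).  The
search is greedy sequential forward selection with a floating drop step,
deterministic with a lowest-column-index tie-break.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .eyes import EAR_FEATURE_NAMES
from .motion import MOTION_FEATURE_NAMES

MODALITY_ORDER = ("CNN", "OF", "PCA", "EAR")


@dataclass
class STSTPVector:
    """Fused per-keyframe feature rows with named modality slices."""

    matrix: np.ndarray               # (n_keyframes, total_dim)
    slices: dict[str, tuple[int, int]]  # name -> (offset, length)

    def __post_init__(self) -> None:
        total = sum(l for _, l in self.slices.values())
        if self.matrix.shape[1] != total:
            raise ValueError("slice bookkeeping does not cover the matrix")

    def block(self, name: str) -> np.ndarray:
        off, length = self.slices[name]
        return self.matrix[:, off:off + length]

    @property
    def column_names(self) -> list[str]:
        names = []
        for mod in MODALITY_ORDER:
            _, length = self.slices[mod]
            if mod == "OF" and length == len(MOTION_FEATURE_NAMES):
                names += list(MOTION_FEATURE_NAMES)
            elif mod == "EAR" and length == len(EAR_FEATURE_NAMES):
                names += list(EAR_FEATURE_NAMES)
            else:
                names += [f"{mod.lower()}_{i}" for i in range(length)]
        return names


def build_ststp(cnn_emb, of_vec, pca_vec, ear_vec) -> STSTPVector:
    """Concatenate modality blocks (CNN, OF, PCA, EAR) per keyframe.

    Each block is (n_keyframes, d_block); any block may be all-zero (absent
    modality placeholder) but row counts must agree.
    """
    blocks = {"CNN": np.atleast_2d(np.asarray(cnn_emb, dtype=float)),
              "OF": np.atleast_2d(np.asarray(of_vec, dtype=float)),
              "PCA": np.atleast_2d(np.asarray(pca_vec, dtype=float)),
              "EAR": np.atleast_2d(np.asarray(ear_vec, dtype=float))}
    rows = {name: b.shape[0] for name, b in blocks.items()}
    if len(set(rows.values())) != 1:
        raise ValueError(f"modality blocks disagree on keyframe count: {rows}")
    slices = {}
    off = 0
    for name in MODALITY_ORDER:
        length = blocks[name].shape[1]
        slices[name] = (off, length)
        off += length
    matrix = np.concatenate([blocks[n] for n in MODALITY_ORDER], axis=1)
    return STSTPVector(matrix=matrix, slices=slices)


# ---------------------------------------------------------------------------
# selection criterion
# ---------------------------------------------------------------------------

def _fit_r2(x: np.ndarray, y: np.ndarray) -> float:
    """R^2 of the least-squares straight-line fit of y on x.

    Equals the squared Pearson correlation; 0 when x is constant.
    """
    vx = x - x.mean()
    vy = y - y.mean()
    sxx = vx @ vx
    syy = vy @ vy
    if sxx == 0 or syy == 0:
        return 0.0
    r = (vx @ vy) / np.sqrt(sxx * syy)
    return float(r * r)


def relevance(features: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-column label relevance: R^2 of the label on each column."""
    y = np.asarray(labels, dtype=float)
    X = np.asarray(features, dtype=float)
    return np.array([_fit_r2(X[:, j], y) for j in range(X.shape[1])])


def redundancy_matrix(features: np.ndarray) -> np.ndarray:
    """Pairwise column R^2 (symmetric, unit diagonal)."""
    X = np.asarray(features, dtype=float)
    Xc = X - X.mean(axis=0)
    ss = (Xc ** 2).sum(axis=0)
    denom = np.sqrt(np.outer(ss, ss))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, Xc.T @ Xc / denom, 0.0)
    np.fill_diagonal(r, 1.0)
    return r ** 2


def selection_criterion(subset, features: np.ndarray, labels: np.ndarray,
                        rel: np.ndarray | None = None,
                        red: np.ndarray | None = None) -> float:
    """Merit J of a column subset (higher is better)."""
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    if rel is None:
        rel = relevance(features, labels)
    if red is None:
        red = redundancy_matrix(features)
    idx = np.asarray(subset, dtype=int)
    k = len(idx)
    total_red = red[np.ix_(idx, idx)].sum() - k  # ordered pairs l != u
    return float(rel[idx].sum() / np.sqrt(k + total_red))


# ---------------------------------------------------------------------------
# guided selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionState:
    pool: list[int]                  # candidate columns after the gate
    selected: list[int]              # final subset, in selection order
    j_history: list[float]           # J after each accepted add/drop
    steps: list[tuple[str, int]]     # ("add"|"drop", column)

    @property
    def final_j(self) -> float:
        return self.j_history[-1] if self.j_history else float("nan")


def guided_select(features: np.ndarray, labels: np.ndarray,
                  tol: float = 1e-4, gate_factor: float = 0.0,
                  max_features: int | None = None) -> SelectionState:
    """Greedy floating forward selection maximising the merit J.

    At each step the pool column with the best J is added; then any selected
    column whose removal improves J is dropped (floating step).  Stops when
    the best improvement is below ``tol`` or the pool is exhausted.  Columns
    with constant values are excluded with a warning; ``gate_factor`` > 0
    additionally pre-filters columns whose relevance is below
    ``gate_factor`` times the pool's mean relevance.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray([1 if l == "LIE" else 0 if l == "TRUTH" else int(l)
                    for l in labels], dtype=float)
    if len(set(y.tolist())) < 2:
        raise ValueError("labels contain a single class")
    rel = relevance(X, y)
    red = redundancy_matrix(X)

    pool = []
    for j in range(X.shape[1]):
        if np.ptp(X[:, j]) == 0:
            warnings.warn(f"column {j} is constant; excluded from selection")
            continue
        pool.append(j)
    if gate_factor > 0 and pool:
        cut = gate_factor * rel[pool].mean()
        pool = [j for j in pool if rel[j] >= cut]
    if len(pool) < 2:
        raise ValueError("need at least two usable feature columns")

    selected: list[int] = []
    j_hist: list[float] = []
    steps: list[tuple[str, int]] = []
    j_cur = -np.inf
    limit = max_features or len(pool)

    def J(s):
        return selection_criterion(s, X, y, rel=rel, red=red)

    while len(selected) < limit:
        candidates = [c for c in pool if c not in selected]
        if not candidates:
            break
        best_c, best_j = None, -np.inf
        for c in candidates:  # ascending index = lowest-index tie-break
            jj = J(selected + [c])
            if jj > best_j + 1e-15:
                best_c, best_j = c, jj
        if best_j <= j_cur + tol and selected:
            break
        selected.append(best_c)
        j_cur = best_j
        j_hist.append(j_cur)
        steps.append(("add", best_c))
        # floating drop: remove the member whose removal most improves J
        while len(selected) > 2:
            best_d, best_jd = None, j_cur
            for d in selected[:-1]:  # never drop the one just added
                rest = [s for s in selected if s != d]
                jj = J(rest)
                if jj > best_jd + tol:
                    best_d, best_jd = d, jj
            if best_d is None:
                break
            selected = [s for s in selected if s != best_d]
            j_cur = best_jd
            j_hist.append(j_cur)
            steps.append(("drop", best_d))
    return SelectionState(pool=pool, selected=selected,
                          j_history=j_hist, steps=steps)
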