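"""Evaluation: confusion metrics, ROC/AUC, stratified k-fold protocol,
modality ablations, and descriptive cue statistics.

LIE is the positive class throughout.  Confusion entries follow the
a1 (true positive), a2 (true negative), b1 (false positive),
b2 (false negative) convention:

    Acc = (a1 + a2) / (a1 + a2 + b1 + b2)
    TPR = a1 / (a1 + b2)        TNR = a2 / (a2 + b1)

Metrics with zero denominators are reported as missing (None), never as 0,
so fold averages stay honest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .fusion import MODALITY_ORDER, build_ststp, guided_select
from .hands import pca_fit, pca_project
from .model import Hyperparams, train_model

log = logging.getLogger(__name__)


@dataclass
class EvalReport:
    a1: int  # true positives (LIE called LIE)
    a2: int  # true negatives
    b1: int  # false positives
    b2: int  # false negatives
    acc: float | None
    tpr: float | None
    tnr: float | None
    auc: float | None = None
    folds: list | None = None

    @property
    def n(self) -> int:
        return self.a1 + self.a2 + self.b1 + self.b2

    def as_dict(self) -> dict:
        return {"a1": self.a1, "a2": self.a2, "b1": self.b1, "b2": self.b2,
                "acc": self.acc, "tpr": self.tpr, "tnr": self.tnr,
                "auc": self.auc}


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def confusion_metrics(labels, predictions) -> EvalReport:
    """Confusion-matrix metrics from binary label/prediction vectors.

    Accepts LIE/TRUTH strings or {0,1} ints (1 = LIE = positive).
    """
    y = _to_binary(labels)
    p = _to_binary(predictions)
    if len(y) == 0 or len(y) != len(p):
        raise ValueError("need equal-length, non-empty label vectors")
    a1 = int(np.sum((y == 1) & (p == 1)))
    a2 = int(np.sum((y == 0) & (p == 0)))
    b1 = int(np.sum((y == 0) & (p == 1)))
    b2 = int(np.sum((y == 1) & (p == 0)))
    return EvalReport(a1=a1, a2=a2, b1=b1, b2=b2,
                      acc=_ratio(a1 + a2, a1 + a2 + b1 + b2),
                      tpr=_ratio(a1, a1 + b2),
                      tnr=_ratio(a2, a2 + b1))


def _to_binary(values) -> np.ndarray:
    out = []
    for v in values:
        if isinstance(v, str):
            out.append(1 if v == "LIE" else 0)
        else:
            out.append(int(v))
    return np.asarray(out, dtype=int)


def roc_auc(labels, scores) -> tuple[np.ndarray, np.ndarray, float]:
    """Empirical ROC (FPR, TPR) and trapezoidal AUC, LIE positive."""
    y = _to_binary(labels)
    fpr, tpr, _ = roc_curve(y, np.asarray(scores, dtype=float))
    return fpr, tpr, float(_trapezoid_auc(fpr, tpr))


# ---------------------------------------------------------------------------
# k-fold protocol
# ---------------------------------------------------------------------------

@dataclass
class FoldOutcome:
    test_idx: np.ndarray
    scores: np.ndarray      # P(LIE) per test subject
    predictions: np.ndarray
    report: EvalReport
    selected: list | None = None


def _prepare_sequences(raw_blocks: list[dict], pca_model, n_components,
                       selected_cols=None):
    """Fuse per-subject modality blocks into beta sequences."""
    seqs = []
    for blocks in raw_blocks:
        hand = blocks["HAND_RAW"]
        if np.ptp(hand) == 0:     # absent modality stays exactly zero
            pca_vec = np.zeros((len(hand), n_components))
        else:
            pca_vec = pca_project(pca_model, hand)
        beta = build_ststp(blocks["CNN"], blocks["OF"], pca_vec,
                           blocks["EAR"]).matrix
        if selected_cols is not None:
            beta = beta[:, selected_cols]
        seqs.append(beta)
    return seqs


def fit_fold_models(raw_blocks, labels, train_idx, n_components=10,
                    use_selection=False, selection_tol=1e-4,
                    hyper: Hyperparams | None = None, seed: int = 0):
    """Fit PCA (and optionally selection + classifier) on training subjects
    only; returns the fused train sequences and the fitted transforms."""
    hand_rows = np.vstack([raw_blocks[i]["HAND_RAW"] for i in train_idx])
    if np.ptp(hand_rows) == 0:
        # hands absent in the entire fold: keep a trivial zero projection
        n_components = min(n_components, hand_rows.shape[1])
        from .hands import PCAModel
        pca_model = PCAModel(mean=np.zeros(hand_rows.shape[1]),
                             basis=np.eye(hand_rows.shape[1])[:n_components],
                             explained_variance=np.zeros(n_components))
    else:
        pca_model = pca_fit(hand_rows, n_components=n_components)

    train_blocks = [raw_blocks[i] for i in train_idx]
    train_seqs = _prepare_sequences(train_blocks, pca_model, n_components)
    selected = None
    if use_selection:
        # selection statistics are computed on per-subject temporal means,
        # not raw keyframe rows: within-subject pseudo-replication would
        # otherwise inflate the apparent relevance of noise columns
        X = np.stack([s.mean(axis=0) for s in train_seqs])
        y = np.array([1 if labels[i] == "LIE" else 0 for i in train_idx])
        try:
            state = guided_select(X, y, tol=selection_tol)
            selected = sorted(state.selected)
        except ValueError:
            selected = None
        if selected:
            train_seqs = [s[:, selected] for s in train_seqs]
    return train_seqs, pca_model, selected


def kfold_evaluate(raw_blocks: list[dict], labels: list[str], k: int = 10,
                   n_components: int = 10, use_selection: bool = False,
                   selection_tol: float = 0.01,
                   hyper: Hyperparams | None = None, seed: int = 0):
    """Subject-level stratified k-fold evaluation of the full pipeline.

    ``raw_blocks`` holds per-subject modality blocks (keys CNN, OF,
    HAND_RAW, EAR, each (n_keyframes, d)); PCA and selection are fitted
    inside training folds only.  Returns (per-fold outcomes, pooled
    EvalReport with trapezoidal AUC from pooled fold scores).
    """
    labels = list(labels)
    n = len(raw_blocks)
    if k > n:
        raise ValueError(f"k={k} exceeds subject count {n}")
    y = _to_binary(labels)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    outcomes = []
    all_scores = np.zeros(n)
    all_preds = np.zeros(n, dtype=int)
    for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros(n), y)):
        train_seqs, pca_model, selected = fit_fold_models(
            raw_blocks, labels, train_idx, n_components=n_components,
            use_selection=use_selection, selection_tol=selection_tol,
            hyper=hyper, seed=seed + fold)
        model, _ = train_model(train_seqs, [labels[i] for i in train_idx],
                               hyper=hyper, seed=seed + fold)
        test_seqs = _prepare_sequences([raw_blocks[i] for i in test_idx],
                                       pca_model, n_components,
                                       selected_cols=selected)
        probs = model.predict_proba(test_seqs)
        scores = probs[:, 1]
        preds = (scores >= 0.5).astype(int)
        all_scores[test_idx] = scores
        all_preds[test_idx] = preds
        outcomes.append(FoldOutcome(
            test_idx=test_idx, scores=scores, predictions=preds,
            report=confusion_metrics(y[test_idx], preds), selected=selected))
    pooled = confusion_metrics(y, all_preds)
    _, _, pooled.auc = roc_auc(y, all_scores)
    pooled.folds = [o.report.as_dict() for o in outcomes]
    return outcomes, pooled


# ---------------------------------------------------------------------------
# ablations
# ---------------------------------------------------------------------------

#: the seven standard configurations: three singles, three pairs, and the
#: full fusion with and without guided selection
ABLATION_CONFIGS: dict[str, tuple[tuple[str, ...], bool]] = {
    "OF": (("OF",), False),
    "Hand-PCA": (("PCA",), False),
    "EAR": (("EAR",), False),
    "OF+Hand-PCA": (("OF", "PCA"), False),
    "OF+EAR": (("OF", "EAR"), False),
    "Hand-PCA+EAR": (("PCA", "EAR"), False),
    "Multi-STSTP": (("CNN", "OF", "PCA", "EAR"), True),
}


def _mask_blocks(raw_blocks, keep: tuple[str, ...]):
    """Zero out modality blocks not in ``keep`` (layout unchanged)."""
    masked = []
    for blocks in raw_blocks:
        out = {}
        for name in ("CNN", "OF", "HAND_RAW", "EAR"):
            mod = "PCA" if name == "HAND_RAW" else name
            arr = blocks[name]
            out[name] = arr if mod in keep else np.zeros_like(arr)
        masked.append(out)
    return masked


def ablation_run(raw_blocks, labels, configs: dict | None = None, k: int = 5,
                 n_components: int = 10, selection_tol: float = 0.01,
                 hyper: Hyperparams | None = None,
                 seed: int = 0) -> pd.DataFrame:
    """Accuracy per modality subset, in the standard seven-row layout."""
    configs = configs or ABLATION_CONFIGS
    rows = []
    for name, (keep, use_sel) in configs.items():
        bad = set(keep) - set(MODALITY_ORDER)
        if bad or not keep:
            raise ValueError(f"unknown or empty modality subset: {keep}")
        masked = _mask_blocks(raw_blocks, keep)
        _, pooled = kfold_evaluate(masked, labels, k=k,
                                   n_components=n_components,
                                   use_selection=use_sel,
                                   selection_tol=selection_tol, hyper=hyper,
                                   seed=seed)
        rows.append({"model": name, "features": "+".join(keep),
                     "accuracy": pooled.acc, "auc": pooled.auc})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# descriptive cue statistics
# ---------------------------------------------------------------------------

def cue_statistics(annotations: pd.DataFrame) -> pd.DataFrame:
    """Mean cue intensity per gender x class stratum.

    ``annotations`` needs columns ``gender``, ``label`` and one column per
    cue (e.g. blink_rate, body_motion_amplitude, ...).  Returns per-stratum
    means plus subject counts; cue columns are also ranked by their overall
    mean so the dominant cue is explicit.
    """
    if len(annotations) == 0:
        raise ValueError("empty cohort")
    for req in ("gender", "label"):
        if req not in annotations.columns:
            missing = annotations.index.tolist()
            raise ValueError(f"missing '{req}' tag for subjects {missing}")
    cue_cols = [c for c in annotations.columns if c not in ("gender", "label")]
    grouped = annotations.groupby(["gender", "label"], as_index=False)
    out = grouped[cue_cols].mean()
    counts = grouped.size().rename(columns={"size": "n"})
    out = out.merge(counts, on=["gender", "label"])
    out.attrs["cue_ranking"] = list(
        annotations[cue_cols].mean().sort_values(ascending=False).index)
    return out
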