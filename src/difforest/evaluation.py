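"""Multi-label evaluation: F1 variants, PR curves, AUPR and the CV driver.

Function prediction is multi-label and the classifier emits a probability
per gene-label pair, so a single fixed threshold under-describes the model:
the precision-recall curve sweeps the threshold over [0, 1] and the area
under it (AUPR), micro-averaged over all pooled gene-label pairs, is the
headline metric. Micro-averaged F1 pools confusion counts over every pair;
macro-averaged F1 averages per-label F1 over labels that have at least one
positive in the evaluated set (labels absent from a fold would otherwise
reward trivial all-negative predictions).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import KFold, train_test_split

from .cascade import (
    CascadeConfig,
    fit_cascade,
    predict_proba,
    threshold_predict,
)
from .diffusion import concat_embeddings, embed_network
from .network_io import LabelMatrix, WeightedGraph

__all__ = [
    "ConfusionCounts",
    "PRCurve",
    "EvalReport",
    "confusion_counts",
    "micro_f1",
    "macro_f1",
    "pr_curve",
    "aupr",
    "micro_aupr",
    "cross_validate",
]


def _as_array(m) -> np.ndarray:
    if isinstance(m, LabelMatrix):
        return np.asarray(m.Y)
    if hasattr(m, "V"):
        return np.asarray(m.V)
    if hasattr(m, "P"):
        return np.asarray(m.P)
    return np.asarray(m)


@dataclass
class ConfusionCounts:
    tp: np.ndarray  # per label
    fp: np.ndarray
    fn: np.ndarray

    @property
    def pooled(self) -> tuple[int, int, int]:
        return int(self.tp.sum()), int(self.fp.sum()), int(self.fn.sum())


def confusion_counts(Y, V) -> ConfusionCounts:
    """Exact per-label TP/FP/FN over gene-label pairs."""
    Y = _as_array(Y).astype(bool)
    V = _as_array(V).astype(bool)
    if Y.shape != V.shape:
        raise ValueError(f"shape mismatch {Y.shape} vs {V.shape}")
    return ConfusionCounts(
        tp=np.sum(Y & V, axis=0),
        fp=np.sum(~Y & V, axis=0),
        fn=np.sum(Y & ~V, axis=0),
    )


def micro_f1(Y, V) -> float:
    """F1 from globally pooled confusion counts."""
    tp, fp, fn = confusion_counts(Y, V).pooled
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def macro_f1(Y, V) -> float:
    """Unweighted mean of per-label F1 over labels with >= 1 positive."""
    cc = confusion_counts(Y, V)
    has_pos = (cc.tp + cc.fn) > 0
    if not np.any(has_pos):
        return 0.0
    denom = 2 * cc.tp + cc.fp + cc.fn
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(denom > 0, 2 * cc.tp / np.maximum(denom, 1), 0.0)
    return float(f1[has_pos].mean())


@dataclass
class PRCurve:
    """Micro-pooled precision/recall at strictly increasing thresholds."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    pooling: str = "micro"


def pr_curve(Y, P) -> PRCurve:
    """Sweep the decision threshold over the distinct scores (plus 0 and 1).

    At each threshold t the prediction is ``P >= t``; precision and recall
    come from pooled gene-label pairs. Precision at zero predicted positives
    is defined as 1 (standard high-threshold convention), recall there is 0
    whenever any positives exist.
    """
    Y = _as_array(Y).astype(bool).ravel()
    P = _as_array(P).astype(float).ravel()
    if Y.shape != P.shape:
        raise ValueError("shape mismatch between labels and scores")
    thresholds = np.unique(np.concatenate([P, [0.0, 1.0]]))
    n_pos = int(Y.sum())
    # sort scores once; counts above each threshold by binary search
    order = np.argsort(P, kind="stable")
    P_sorted = P[order]
    Y_sorted = Y[order]
    cum_pos = np.concatenate([[0], np.cumsum(Y_sorted)])  # positives below rank
    prec = np.empty_like(thresholds)
    rec = np.empty_like(thresholds)
    total = P.size
    for k, t in enumerate(thresholds):
        lo = int(np.searchsorted(P_sorted, t, side="left"))
        pred_pos = total - lo
        tp = n_pos - int(cum_pos[lo])
        prec[k] = tp / pred_pos if pred_pos else 1.0
        rec[k] = tp / n_pos if n_pos else 1.0
    return PRCurve(thresholds=thresholds, precision=prec, recall=rec)


def aupr(curve: PRCurve) -> float:
    """Area under the PR curve by trapezoidal integration over recall.

    Points are traversed from the highest threshold down, so recall is
    non-decreasing and, where several thresholds tie on recall, the segment
    arriving at that recall ends on the highest-precision point (the
    operating point a practitioner would choose); lower-precision ties form
    zero-width segments that contribute nothing.
    """
    r = curve.recall[::-1]  # thresholds strictly increasing -> reverse
    p = curve.precision[::-1]
    return float(np.trapezoid(p, r))


def micro_aupr(Y, P) -> float:
    """Convenience: AUPR of the micro-pooled PR curve of (Y, P)."""
    return aupr(pr_curve(Y, P))


@dataclass
class EvalReport:
    """Per-fold and aggregate metrics of a cross-validation run."""

    folds: list[dict] = field(default_factory=list)
    fold_assignment: np.ndarray | None = None
    seed: int = 0

    def metric(self, name: str) -> np.ndarray:
        return np.array([f[name] for f in self.folds])

    def summary(self) -> dict[str, dict[str, float]]:
        out = {}
        for name in ("micro_f1", "macro_f1", "aupr"):
            vals = self.metric(name)
            out[name] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1))}
        return out

    def to_tsv(self, path: str | Path) -> None:
        lines = ["# fold\tmetric\tvalue"]
        for i, f in enumerate(self.folds):
            for name in ("micro_f1", "macro_f1", "aupr"):
                lines.append(f"{i}\t{name}\t{f[name]:.6f}")
        Path(path).write_text("\n".join(lines) + "\n")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"seed": self.seed, "folds": self.folds, "summary": self.summary()},
                indent=2,
            )
        )


def cross_validate(
    networks: list[WeightedGraph],
    labels: LabelMatrix,
    cascade_config: CascadeConfig,
    alpha: float = 0.5,
    d: int = 100,
    n_folds: int = 5,
    threshold: float = 0.5,
    val_fraction: float = 0.2,
    seed: int = 0,
    n_repeats: int = 1,
) -> EvalReport:
    """K-fold cross-validated function prediction over one or more networks.

    Embeddings are computed once on the full networks before splitting — the
    diffusion/SVD step is unsupervised, so no label information leaks into
    test folds. Genes with at least one label are partitioned into folds;
    per fold the cascade trains on the remaining genes (with an internal
    validation split of ``val_fraction`` for early stopping) and is scored
    on the held-out fold at the given binarisation threshold.
    """
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    embeddings = [embed_network(g, alpha=alpha, d=d) for g in networks]
    X = concat_embeddings(embeddings).X_full
    Y = np.asarray(labels.Y)
    eligible = np.flatnonzero(Y.sum(axis=1) > 0)
    report = EvalReport(seed=seed)
    assignment = np.full(Y.shape[0], -1)
    for rep in range(n_repeats):
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed + rep)
        for fold_id, (tr, te) in enumerate(kf.split(eligible)):
            train_idx, test_idx = eligible[tr], eligible[te]
            if rep == 0:
                assignment[test_idx] = fold_id
            if Y[test_idx].sum() == 0:
                import warnings

                warnings.warn(f"fold {fold_id} has no positive labels")
            fit_idx, val_idx = train_test_split(
                train_idx,
                test_size=val_fraction,
                random_state=seed + 97 * rep + fold_id,
            )
            cfg = CascadeConfig(
                **{
                    **cascade_config.__dict__,
                    "seed": cascade_config.seed + 1000 * rep + fold_id,
                }
            )
            model = fit_cascade(
                X[fit_idx], Y[fit_idx], X[val_idx], Y[val_idx], cfg
            )
            P = predict_proba(model, X[test_idx]).P
            V = threshold_predict(P, threshold).V
            report.folds.append(
                {
                    "repeat": rep,
                    "fold": fold_id,
                    "n_test": int(test_idx.size),
                    "micro_f1": micro_f1(Y[test_idx], V),
                    "macro_f1": macro_f1(Y[test_idx], V),
                    "aupr": micro_aupr(Y[test_idx], P),
                    "opt_level": model.opt_level,
                }
            )
    report.fold_assignment = assignment
    return report
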