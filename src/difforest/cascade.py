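"""Multi-label cascade-forest classifier with F1-based depth selection.

A cascade is a stack of levels; each level holds N forests whose C-dimensional
class-probability vectors are concatenated into an N*C "class vector" block
and appended to the raw features before the next level — the deep-forest way
of learning representations without gradients. To keep those augmented
features honest, each forest's training-set class vector comes from k-fold
out-of-fold predictions rather than in-sample fits, and the forest is then
refit on the full training data for inference.

Depth is chosen automatically: after each level the cascade's micro-averaged
F1 (probabilities binarised at a fixed threshold) is measured on a held-out
validation split; growth stops once the best level has not improved for
``early_stopping_rounds`` consecutive levels, and the best level becomes the
prediction depth. Per the standard deep-forest recipe, half the forests are
Breiman random forests (sqrt-feature subsampling) and half are completely-
random forests (single random feature per split), which keeps the levels
diverse.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import joblib
import numpy as np
from sklearn.base import clone
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.model_selection import KFold

__all__ = [
    "CascadeConfig",
    "LevelModel",
    "CascadeModel",
    "ProbMatrix",
    "BinaryPrediction",
    "fit_level",
    "fit_cascade",
    "predict_proba",
    "threshold_predict",
    "micro_f1_binary",
]


@dataclass
class CascadeConfig:
    """Hyperparameters of the cascade.

    Defaults mirror the reference configuration: 8 forests of 500 trees per
    level and patience m=4; scale ``n_forests``/``n_trees`` down for desk-
    size experiments. ``forest_mix`` is the fraction of completely-random
    forests per level.
    """

    n_forests: int = 8
    n_trees: int = 500
    forest_mix: float = 0.5
    cv_folds: int = 3
    early_stopping_rounds: int = 4
    level_metric_threshold: float = 0.5
    max_levels: int = 20
    seed: int = 0
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if self.n_forests < 1 or self.n_trees < 1:
            raise ValueError("need at least one forest with at least one tree")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.early_stopping_rounds < 1:
            raise ValueError("early_stopping_rounds must be >= 1")
        if not 0.0 <= self.forest_mix <= 1.0:
            raise ValueError("forest_mix must be in [0, 1]")


@dataclass
class ProbMatrix:
    """Per-label probabilities in [0, 1]; rows are NOT normalised because
    labels are not mutually exclusive."""

    P: np.ndarray


@dataclass
class BinaryPrediction:
    V: np.ndarray
    threshold: float


def _make_forest(index: int, config: CascadeConfig, seed: int):
    """Forest ``index`` of a level: completely-random first, Breiman after."""
    n_random = int(round(config.forest_mix * config.n_forests))
    common = dict(
        n_estimators=config.n_trees,
        random_state=seed,
        n_jobs=config.n_jobs,
        min_samples_leaf=1,
    )
    if index < n_random:
        return ExtraTreesClassifier(max_features=1, **common)
    return RandomForestClassifier(max_features="sqrt", **common)


def _proba_matrix(forest, X: np.ndarray, C: int) -> np.ndarray:
    """Positive-class probability per label from a fitted multi-output forest.

    A label constant in training yields a single-class forest output; its
    probability is then that constant (0 or 1).
    """
    raw = forest.predict_proba(X)
    if not isinstance(raw, list):
        raw = [raw]
    out = np.zeros((X.shape[0], C))
    classes = forest.classes_
    if not isinstance(classes, list):
        classes = [classes]
    for c in range(C):
        cls = np.asarray(classes[c])
        pc = raw[c]
        if cls.size == 2:
            out[:, c] = pc[:, int(np.flatnonzero(cls == 1)[0])]
        else:
            out[:, c] = float(cls[0])
    return out


@dataclass
class LevelModel:
    """One cascade level: N forests refit on the full training data."""

    forests: list = field(default_factory=list)
    C: int = 0

    def forest_probas(self, X: np.ndarray) -> list[np.ndarray]:
        return [_proba_matrix(f, X, self.C) for f in self.forests]

    def augmentation(self, X: np.ndarray) -> np.ndarray:
        """N*C block: the per-forest class vectors, concatenated in order."""
        return np.hstack(self.forest_probas(X))

    def mean_proba(self, X: np.ndarray) -> np.ndarray:
        return np.mean(self.forest_probas(X), axis=0)


@dataclass
class CascadeModel:
    """Fitted cascade: all grown levels, the selected depth and its history."""

    levels: list[LevelModel]
    opt_level: int
    history: list[float]
    C: int
    raw_width: int
    config: CascadeConfig

    def save(self, model_dir: str | Path) -> None:
        model_dir = Path(model_dir)
        model_dir.mkdir(parents=True, exist_ok=True)
        meta = {
            "opt_level": self.opt_level,
            "C": self.C,
            "raw_width": self.raw_width,
            "n_levels": len(self.levels),
            "config": asdict(self.config),
        }
        (model_dir / "model.json").write_text(json.dumps(meta, indent=2))
        lines = ["# level\tval_micro_f1"] + [
            f"{i}\t{f1:.6f}" for i, f1 in enumerate(self.history)
        ]
        (model_dir / "history.tsv").write_text("\n".join(lines) + "\n")
        for i, level in enumerate(self.levels):
            ldir = model_dir / f"level_{i:03d}"
            ldir.mkdir(exist_ok=True)
            for j, forest in enumerate(level.forests):
                joblib.dump(forest, ldir / f"forest_{j:02d}.joblib")

    @classmethod
    def load(cls, model_dir: str | Path) -> "CascadeModel":
        model_dir = Path(model_dir)
        meta = json.loads((model_dir / "model.json").read_text())
        history = [
            float(line.split("\t")[1])
            for line in (model_dir / "history.tsv").read_text().splitlines()
            if line and not line.startswith("#")
        ]
        levels = []
        for i in range(meta["n_levels"]):
            ldir = model_dir / f"level_{i:03d}"
            forests = [
                joblib.load(p) for p in sorted(ldir.glob("forest_*.joblib"))
            ]
            levels.append(LevelModel(forests=forests, C=meta["C"]))
        return cls(
            levels=levels,
            opt_level=meta["opt_level"],
            history=history,
            C=meta["C"],
            raw_width=meta["raw_width"],
            config=CascadeConfig(**meta["config"]),
        )


def _level_seed(master_seed: int, level_index: int, offset: int = 0) -> int:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(level_index, offset))
    return int(ss.generate_state(1)[0] % (2**31))


def fit_level(
    X_aug: np.ndarray,
    Y: np.ndarray,
    config: CascadeConfig,
    level_seed: int,
) -> tuple[LevelModel, np.ndarray]:
    """Fit the N forests of one level and build its training class vectors.

    Returns the fitted level (forests refit on all rows, for inference) and
    the n x N*C training augmentation block assembled from out-of-fold
    predictions of ``cv_folds``-fold cross-validation, so the block carries
    no in-sample leakage into the next level.
    """
    Y = np.asarray(Y)
    n, C = Y.shape
    pos_counts = Y.sum(axis=0)
    rare = np.flatnonzero(pos_counts < config.cv_folds)
    if rare.size:
        warnings.warn(
            f"{rare.size} label(s) have fewer than {config.cv_folds} positive "
            "examples; folds are built without stratification",
            UserWarning,
        )
    kf = KFold(n_splits=config.cv_folds, shuffle=True, random_state=level_seed)
    splits = list(kf.split(X_aug))
    level = LevelModel(C=C)
    blocks = []
    for j in range(config.n_forests):
        proto = _make_forest(j, config, seed=_level_seed(level_seed, j, 1))
        oof = np.zeros((n, C))
        for tr, te in splits:
            est = clone(proto)
            est.fit(X_aug[tr], Y[tr])
            oof[te] = _proba_matrix(est, X_aug[te], C)
        full = clone(proto)
        full.fit(X_aug, Y)
        level.forests.append(full)
        blocks.append(oof)
    return level, np.hstack(blocks)


def micro_f1_binary(Y: np.ndarray, V: np.ndarray) -> float:
    """Micro-averaged F1 from globally pooled confusion counts."""
    Y = np.asarray(Y).astype(bool)
    V = np.asarray(V).astype(bool)
    tp = int(np.sum(Y & V))
    fp = int(np.sum(~Y & V))
    fn = int(np.sum(Y & ~V))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def fit_cascade(
    X_train: np.ndarray,
    Y_train: np.ndarray,
    X_val: np.ndarray,
    Y_val: np.ndarray,
    config: CascadeConfig,
    verbose: bool = False,
) -> CascadeModel:
    """Grow the cascade level by level with early stopping.

    Level 0 sees a zero-valued augmentation block of width N*C stacked with
    the raw features, so every level sees the same feature width. After each
    level, validation micro-F1 (binarised at ``level_metric_threshold``) is
    recorded; growth stops when the running-best level is
    ``early_stopping_rounds`` levels old, or at ``max_levels``. The selected
    depth is the argmax of the history (first maximum on ties).

    The validation split must be disjoint from any test data: stopping on
    test would leak.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_val = np.asarray(X_val, dtype=float)
    Y_train = np.asarray(Y_train)
    Y_val = np.asarray(Y_val)
    if X_val.shape[0] == 0:
        raise ValueError("empty validation set")
    if X_train.shape[0] != Y_train.shape[0] or X_val.shape[0] != Y_val.shape[0]:
        raise ValueError("feature/label row mismatch")
    C = Y_train.shape[1]
    nc = config.n_forests * C
    raw_width = X_train.shape[1]
    aug_train = np.zeros((X_train.shape[0], nc))
    aug_val = np.zeros((X_val.shape[0], nc))
    levels: list[LevelModel] = []
    history: list[float] = []
    opt = 0
    for level_idx in range(config.max_levels):
        Xin_train = np.hstack([aug_train, X_train])
        Xin_val = np.hstack([aug_val, X_val])
        assert Xin_train.shape[1] == raw_width + nc  # constant width contract
        level, aug_train = fit_level(
            Xin_train, Y_train, config, _level_seed(config.seed, level_idx)
        )
        val_probas = level.forest_probas(Xin_val)
        aug_val = np.hstack(val_probas)
        val_mean = np.mean(val_probas, axis=0)
        f1 = micro_f1_binary(Y_val, val_mean >= config.level_metric_threshold)
        levels.append(level)
        history.append(f1)
        opt = int(np.argmax(history))  # first maximum on ties
        if verbose:
            print(f"level {level_idx}: val micro-F1 = {f1:.4f} (best: {opt})")
        if level_idx - opt >= config.early_stopping_rounds:
            break
    return CascadeModel(
        levels=levels,
        opt_level=opt,
        history=history,
        C=C,
        raw_width=raw_width,
        config=config,
    )


def predict_proba(model: CascadeModel, X: np.ndarray) -> ProbMatrix:
    """Pass features through levels 0..opt_level; average the final forests.

    Deterministic for a fixed trained model.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.raw_width:
        raise ValueError(
            f"feature width {X.shape[1]} != training width {model.raw_width}"
        )
    nc = model.config.n_forests * model.C
    aug = np.zeros((X.shape[0], nc))
    for level in model.levels[: model.opt_level + 1]:
        Xin = np.hstack([aug, X])
        probas = level.forest_probas(Xin)
        aug = np.hstack(probas)
    return ProbMatrix(P=np.mean(probas, axis=0))


def threshold_predict(P: ProbMatrix | np.ndarray, t: float) -> BinaryPrediction:
    """Assign label j to a gene iff its probability is >= t (monotone in t)."""
    arr = P.P if isinstance(P, ProbMatrix) else np.asarray(P)
    return BinaryPrediction(V=(arr >= t).astype(np.int8), threshold=t)
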