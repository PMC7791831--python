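"""Per-motif gradient-boosted classifiers for m6A vs unmodified calls.

One gradient-boosted tree ensemble is trained for each of the 12 concrete
RRACH 5-mers; at prediction time a feature vector is routed to the model of
its own motif and the ensemble emits a per-read modification probability.
Evaluation follows the usual conventions: TPR = TP/(TP+FN),
FPR = FP/(FP+TN), accuracy, and ROC/AUC computed by threshold sweep with
tied scores grouped at one threshold.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import math
import zipfile
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import xgboost as xgb
from sklearn.model_selection import StratifiedKFold, train_test_split

from .sigio import SiteFeatureVector

__all__ = [
    "FEATURE_SCHEMA_VERSION",
    "TrainConfig",
    "MotifModel",
    "ModelBundle",
    "MotifEval",
    "EvalReport",
    "enumerate_rrach_motifs",
    "confusion_metrics",
    "roc_auc",
    "train_bundle",
    "cross_validate",
    "predict_site",
    "predict_many",
]

FEATURE_SCHEMA_VERSION = "rrach5-mean-median-std-dwell-v1"


def enumerate_rrach_motifs() -> list[str]:
    """The lexicographically sorted expansion of [AG][AG]AC[ACT] (12 motifs)."""
    return sorted(
        "".join(p) for p in itertools.product("AG", "AG", "A", "C", "ACT")
    )


@dataclass
class TrainConfig:
    """Training hyperparameters.

    ``split_ratio`` is the train fraction of the stratified shuffle split
    (4:1 by default); ``n_trees``/``max_depth``/``learning_rate`` parameterize
    the boosted ensemble; ``extra`` is passed through to the booster.
    """

    split_ratio: float = 0.8
    cv_folds: int = 10
    seed: int = 0
    n_trees: int = 100
    max_depth: int = 6
    learning_rate: float = 0.3
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.split_ratio < 1.0:
            raise ValueError("split_ratio must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    def booster_params(self) -> dict:
        params = {
            "objective": "binary:logistic",
            "max_depth": self.max_depth,
            "eta": self.learning_rate,
            "tree_method": "hist",
            "seed": self.seed,
            "nthread": 1,
        }
        params.update(self.extra)
        return params


@dataclass
class MotifModel:
    """A trained ensemble for one motif; ``booster`` is None when untrainable."""

    motif: str
    booster: xgb.Booster | None
    n_train: int = 0
    n_test: int = 0

    @property
    def trainable(self) -> bool:
        return self.booster is not None

    def predict(self, features: np.ndarray) -> np.ndarray:
        if self.booster is None:
            raise ValueError(f"no model for motif {self.motif}")
        X = np.atleast_2d(np.asarray(features, dtype=np.float32))
        return self.booster.inplace_predict(X)


@dataclass
class MotifEval:
    motif: str
    n_test: int
    tp: int
    fp: int
    tn: int
    fn: int
    tpr: float
    fpr: float
    accuracy: float
    auc: float


@dataclass
class EvalReport:
    """Pooled and per-motif held-out performance."""

    tp: int
    fp: int
    tn: int
    fn: int
    tpr: float
    fpr: float
    accuracy: float
    roc_points: np.ndarray
    auc: float
    per_motif: dict[str, MotifEval] = field(default_factory=dict)


class ModelBundle:
    """The 12 per-motif models plus routing and training metadata."""

    def __init__(self, models: dict[str, MotifModel], config: TrainConfig,
                 schema_version: str = FEATURE_SCHEMA_VERSION,
                 training_digest: str = ""):
        expected = enumerate_rrach_motifs()
        if sorted(models) != expected:
            raise ValueError("bundle must contain exactly the 12 RRACH motifs")
        self.models = models
        self.config = config
        self.schema_version = schema_version
        self.training_digest = training_digest

    def save(self, path) -> None:
        meta = {
            "schema_version": self.schema_version,
            "training_digest": self.training_digest,
            "config": asdict(self.config),
            "motifs": {
                m: {"trainable": mm.trainable, "n_train": mm.n_train, "n_test": mm.n_test}
                for m, mm in self.models.items()
            },
        }
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            zf.writestr("meta.json", json.dumps(meta, indent=1))
            for motif, mm in self.models.items():
                if mm.booster is not None:
                    zf.writestr(f"models/{motif}.ubj", mm.booster.save_raw("ubj"))

    @classmethod
    def load(cls, path) -> "ModelBundle":
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            if meta["schema_version"] != FEATURE_SCHEMA_VERSION:
                raise ValueError(
                    f"feature schema mismatch: bundle has {meta['schema_version']!r}"
                )
            models = {}
            for motif, info in meta["motifs"].items():
                booster = None
                if info["trainable"]:
                    booster = xgb.Booster()
                    booster.load_model(bytearray(zf.read(f"models/{motif}.ubj")))
                models[motif] = MotifModel(motif, booster, info["n_train"], info["n_test"])
        cfg = meta["config"]
        config = TrainConfig(**cfg)
        return cls(models, config, meta["schema_version"], meta["training_digest"])


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> tuple[float, float, float]:
    """TPR, FPR, accuracy from confusion counts; NaN marks a zero denominator.

    FPR follows the standard ROC definition FP/(FP+TN).
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be nonnegative")
    tpr = tp / (tp + fn) if tp + fn > 0 else math.nan
    fpr = fp / (fp + tn) if fp + tn > 0 else math.nan
    total = tp + fp + tn + fn
    acc = (tp + tn) / total if total > 0 else math.nan
    return tpr, fpr, acc


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> tuple[np.ndarray, float]:
    """ROC points and trapezoidal AUC by threshold sweep over distinct scores.

    Equal scores are grouped at a single threshold, which makes the AUC equal
    to the Mann-Whitney pair statistic P(s+ > s-) + P(s+ = s-)/2.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    pos = int(y.sum())
    neg = int(y.size - pos)
    if pos == 0 or neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-s, kind="mergesort")
    s_sorted, y_sorted = s[order], y[order]
    # indices where a tie group of equal scores ends
    ends = np.flatnonzero(np.diff(s_sorted) != 0)
    ends = np.append(ends, s_sorted.size - 1)
    tps = np.cumsum(y_sorted)[ends]
    fps = np.cumsum(1 - y_sorted)[ends]
    tpr = np.concatenate(([0.0], tps / pos))
    fpr = np.concatenate(([0.0], fps / neg))
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def _as_xy(labeled: Iterable[tuple[SiteFeatureVector, int]]):
    vectors, labels = [], []
    for v, lab in labeled:
        vectors.append(v)
        labels.append(int(lab))
    X = np.array([v.features for v in vectors], dtype=np.float32)
    y = np.asarray(labels, dtype=int)
    motifs = np.array([v.motif for v in vectors])
    return X, y, motifs


def _evaluate(scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5,
              motif: str = "", per_motif_masks: dict[str, np.ndarray] | None = None) -> EvalReport:
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tpr, fpr, acc = confusion_metrics(tp, fp, tn, fn)
    points, auc = roc_auc(scores, labels)
    report = EvalReport(tp, fp, tn, fn, tpr, fpr, acc, points, auc)
    if per_motif_masks:
        for m, mask in per_motif_masks.items():
            ys, ss = labels[mask], scores[mask]
            if ys.size == 0 or len(np.unique(ys)) < 2:
                continue
            sub = _evaluate(ss, ys, threshold)
            report.per_motif[m] = MotifEval(
                m, int(ys.size), sub.tp, sub.fp, sub.tn, sub.fn,
                sub.tpr, sub.fpr, sub.accuracy, sub.auc,
            )
    return report


def train_bundle(labeled: Iterable[tuple[SiteFeatureVector, int]],
                 config: TrainConfig | None = None) -> tuple[ModelBundle, EvalReport]:
    """Train one ensemble per motif with a stratified train/test split.

    Motifs lacking two examples of each class are flagged untrainable and
    routing to them raises at prediction time.  The held-out report pools
    confusion counts and ROC scores across motifs.
    """
    config = config or TrainConfig()
    X, y, motifs = _as_xy(labeled)
    digest = hashlib.sha256(X.tobytes() + y.tobytes()).hexdigest()[:16]

    models: dict[str, MotifModel] = {}
    heldout_scores, heldout_labels, heldout_motifs = [], [], []
    for motif in enumerate_rrach_motifs():
        mask = motifs == motif
        Xm, ym = X[mask], y[mask]
        if Xm.shape[0] < 4 or np.sum(ym == 1) < 2 or np.sum(ym == 0) < 2:
            models[motif] = MotifModel(motif, None)
            continue
        Xtr, Xte, ytr, yte = train_test_split(
            Xm, ym, train_size=config.split_ratio, stratify=ym, random_state=config.seed
        )
        dtrain = xgb.DMatrix(Xtr, label=ytr)
        booster = xgb.train(config.booster_params(), dtrain, num_boost_round=config.n_trees)
        models[motif] = MotifModel(motif, booster, n_train=len(ytr), n_test=len(yte))
        heldout_scores.append(booster.inplace_predict(Xte))
        heldout_labels.append(yte)
        heldout_motifs.extend([motif] * len(yte))

    bundle = ModelBundle(models, config, training_digest=digest)
    scores = np.concatenate(heldout_scores) if heldout_scores else np.empty(0)
    labels = np.concatenate(heldout_labels) if heldout_labels else np.empty(0, dtype=int)
    hm = np.array(heldout_motifs)
    masks = {m: hm == m for m in np.unique(hm)} if hm.size else None
    report = _evaluate(scores, labels, per_motif_masks=masks)
    return bundle, report


def cross_validate(labeled: Iterable[tuple[SiteFeatureVector, int]],
                   folds: int | None = None,
                   seed: int | None = None,
                   config: TrainConfig | None = None) -> EvalReport:
    """Stratified k-fold cross-validation pooled over out-of-fold scores.

    Every example receives exactly one out-of-fold probability (per motif);
    the ROC/AUC is computed once over the pooled scores.
    """
    config = config or TrainConfig()
    folds = folds if folds is not None else config.cv_folds
    seed = seed if seed is not None else config.seed
    X, y, motifs = _as_xy(labeled)
    if X.shape[0] < folds:
        raise ValueError("fewer examples than folds")

    oof = np.full(X.shape[0], np.nan)
    for motif in np.unique(motifs):
        mask = motifs == motif
        idx = np.flatnonzero(mask)
        ym = y[idx]
        if len(np.unique(ym)) < 2:
            raise ValueError(f"motif {motif} has a single class")
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        for tr, te in skf.split(X[idx], ym):
            dtrain = xgb.DMatrix(X[idx[tr]], label=ym[tr])
            booster = xgb.train(config.booster_params(), dtrain, num_boost_round=config.n_trees)
            oof[idx[te]] = booster.inplace_predict(X[idx[te]])

    masks = {m: motifs == m for m in np.unique(motifs)}
    return _evaluate(oof, y, per_motif_masks=masks)


def predict_site(bundle: ModelBundle, v: SiteFeatureVector) -> float:
    """Per-read modification probability, routed to the motif's own model."""
    if v.motif not in bundle.models:
        raise ValueError(f"no model for motif {v.motif}")
    return float(bundle.models[v.motif].predict(v.features)[0])


def predict_many(bundle: ModelBundle, vectors: Sequence[SiteFeatureVector]) -> np.ndarray:
    """Vectorized :func:`predict_site` over many feature vectors."""
    if not vectors:
        return np.empty(0)
    X = np.array([v.features for v in vectors], dtype=np.float32)
    motifs = np.array([v.motif for v in vectors])
    out = np.empty(len(vectors))
    for motif in np.unique(motifs):
        model = bundle.models.get(motif)
        if model is None or not model.trainable:
            raise ValueError(f"no model for motif {motif}")
        mask = motifs == motif
        out[mask] = model.predict(X[mask])
    return out
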