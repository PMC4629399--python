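"""Feature assembly, the RBF-SVM potency classifier, and its evaluation.

The classifier distinguishes functional from non-functional guides using a
176-entry feature vector combining sequence composition, motif flags,
thermodynamics, structural accessibility, and position-specific one-hot
encoding.  Training follows the standard libsvm protocol: features min-max
scaled to [0,1] on the training data, RBF kernel, (C, gamma) chosen by
log-spaced grid search with internal cross-validation, and probability-style
scores in [0,1] via Platt scaling.

Two evaluation modes mirror how such models are validated: stratified
tenfold cross-validation, and leave-one-gene-out cross-validation where all
guides for one gene are held out per fold (tests gene-level
generalization).  ROC-AUC and precision-recall machinery round this out.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import joblib
import numpy as np
import RNA
from sklearn.calibration import CalibratedClassifierCV
from sklearn.metrics import precision_recall_curve, roc_auc_score
from sklearn.model_selection import GridSearchCV, LeaveOneGroupOut, StratifiedKFold
from sklearn.svm import SVC

from ._seq import validate_guide
from .prefilter import apply_prefilters
from .screen_io import LabeledScreen, ScreenRecord
from .sequence_features import SequenceFeatureSet, kmer_names
from .structure_features import (
    ACCESSIBILITY_POSITIONS,
    DEFAULT_SCAFFOLD,
    assemble_sgrna,
    duplex_dg,
    guide_self_fold_dg,
    sgrna_accessibility,
)

N_FEATURES = 176


def feature_names() -> list[str]:
    """Manifest of the 176 feature names, in vector order."""
    names = ["gc"]
    names += [f"mono_{b}" for b in kmer_names(1)]
    names += [f"di_{d}" for d in kmer_names(2)]
    names += [f"tri_{t}" for t in kmer_names(3)]
    names += ["repetitive", "gggg", "uuu_seed", "self_fold_dg", "duplex_dg"]
    names += [f"access_{p}" for p in ACCESSIBILITY_POSITIONS]
    names += [f"pos{i}_{b}" for i in range(1, 21) for b in kmer_names(1)]
    assert len(names) == N_FEATURES
    return names


def assemble_features(guide: str, scaffold: str = DEFAULT_SCAFFOLD) -> np.ndarray:
    """Raw (unscaled) feature vector for one guide; deterministic."""
    g = validate_guide(guide)
    seq = SequenceFeatureSet.from_guide(g)
    access = sgrna_accessibility(assemble_sgrna(g, scaffold)).accessible
    vec = np.concatenate(
        [
            [seq.gc],
            seq.mono_counts,
            seq.di_counts,
            seq.tri_counts,
            [float(seq.repetitive), float(seq.gggg), float(seq.uuu_seed)],
            [guide_self_fold_dg(g), duplex_dg(g)],
            np.asarray(access, dtype=float),
            seq.pos_onehot.ravel(),
        ]
    ).astype(float)
    assert vec.shape == (N_FEATURES,)
    return vec


def assemble_feature_matrix(guides, scaffold: str = DEFAULT_SCAFFOLD) -> np.ndarray:
    return np.vstack([assemble_features(g, scaffold) for g in guides])


def _manifest(scaffold: str) -> dict:
    names = feature_names()
    digest = hashlib.sha256(
        json.dumps({"features": names, "scaffold": scaffold}).encode()
    ).hexdigest()
    return {
        "features": names,
        "scaffold": scaffold,
        "fold_engine": f"ViennaRNA {RNA.__version__}",
        "hash": digest,
    }


def default_grid(step: int = 4) -> dict:
    """Log2-spaced (C, gamma) grid: C in 2^-5..2^15, gamma in 2^-15..2^3."""
    return {
        "C": [2.0**e for e in range(-5, 16, step)],
        "gamma": [2.0**e for e in range(-15, 4, step)],
    }


@dataclass
class TrainedModel:
    """RBF-SVM potency classifier with its scaling constants and manifest."""

    svc: CalibratedClassifierCV  # Platt-calibrated RBF SVC
    feature_min: np.ndarray
    feature_range: np.ndarray  # max - min, zeros replaced by 1
    C: float
    gamma: float
    manifest: dict

    def predict_scores(self, guides, scaffold: str | None = None) -> np.ndarray:
        """Probability-style potency score in [0,1] per guide."""
        sc = self.manifest["scaffold"] if scaffold is None else scaffold
        if _manifest(sc)["hash"] != self.manifest["hash"]:
            raise ValueError("feature manifest mismatch between model and assembler")
        X = assemble_feature_matrix(guides, sc)
        Xs = (X - self.feature_min) / self.feature_range
        return self.svc.predict_proba(Xs)[:, 1]

    def save(self, path) -> None:
        joblib.dump(
            {
                "manifest": self.manifest,
                "C": self.C,
                "gamma": self.gamma,
                "feature_min": self.feature_min,
                "feature_range": self.feature_range,
                "svc": self.svc,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "TrainedModel":
        blob = joblib.load(path)
        model = cls(
            svc=blob["svc"],
            feature_min=blob["feature_min"],
            feature_range=blob["feature_range"],
            C=blob["C"],
            gamma=blob["gamma"],
            manifest=blob["manifest"],
        )
        if _manifest(model.manifest["scaffold"])["hash"] != model.manifest["hash"]:
            raise ValueError("model file manifest does not match this feature assembler")
        return model


def _fit(
    X: np.ndarray, y: np.ndarray, grid: dict, seed: int, scaffold: str
) -> TrainedModel:
    fmin = X.min(axis=0)
    frange = X.max(axis=0) - fmin
    frange[frange == 0] = 1.0
    Xs = (X - fmin) / frange
    n_splits = int(min(3, np.bincount(y).min()))
    if len(grid["C"]) * len(grid["gamma"]) > 1 and n_splits >= 2:
        cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        search = GridSearchCV(SVC(kernel="rbf"), grid, cv=cv, scoring="accuracy", n_jobs=1)
        search.fit(Xs, y)
        C, gamma = search.best_params_["C"], search.best_params_["gamma"]
    else:
        C, gamma = grid["C"][0], grid["gamma"][0]
    # probability-style scores via Platt (sigmoid) scaling on seeded CV splits
    platt_cv = StratifiedKFold(
        n_splits=int(min(5, np.bincount(y).min())), shuffle=True, random_state=seed
    )
    svc = CalibratedClassifierCV(
        SVC(kernel="rbf", C=C, gamma=gamma), method="sigmoid", cv=platt_cv, ensemble=False
    )
    svc.fit(Xs, y)
    return TrainedModel(
        svc=svc,
        feature_min=fmin,
        feature_range=frange,
        C=float(C),
        gamma=float(gamma),
        manifest=_manifest(scaffold),
    )


def train_svm(
    screen: LabeledScreen,
    grid: dict | None = None,
    seed: int = 0,
    scaffold: str = DEFAULT_SCAFFOLD,
    prefilter: bool = True,
) -> TrainedModel:
    """Train the potency classifier on the labeled activity extremes.

    With ``prefilter=True`` (default) guides failing the hard pre-filters
    are dropped from the training set, matching a design pipeline in which
    the model only ever scores pre-screened candidates.
    """
    recs, y = screen.training_records()
    if prefilter:
        keep = [i for i, r in enumerate(recs) if apply_prefilters(r.guide_seq).passed]
        recs = [recs[i] for i in keep]
        y = y[keep]
    if len(set(y.tolist())) < 2:
        raise ValueError("training requires both functional and non-functional guides")
    if min(np.bincount(y)) < 10:
        raise ValueError("need at least 10 records per class to train")
    X = assemble_feature_matrix([r.guide_seq for r in recs], scaffold)
    return _fit(X, y, grid or default_grid(), seed, scaffold)


def predict_scores(model: TrainedModel, guides, scaffold: str | None = None) -> np.ndarray:
    """Functional form of :meth:`TrainedModel.predict_scores`."""
    return model.predict_scores(guides, scaffold)


@dataclass
class CVResult:
    mode: str  # "tenfold" or "leave-one-gene-out"
    scores: np.ndarray  # pooled out-of-fold scores, one per record
    labels: np.ndarray
    fold_ids: np.ndarray
    auc: float


def crossvalidate(
    screen: LabeledScreen,
    mode: str = "tenfold",
    seed: int = 0,
    grid: dict | None = None,
    scaffold: str = DEFAULT_SCAFFOLD,
) -> CVResult:
    """Out-of-fold evaluation of the classifier on a labeled screen.

    ``tenfold``: stratified 10-fold CV over the extreme-class records.
    ``leave-one-gene-out``: one fold per gene; all guides of the held-out
    gene are scored by a model trained on the other genes.  Every record is
    scored exactly once out-of-fold; the AUC pools all out-of-fold scores.
    """
    recs, y = screen.training_records()
    X = assemble_feature_matrix([r.guide_seq for r in recs], scaffold)
    grid = grid or default_grid()
    scores = np.full(len(y), np.nan)
    fold_ids = np.full(len(y), -1)

    if mode == "tenfold":
        splitter = StratifiedKFold(n_splits=10, shuffle=True, random_state=seed)
        splits = splitter.split(X, y)
    elif mode == "leave-one-gene-out":
        genes = np.array([r.gene_id for r in recs])
        if len(set(genes)) < 2:
            raise ValueError("leave-one-gene-out requires at least 2 genes")
        splits = LeaveOneGroupOut().split(X, y, groups=genes)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    for k, (train_idx, test_idx) in enumerate(splits):
        if len(set(y[train_idx].tolist())) < 2:
            raise ValueError("a fold's training split lost one class entirely")
        model = _fit(X[train_idx], y[train_idx], grid, seed + k, scaffold)
        Xs = (X[test_idx] - model.feature_min) / model.feature_range
        scores[test_idx] = model.svc.predict_proba(Xs)[:, 1]
        fold_ids[test_idx] = k
    assert not np.isnan(scores).any()
    return CVResult(
        mode=mode, scores=scores, labels=y, fold_ids=fold_ids, auc=roc_auc(scores, y)
    )


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve; equals P(random positive outranks random
    negative), with ties counted 1/2."""
    y = np.asarray(labels, dtype=int)
    if len(set(y.tolist())) < 2:
        raise ValueError("ROC AUC requires both classes")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def pr_curve(scores, labels) -> dict:
    """Precision/recall at every distinct score threshold, descending.

    Also reports the precision background (positive-class fraction), the
    expected precision of random selection.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(set(y.tolist())) < 2:
        raise ValueError("precision-recall requires both classes")
    precision, recall, thresholds = precision_recall_curve(y, s)
    # sklearn returns thresholds ascending with a final (p=1, r=0) anchor;
    # flip to descending-threshold order and drop the anchor point.
    order = slice(len(thresholds) - 1, None, -1)
    return {
        "threshold": thresholds[order],
        "precision": precision[:-1][order],
        "recall": recall[:-1][order],
        "baseline": float(y.mean()),
    }
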