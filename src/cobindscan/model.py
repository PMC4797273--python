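"""Classifiers that discriminate co-occupied from solo binding events.

Four classifier kinds mirror the usual linear/non-linear contrast for this
problem: an RBF-kernel soft-margin classifier (``rbf_margin``) and a random
forest (``tree_ensemble``) as the non-linear pair, Gaussian naive Bayes
(``gaussian_nb``) and linear discriminant analysis (``linear_discriminant``)
as the linear pair. The margin and tree kinds delegate to scikit-learn; NB
and LDA are computed from their closed forms (per-class Gaussian moments,
and pooled-covariance weight vector w = Sigma^-1 (mu1 - mu0)), so the
linear-vs-nonlinear comparison rests on transparent arithmetic.

Evaluation follows repeated stratified splitting: two thirds of each class
train, the rest test, repeated (default 10 times) with ROC/AUC/ACC per
repetition and their means. A trained model can be transferred to another
cell type's feature matrix without refitting (training-cell standardization
reused); |delta AUC| between within-cell and cross-cell evaluation measures
how conserved the feature-co-occupancy relation is across cell types.
"""

from __future__ import annotations

import base64
import json
import pickle
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from .events import ValidationError
from .features import FeatureMatrix

CLASSIFIER_KINDS = ("rbf_margin", "tree_ensemble", "gaussian_nb", "linear_discriminant")

_SERIALIZATION_VERSION = 1
_VAR_FLOOR = 1e-9


@dataclass(frozen=True)
class ClassifierSpec:
    kind: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValidationError(
                f"unknown classifier kind {self.kind!r}; choose from {CLASSIFIER_KINDS}"
            )


@dataclass
class TrainedModel:
    spec: ClassifierSpec
    feature_names: list[str]
    mean_: np.ndarray          # training standardization
    sd_: np.ndarray
    params: dict               # kind-specific fitted parameters
    train_cell: str = ""
    tf_pair: str = ""

    @property
    def threshold(self) -> float:
        """Default decision threshold for accuracy: probability 0.5 for the
        tree ensemble, decision value / log-odds 0 otherwise."""
        return 0.5 if self.spec.kind == "tree_ensemble" else 0.0


@dataclass
class EvaluationResult:
    auc_per_rep: list
    acc_per_rep: list
    roc_points: np.ndarray      # (fpr, tpr) pairs from the last repetition
    train_cell: str = ""
    test_cell: str = ""
    feature_set: str = ""
    classifier: str = ""

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.auc_per_rep))

    @property
    def mean_acc(self) -> float:
        return float(np.mean(self.acc_per_rep))


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split(
    matrix: FeatureMatrix, train_frac: float = 2 / 3, seed: int = 0
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Stratified random split: ``train_frac`` of each class (floor) trains.

    Disjoint and exhaustive; deterministic for a given seed.
    """
    if not (0 < train_frac < 1):
        raise ValidationError(f"train_frac must be in (0, 1), got {train_frac}")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in (0, 1):
        idx = np.flatnonzero(matrix.labels == cls)
        if len(idx) < 3:
            raise ValidationError(f"class {cls} has {len(idx)} rows; need at least 3")
        perm = rng.permutation(idx)
        n_train = int(np.floor(train_frac * len(idx)))
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    return matrix.subset_rows(np.sort(train_idx)), matrix.subset_rows(np.sort(test_idx))


# ---------------------------------------------------------------------------
# fitting and scoring
# ---------------------------------------------------------------------------

def _standardize_params(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd = np.where(sd < 1e-12, 1.0, sd)  # constant features retained, sd floored
    return mean, sd


def fit(
    spec: ClassifierSpec,
    train: FeatureMatrix,
    train_cell: str = "",
    tf_pair: str = "",
) -> TrainedModel:
    """Fit one classifier on a training matrix (no missing cells allowed).

    Features are z-scored with training-set statistics for every kind; the
    statistics are stored on the model and reapplied at prediction time.
    """
    if train.missing_mask.any():
        raise ValidationError("training matrix contains missing cells; drop rows first")
    y = train.labels
    if len(np.unique(y)) < 2:
        raise ValidationError("training data must contain both classes")
    mean, sd = _standardize_params(train.values)
    x = (train.values - mean) / sd
    hp = dict(spec.hyperparameters)

    if spec.kind == "gaussian_nb":
        params = _fit_gaussian_nb(x, y)
    elif spec.kind == "linear_discriminant":
        params = _fit_lda(x, y, ridge=hp.get("ridge", 0.0))
    elif spec.kind == "rbf_margin":
        clf = SVC(
            C=hp.get("C", 1.0),
            kernel="rbf",
            gamma=hp.get("gamma", 1.0 / x.shape[1]),
            random_state=spec.seed,
        )
        clf.fit(x, y)
        params = {"sklearn": clf}
    elif spec.kind == "tree_ensemble":
        clf = RandomForestClassifier(
            n_estimators=hp.get("n_estimators", 100),
            random_state=spec.seed,
            n_jobs=1,
        )
        clf.fit(x, y)
        params = {"sklearn": clf}
    return TrainedModel(spec, list(train.feature_names), mean, sd, params,
                        train_cell=train_cell, tf_pair=tf_pair)


def _fit_gaussian_nb(x: np.ndarray, y: np.ndarray) -> dict:
    params = {"prior": {}, "mu": {}, "var": {}}
    for cls in (0, 1):
        xc = x[y == cls]
        params["prior"][cls] = len(xc) / len(x)
        params["mu"][cls] = xc.mean(axis=0)
        params["var"][cls] = np.maximum(xc.var(axis=0, ddof=0), _VAR_FLOOR)
    return params


def _fit_lda(x: np.ndarray, y: np.ndarray, ridge: float = 0.0) -> dict:
    mu0 = x[y == 0].mean(axis=0)
    mu1 = x[y == 1].mean(axis=0)
    n0, n1 = int((y == 0).sum()), int((y == 1).sum())
    centered = np.vstack([x[y == 0] - mu0, x[y == 1] - mu1])
    cov = centered.T @ centered / (len(x) - 2)
    if ridge:
        cov = cov + ridge * np.eye(len(cov))
    try:
        w = np.linalg.solve(cov, mu1 - mu0)
        if not np.all(np.isfinite(w)) or np.linalg.cond(cov) > 1e12:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        # singular pooled covariance: ridge fallback
        eps = 1e-6 * np.trace(cov) / len(cov) + 1e-12
        cov = cov + eps * np.eye(len(cov))
        w = np.linalg.solve(cov, mu1 - mu0)
    b = -0.5 * (mu0 + mu1) @ w + np.log(n1 / n0)
    return {"w": w, "b": float(b), "mu0": mu0, "mu1": mu1, "cov": cov}


def score(model: TrainedModel, rows: FeatureMatrix) -> np.ndarray:
    """Real-valued scores, higher meaning more co-occupied-like.

    Log-odds for NB/LDA, decision value for the margin kind, class-1
    probability for the tree ensemble.
    """
    if list(rows.feature_names) != list(model.feature_names):
        extra = set(rows.feature_names) - set(model.feature_names)
        missing = set(model.feature_names) - set(rows.feature_names)
        raise ValidationError(
            f"feature mismatch: missing {sorted(missing)}, unexpected {sorted(extra)}; "
            "order must also match"
        )
    if rows.missing_mask.any():
        raise ValidationError("scoring matrix contains missing cells; drop rows first")
    x = (rows.values - model.mean_) / model.sd_
    kind = model.spec.kind
    p = model.params
    if kind == "gaussian_nb":
        ll = {}
        for cls in (0, 1):
            mu, var = p["mu"][cls], p["var"][cls]
            ll[cls] = (
                np.log(p["prior"][cls])
                - 0.5 * np.sum(np.log(2 * np.pi * var))
                - 0.5 * np.sum((x - mu) ** 2 / var, axis=1)
            )
        return ll[1] - ll[0]
    if kind == "linear_discriminant":
        return x @ p["w"] + p["b"]
    if kind == "rbf_margin":
        if "sklearn" in p:
            return p["sklearn"].decision_function(x)
        # model restored from JSON: evaluate the kernel expansion directly
        sv, dual, b, gamma = p["sv"], p["dual"], p["intercept"], p["gamma"]
        d2 = ((x[:, None, :] - sv[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-gamma * d2) @ dual + b
    if kind == "tree_ensemble":
        return p["sklearn"].predict_proba(x)[:, 1]
    raise ValidationError(f"unknown kind {kind!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC points and AUC.

    AUC is the rank statistic P(score_pos > score_neg) + 0.5 P(tie); the ROC
    curve sweeps thresholds over the unique scores, starts at (0, 0) and
    ends at (1, 1), ties advancing both coordinates in one step.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("roc_auc requires both classes")
    ranks = sps.rankdata(scores)
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-scores, kind="stable")
    s, l = scores[order], labels[order]
    # step only at the last occurrence of each unique score
    last = np.r_[s[1:] != s[:-1], True]
    tp = np.cumsum(l == 1)[last] / n_pos
    fp = np.cumsum(l == 0)[last] / n_neg
    points = np.column_stack([np.r_[0.0, fp], np.r_[0.0, tp]])
    return points, float(auc)


def accuracy(scores, labels, threshold: float = 0.0) -> float:
    """Fraction of rows where (score > threshold) matches the label."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    return float(np.mean((scores > threshold).astype(int) == labels))


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate(
    matrix: FeatureMatrix,
    spec: ClassifierSpec,
    reps: int = 10,
    seed: int = 0,
    train_frac: float = 2 / 3,
    train_cell: str = "",
    feature_set: str = "",
) -> EvaluationResult:
    """Repeated stratified split / fit / score, with AUC and ACC per rep.

    The master seed fans out deterministically: repetition ``i`` uses
    ``seed + i`` for both the split and the classifier's own randomness.
    """
    matrix = matrix.drop_missing_rows()
    aucs, accs = [], []
    roc_points = None
    for rep in range(reps):
        rep_seed = int((seed + rep) % 2**31)
        train, test = split(matrix, train_frac=train_frac, seed=rep_seed)
        rep_spec = ClassifierSpec(spec.kind, dict(spec.hyperparameters), seed=rep_seed)
        model = fit(rep_spec, train, train_cell=train_cell)
        s = score(model, test)
        roc_points, auc = roc_auc(s, test.labels)
        aucs.append(auc)
        accs.append(accuracy(s, test.labels, threshold=model.threshold))
    return EvaluationResult(
        aucs, accs, roc_points,
        train_cell=train_cell, test_cell=train_cell,
        feature_set=feature_set, classifier=spec.kind,
    )


def cross_cell(
    model: TrainedModel, matrix_other_cell: FeatureMatrix, test_cell: str = "",
    feature_set: str = "",
) -> EvaluationResult:
    """Apply a trained model to another cell's full matrix without refitting.

    The training cell's standardization is reused; no split is performed.
    """
    matrix = matrix_other_cell.drop_missing_rows()
    s = score(model, matrix)
    roc_points, auc = roc_auc(s, matrix.labels)
    acc = accuracy(s, matrix.labels, threshold=model.threshold)
    return EvaluationResult(
        [auc], [acc], roc_points,
        train_cell=model.train_cell, test_cell=test_cell,
        feature_set=feature_set, classifier=model.spec.kind,
    )


def delta_auc(within: EvaluationResult, cross: EvaluationResult) -> float:
    """|mean AUC(within-cell) - mean AUC(cross-cell)| for one test cell."""
    if within.test_cell != cross.test_cell:
        raise ValidationError(
            f"test cells differ: {within.test_cell!r} vs {cross.test_cell!r}"
        )
    if within.feature_set != cross.feature_set or within.classifier != cross.classifier:
        raise ValidationError("feature set and classifier must match for |dAUC|")
    return abs(within.mean_auc - cross.mean_auc)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def model_to_json(model: TrainedModel) -> str:
    """Versioned JSON serialization; portable across cells by construction.

    NB and LDA store their closed-form parameters natively; the RBF margin
    stores its kernel expansion (support vectors, dual coefficients,
    intercept, gamma); the tree ensemble embeds an opaque payload.
    """
    p = model.params
    kind = model.spec.kind
    if kind in ("rbf_margin",) and "sklearn" in p:
        clf = p["sklearn"]
        payload = {
            "sv": clf.support_vectors_.tolist(),
            "dual": clf.dual_coef_[0].tolist(),
            "intercept": float(clf.intercept_[0]),
            "gamma": float(clf._gamma),
        }
    elif kind == "tree_ensemble":
        payload = {"pickle_b64": base64.b64encode(pickle.dumps(p["sklearn"])).decode()}
    elif kind == "gaussian_nb":
        payload = {
            "prior": {str(k): v for k, v in p["prior"].items()},
            "mu": {str(k): v.tolist() for k, v in p["mu"].items()},
            "var": {str(k): v.tolist() for k, v in p["var"].items()},
        }
    else:
        payload = {"w": p["w"].tolist(), "b": p["b"]}
    return json.dumps(
        {
            "version": _SERIALIZATION_VERSION,
            "spec": {"kind": kind, "hyperparameters": model.spec.hyperparameters,
                     "seed": model.spec.seed},
            "feature_names": model.feature_names,
            "standardization": {"mean": model.mean_.tolist(), "sd": model.sd_.tolist()},
            "train_cell": model.train_cell,
            "tf_pair": model.tf_pair,
            "params": payload,
        }
    )


def model_from_json(text: str) -> TrainedModel:
    d = json.loads(text)
    if d.get("version") != _SERIALIZATION_VERSION:
        raise ValidationError(f"unsupported model version {d.get('version')}")
    spec = ClassifierSpec(d["spec"]["kind"], d["spec"]["hyperparameters"], d["spec"]["seed"])
    pj = d["params"]
    if spec.kind == "rbf_margin":
        params = {
            "sv": np.array(pj["sv"]),
            "dual": np.array(pj["dual"]),
            "intercept": pj["intercept"],
            "gamma": pj["gamma"],
        }
    elif spec.kind == "tree_ensemble":
        params = {"sklearn": pickle.loads(base64.b64decode(pj["pickle_b64"]))}
    elif spec.kind == "gaussian_nb":
        params = {
            "prior": {int(k): v for k, v in pj["prior"].items()},
            "mu": {int(k): np.array(v) for k, v in pj["mu"].items()},
            "var": {int(k): np.array(v) for k, v in pj["var"].items()},
        }
    else:
        params = {"w": np.array(pj["w"]), "b": pj["b"]}
    return TrainedModel(
        spec,
        list(d["feature_names"]),
        np.array(d["standardization"]["mean"]),
        np.array(d["standardization"]["sd"]),
        params,
        train_cell=d["train_cell"],
        tf_pair=d["tf_pair"],
    )
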