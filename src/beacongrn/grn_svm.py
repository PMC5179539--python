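"""Supervised TF-target classification with soft-margin SVMs.

Two feature constructions turn a (regulator, target) pair into a vector:

* global -- the concatenated expression profiles ``(e(r_1..k), e(t_1..k))``;
  one classifier is trained for all regulators' pairs at once.
* local -- the target's consecutive log2 fold changes
  ``log2((e(t_{j+1})+eps)/(e(t_j)+eps))``; one classifier per regulator, so
  the regulator enters only through which examples are labelled positive.

Training delegates the quadratic program to scikit-learn's SVC; the model
surface exposed here (dual coefficients, bias, kernel spec, decision values
via the kernel expansion) is what the rest of the pipeline relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .data_io import ExpressionMatrix

__all__ = [
    "KernelSpec",
    "PairFeatureVector",
    "PairSVM",
    "LocalModel",
    "global_features",
    "local_features",
    "eval_kernel",
    "sample_negatives",
    "train_soft_margin",
    "score_pairs",
    "train_regulator_models",
    "predict_targets",
]

DEFAULT_C = 1000.0
DEFAULT_EPSILON = 1.0  # pseudocount (FPKM) guarding zeros in log ratios


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and parameters: linear ``x.y + c`` or RBF ``exp(-gamma ||x-y||^2)``.

    ``gamma=None`` means the scanner default 1/n_features, resolved at fit
    or evaluation time.
    """

    kind: str = "rbf"
    c: float = 0.0
    gamma: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "rbf"):
            raise ValueError(f"kernel kind must be 'linear' or 'rbf', got {self.kind!r}")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be positive")

    def resolve_gamma(self, n_features: int) -> float:
        return 1.0 / n_features if self.gamma is None else self.gamma


@dataclass
class PairFeatureVector:
    mode: str
    values: np.ndarray
    regulator_id: str
    target_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite feature for pair ({self.regulator_id}, {self.target_id})")


def global_features(
    r_profile: np.ndarray, t_profile: np.ndarray,
    regulator_id: str = "", target_id: str = "",
) -> PairFeatureVector:
    """Concatenate regulator then target profiles into a length-2k vector."""
    r = np.asarray(r_profile, dtype=float)
    t = np.asarray(t_profile, dtype=float)
    if r.shape != t.shape:
        raise ValueError(f"profile lengths differ: {r.shape} vs {t.shape}")
    return PairFeatureVector("global", np.concatenate([r, t]), regulator_id, target_id)


def local_features(
    t_profile: np.ndarray, epsilon: float = DEFAULT_EPSILON,
    regulator_id: str = "", target_id: str = "",
) -> PairFeatureVector:
    """Consecutive log2 fold changes of the target profile (length k-1)."""
    t = np.asarray(t_profile, dtype=float)
    if t.size < 2:
        raise ValueError("profile needs at least two timepoints")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    vals = np.log2((t[1:] + epsilon) / (t[:-1] + epsilon))
    return PairFeatureVector("local", vals, regulator_id, target_id)


def eval_kernel(spec: KernelSpec, x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"vector lengths differ: {x.shape} vs {y.shape}")
    if spec.kind == "linear":
        return float(x @ y + spec.c)
    gamma = spec.resolve_gamma(x.size)
    return float(np.exp(-gamma * np.sum((x - y) ** 2)))


def sample_negatives(
    candidate_genes: Iterable[str],
    regulon: set[str],
    n_neg: int,
    seed: int,
    regulator: str | None = None,
) -> set[str]:
    """Draw ``n_neg`` genes outside the regulon (and not the regulator itself).

    Sampling is over the sorted candidate list so the draw depends only on
    the seed and the set contents, not on input ordering.
    """
    pool = sorted(set(candidate_genes) - set(regulon) - ({regulator} if regulator else set()))
    if n_neg > len(pool):
        raise ValueError(
            f"cannot sample {n_neg} negatives from {len(pool)} eligible candidates"
        )
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(pool), size=n_neg, replace=False)
    return {pool[i] for i in picked}


class PairSVM(BaseEstimator, ClassifierMixin):
    """Soft-margin SVM over pair feature vectors (scikit-learn estimator).

    Parameters
    ----------
    kernel : 'rbf' or 'linear'
    C : box constraint on the dual coefficients (default 1000).
    gamma : RBF width; None means 1/n_features.
    kernel_constant : additive constant ``c`` of the linear kernel.

    Fitted attributes: ``support_vectors_``, ``dual_coef_`` (signed y_i a_i),
    ``intercept_``, ``gamma_``, ``n_features_in_``.  Ties ``f(x) = 0``
    classify as -1.
    """

    def __init__(
        self,
        kernel: str = "rbf",
        C: float = DEFAULT_C,
        gamma: float | None = None,
        kernel_constant: float = 0.0,
    ) -> None:
        self.kernel = kernel
        self.C = C
        self.gamma = gamma
        self.kernel_constant = kernel_constant

    def _spec(self, n_features: int) -> KernelSpec:
        gamma = KernelSpec(self.kernel, self.kernel_constant, self.gamma).resolve_gamma(n_features)
        return KernelSpec(self.kernel, self.kernel_constant, gamma)

    def fit(self, X, y) -> "PairSVM":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_pairs, n_features)")
        labels = set(np.unique(y).tolist())
        if not labels <= {-1, 1}:
            raise ValueError(f"labels must be +1/-1, got {sorted(labels)}")
        if len(labels) < 2:
            raise ValueError("training needs both classes present")
        spec = self._spec(X.shape[1])
        if spec.kind == "rbf":
            svc = SVC(kernel="rbf", C=self.C, gamma=spec.gamma)
        elif spec.c == 0.0:
            svc = SVC(kernel="linear", C=self.C)
        else:
            const = spec.c
            svc = SVC(kernel=lambda A, B: A @ B.T + const, C=self.C)
        svc.fit(X, y)
        self._svc = svc
        self._X_fit = X
        self.n_features_in_ = X.shape[1]
        self.gamma_ = spec.gamma
        self.kernel_spec_ = spec
        self.classes_ = np.array([-1, 1])
        if svc.kernel == "precomputed" or callable(svc.kernel):
            self.support_vectors_ = X[svc.support_]
        else:
            self.support_vectors_ = svc.support_vectors_
        self.dual_coef_ = svc.dual_coef_
        self.intercept_ = svc.intercept_
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "dual_coef_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature dimension {X.shape[1]} does not match training dimension "
                f"{self.n_features_in_}"
            )
        return self._svc.decision_function(X)

    def kernel_expansion(self, X) -> np.ndarray:
        """Decision values computed explicitly as sum_i y_i a_i k(x_i, x) + b."""
        check_is_fitted(self, "dual_coef_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        K = np.array(
            [[eval_kernel(self.kernel_spec_, sv, x) for sv in self.support_vectors_] for x in X]
        )
        return K @ self.dual_coef_.ravel() + self.intercept_[0]

    def predict(self, X) -> np.ndarray:
        f = self.decision_function(X)
        return np.where(f > 0, 1, -1)


@dataclass
class TrainingSet:
    X: np.ndarray
    y: np.ndarray
    provenance: list[str] = field(default_factory=list)


def train_soft_margin(
    train: TrainingSet, kernel: KernelSpec | None = None, C: float = DEFAULT_C
) -> PairSVM:
    kernel = kernel or KernelSpec()
    model = PairSVM(kernel=kernel.kind, C=C, gamma=kernel.gamma, kernel_constant=kernel.c)
    return model.fit(train.X, train.y)


@dataclass
class PredictionResult:
    regulator_id: str
    target_id: str
    score: float
    predicted_class: int


def score_pairs(model: PairSVM, features: Sequence[PairFeatureVector]) -> list[PredictionResult]:
    if not features:
        return []
    X = np.array([f.values for f in features])
    scores = model.decision_function(X)
    return [
        PredictionResult(f.regulator_id, f.target_id, float(s), 1 if s > 0 else -1)
        for f, s in zip(features, scores)
    ]


@dataclass
class LocalModel:
    """A trained classifier together with the identities it must not re-score."""

    regulator: str
    model: PairSVM
    mode: str
    positives: set[str]
    epsilon: float = DEFAULT_EPSILON


def pair_features(
    expression: ExpressionMatrix, regulator: str, target: str,
    mode: str, epsilon: float = DEFAULT_EPSILON,
) -> PairFeatureVector:
    if mode == "global":
        return global_features(
            expression.profile(regulator), expression.profile(target), regulator, target
        )
    if mode == "local":
        return local_features(expression.profile(target), epsilon, regulator, target)
    raise ValueError(f"mode must be 'global' or 'local', got {mode!r}")


def _training_matrix(
    expression: ExpressionMatrix, regulator: str,
    positives: Iterable[str], negatives: Iterable[str],
    mode: str, epsilon: float,
) -> TrainingSet:
    feats, ys, prov = [], [], []
    for t in sorted(positives):
        feats.append(pair_features(expression, regulator, t, mode, epsilon).values)
        ys.append(1)
        prov.append("positive")
    for t in sorted(negatives):
        feats.append(pair_features(expression, regulator, t, mode, epsilon).values)
        ys.append(-1)
        prov.append("negative")
    return TrainingSet(np.array(feats), np.array(ys), prov)


def train_regulator_models(
    expression: ExpressionMatrix,
    regulons: Mapping[str, set[str]],
    mode: str = "local",
    kernel: KernelSpec | None = None,
    C: float = DEFAULT_C,
    seed: int = 0,
    negatives: Mapping[str, set[str]] | None = None,
    epsilon: float = DEFAULT_EPSILON,
) -> dict[str, LocalModel]:
    """Train one model per regulator (local) or one shared model (global).

    Negatives default to a balanced seeded draw from all expressed genes.
    In global mode all regulators' pairs are pooled into a single training
    problem; the returned map still has one entry per regulator, sharing the
    fitted classifier, so prediction bookkeeping stays per-regulator.
    """
    kernel = kernel or KernelSpec()
    regulons = {r: set(t) for r, t in regulons.items()}
    if negatives is None:
        negatives = {}
        for i, (reg, targets) in enumerate(sorted(regulons.items())):
            negatives[reg] = sample_negatives(
                expression.gene_ids, targets, len(targets), seed + i, regulator=reg
            )
    if mode == "global":
        sets = [
            _training_matrix(expression, reg, regulons[reg], negatives[reg], mode, epsilon)
            for reg in sorted(regulons)
        ]
        pooled = TrainingSet(
            np.vstack([s.X for s in sets]), np.concatenate([s.y for s in sets])
        )
        shared = train_soft_margin(pooled, kernel, C)
        return {
            reg: LocalModel(reg, shared, mode, set(regulons[reg]), epsilon)
            for reg in sorted(regulons)
        }
    models = {}
    for reg in sorted(regulons):
        ts = _training_matrix(expression, reg, regulons[reg], negatives[reg], mode, epsilon)
        models[reg] = LocalModel(reg, train_soft_margin(ts, kernel, C), mode, set(regulons[reg]), epsilon)
    return models


def predict_targets(
    models: Mapping[str, LocalModel],
    de_genes: Iterable[str],
    expression: ExpressionMatrix,
) -> dict[str, dict[str, float]]:
    """Score all DE genes not used as training positives; keep f > 0.

    Returns, per regulator, the predicted target set as a ``{gene: score}``
    map (scores retained for ranking downstream).
    """
    de_genes = sorted(set(de_genes))
    out: dict[str, dict[str, float]] = {}
    for reg, lm in sorted(models.items()):
        if reg not in expression:
            raise KeyError(f"regulator {reg!r} absent from expression matrix")
        candidates = [g for g in de_genes if g not in lm.positives and g != reg]
        feats = [pair_features(expression, reg, g, lm.mode, lm.epsilon) for g in candidates]
        preds = score_pairs(lm.model, feats)
        out[reg] = {p.target_id: p.score for p in preds if p.predicted_class == 1}
    return out
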