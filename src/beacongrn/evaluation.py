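"""Cross-validation protocol, ROC/AUC, and method comparison reports.

The three-fold protocol splits the differentially expressed positives and
the sampled negatives into three folds each; every training set consists of
two folds of each class plus all stably expressed (non-DE) positives, which
never enter a test fold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .clr import CLR
from .data_io import ExpressionMatrix
from .grn_svm import (
    DEFAULT_C,
    KernelSpec,
    TrainingSet,
    _training_matrix,
    pair_features,
    sample_negatives,
    score_pairs,
    train_soft_margin,
)

__all__ = [
    "CVSplit",
    "make_threefold_splits",
    "roc_auc",
    "cross_validated_auc",
    "compare_methods",
]


@dataclass
class CVSplit:
    """Fold structure: test (positives, negatives) per fold + shared stable positives."""

    folds: list[tuple[set[str], set[str]]]
    stable_positives: set[str]

    def train_sets(self, fold: int) -> tuple[set[str], set[str]]:
        """Training (positives, negatives) for one held-out fold."""
        pos: set[str] = set(self.stable_positives)
        neg: set[str] = set()
        for i, (p, n) in enumerate(self.folds):
            if i != fold:
                pos |= p
                neg |= n
        return pos, neg


def _partition(items: Iterable[str], n_folds: int, rng: np.random.Generator) -> list[set[str]]:
    items = sorted(items)
    order = rng.permutation(len(items))
    folds: list[set[str]] = [set() for _ in range(n_folds)]
    for pos, idx in enumerate(order):
        folds[pos % n_folds].add(items[idx])
    return folds


def make_threefold_splits(
    de_positives: set[str],
    negatives: set[str],
    stable_positives: set[str],
    seed: int,
    n_folds: int = 3,
) -> CVSplit:
    """Seeded balanced partition of DE positives and negatives into folds."""
    if len(de_positives) < n_folds or len(negatives) < n_folds:
        raise ValueError(
            f"need at least {n_folds} DE positives and negatives, got "
            f"{len(de_positives)} / {len(negatives)}"
        )
    rng = np.random.default_rng(seed)
    pos_folds = _partition(de_positives, n_folds, rng)
    neg_folds = _partition(negatives, n_folds, rng)
    return CVSplit(list(zip(pos_folds, neg_folds)), set(stable_positives))


def roc_auc(scores, labels) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """ROC curve by threshold sweep and its trapezoidal area.

    ``labels`` are +1/-1 (or truthy/falsy); with tied scores the curve moves
    diagonally, which makes the trapezoidal area equal to the Mann-Whitney
    probability with ties credited 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray([1 if l > 0 else 0 for l in np.asarray(labels).ravel()])
    if labels.min() == labels.max():
        raise ValueError("both classes must be present to compute a ROC curve")
    fpr, tpr, thresholds = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, thresholds, auc


def cross_validated_auc(
    expression: ExpressionMatrix,
    regulator: str,
    regulon: set[str],
    de_genes: set[str],
    mode: str = "local",
    kernel: KernelSpec | None = None,
    C: float = DEFAULT_C,
    seed: int = 0,
    negatives: set[str] | None = None,
    epsilon: float = 1.0,
) -> tuple[float, list[float]]:
    """Mean held-out AUC of one regulator's classifier over three folds.

    The negative set is drawn once (seeded) before splitting when not
    supplied; its size matches the full regulon.
    """
    kernel = kernel or KernelSpec()
    regulon = set(regulon)
    de_pos = regulon & set(de_genes)
    stable = regulon - de_pos
    if negatives is None:
        negatives = sample_negatives(
            expression.gene_ids, regulon, len(regulon), seed, regulator=regulator
        )
    split = make_threefold_splits(de_pos, set(negatives), stable, seed)
    aucs = []
    for fold, (test_pos, test_neg) in enumerate(split.folds):
        train_pos, train_neg = split.train_sets(fold)
        ts = _training_matrix(expression, regulator, train_pos, train_neg, mode, epsilon)
        model = train_soft_margin(ts, kernel, C)
        feats = [
            pair_features(expression, regulator, g, mode, epsilon)
            for g in sorted(test_pos) + sorted(test_neg)
        ]
        preds = score_pairs(model, feats)
        scores = [p.score for p in preds]
        labels = [1] * len(test_pos) + [-1] * len(test_neg)
        aucs.append(roc_auc(scores, labels)[3])
    return float(np.mean(aucs)), aucs


def _global_cv_auc(
    expression: ExpressionMatrix,
    regulons: Mapping[str, set[str]],
    de_genes: set[str],
    kernel: KernelSpec,
    C: float,
    seed: int,
    negatives: Mapping[str, set[str]],
    epsilon: float,
) -> dict[str, tuple[float, list[float]]]:
    """Pooled-training CV: one shared classifier per fold, evaluated per regulator."""
    splits = {}
    for i, reg in enumerate(sorted(regulons)):
        regulon = set(regulons[reg])
        de_pos = regulon & de_genes
        splits[reg] = make_threefold_splits(
            de_pos, set(negatives[reg]), regulon - de_pos, seed + i
        )
    per_reg_aucs: dict[str, list[float]] = {r: [] for r in regulons}
    for fold in range(3):
        blocks = []
        for reg in sorted(regulons):
            tp, tn = splits[reg].train_sets(fold)
            blocks.append(_training_matrix(expression, reg, tp, tn, "global", epsilon))
        pooled = TrainingSet(
            np.vstack([b.X for b in blocks]), np.concatenate([b.y for b in blocks])
        )
        model = train_soft_margin(pooled, kernel, C)
        for reg in sorted(regulons):
            test_pos, test_neg = splits[reg].folds[fold]
            feats = [
                pair_features(expression, reg, g, "global", epsilon)
                for g in sorted(test_pos) + sorted(test_neg)
            ]
            preds = score_pairs(model, feats)
            labels = [1] * len(test_pos) + [-1] * len(test_neg)
            per_reg_aucs[reg].append(roc_auc([p.score for p in preds], labels)[3])
    return {r: (float(np.mean(a)), a) for r, a in per_reg_aucs.items()}


def compare_methods(
    expression: ExpressionMatrix,
    regulons: Mapping[str, set[str]],
    de_genes: set[str],
    seed: int = 0,
    C: float = DEFAULT_C,
    n_bins: int | None = None,
    epsilon: float = 1.0,
) -> pd.DataFrame:
    """AUC comparison of local/global x linear/RBF SVMs against CLR.

    CLR needs no training: its edge weights are computed once on the full
    expression matrix and evaluated on exactly the same positive/negative
    pairs used for the supervised folds (pooled over folds).
    """
    de_genes = set(de_genes)
    negatives = {
        reg: sample_negatives(
            expression.gene_ids, set(regulons[reg]), len(regulons[reg]), seed + i, regulator=reg
        )
        for i, reg in enumerate(sorted(regulons))
    }
    rows = []
    for kernel_kind in ("linear", "rbf"):
        spec = KernelSpec(kernel_kind)
        for i, reg in enumerate(sorted(regulons)):
            mean_auc, fold_aucs = cross_validated_auc(
                expression, reg, set(regulons[reg]), de_genes,
                mode="local", kernel=spec, C=C, seed=seed + i,
                negatives=negatives[reg], epsilon=epsilon,
            )
            rows.append(("local", kernel_kind, reg, mean_auc, fold_aucs))
        glob = _global_cv_auc(
            expression, regulons, de_genes, spec, C, seed, negatives, epsilon
        )
        for reg, (mean_auc, fold_aucs) in sorted(glob.items()):
            rows.append(("global", kernel_kind, reg, mean_auc, fold_aucs))

    clr = CLR(n_bins=n_bins).fit(expression)
    for reg in sorted(regulons):
        regulon = set(regulons[reg])
        pos = sorted(regulon & de_genes)
        neg = sorted(negatives[reg])
        scores = [clr.edge_weight(reg, g) for g in pos + neg]
        labels = [1] * len(pos) + [-1] * len(neg)
        auc = roc_auc(scores, labels)[3]
        rows.append(("clr", "-", reg, auc, [auc]))

    records = []
    for method, kernel_kind, reg, mean_auc, fold_aucs in rows:
        for fold, auc in enumerate(fold_aucs):
            records.append(
                {
                    "regulator": reg,
                    "method": method,
                    "kernel": kernel_kind,
                    "fold": fold,
                    "auc": auc,
                    "mean_auc": mean_auc,
                }
            )
    return pd.DataFrame.from_records(records)
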