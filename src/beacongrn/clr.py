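"""Context likelihood of relatedness (CLR): the unsupervised baseline.

Profiles are discretised into equal-width bins (by default ceil(sqrt(n))
bins for n samples, the usual consistency guard for the plug-in estimator
at short series), pairwise mutual information
is estimated by the plug-in formula in nats, each MI value is z-scored
against its row background (mean/sd over a gene's other MI values, negative
part clipped to zero), and the two directed components combine as
``w_ij = sqrt(z_ij^2 + z_ji^2)``.  Edges incident to a declared regulator
set are ranked by decreasing weight.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .data_io import ExpressionMatrix

__all__ = ["default_bins", "discretize", "mutual_information", "clr_scores", "rank_edges", "CLR"]


def discretize(profile: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width bin indices over [min, max]; the max lands in the top bin.

    A constant profile maps entirely to bin 0.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    x = np.asarray(profile, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros(x.size, dtype=int)
    idx = np.floor((x - lo) / (hi - lo) * n_bins).astype(int)
    return np.minimum(idx, n_bins - 1)


def mutual_information(bins_i: np.ndarray, bins_j: np.ndarray) -> float:
    """Plug-in mutual information (natural log) of two discretised profiles."""
    bi = np.asarray(bins_i)
    bj = np.asarray(bins_j)
    if bi.shape != bj.shape:
        raise ValueError("bin vectors must have equal length")
    n = bi.size
    joint: dict[tuple[int, int], int] = {}
    ci: dict[int, int] = {}
    cj: dict[int, int] = {}
    for a, b in zip(bi.tolist(), bj.tolist()):
        joint[(a, b)] = joint.get((a, b), 0) + 1
        ci[a] = ci.get(a, 0) + 1
        cj[b] = cj.get(b, 0) + 1
    mi = 0.0
    for (a, b), c in joint.items():
        p_ab = c / n
        mi += p_ab * np.log(p_ab * n * n / (ci[a] * cj[b]))
    return max(mi, 0.0)


def default_bins(n_samples: int) -> int:
    """Equal-width bin count for the plug-in MI estimator: ceil(sqrt(n)).

    A plug-in estimate with nearly as many bins as samples saturates (every
    joint cell unique, MI -> log n for all pairs), so the bin count must
    grow slower than the sample count.
    """
    return max(2, int(np.ceil(np.sqrt(n_samples))))


def mi_matrix(values: np.ndarray, n_bins: int | None = None) -> np.ndarray:
    """Symmetric gene x gene MI matrix; diagonal holds each profile's entropy."""
    if n_bins is None:
        n_bins = default_bins(values.shape[1])
    bins = [discretize(row, n_bins) for row in values]
    n = len(bins)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            M[i, j] = M[j, i] = mutual_information(bins[i], bins[j])
    return M


def clr_scores(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Directed z components and combined CLR weights from an MI matrix.

    Row backgrounds (mean, sample sd) exclude the diagonal self-MI.  Rows
    with zero background sd contribute z = 0.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("MI matrix must be square")
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError("MI matrix must be symmetric")
    n = M.shape[0]
    off = ~np.eye(n, dtype=bool)
    mu = np.array([M[i, off[i]].mean() for i in range(n)])
    sd = np.array([M[i, off[i]].std(ddof=1) if n > 2 else 0.0 for i in range(n)])
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (M - mu[:, None]) / sd[:, None]
    z[sd == 0.0] = 0.0
    z = np.maximum(z, 0.0)
    np.fill_diagonal(z, 0.0)
    w = np.sqrt(z**2 + z.T**2)
    return z, w


def rank_edges(
    w: np.ndarray, gene_ids: Sequence[str], regulators: Iterable[str]
) -> list[tuple[str, str, float]]:
    """Regulator-row edges sorted by decreasing weight, ties lexicographic."""
    index = {g: i for i, g in enumerate(gene_ids)}
    regs = sorted(set(regulators))
    missing = [r for r in regs if r not in index]
    if missing:
        raise KeyError(f"regulators not in gene set: {', '.join(missing)}")
    edges = [
        (reg, g, float(w[index[reg], j]))
        for reg in regs
        for j, g in enumerate(gene_ids)
        if g != reg
    ]
    edges.sort(key=lambda e: (-e[2], e[0], e[1]))
    return edges


class CLR(BaseEstimator):
    """CLR network scorer as an estimator.

    Parameters
    ----------
    n_bins : number of equal-width bins per profile; None (default) uses
        ``ceil(sqrt(n_samples))``.

    After ``fit`` the instance carries ``n_bins_``, ``gene_ids_``, ``mi_``
    (MI matrix, nats), ``z_`` (directed background z components) and
    ``weights_`` (symmetric CLR edge weights).
    """

    def __init__(self, n_bins: int | None = None) -> None:
        self.n_bins = n_bins

    def fit(self, expression: ExpressionMatrix | np.ndarray, gene_ids=None) -> "CLR":
        if isinstance(expression, ExpressionMatrix):
            values = expression.values
            gene_ids = expression.gene_ids
        else:
            values = np.asarray(expression, dtype=float)
            if gene_ids is None:
                gene_ids = [f"g{i}" for i in range(values.shape[0])]
        self.gene_ids_ = list(gene_ids)
        self.n_bins_ = self.n_bins if self.n_bins is not None else default_bins(values.shape[1])
        self.mi_ = mi_matrix(values, self.n_bins_)
        self.z_, self.weights_ = clr_scores(self.mi_)
        return self

    def rank_edges(self, regulators: Iterable[str]) -> list[tuple[str, str, float]]:
        return rank_edges(self.weights_, self.gene_ids_, regulators)

    def edge_weight(self, gene_a: str, gene_b: str) -> float:
        i = self.gene_ids_.index(gene_a)
        j = self.gene_ids_.index(gene_b)
        return float(self.weights_[i, j])
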