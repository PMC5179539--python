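"""Correlation filtering, k-means clustering, overlaps and network assembly.

After prediction the per-regulator target lists (known plus predicted) are
filtered by Pearson correlation with the regulator's profile (keep r >= 0.6
by default), clustered by k-means on their expression profiles, checked for
inter-regulator overlap (Venn regions), screened for strongly negative
correlations (r <= -0.6), and merged into one directed network.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from .data_io import ExpressionMatrix

__all__ = [
    "pearson",
    "correlation_table",
    "correlation_filter",
    "TimecourseKMeans",
    "kmeans_cluster",
    "ClusterAssignment",
    "overlap_counts",
    "negative_correlation_report",
    "NetworkEdge",
    "Network",
    "assemble_network",
]

# Inter-regulator wiring of the seed-maturation master regulators: LEC1
# activates ABI3, and ABI3 and FUS3 regulate each other.  Added to an
# assembled network only when those ids are among its regulators.
MASTER_REGULATOR_EDGES = [("LEC1", "ABI3"), ("ABI3", "FUS3"), ("FUS3", "ABI3")]


def pearson(r_profile, t_profile) -> tuple[float, bool]:
    """Pearson r and a definedness flag (False when either profile is constant)."""
    x = np.asarray(r_profile, dtype=float)
    y = np.asarray(t_profile, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points for a correlation")
    if x.std() == 0.0 or y.std() == 0.0:
        return float("nan"), False
    r = float(np.corrcoef(x, y)[0, 1])
    return r, True


def correlation_table(
    expression: ExpressionMatrix, targets_per_regulator: Mapping[str, Iterable[str]]
) -> pd.DataFrame:
    """Tidy (regulator, target, r, defined) table over all listed pairs."""
    rows = []
    for reg in sorted(targets_per_regulator):
        rp = expression.profile(reg)
        for t in sorted(set(targets_per_regulator[reg])):
            r, ok = pearson(rp, expression.profile(t))
            rows.append({"regulator": reg, "target": t, "r": r, "defined": ok})
    return pd.DataFrame.from_records(rows, columns=["regulator", "target", "r", "defined"])


def correlation_filter(table: pd.DataFrame, threshold: float = 0.6) -> dict[str, set[str]]:
    """Per regulator, the targets with defined r >= threshold."""
    keep = table[table["defined"] & (table["r"] >= threshold)]
    out: dict[str, set[str]] = {reg: set() for reg in table["regulator"].unique()}
    for _, row in keep.iterrows():
        out[row["regulator"]].add(row["target"])
    return out


class TimecourseKMeans(BaseEstimator, ClusterMixin):
    """Lloyd's k-means with seeded restarts and farthest-point repair.

    Centers are initialised as a random sample of the data points; an empty
    cluster arising during iteration is re-seeded with the point farthest
    from its current center so the returned solution always has ``n_clusters``
    nonempty clusters.  The best of ``n_restarts`` runs by within-cluster sum
    of squares is kept.

    Fitted attributes: ``labels_`` (0-based), ``cluster_centers_``,
    ``inertia_``, ``n_iter_``.
    """

    def __init__(
        self,
        n_clusters: int = 3,
        n_restarts: int = 20,
        max_iter: int = 300,
        random_state: int = 0,
    ) -> None:
        self.n_clusters = n_clusters
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.random_state = random_state

    def _lloyd(self, X: np.ndarray, rng: np.random.Generator):
        n = X.shape[0]
        centers = X[rng.choice(n, size=self.n_clusters, replace=False)].copy()
        labels = np.full(n, -1)
        for it in range(1, self.max_iter + 1):
            d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            new_labels = d2.argmin(axis=1)
            for c in range(self.n_clusters):
                members = new_labels == c
                if not members.any():
                    far = d2[np.arange(n), new_labels].argmax()
                    centers[c] = X[far]
                    new_labels[far] = c
                    members = new_labels == c
                centers[c] = X[members].mean(axis=0)
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
        inertia = float(((X - centers[labels]) ** 2).sum())
        return labels, centers, inertia, it

    def fit(self, X, y=None) -> "TimecourseKMeans":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_genes, n_timepoints)")
        if not 1 <= self.n_clusters <= X.shape[0]:
            raise ValueError(
                f"n_clusters={self.n_clusters} out of range for {X.shape[0]} points"
            )
        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(self.n_restarts):
            labels, centers, inertia, n_iter = self._lloyd(X, rng)
            if best is None or inertia < best[2] - 1e-12:
                best = (labels, centers, inertia, n_iter)
        self.labels_, self.cluster_centers_, self.inertia_, self.n_iter_ = best
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        d2 = ((X[:, None, :] - self.cluster_centers_[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)


@dataclass
class ClusterAssignment:
    """1-based cluster labels ordered by the timepoint of peak mean expression."""

    assignment: dict[str, int]
    centroids: np.ndarray          # row c-1 = centroid of cluster c
    objective: float
    n_iter: int
    known_flags: dict[str, bool] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return self.centroids.shape[0]

    def members(self, cluster: int) -> set[str]:
        return {g for g, c in self.assignment.items() if c == cluster}


def kmeans_cluster(
    profiles: Mapping[str, np.ndarray] | ExpressionMatrix,
    k: int,
    seed: int = 0,
    n_restarts: int = 20,
    known_genes: Iterable[str] = (),
) -> ClusterAssignment:
    """Cluster gene profiles into k groups; clusters renumbered by peak time."""
    if isinstance(profiles, ExpressionMatrix):
        genes = list(profiles.gene_ids)
        X = profiles.values
    else:
        genes = sorted(profiles)
        X = np.array([profiles[g] for g in genes], dtype=float)
    km = TimecourseKMeans(n_clusters=k, n_restarts=n_restarts, random_state=seed).fit(X)
    # order clusters by when their mean profile peaks (earliest peak = cluster 1)
    peaks = [(int(np.argmax(c)), -float(np.max(c)), i) for i, c in enumerate(km.cluster_centers_)]
    order = [i for _, _, i in sorted(peaks)]
    relabel = {old: new + 1 for new, old in enumerate(order)}
    assignment = {g: relabel[int(l)] for g, l in zip(genes, km.labels_)}
    centroids = km.cluster_centers_[order]
    known = set(known_genes)
    return ClusterAssignment(
        assignment=assignment,
        centroids=centroids,
        objective=km.inertia_,
        n_iter=km.n_iter_,
        known_flags={g: g in known for g in genes},
    )


def overlap_counts(target_sets: Mapping[str, set[str]]) -> dict[str, int]:
    """Exclusive Venn-region counts for 2 or 3 named sets.

    Keys are '&'-joined sorted name combinations, e.g. ``'ABI3&FUS3'``; each
    count covers genes in exactly those sets, so counts sum to |union|.
    """
    names = sorted(target_sets)
    if len(names) not in (2, 3):
        raise ValueError("overlap_counts expects 2 or 3 sets")
    sets = {n: set(target_sets[n]) for n in names}
    out: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(set(), *(sets[n] for n in names if n not in combo))
            out["&".join(combo)] = len(inside - outside)
    return out


def negative_correlation_report(
    table: pd.DataFrame,
    clusters: Mapping[str, ClusterAssignment],
    direct_flags: Mapping[str, Mapping[str, bool]] | None = None,
    threshold: float = -0.6,
) -> pd.DataFrame:
    """Targets anti-correlated with their regulator (r <= threshold), per cluster.

    ``direct_flags[regulator][target]`` marks confirmed promoter binding;
    unknown targets are reported with ``direct=False``.  Per-cluster mean r
    and membership counts are attached to every row.
    """
    direct_flags = direct_flags or {}
    rows = []
    strong = table[table["defined"] & (table["r"] <= threshold)]
    for _, rec in strong.iterrows():
        reg, target = rec["regulator"], rec["target"]
        cl = clusters.get(reg)
        cluster_id = cl.assignment.get(target) if cl else None
        rows.append(
            {
                "regulator": reg,
                "target": target,
                "cluster": cluster_id,
                "r": rec["r"],
                "direct": bool(direct_flags.get(reg, {}).get(target, False)),
            }
        )
    report = pd.DataFrame.from_records(
        rows, columns=["regulator", "target", "cluster", "r", "direct"]
    )
    if len(report):
        stats = (
            report.groupby(["regulator", "cluster"], dropna=False)["r"]
            .agg(cluster_mean_r="mean", cluster_n="size")
            .reset_index()
        )
        report = report.merge(stats, on=["regulator", "cluster"], how="left")
    else:
        report["cluster_mean_r"] = pd.Series(dtype=float)
        report["cluster_n"] = pd.Series(dtype=int)
    return report.sort_values(["regulator", "cluster", "target"]).reset_index(drop=True)


@dataclass(frozen=True)
class NetworkEdge:
    regulator: str
    target: str
    source: str                 # known | predicted | fixed
    r: float | None = None
    cluster: int | None = None
    direct_status: str = "unscanned"   # direct | indirect | unscanned

    def __post_init__(self) -> None:
        if self.regulator == self.target:
            raise ValueError(f"self-edge {self.regulator} not allowed")
        if self.source not in ("known", "predicted", "fixed"):
            raise ValueError(f"bad edge source {self.source!r}")
        if self.direct_status not in ("direct", "indirect", "unscanned"):
            raise ValueError(f"bad direct status {self.direct_status!r}")


@dataclass
class Network:
    edges: list[NetworkEdge]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "regulator": e.regulator,
                    "target": e.target,
                    "source": e.source,
                    "r": "" if e.r is None else f"{e.r:.6g}",
                    "cluster": "" if e.cluster is None else e.cluster,
                    "direct_status": e.direct_status,
                }
                for e in self.edges
            ],
            columns=["regulator", "target", "source", "r", "cluster", "direct_status"],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "Network":
        df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
        edges = []
        for _, row in df.iterrows():
            edges.append(
                NetworkEdge(
                    row["regulator"],
                    row["target"],
                    row["source"],
                    float(row["r"]) if row["r"] != "" else None,
                    int(float(row["cluster"])) if row["cluster"] != "" else None,
                    row["direct_status"],
                )
            )
        return cls(edges)

    def edge_set(self) -> set[tuple]:
        return {
            (e.regulator, e.target, e.source, None if e.r is None else round(e.r, 6),
             e.cluster, e.direct_status)
            for e in self.edges
        }


def assemble_network(
    predicted: Mapping[str, Iterable[str]],
    known: Mapping[str, Iterable[str]],
    correlations: pd.DataFrame | None = None,
    clusters: Mapping[str, ClusterAssignment] | None = None,
    direct_status: Mapping[str, Mapping[str, str]] | None = None,
    fixed_edges: Sequence[tuple[str, str]] | None = None,
) -> Network:
    """Merge per-regulator predicted and known target sets into one network.

    A target both known and predicted yields a single edge with
    ``source='known'``.  ``fixed_edges`` defaults to the master-regulator
    wiring restricted to regulators actually present.  Edge order is
    deterministic: fixed edges first, then (regulator, target) sorted.
    """
    regs = sorted(set(predicted) | set(known))
    corr: dict[tuple[str, str], float] = {}
    if correlations is not None:
        for _, row in correlations.iterrows():
            if row["defined"]:
                corr[(row["regulator"], row["target"])] = float(row["r"])
    clusters = clusters or {}
    direct_status = direct_status or {}

    if fixed_edges is None:
        fixed_edges = [(a, b) for a, b in MASTER_REGULATOR_EDGES if a in regs and b in regs]
    edges: list[NetworkEdge] = [
        NetworkEdge(a, b, "fixed") for a, b in fixed_edges
    ]
    seen = {(e.regulator, e.target) for e in edges}
    for reg in regs:
        known_t = set(known.get(reg, ()))
        pred_t = set(predicted.get(reg, ()))
        for target in sorted(known_t | pred_t):
            if (reg, target) in seen or target == reg:
                continue
            seen.add((reg, target))
            cl = clusters.get(reg)
            edges.append(
                NetworkEdge(
                    regulator=reg,
                    target=target,
                    source="known" if target in known_t else "predicted",
                    r=corr.get((reg, target)),
                    cluster=cl.assignment.get(target) if cl else None,
                    direct_status=direct_status.get(reg, {}).get(target, "unscanned"),
                )
            )
    return Network(edges)
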