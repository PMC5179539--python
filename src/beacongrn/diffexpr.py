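"""Voom-style normalisation and moderated t-tests between consecutive timepoints.

The pipeline mirrors the standard limma/voom treatment of RNA-seq counts at
desk scale: counts become log2-CPM with precision weights taken from a
lowess-smoothed mean-variance trend, each pair of consecutive timepoints is
tested with an empirical-Bayes moderated t-statistic, and p-values are
Benjamini-Hochberg adjusted per contrast.  A gene is declared differentially
expressed when any consecutive contrast has adjusted p below ``alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .data_io import CountMatrix

__all__ = [
    "VoomResult",
    "voom_logcpm",
    "moderated_t_consecutive",
    "bh_adjust",
    "de_filter",
    "de_genes_from_counts",
]


@dataclass
class VoomResult:
    logcpm: pd.DataFrame          # genes x samples
    weights: pd.DataFrame         # same shape, strictly positive
    samples: list[tuple[str, str]]
    timepoint_order: list[str]
    dropped_genes: list[str]      # all-zero rows removed before modelling


def voom_logcpm(counts: CountMatrix, span: float = 0.5) -> VoomResult:
    """Convert counts to log2-CPM with inverse mean-variance precision weights.

    logCPM = log2((count + 0.5) / (library_size + 1) * 1e6).  The residual
    quarter-root standard deviation (within timepoint groups) is smoothed
    against the group-mean logCPM by lowess; each observation's weight is the
    inverse fourth power of the trend value at its fitted logCPM.
    """
    lib = counts.counts.sum(axis=0).astype(float)
    if np.any(lib <= 0):
        raise ValueError("every sample must have a positive library size")
    keep = counts.counts.sum(axis=1) > 0
    dropped = [g for g, k in zip(counts.gene_ids, keep) if not k]
    mat = counts.counts[keep].astype(float)
    genes = [g for g, k in zip(counts.gene_ids, keep) if k]

    logcpm = np.log2((mat + 0.5) / (lib + 1.0) * 1e6)

    # group structure: columns per timepoint
    groups = {}
    for j, (t, _) in enumerate(counts.samples):
        groups.setdefault(t, []).append(j)

    fitted = np.empty_like(logcpm)
    resid_ss = np.zeros(logcpm.shape[0])
    df_resid = 0
    for cols in groups.values():
        cols = np.asarray(cols)
        gmean = logcpm[:, cols].mean(axis=1, keepdims=True)
        fitted[:, cols] = gmean
        resid_ss += ((logcpm[:, cols] - gmean) ** 2).sum(axis=1)
        df_resid += len(cols) - 1
    if df_resid <= 0:
        raise ValueError("need replicates within timepoints to estimate the trend")
    sqrt_sd = (resid_ss / df_resid) ** 0.25  # quarter-root variance, voom's y-axis
    mean_logcpm = logcpm.mean(axis=1)

    trend = lowess(sqrt_sd, mean_logcpm, frac=span, return_sorted=True)
    tx, ty = trend[:, 0], np.maximum(trend[:, 1], 1e-4)
    pred = np.interp(fitted, tx, ty)
    weights = 1.0 / pred**4

    sample_names = counts.sample_names
    return VoomResult(
        logcpm=pd.DataFrame(logcpm, index=genes, columns=sample_names),
        weights=pd.DataFrame(weights, index=genes, columns=sample_names),
        samples=list(counts.samples),
        timepoint_order=list(counts.timepoint_order),
        dropped_genes=dropped,
    )


def _trigamma_inverse(y: np.ndarray) -> np.ndarray:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    y = np.asarray(y, dtype=float)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif) < 1e-10 * x):
            break
    return x


def _fit_prior(log_s2: np.ndarray, d: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) from log sample variances.

    Under the scaled-F model, log s^2 - log s0^2 follows a log-F(d, d0)
    distribution whose mean and variance involve digamma/trigamma terms; the
    moments of the observed log s^2 identify both hyperparameters.
    """
    z = log_s2[np.isfinite(log_s2)]
    if z.size < 2:
        return np.inf, float(np.exp(z.mean())) if z.size else 1.0
    evar = z.var(ddof=1) - special.polygamma(1, d / 2.0)
    if evar <= 0:
        d0 = np.inf
        log_s0 = z.mean() - special.polygamma(0, d / 2.0) + np.log(d / 2.0)
    else:
        d0 = 2.0 * float(_trigamma_inverse(np.array(evar)))
        log_s0 = (
            z.mean()
            - special.polygamma(0, d / 2.0)
            + np.log(d / 2.0)
            + special.polygamma(0, d0 / 2.0)
            - np.log(d0 / 2.0)
        )
    return d0, float(np.exp(log_s0))


def moderated_t_consecutive(
    logcpm: pd.DataFrame,
    weights: pd.DataFrame,
    samples: list[tuple[str, str]],
    timepoint_order: list[str] | None = None,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Moderated t-tests of each timepoint against its predecessor.

    Parameters
    ----------
    logcpm, weights : DataFrame, genes x samples
    samples : list of (timepoint, replicate) labels, one per column.
    timepoint_order : explicit ordering of the series (default: order of
        first appearance in ``samples``).
    prior_df : override for the empirical-Bayes prior degrees of freedom d0;
        ``0`` reduces the statistic to the ordinary two-sample t, ``None``
        estimates d0 from the data per contrast.

    Returns a tidy frame with one row per (gene, contrast) and columns
    gene_id, contrast, log2fc, t, df, p_value.
    """
    if timepoint_order is None:
        timepoint_order = []
        for t, _ in samples:
            if t not in timepoint_order:
                timepoint_order.append(t)
    cols_by_tp: dict[str, list[int]] = {}
    for j, (t, _) in enumerate(samples):
        cols_by_tp.setdefault(t, []).append(j)
    for t in timepoint_order:
        if len(cols_by_tp.get(t, [])) < 2:
            raise ValueError(f"timepoint {t!r} has fewer than 2 replicates")

    x = logcpm.to_numpy(dtype=float)
    w = weights.to_numpy(dtype=float)
    genes = list(logcpm.index)
    out = []
    for prev, curr in zip(timepoint_order[:-1], timepoint_order[1:]):
        c1 = np.asarray(cols_by_tp[prev])
        c2 = np.asarray(cols_by_tp[curr])
        w1, w2 = w[:, c1], w[:, c2]
        m1 = (w1 * x[:, c1]).sum(axis=1) / w1.sum(axis=1)
        m2 = (w2 * x[:, c2]).sum(axis=1) / w2.sum(axis=1)
        resid = np.concatenate(
            [x[:, c1] - m1[:, None], x[:, c2] - m2[:, None]], axis=1
        )
        wres = np.concatenate([w1, w2], axis=1)
        d = len(c1) + len(c2) - 2
        s2 = (wres * resid**2).sum(axis=1) / d
        if prior_df is None:
            with np.errstate(divide="ignore"):
                d0, s0_2 = _fit_prior(np.log(s2), d)
        else:
            d0, s0_2 = float(prior_df), 0.0
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_2)
            df_total = np.inf
        else:
            s2_post = (d0 * s0_2 + d * s2) / (d0 + d)
            df_total = d0 + d
        se = np.sqrt(s2_post * (1.0 / w1.sum(axis=1) + 1.0 / w2.sum(axis=1)))
        delta = m2 - m1
        with np.errstate(divide="ignore", invalid="ignore"):
            t_stat = np.where(delta == 0.0, 0.0, delta / se)
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t_stat))
        else:
            p = 2.0 * stats.t.sf(np.abs(t_stat), df_total)
        out.append(
            pd.DataFrame(
                {
                    "gene_id": genes,
                    "contrast": f"{curr}_vs_{prev}",
                    "log2fc": delta,
                    "t": t_stat,
                    "df": df_total,
                    "p_value": np.clip(p, 0.0, 1.0),
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_per_contrast(results: pd.DataFrame, pooled: bool = False) -> pd.DataFrame:
    """Attach BH-adjusted p-values, by default independently per contrast."""
    results = results.copy()
    if pooled:
        results["adj_p"] = bh_adjust(results["p_value"].to_numpy())
    else:
        results["adj_p"] = (
            results.groupby("contrast", sort=False)["p_value"]
            .transform(lambda s: bh_adjust(s.to_numpy()))
        )
    return results


def de_filter(results: pd.DataFrame, alpha: float = 0.05) -> set[str]:
    """Genes whose adjusted p is strictly below ``alpha`` in any contrast."""
    if "adj_p" not in results.columns:
        results = adjust_per_contrast(results)
    hit = results.loc[results["adj_p"] < alpha, "gene_id"]
    return set(hit)


def de_genes_from_counts(
    counts: CountMatrix, alpha: float = 0.05, pooled_bh: bool = False,
    prior_df: float | None = None,
) -> tuple[set[str], pd.DataFrame]:
    """Full consecutive-timepoint DE pipeline: voom, moderated t, BH, filter."""
    voom = voom_logcpm(counts)
    res = moderated_t_consecutive(
        voom.logcpm, voom.weights, voom.samples, voom.timepoint_order, prior_df=prior_df
    )
    res = adjust_per_contrast(res, pooled=pooled_bh)
    return de_filter(res, alpha=alpha), res
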