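"""Differential expression: count merging, normalization, NB Wald testing.

External raw-count matrices (e.g. a published benign-tissue RNA-seq set) are
inner-joined with panel counts on canonical gene ids, normalized by
median-of-ratios size factors, and tested gene-wise with a negative-binomial
Wald test against a two-condition design, BH-adjusted.

The test engine is a deliberately simple NB Wald implementation: per-gene
method-of-moments dispersion (floored at 1e-8), group means on the
normalized scale, delta-method standard error of the log2 fold change, and a
two-sided p-value from a t reference with residual degrees of freedom (the
plug-in dispersion makes the statistic t-like rather than normal at small
n).  It has no dispersion shrinkage toward a trend, no Cox-Reid adjustment,
no independent filtering and no LFC shrinkage, so its per-gene outputs will
differ from a full GLM fit; calibration and planted-effect recovery are what
the test suite pins down.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import MergeError, ValidationError

logger = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-8


@dataclass
class MergeReport:
    genes_merged: int = 0
    dropped_panel: list[str] = field(default_factory=list)
    dropped_external: list[str] = field(default_factory=list)


def merge_counts(
    panel: pd.DataFrame, external: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series, MergeReport]:
    """Inner-join two counts matrices on gene ids.

    Returns ``(merged, source, report)``: the merged genes x samples matrix,
    a per-sample source tag ("panel"/"external"), and a join report listing
    genes dropped from each side.  Disjoint gene sets are a fatal error.
    """
    overlap = [str(s) for s in set(panel.columns) & set(external.columns)]
    if overlap:
        raise MergeError(f"sample ids collide between panel and external: {sorted(overlap)[:5]}")
    shared = panel.index.intersection(external.index)
    if len(shared) == 0:
        raise MergeError("no genes shared between panel and external counts")
    shared = sorted(shared)
    merged = pd.concat([panel.loc[shared], external.loc[shared]], axis=1)
    source = pd.Series(
        ["panel"] * panel.shape[1] + ["external"] * external.shape[1],
        index=list(panel.columns) + list(external.columns), name="source",
    )
    report = MergeReport(
        genes_merged=len(shared),
        dropped_panel=sorted(set(panel.index) - set(shared)),
        dropped_external=sorted(set(external.index) - set(shared)),
    )
    return merged, source, report


def size_factors(counts: pd.DataFrame, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    factor_j = median over reference genes of count_gj / geomean_g, where the
    reference set is the genes with strictly positive counts in every sample.
    If no such gene exists, ``pseudo_reference=True`` falls back to computing
    the geometric mean over positive entries only (a pseudo-reference);
    otherwise that situation is an error.  A single sample gets factor 1.
    """
    if counts.shape[1] == 1:
        return pd.Series([1.0], index=counts.columns, name="size_factor")
    values = counts.to_numpy(dtype=float)
    all_positive = (values > 0).all(axis=1)
    if all_positive.any():
        ref = values[all_positive]
        log_geomean = np.log(ref).mean(axis=1)
    else:
        if not pseudo_reference:
            raise ValidationError(
                "no gene has all-positive counts; pass pseudo_reference=True "
                "to fall back to a positive-entry pseudo-reference"
            )
        # pseudo-reference: geometric mean over each gene's positive entries
        logs = np.full(values.shape, np.nan)
        np.log(values, where=values > 0, out=logs)
        log_geomean = np.nanmean(logs, axis=1)
        keep = ~np.isnan(log_geomean)
        ref, log_geomean = values[keep], log_geomean[keep]
    factors = []
    for j in range(counts.shape[1]):
        col = ref[:, j]
        pos = col > 0
        log_ratio = np.full(len(col), np.nan)
        log_ratio[pos] = np.log(col[pos]) - log_geomean[pos]
        factors.append(float(np.exp(np.nanmedian(log_ratio))))
    out = pd.Series(factors, index=counts.columns, name="size_factor")
    if (out <= 0).any() or out.isna().any():
        raise ValidationError("size factors must be positive and finite")
    return out


def _dispersion_mom(norm: np.ndarray, groups: list[np.ndarray]) -> float:
    """Method-of-moments NB dispersion from within-group moments.

    alpha solves var = mu + alpha mu^2 with pooled within-group variance and
    the grand within-group mean; floored at DISPERSION_FLOOR.
    """
    ss, df, total, n = 0.0, 0, 0.0, 0
    for idx in groups:
        x = norm[idx]
        if len(x) >= 2:
            ss += (len(x) - 1) * x.var(ddof=1)
            df += len(x) - 1
        total += x.sum()
        n += len(x)
    if df == 0 or n == 0:
        return DISPERSION_FLOOR
    var = ss / df
    mu = total / n
    if mu <= 0:
        return DISPERSION_FLOOR
    return max(DISPERSION_FLOOR, (var - mu) / (mu * mu))


def nb_wald_test(
    counts: pd.DataFrame,
    condition: pd.Series,
    alpha: float = 0.01,
    source: pd.Series | None = None,
) -> pd.DataFrame:
    """Two-condition negative-binomial Wald test, gene-wise.

    ``condition`` maps each sample (column) to one of exactly two labels;
    the log2 fold change is second label vs first, in sorted label order.
    Each condition needs >= 2 samples.  All-zero genes are excluded before
    testing (and before BH, which changes m) and reported via the
    ``tested`` flag.  When ``source`` tags are supplied and conditions
    coincide exactly with sources, a confounding warning is logged — the
    design cannot separate biology from batch in that case.

    Returns a DataFrame: gene, base_mean, log2fc, se, wald_z, p, padj,
    significant (padj < alpha), tested.
    """
    condition = condition.reindex(counts.columns)
    if condition.isna().any():
        raise ValidationError("every sample needs a condition label")
    labels = sorted(condition.unique())
    if len(labels) != 2:
        raise ValidationError(f"exactly two condition labels required, got {labels}")
    idx_a = np.where((condition == labels[0]).to_numpy())[0]
    idx_b = np.where((condition == labels[1]).to_numpy())[0]
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValidationError("each condition needs at least two samples")
    if source is not None:
        source = source.reindex(counts.columns)
        if condition.groupby(source).nunique().eq(1).all() and source.nunique() > 1:
            logger.warning(
                "condition labels coincide with data sources; condition and "
                "batch effects are confounded in this design"
            )

    sf = size_factors(counts, pseudo_reference=True)
    norm_all = counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    inv_sf = 1.0 / sf.to_numpy()

    rows = []
    pvals, tested_rows = [], []
    for i, gene in enumerate(counts.index):
        norm = norm_all[i]
        base_mean = float(norm.mean())
        if counts.iloc[i].sum() == 0:
            rows.append({"gene": gene, "base_mean": 0.0, "log2fc": math.nan,
                         "se": math.nan, "wald_z": math.nan, "p": math.nan,
                         "padj": math.nan, "significant": False, "tested": False})
            continue
        mu_a = float(norm[idx_a].mean())
        mu_b = float(norm[idx_b].mean())
        disp = _dispersion_mom(norm, [idx_a, idx_b])
        # Var(mu_hat_g) = (1/n^2) sum_j (mu/s_j + alpha mu^2); delta method on log2
        def var_log(mu, idx):
            if mu <= 0:
                return math.inf
            return (np.sum(mu * inv_sf[idx] + disp * mu * mu) / (len(idx) ** 2)) / (mu * mu)
        v = var_log(mu_a, idx_a) + var_log(mu_b, idx_b)
        se = math.sqrt(v) / math.log(2) if math.isfinite(v) else math.inf
        if mu_a > 0 and mu_b > 0:
            # difference of logs, not log of ratio: label swap then negates
            # the fold change bitwise-exactly
            log2fc = math.log2(mu_b) - math.log2(mu_a)
        else:
            # one condition entirely zero: direction is known, magnitude is not
            log2fc = math.inf if mu_a == 0 else -math.inf
        if math.isfinite(se) and se > 0 and math.isfinite(log2fc):
            z = log2fc / se
            # t reference with residual df: the plug-in dispersion makes the
            # statistic t-like, not normal, at small n
            p = float(2.0 * stats.t.sf(abs(z), df=len(idx_a) + len(idx_b) - 2))
        elif not math.isfinite(log2fc):
            # fall back to a conservative two-sample test on normalized counts
            z = math.nan
            p = float(stats.mannwhitneyu(
                norm[idx_a], norm[idx_b], alternative="two-sided"
            ).pvalue) if base_mean > 0 else math.nan
        else:
            z, p = math.nan, math.nan
        row = {"gene": gene, "base_mean": base_mean, "log2fc": log2fc,
               "se": se, "wald_z": z, "p": p, "padj": math.nan,
               "significant": False, "tested": True}
        if not math.isnan(p):
            pvals.append(p)
            tested_rows.append(len(rows))
        rows.append(row)

    result = pd.DataFrame(rows)
    if pvals:
        _, padj, _, _ = multipletests(pvals, method="fdr_bh")
        result.loc[tested_rows, "padj"] = padj
    result["significant"] = result["padj"] < alpha
    return result.reset_index(drop=True)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving with input."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
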