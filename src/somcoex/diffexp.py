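"""Differential expression: log2 fold differences against the first growth
point and a simplified negative-binomial Wald test with Benjamini-Hochberg
FDR control.

The test reproduces the *contract* of the usual NB differential-expression
workflow -- per-gene NB test of equal means after size-factor scaling,
followed by BH adjustment and selection at FDR < 0.05 -- in a deliberately
simplified form: dispersion is estimated per gene by the method of moments
from within-group variability (no empirical-Bayes shrinkage), the Wald
statistic is the difference of log mean estimates over its delta-method
standard error, and there is no fold-change shrinkage or independent
filtering.  With duplicate libraries per condition the per-gene dispersion
estimate is very noisy (one residual degree of freedom per group); to keep
the test from turning anti-conservative whenever that estimate happens to
undershoot, every per-gene dispersion is floored at the global median of
the positive per-gene estimates (which also serves as the fallback for
non-positive estimates), and at an absolute floor of 1e-8.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm as _normal

from .io import CountMatrix, SampleMetadata, SomcoexError, ValidationError
from .normalization import ExpressionMatrix

__all__ = [
    "log2_fold_vs_reference",
    "nb_wald_test",
    "bh_adjust",
    "significant_genes",
    "run_differential_expression",
]

_DISPERSION_FLOOR = 1e-8
_MEAN_OFFSET = 0.5  # pseudo-mean protecting log / variance at zero counts


def log2_fold_vs_reference(
    norm: ExpressionMatrix, metadata: SampleMetadata, reference: int | None = None
) -> pd.DataFrame:
    """Per-gene log2 fold difference of each growth point against the reference.

    Within each substrate, lfc(g, GPk) = mean log2 value at GPk minus the
    mean log2 value at the reference growth point (the earliest one by
    default).  Returns a tidy frame (gene_id, substrate, growth_point, lfc).
    """
    if norm.scale != "log2_normalized":
        raise ValidationError("fold differences need a log2-scale matrix")
    ref = metadata.reference_growth_point if reference is None else int(reference)
    frames = []
    for s in metadata.substrates:
        ref_samples = metadata.samples_for(s, ref)
        if not ref_samples:
            raise SomcoexError(f"reference growth point {ref} missing on substrate {s!r}")
        ref_mean = norm.values[ref_samples].mean(axis=1)
        for g in metadata.growth_points:
            if g == ref:
                continue
            lfc = norm.values[metadata.samples_for(s, g)].mean(axis=1) - ref_mean
            frames.append(
                pd.DataFrame(
                    {
                        "gene_id": norm.values.index,
                        "substrate": s,
                        "growth_point": g,
                        "lfc": lfc.to_numpy(),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def _group_moments(
    y: np.ndarray, inv_factors: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean, within-group MoM dispersion estimate and its df, per gene.

    ``y`` is size-factor-normalized counts (genes x samples of one group).
    Var(y_j) = mu / s_j + alpha * mu^2, so the sample variance estimates
    mu * mean(1/s_j) + alpha * mu^2 and alpha is solved by moments.
    """
    mu = y.mean(axis=1)
    if y.shape[1] < 2:
        return mu, np.full_like(mu, np.nan), np.zeros_like(mu)
    var = y.var(axis=1, ddof=1)
    shot = mu * inv_factors.mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var - shot) / np.square(mu)
    alpha[~np.isfinite(alpha)] = np.nan
    df = np.full_like(mu, float(y.shape[1] - 1))
    return mu, alpha, df


def nb_wald_test(
    counts: CountMatrix,
    size_factors: pd.Series,
    group_a: list[str],
    group_b: list[str],
) -> pd.Series:
    """Two-sided per-gene p-value for equal NB means between two sample groups.

    Counts are scaled by the size factors; group means are compared on the
    log scale with a Wald statistic whose variance comes from the NB
    mean-variance relation with a per-gene moment dispersion estimate,
    floored at the global median of positive per-gene estimates (the
    typical dispersion) and at 1e-8.  A gene with zero counts in both
    groups gets p = 1 by convention.
    """
    if len(group_a) + len(group_b) < 2 or not group_a or not group_b:
        raise ValidationError("each group needs >=1 sample and >=2 samples in total")
    missing = [s for s in [*group_a, *group_b] if s not in counts.counts.columns]
    if missing:
        raise ValidationError(f"samples not in count matrix: {missing}")
    fa = size_factors.reindex(group_a).to_numpy(dtype=float)
    fb = size_factors.reindex(group_b).to_numpy(dtype=float)
    if np.isnan(fa).any() or np.isnan(fb).any() or (fa <= 0).any() or (fb <= 0).any():
        raise ValidationError("invalid size factors for test samples")

    ya = counts.counts[group_a].to_numpy(dtype=float) / fa
    yb = counts.counts[group_b].to_numpy(dtype=float) / fb
    mu_a, alpha_a, df_a = _group_moments(ya, 1.0 / fa)
    mu_b, alpha_b, df_b = _group_moments(yb, 1.0 / fb)

    # pool the within-group dispersion estimates, weighted by df
    num = np.nansum(
        np.stack([np.nan_to_num(alpha_a) * df_a, np.nan_to_num(alpha_b) * df_b]), axis=0
    )
    den = df_a * ~np.isnan(alpha_a) + df_b * ~np.isnan(alpha_b)
    with np.errstate(invalid="ignore"):
        alpha = np.where(den > 0, num / np.maximum(den, 1.0), np.nan)
    positive = alpha[np.isfinite(alpha) & (alpha > 0)]
    typical = float(np.median(positive)) if positive.size else _DISPERSION_FLOOR
    alpha = np.where(np.isfinite(alpha), np.maximum(alpha, typical), typical)
    alpha = np.maximum(alpha, _DISPERSION_FLOOR)

    def var_log_mean(mu: np.ndarray, inv_f: np.ndarray) -> np.ndarray:
        m = np.maximum(mu, _MEAN_OFFSET)
        var_mean = (m * inv_f.sum() + alpha * m**2 * len(inv_f)) / len(inv_f) ** 2
        return var_mean / m**2

    z = (np.log(mu_a + _MEAN_OFFSET) - np.log(mu_b + _MEAN_OFFSET)) / np.sqrt(
        var_log_mean(mu_a, 1.0 / fa) + var_log_mean(mu_b, 1.0 / fb)
    )
    p = 2.0 * _normal.sf(np.abs(z))
    p[(mu_a == 0) & (mu_b == 0)] = 1.0
    return pd.Series(np.clip(p, 0.0, 1.0), index=counts.counts.index, name="pvalue")


def bh_adjust(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adj_i = min over j >= rank(i) of p_(j) * m / j, capped at 1.  Output
    order matches input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p-values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def significant_genes(table: pd.DataFrame, alpha: float = 0.05) -> dict[tuple[str, int], set[str]]:
    """Genes with adjusted p strictly below ``alpha``, per (substrate, GP) contrast."""
    out: dict[tuple[str, int], set[str]] = {}
    for (s, g), sub in table.groupby(["substrate", "growth_point"], sort=False):
        out[(s, int(g))] = set(sub.loc[sub["padj"] < alpha, "gene_id"])
    return out


def run_differential_expression(
    counts: CountMatrix,
    metadata: SampleMetadata,
    norm: ExpressionMatrix,
    size_factors: pd.Series,
    reference: int | None = None,
) -> pd.DataFrame:
    """Full fold-change table: within-substrate GPk vs reference contrasts.

    Combines the log2 fold differences (from the log2-normalized matrix)
    with NB Wald p-values (from raw counts + size factors), BH-adjusted
    within each contrast.  Returns a tidy frame (gene_id, substrate,
    growth_point, lfc, pvalue, padj).
    """
    ref = metadata.reference_growth_point if reference is None else int(reference)
    lfc = log2_fold_vs_reference(norm, metadata, ref)
    frames = []
    for s in metadata.substrates:
        ref_samples = metadata.samples_for(s, ref)
        for g in metadata.growth_points:
            if g == ref:
                continue
            p = nb_wald_test(counts, size_factors, metadata.samples_for(s, g), ref_samples)
            sub = lfc[(lfc["substrate"] == s) & (lfc["growth_point"] == g)].copy()
            sub["pvalue"] = p.reindex(sub["gene_id"]).to_numpy()
            sub["padj"] = bh_adjust(sub["pvalue"].to_numpy())
            frames.append(sub)
    return pd.concat(frames, ignore_index=True)
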