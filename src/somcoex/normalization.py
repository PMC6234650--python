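"""Normalization and QC: CPM, median-of-ratios size factors, log2 transform,
the per-condition minimum-read filter, replicate correlation and
housekeeping-gene consistency checks.

Two normalization paths are kept deliberately separate, as time-course
wood-decay studies keep them: CPM (library-size scaling only) for
abundance reporting and the 2.5x-median high-expression rule, and
median-of-ratios size factors + log2 for everything model-facing (fold
differences, SOM training).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .io import AnnotationTable, CountMatrix, SampleMetadata, SomcoexError, ValidationError

__all__ = [
    "ExpressionMatrix",
    "cpm",
    "size_factors_median_ratio",
    "normalized_log2",
    "filter_min_mean_reads",
    "ReplicateQC",
    "replicate_spearman",
    "replicate_pair_coherence",
    "housekeeping_check",
]


@dataclass
class ExpressionMatrix:
    """Real-valued genes x samples matrix with a scale tag.

    ``scale`` is ``"cpm"`` (non-negative, columns sum to 1e6) or
    ``"log2_normalized"`` (log2 of size-factor-normalized counts plus a
    pseudocount).
    """

    values: pd.DataFrame
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in {"cpm", "log2_normalized"}:
            raise ValidationError(f"unknown scale tag {self.scale!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def cpm(counts: CountMatrix) -> ExpressionMatrix:
    """Counts per million: each count scaled by its library size x 1e6."""
    lib = counts.library_sizes()
    zero = lib.index[lib == 0]
    if len(zero):
        raise SomcoexError(f"zero library size for sample(s): {list(zero)}")
    vals = counts.counts / lib * 1e6
    return ExpressionMatrix(vals, "cpm")


def size_factors_median_ratio(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios sequencing-depth factors, geometric mean 1.

    For each sample the factor is the median, over genes expressed in all
    samples, of the ratio count / per-gene geometric mean.  Factors are
    rescaled so their geometric mean is exactly 1, making them pure
    relative-depth multipliers.
    """
    x = counts.counts.to_numpy(dtype=float)
    ref = (x > 0).all(axis=1)
    if not ref.any():
        raise SomcoexError(
            "no gene with nonzero counts in all samples; filter low-count genes first"
        )
    xr = x[ref]
    geomean = np.exp(np.log(xr).mean(axis=1, keepdims=True))
    factors = np.median(xr / geomean, axis=0)
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.counts.columns, name="size_factor")


def normalized_log2(
    counts: CountMatrix, factors: pd.Series, pseudocount: float = 1.0
) -> ExpressionMatrix:
    """log2(count / size_factor + pseudocount); zero counts stay at 0 by default."""
    if not np.all(np.isfinite(factors)) or (factors <= 0).any():
        raise ValidationError("size factors must be finite and positive")
    f = factors.reindex(counts.counts.columns)
    if f.isna().any():
        raise ValidationError(f"missing size factors for: {list(f.index[f.isna()])}")
    vals = np.log2(counts.counts / f + pseudocount)
    return ExpressionMatrix(vals, "log2_normalized")


def filter_min_mean_reads(
    counts: CountMatrix,
    metadata: SampleMetadata,
    threshold: float = 5.0,
    scope: str = "all",
) -> list[str]:
    """Genes whose per-condition mean raw count strictly exceeds ``threshold``.

    The mean is taken across the replicates of each (substrate, growth
    point) condition.  ``scope="all"`` (default) requires the criterion in
    every condition; ``scope="any"`` in at least one.  Returns kept gene
    IDs in original order.
    """
    if scope not in {"all", "any"}:
        raise ValidationError(f"scope must be 'all' or 'any', got {scope!r}")
    metadata.check_covers(counts)
    cond_means = pd.DataFrame(
        {
            (s, g): counts.counts[metadata.samples_for(s, g)].mean(axis=1)
            for s, g in metadata.conditions
        }
    )
    passed = (cond_means > threshold)
    keep = passed.all(axis=1) if scope == "all" else passed.any(axis=1)
    return list(counts.counts.index[keep])


@dataclass
class ReplicateQC:
    """Sample-sample Spearman correlations and their average-linkage tree."""

    correlation: pd.DataFrame  # symmetric, NaN where undefined
    linkage: np.ndarray | None  # scipy linkage matrix on distance 1 - rho


def replicate_spearman(norm: ExpressionMatrix) -> ReplicateQC:
    """Spearman's rank correlation between sample columns, plus a dendrogram.

    Average-linkage hierarchical clustering on distance 1 - rho.  A
    constant column has undefined rank correlation; those pairs are
    reported as NaN and, if any exist, the tree is skipped.
    """
    df = norm.values
    if df.shape[1] < 2:
        raise ValidationError("need at least 2 samples")
    x = df.to_numpy(dtype=float)
    constant = np.ptp(x, axis=0) == 0
    # Spearman = Pearson on average ranks; constant columns have zero rank
    # variance and yield NaN for their pairs
    ranks = np.apply_along_axis(rankdata, 0, x)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    np.fill_diagonal(rho, np.where(constant, np.nan, 1.0))
    corr = pd.DataFrame(rho, index=df.columns, columns=df.columns)
    link = None
    if not constant.any():
        dist = squareform(np.clip(1.0 - rho, 0.0, None), checks=False)
        link = linkage(dist, method="average")
    return ReplicateQC(corr, link)


def replicate_pair_coherence(qc: ReplicateQC, metadata: SampleMetadata) -> pd.Series:
    """Per condition: do its two replicates merge before any cross-condition join?

    True for a condition when its replicate leaves are joined directly by
    a linkage step (i.e. they form a pure two-leaf cluster).  Reported,
    never enforced: a QC signal, not a gate.
    """
    if qc.linkage is None:
        raise SomcoexError("no dendrogram available (constant sample present)")
    samples = list(qc.correlation.index)
    n = len(samples)
    # cluster id -> set of leaf indices
    members: dict[int, set[int]] = {i: {i} for i in range(n)}
    direct_pairs: set[frozenset[int]] = set()
    for k, (a, b, _, _) in enumerate(qc.linkage[:, :4].tolist()):
        a, b = int(a), int(b)
        merged = members[a] | members[b]
        if len(merged) == 2:
            direct_pairs.add(frozenset(merged))
        members[n + k] = merged
    out = {}
    for s, g in metadata.conditions:
        reps = [samples.index(x) for x in metadata.samples_for(s, g) if x in samples]
        if len(reps) == 2:
            out[(s, g)] = frozenset(reps) in direct_pairs
    return pd.Series(out, name="replicates_join_first")


def housekeeping_check(
    norm: ExpressionMatrix,
    metadata: SampleMetadata,
    annotations: AnnotationTable,
    threshold: float = 1.0,
) -> pd.DataFrame:
    """Stability check of housekeeping controls across all conditions.

    For every gene annotated in the ``housekeeping`` namespace, computes
    per-condition mean log2 expression, the max - min spread across
    conditions, and flags genes whose spread exceeds ``threshold`` (log2
    units).  Large spreads indicate inconsistent growth or normalization
    problems.
    """
    hk = [g for g in annotations.genes_with("housekeeping") if g in norm.values.index]
    if not hk:
        warnings.warn("no housekeeping-annotated genes found in matrix", stacklevel=2)
        return pd.DataFrame(columns=["spread", "flagged"])
    sub = norm.values.loc[hk]
    cond_means = pd.DataFrame(
        {
            (s, g): sub[metadata.samples_for(s, g)].mean(axis=1)
            for s, g in metadata.conditions
        }
    )
    spread = cond_means.max(axis=1) - cond_means.min(axis=1)
    out = cond_means.copy()
    out.columns = [f"{s}{g}" for s, g in out.columns]
    out["spread"] = spread
    out["flagged"] = spread > threshold
    return out
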