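"""Node-level analysis of a trained SOM: per-condition node profiles,
condition-specific node calls, the high-expression (2.5x median CPM) gene
filter, per-node annotation overlays, and Tatami-map rendering.

A *Tatami map* is the grid rendering of SOM nodes coloured by mean log2
transcription per condition, with condition-specific nodes highlighted.
A node is condition-specific when its mean log2 expression strictly
exceeds a high-expression threshold (the 95th percentile of all
gene x sample values by default, overridable with a fixed cut such as
10.2) and/or its log2 fold difference against the first growth point
strictly exceeds a fold threshold (2 by default).  The two criteria are
combined with ``any`` by default (either criterion suffices); reference
growth-point conditions can only satisfy the mean criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import AnnotationTable, SampleMetadata, SomcoexError, ValidationError
from .normalization import ExpressionMatrix
from .som import NodeAssignment

__all__ = [
    "NodeProfile",
    "NodeCallConfig",
    "node_condition_means",
    "expression_percentile_threshold",
    "call_condition_specific_nodes",
    "HighExpressionResult",
    "high_expression_genes",
    "annotate_nodes",
    "nodes_containing",
    "render_tatami",
]


@dataclass
class NodeProfile:
    """Per-node condition means, fold differences vs the reference GP, sizes.

    ``means``: node x condition mean log2 expression over member genes and
    replicates (NaN for empty nodes).  ``folds``: node x (substrate, GPk >
    reference) log2 fold difference within substrate.  Empty nodes carry
    undefined profiles and are excluded from calls.
    """

    means: pd.DataFrame
    folds: pd.DataFrame
    member_count: pd.Series

    @property
    def node_ids(self) -> np.ndarray:
        return self.means.index.to_numpy()


@dataclass
class NodeCallConfig:
    """Thresholds for condition-specific node calling.

    ``percentile`` sets the data-driven mean-expression cut;
    ``abs_threshold_override`` replaces it with a fixed value (e.g. 10.2
    log2 reads).  ``combine`` is ``any`` (either criterion) or ``all``
    (both).  All comparisons are strict.
    """

    percentile: float = 95.0
    abs_threshold_override: float | None = None
    lfc_threshold: float = 2.0
    combine: str = "any"

    def __post_init__(self) -> None:
        if not 0.0 < self.percentile < 100.0:
            raise ValidationError("percentile must lie in (0, 100)")
        if self.combine not in {"any", "all"}:
            raise ValidationError("combine must be 'any' or 'all'")
        if not np.isfinite(self.lfc_threshold):
            raise ValidationError("lfc_threshold must be finite")


def node_condition_means(
    assignment: NodeAssignment,
    norm: ExpressionMatrix,
    metadata: SampleMetadata,
    reference: int | None = None,
) -> NodeProfile:
    """Average member-gene log2 values per node and condition.

    The mean runs over all member-gene x replicate values of the
    condition; folds are mean(GPk) - mean(reference GP) within substrate.
    """
    if norm.scale != "log2_normalized":
        raise ValidationError("node profiles need a log2-scale matrix")
    ref = metadata.reference_growth_point if reference is None else int(reference)
    nodes = pd.Index(range(1, assignment.n_nodes + 1), name="node_id")
    node_of = assignment.gene_to_node.reindex(norm.values.index)
    if node_of.isna().any():
        raise ValidationError("assignment does not cover all genes in the matrix")

    cols = pd.MultiIndex.from_tuples(metadata.conditions, names=["substrate", "growth_point"])
    means = pd.DataFrame(np.nan, index=nodes, columns=cols)
    for s, g in metadata.conditions:
        vals = norm.values[metadata.samples_for(s, g)]
        per_gene = vals.to_numpy().reshape(len(vals), -1)
        stacked = pd.DataFrame(
            {"node": np.repeat(node_of.to_numpy(), per_gene.shape[1]), "v": per_gene.ravel()}
        )
        m = stacked.groupby("node")["v"].mean()
        means.loc[m.index, (s, g)] = m.to_numpy()

    fold_cols = pd.MultiIndex.from_tuples(
        [(s, g) for s, g in metadata.conditions if g != ref],
        names=["substrate", "growth_point"],
    )
    folds = pd.DataFrame(np.nan, index=nodes, columns=fold_cols)
    for s, g in fold_cols:
        folds[(s, g)] = means[(s, g)] - means[(s, ref)]

    counts = node_of.value_counts().reindex(nodes, fill_value=0).astype(int)
    counts.name = "member_count"
    return NodeProfile(means, folds, counts)


def expression_percentile_threshold(
    norm: ExpressionMatrix, percentile: float = 95.0, override: float | None = None
) -> float:
    """High-expression cut: a percentile of ALL gene x sample log2 values.

    Linear-interpolation quantile; when ``override`` is given (e.g. a
    fixed 10.2 log2-reads cut) it is returned unchanged.
    """
    if override is not None:
        return float(override)
    vals = norm.values.to_numpy().ravel()
    if vals.size == 0:
        raise ValidationError("empty expression matrix")
    return float(np.percentile(vals, percentile))


def call_condition_specific_nodes(
    profiles: NodeProfile,
    config: NodeCallConfig,
    norm: ExpressionMatrix | None = None,
    mean_threshold: float | None = None,
) -> dict[tuple[str, int], set[int]]:
    """Flag nodes with high and/or differential transcription per condition.

    A node is flagged for (substrate, GPk) when its condition mean
    strictly exceeds the high-expression threshold and/or its fold vs the
    reference GP strictly exceeds ``lfc_threshold``, combined per
    ``config.combine``.  Reference-GP conditions have no fold and can
    only satisfy the mean criterion (under ``combine=all`` they are never
    flagged, since the fold criterion is unsatisfiable there).  The mean
    threshold is resolved from ``config.abs_threshold_override``, an
    explicit ``mean_threshold``, or the configured percentile of ``norm``.
    """
    if mean_threshold is None:
        if config.abs_threshold_override is not None:
            mean_threshold = float(config.abs_threshold_override)
        elif norm is not None:
            mean_threshold = expression_percentile_threshold(norm, config.percentile)
        else:
            raise ValidationError("provide norm or mean_threshold to resolve the cut")

    out: dict[tuple[str, int], set[int]] = {}
    for s, g in profiles.means.columns:
        mean_ok = profiles.means[(s, g)] > mean_threshold
        if (s, g) in profiles.folds.columns:
            fold_ok = profiles.folds[(s, g)] > config.lfc_threshold
        else:
            fold_ok = pd.Series(False, index=profiles.means.index)
        flagged = (mean_ok | fold_ok) if config.combine == "any" else (mean_ok & fold_ok)
        flagged &= profiles.means[(s, g)].notna()
        out[(s, int(g))] = set(profiles.means.index[flagged].astype(int))
    return out


@dataclass
class HighExpressionResult:
    """Genes above factor x median CPM, per (substrate, growth point)."""

    per_condition: dict[tuple[str, int], set[str]]
    thresholds: dict[tuple[str, int], float]

    @property
    def union(self) -> set[str]:
        out: set[str] = set()
        for s in self.per_condition.values():
            out |= s
        return out


def high_expression_genes(
    cpm_matrix: ExpressionMatrix,
    metadata: SampleMetadata,
    factor: float = 2.5,
    annotations: AnnotationTable | None = None,
    scope: str | None = None,
) -> HighExpressionResult:
    """Genes with CPM strictly above ``factor`` x the median, per growth point.

    Replicates are averaged within each (substrate, growth point); the
    median is taken over the scoped gene set (all genes, or only those in
    an annotation namespace such as CAZy or P450_clan) at that condition
    -- linear-interpolation quantile.  Strict inequality throughout.
    """
    if cpm_matrix.scale != "cpm":
        raise ValidationError("high-expression rule operates on CPM values")
    genes = cpm_matrix.values.index
    if scope is not None:
        if annotations is None:
            raise ValidationError("scope restriction requires an annotation table")
        scoped = [g for g in annotations.genes_with(scope) if g in genes]
        if not scoped:
            raise SomcoexError(f"no genes in matrix carry namespace {scope!r}")
        genes = pd.Index(scoped)
    sub = cpm_matrix.values.loc[genes]

    per_condition: dict[tuple[str, int], set[str]] = {}
    thresholds: dict[tuple[str, int], float] = {}
    for s, g in metadata.conditions:
        mean_cpm = sub[metadata.samples_for(s, g)].mean(axis=1)
        cut = factor * float(np.median(mean_cpm.to_numpy()))
        thresholds[(s, int(g))] = cut
        per_condition[(s, int(g))] = set(mean_cpm.index[mean_cpm > cut])
    return HighExpressionResult(per_condition, thresholds)


def annotate_nodes(
    assignment: NodeAssignment, annotations: AnnotationTable
) -> pd.DataFrame:
    """Per-node counts of member genes by (namespace, label).

    Genes without any annotation are counted under
    ``("unannotated", "unannotated")``.  The result is a tidy frame
    (node_id, namespace, label, count) suitable for co-occurrence queries
    such as nodes holding both a P450 and a glutathione-S-transferase.
    """
    rows = []
    for g, node in assignment.gene_to_node.items():
        pairs = annotations.get(g) or {("unannotated", "unannotated")}
        for ns, lab in sorted(pairs):
            rows.append((int(node), ns, lab))
    df = pd.DataFrame(rows, columns=["node_id", "namespace", "label"])
    return (
        df.groupby(["node_id", "namespace", "label"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )


def nodes_containing(
    node_annotations: pd.DataFrame, namespace: str | None = None, label: str | None = None
) -> set[int]:
    """Nodes with at least one member matching the namespace/label filter.

    Intersect results of two calls to report label co-occurrence.
    """
    m = pd.Series(True, index=node_annotations.index)
    if namespace is not None:
        m &= node_annotations["namespace"] == namespace
    if label is not None:
        m &= node_annotations["label"] == label
    return set(node_annotations.loc[m, "node_id"].astype(int))


def render_tatami(
    profiles: NodeProfile,
    calls: dict[tuple[str, int], set[int]],
    rows: int,
    cols: int,
    path: str | Path,
    label_nodes: bool = True,
) -> Path:
    """Write a Tatami-map figure: one heat-grid panel per condition.

    Nodes are coloured by mean log2 value (row-major layout, node 1 at
    the top left), flagged nodes are outlined, and node IDs are printed
    in each cell when ``label_nodes`` is set.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    conditions = list(profiles.means.columns)
    n_panels = len(conditions)
    ncol = min(5, n_panels)
    nrow = int(np.ceil(n_panels / ncol))
    fig, axes = plt.subplots(
        nrow, ncol, figsize=(2.2 * ncol, 2.6 * nrow), squeeze=False
    )
    vmin = np.nanmin(profiles.means.to_numpy()) if profiles.means.notna().any().any() else 0
    vmax = np.nanmax(profiles.means.to_numpy()) if profiles.means.notna().any().any() else 1
    for ax in axes.ravel()[n_panels:]:
        ax.axis("off")
    for k, (s, g) in enumerate(conditions):
        ax = axes.ravel()[k]
        grid_vals = profiles.means[(s, g)].to_numpy().reshape(rows, cols)
        ax.imshow(grid_vals, cmap="viridis", vmin=vmin, vmax=vmax)
        for node in sorted(calls.get((s, int(g)), set())):
            r, c = (node - 1) // cols, (node - 1) % cols
            ax.add_patch(
                Rectangle((c - 0.5, r - 0.5), 1, 1, fill=False, edgecolor="red", lw=1.2)
            )
        if label_nodes:
            fs = max(2.0, 7.0 - 0.01 * rows * cols)
            for node in range(1, rows * cols + 1):
                r, c = (node - 1) // cols, (node - 1) % cols
                ax.text(c, r, str(node), ha="center", va="center", fontsize=fs, color="w")
        ax.set_title(f"{s} GP{g}", fontsize=8)
        ax.set_xticks([])
        ax.set_yticks([])
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
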