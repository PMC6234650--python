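"""Negative-binomial time-course simulator with planted co-expression modules.

Emulates a two-substrate (aspen ``AH`` / spruce ``WH``), five-growth-point,
two-replicate wood-decay transcriptome: gene-level counts are drawn from a
negative binomial with variance ``mu + alpha * mu**2``, library sizes vary
per sample, and a handful of planted gene modules follow distinct temporal
profiles (rising, falling, substrate-divergent, late burst) on top of a
flat background.  Housekeeping genes (chitin synthase / NADH dehydrogenase
style controls) are flat across all conditions and moderately-to-highly
expressed, as real housekeeping controls are.

Ground truth (module membership and true per-condition mean log2
expression) is retained so downstream stages -- normalization, differential
expression, SOM clustering and condition-specific node calling -- can be
tested for recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import AnnotationTable, CountMatrix, SampleMetadata, ValidationError

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "generate_truth",
    "simulate_counts",
    "make_annotations",
    "PROFILE_SHAPES",
]

#: profile shapes cycled over planted modules, in this order
PROFILE_SHAPES = ("rising", "falling", "substrate_divergent", "late_burst", "flat")

#: mock CAZy family labels reused for planted modules in annotation output
MODULE_FAMILIES = ("AA2", "AA9", "GH5", "GH16", "AA3", "CE1", "PL1", "AA5")

HOUSEKEEPING_FAMILIES = ("chitin synthase", "NADH dehydrogenase")


@dataclass(frozen=True)
class SimConfig:
    """Study-design and noise parameters of the simulator.

    Defaults mirror the two-substrate, five-growth-point, duplicate
    design: 20 samples named ``AH1_1 .. WH5_2``.  ``dispersion`` is the NB
    dispersion alpha in ``var = mu + alpha * mu**2``; ``replicate_sigma``
    is log-normal replicate noise on the mean, in log2 units.
    """

    n_genes: int = 5000
    n_modules: int = 4
    module_size: int = 50
    substrates: Sequence[str] = ("AH", "WH")
    growth_points: Sequence[int] = (1, 2, 3, 4, 5)
    n_replicates: int = 2
    baseline_log2_mean_range: tuple[float, float] = (3.0, 9.0)
    dispersion: float = 0.02
    library_size_range: tuple[int, int] = (500_000, 1_500_000)
    effect_log2fc: float = 3.0
    replicate_sigma: float = 0.1
    background_condition_sigma: float = 0.3
    n_housekeeping: int = 27
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValidationError("n_genes must be positive")
        if self.n_modules < 0 or self.module_size <= 0:
            raise ValidationError("n_modules must be >=0 and module_size positive")
        if self.n_housekeeping < 0:
            raise ValidationError("n_housekeeping must be non-negative")
        if self.n_modules * self.module_size + self.n_housekeeping > self.n_genes:
            raise ValidationError(
                "module_size * n_modules + n_housekeeping exceeds n_genes"
            )
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        if len(self.growth_points) < 2:
            raise ValidationError("growth_points needs >=2 levels")
        lo, hi = self.baseline_log2_mean_range
        if lo > hi:
            raise ValidationError("baseline_log2_mean_range min > max")
        lo, hi = self.library_size_range
        if lo > hi or lo <= 0:
            raise ValidationError("library_size_range must be positive with min <= max")
        if self.n_replicates <= 0:
            raise ValidationError("n_replicates must be positive")
        if self.effect_log2fc < 0:
            raise ValidationError("effect_log2fc must be non-negative")
        if self.replicate_sigma < 0:
            raise ValidationError("replicate_sigma must be non-negative")
        if self.background_condition_sigma < 0:
            raise ValidationError("background_condition_sigma must be non-negative")

    @property
    def conditions(self) -> list[tuple[str, int]]:
        return [(s, int(g)) for s in self.substrates for g in self.growth_points]


@dataclass
class SyntheticTruth:
    """Planted structure: who belongs to which module, and true means.

    ``gene_labels`` maps every gene to a module ID, ``"background"`` or
    ``"housekeeping"``; ``true_log2`` holds each gene's true mean log2
    expected count per (substrate, growth point); ``module_profiles`` the
    shared per-module profile; ``module_shapes`` the shape name per module.
    """

    gene_labels: pd.Series  # gene_id -> label
    module_shapes: dict[str, str]
    module_profiles: pd.DataFrame  # module_id x conditions (MultiIndex)
    true_log2: pd.DataFrame  # gene_id x conditions (MultiIndex)
    config: SimConfig = field(repr=False, default=None)

    def members(self, label: str) -> list[str]:
        return list(self.gene_labels.index[self.gene_labels == label])

    @property
    def module_ids(self) -> list[str]:
        return list(self.module_profiles.index)


def _shape_profile(
    shape: str, base: float, effect: float, substrates: Sequence[str], gps: Sequence[int]
) -> dict[tuple[str, int], float]:
    """True mean log2 per condition for one module.

    ``rising`` climbs monotonically by ``effect`` from the first to the
    last growth point on both substrates; ``falling`` is its mirror;
    ``substrate_divergent`` rises on the first substrate and falls on the
    second (a reversed profile across substrates); ``late_burst`` is flat
    until the final growth point.
    """
    n = len(gps)
    frac = {g: i / (n - 1) for i, g in enumerate(gps)}
    out: dict[tuple[str, int], float] = {}
    for si, s in enumerate(substrates):
        for g in gps:
            f = frac[g]
            if shape == "flat":
                v = base
            elif shape == "rising":
                v = base + effect * f
            elif shape == "falling":
                v = base + effect * (1.0 - f)
            elif shape == "substrate_divergent":
                v = base + effect * (f if si == 0 else 1.0 - f)
            elif shape == "late_burst":
                v = base + (effect if g == gps[-1] else 0.0)
            else:
                raise ValidationError(f"unknown profile shape {shape!r}")
            out[(s, int(g))] = v
    return out


def generate_truth(config: SimConfig) -> SyntheticTruth:
    """Plant modules, housekeeping genes and background; deterministic per seed."""
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    width = max(5, len(str(config.n_genes)))
    genes = [f"g{i:0{width}d}" for i in range(1, config.n_genes + 1)]
    order = rng.permutation(config.n_genes)

    labels = pd.Series("background", index=pd.Index(genes, name="gene_id"))
    conditions = pd.MultiIndex.from_tuples(
        config.conditions, names=["substrate", "growth_point"]
    )
    gps = [int(g) for g in config.growth_points]
    lo, hi = config.baseline_log2_mean_range

    module_shapes: dict[str, str] = {}
    profiles: dict[str, dict[tuple[str, int], float]] = {}
    pos = 0
    for m in range(config.n_modules):
        mid = f"module_{m + 1}"
        idx = order[pos : pos + config.module_size]
        pos += config.module_size
        labels.iloc[idx] = mid
        shape = PROFILE_SHAPES[m % len(PROFILE_SHAPES)]
        module_shapes[mid] = shape
        base = rng.uniform(lo, hi)
        profiles[mid] = _shape_profile(
            shape, base, config.effect_log2fc, list(config.substrates), gps
        )

    hk_idx = order[pos : pos + config.n_housekeeping]
    pos += config.n_housekeeping
    labels.iloc[hk_idx] = "housekeeping"

    true = np.empty((config.n_genes, len(conditions)))
    # background genes: flat at a per-gene baseline over the full range;
    # housekeeping controls: flat, drawn from the upper half of the range
    baselines = rng.uniform(lo, hi, size=config.n_genes)
    baselines[hk_idx] = rng.uniform((lo + hi) / 2.0, hi, size=len(hk_idx))
    true[:] = baselines[:, None]
    # background genes carry modest per-condition biological variation
    # (unmodelled regulation); housekeeping genes stay exactly flat
    bg_mask = np.asarray(labels == "background")
    true[bg_mask] += rng.normal(
        0.0, config.background_condition_sigma, size=(int(bg_mask.sum()), len(conditions))
    )
    for mid, prof in profiles.items():
        row = np.array([prof[c] for c in conditions])
        true[np.asarray(labels == mid)] = row

    module_profiles = pd.DataFrame(
        [[profiles[mid][c] for c in conditions] for mid in profiles],
        index=pd.Index(list(profiles), name="module_id"),
        columns=conditions,
    )
    true_log2 = pd.DataFrame(true, index=labels.index, columns=conditions)
    return SyntheticTruth(labels, module_shapes, module_profiles, true_log2, config)


def simulate_counts(
    truth: SyntheticTruth, config: SimConfig | None = None
) -> tuple[CountMatrix, SampleMetadata]:
    """Draw NB counts for the full design from a truth object.

    Sample columns are ordered substrate-major, then growth point, then
    replicate, and named ``{substrate}{growth_point}_{replicate}``.  The
    NB mean of gene g in sample s is ``scale_s * 2**(true_log2 + eps)``
    with ``eps ~ N(0, replicate_sigma)`` drawn per gene and sample and
    ``scale_s`` the sample's library size over the geometric mean of all
    library sizes.  One RNG stream, seeded from ``config.seed``; draws are
    gene-major within each array draw.
    """
    config = config or truth.config
    config.validate()
    if list(truth.true_log2.columns) != [tuple(c) for c in config.conditions]:
        raise ValidationError("truth conditions do not match config")
    rng = np.random.default_rng([config.seed, 1])

    sample_rows = []
    for s in config.substrates:
        for g in config.growth_points:
            for r in range(1, config.n_replicates + 1):
                sample_rows.append((f"{s}{g}_{r}", s, int(g), r))
    sample_ids = [r[0] for r in sample_rows]
    n_samples = len(sample_ids)

    lo, hi = config.library_size_range
    lib_sizes = rng.integers(lo, hi + 1, size=n_samples).astype(float)
    scale = lib_sizes / np.exp(np.mean(np.log(lib_sizes)))

    # per-sample condition column of the truth table
    cond_idx = [truth.true_log2.columns.get_loc((s, g)) for _, s, g, _ in sample_rows]
    mu_log2 = truth.true_log2.to_numpy()[:, cond_idx]
    noise = rng.normal(0.0, config.replicate_sigma, size=mu_log2.shape)
    mu = scale[None, :] * np.exp2(mu_log2 + noise)

    if config.dispersion < 1e-12:
        counts = rng.poisson(mu)
    else:
        shape = 1.0 / config.dispersion
        lam = rng.gamma(shape, mu * config.dispersion)
        counts = rng.poisson(lam)

    cm = CountMatrix(
        pd.DataFrame(counts.astype(np.int64), index=truth.true_log2.index, columns=sample_ids)
    )
    md = SampleMetadata(
        pd.DataFrame(
            {
                "substrate": [r[1] for r in sample_rows],
                "growth_point": [r[2] for r in sample_rows],
                "replicate": [r[3] for r in sample_rows],
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    return cm, md


def make_annotations(truth: SyntheticTruth) -> AnnotationTable:
    """Mock annotation table: module labels reused as CAZy families.

    Each planted module is tagged with one CAZy family (cycled from a
    small list); housekeeping genes alternate between the two control
    families (chitin synthase, NADH dehydrogenase) under the
    ``housekeeping`` namespace.  Background genes carry no annotation.
    """
    rows = []
    for m, mid in enumerate(truth.module_ids):
        fam = MODULE_FAMILIES[m % len(MODULE_FAMILIES)]
        for g in truth.members(mid):
            rows.append((g, "CAZy", fam))
    for i, g in enumerate(truth.members("housekeeping")):
        rows.append((g, "housekeeping", HOUSEKEEPING_FAMILIES[i % 2]))
    return AnnotationTable(pd.DataFrame(rows, columns=["gene_id", "namespace", "label"]))


def truth_table(truth: SyntheticTruth) -> pd.DataFrame:
    """Flat gene table (label, shape) for writing truth.tsv."""
    shapes = truth.gene_labels.map(lambda l: truth.module_shapes.get(l, "flat"))
    return pd.DataFrame({"label": truth.gene_labels, "profile_shape": shapes})
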