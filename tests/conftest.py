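"""Shared fixtures: a full default pipeline run (expensive, session-scoped)
and small hand-built toy objects."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

import somcoex as sx


@dataclass
class PipelineRun:
    """Products of one full run on the default synthetic dataset."""

    config: sx.SimConfig
    truth: sx.SyntheticTruth
    counts: sx.CountMatrix
    metadata: sx.SampleMetadata
    annotations: sx.AnnotationTable
    kept: list
    filtered: sx.CountMatrix
    size_factors: pd.Series
    norm: sx.ExpressionMatrix
    cpm: sx.ExpressionMatrix
    grid: sx.SOMGrid
    assignment: sx.NodeAssignment
    profiles: sx.NodeProfile
    calls: dict
    qe_initial: float
    qe_final: float

    def modal_node(self, module_id: str) -> int:
        members = [
            g for g in self.truth.members(module_id) if g in self.assignment.gene_to_node.index
        ]
        nodes = self.assignment.gene_to_node.loc[members].to_numpy()
        vals, cnt = np.unique(nodes, return_counts=True)
        return int(vals[np.argmax(cnt)])


@pytest.fixture(scope="session")
def pipeline() -> PipelineRun:
    """Default synthetic study: 5,000 genes, 4 planted modules of 50, 27
    housekeeping genes, 2 substrates x 5 growth points x 2 replicates,
    24x20 SOM trained for 480,000 steps.  Fixed seed throughout."""
    cfg = sx.SimConfig(seed=1)
    truth = sx.generate_truth(cfg)
    counts, metadata = sx.simulate_counts(truth, cfg)
    annotations = sx.make_annotations(truth)
    kept = sx.filter_min_mean_reads(counts, metadata)
    filtered = counts.subset_genes(kept)
    factors = sx.size_factors_median_ratio(filtered)
    norm = sx.normalized_log2(filtered, factors)
    cpm_mat = sx.cpm(counts)
    grid = sx.init_grid(24, 20, norm.values, seed=1)
    qe0 = sx.quantization_error(grid, norm.values)
    sx.train(grid, norm.values, seed=1)
    qe1 = sx.quantization_error(grid, norm.values)
    assignment = sx.assign(grid, norm.values)
    profiles = sx.node_condition_means(assignment, norm, metadata)
    calls = sx.call_condition_specific_nodes(profiles, sx.NodeCallConfig(), norm=norm)
    return PipelineRun(
        cfg, truth, counts, metadata, annotations, kept, filtered, factors,
        norm, cpm_mat, grid, assignment, profiles, calls, qe0, qe1,
    )


@pytest.fixture
def toy_counts() -> sx.CountMatrix:
    """3 genes x 4 samples with simple integer counts."""
    return sx.CountMatrix(
        pd.DataFrame(
            [[10, 20, 30, 40], [5, 10, 15, 20], [100, 200, 300, 400]],
            index=["gA", "gB", "gC"],
            columns=["s1", "s2", "s3", "s4"],
        )
    )


@pytest.fixture
def toy_metadata() -> sx.SampleMetadata:
    """One substrate, two growth points, duplicate samples."""
    return sx.SampleMetadata(
        pd.DataFrame(
            {
                "substrate": ["AH"] * 4,
                "growth_point": [1, 1, 2, 2],
                "replicate": [1, 2, 1, 2],
            },
            index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
        )
    )
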