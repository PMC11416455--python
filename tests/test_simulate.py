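"""The synthetic-data generator: design arithmetic, distributional shape,
ground-truth consistency and companion resources."""

import numpy as np
import pandas as pd
import pytest

from evmirna.containers import condition_label
from evmirna.errors import SpecificationError
from evmirna.simulate import (
    DesignSpec,
    EffectSpec,
    gene_universe,
    simulate_annotation,
    simulate_counts,
    simulate_pathways,
    simulate_target_map,
)


class TestSimulateCounts:
    def test_default_design_yields_42_samples(self):
        cm, _ = simulate_counts(DesignSpec(n_mirnas=20), EffectSpec(
            n_increasing=0, n_decreasing=0, n_genotype_cluster=0, n_ubiquitous=0), 0)
        # 14 condition cells (1 iPSC + 2 regions x 3 timepoints, x 2 genotypes) x 3
        assert cm.counts.shape[1] == 42
        cells = cm.samples.groupby(["genotype", "region", "timepoint"]).size()
        assert len(cells) == 14
        assert (cells == 3).all()

    def test_same_seed_is_bit_identical(self):
        a, _ = simulate_counts(DesignSpec(n_mirnas=50), EffectSpec(n_genotype_cluster=10,
                               n_increasing=5, n_decreasing=5, n_ubiquitous=3), 7)
        b, _ = simulate_counts(DesignSpec(n_mirnas=50), EffectSpec(n_genotype_cluster=10,
                               n_increasing=5, n_decreasing=5, n_ubiquitous=3), 7)
        assert a.counts.equals(b.counts)
        assert a.samples.equals(b.samples)

    def test_degenerate_poisson_case(self):
        # dispersion 0, no library variation, no effects: iid Poisson columns
        design = DesignSpec(n_mirnas=200, nb_dispersion=0.0, library_size_cv=0.0,
                            mean_library_size=2e5)
        effects = EffectSpec(n_increasing=0, n_decreasing=0, n_genotype_cluster=0,
                             n_ubiquitous=0, composition_bias_fraction=0.0)
        cm, truth = simulate_counts(design, effects, 3)
        y = cm.counts.to_numpy(float)
        m, v = y.mean(axis=1), y.var(axis=1, ddof=1)
        big = m > 50
        # index of dispersion ~ 1 for Poisson
        assert np.median(v[big] / m[big]) == pytest.approx(1.0, abs=0.15)

    def test_overdispersion_exceeds_poisson(self):
        design = DesignSpec(n_mirnas=200, nb_dispersion=0.3, library_size_cv=0.0)
        effects = EffectSpec(n_increasing=0, n_decreasing=0, n_genotype_cluster=0,
                             n_ubiquitous=0, composition_bias_fraction=0.0)
        cm, _ = simulate_counts(design, effects, 3)
        y = cm.counts.to_numpy(float)
        m, v = y.mean(axis=1), y.var(axis=1, ddof=1)
        big = m > 100
        assert np.median(v[big] / m[big]) > 2.0

    def test_mean_converges_to_library_times_abundance(self):
        # empirical condition mean ~ library_size x relative abundance
        design = DesignSpec(n_mirnas=40, replicates_per_condition=1000,
                            library_size_cv=0.0, nb_dispersion=0.1,
                            mean_library_size=5e5)
        effects = EffectSpec(n_increasing=3, n_decreasing=3, n_genotype_cluster=5,
                             n_ubiquitous=2, composition_bias_fraction=0.0)
        cm, truth = simulate_counts(design, effects, 11)
        cond = cm.condition_of()
        emp = cm.counts.T.groupby(cond).mean().T
        expected = 2.0 ** truth.true_log2_mean * design.mean_library_size
        abundant = (expected > 50).all(axis=1)
        rel = (emp[expected.columns][abundant] / expected[abundant] - 1).abs()
        assert float(rel.to_numpy().max()) < 0.05

    def test_planted_classes_are_monotone_in_truth(self, small_sim):
        _, truth = small_sim
        tl = truth.true_log2_mean
        for cls, sign in (("increasing", 1), ("decreasing", -1)):
            for mid in truth.of_class(cls):
                for g in ("IC", "RTT"):
                    for region in ("dorsal", "ventral"):
                        seq = [tl.loc[mid, condition_label(g, "iPSC", "D0")]] + [
                            tl.loc[mid, condition_label(g, region, t)]
                            for t in ("D13", "D40", "D75")
                        ]
                        d = np.diff(seq) * sign
                        assert (d > 0).all()

    def test_ubiquitous_true_log2cpm_is_pinned(self, small_sim):
        _, truth = small_sim
        for mid in truth.of_class("ubiquitous"):
            cpm = truth.true_log2_mean.loc[mid] + np.log2(1e6)
            assert np.allclose(cpm, EffectSpec().ubiquitous_log2_cpm, atol=1e-9)

    def test_invalid_class_counts_rejected(self):
        with pytest.raises(SpecificationError):
            simulate_counts(DesignSpec(n_mirnas=10),
                            EffectSpec(n_increasing=8, n_decreasing=8), 0)

    def test_zero_replicates_rejected(self):
        with pytest.raises(SpecificationError):
            DesignSpec(replicates_per_condition=0)


class TestAnnotation:
    def test_no_elevated_class_no_cluster(self):
        _, truth = simulate_counts(
            DesignSpec(n_mirnas=20),
            EffectSpec(n_increasing=0, n_decreasing=0, n_genotype_cluster=0,
                       n_ubiquitous=0), 0)
        ann = simulate_annotation(truth, seed=1)
        assert ann.table["cluster_id"].isna().all()

    def test_cluster_intervals_disjoint_and_ordered(self):
        _, truth = simulate_counts(
            DesignSpec(n_mirnas=30),
            EffectSpec(n_increasing=0, n_decreasing=0, n_genotype_cluster=15,
                       n_ubiquitous=0), 0)
        ann = simulate_annotation(truth, cluster_locus=("chr14", 100_000, 115_000),
                                  seed=1)
        members = ann.cluster_members(ann.table["cluster_id"].dropna().iloc[0])
        assert len(members) == 15
        starts, ends = members["start"].to_numpy(), members["end"].to_numpy()
        assert (ends <= 115_000).all() and (starts >= 100_000).all()
        assert (starts[1:] >= ends[:-1]).all()  # non-overlapping
        # genomic order equals miRNA index order within the cluster
        assert list(members.index) == truth.of_class("genotype_elevated")

    def test_locus_too_small_errors(self):
        _, truth = simulate_counts(
            DesignSpec(n_mirnas=30),
            EffectSpec(n_increasing=0, n_decreasing=0, n_genotype_cluster=15,
                       n_ubiquitous=0), 0)
        with pytest.raises(SpecificationError):
            simulate_annotation(truth, cluster_locus=("chr14", 100, 110), seed=1)


@pytest.fixture(scope="module")
def truth():
    _, t = simulate_counts(
        DesignSpec(n_mirnas=40),
        EffectSpec(n_increasing=5, n_decreasing=5, n_genotype_cluster=10,
                   n_ubiquitous=3), 2)
    return t


class TestTargetsAndPathways:

    def test_constant_zero_targets(self, truth):
        tm = simulate_target_map(truth, targets_per_mirna=0, distribution="constant",
                                 seed=0)
        assert all(len(s) == 0 for s in tm.targets.values())

    def test_full_enrichment_is_subset_of_block(self, truth):
        tm = simulate_target_map(truth, enriched_pathway_fraction=1.0, seed=0,
                                 enriched_block_size=100)
        block = set(gene_universe(2000)[:100])
        union = set()
        for m in truth.of_class("genotype_elevated"):
            union |= tm.targets[m]
        assert union <= block

    def test_target_map_reproducible(self, truth):
        a = simulate_target_map(truth, seed=9)
        b = simulate_target_map(truth, seed=9)
        assert a.targets == b.targets

    def test_single_pathway_equals_universe(self):
        pc = simulate_pathways(n_pathways=1, genes_per_pathway=50, n_genes=50, seed=0)
        assert len(pc) == 1
        assert next(iter(pc.pathways.values())) == frozenset(gene_universe(50))

    def test_pathways_reproducible(self):
        a = simulate_pathways(seed=4)
        b = simulate_pathways(seed=4)
        assert a.pathways == b.pathways
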