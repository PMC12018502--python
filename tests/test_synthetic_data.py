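import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dfcdtx import synthetic_data as sim
from dfcdtx.dfcd import FCDParams, dfcd_variability


def affected_subject_means(config, params=FCDParams(normalize=False)):
    subjects, atlas, table = sim.generate_cohort(config)
    aff = np.isin(atlas.labels, config.affected)
    means = {"patient": [], "control": []}
    for subject, row in zip(subjects, table.table.itertuples()):
        dmap = dfcd_variability(subject, atlas, params)
        means[row.group].append(dmap.to_volume()[aff & dmap.mask].mean())
    return means


def affected_group_means(config, params=FCDParams(normalize=False)):
    means = affected_subject_means(config, params)
    return {g: float(np.mean(v)) for g, v in means.items()}


class TestCohort:
    def test_seeded_determinism(self):
        cfg = sim.SimConfig(n_per_group=2, T=60, seed=7)
        a = sim.generate_cohort(cfg)
        b = sim.generate_cohort(cfg)
        for s1, s2 in zip(a[0], b[0]):
            np.testing.assert_array_equal(s1.data, s2.data)
        pd.testing.assert_frame_equal(a[2].table, b[2].table)

    def test_different_seeds_differ(self):
        a = sim.generate_cohort(sim.SimConfig(n_per_group=1, T=60, seed=1))
        b = sim.generate_cohort(sim.SimConfig(n_per_group=1, T=60, seed=2))
        assert not np.array_equal(a[0][0].data, b[0][0].data)

    def test_atlas_tiles_grid(self):
        cfg = sim.SimConfig()
        atlas = sim.make_atlas(cfg)
        assert len(atlas.region_ids) == cfg.n_regions
        # equal-size rectangular parcels
        counts = np.bincount(atlas.labels.ravel())[1:]
        assert len(set(counts)) == 1

    def test_impossible_tiling_errors(self):
        with pytest.raises(ValueError, match="tile"):
            sim.make_atlas(sim.SimConfig(grid_shape=(7, 5, 3), n_regions=11))

    def test_groups_balanced(self):
        cfg = sim.SimConfig(n_per_group=6, T=60, seed=0)
        _, _, table = sim.generate_cohort(cfg)
        counts = table.table.groupby("group")["sex"].value_counts()
        assert counts.min() == counts.max()

    def test_effect_direction_lower_patient_variability(self):
        """Patients' affected parcels must show lower dFCD variability."""
        cfg = sim.SimConfig(n_per_group=6, T=230, seed=3)
        means = affected_group_means(cfg)
        assert means["patient"] < means["control"]

    def test_null_config_symmetric(self):
        cfg = sim.SimConfig(n_per_group=6, T=150, seed=5,
                            switch_rate_patient=0.08)
        means = affected_subject_means(cfg)
        # same switching process in both groups: difference is pure noise
        p = stats.ttest_ind(means["patient"], means["control"]).pvalue
        assert p > 0.05

    def test_monotone_in_switch_rate_gap(self):
        """A wider control-patient switch-rate gap widens the group gap."""
        diffs = []
        for rate in (0.08, 0.04, 0.01):
            cfg = sim.SimConfig(n_per_group=6, T=230, seed=11,
                                switch_rate_patient=rate)
            means = affected_group_means(cfg)
            diffs.append(means["control"] - means["patient"])
        rho = stats.spearmanr(diffs, [0.0, 0.04, 0.07]).statistic
        assert rho == 1.0


@pytest.fixture(scope="module")
def atlas():
    return sim.make_atlas(sim.SimConfig())


class TestExpression:

    def test_planted_correlations(self, atlas, rng):
        diff = rng.standard_normal(24)
        cfg = sim.ExpressionSimConfig(n_genes=50, n_linked_pos=3,
                                      n_linked_neg=2, link_strength=0.99,
                                      seed=4)
        result = sim.generate_expression(atlas, diff, cfg)
        for g in result.planted_pos:
            assert np.corrcoef(result.matrix[g], diff)[0, 1] > 0.9
        for g in result.planted_neg:
            assert np.corrcoef(result.matrix[g], diff)[0, 1] < -0.9

    def test_null_genes_within_permutation_envelope(self, atlas, rng):
        diff = rng.standard_normal(24)
        cfg = sim.ExpressionSimConfig(n_genes=200, n_linked_pos=0,
                                      n_linked_neg=0, link_strength=0.5,
                                      seed=6)
        result = sim.generate_expression(atlas, diff, cfg)
        def max_abs_corr(target):
            return max(abs(np.corrcoef(result.matrix[g], target)[0, 1])
                       for g in result.matrix.columns)

        observed = max_abs_corr(diff)
        # permutation oracle for the max-|r| null envelope
        perm_rng = np.random.default_rng(0)
        envelope = [max_abs_corr(perm_rng.permutation(diff))
                    for _ in range(100)]
        assert observed <= np.max(envelope)

    def test_seeded_determinism(self, atlas, rng):
        diff = rng.standard_normal(24)
        cfg = sim.ExpressionSimConfig(n_genes=30, seed=9, n_linked_pos=2,
                                      n_linked_neg=2)
        a = sim.generate_expression(atlas, diff, cfg)
        b = sim.generate_expression(atlas, diff, cfg)
        pd.testing.assert_frame_equal(a.matrix, b.matrix)

    def test_too_few_regions_error(self):
        labels = np.zeros((2, 1, 1), dtype=np.int32)
        labels[0] = 1
        labels[1] = 2
        from dfcdtx.imaging_io import AtlasParcellation
        atlas2 = AtlasParcellation(labels=labels, affine=np.eye(4))
        with pytest.raises(ValueError, match="3 regions"):
            sim.generate_expression(atlas2, np.array([1.0, 2.0]),
                                    sim.ExpressionSimConfig(n_genes=5,
                                                            n_linked_pos=1,
                                                            n_linked_neg=0))

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            sim.ExpressionSimConfig(n_genes=3, n_linked_pos=2, n_linked_neg=2)
        with pytest.raises(ValueError):
            sim.ExpressionSimConfig(link_strength=1.0)


class TestGeneSetsAndPPI:
    def test_gene_sets_deterministic_and_sized(self):
        genes = [f"G{i}" for i in range(100)]
        a = sim.generate_gene_sets(genes, 5, genes[:10], seed=1, set_size=8)
        b = sim.generate_gene_sets(genes, 5, genes[:10], seed=1, set_size=8)
        assert a == b
        assert len(a) == 5
        assert all(len(v) == 8 for v in a.values())
        overlap = len(set(a["SET_PLANTED"]) & set(genes[:10]))
        assert overlap >= 6

    def test_set_size_exceeding_universe_errors(self):
        with pytest.raises(ValueError, match="universe"):
            sim.generate_gene_sets(["A", "B"], 2, ["A"], seed=0, set_size=5)

    def test_ppi_edges_no_self_loops_and_deterministic(self):
        genes = [f"G{i}" for i in range(50)]
        a = sim.generate_ppi_edges(genes, genes[:3], seed=2)
        b = sim.generate_ppi_edges(genes, genes[:3], seed=2)
        pd.testing.assert_frame_equal(a, b)
        assert (a["gene_a"] != a["gene_b"]).all()
        assert a["confidence"].between(0, 1).all()

    def test_ppi_hubs_have_high_confidence_degree(self):
        genes = [f"G{i}" for i in range(60)]
        edges = sim.generate_ppi_edges(genes, ["G0", "G1"], hub_degree=12,
                                       seed=3)
        strong = edges[edges["confidence"] > 0.9]
        degree = pd.concat([strong["gene_a"], strong["gene_b"]]).value_counts()
        assert degree["G0"] >= 12 and degree["G1"] >= 12
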