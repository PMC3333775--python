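import numpy as np
import pytest
from scipy import stats

from omicsets.exceptions import InputError
from omicsets.simulation import (
    BackboneConfig,
    CollectionSpec,
    SpikeInConfig,
    band_collection,
    calibrate_delta,
    generate_backbone,
    permute_labels_backbone,
    run_scenario,
    spike_in,
    synthetic_collection,
)


class TestBackbone:
    def test_seed_reproducible(self):
        cfg = BackboneConfig(n_genes=50, seed=42)
        a = generate_backbone(cfg)
        b = generate_backbone(cfg)
        for ma, mb in zip(a.matrices, b.matrices):
            np.testing.assert_array_equal(ma.values.to_numpy(), mb.values.to_numpy())
        assert (a.phenotype.labels == b.phenotype.labels).all()

    def test_class_split(self):
        study = generate_backbone(BackboneConfig(n_genes=20, seed=1))
        labels = study.phenotype.labels
        assert int(labels.sum()) == 49 and len(labels) == 99

    def test_independent_platforms_nearly_uncorrelated(self):
        study = generate_backbone(BackboneConfig(n_genes=200, seed=2))
        e1 = study.matrix("E1").values.to_numpy()
        e2 = study.matrix("E2").values.to_numpy()
        same_gene_r = [np.corrcoef(e1[g], e2[g])[0, 1] for g in range(50)]
        assert abs(np.mean(same_gene_r)) < 0.05
        inter_gene_r = [np.corrcoef(e1[g], e1[g + 1])[0, 1] for g in range(50)]
        assert abs(np.mean(inter_gene_r)) < 0.05

    def test_pair_correlation_close_to_rho(self):
        study = generate_backbone(BackboneConfig(n_genes=400, rho_pair=0.6, seed=3))
        e1 = study.matrix("E1").values.to_numpy()
        e2 = study.matrix("E2").values.to_numpy()
        r = np.mean([np.corrcoef(e1[g], e2[g])[0, 1] for g in range(400)])
        assert r == pytest.approx(0.6, abs=0.05)

    def test_cn_autocorrelation_decays_with_distance(self):
        study = generate_backbone(
            BackboneConfig(n_genes=600, cn_autocorr_length=50, seed=4)
        )
        c1 = study.matrix("C1").values.to_numpy()
        adjacent = np.mean([np.corrcoef(c1[g], c1[g + 1])[0, 1] for g in range(300)])
        distant = np.mean([np.corrcoef(c1[g], c1[g + 300])[0, 1] for g in range(300)])
        assert adjacent > 0.8  # exp(-1/50) = 0.98 population value
        assert adjacent > distant + 0.5
        # expression platforms stay independent along the genome
        e1 = study.matrix("E1").values.to_numpy()
        adj_e = np.mean([np.corrcoef(e1[g], e1[g + 1])[0, 1] for g in range(300)])
        assert abs(adj_e) < 0.1

    def test_permute_labels_keeps_matrices_and_counts(self):
        study = generate_backbone(BackboneConfig(n_genes=30, seed=5))
        permuted = permute_labels_backbone(study, seed=8)
        for a, b in zip(study.matrices, permuted.matrices):
            np.testing.assert_array_equal(a.values.to_numpy(), b.values.to_numpy())
        assert permuted.phenotype.labels.sum() == study.phenotype.labels.sum()


class TestCollections:
    def test_synthetic_sets_disjoint_sized_in_bounds(self):
        universe = [f"g{i}" for i in range(4000)]
        coll = synthetic_collection(universe, n_sets=50, seed=6)
        seen = set()
        for sid in coll.set_ids:
            genes = set(coll.genes(sid))
            assert 10 <= len(genes) <= 100
            assert seen.isdisjoint(genes)
            seen |= genes

    def test_oversized_request_rejected(self):
        with pytest.raises(InputError):
            synthetic_collection([f"g{i}" for i in range(30)], n_sets=10,
                                 size_sampler=lambda rng: 10, seed=0)

    def test_gene_assignment_uniform(self):
        # chi-square goodness of fit on per-gene inclusion counts
        universe = [f"g{i}" for i in range(40)]
        counts = np.zeros(40)
        for rep in range(500):
            coll = synthetic_collection(universe, n_sets=2,
                                        size_sampler=lambda rng: 5, seed=rep)
            for sid in coll.set_ids:
                for g in coll.genes(sid):
                    counts[int(g[1:])] += 1
        expected = counts.sum() / 40
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert stats.chi2.sf(chi2, df=39) > 0.01

    def test_band_collection_partitions_in_order(self):
        universe = [f"g{i:03d}" for i in range(95)]
        coll = band_collection(universe, band_size=10)
        flattened = [g for sid in coll.set_ids for g in coll.genes(sid)]
        assert flattened == universe  # exact partition, adjacency preserved
        assert len(coll.genes(coll.set_ids[-1])) == 5


class TestCalibrateDelta:
    def test_normal_approximation_anchor(self):
        # sd=1, 49/50, beta=0.5: Delta ~ z_{0.975} * sqrt(1/49 + 1/50)
        delta = calibrate_delta(1.0, 49, 50, beta=0.5, alpha=0.05)
        anchor = stats.norm.ppf(0.975) * np.sqrt(1 / 49 + 1 / 50)
        assert delta == pytest.approx(anchor, abs=0.01)

    def test_achieved_power_matches_independent_oracle(self):
        sm_power = pytest.importorskip("statsmodels.stats.power")
        for beta in (0.166, 0.5, 0.84):
            delta = calibrate_delta(1.3, 49, 50, beta=beta)
            achieved = sm_power.TTestIndPower().power(
                effect_size=delta / 1.3, nobs1=49, ratio=50 / 49, alpha=0.05
            )
            assert achieved == pytest.approx(beta, abs=1e-6)

    def test_monotone_in_beta_and_proportional_to_sd(self):
        deltas = [calibrate_delta(1.0, 49, 50, b) for b in (0.1, 0.3, 0.6, 0.9)]
        assert all(a < b for a, b in zip(deltas, deltas[1:]))
        assert calibrate_delta(2.0, 49, 50, 0.5) == pytest.approx(
            2 * calibrate_delta(1.0, 49, 50, 0.5), rel=1e-6
        )

    def test_vanishes_as_beta_approaches_alpha(self):
        assert calibrate_delta(1.0, 49, 50, beta=0.0501, alpha=0.05) < 0.02

    def test_beta_at_or_below_alpha_rejected(self):
        with pytest.raises(InputError):
            calibrate_delta(1.0, 49, 50, beta=0.05, alpha=0.05)


class TestSpikeIn:
    @staticmethod
    def small_study(seed=9, n_genes=200):
        return generate_backbone(BackboneConfig(n_genes=n_genes, seed=seed))

    @staticmethod
    def collection(study, n_sets=10, size=12, seed=0):
        return synthetic_collection(
            sorted(study.availability), n_sets=n_sets,
            size_sampler=lambda rng: size, seed=seed,
        )

    def test_gamma_zero_leaves_study_bit_identical(self):
        study = self.small_study()
        coll = self.collection(study)
        spiked, truth = spike_in(study, coll, SpikeInConfig(gamma=0.0), seed=1)
        for a, b in zip(study.matrices, spiked.matrices):
            np.testing.assert_array_equal(a.values.to_numpy(), b.values.to_numpy())
        assert len(truth.spiked_set_ids) == 10
        assert truth.altered_union() == frozenset()

    def test_gamma_one_shifts_every_set_gene_by_delta(self):
        study = self.small_study()
        coll = self.collection(study, n_sets=4)
        cfg = SpikeInConfig(n_spiked_sets=2, gamma=1.0, beta=0.84)
        spiked, truth = spike_in(study, coll, cfg, seed=2)
        class1 = (study.phenotype.labels == 1).to_numpy()
        for sid in truth.spiked_set_ids:
            for m_old, m_new in zip(study.matrices, spiked.matrices):
                genes = truth.altered[m_new.platform_id][sid]
                assert sorted(genes) == sorted(coll.genes(sid))
                old = m_old.values.loc[genes].to_numpy()
                new = m_new.values.loc[genes].to_numpy()
                np.testing.assert_allclose(
                    new[:, class1] - old[:, class1], truth.delta[sid]
                )
                np.testing.assert_array_equal(new[:, ~class1], old[:, ~class1])

    def test_only_class1_entries_of_altered_genes_change(self):
        study = self.small_study()
        coll = self.collection(study)
        spiked, truth = spike_in(study, coll, SpikeInConfig(gamma=0.4), seed=3)
        class1 = (study.phenotype.labels == 1).to_numpy()
        for m_old, m_new in zip(study.matrices, spiked.matrices):
            altered = sorted(
                {g for genes in truth.altered[m_new.platform_id].values() for g in genes}
            )
            untouched = [g for g in m_old.gene_ids if g not in set(altered)]
            np.testing.assert_array_equal(
                m_old.values.loc[untouched].to_numpy(),
                m_new.values.loc[untouched].to_numpy(),
            )
            np.testing.assert_array_equal(
                m_old.values.loc[altered].to_numpy()[:, ~class1],
                m_new.values.loc[altered].to_numpy()[:, ~class1],
            )

    def test_binomial_counts_and_platform_independence(self):
        study = self.small_study(n_genes=120)
        coll = self.collection(study, n_sets=2, size=50)
        cfg = SpikeInConfig(n_spiked_sets=1, gamma=0.1)
        counts = {"E1": [], "E2": []}
        joint = []
        for rep in range(400):
            _, truth = spike_in(study, coll, cfg, seed=rep)
            sid = truth.spiked_set_ids[0]
            a = set(truth.altered["E1"][sid])
            b = set(truth.altered["E2"][sid])
            counts["E1"].append(len(a))
            counts["E2"].append(len(b))
            joint.append(len(a & b))
        assert np.mean(counts["E1"]) == pytest.approx(5.0, abs=0.6)
        assert np.mean(counts["E2"]) == pytest.approx(5.0, abs=0.6)
        # independent selection: E[|A ∩ B|] = n * gamma^2 = 0.5
        assert np.mean(joint) == pytest.approx(0.5, abs=0.3)


class TestRunScenario:
    CFG = dict(
        backbone=BackboneConfig(n_genes=400),
        collection_spec=CollectionSpec(n_sets=12, size_min=5, size_max=15),
    )

    def test_fixed_seed_reproducible(self):
        kw = dict(beta=0.5, gamma=0.5, n_reps=2, seed=77, methods=["INT", "E1"])
        a = run_scenario(self.CFG["backbone"], self.CFG["collection_spec"], **kw)
        b = run_scenario(self.CFG["backbone"], self.CFG["collection_spec"], **kw)
        for ra, rb in zip(a.reps, b.reps):
            for m in ra.tables:
                np.testing.assert_array_equal(
                    ra.tables[m]["p"].to_numpy(), rb.tables[m]["p"].to_numpy()
                )
            assert ra.truth.spiked_set_ids == rb.truth.spiked_set_ids

    def test_unaltered_spike_gives_chance_level_auc(self):
        from omicsets.evaluation import evaluate_scenario

        res = run_scenario(
            self.CFG["backbone"], self.CFG["collection_spec"],
            beta=0.5, gamma=0.0, n_reps=12, seed=13, methods=["INT"],
        )
        auc = evaluate_scenario(res).auc.loc["INT", "mean"]
        assert auc == pytest.approx(0.5, abs=0.15)

    def test_selfcontained_pipeline_runs(self):
        res = run_scenario(
            self.CFG["backbone"], self.CFG["collection_spec"],
            beta=0.84, gamma=1.0, n_reps=1, seed=5, methods=["INT"],
            test="selfcontained", permutations=10,
        )
        table = res.reps[0].tables["INT"]
        assert ((table["p"] >= 0) & (table["p"] <= 1)).all()
        assert res.n_failed == 0
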