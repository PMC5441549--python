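import dataclasses
import filecmp
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methconcord import DesignSpec, SimulationConfig, differential_test
from methconcord.enrichment import build_seed_network, ppi_enrichment_ztest
from methconcord.preprocess import beta_matrix_to_m, replicate_correlation
from methconcord.synthetic_data import (simulate_expression_study,
                                        simulate_gene_sets, simulate_interactome,
                                        simulate_methylation_study,
                                        write_fixture_dir)


def _null_config(**kwargs):
    fractions = {"iPS": 0.0, "ONS": 0.0, "fibroblast": 0.0}
    return SimulationConfig(n_probes=800, disease_effect_fractions=fractions,
                            shared_core_size=0, interactome_genes=300, **kwargs)


class TestMethylationStudy:
    def test_same_seed_byte_identical(self, small_config):
        b1, s1, t1 = simulate_methylation_study(small_config)
        b2, s2, t2 = simulate_methylation_study(small_config)
        assert b1.to_numpy().tobytes() == b2.to_numpy().tobytes()
        pd.testing.assert_frame_equal(s1.frame, s2.frame)
        assert t1.disease_probes == t2.disease_probes

    def test_shape_and_core_bookkeeping(self, small_config, small_study):
        beta, sheet, truth = small_study
        cfg = small_config
        units = (cfg.n_patients + cfg.n_controls) * (cfg.ips_clones + 2) + cfg.include_es
        assert beta.shape == (cfg.n_probes, units * cfg.technical_replicates)
        assert len(truth.shared_core) == cfg.shared_core_size
        directions = set()
        for ct in cfg.cell_types:
            planted = round(cfg.disease_effect_fractions[ct] * cfg.n_probes)
            assert len(truth.disease_probes[ct]) == planted
            for probe, d in truth.shared_core.items():
                assert truth.disease_probes[ct][probe] == d
            directions |= set(truth.disease_probes[ct].values())
        assert directions == {"hypo", "hyper"}
        assert sum(d == "hypo" for d in truth.shared_core.values()) == 4

    def test_beta_in_unit_interval(self, small_study):
        beta, _, _ = small_study
        values = beta.to_numpy()
        assert values.min() > 0 and values.max() < 1

    def test_null_noiseless_config_is_degenerate(self):
        config = _null_config(biological_sd_m=0.0, technical_sd_m=0.0, seed=1,
                              include_es=False)
        beta, sheet, _ = simulate_methylation_study(config)
        m = beta_matrix_to_m(beta)
        table, summary = replicate_correlation(m, sheet)
        np.testing.assert_allclose(table["r2"], 1.0)
        ids = sheet.frame.loc[sheet.frame["cell_type"] == "iPS", "sample_id"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = differential_test(m[list(ids)], sheet.subset(ids),
                                    DesignSpec(("patient", "control")))
        assert (res["q"] < 0.05).sum() == 0

    def test_planted_outlier_shifts_one_sample(self):
        config = _null_config(seed=2, planted_outlier=True)
        beta_out, sheet, _ = simulate_methylation_study(config)
        beta_ref, _, _ = simulate_methylation_study(dataclasses.replace(config, planted_outlier=False))
        diff = (beta_out != beta_ref).any(axis=0)
        assert diff.sum() == 1

    def test_inconsistent_config_errors(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_probes=100, shared_core_size=50)
        with pytest.raises(ValueError):
            SimulationConfig(disease_effect_fractions={"iPS": 0.1})

    def test_detection_power_matches_analytic_oracle(self):
        """Sensitivity for planted effects over replicate studies is within
        Monte-Carlo error of closed-form two-sample t power at the induced
        M-scale effect size."""
        n_reps, hits, total = 10, 0, 0
        deltas = []
        for rep in range(n_reps):
            config = SimulationConfig(
                n_probes=400, include_es=False, ips_clones=1,
                disease_effect_fractions={"iPS": 0.0, "ONS": 0.1, "fibroblast": 0.0},
                shared_core_size=0, interactome_genes=300, seed=100 + rep)
            beta, sheet, truth = simulate_methylation_study(config)
            ids = sheet.frame.loc[sheet.frame["cell_type"] == "ONS", "sample_id"]
            m = beta_matrix_to_m(beta[list(ids)])
            res = differential_test(m, sheet.subset(ids), DesignSpec(("patient", "control")),
                                    moderate=False)
            planted = set(truth.disease_probes["ONS"])
            calls = set(res.index[res["q"] < 0.05])
            hits += len(planted & calls)
            total += len(planted)
            for probe in planted:
                i = res.index.get_loc(probe)
                deltas.append(abs(res["effect"].iloc[i]))
        sensitivity = hits / total
        # analytic per-probe power at the median induced M-scale effect
        delta = float(np.median(deltas))
        n1 = n2 = 4
        sd = np.sqrt(SimulationConfig().biological_sd_m ** 2
                     + SimulationConfig().technical_sd_m ** 2 / 3)
        ncp = delta / (sd * np.sqrt(1 / n1 + 1 / n2))
        df = n1 + n2 - 2
        tcrit = stats.t.ppf(1 - 0.025, df)  # plain alpha: BH at q<0.05 sits near it with many true effects
        power = 1 - stats.nct.cdf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp)
        assert sensitivity == pytest.approx(power, abs=0.15)


class TestExpressionStudy:
    def test_full_coupling_full_concordance(self, small_config):
        config = dataclasses.replace(small_config, coupling_fraction=1.0,
                                     concordance_prob=1.0, de_background_fraction=0.0)
        _, _, truth = simulate_methylation_study(config)
        _, _, truth = simulate_expression_study(config, truth)
        for ct in config.cell_types:
            dm = truth.disease_genes(ct)
            de = truth.de_genes[ct]
            assert set(de) == set(dm)
            for g, d in de.items():
                assert (dm[g] == "hypo") == (d == "up")

    def test_zero_coupling_independent(self, small_config):
        config = dataclasses.replace(small_config, coupling_fraction=0.0,
                                     de_background_fraction=0.0)
        _, _, truth = simulate_methylation_study(config)
        _, _, truth = simulate_expression_study(config, truth)
        assert all(len(v) == 0 for v in truth.de_genes.values())

    def test_concordance_fraction_within_binomial_ci(self):
        config = SimulationConfig(n_probes=5000, concordance_prob=0.8,
                                  coupling_fraction=1.0, de_background_fraction=0.0,
                                  interactome_genes=500, seed=21)
        _, _, truth = simulate_methylation_study(config)
        _, _, truth = simulate_expression_study(config, truth)
        dm = truth.disease_genes("ONS")
        de = truth.de_genes["ONS"]
        coupled = [g for g in de if g in dm]
        assert len(coupled) >= 200
        concordant = sum((dm[g] == "hypo") == (de[g] == "up") for g in coupled)
        frac = concordant / len(coupled)
        half_width = 2.576 * np.sqrt(0.8 * 0.2 / len(coupled))
        assert abs(frac - 0.8) < half_width

    def test_raw_matrix_nonnegative(self, small_full_fixture):
        assert (small_full_fixture["expr"].to_numpy() > 0).all()


class TestInteractome:
    def test_tree_when_m_is_one(self, small_config):
        config = dataclasses.replace(small_config, attachment_m=1)
        _, _, truth = simulate_methylation_study(config)
        graph, _ = simulate_interactome(config, truth)
        assert graph.number_of_edges() == graph.number_of_nodes() - 1

    def test_null_seed_enrichment_mean_z_near_zero(self):
        """With unbiased seeds the enrichment Z over replicate studies is
        centered on zero (|mean| < 3 SE)."""
        zs = []
        for rep in range(50):
            config = SimulationConfig(n_probes=800, interactome_genes=300,
                                      seed_enrichment=0.0, include_es=False,
                                      seed=300 + rep)
            _, _, truth = simulate_methylation_study(config)
            graph, seeds = simulate_interactome(config, truth)
            seed_net = build_seed_network(seeds, graph)
            query = sorted(truth.all_disease_genes())
            universe = len(set(truth.gene_of_probe.values()))
            res = ppi_enrichment_ztest(query, seed_net, universe, n_binding="query")
            zs.append(res.Z)
        mean, se = np.mean(zs), np.std(zs, ddof=1) / np.sqrt(len(zs))
        assert abs(mean) < 3 * se

    def test_enriched_seeds_power(self):
        """Strongly disease-weighted seeds drive Z past the 1.65 critical
        value in at least 90% of replicate studies."""
        hits = 0
        n_reps = 25
        for rep in range(n_reps):
            config = SimulationConfig(n_probes=2000, interactome_genes=600,
                                      seed_enrichment=30.0, n_seed_genes=40,
                                      include_es=False, seed=400 + rep)
            _, _, truth = simulate_methylation_study(config)
            graph, seeds = simulate_interactome(config, truth)
            seed_net = build_seed_network(seeds, graph)
            query = sorted(truth.all_disease_genes())
            universe = len(set(truth.gene_of_probe.values()))
            res = ppi_enrichment_ztest(query, seed_net, universe, n_binding="query")
            hits += res.Z >= 1.65
        assert hits / n_reps >= 0.9


class TestGeneSetsAndFixture:
    def test_enriched_sets_contain_disease_genes(self, small_config, small_study):
        _, _, truth = small_study
        sets = simulate_gene_sets(small_config, truth)
        assert len(sets) == small_config.n_gene_sets
        disease = truth.all_disease_genes()
        enriched = [s for name, s in sets.items() if name.startswith("SET_ENRICHED")]
        background = [s for name, s in sets.items() if not name.startswith("SET_ENRICHED")]
        enr_frac = np.mean([len(s & disease) / len(s) for s in enriched])
        bg_frac = np.mean([len(s & disease) / len(s) for s in background])
        assert enr_frac > 3 * bg_frac

    def test_fixture_dir_deterministic_bytes(self, tmp_path):
        config = _null_config(seed=31)
        p1 = write_fixture_dir(config, tmp_path / "a")
        p2 = write_fixture_dir(config, tmp_path / "b")
        for name in p1:
            assert filecmp.cmp(p1[name], p2[name], shallow=False), name
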