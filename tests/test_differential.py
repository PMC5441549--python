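import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methconcord import SimulationConfig
from methconcord.differential import (DesignSpec, bh_adjust, call_differential,
                                      collapse_technical_replicates,
                                      directional_gene_map, differential_test,
                                      fit_group_model, moderate_variances,
                                      moderated_t_test)
from methconcord.io_formats import SampleSheet
from methconcord.preprocess import beta_matrix_to_m
from methconcord.synthetic_data import simulate_methylation_study


def _sheet(rows):
    return SampleSheet(pd.DataFrame(rows))


def _two_group_sheet(g1, g2, cell_type="ONS"):
    rows = []
    for i, s in enumerate(g1):
        rows.append({"sample_id": s, "subject_id": f"P{i}", "cell_type": cell_type,
                     "status": "patient", "clone_id": "cl1"})
    for i, s in enumerate(g2):
        rows.append({"sample_id": s, "subject_id": f"C{i}", "cell_type": cell_type,
                     "status": "control", "clone_id": "cl1"})
    return _sheet(rows)


class TestCollapseReplicates:
    def test_identical_replicates_collapse_to_same_column(self, rng):
        x = rng.normal(size=20)
        matrix = pd.DataFrame({"s1": x, "s2": x})
        sheet = _sheet([{"sample_id": s, "subject_id": "A", "cell_type": "iPS",
                         "status": "patient", "clone_id": "cl1", "passage": i + 1}
                        for i, s in enumerate(["s1", "s2"])])
        out, osheet = collapse_technical_replicates(matrix, sheet)
        assert out.shape[1] == 1
        np.testing.assert_allclose(out.iloc[:, 0], x)

    def test_mean_of_pair(self):
        matrix = pd.DataFrame({"s1": [1.0], "s2": [3.0]})
        sheet = _sheet([{"sample_id": s, "subject_id": "A", "cell_type": "iPS",
                         "status": "patient", "clone_id": "cl1"} for s in ["s1", "s2"]])
        out, _ = collapse_technical_replicates(matrix, sheet)
        assert out.iloc[0, 0] == 2.0

    def test_unit_count_matches_subject_clone_celltype(self, small_study):
        beta, sheet, _ = small_study
        out, osheet = collapse_technical_replicates(beta, sheet)
        units = {(r.subject_id, r.clone_id, r.cell_type)
                 for r in sheet.frame.itertuples()}
        assert out.shape[1] == len(units)
        # clones stay separate: biological replicates are not averaged
        ips = osheet.frame[osheet.frame["cell_type"] == "iPS"]
        assert ips.groupby("subject_id")["clone_id"].nunique().max() == 2

    def test_block_policy_passthrough(self, small_study):
        beta, sheet, _ = small_study
        out, _ = collapse_technical_replicates(beta, sheet, policy="block")
        assert out.shape == beta.shape


class TestFitGroupModel:
    def test_zero_variance_groups(self):
        matrix = pd.DataFrame({"a": [0.0], "b": [0.0], "c": [1.0], "d": [1.0]})
        fit = fit_group_model(matrix, _two_group_sheet(["a", "b"], ["c", "d"]),
                              DesignSpec(("patient", "control")))
        assert fit["effect"].iloc[0] == -1.0 and fit["s2"].iloc[0] == 0.0

    def test_hand_arithmetic(self):
        matrix = pd.DataFrame({s: [v] for s, v in
                               zip("abcdef", [1.0, 2.0, 3.0, 4.0, 5.0, 6.0])})
        fit = fit_group_model(matrix, _two_group_sheet(["a", "b", "c"], ["d", "e", "f"]),
                              DesignSpec(("patient", "control")))
        assert fit["effect"].iloc[0] == -3.0
        assert fit["s2"].iloc[0] == pytest.approx(1.0)
        assert fit["df"].iloc[0] == 4

    def test_matches_least_squares_oracle(self, rng):
        matrix = pd.DataFrame(rng.normal(size=(100, 9)),
                              columns=[f"s{i}" for i in range(9)])
        g1, g2 = [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 9)]
        fit = fit_group_model(matrix, _two_group_sheet(g1, g2),
                              DesignSpec(("patient", "control")))
        X = np.column_stack([np.ones(9), [1] * 4 + [0] * 5])
        for probe in rng.choice(100, size=20, replace=False):
            y = matrix.iloc[probe].to_numpy()
            coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
            effect_ols = coef[1] - 0  # group indicator contrast vs control mean
            s2_ols = res[0] / (9 - 2)
            assert fit["effect"].iloc[probe] == pytest.approx(effect_ols, abs=1e-10)
            assert fit["s2"].iloc[probe] == pytest.approx(s2_ols, abs=1e-10)

    def test_single_unit_group_errors(self):
        matrix = pd.DataFrame({"a": [1.0], "b": [2.0], "c": [3.0]})
        with pytest.raises(ValueError, match=">= 2 units"):
            fit_group_model(matrix, _two_group_sheet(["a"], ["b", "c"]),
                            DesignSpec(("patient", "control")))


class TestModeration:
    def test_identical_variances_unchanged(self):
        s2 = np.full(50, 2.5)
        s2_post, d0, s0_2 = moderate_variances(s2, df=4)
        assert np.isinf(d0)
        np.testing.assert_allclose(s2_post, s2, rtol=1e-12)
        assert s0_2 == pytest.approx(2.5)

    def test_d0_zero_recovers_ordinary_t(self, rng):
        matrix = pd.DataFrame(rng.normal(size=(200, 10)),
                              columns=[f"s{i}" for i in range(10)])
        g1, g2 = [f"s{i}" for i in range(5)], [f"s{i}" for i in range(5, 10)]
        fit = fit_group_model(matrix, _two_group_sheet(g1, g2),
                              DesignSpec(("patient", "control")))
        res = moderated_t_test(fit, d0=0.0)
        t_ref, p_ref = stats.ttest_ind(matrix[g1], matrix[g2], axis=1)
        np.testing.assert_allclose(res["t"], t_ref, atol=1e-8)
        np.testing.assert_allclose(res["p"], p_ref, atol=1e-8)

    def test_parameter_recovery_from_simulated_prior(self):
        """Moment matching recovers (d0, s0^2) from 10,000 simulated variances."""
        rng = np.random.default_rng(42)
        d0_true, s0_true, df = 4.0, 2.0, 6
        sigma2 = d0_true * s0_true / rng.chisquare(d0_true, size=10_000)
        s2 = sigma2 * rng.chisquare(df, size=10_000) / df
        _, d0, s0_2 = moderate_variances(s2, df=df)
        assert d0 == pytest.approx(d0_true, rel=0.25)
        assert s0_2 == pytest.approx(s0_true, rel=0.10)

    def test_too_few_probes_errors(self):
        with pytest.raises(ValueError, match=">= 10"):
            moderate_variances(np.ones(5), df=4)

    def test_shrinkage_direction(self, rng):
        s2 = rng.chisquare(4, size=1000) / 4
        s2_post, d0, s0_2 = moderate_variances(s2, df=4)
        # posterior variances lie between the observations and the prior scale
        pulled = np.abs(s2_post - s0_2) <= np.abs(s2 - s0_2) + 1e-12
        assert pulled.all()


class TestAgainstLimmaOracle:
    def test_moderated_t_matches_limma_ebayes(self, rng, tmp_path):
        """The full moderation pipeline (hyperparameters, t, p) reproduces
        limma's lmFit + eBayes on a heteroscedastic two-group fixture."""
        matrix = pd.DataFrame(
            rng.normal(size=(150, 8)) * np.sqrt(rng.gamma(2.0, 1.0, size=(150, 1))),
            index=[f"p{i}" for i in range(150)], columns=[f"s{i}" for i in range(8)])
        mat_file = tmp_path / "mat.tsv"
        matrix.to_csv(mat_file, sep="\t")
        out_file = tmp_path / "limma.tsv"
        r_code = f'''
        suppressMessages(library(limma))
        m <- as.matrix(read.delim("{mat_file}", row.names=1))
        design <- cbind(Intercept=1, grp=c(1,1,1,1,0,0,0,0))
        fit <- eBayes(lmFit(m, design))
        out <- data.frame(t=fit$t[,"grp"], p=fit$p.value[,"grp"],
                          d0=fit$df.prior, s02=fit$s2.prior)
        write.table(out, "{out_file}", sep="\\t", quote=FALSE)
        '''
        import subprocess
        proc = subprocess.run(["Rscript", "-e", r_code], capture_output=True, text=True)
        assert proc.returncode == 0, proc.stderr
        ref = pd.read_csv(out_file, sep="\t")
        g1, g2 = [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)]
        fit = fit_group_model(matrix, _two_group_sheet(g1, g2),
                              DesignSpec(("patient", "control")))
        res = moderated_t_test(fit)
        assert res.attrs["d0"] == pytest.approx(ref["d0"].iloc[0], rel=1e-5)
        np.testing.assert_allclose(res["t"], ref["t"], atol=1e-10)
        np.testing.assert_allclose(res["p"], ref["p"], atol=1e-10)


class TestBHAdjust:
    def test_single_p(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_all_equal(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_monotone_consistent_with_p(self, rng):
        p = rng.uniform(size=100)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)
        assert np.all(q >= p - 1e-15) and q.max() <= 1.0


class TestCallDifferential:
    def _results(self, p):
        res = pd.DataFrame({"p": p, "q": bh_adjust(p),
                            "effect": np.ones(len(p)),
                            "direction": ["up"] * len(p),
                            "gene_symbol": [f"G{i}" for i in range(len(p))]},
                           index=[f"cg{i}" for i in range(len(p))])
        return res

    def test_all_null_empty(self):
        calls, genes = call_differential(self._results(np.ones(20)), alpha=0.05)
        assert len(calls) == 0 and genes == []

    def test_single_signal_only(self):
        p = np.ones(20)
        p[7] = 1e-12
        calls, genes = call_differential(self._results(p), alpha=0.05)
        assert list(calls.index) == ["cg7"] and genes == ["G7"]

    def test_global_null_full_scale_makes_no_calls(self):
        """A full-width null study (no planted effects) yields zero q<0.05 calls."""
        fractions = {"iPS": 0.0, "ONS": 0.0, "fibroblast": 0.0}
        config = SimulationConfig(n_probes=27578, disease_effect_fractions=fractions,
                                  shared_core_size=0, include_es=False, seed=99)
        beta, sheet, _ = simulate_methylation_study(config)
        ids = sheet.frame.loc[sheet.frame["cell_type"] == "ONS", "sample_id"]
        m = beta_matrix_to_m(beta[list(ids)])
        res = differential_test(m, sheet.subset(ids), DesignSpec(("patient", "control")))
        assert (res["q"] < 0.05).sum() == 0


class TestDirectionalGeneMap:
    def test_relabelling_and_ambiguity(self):
        calls = pd.DataFrame({"direction": ["up", "down", "up", "down"],
                              "gene_symbol": ["A", "B", "C", "C"]},
                             index=["cg1", "cg2", "cg3", "cg4"])
        mapped = directional_gene_map(calls, ("hyper", "hypo"))
        assert mapped == {"A": "hyper", "B": "hypo"}  # C conflicts, dropped
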