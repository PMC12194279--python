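import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from poolcomp import experiment as ex
from poolcomp.datatypes import FilterSettings
from poolcomp.synthetic import SimConfig


class TestOneWayAnova:
    def test_identical_groups(self):
        table = ex.one_way_anova([1, 1, 1, 2, 2, 2], list("aaabbb"))
        # every group internally constant -> F compares zero within MS
        assert table.term("group")["F"] == float("inf")
        table2 = ex.one_way_anova([3, 3, 3, 3], list("aabb"))
        assert table2.term("group")["F"] == 0.0
        assert table2.term("group")["p"] == pytest.approx(1.0)

    def test_hand_computed_f(self):
        table = ex.one_way_anova([1, 2, 3, 4, 5, 6], list("aaabbb"))
        row = table.term("group")
        assert row["ss"] == pytest.approx(13.5)
        assert row["df"] == 1
        assert table.term("residual")["ss"] == pytest.approx(4.0)
        assert row["F"] == pytest.approx(13.5)

    def test_matches_scipy_oracle(self, rng):
        for _ in range(20):
            k = rng.integers(2, 5)
            groups, values = [], []
            for i in range(k):
                n = int(rng.integers(3, 8))
                groups += [f"g{i}"] * n
                values += list(rng.normal(i * 0.3, 1.0, n))
            table = ex.one_way_anova(values, groups)
            f_ref, p_ref = sps.f_oneway(
                *[np.array(values)[np.array(groups) == g] for g in dict.fromkeys(groups)]
            )
            assert table.term("group")["F"] == pytest.approx(f_ref, abs=1e-8)
            assert table.term("group")["p"] == pytest.approx(p_ref, abs=1e-8)

    def test_type_i_error_rate(self):
        rng = np.random.default_rng(77)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            values = rng.normal(size=30)
            groups = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
            p = ex.one_way_anova(values, groups).term("group")["p"]
            rejections += p < 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.02)

    def test_too_few_groups(self):
        with pytest.raises(ValueError):
            ex.one_way_anova([1, 2], ["a", "a"])


class TestTwoWayAnova:
    def test_additive_means_zero_interaction(self):
        rows = []
        for a in range(3):
            for b in range(2):
                for _ in range(2):
                    rows.append((a + 10 * b, f"a{a}", f"b{b}"))
        values, fa, fb = zip(*rows)
        table = ex.two_way_anova(values, fa, fb, factor_names=("A", "B"))
        assert table.term("A:B")["ss"] == pytest.approx(0.0, abs=1e-10)

    def test_single_level_factor_reduces_to_one_way(self, rng):
        values = rng.normal(size=9)
        fa = ["x"] * 3 + ["y"] * 3 + ["z"] * 3
        fb = ["only"] * 9
        two = ex.two_way_anova(values, fa, fb, factor_names=("A", "B"))
        one = ex.one_way_anova(values, fa, factor="A")
        assert two.term("A")["F"] == pytest.approx(one.term("A")["F"])
        assert two.term("A")["p"] == pytest.approx(one.term("A")["p"])

    def test_empty_cell_named(self):
        with pytest.raises(ValueError, match=r"\(a0, b1\)"):
            ex.two_way_anova([1.0, 2.0], ["a0", "a1"], ["b0", "b1"])

    def test_matches_statsmodels_oracle(self, rng):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        values, fa, fb = [], [], []
        for a in ("u", "v"):
            for b in ("x", "y"):
                for _ in range(4):
                    values.append(float(rng.normal()))
                    fa.append(a)
                    fb.append(b)
        table = ex.two_way_anova(values, fa, fb, factor_names=("A", "B"))
        df = pd.DataFrame({"y": values, "A": fa, "B": fb})
        fit = ols("y ~ C(A) * C(B)", data=df).fit()
        ref = sm.stats.anova_lm(fit, typ=1)
        assert table.term("A")["ss"] == pytest.approx(ref.loc["C(A)", "sum_sq"], abs=1e-8)
        assert table.term("B")["ss"] == pytest.approx(ref.loc["C(B)", "sum_sq"], abs=1e-8)
        assert table.term("A:B")["ss"] == pytest.approx(
            ref.loc["C(A):C(B)", "sum_sq"], abs=1e-8
        )
        assert table.term("A:B")["p"] == pytest.approx(
            ref.loc["C(A):C(B)", "PR(>F)"], abs=1e-8
        )

    def test_df_sum_to_n_minus_one(self, rng):
        values = rng.normal(size=24)
        fa = (["a"] * 4 + ["b"] * 4) * 3
        fb = ["x"] * 8 + ["y"] * 8 + ["z"] * 8
        table = ex.two_way_anova(values, fa, fb)
        assert table.terms["df"].sum() == 23


class TestTukey:
    def test_two_groups_equal_t_test(self, rng):
        a = rng.normal(0, 1, 8)
        b = rng.normal(0.7, 1, 9)
        tukey = ex.tukey_hsd(np.concatenate([a, b]), ["a"] * 8 + ["b"] * 9)
        p_tukey = tukey.pairs["p"].iloc[0]
        t_ref, p_ref = sps.ttest_ind(a, b)
        assert p_tukey == pytest.approx(p_ref, abs=1e-6)

    def test_identical_groups_share_letter(self):
        values = [1.0, 1.1, 0.9] * 3
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        tukey = ex.tukey_hsd(values, groups)
        assert len(set(tukey.letters.values())) == 1

    def test_separated_groups_distinct_letters(self, rng):
        values = np.concatenate(
            [rng.normal(0, 0.1, 5), rng.normal(10, 0.1, 5), rng.normal(20, 0.1, 5)]
        )
        groups = ["lo"] * 5 + ["mid"] * 5 + ["hi"] * 5
        tukey = ex.tukey_hsd(values, groups)
        assert len(set(tukey.letters.values())) == 3

    def test_matches_scipy_oracle(self, rng):
        for _ in range(20):
            samples = [rng.normal(rng.normal(), 1.0, int(rng.integers(4, 8)))
                       for _ in range(3)]
            values = np.concatenate(samples)
            groups = sum([[f"g{i}"] * len(s) for i, s in enumerate(samples)], [])
            mine = ex.tukey_hsd(values, groups)
            ref = sps.tukey_hsd(*samples)
            for _, row in mine.pairs.iterrows():
                i = int(row["level_a"][1])
                j = int(row["level_b"][1])
                assert row["p"] == pytest.approx(ref.pvalue[i, j], abs=1e-8)

    def test_letters_consistent_with_significance(self, rng):
        values = np.concatenate([rng.normal(0, 1, 6), rng.normal(0.2, 1, 6),
                                 rng.normal(8, 1, 6)])
        groups = ["a"] * 6 + ["b"] * 6 + ["c"] * 6
        tukey = ex.tukey_hsd(values, groups)
        for _, row in tukey.pairs.iterrows():
            shared = set(tukey.letters[row["level_a"]]) & set(tukey.letters[row["level_b"]])
            if row["p"] < tukey.alpha:
                assert not shared
            else:
                assert shared


class TestLevene:
    def test_mean_shifted_groups_statistic_zero(self):
        base = [1.0, 2.0, 3.0, 4.0]
        values = base + [x + 10 for x in base]
        w, p = ex.levene_test(values, ["a"] * 4 + ["b"] * 4)
        assert w == 0.0
        assert p == 1.0

    def test_matches_scipy_oracle(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, 10)
            b = rng.normal(0, 2, 12)
            w_ref, p_ref = sps.levene(a, b, center="median")
            w, p = ex.levene_test(np.concatenate([a, b]), ["a"] * 10 + ["b"] * 12)
            assert w == pytest.approx(w_ref, abs=1e-8)
            assert p == pytest.approx(p_ref, abs=1e-8)

    def test_type_i_error_rate(self):
        rng = np.random.default_rng(31)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            values = rng.normal(size=24)
            _, p = ex.levene_test(values, ["a"] * 12 + ["b"] * 12)
            rejections += p < 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.02)

    def test_power_against_variance_ratio(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0, np.sqrt(10), 30)
        _, p = ex.levene_test(np.concatenate([a, b]), ["a"] * 30 + ["b"] * 30)
        assert p < 0.01

    def test_mean_centering_option(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(0, 1.5, 10)
        w_ref, _ = sps.levene(a, b, center="mean")
        w, _ = ex.levene_test(np.concatenate([a, b]), ["a"] * 10 + ["b"] * 10,
                              center="mean")
        assert w == pytest.approx(w_ref, abs=1e-8)


class TestConfigParsing:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "cfg.txt"
        path.write_text(
            "n_accessions = 3\n"
            "n_markers = 250\n"
            "# a comment line\n"
            "pool_sizes = 20, 30, 60\n"
            "divergence_theta = 0.2\n"
            "seed = 9\n"
        )
        cfg = ex.read_config(path)
        assert cfg.n_accessions == 3
        assert cfg.pool_sizes == (20, 30, 60)
        assert cfg.divergence_theta == 0.2
        assert cfg.seed == 9

    def test_malformed_line(self, tmp_path):
        path = tmp_path / "cfg.txt"
        path.write_text("n_markers 250\n")
        with pytest.raises(ValueError, match="key = value"):
            ex.read_config(path)


class TestFullExperiment:
    @pytest.fixture(scope="class")
    @staticmethod
    def bundle(tmp_path_factory):
        outdir = tmp_path_factory.mktemp("run")
        cfg = SimConfig(n_markers=300, seed=41)
        return (
            ex.run_full_experiment(
                cfg, outdir, amova_permutations=49, mantel_permutations=49
            ),
            outdir,
        )

    def test_smoke_emits_all_artifacts(self, bundle):
        _, outdir = bundle
        expected = {
            "score_report.csv", "count_report.csv", "design_map.csv",
            "sample_map.csv", "truth.csv", "sweep.csv", "diversity.csv",
            "delta_he.csv", "stats_one_way.csv", "stats_delta_he_two_way.csv",
            "structure_nei_ind.csv", "structure_nei_pool.csv", "structure_fst_ind.csv",
        }
        present = {p.name for p in outdir.glob("*.csv")}
        assert expected <= present
        assert (outdir / "manifest.json").exists()
        assert (outdir / "structure_summary.json").exists()

    def test_manifest_lists_config_and_outputs(self, bundle):
        _, outdir = bundle
        manifest = json.loads((outdir / "manifest.json").read_text())
        assert manifest["config"]["n_markers"] == 300
        assert "sweep.csv" in manifest["outputs"]

    def test_sweep_has_full_grid(self, bundle):
        result, _ = bundle
        assert len(result["sweep"]) == 900

    def test_same_seed_reproduces_bundle(self, bundle, tmp_path):
        result, _ = bundle
        cfg = SimConfig(n_markers=300, seed=41)
        again = ex.run_full_experiment(
            cfg, tmp_path / "again", amova_permutations=49, mantel_permutations=49
        )
        pd.testing.assert_frame_equal(result["sweep"], again["sweep"])
        pd.testing.assert_frame_equal(result["delta_he"], again["delta_he"])
        assert (
            result["structure"]["amova_ind"].p_value
            == again["structure"]["amova_ind"].p_value
        )

    def test_stage_failure_is_labeled(self, tmp_path):
        cfg = SimConfig(n_markers=300, seed=41)
        with pytest.raises(RuntimeError, match="stage"):
            ex.run_full_experiment(
                cfg, tmp_path / "x", reference_size=999,
                amova_permutations=0, mantel_permutations=0,
            )

    def test_amova_pool_unit_count(self, bundle):
        result, _ = bundle
        pool_amova = result["structure"]["amova_pool"]
        # 5 accessions x 4 libraries at the reference size: df 4 / 15
        assert pool_amova.df_between == 4
        assert pool_amova.df_within == 15


class TestAggregateSweep:
    def test_averages_over_other_factors(self):
        sweep = pd.DataFrame(
            {
                "accession": ["A", "A", "B", "B"],
                "depth": [1.8, 4.8, 1.8, 4.8],
                "ccc": [0.5, 0.9, 0.6, 1.0],
            }
        )
        agg = ex.aggregate_sweep(sweep, "ccc", "depth")
        assert len(agg) == 4
        assert set(agg.columns) == {"accession", "depth", "ccc"}
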