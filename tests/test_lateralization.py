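import numpy as np
import pandas as pd
import pingouin as pg
import pytest
import scipy.stats

from conftest import make_summary
from hemigrad.embedding import GradientSet
from hemigrad.lateralization import (
    global_hemisphere_test,
    hemispheric_difference,
    minmax_normalize,
    network_pair_distance_test,
    permutation_network_test,
    rm_anova_hemisphere_network,
    summarize_networks,
    zscore_difference_map,
)
from _reference import signflip_enumeration_pvalue


def gset(values):
    v = np.asarray(values, dtype=float)[:, None]
    return GradientSet(v, np.array([0.5]), np.array([1.0]),
                       [f"p{i}" for i in range(len(v))])


class TestMinmax:
    def test_linear_map_endpoints(self):
        np.testing.assert_allclose(
            minmax_normalize(gset([2, 4, 6])), [0.0, 50.0, 100.0]
        )

    def test_range_contract(self, rng):
        out = minmax_normalize(gset(rng.standard_normal(20)))
        assert out.min() == 0.0 and out.max() == 100.0

    def test_affine_invariance(self, rng):
        v = rng.standard_normal(15)
        np.testing.assert_allclose(
            minmax_normalize(gset(v)), minmax_normalize(gset(3.2 * v + 11)),
            atol=1e-10,
        )

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            minmax_normalize(gset([1, 1, 1]))


class TestSummaries:
    def test_network_means(self, toy_atlas):
        values = np.array([10.0, 20.0, 30.0, 40.0, 1.0, 2.0, 3.0, 7.0, 9.0])
        out = summarize_networks(values, toy_atlas, "sub-000")
        def cell(net, hemi):
            m = out[(out["network"] == net) & (out["hemisphere"] == hemi)]
            return float(m["mean_gradient"].iloc[0])
        assert cell("alpha", "L") == pytest.approx(15.0)
        assert cell("alpha", "R") == pytest.approx(35.0)
        assert cell("beta", "L") == pytest.approx(2.0)
        assert cell("beta", "R") == pytest.approx(8.0)

    def test_matches_double_loop_oracle(self, toy_atlas, rng):
        values = rng.standard_normal(toy_atlas.n_parcels)
        out = summarize_networks(values, toy_atlas, "s")
        table = toy_atlas.table.assign(v=values)
        for _, row in out.iterrows():
            acc, count = 0.0, 0
            for _, prow in table.iterrows():
                if (prow["network"] == row["network"]
                        and prow["hemisphere"] == row["hemisphere"]):
                    acc += prow["v"]
                    count += 1
            assert row["mean_gradient"] == pytest.approx(acc / count)

    def test_single_hemisphere_network_warns(self, caplog):
        import pandas as pd
        from hemigrad.atlas import ParcelAtlas
        atlas = ParcelAtlas(pd.DataFrame(
            {"parcel_id": ["a", "b"], "hemisphere": ["L", "L"],
             "network": ["solo", "solo"]}
        ))
        with caplog.at_level("WARNING"):
            out = summarize_networks(np.array([1.0, 3.0]), atlas, "s")
        assert len(out) == 1
        assert out["hemisphere"].iloc[0] == "L"
        diffs = hemispheric_difference(out)
        assert diffs.empty


class TestDifferences:
    def test_symmetric_and_arithmetic(self):
        vals = np.zeros((2, 2, 2))
        vals[:, 0, :] = [[70.0, 50.0], [60.0, 40.0]]  # L
        vals[:, 1, :] = [[65.0, 50.0], [55.0, 40.0]]  # R
        summary = make_summary(vals, ["n1", "n2"])
        diffs = hemispheric_difference(summary)
        d = diffs.set_index(["participant_id", "network"])["diff"]
        assert d.loc[("sub-000", "n1")] == pytest.approx(5.0)
        assert d.loc[("sub-000", "n2")] == pytest.approx(0.0)

    def test_left_right_swap_negates(self, rng):
        vals = rng.uniform(0, 100, size=(5, 2, 3))
        summary = make_summary(vals, ["a", "b", "c"])
        swapped = summary.copy()
        swapped["hemisphere"] = swapped["hemisphere"].map({"L": "R", "R": "L"})
        d1 = hemispheric_difference(summary).set_index(["participant_id", "network"])
        d2 = hemispheric_difference(swapped).set_index(["participant_id", "network"])
        np.testing.assert_allclose(d1["diff"], -d2.loc[d1.index, "diff"])


class TestZScoreMap:
    def test_population_sd_formula(self):
        diffs = pd.DataFrame(
            {"participant_id": ["s"] * 3, "network": ["a", "b", "c"],
             "diff": [-1.0, 0.0, 1.0]}
        )
        z = zscore_difference_map(diffs)
        np.testing.assert_allclose(z.to_numpy(), [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_normalization_contract(self, rng):
        nets = [f"n{i}" for i in range(6)]
        diffs = pd.DataFrame(
            [
                {"participant_id": f"s{p}", "network": n,
                 "diff": rng.standard_normal()}
                for p in range(4) for n in nets
            ]
        )
        z = zscore_difference_map(diffs)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=0) == pytest.approx(1.0)

    def test_degenerate_rejected(self):
        diffs = pd.DataFrame(
            {"participant_id": ["s"] * 3, "network": ["a", "b", "c"],
             "diff": [2.0, 2.0, 2.0]}
        )
        with pytest.raises(ValueError, match="zero variance"):
            zscore_difference_map(diffs)


class TestGlobalTest:
    def test_identical_hemispheres(self, rng):
        vals = np.repeat(rng.uniform(0, 100, size=(4, 1, 3)), 2, axis=1)
        res = global_hemisphere_test(make_summary(vals, ["a", "b", "c"]))
        assert res.t == 0.0 and res.p == 1.0
        assert res.frac_left_higher == 0.0

    def test_constant_offset_degenerate(self, rng, caplog):
        vals = np.repeat(rng.uniform(0, 100, size=(4, 1, 3)), 2, axis=1)
        vals[:, 0, :] += 5.0
        with caplog.at_level("WARNING"):
            res = global_hemisphere_test(make_summary(vals, ["a", "b", "c"]))
        assert res.p == 0.0 and np.isinf(res.t)
        assert res.frac_left_higher == 1.0

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(99)
        pvals = []
        for _ in range(500):
            vals = rng.normal(50, 10, size=(12, 2, 3))
            pvals.append(global_hemisphere_test(make_summary(vals, list("abc"))).p)
        assert scipy.stats.kstest(pvals, "uniform").pvalue > 0.01


class TestRmAnova:
    def test_matches_pingouin(self):
        rng = np.random.default_rng(21)
        vals = rng.normal(50, 10, size=(15, 2, 4)) + rng.normal(
            0, 6, size=(15, 1, 1)
        )
        summary = make_summary(vals, [f"n{j}" for j in range(4)])
        mine = rm_anova_hemisphere_network(summary).set_index("effect")
        ref = pg.rm_anova(
            data=summary, dv="mean_gradient",
            within=["hemisphere", "network"], subject="participant_id",
        ).set_index("Source")
        pairs = [
            ("hemisphere", "hemisphere"),
            ("network", "network"),
            ("hemisphere:network", "hemisphere * network"),
        ]
        for my_name, pg_name in pairs:
            assert mine.loc[my_name, "F"] == pytest.approx(
                ref.loc[pg_name, "F"], rel=1e-8
            )
            assert mine.loc[my_name, "p_gg"] == pytest.approx(
                ref.loc[pg_name, "p_GG_corr"], rel=1e-6
            )
            assert mine.loc[my_name, "eps_gg"] == pytest.approx(
                ref.loc[pg_name, "eps"], rel=1e-6
            )

    def test_compound_symmetry_epsilon_near_one(self):
        rng = np.random.default_rng(5)
        n, m = 40, 4
        subj = rng.normal(0, 5, size=(n, 1, 1))
        vals = 50 + subj + rng.normal(0, 3, size=(n, 2, m))
        summary = make_summary(vals, [f"n{j}" for j in range(m)])
        res = rm_anova_hemisphere_network(summary).set_index("effect")
        for eff in ("network", "hemisphere:network"):
            assert res.loc[eff, "eps_gg"] > 0.8
            assert res.loc[eff, "p_gg"] == pytest.approx(
                res.loc[eff, "p_uncorrected"], abs=0.05
            )

    def test_null_calibration(self):
        rng = np.random.default_rng(31)
        rejections = {"hemisphere": 0, "network": 0, "hemisphere:network": 0}
        reps = 200
        for _ in range(reps):
            vals = rng.normal(50, 10, size=(12, 2, 3))
            res = rm_anova_hemisphere_network(
                make_summary(vals, list("abc"))
            ).set_index("effect")
            for eff in rejections:
                rejections[eff] += res.loc[eff, "p_gg"] < 0.05
        for eff, count in rejections.items():
            assert count / reps < 0.11, eff  # conservative band around 0.05

    def test_planted_interaction_detected(self):
        rng = np.random.default_rng(41)
        detected = 0
        reps = 20
        for _ in range(reps):
            vals = rng.normal(50, 10, size=(100, 2, 4))
            vals[:, 0, 0] += 6.0  # hemisphere effect in one network only
            res = rm_anova_hemisphere_network(
                make_summary(vals, [f"n{j}" for j in range(4)])
            ).set_index("effect")
            detected += res.loc["hemisphere:network", "p_gg"] < 0.05
        assert detected >= 0.9 * reps

    def test_covariate_absorbs_between_subject_variance(self):
        rng = np.random.default_rng(51)
        n = 30
        global_shift = rng.normal(0, 5, size=(n, 1, 1))
        vals = rng.normal(50, 0.5, size=(n, 2, 3))
        vals[:, 0, :] += global_shift[:, 0, :]  # L-R contrast driven by covariate
        summary = make_summary(vals, list("abc"))
        cov = pd.Series(
            global_shift[:, 0, 0], index=[f"sub-{i:03d}" for i in range(n)]
        )
        res = rm_anova_hemisphere_network(summary, covariate=cov).set_index("effect")
        without = rm_anova_hemisphere_network(summary).set_index("effect")
        # the covariate explains the hemisphere-contrast variance, so the
        # residual error shrinks and the F statistic sharpens; one error df
        # is charged per contrast variable
        assert res.loc["hemisphere", "F"] > without.loc["hemisphere", "F"]
        assert res.loc["hemisphere", "df2"] == without.loc["hemisphere", "df2"] - 1
        assert (
            res.loc["hemisphere:network", "df2"]
            == without.loc["hemisphere:network", "df2"] - 2
        )

    def test_incomplete_design_rejected(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(50, 10, size=(6, 2, 3))
        summary = make_summary(vals, list("abc"))
        broken = summary[
            ~((summary["network"] == "b") & (summary["hemisphere"] == "R"))
        ]
        with pytest.raises(ValueError, match="missing cells"):
            rm_anova_hemisphere_network(broken)


def diff_table(values_by_network):
    rows = []
    for net, vals in values_by_network.items():
        for i, v in enumerate(vals):
            rows.append(
                {"participant_id": f"sub-{i:03d}", "network": net, "diff": v}
            )
    return pd.DataFrame(rows)


class TestPermutation:
    def test_exact_five_participant_enumeration(self):
        diffs = diff_table({"net": np.ones(5)})
        res = permutation_network_test(diffs, n_resamples=5000, seed=1)
        assert res["exhaustive"].iloc[0]
        assert res["p_uncorrected"].iloc[0] == pytest.approx(2 / 32)
        # independent full enumeration
        assert signflip_enumeration_pvalue(np.ones(5)) == pytest.approx(2 / 32)

    def test_all_zero_diffs(self):
        diffs = diff_table({"net": np.zeros(6)})
        res = permutation_network_test(diffs, n_resamples=500, seed=1)
        assert res["p_uncorrected"].iloc[0] == pytest.approx(1.0)

    def test_matches_enumeration_on_random_diffs(self, rng):
        d = rng.standard_normal(8)
        res = permutation_network_test(
            diff_table({"net": d}), n_resamples=5000, seed=0
        )
        assert res["p_uncorrected"].iloc[0] == pytest.approx(
            signflip_enumeration_pvalue(d)
        )

    def test_invariances(self, rng):
        d = rng.standard_normal(9)
        base = permutation_network_test(
            diff_table({"net": d}), n_resamples=2000, seed=3
        )["p_uncorrected"].iloc[0]
        scaled = permutation_network_test(
            diff_table({"net": 7.5 * d}), n_resamples=2000, seed=3
        )["p_uncorrected"].iloc[0]
        relabeled = permutation_network_test(
            diff_table({"net": d[::-1]}), n_resamples=2000, seed=3
        )["p_uncorrected"].iloc[0]
        assert scaled == base
        assert relabeled == base

    def test_bonferroni_and_determinism(self, rng):
        diffs = diff_table(
            {f"n{j}": rng.standard_normal(20) for j in range(4)}
        )
        a = permutation_network_test(diffs, n_resamples=1000, seed=9)
        b = permutation_network_test(diffs, n_resamples=1000, seed=9)
        pd.testing.assert_frame_equal(a, b)
        np.testing.assert_allclose(
            a["p_bonferroni"], np.minimum(1.0, 4 * a["p_uncorrected"])
        )

    def test_bootstrap_scheme_agrees_with_signflip(self, rng):
        d = rng.standard_normal(30) + 0.4
        diffs = diff_table({"net": d})
        p_flip = permutation_network_test(
            diffs, n_resamples=4000, seed=2
        )["p_uncorrected"].iloc[0]
        p_boot = permutation_network_test(
            diffs, n_resamples=4000, seed=2, scheme="bootstrap"
        )["p_uncorrected"].iloc[0]
        # both target the same null hypothesis; agreement is approximate
        assert p_boot == pytest.approx(p_flip, abs=0.05)
        with pytest.raises(ValueError, match="scheme"):
            permutation_network_test(diffs, scheme="jackknife")

    def test_too_few_participants(self):
        with pytest.raises(ValueError, match="at least 5"):
            permutation_network_test(diff_table({"net": np.ones(4)}))


class TestPairDistance:
    def test_distances_match_subject_loop(self, rng):
        vals = rng.uniform(0, 100, size=(8, 2, 3))
        summary = make_summary(vals, ["a", "b", "c"])
        res = network_pair_distance_test(summary, "a", "b")
        manual_L = [vals[i, 0, 1] - vals[i, 0, 0] for i in range(8)]
        manual_R = [vals[i, 1, 1] - vals[i, 1, 0] for i in range(8)]
        assert res.mean_left == pytest.approx(np.mean(manual_L))
        assert res.mean_right == pytest.approx(np.mean(manual_R))
        t_ref = scipy.stats.ttest_rel(manual_L, manual_R)
        assert res.t == pytest.approx(t_ref.statistic)
        assert res.p == pytest.approx(t_ref.pvalue)

    def test_planted_shift_detected_with_sign(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(0, 2, size=(40, 2, 2))
        vals[:, :, 1] += 30.0  # network b sits above network a
        vals[:, 0, 0] += 10.0  # LH: a moves toward b -> smaller LH distance
        res = network_pair_distance_test(make_summary(vals, ["a", "b"]), "a", "b")
        assert res.mean_left < res.mean_right
        assert res.t < 0 and res.p < 0.001

    def test_symmetric_null_calibrated(self):
        rng = np.random.default_rng(17)
        pvals = [
            network_pair_distance_test(
                make_summary(rng.normal(50, 5, size=(10, 2, 2)), ["a", "b"]),
                "a", "b",
            ).p
            for _ in range(300)
        ]
        assert scipy.stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_missing_network_rejected(self, rng):
        summary = make_summary(rng.normal(size=(6, 2, 2)), ["a", "b"])
        with pytest.raises(ValueError, match="missing"):
            network_pair_distance_test(summary, "a", "zzz")
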