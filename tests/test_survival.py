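import numpy as np
import pandas as pd
import pytest

import immunesig as im


def _clin(times, events, index=None, **extra):
    df = pd.DataFrame({"time": times, "event": events, **extra})
    df.index = index or [f"s{i}" for i in range(len(times))]
    return im.ClinicalTable(df)


class TestComputeMetagenes:
    def _ann(self):
        return im.FeatureAnnotation(feature_to_gene={"p1": "G", "p2": "G"})

    def test_two_step_average_hand_computed(self):
        df = pd.DataFrame(
            {"s1": [2.0, 4.0, 6.0], "s2": [1.0, 1.0, 1.0]},
            index=["p1", "p2", "q"],
        )
        x = im.ExpressionMatrix(df, "d")
        sigs = im.SignatureSet(signatures={"S": frozenset({"p1", "p2", "q"})})
        mg = im.compute_metagenes(x, sigs, self._ann())
        # same-gene probes first: mean(2,4)=3; then mean(3, 6) = 4.5
        assert mg.data.loc["S", "s1"] == pytest.approx(4.5)
        assert mg.data.loc["S", "s2"] == pytest.approx(1.0)

    def test_single_probe_signature_is_identity(self, rng):
        from tests.conftest import random_matrix

        x = random_matrix(rng, 5, 6)
        sigs = im.SignatureSet(signatures={"S": frozenset({"g2"})})
        mg = im.compute_metagenes(x, sigs, im.FeatureAnnotation())
        np.testing.assert_array_equal(
            mg.data.loc["S"].to_numpy(), x.data.loc["g2"].to_numpy()
        )

    def test_planted_metagene_tracks_latent_factor(self):
        mats, truth = im.simulate_datasets(
            n_datasets=2, n_samples=100, n_conserved=2, n_private=0,
            module_size=20, n_background=10, seed=13,
        )
        ann = im.simulate_annotation(truth, seed=13)
        sigs = im.SignatureSet(
            signatures={m: truth.conserved_modules[m]
                        for m in truth.conserved_modules}
        )
        mg = im.compute_metagenes(mats[0], sigs, ann)
        for mod in truth.conserved_modules:
            f = truth.factors[("DS1", mod)]
            r = np.corrcoef(mg.data.loc[mod].to_numpy(), f)[0, 1]
            assert abs(r) >= 0.9

    def test_absent_members_dropped_not_fatal(self, rng):
        from tests.conftest import random_matrix

        x = random_matrix(rng, 5, 6)
        sigs = im.SignatureSet(signatures={"S": frozenset({"g1", "nope"})})
        mg = im.compute_metagenes(x, sigs, im.FeatureAnnotation())
        np.testing.assert_array_equal(
            mg.data.loc["S"].to_numpy(), x.data.loc["g1"].to_numpy()
        )


class TestMetageneDendrogram:
    def test_identical_metagenes_merge_at_height_zero(self, rng):
        row = rng.normal(0, 1, 30)
        data = pd.DataFrame(
            [row, row, rng.normal(0, 1, 30)], index=["a", "b", "c"]
        )
        tree = im.metagene_dendrogram(im.MetageneTable(data))
        assert tree.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_constant_row_rejected_by_name(self):
        data = pd.DataFrame(
            [[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["flat", "ok"]
        )
        with pytest.raises(ValueError, match="flat"):
            im.metagene_dendrogram(im.MetageneTable(data))

    def test_same_parent_factor_pairs_before_unrelated(self, rng):
        f1, f2 = rng.normal(0, 1, (2, 60))
        data = pd.DataFrame(
            {
                "a1": f1 + rng.normal(0, 0.2, 60),
                "a2": f1 + rng.normal(0, 0.2, 60),
                "b1": f2 + rng.normal(0, 0.2, 60),
            }
        ).T
        tree = im.metagene_dendrogram(im.MetageneTable(data))
        # first merge joins the two children of the same factor
        first = sorted(int(i) for i in tree.linkage[0, :2])
        assert [tree.names[i] for i in first] == ["a1", "a2"]

    def test_tree_invariant_to_signature_order(self, rng):
        rows = rng.normal(0, 1, size=(4, 40))
        data = pd.DataFrame(rows, index=["a", "b", "c", "d"])
        t1 = im.metagene_dendrogram(im.MetageneTable(data))
        t2 = im.metagene_dendrogram(im.MetageneTable(data.iloc[::-1]))
        assert t1.to_newick().count("(") == t2.to_newick().count("(")
        # cophenetic structure identical: same merge heights
        np.testing.assert_allclose(
            np.sort(t1.linkage[:, 2]), np.sort(t2.linkage[:, 2]), atol=1e-12
        )

    def test_newick_is_parseable(self, rng):
        from io import StringIO

        from Bio import Phylo

        data = pd.DataFrame(rng.normal(0, 1, size=(3, 30)), index=["a", "b", "c"])
        nwk = im.metagene_dendrogram(im.MetageneTable(data)).to_newick()
        tree = Phylo.read(StringIO(nwk), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == ["a", "b", "c"]


class TestCoxUnivariate:
    def test_matches_partial_likelihood_grid_oracle(self):
        """4 observations, no ties, no censoring: β̂ maximizes the
        analytic Cox partial likelihood (grid + golden refinement)."""
        times = [1.0, 2.0, 3.0, 4.0]
        events = [1, 1, 1, 1]
        z = np.array([0.5, -0.2, 0.8, -1.0])
        values = pd.Series(z, index=[f"s{i}" for i in range(4)])
        clin = _clin(times, events)

        order = np.argsort(times)  # event order

        def log_pl(beta):
            total = 0.0
            at_risk = list(order)
            for i in order:
                total += beta * z[i] - np.log(
                    np.sum(np.exp(beta * z[at_risk]))
                )
                at_risk.remove(i)
            return total

        grid = np.linspace(-5, 5, 20001)
        beta_oracle = grid[np.argmax([log_pl(b) for b in grid])]
        row = im.cox_univariate(values, clin)
        assert np.log(row["hazard_ratio"]) == pytest.approx(beta_oracle, abs=1e-3)
        assert row["ci_low"] <= row["hazard_ratio"] <= row["ci_high"]

    def test_efron_equals_breslow_without_ties(self, rng):
        n = 80
        z = rng.normal(0, 1, n)
        t = rng.exponential(1 / np.exp(0.4 * z))  # continuous: no ties
        values = pd.Series(z, index=[f"s{i}" for i in range(n)])
        clin = _clin(list(t), [1] * n)
        b_efron = im.cox_beta(values, clin, ties="efron")
        b_breslow = im.cox_beta(values, clin, ties="breslow")
        assert b_efron == pytest.approx(b_breslow, abs=1e-8)
        # the inferential fitter agrees with the point-estimate route
        b_full = np.log(im.cox_univariate(values, clin)["hazard_ratio"])
        assert b_full == pytest.approx(b_efron, abs=1e-6)

    def test_all_censored_rejected(self):
        values = pd.Series([1.0, 2.0, 3.0], index=["s0", "s1", "s2"])
        with pytest.raises(ValueError, match="events"):
            im.cox_univariate(values, _clin([1, 2, 3], [0, 0, 0]))

    def test_disjoint_sample_ids_rejected(self):
        values = pd.Series([1.0, 2.0], index=["x1", "x2"])
        with pytest.raises(ValueError, match="shared"):
            im.cox_univariate(values, _clin([1, 2], [1, 1]))


class TestStratifiedSurvival:
    def test_all_stratum_equals_unstratified(self, rng):
        n = 60
        z = rng.normal(0, 1, n)
        t = rng.exponential(1 / np.exp(0.5 * z))
        ids = [f"s{i}" for i in range(n)]
        clin = _clin(list(t), [1] * n, index=ids)
        mg = im.MetageneTable(pd.DataFrame([z], index=["M"], columns=ids))
        report = im.stratified_survival(mg, clin).table
        single = im.cox_univariate(mg.data.loc["M"], clin)
        row = report[report["stratum"] == "All"].iloc[0]
        assert row["hazard_ratio"] == pytest.approx(single["hazard_ratio"])
        assert row["p_value"] == pytest.approx(single["p_value"])

    def test_tertiles_split_nine_samples_evenly(self):
        s = pd.Series(np.arange(9.0), index=[f"s{i}" for i in range(9)])
        bins = im.tertile_bins(s)
        assert (bins.value_counts() == 3).all()
        assert list(bins[["s0", "s4", "s8"]]) == ["low", "med", "high"]

    def test_no_event_stratum_reported_with_missing_estimates(self, rng):
        n = 30
        ids = [f"s{i}" for i in range(n)]
        events = [1] * 15 + [0] * 15
        grade = ["hi"] * 15 + ["lo"] * 15
        clin = _clin(list(rng.exponential(1, n)), events, index=ids, grade=grade)
        mg = im.MetageneTable(
            pd.DataFrame([rng.normal(0, 1, n)], index=["M"], columns=ids)
        )
        report = im.stratified_survival(mg, clin, [("grade", "levels")]).table
        lo = report[report["stratum"] == "grade = lo"].iloc[0]
        assert np.isnan(lo["hazard_ratio"]) and lo["events"] == 0
        hi = report[report["stratum"] == "grade = hi"].iloc[0]
        assert np.isfinite(hi["hazard_ratio"])

    def test_planted_interaction_detected_only_in_high_tertile(self):
        rng = np.random.default_rng(42)
        n = 900
        ids = [f"s{i}" for i in range(n)]
        p_meta = rng.normal(0, 1, n)  # continuous stratifier
        z = rng.normal(0, 1, n)
        high = p_meta > np.quantile(p_meta, 2 / 3)
        rate = 0.3 * np.exp(np.where(high, -0.8 * z, 0.0))
        t = rng.exponential(1 / rate)
        clin = _clin(list(t), [1] * n, index=ids, P=list(p_meta))
        mg = im.MetageneTable(pd.DataFrame([z], index=["M"], columns=ids))
        report = im.stratified_survival(mg, clin, [("P", "tertiles")]).table
        by = {r["stratum"]: r for _, r in report.iterrows()}
        assert by["P (high)"]["p_value"] <= 0.05
        assert by["P (low)"]["p_value"] > 0.05
        assert by["P (med)"]["p_value"] > 0.05

    def test_significance_star_coding(self):
        assert im.significance_stars(0.0005) == "***"
        assert im.significance_stars(0.005) == "**"
        assert im.significance_stars(0.03) == "*"
        assert im.significance_stars(0.2) == ""
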