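"""LFQ normalization, the Epanechnikov empirical null, interactor calling,
BH adjustment and the binary class-specificity tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from ejmotif._stats import EpanechnikovKDE, bh_adjust
from ejmotif.interactome import (
    annotation_overlap_significance,
    binary_class_enrichment,
    call_interactors,
    chi_square_overlap,
    epanechnikov_null,
    normalize_intensities,
    strict_presence_filter,
)
from ejmotif.simulate import gen_lfq_table


def _long_table(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id", "experiment", "sample", "fraction", "condition",
            "intensity",
        ],
    )


class TestNormalizeIntensities:
    def test_single_fraction_column_sum(self):
        t = _long_table(
            [
                ("p1", "e1", "s1", "f1", "vector_control", 3.0),
                ("p2", "e1", "s1", "f1", "vector_control", 1.0),
            ]
        )
        out = normalize_intensities(t).set_index("protein_id")["total"]
        # shares 0.75/0.25, then median-rescaled so the median total is 1
        assert out["p1"] / out["p2"] == pytest.approx(3.0)
        assert np.median(out.values) == pytest.approx(1.0)

    def test_invariant_to_global_experiment_scaling(self, rng):
        rows = []
        for p in range(5):
            for s in ("s1", "s2"):
                for f in ("f1", "f2"):
                    v = rng.uniform(1, 100)
                    rows.append((f"p{p}", "e1", s, f, "vector_control", v))
                    rows.append((f"p{p}", "e2", s, f, "vector_control", v * 10))
        out = normalize_intensities(_long_table(rows))
        piv = out.pivot_table(index=["protein_id", "sample"], columns="experiment",
                              values="total")
        np.testing.assert_allclose(piv["e1"].values, piv["e2"].values)

    def test_matches_three_step_spreadsheet_oracle(self, rng):
        rows = []
        for p in range(20):
            for e in ("e1", "e2"):
                for s in ("s1", "s2"):
                    for f in ("f1", "f2", "f3"):
                        rows.append(
                            (f"p{p:02d}", e, s, f, "bait_A", rng.uniform(0, 50))
                        )
        t = _long_table(rows)
        out = normalize_intensities(t).set_index(
            ["protein_id", "experiment", "sample"]
        )["total"]
        # independent recomputation with explicit loops
        for e in ("e1", "e2"):
            sub = t[t.experiment == e]
            totals = {}
            for p in sorted(sub.protein_id.unique()):
                for s in ("s1", "s2"):
                    acc = 0.0
                    for f in ("f1", "f2", "f3"):
                        col = sub[(sub["sample"] == s) & (sub.fraction == f)]
                        val = col[col.protein_id == p].intensity.sum()
                        acc += val / col.intensity.sum()
                    totals[(p, s)] = acc
            med = np.median([v for v in totals.values() if v > 0])
            for (p, s), v in totals.items():
                assert out[(p, e, s)] == pytest.approx(v / med)

    def test_preserves_within_fraction_rank_order(self, rng):
        vals = rng.uniform(0, 10, size=8)
        rows = [
            (f"p{i}", "e1", "s1", "f1", "bait_A", v) for i, v in enumerate(vals)
        ]
        out = normalize_intensities(_long_table(rows)).set_index("protein_id")
        order_in = np.argsort(vals)
        order_out = np.argsort(out.loc[[f"p{i}" for i in range(8)], "total"].values)
        np.testing.assert_array_equal(order_in, order_out)

    def test_all_zero_table_rejected(self):
        t = _long_table([("p1", "e1", "s1", "f1", "vector_control", 0.0)])
        with pytest.raises(ValueError):
            normalize_intensities(t)

    def test_zero_total_fraction_dropped_with_warning(self):
        t = _long_table(
            [
                ("p1", "e1", "s1", "f1", "bait_A", 4.0),
                ("p1", "e1", "s1", "f2", "bait_A", 0.0),
                ("p2", "e1", "s1", "f2", "bait_A", 0.0),
            ]
        )
        with pytest.warns(UserWarning, match="zero total"):
            out = normalize_intensities(t)
        assert out.shape[0] == 1


class TestEpanechnikovNull:
    def test_compact_support_limits(self):
        kde = epanechnikov_null([1.0, 2.0, 3.0], bandwidth=0.5)
        assert kde.cdf(1.0 - 0.5 - 1e-9) == 0.0
        assert kde.cdf(3.0 + 0.5 + 1e-9) == 1.0

    def test_symmetry_center_is_half(self):
        kde = epanechnikov_null([-1.0, 0.0, 1.0], bandwidth=0.7)
        assert kde.cdf(0.0) == pytest.approx(0.5)

    def test_two_point_example(self):
        # {0, 2}, h=1: at x=0 the first kernel contributes 1/2, the second 0
        kde = epanechnikov_null([0.0, 2.0], bandwidth=1.0)
        assert kde.cdf(0.0) == pytest.approx(0.25)

    def test_cdf_monotone_on_dense_grid(self, rng):
        kde = epanechnikov_null(rng.normal(size=40))
        grid = np.linspace(-5, 5, 2001)
        diffs = np.diff(kde.cdf(grid))
        assert np.all(diffs >= -1e-12)

    def test_density_integrates_to_one(self, rng):
        kde = epanechnikov_null(rng.normal(size=25))
        lo = kde.support.min() - kde.bandwidth
        hi = kde.support.max() + kde.bandwidth
        result = integrate.quad(lambda x: kde.pdf(x), lo, hi, limit=200,
                                full_output=1)
        assert result[0] == pytest.approx(1.0, abs=1e-6)

    def test_density_matches_sklearn_kernel_density(self, rng):
        from sklearn.neighbors import KernelDensity

        x = rng.normal(size=30)
        h = 0.6
        kde = EpanechnikovKDE(x, bandwidth=h)
        sk = KernelDensity(kernel="epanechnikov", bandwidth=h).fit(x[:, None])
        grid = np.linspace(-3, 3, 50)
        np.testing.assert_allclose(
            kde.pdf(grid), np.exp(sk.score_samples(grid[:, None])), atol=1e-10
        )

    def test_insufficient_values_rejected(self):
        with pytest.raises(ValueError):
            epanechnikov_null([1.0])


class TestCallInteractors:
    def test_value_beyond_support_is_floored(self):
        rows = []
        for p in range(50):
            rows.append((f"p{p:02d}", "e1", "s1", "f1", "vector_control", 10.0 + p))
            rows.append((f"p{p:02d}", "e1", "s2", "f1", "bait_A",
                         10.0 + p if p else 1e5))
        totals = normalize_intensities(_long_table(rows))
        calls = call_interactors(totals, "bait_A").set_index("protein_id")
        assert calls.loc["p00", "p_raw"] == pytest.approx(1.0 / 51)

    def test_null_calibration_uniform_p(self):
        table, _ = gen_lfq_table(n_proteins=500, n_spiked=0, seed=2)
        calls = call_interactors(normalize_intensities(table), "bait_A")
        ks = stats.kstest(calls["p_raw"], "uniform").statistic
        assert ks < 0.1
        assert abs((calls["p_raw"] < 0.05).mean() - 0.05) <= 0.03

    def test_spiked_recall_and_fdr(self):
        table, truth = gen_lfq_table(
            n_proteins=200, n_spiked=10, spike_fold=8.0, pi_zero=0.3, seed=1
        )
        calls = call_interactors(normalize_intensities(table), "bait_A")
        m = calls.merge(truth, on="protein_id")
        tp = int((m.spiked & m.significant).sum())
        fp = int((~m.spiked & m.significant).sum())
        assert tp / 10 >= 0.8
        assert fp / max(tp + fp, 1) <= 0.1

    def test_significance_flag_matches_thresholds(self):
        table, _ = gen_lfq_table(n_proteins=50, n_spiked=5, seed=4)
        calls = call_interactors(normalize_intensities(table), "bait_A")
        expected = (calls.mean_pseudolog2_fc > 0.5) & (calls.p_adj <= 0.05)
        pd.testing.assert_series_equal(
            calls.significant, expected, check_names=False
        )

    def test_pooled_path_also_calibrated(self):
        table, _ = gen_lfq_table(n_proteins=400, n_spiked=0, seed=6)
        calls = call_interactors(
            normalize_intensities(table), "bait_A", combine="pooled"
        )
        assert stats.kstest(calls["p_raw"], "uniform").statistic < 0.1


class TestBHAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_and_degenerate(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])
        np.testing.assert_allclose(bh_adjust([1.0, 1.0]), [1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @pytest.mark.parametrize(
        "base",
        [
            (0.001, 0.01, 0.02, 0.8),
            (0.04, 0.04, 0.04, 0.2, 0.9),
            (0.5, 0.01, 0.03, 0.02, 0.9, 1.0),
        ],
    )
    def test_equals_brute_force_on_all_permutations(self, base):
        def brute(p):
            p = np.asarray(p)
            n = len(p)
            order = np.argsort(p, kind="stable")
            adj = np.empty(n)
            running = np.inf
            for rank in range(n, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * n / rank)
                adj[i] = running
            return np.minimum(adj, 1.0)

        for perm in itertools.permutations(base):
            np.testing.assert_allclose(bh_adjust(list(perm)), brute(perm))


class TestBinaryClassEnrichment:
    @staticmethod
    def _presence(k_a, m_a, k_b, m_b):
        cols = {f"a{i}": [1 if i < k_a else 0] for i in range(m_a)}
        cols.update({f"b{i}": [1 if i < k_b else 0] for i in range(m_b)})
        labels = {f"a{i}": "A" for i in range(m_a)}
        labels.update({f"b{i}": "B" for i in range(m_b)})
        return pd.DataFrame(cols, index=["prey"]), labels

    def test_six_of_six_versus_zero(self):
        pres, labels = self._presence(6, 6, 0, 6)
        row = binary_class_enrichment(pres, labels).iloc[0]
        assert row.ratio_A == np.inf
        assert row.p_A == pytest.approx(0.015625)
        assert row.specific == "A"

    def test_equal_presence_not_specific(self):
        pres, labels = self._presence(3, 6, 3, 6)
        assert binary_class_enrichment(pres, labels).iloc[0].specific is None

    def test_five_fold_but_insignificant(self):
        pres, labels = self._presence(5, 5, 1, 5)
        row = binary_class_enrichment(pres, labels).iloc[0]
        assert row.ratio_A == pytest.approx(5.0)
        assert row.p_A == pytest.approx(7 / 64)
        assert row.specific is None

    def test_label_swap_symmetry(self, rng):
        pres = pd.DataFrame(
            rng.integers(0, 2, size=(30, 10)),
            columns=[f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)],
            index=[f"prey{i}" for i in range(30)],
        )
        labels = {f"a{i}": "A" for i in range(5)}
        labels.update({f"b{i}": "B" for i in range(5)})
        swapped = {k: ("B" if v == "A" else "A") for k, v in labels.items()}
        r1 = binary_class_enrichment(pres, labels).set_index("protein_id")
        r2 = binary_class_enrichment(pres, swapped).set_index("protein_id")
        sel1a = set(r1[r1.specific == "A"].index)
        sel2b = set(r2[r2.specific == "B"].index)
        assert sel1a == sel2b

    def test_absent_protein_excluded(self):
        pres, labels = self._presence(0, 3, 0, 3)
        assert binary_class_enrichment(pres, labels).empty

    def test_single_class_rejected(self):
        pres, _ = self._presence(2, 3, 1, 3)
        with pytest.raises(ValueError):
            binary_class_enrichment(pres, {c: "A" for c in pres.columns})


class TestStrictPresenceFilter:
    def test_control_hit_excluded(self):
        out = strict_presence_filter(
            {"line1": {"x", "y"}}, {"line1": {"y"}}
        )
        assert out == {"x"}

    def test_intersection_across_groups(self):
        cond = {"l1": {"x", "y"}, "l2": {"x"}, "l3": {"x", "z"}}
        ctrl = {"l1": set(), "l2": set(), "l3": set()}
        assert strict_presence_filter(cond, ctrl) == {"x"}

    def test_matches_set_algebra_oracle(self, rng):
        universe = [f"p{i}" for i in range(30)]
        cond, ctrl = {}, {}
        for g in ("g1", "g2", "g3"):
            cond[g] = {p for p in universe if rng.random() < 0.5}
            ctrl[g] = {p for p in universe if rng.random() < 0.3}
        expected = set(universe)
        for g in cond:
            expected &= cond[g] - ctrl[g]
        assert strict_presence_filter(cond, ctrl) == expected

    def test_empty_groups_rejected(self):
        with pytest.raises(ValueError):
            strict_presence_filter({}, {})


class TestOverlapSignificance:
    def test_observed_at_mean_gives_half(self, rng):
        res = rng.normal(10, 2, size=30)
        p = annotation_overlap_significance(res.mean(), res, tail="lower")
        assert p == pytest.approx(0.5)

    def test_three_sigma_lower_tail(self, rng):
        res = rng.normal(10, 2, size=30)
        mu, sd = res.mean(), res.std(ddof=1)
        p = annotation_overlap_significance(mu - 3 * sd, res, tail="lower")
        assert p == pytest.approx(stats.norm.cdf(-3), rel=1e-6)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            annotation_overlap_significance(1.0, [2.0, 2.0, 2.0])

    def test_chi_square_diagonal_table(self):
        stat, p = chi_square_overlap([[10, 0], [0, 10]])
        assert stat == pytest.approx(20.0)
        assert p < 0.001
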