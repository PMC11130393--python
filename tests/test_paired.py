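"""Paired statistic: null construction, PSM binning, calibration, rates, DE."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from tmtprofiler import (
    PairedExpressionModel,
    build_null,
    expression_rates,
    export_signatures,
    pooled_differential_expression,
    psm_bin,
    sample_statistic,
)
from tmtprofiler.paired import NullDistribution, mean_fold_change, rate_dispersion
from conftest import make_matrix


def _sheet_with_pairs(n_pairs, set_id="s1", extra_normals=0):
    rows = []
    for i in range(n_pairs):
        rows.append((f"T{i}", f"PT{i}", set_id, f"ch{2*i}", "tumor", f"pr{i}", "", 1.0, 1))
        rows.append((f"N{i}", f"PT{i}", set_id, f"ch{2*i+1}", "normal", f"pr{i}", "", 1.0, 1))
    for j in range(extra_normals):
        rows.append((f"X{j}", f"PX{j}", set_id, f"chx{j}", "normal", "", "", 1.0, 1))
    rows.append((f"REF_{set_id}", "POOL", set_id, "134N", "reference", "", "", 1.0, 0))
    return pd.DataFrame(rows, columns=["sample_id", "patient_id", "set_id", "channel",
                                       "tissue", "pair_id", "subset_label", "time",
                                       "event"])


class TestBuildNull:
    def test_identical_normals_give_zero_null(self):
        sheet = _sheet_with_pairs(3)
        df = pd.DataFrame(2.0, index=[f"P{i}" for i in range(5)],
                          columns=[s for s in sheet.sample_id if s != "REF_s1"])
        null = build_null(make_matrix(df, set_id="s1"), sheet, "N0")
        assert len(null) == 2 * 5
        assert np.allclose(null.values, 0.0)

    def test_size_three_normals_ten_proteins(self):
        sheet = _sheet_with_pairs(3)
        rng = np.random.default_rng(0)
        cols = [s for s in sheet.sample_id if s != "REF_s1"]
        df = pd.DataFrame(np.exp2(rng.normal(0, 1, (10, len(cols)))),
                          index=[f"P{i}" for i in range(10)], columns=cols)
        for n in ["N0", "N1", "N2"]:
            assert len(build_null(make_matrix(df, set_id="s1"), sheet, n)) == (3 - 1) * 10

    def test_matches_brute_force_double_loop(self):
        sheet = _sheet_with_pairs(4)
        rng = np.random.default_rng(1)
        cols = [s for s in sheet.sample_id if s != "REF_s1"]
        vals = np.exp2(rng.normal(0, 1, (8, len(cols))))
        vals[rng.random((8, len(cols))) < 0.2] = np.nan
        df = pd.DataFrame(vals, index=[f"P{i}" for i in range(8)], columns=cols)
        matrix = make_matrix(df, set_id="s1")
        null = build_null(matrix, sheet, "N1")
        expected = []
        for h in ["N0", "N2", "N3"]:
            for p in df.index:
                xi, xh = df.loc[p, "N1"], df.loc[p, h]
                if np.isfinite(xi) and np.isfinite(xh):
                    expected.append(np.log2(xi) - np.log2(xh))
        assert sorted(np.round(null.values, 12)) == sorted(np.round(expected, 12))

    def test_single_normal_in_set_is_an_error(self):
        sheet = _sheet_with_pairs(1)
        df = pd.DataFrame(1.0, index=["P0"], columns=["T0", "N0"])
        with pytest.raises(ValueError, match="no other normal"):
            build_null(make_matrix(df, set_id="s1"), sheet, "N0")

    def test_tumor_sample_rejected(self):
        sheet = _sheet_with_pairs(2)
        df = pd.DataFrame(1.0, index=["P0"], columns=["T0", "N0", "T1", "N1"])
        with pytest.raises(ValueError, match="not a normal"):
            build_null(make_matrix(df, set_id="s1"), sheet, "T0")


class TestPsmBin:
    def test_p4_keeps_strict_interior(self):
        tags = np.array([2, 3, 4, 5, 6, 7, 8])
        vals = tags.astype(float)
        kept = psm_bin(vals, 4, tags=tags)
        assert sorted(kept) == [3, 4, 5, 6, 7]

    def test_p1_keeps_only_p1(self):
        tags = np.array([1, 2, 3])
        kept = psm_bin(np.array([10.0, 20.0, 30.0]), 1, tags=tags)
        assert list(kept) == [10.0]

    def test_exhaustive_indicator_grid(self):
        # strict double inequality p_j/2 < p < 2 p_j on the full 1..50 grid
        for p_j in range(1, 51):
            tags = np.arange(1, 51)
            kept = set(psm_bin(tags.astype(float), p_j, tags=tags).astype(int))
            expected = {p for p in range(1, 51) if 0.5 * p_j < p < 2 * p_j}
            assert kept == expected
            assert p_j in kept  # B(p_j, p_j) = 1 always

    @given(p_j=st.integers(1, 40), widen=st.floats(1.0, 3.0))
    @settings(max_examples=50, deadline=None)
    def test_widening_bounds_never_removes_values(self, p_j, widen):
        tags = np.arange(1, 101)
        narrow = set(psm_bin(tags.astype(float), p_j, tags=tags))
        wide = set(psm_bin(tags.astype(float), p_j, lower=0.5 / widen,
                           upper=2.0 * widen, tags=tags))
        assert narrow <= wide


class TestSampleStatistic:
    def test_zero_ratio_gives_half(self):
        _, p = sample_statistic(0.0, np.array([-1.0, 0.5, 1.0, -0.5, 0.2]))
        assert p == pytest.approx(0.5)

    def test_criticial_value_gives_alpha(self):
        null = np.array([-1.0, 1.0, -1.0, 1.0, -1.0, 1.0])  # sd ~ 1.095
        sd = np.std(null, ddof=1)
        a_t, p = sample_statistic(1.6449 * sd, null)
        assert a_t == pytest.approx(1.6449, rel=1e-6)
        assert p == pytest.approx(0.05, abs=1e-4)

    def test_hand_computed_example(self):
        # null {-1, 1}: sd (ddof=1) = sqrt(2); a = 2.828 -> a_tilde = 2.0
        a_t, p = sample_statistic(2.828, np.array([-1.0, 1.0]))
        assert a_t == pytest.approx(2.0, abs=1e-3)
        assert p == pytest.approx(1 - stats.norm.cdf(2.0), abs=1e-4)
        assert p == pytest.approx(0.0228, abs=1e-4)

    def test_zero_sd_is_undefined_not_significant(self):
        a_t, p = sample_statistic(3.0, np.array([1.0, 1.0, 1.0]))
        assert np.isnan(a_t) and np.isnan(p)

    def test_pvalue_monotone_in_magnitude(self):
        null = np.random.default_rng(2).normal(0, 1, 50)
        ps = [sample_statistic(a, null)[1] for a in np.linspace(0, 4, 9)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_pvalue_range(self):
        null = np.random.default_rng(3).normal(0, 1, 30)
        for a in (-5.0, -0.1, 0.0, 0.1, 5.0):
            _, p = sample_statistic(a, null)
            assert 0.0 < p <= 0.5


class TestProfileCohort:
    def _cohort(self, seed=3, effect=2.0, noise=0.25):
        from tmtprofiler import CohortSpec, preprocess_cohort, simulate_cohort

        spec = CohortSpec(n_sets=3, channels_per_set=13, n_proteins=120,
                          common_core_fraction=0.4, n_subtypes=2, signature_size=8,
                          signature_effect=effect, noise_sd=noise, seed=seed)
        psms, sheet, truth = simulate_cohort(spec)
        matrix, _ = preprocess_cohort(psms, sheet)
        return matrix, sheet, truth

    def test_signature_proteins_called_in_planted_direction(self):
        matrix, sheet, truth = self._cohort()
        res = PairedExpressionModel(matrix, sheet).fit()
        prof = res.profiles.set_index(["sample_id", "protein_id"])
        truth_calls = truth.true_calls_frame()
        checked = hits = 0
        for row in truth_calls.itertuples():
            key = (row.sample_id, row.protein_id)
            if key in prof.index:
                checked += 1
                hits += prof.loc[key, "call"] == row.call
        assert checked > 50
        assert hits / checked >= 0.95

    def test_negating_paired_ratios_swaps_calls_exactly(self):
        matrix, sheet, _ = self._cohort(seed=4)
        res = PairedExpressionModel(matrix, sheet).fit()
        # replace each tumor column t by n^2 / t: a -> -a while every null
        # distribution (built from normal samples only) stays identical
        neg = matrix.copy()
        pairs = sheet[sheet.pair_id != ""].groupby("pair_id").sample_id.apply(list)
        info = sheet.set_index("sample_id")
        for members in pairs:
            t = [m for m in members if info.loc[m, "tissue"] == "tumor"][0]
            n = [m for m in members if m != t][0]
            if t in neg.ratios.columns and n in neg.ratios.columns:
                neg.ratios[t] = neg.ratios[n] ** 2 / neg.ratios[t]
        res_neg = PairedExpressionModel(neg, sheet).fit()
        a = res.profiles.set_index(["sample_id", "protein_id"])
        b = res_neg.profiles.set_index(["sample_id", "protein_id"])
        common = a.index.intersection(b.index)
        assert len(common) > 100
        swap = {"over": "under", "under": "over", "none": "none"}
        assert (b.loc[common, "call"] == a.loc[common, "call"].map(swap)).all()
        assert np.allclose(b.loc[common, "a"], -a.loc[common, "a"], atol=1e-9)

    def test_protein_missing_from_pair_has_no_row(self):
        matrix, sheet, _ = self._cohort(seed=5)
        # knock a protein out of one tumor sample
        tumor = [s for s in matrix.ratios.columns if s.startswith("T")][0]
        prot = matrix.ratios.index[0]
        matrix.ratios.loc[prot, tumor] = np.nan
        res = PairedExpressionModel(matrix, sheet).fit()
        sub = res.profiles[(res.profiles.sample_id == tumor) &
                           (res.profiles.protein_id == prot)]
        assert len(sub) == 0


class TestRates:
    def _profiles(self):
        rows = [
            ("S1", "PA", 1.0, 2.0, 0.02, "over", 10),
            ("S2", "PA", 0.5, 1.0, 0.16, "none", 10),
            ("S3", "PA", -1.2, -2.4, 0.008, "under", 10),
            ("S4", "PA", 0.1, 0.2, 0.42, "none", 10),
            ("S1", "PB", 0.0, 0.0, 0.5, "none", 10),
            ("S2", "PB", 0.2, 0.4, 0.34, "none", 10),
        ]
        df = pd.DataFrame(rows, columns=["sample_id", "protein_id", "a", "a_tilde",
                                         "pvalue", "call", "null_size"])
        df["fold_change"] = np.exp2(df.a)
        return df

    def test_quarter_rate(self):
        grouping = pd.Series("g1", index=["S1", "S2", "S3", "S4"])
        rates = expression_rates(self._profiles(), grouping)
        assert rates.loc[("PA", "g1"), "over_rate"] == pytest.approx(0.25)
        assert rates.loc[("PA", "g1"), "under_rate"] == pytest.approx(0.25)
        assert rates.loc[("PA", "g1"), "n_evaluable"] == 4

    def test_never_called_protein_has_zero_rates(self):
        grouping = pd.Series("g1", index=["S1", "S2", "S3", "S4"])
        rates = expression_rates(self._profiles(), grouping)
        assert rates.loc[("PB", "g1"), "over_rate"] == 0.0
        assert rates.loc[("PB", "g1"), "under_rate"] == 0.0

    def test_rates_match_brute_force_counting(self):
        rng = np.random.default_rng(6)
        samples = [f"S{i}" for i in range(30)]
        rows = []
        for s in samples:
            for p in ["PA", "PB", "PC"]:
                call = rng.choice(["over", "under", "none"], p=[0.2, 0.1, 0.7])
                rows.append((s, p, 0.0, 0.0, 0.01 if call != "none" else 0.4, call, 5))
        prof = pd.DataFrame(rows, columns=["sample_id", "protein_id", "a", "a_tilde",
                                           "pvalue", "call", "null_size"])
        prof["fold_change"] = 1.0
        grouping = pd.Series([f"g{i % 3}" for i in range(30)], index=samples)
        rates = expression_rates(prof, grouping)
        for (p, g), row in rates.iterrows():
            members = [s for s in samples if grouping[s] == g]
            sub = prof[(prof.protein_id == p) & (prof.sample_id.isin(members))]
            assert row.over_rate == pytest.approx((sub.call == "over").mean())
            assert row.n_evaluable == len(sub)

    def test_dispersion_zero_for_identical_rates(self):
        idx = pd.MultiIndex.from_product([["PA"], ["g1", "g2"]],
                                         names=["protein_id", "group"])
        rates = pd.DataFrame({"n_evaluable": 4, "over_rate": 0.4, "under_rate": 0.0},
                             index=idx)
        assert rate_dispersion(rates)["PA"] == pytest.approx(0.0)

    def test_dispersion_population_convention(self):
        idx = pd.MultiIndex.from_product([["PA"], ["g1", "g2"]],
                                         names=["protein_id", "group"])
        rates = pd.DataFrame({"n_evaluable": 4, "over_rate": [0.0, 1.0],
                              "under_rate": 0.0}, index=idx)
        assert rate_dispersion(rates)["PA"] == pytest.approx(0.25)

    def test_dispersion_matches_numpy_variance(self):
        rng = np.random.default_rng(7)
        groups = [f"g{i}" for i in range(5)]
        idx = pd.MultiIndex.from_product([["PA", "PB"], groups],
                                         names=["protein_id", "group"])
        rates = pd.DataFrame({"n_evaluable": 4,
                              "over_rate": rng.random(10),
                              "under_rate": 0.0}, index=idx)
        out = rate_dispersion(rates)
        for p in ["PA", "PB"]:
            assert out[p] == pytest.approx(np.var(rates.over_rate[p].to_numpy()))

    def test_mean_fold_change_over_called_samples(self):
        prof = self._profiles()
        mfc = mean_fold_change(prof)
        expected = np.mean([2.0 ** 1.0, 2.0 ** -1.2])
        assert mfc["PA"] == pytest.approx(expected)
        assert "PB" not in mfc.index


class TestPooledDifferentialExpression:
    def _matrix(self, seed=8, shift=0.0, n=40):
        rng = np.random.default_rng(seed)
        a = np.exp2(rng.normal(0, 0.5, (n, 10)))
        b = np.exp2(rng.normal(shift, 0.5, (n, 10)))
        df = pd.DataFrame(np.hstack([a, b]),
                          index=[f"P{i:02d}" for i in range(n)],
                          columns=[f"A{i}" for i in range(10)] + [f"B{i}" for i in range(10)])
        return make_matrix(df)

    def test_identical_groups_yield_no_discoveries(self):
        m = self._matrix()
        out = pooled_differential_expression(m, [f"A{i}" for i in range(10)],
                                             [f"B{i}" for i in range(10)])
        assert (out.qvalue < 0.05).sum() == 0
        assert (out.qvalue >= out.pvalue - 1e-12).all()

    def test_complete_separation_reaches_minimal_ranksum_p(self):
        m = self._matrix()
        # completely separated, tie-free values; 8 vs 8 keeps the rank-sum
        # null exact, where the minimal two-sided p is 2 / C(16, 8)
        m.ratios.loc["P00", [f"A{i}" for i in range(8)]] = 100.0 + np.arange(8)
        m.ratios.loc["P00", [f"B{i}" for i in range(8)]] = 0.01 + 0.001 * np.arange(8)
        out = pooled_differential_expression(m, [f"A{i}" for i in range(8)],
                                             [f"B{i}" for i in range(8)])
        p_min = 2.0 / 12870
        assert out.loc["P00", "pvalue"] == pytest.approx(p_min, rel=1e-6)
        assert out.pvalue.idxmin() == "P00"
        assert out.loc["P00", "qvalue"] < 0.05

    def test_coverage_filter(self):
        m = self._matrix()
        m.ratios.loc["P01"] = np.nan
        m.ratios.loc["P01", ["A0", "A1"]] = 1.0  # 10% coverage
        out = pooled_differential_expression(m, [f"A{i}" for i in range(10)],
                                             [f"B{i}" for i in range(10)],
                                             coverage=0.2)
        assert "P01" not in out.index

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            pooled_differential_expression(self._matrix(), [], ["B0"])


class TestExportSignatures:
    def _profiles(self, n_over=30, sample="S1"):
        rng = np.random.default_rng(9)
        rows = []
        for i in range(n_over):
            rows.append((sample, f"P{i:02d}", 1.0, 2.0, rng.uniform(1e-5, 0.04),
                         "over", 10))
        df = pd.DataFrame(rows, columns=["sample_id", "protein_id", "a", "a_tilde",
                                         "pvalue", "call", "null_size"])
        df["fold_change"] = 2.0
        return df

    def _corr(self, features, rho=0.9):
        return pd.DataFrame({"feature": features, "rho": rho})

    def test_no_calls_sample_skipped(self):
        prof = self._profiles()
        prof["call"] = "none"
        out = export_signatures(prof, self._corr(prof.protein_id.unique()))
        assert out == {}

    def test_low_correlation_filters_everything(self):
        prof = self._profiles()
        out = export_signatures(prof, self._corr(prof.protein_id.unique(), rho=0.5))
        assert out == {}

    def test_cap_keeps_smallest_pvalues(self):
        prof = self._profiles(n_over=30)
        out = export_signatures(prof, self._corr(prof.protein_id.unique()), cap=10)
        up, down = out["S1"]
        assert len(up) == 10 and down == []
        expected = prof.nsmallest(10, "pvalue").protein_id.tolist()
        assert up == expected
        assert set(up).isdisjoint(down)
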