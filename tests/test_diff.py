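"""Differential-activation statistic: normalization, SD trend, z-scores,
empirical-Bayes lfdr, calling, and mark intersection."""

import math

import numpy as np
import pandas as pd
import pytest

from ecdna_regulome import (
    CountTable,
    GenomicInterval,
    PeakSet,
    ValidationError,
    call_differential,
    common_peaks,
    fit_sd_trend,
    intersect_marks,
    lfdr,
    normalize,
    rle_size_factors,
    top_percentile_subset,
    zscores,
)
from ecdna_regulome.diff import MeanSDTrend
from conftest import brute_force_overlap_names, random_peakset


def _table(counts: np.ndarray, samples=None, conditions=None) -> CountTable:
    n_p, n_s = counts.shape
    samples = samples or [f"s{i}" for i in range(n_s)]
    conditions = conditions or (
        ["vehicle"] * (n_s // 2) + ["treated"] * (n_s - n_s // 2)
    )
    meta = pd.DataFrame(
        {"condition": conditions,
         "replicate": list(range(1, n_s + 1))},
        index=pd.Index(samples, name="sample"),
    )
    return CountTable(
        counts=pd.DataFrame(
            counts.astype(float),
            index=[f"peak_{i}" for i in range(n_p)], columns=samples,
        ),
        meta=meta,
    )


class TestTopPercentile:
    def test_top_30_of_ten_values(self):
        counts = np.column_stack([np.arange(1, 11)] * 2)
        table = _table(counts)
        subset = top_percentile_subset(table, q=0.30)
        values = sorted(table.counts.loc[subset, "s0"])
        assert values == [8, 9, 10]

    def test_identical_rankings_match_single_sample(self):
        vals = np.arange(1, 11)
        one = top_percentile_subset(_table(np.column_stack([vals, vals])))
        four = top_percentile_subset(
            _table(np.column_stack([vals, vals, vals, vals]))
        )
        assert set(one) == set(four)

    def test_anticorrelated_samples_intersection_oracle(self):
        rng = np.random.default_rng(0)
        a = rng.permutation(100).astype(float)
        b = 99 - a  # perfectly anti-correlated ranking
        table = _table(np.column_stack([a, b]))
        subset = set(top_percentile_subset(table, q=0.60))
        # explicit per-sample quantile + set intersection oracle
        per_sample = []
        for col in table.counts.columns:
            v = table.counts[col]
            thr = np.sort(v)[-60]
            per_sample.append(set(v.index[v >= thr]))
        assert subset == per_sample[0] & per_sample[1]
        assert len(subset) < min(len(s) for s in per_sample)

    def test_empty_intersection_is_error(self):
        a = np.array([10.0, 1, 1, 1, 1, 1, 1, 1, 1, 1])
        b = a[::-1].copy()
        with pytest.raises(ValidationError, match="increase q"):
            top_percentile_subset(_table(np.column_stack([a, b])), q=0.1)


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = np.tile(np.arange(10, 20.0)[:, None], (1, 4))
        table = _table(counts)
        f = rle_size_factors(table, table.peaks)
        assert np.allclose(f, 1.0)

    def test_doubled_sample_hand_computed(self):
        # B = 2*A on every peak -> factors (2^-1/2, 2^1/2)
        a = np.arange(10, 20.0)
        table = _table(np.column_stack([a, 2 * a]))
        f = rle_size_factors(table, table.peaks)
        assert f.iloc[0] == pytest.approx(2 ** -0.5, rel=1e-12)
        assert f.iloc[1] == pytest.approx(2 ** 0.5, rel=1e-12)

    def test_geometric_mean_is_one(self, small_table):
        f = rle_size_factors(small_table, small_table.peaks)
        assert np.exp(np.log(f).mean()) == pytest.approx(1.0, abs=1e-9)

    def test_scale_equivariance(self, small_table):
        f0 = rle_size_factors(small_table, small_table.peaks)
        scaled = small_table.counts.copy()
        lam = 3.0
        scaled["v1"] *= lam
        table2 = CountTable(counts=scaled, meta=small_table.meta)
        f1 = rle_size_factors(table2, table2.peaks)
        # factor of the scaled sample rises by lambda, up to the
        # geometric-mean renormalization lambda^(1/n)
        n = len(f0)
        assert f1["v1"] / f0["v1"] == pytest.approx(
            lam / lam ** (1 / n), rel=1e-9
        )

    def test_all_zero_subset_is_error(self):
        counts = np.ones((10, 2))
        counts[0, 0] = 0.0
        table = _table(counts)
        with pytest.raises(ValidationError):
            rle_size_factors(table, ["peak_0"])


class TestNormalize:
    def test_unit_factors_identity(self, small_table):
        f = pd.Series(1.0, index=small_table.samples)
        assert normalize(small_table, f).equals(small_table.counts)

    def test_division_and_round_trip(self, small_table):
        f = pd.Series([2.0, 1.0, 0.5, 1.25], index=small_table.samples)
        norm = normalize(small_table, f)
        assert norm.iloc[0, 0] == small_table.counts.iloc[0, 0] / 2.0
        assert np.allclose(norm * f, small_table.counts)

    def test_nonpositive_factor_rejected(self, small_table):
        f = pd.Series([1.0, 1.0, -1.0, 1.0], index=small_table.samples)
        with pytest.raises(ValidationError):
            normalize(small_table, f)


class TestSdTrend:
    @staticmethod
    def _proportional_sd_data(n=500, n_samples=4, factor=0.1):
        """Noiseless construction with SD exactly factor*mean: each peak's
        samples are m*(1 + factor*c) for centered unit-SD offsets c."""
        m = np.linspace(10, 1000, n)
        c = np.array([-1.5, -0.5, 0.5, 1.5])
        c = (c - c.mean()) / c.std(ddof=1)
        x = m[:, None] * (1 + factor * c[None, :])
        return pd.DataFrame(x, index=[f"p{i}" for i in range(n)],
                            columns=[f"s{j}" for j in range(n_samples)])

    def test_recovers_proportional_trend(self):
        norm = self._proportional_sd_data()
        trend = fit_sd_trend(norm)
        m = np.linspace(10, 1000, 200)
        lo, hi = np.percentile(m, [10, 90])
        central = m[(m >= lo) & (m <= hi)]
        rel = np.abs(trend(central) / (0.1 * central) - 1)
        assert rel.max() <= 0.05

    def test_flat_trend(self):
        rng = np.random.default_rng(1)
        m = rng.uniform(10, 1000, size=300)
        c = np.array([-1.5, -0.5, 0.5, 1.5])
        c = (c - c.mean()) / c.std(ddof=1)
        x = m[:, None] + 2.0 * c[None, :]  # SD exactly 2 everywhere
        norm = pd.DataFrame(x, index=[f"p{i}" for i in range(300)],
                            columns=list("abcd"))
        trend = fit_sd_trend(norm)
        assert np.allclose(trend(np.linspace(50, 950, 50)), 2.0, rtol=1e-6)

    def test_constant_extrapolation_below_range(self):
        norm = self._proportional_sd_data()
        trend = fit_sd_trend(norm)
        m_min = norm.mean(axis=1).min()
        assert trend(m_min - 100) == pytest.approx(trend(m_min))
        assert trend(-1e9) == pytest.approx(trend(m_min))

    def test_positive_floor(self):
        norm = self._proportional_sd_data(factor=1e-9)
        trend = fit_sd_trend(norm)
        assert trend.sd_floor > 0
        assert (trend.fitted >= trend.sd_floor).all()

    def test_degenerate_means_rejected(self):
        x = np.ones((50, 4)) * 5
        norm = pd.DataFrame(x, columns=list("abcd"))
        with pytest.raises(ValidationError):
            fit_sd_trend(norm)


def _unit_trend() -> MeanSDTrend:
    return MeanSDTrend(grid=np.array([0.0, 1e6]),
                       fitted=np.array([1.0, 1.0]), sd_floor=1.0)


class TestZScores:
    def test_closed_form(self):
        # sigma = 1, n1 = n2 = 2, group means 3 and 1 -> z = 2
        norm = pd.DataFrame(
            [[1.0, 1.0, 3.0, 3.0]], index=["p"],
            columns=["c1", "c2", "t1", "t2"],
        )
        z = zscores(norm, _unit_trend(), ["c1", "c2"], ["t1", "t2"])
        assert z["p"] == pytest.approx(2.0 / math.sqrt(0.5 + 0.5))

    def test_equal_means_zero(self):
        norm = pd.DataFrame(
            [[5.0, 7.0, 7.0, 5.0]], index=["p"],
            columns=["c1", "c2", "t1", "t2"],
        )
        z = zscores(norm, _unit_trend(), ["c1", "c2"], ["t1", "t2"])
        assert z["p"] == 0.0

    def test_swapping_groups_negates(self, small_table):
        f = rle_size_factors(small_table, small_table.peaks)
        norm = normalize(small_table, f)
        trend = _unit_trend()
        z1 = zscores(norm, trend, ["v1", "v2"], ["t1", "t2"])
        z2 = zscores(norm, trend, ["t1", "t2"], ["v1", "v2"])
        assert np.allclose(z1, -z2)

    def test_invariant_to_joint_rescaling(self):
        rng = np.random.default_rng(3)
        norm = pd.DataFrame(
            rng.uniform(10, 100, size=(40, 4)),
            columns=["c1", "c2", "t1", "t2"],
        )
        lam = 7.0
        t1 = MeanSDTrend(grid=np.array([0.0, 1e6]),
                         fitted=np.array([2.0, 2.0]), sd_floor=2.0)
        t2 = MeanSDTrend(grid=np.array([0.0, 1e6 * lam]),
                         fitted=np.array([2.0 * lam, 2.0 * lam]),
                         sd_floor=2.0 * lam)
        z1 = zscores(norm, t1, ["c1", "c2"], ["t1", "t2"])
        z2 = zscores(norm * lam, t2, ["c1", "c2"], ["t1", "t2"])
        assert np.allclose(z1, z2)


class TestLfdr:
    def test_pure_null_theoretical(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=5000)
        lf, null = lfdr(z, null_mode="theoretical")
        assert null.delta == 0.0 and null.sigma0 == 1.0
        assert np.median(lf) >= 0.9
        assert (lf < 0.3).mean() <= 0.02

    def test_mixture_tail_is_significant(self):
        # 0.9*N(0,1) + 0.1*N(4,1): the z>3 tail is dominated by the
        # alternative; true lfdr(3) = 0.9*phi(3)/f(3) ~ 0.37 and drops
        # fast, so the mean over the tail must be < 0.3
        rng = np.random.default_rng(1)
        z = np.concatenate(
            [rng.normal(size=4500), rng.normal(4.0, 1.0, size=500)]
        )
        lf, null = lfdr(z, null_mode="empirical")
        assert lf[z > 3].mean() < 0.3
        assert 0.8 <= null.sigma0 <= 1.2
        assert abs(null.delta) < 0.3

    def test_values_clamped_to_unit_interval(self):
        rng = np.random.default_rng(2)
        z = np.concatenate([rng.normal(size=300),
                            rng.uniform(-8, 8, size=100)])
        lf, _ = lfdr(z, null_mode="theoretical")
        assert (lf >= 0).all() and (lf <= 1).all()

    def test_empirical_needs_enough_values(self):
        with pytest.raises(ValidationError):
            lfdr(np.zeros(50), null_mode="empirical")

    def test_series_index_preserved(self):
        rng = np.random.default_rng(3)
        z = pd.Series(rng.normal(size=300),
                      index=[f"p{i}" for i in range(300)])
        lf, _ = lfdr(z, null_mode="theoretical")
        assert list(lf.index) == list(z.index)


class TestCallDifferential:
    def _setup(self, seed=0, n=1000):
        rng = np.random.default_rng(seed)
        m = np.exp(rng.uniform(np.log(50), np.log(500), size=n))
        x = rng.normal(m[:, None], 0.1 * m[:, None], size=(n, 4))
        norm = pd.DataFrame(np.abs(x), columns=["c1", "c2", "t1", "t2"],
                            index=[f"p{i}" for i in range(n)])
        return norm

    def test_call_logic_fc_and_lfdr(self):
        norm = self._setup()
        # spike 30 mid-range peaks four-fold in the treated condition;
        # their pooled means stay inside the null-dominated mean range so
        # the SD trend there reflects null variability
        mid = norm[(norm.mean(axis=1) > 80) & (norm.mean(axis=1) < 200)]
        spiked = list(mid.index[:30])
        norm.loc[spiked, ["t1", "t2"]] *= 4.0
        trend = fit_sd_trend(norm)
        res = call_differential(
            norm, trend, ["c1", "c2"], ["t1", "t2"],
            null_mode="theoretical",
        )
        assert res.loc[spiked, "called"].mean() >= 0.8
        called = res[res["called"]]
        assert (called["fc"] > 2).all()
        assert (called["lfdr"] < 0.3).all()
        assert (called["z"] > 0).all()

    def test_full_table_returned(self):
        norm = self._setup(seed=1)
        trend = fit_sd_trend(norm)
        res = call_differential(norm, trend, ["c1", "c2"], ["t1", "t2"],
                                null_mode="theoretical")
        assert len(res) == len(norm)
        assert set(res.columns) == {
            "mean_ctrl", "mean_trt", "fc", "log2fc", "z", "lfdr", "called"
        }

    def test_log2fc_sign_matches_z_sign(self):
        norm = self._setup(seed=2)
        trend = fit_sd_trend(norm)
        res = call_differential(norm, trend, ["c1", "c2"], ["t1", "t2"],
                                null_mode="theoretical")
        nz = res[res["z"] != 0]
        assert (np.sign(nz["log2fc"]) == np.sign(nz["z"])).all()


class TestMarkIntersection:
    def test_overlap_kept_abutment_dropped(self):
        called = PeakSet("H3K27ac", [
            GenomicInterval("chr1", 100, 200, "a"),
            GenomicInterval("chr1", 300, 400, "b"),
        ])
        marks = PeakSet("H3K4me1", [
            GenomicInterval("chr1", 150, 300, "m0"),
        ])
        subset, n = intersect_marks(called, marks)
        assert n == 1 and subset.names() == ["a"]

    def test_identical_sets_all_common(self):
        rng = np.random.default_rng(0)
        a = random_peakset(rng, 20)
        assert len(common_peaks(a, a)) == len(a)

    def test_disjoint_chromosomes_empty(self):
        a = PeakSet("x", [GenomicInterval("chr1", 0, 100, "a")])
        b = PeakSet("y", [GenomicInterval("chr2", 0, 100, "b")])
        assert len(common_peaks(a, b)) == 0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = random_peakset(rng, int(rng.integers(1, 30)), prefix="a")
        b = random_peakset(rng, int(rng.integers(1, 30)), prefix="b")
        subset, n = intersect_marks(a, b)
        expected = brute_force_overlap_names(a, b)
        assert set(subset.names()) == expected and n == len(expected)
        assert set(common_peaks(b, a).names()) == \
            brute_force_overlap_names(b, a)
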