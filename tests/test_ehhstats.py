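import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_panel
from oracles import naive_ehh
from sparseselect.ehhstats import (
    EHHUndefinedError,
    _gap_factor,
    _integrate_between,
    _integrate_side,
    ehh,
    ihs_call_windows,
    ihs_raw,
    ihs_scan,
    ihs_standardize,
    xpehh,
    xpehh_call_windows,
    xpehh_scan,
    xpehh_standardize,
)
from sparseselect.simdata import SweepConfig, simulate_population_pair, thin_to_count


class TestEHH:
    def test_identical_carriers_stay_at_one(self, toy_identical_panel):
        curve = ehh(toy_identical_panel, 2, "derived")
        assert np.allclose(curve.values, 1.0)

    def test_focal_value_is_one_for_allele_cores(self, random_panels):
        for panel in random_panels[:5]:
            j = panel.n_snps // 2
            for cls in ("ancestral", "derived"):
                try:
                    curve = ehh(panel, j, cls)
                except EHHUndefinedError:
                    continue
                assert curve.values[j] == 1.0

    def test_two_two_split_gives_one_third(self):
        # 4 carriers of the derived focal allele split 2/2 at the next SNP
        a = np.array(
            [
                [1, 0],
                [1, 0],
                [1, 1],
                [1, 1],
                [0, 0],
                [0, 1],
            ],
            dtype=np.uint8,
        )
        curve = ehh(make_panel(a), 0, "derived")
        assert curve.values[1] == pytest.approx(1 / 3)  # 2*C(2,2)/C(4,2)

    def test_monotone_non_increasing_from_focal(self, random_panels):
        for panel in random_panels:
            j = panel.n_snps // 2
            for cls in ("ancestral", "derived", "pooled"):
                try:
                    curve = ehh(panel, j, cls)
                except EHHUndefinedError:
                    continue
                assert np.all(np.diff(curve.right) <= 1e-12)
                assert np.all(np.diff(curve.left) <= 1e-12)

    def test_matches_pairwise_identity_oracle(self, random_panels):
        for panel in random_panels[:5]:
            focal = panel.n_snps // 2
            carriers = np.nonzero(panel.alleles[:, focal] == 1)[0]
            if carriers.size < 2:
                continue
            curve = ehh(panel, focal, "derived")
            for x in (0, focal, panel.n_snps - 1):
                assert curve.values[x] == pytest.approx(
                    naive_ehh(panel.alleles, focal, carriers, x)
                )

    def test_single_carrier_is_undefined(self):
        a = np.array([[1, 0], [0, 1], [0, 0], [0, 1]], dtype=np.uint8)
        with pytest.raises(EHHUndefinedError):
            ehh(make_panel(a), 0, "derived")


class TestIntegration:
    def test_hand_trapezoid_three_points(self):
        # EHH 1.0, 0.5, 0.1 at cM 0, 0.01, 0.02 (10 kb steps: no gap damping)
        values = np.array([1.0, 0.5, 0.1])
        bp = np.array([0, 10_000, 20_000])
        cM = np.array([0.0, 0.01, 0.02])
        area = _integrate_side(values, bp, cM, focal=0, step=1)
        assert area == pytest.approx(0.5 * 1.5 * 0.01 + 0.5 * 0.6 * 0.01)

    def test_truncates_below_cutoff(self):
        values = np.array([1.0, 0.04, 0.9])  # curve would "recover" after 0.04
        bp = np.array([0, 10_000, 20_000])
        cM = bp * 1e-6  # 1 cM/Mb
        area = _integrate_side(values, bp, cM, focal=0, step=1)
        # includes the trapezoid down to the crossing SNP, then stops
        assert area == pytest.approx(0.5 * 1.04 * 0.01)

    @pytest.mark.parametrize(
        "gap,factor",
        [(10_000, 1.0), (20_000, 1.0), (100_000, 0.2), (200_000, 0.1), (500_000, 0.1)],
    )
    def test_gap_damping_factor(self, gap, factor):
        assert _gap_factor(gap) == pytest.approx(factor)

    def test_gap_scaled_trapezoid(self):
        values = np.array([1.0, 0.8])
        bp = np.array([0, 100_000])
        cM = np.array([0.0, 0.1])
        area = _integrate_side(values, bp, cM, focal=0, step=1)
        assert area == pytest.approx(0.5 * 1.8 * 0.1 * 0.2)  # 20000/100000

    def test_huge_gap_truncates_entirely(self):
        values = np.array([1.0, 0.9])
        bp = np.array([0, 3_000_000])
        cM = np.array([0.0, 3.0])
        assert _integrate_side(values, bp, cM, focal=0, step=1) == 0.0

    def test_integral_ratio_e_gives_unit_statistic(self):
        # direct check of the bp-trapezoid helper used by the two-population
        # statistic: curves with integral ratio e produce ln-ratio exactly 1
        bp = np.array([0, 1000, 2000])
        hi = np.array([1.0, 1.0, 1.0])
        lo = hi / math.e
        i_hi = _integrate_between(hi, bp, 0, 2)
        i_lo = _integrate_between(lo, bp, 0, 2)
        assert math.log(i_hi / i_lo) == pytest.approx(1.0)


class TestIHS:
    def test_symmetric_cores_give_zero(self):
        # ancestral and derived carriers have mirror-image structure
        block = np.array(
            [
                [0, 0, 0],
                [0, 1, 0],
                [1, 0, 1],
                [1, 1, 1],
            ],
            dtype=np.uint8,
        )
        a = np.hstack([block[:, :1], np.array([[0], [0], [1], [1]]), block[:, 1:]])
        panel = make_panel(a.astype(np.uint8))
        assert ihs_raw(panel, 1) == pytest.approx(0.0)

    def test_derived_integral_double_gives_log_half(self):
        # derived carriers identical twice as far as ancestral carriers
        a = np.array(
            [
                [0, 0, 0, 1, 0],
                [1, 0, 0, 1, 1],
                [0, 1, 1, 0, 0],
                [1, 1, 1, 0, 1],
            ],
            dtype=np.uint8,
        )
        panel = make_panel(a)
        raw = ihs_raw(panel, 3)
        curve_a = ehh(panel, 3, "ancestral").values
        curve_d = ehh(panel, 3, "derived").values
        cM = panel.positions_cM
        expect = math.log(
            np.trapezoid(curve_a, cM) / np.trapezoid(curve_d, cM)
        )
        assert raw == pytest.approx(expect)

    def test_undefined_when_core_too_small(self):
        a = np.array([[1, 0], [0, 1], [0, 0], [0, 1]], dtype=np.uint8)
        assert math.isnan(ihs_raw(make_panel(a), 0))

    def test_sweeps_push_raw_ihs_negative(self, sweep_batch):
        vals = []
        for p in sweep_batch:
            v = ihs_raw(p, p.focal_snp_index)
            if np.isfinite(v):
                vals.append(v)
        assert len(vals) >= 20
        assert np.mean(vals) < -0.5


class TestStandardize:
    def _table(self, daf, raw):
        return pd.DataFrame(
            {"chrom": "1", "position_bp": np.arange(1, len(daf) + 1), "daf": daf,
             "raw": raw}
        )

    def test_two_bin_hand_zscores(self):
        daf = np.array([0.01, 0.02, 0.03, 0.51, 0.52, 0.53])
        raw = np.array([1.0, 2.0, 3.0, 10.0, 20.0, 30.0])
        out = ihs_standardize(self._table(daf, raw), n_bins=2)
        lo = raw[:3]
        expect = (lo - lo.mean()) / lo.std()
        assert np.allclose(out["std"][:3], expect)

    def test_constant_bin_flagged_nan(self):
        daf = np.array([0.1, 0.12, 0.9, 0.92])
        raw = np.array([5.0, 5.0, 1.0, 2.0])
        out = ihs_standardize(self._table(daf, raw), n_bins=2)
        assert out["std"][:2].isna().all()
        assert out["std"][2:].notna().all()

    def test_bin_means_exactly_centred(self, neutral_batch):
        tab = ihs_standardize(ihs_scan(thin_to_count(neutral_batch[0], 150, seed=0)))
        t = tab[np.isfinite(tab["std"])]
        edges = np.linspace(0.0, 1.0, 21)
        bins = np.clip(np.digitize(t["daf"].to_numpy(), edges[1:-1]), 0, 19)
        for _, grp in t.groupby(bins):
            if len(grp) >= 2:
                assert abs(grp["std"].mean()) < 1e-9

    def test_idempotent(self, neutral_batch):
        tab = ihs_scan(thin_to_count(neutral_batch[1], 150, seed=0))
        once = ihs_standardize(tab)
        twice = ihs_standardize(once.drop(columns="std").assign(raw=once["std"]))
        ok = np.isfinite(once["std"]) & np.isfinite(twice["std"])
        assert np.allclose(once["std"][ok], twice["std"][ok], atol=1e-12)


class TestWindows:
    def _table(self, chroms, pos, std):
        return pd.DataFrame(
            {"chrom": chroms, "position_bp": pos, "std": std, "daf": 0.5}
        )

    def test_no_window_called_when_no_extreme_score(self):
        t = self._table("1", np.arange(1, 2001) * 1000, np.zeros(2000))
        wins = ihs_call_windows(t, window_bp=100_000)
        assert not wins["called"].any()

    def test_single_enriched_window_called_alone(self):
        rng = np.random.default_rng(0)
        pos = np.arange(1, 2001) * 1000  # 2 Mb over 200 x 10 kb windows
        std = np.zeros(2000)
        std[1000:1010] = 3.0  # one window at 90%+ extreme SNPs
        wins = ihs_call_windows(self._table("1", pos, std), window_bp=10_000)
        called = wins[wins["called"]]
        assert len(called) == 1
        assert called.iloc[0]["stat"] > 0.8

    def test_xpehh_max_window_is_called(self):
        rng = np.random.default_rng(1)
        pos = np.arange(1, 2001) * 1000
        std = rng.normal(size=2000)
        std[555] = 10.0
        wins = xpehh_call_windows(self._table("1", pos, std), window_bp=10_000)
        called = wins[wins["called"]]
        assert (called["stat"] >= 10.0).any()

    def test_xpehh_degenerate_equal_scores_calls_nothing(self):
        t = self._table("1", np.arange(1, 301) * 1000, np.ones(300))
        wins = xpehh_call_windows(t, window_bp=10_000)
        assert not wins["called"].any()


@pytest.fixture(scope="module")
def pair():
    return simulate_population_pair(SweepConfig(seed=77), sweep=True)


class TestXPEHH:

    def test_identical_populations_give_zero(self, pair):
        t, _ = pair
        tab = xpehh_scan(t, t, radius_bp=200_000)
        finite = tab["raw"][np.isfinite(tab["raw"])]
        assert len(finite) > 0
        assert np.allclose(finite, 0.0)

    def test_antisymmetric_under_population_swap(self, pair):
        t, r = pair
        shared = t.positions_bp[:: max(1, t.n_snps // 40)]
        for p in shared[5:10]:
            a = xpehh(t, r, int(p))
            b = xpehh(r, t, int(p))
            if np.isfinite(a):
                assert a == pytest.approx(-b)

    def test_sweep_target_scores_positive_at_focal(self, pair):
        t, r = pair
        focal_bp = int(t.positions_bp[t.focal_snp_index])
        v = xpehh(t, r, focal_bp)
        assert np.isfinite(v) and v > 0

    def test_standardization_zero_mean_unit_sd(self, pair):
        t, r = pair
        tab = xpehh_standardize(xpehh_scan(t, r, radius_bp=200_000))
        s = tab["std"][np.isfinite(tab["std"])].to_numpy()
        assert abs(s.mean()) < 1e-9 and abs(s.std() - 1) < 1e-9
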