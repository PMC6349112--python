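"""ddG, Phi_b, Bronsted slopes, and double-mutant coupling energies."""

import numpy as np
import pytest

import tsphi as T
from tsphi.constants import R_KCAL


def rec(kon, koff, actr="WT", ncbd="X", cond="buffer", **err):
    return T.RateConstants(actr, ncbd, kon, koff, T.kd_nM(kon, koff),
                           condition=cond, **err)


class TestDDG:
    def test_identical_records_give_zero(self):
        wt = rec(21.3, 2.2)
        d = T.ddg_from_rates(wt, wt)
        assert d.ddG_TS == 0.0 and d.ddG_Eq == 0.0

    def test_kd_ratio_e_gives_RT(self):
        wt = rec(10.0, 1.0)
        mut = rec(10.0, np.e)  # K_d ratio exactly e
        d = T.ddg_from_rates(wt, mut, T=277.0)
        assert d.ddG_Eq == pytest.approx(R_KCAL * 277.0, rel=1e-12)
        assert d.ddG_Eq == pytest.approx(0.5504, abs=2e-4)

    def test_null_mutant_E1066A_below_significance(self, table1_lookup):
        wt = table1_lookup[("WT", "Y2108W", "buffer")]
        mut = table1_lookup[("E1066A", "Y2108W", "buffer")]
        d = T.ddg_from_rates(wt, mut)
        assert abs(d.ddG_Eq) == pytest.approx(0.16, abs=0.01)
        assert abs(d.ddG_Eq) < 0.18
        with pytest.raises(T.PhiBUndetermined):
            T.phi_b(d)

    def test_condition_mismatch_rejected_unless_overridden(self, table1_lookup):
        wt = table1_lookup[("WT", "Y2108W", "buffer")]
        mut = table1_lookup[("WT", "A2098G", "TMAO")]
        with pytest.raises(T.ConditionMismatch):
            T.ddg_from_rates(wt, mut)
        T.ddg_from_rates(wt, mut, allow_condition_mismatch=True)


class TestPhiB:
    def test_table_values_A2098G_and_T2073A(self, table1_lookup):
        wt_tmao = table1_lookup[("WT", "Y2108W", "TMAO")]
        a2098g = table1_lookup[("WT", "A2098G", "TMAO")]
        p = T.phi_b(T.ddg_from_rates(wt_tmao, a2098g))
        assert p.value == pytest.approx(0.45, abs=0.02)
        assert p.category == "intermediate"
        wt = table1_lookup[("WT", "Y2108W", "buffer")]
        t2073a = table1_lookup[("WT", "T2073A", "buffer")]
        p2 = T.phi_b(T.ddg_from_rates(wt, t2073a))
        assert p2.value == pytest.approx(0.49, abs=0.02)
        assert p2.category == "intermediate"

    def test_pure_kon_perturbation_gives_phi_one(self):
        wt = rec(20.0, 2.0)
        mut = rec(10.0, 2.0)  # k_on halved, k_off unchanged -> K_d doubled
        p = T.phi_b(T.ddg_from_rates(wt, mut))
        assert p.value == pytest.approx(1.0, rel=1e-12)

    def test_pure_koff_perturbation_gives_phi_zero(self):
        wt = rec(20.0, 2.0)
        mut = rec(20.0, 4.0)
        p = T.phi_b(T.ddg_from_rates(wt, mut))
        assert p.value == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_limits_hold_for_random_rate_tables(self, seed):
        rng = np.random.default_rng(seed)
        kon, koff = rng.uniform(1, 100), rng.uniform(0.1, 10)
        f = rng.uniform(1.5, 5.0)
        p1 = T.phi_b(T.ddg_from_rates(rec(kon, koff), rec(kon / f, koff)))
        p0 = T.phi_b(T.ddg_from_rates(rec(kon, koff), rec(kon, koff * f)))
        assert p1.value == pytest.approx(1.0, rel=1e-10)
        assert p0.value == pytest.approx(0.0, abs=1e-10)

    def test_unit_rescaling_invariance(self):
        wt, mut = rec(20.0, 2.0), rec(11.0, 3.0)
        p = T.phi_b(T.ddg_from_rates(wt, mut))
        wt2 = rec(20.0 * 1e3, 2.0 * 60)   # different time/conc units, both rows
        mut2 = rec(11.0 * 1e3, 3.0 * 60)
        p2 = T.phi_b(T.ddg_from_rates(wt2, mut2))
        assert p2.value == pytest.approx(p.value, rel=1e-12)

    def test_categories(self):
        assert T.PhiB.categorise(0.1) == "low"
        assert T.PhiB.categorise(0.3) == "intermediate"
        assert T.PhiB.categorise(0.59) == "intermediate"
        assert T.PhiB.categorise(0.6) == "high"

    def test_error_propagation_matches_monte_carlo(self, table1, table1_lookup):
        """Delta-method Phi_b errors within 10% of 1e4-draw resampling."""
        rng = np.random.default_rng(0)
        cases = [(("WT", "Y2108W", "TMAO"), ("WT", "A2098G", "TMAO")),
                 (("WT", "Y2108W", "buffer"), ("WT", "T2073A", "buffer"))]
        for wt_key, mut_key in cases:
            wt, mut = table1_lookup[wt_key], table1_lookup[mut_key]
            p = T.phi_b(T.ddg_from_rates(wt, mut))
            draws = []
            for _ in range(10_000):
                def jitter(r):
                    return T.RateConstants(
                        r.actr_variant, r.ncbd_variant,
                        max(rng.normal(r.kon, r.kon_err), 1e-6),
                        r.koff,
                        max(rng.normal(r.kd, r.kd_err), 1e-6),
                        condition=r.condition)
                d = T.ddg_from_rates(jitter(wt), jitter(mut))
                draws.append(d.ddG_TS / d.ddG_Eq)
            assert p.error == pytest.approx(np.std(draws), rel=0.10)


class TestBronsted:
    def test_exact_line_recovered(self):
        wt = rec(20.0, 2.0)
        pts = []
        RT = R_KCAL * 277.0
        for ddg_eq in (0.4, 0.8, 1.2, -0.5):
            kon = 20.0 * np.exp(-0.5 * ddg_eq / RT)
            kd = T.kd_nM(20.0, 2.0) * np.exp(ddg_eq / RT)
            pts.append(T.ddg_from_rates(wt, rec(kon, kon * kd / 1e3)))
        fit = T.bronsted(pts)
        assert fit.alpha == pytest.approx(0.5, abs=1e-10)
        assert fit.intercept == pytest.approx(0.0, abs=1e-10)

    def test_noiseless_synthetic_panel_recovers_alpha_exactly(self):
        records, truth = T.gen_panel(T.PanelScenario(alpha=0.23))
        fits = T.bronsted_by_background(records, side="ncbd",
                                        ref_actr="WT", ref_ncbd="WTB")
        for f in fits:
            assert f.alpha == pytest.approx(0.23, abs=1e-10)

    def test_noisy_panel_recovers_alpha_within_3se(self):
        scn = T.PanelScenario(alpha=0.25, noise_sigma_log=0.05, seed=21)
        records, _ = T.gen_panel(scn)
        (fit,) = T.bronsted_by_background(records, side="ncbd",
                                          ref_actr="WT", ref_ncbd="WTB")
        assert abs(fit.alpha - 0.25) < 3 * fit.alpha_se

    def test_degenerate_spread_warns(self):
        wt = rec(20.0, 2.0)
        RT = R_KCAL * 277.0
        pts = []
        for ddg_eq in (0.30, 0.33, 0.36):
            kon = 20.0 * np.exp(-0.2 * ddg_eq / RT)
            kd = T.kd_nM(20.0, 2.0) * np.exp(ddg_eq / RT)
            pts.append(T.ddg_from_rates(wt, rec(kon, kon * kd / 1e3)))
        with pytest.warns(UserWarning, match="spread"):
            T.bronsted(pts)

    def test_fewer_than_three_points_rejected(self):
        wt = rec(20.0, 2.0)
        with pytest.raises(ValueError):
            T.bronsted([T.ddg_from_rates(wt, rec(10.0, 2.0))] * 2)


class TestCoupling:
    RT = R_KCAL * 277.0

    def quartet(self, excess_ln=0.0):
        wt = rec(20.0, 2.0)
        kd0 = T.kd_nM(20.0, 2.0)
        a = rec(20.0, 2.0 * 2.0, actr="mA")           # ddG_Eq = RT ln 2
        b = rec(20.0, 2.0 * 3.0, ncbd="mB")           # ddG_Eq = RT ln 3
        kd_ab = kd0 * 6.0 * np.exp(excess_ln)
        ab = rec(20.0, 20.0 * kd_ab / 1e3, actr="mA", ncbd="mB")
        return wt, a, b, ab

    def test_additive_quartet_gives_zero(self):
        c = T.coupling_energy(*self.quartet(0.0), T=277.0)
        assert c.dddG_C == pytest.approx(0.0, abs=1e-12)

    def test_ln_space_excess_maps_to_RT(self):
        c = T.coupling_energy(*self.quartet(1.0), T=277.0)
        assert c.dddG_C == pytest.approx(self.RT, rel=1e-10)

    def test_symmetric_under_label_swap(self):
        wt, a, b, ab = self.quartet(0.7)
        c1 = T.coupling_energy(wt, a, b, ab, T=277.0)
        c2 = T.coupling_energy(wt, b, a, ab, T=277.0)
        assert c1.dddG_C == pytest.approx(c2.dddG_C, rel=1e-12)

    def test_missing_corner_named(self):
        wt, a, b, ab = self.quartet()
        with pytest.raises(ValueError, match="wt/mutB"):
            T.coupling_energy(wt, a, None, ab)


class TestBackgroundComparison:
    def test_identical_kinetics_zero_difference(self):
        records, _ = T.gen_panel(T.PanelScenario(
            alpha=0.3, backgrounds={"WTB": 0.0, "B1": 0.0, "B2": 0.0}))
        df = T.phi_background_comparison(records, side="ncbd",
                                         ref_actr="WT", ref_ncbd="WTB")
        assert T.mean_abs_phi_difference(df) == pytest.approx(0.0, abs=1e-12)

    def test_background_independent_truth_with_noise(self):
        """With background-independent Phi_b and 5% rate noise, the mean |d|
        stays within the Monte-Carlo range of its noise-propagated expectation."""
        scn = T.PanelScenario(
            alpha=0.4, noise_sigma_log=0.05, seed=17,
            backgrounds={"WTB": 0.0, "B1": 0.6, "B2": -0.4},
            probes={"M1": 0.5, "M2": 0.9, "M3": 1.3, "M4": -0.6})
        records, _ = T.gen_panel(scn)
        df = T.phi_background_comparison(records, side="ncbd",
                                         ref_actr="WT", ref_ncbd="WTB")
        observed = T.mean_abs_phi_difference(df)
        # Monte-Carlo reference distribution over generator seeds
        ref = [T.mean_abs_phi_difference(T.phi_background_comparison(
            T.gen_panel(T.PanelScenario(**{**scn.__dict__, "seed": 1000 + s}))[0],
            side="ncbd", ref_actr="WT", ref_ncbd="WTB"))
            for s in range(30)]
        assert np.min(ref) * 0.5 <= observed <= np.max(ref) * 2.0

    def test_ddg_filter_restricts_backgrounds(self):
        records, _ = T.gen_panel(T.PanelScenario(
            alpha=0.3, backgrounds={"WTB": 0.0, "Bsmall": 0.4, "Bbig": 2.0}))
        df_all = T.phi_background_comparison(records, side="ncbd",
                                             ref_actr="WT", ref_ncbd="WTB")
        df_filt = T.phi_background_comparison(records, side="ncbd",
                                              ref_actr="WT", ref_ncbd="WTB",
                                              ddg_eq_filter=1.0)
        assert set(df_all["background"]) == {"Bsmall", "Bbig"}
        assert set(df_filt["background"]) == {"Bsmall"}
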