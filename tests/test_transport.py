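import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nrampkit import synthetic as syn
from nrampkit import transport as tq
from nrampkit.transport import (
    AssayConditions,
    BcecfCalibration,
    FluorescenceTrace,
    FuraCalibration,
)


class TestNernst:
    def test_equal_concentrations_zero(self):
        assert tq.nernst_potential(AssayConditions(K_in=120, K_out=120)) == 0.0

    def test_tenfold_gradient_at_25C(self):
        up = tq.nernst_potential(AssayConditions(K_in=12, K_out=120, temperature=298.15))
        down = tq.nernst_potential(AssayConditions(K_in=120, K_out=12, temperature=298.15))
        assert up == pytest.approx(59.16, abs=0.01)
        assert down == pytest.approx(-59.16, abs=0.01)

    def test_antisymmetry(self):
        a = tq.nernst_potential(AssayConditions(K_in=90, K_out=30))
        b = tq.nernst_potential(AssayConditions(K_in=30, K_out=90))
        assert a == pytest.approx(-b, abs=1e-12)

    def test_zero_concentration_errors(self):
        with pytest.raises(ValueError):
            tq.nernst_potential(AssayConditions(K_in=0, K_out=120))


class TestFura2:
    calib = FuraCalibration(Kd=0.2, Rmin=0.5, Rmax=5.0, beta=2.0)

    def test_rmin_gives_zero(self):
        assert tq.fura2_concentration(0.5, self.calib) == 0.0

    def test_midpoint_equals_kd_when_beta_one(self):
        calib = FuraCalibration(Kd=0.7, Rmin=0.5, Rmax=5.0, beta=1.0)
        r_mid = (calib.Rmin + calib.Rmax) / 2  # (R−Rmin)/(Rmax−R) = 1
        assert tq.fura2_concentration(r_mid, calib) == pytest.approx(0.7)

    def test_worked_arithmetic(self):
        # Kd 0.2, beta 2, Rmin 0.5, Rmax 5.0, R 2.0 → 0.2·2·(1.5/3.0)
        assert tq.fura2_concentration(2.0, self.calib) == pytest.approx(0.2)

    def test_strictly_increasing_in_ratio(self):
        ratios = np.linspace(0.51, 4.99, 200)
        conc = tq.fura2_concentration(ratios, self.calib)
        assert np.all(np.diff(conc) > 0)

    def test_saturation_errors(self):
        with pytest.raises(ValueError, match="saturat"):
            tq.fura2_concentration(5.0, self.calib)

    def test_below_rmin_clamps_with_warning(self):
        with pytest.warns(UserWarning, match="clamping"):
            assert tq.fura2_concentration(0.3, self.calib) == 0.0

    @settings(deadline=None, max_examples=30)
    @given(st.floats(min_value=0.001, max_value=50.0))
    def test_ratio_concentration_round_trip(self, conc):
        r = tq.fura2_ratio(conc, self.calib)
        assert tq.fura2_concentration(r, self.calib) == pytest.approx(conc, rel=1e-9)


class TestQuenchFraction:
    @staticmethod
    def make_trace(factor_mid=0.7, factor_plateau=0.4):
        time = np.arange(0.0, 100.0, 1.0)
        f = np.ones_like(time) * 1000.0
        f[(time >= 40) & (time < 80)] = 1000.0 * factor_mid
        f[time >= 80] = 1000.0 * factor_plateau
        return FluorescenceTrace(
            time=time,
            channels={"ex340": f.copy(), "ex380": f.copy()},
            events={"substrate": 40.0, "ionomycin": 80.0},
        )

    def test_baseline_is_zero(self):
        trace = self.make_trace()
        q = tq.quench_fraction(trace, 10.0, baseline_window=(0, 30), ionomycin_plateau=(85, 99))
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_plateau_is_one(self):
        trace = self.make_trace()
        q = tq.quench_fraction(trace, 90.0, baseline_window=(0, 30), ionomycin_plateau=(85, 99))
        assert q == pytest.approx(1.0, abs=1e-12)

    def test_worked_arithmetic(self):
        # F = 0.7·baseline both channels, plateau at 0.4·baseline → 0.3/0.6 = 0.5
        trace = self.make_trace(0.7, 0.4)
        q = tq.quench_fraction(trace, 60.0, baseline_window=(0, 30), ionomycin_plateau=(85, 99))
        assert q == pytest.approx(0.5, abs=1e-12)

    def test_simulated_quench_trace_recovers_truth(self):
        trace, truth = syn.simulate_trace(syn.TraceSpec(mode="metal_quench", noise_sigma=0.0))
        t_eval = np.array([100.0, 150.0, 200.0])
        q = tq.quench_fraction(
            trace, t_eval, baseline_window=(0, 25), ionomycin_plateau=(250, 300)
        )
        expected = np.interp(t_eval, truth["time"], truth["fraction_imported"])
        assert np.allclose(q, expected, atol=1e-9)

    def test_zero_baseline_errors(self):
        time = np.arange(0.0, 10.0)
        trace = FluorescenceTrace(
            time=time, channels={"a": np.zeros_like(time), "b": np.ones_like(time)}
        )
        with pytest.raises(ValueError, match="baseline"):
            tq.quench_fraction(trace, 5.0, baseline_window=(0, 3), ionomycin_plateau=(8, 9))


class TestBcecf:
    calib = BcecfCalibration(pKa_dye=6.98, Rmin=0.2, Rmax=2.0)

    def test_midpoint_gives_pka(self):
        r_mid = (self.calib.Rmin + self.calib.Rmax) / 2
        assert tq.bcecf_pH(r_mid, self.calib) == pytest.approx(6.98)

    def test_worked_arithmetic(self):
        # (R−Rmin)/(Rmax−R) = 10 → pH = 6.98 + 1
        r = (self.calib.Rmin + 10 * self.calib.Rmax) / 11
        assert tq.bcecf_pH(r, self.calib) == pytest.approx(7.98)

    @settings(deadline=None, max_examples=30)
    @given(st.floats(min_value=6.0, max_value=8.0))
    def test_round_trip(self, ph0):
        assert tq.bcecf_pH(tq.bcecf_ratio(ph0, self.calib), self.calib) == pytest.approx(
            ph0, abs=1e-9
        )

    def test_strictly_increasing(self):
        ratios = np.linspace(0.21, 1.99, 100)
        ph = tq.bcecf_pH(ratios, self.calib)
        assert np.all(np.diff(ph) > 0)

    def test_orientation_flag_flips_monotonicity(self):
        calib = BcecfCalibration(pKa_dye=6.98, Rmin=0.2, Rmax=2.0, ratio_increases_with_pH=False)
        ratios = np.linspace(0.21, 1.99, 100)
        assert np.all(np.diff(tq.bcecf_pH(ratios, calib)) < 0)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            tq.bcecf_pH(2.0, self.calib)


class TestNetProtonImport:
    paper_conditions = AssayConditions(
        buffer_conc=0.5, buffer_pKa=7.20, dye_conc=150.0, dye_pKa=6.98
    )

    def test_no_change_is_zero(self):
        assert tq.net_proton_import(7.0, 7.0, self.paper_conditions) == 0.0

    def test_symmetric_pka_crossing_closed_form(self):
        cond = AssayConditions(buffer_conc=1.0, buffer_pKa=7.0, dye_conc=0.0)
        # single species, pH pKa+0.5 → pKa−0.5: Δprot = C·(1/(1+10^-.5) − 1/(1+10^.5))
        expected = 1000.0 * (1 / (1 + 10**-0.5) - 1 / (1 + 10**0.5))
        got = tq.net_proton_import(7.5, 6.5, cond)
        assert got == pytest.approx(expected, abs=1e-9)
        assert got == pytest.approx(0.519 * 1000.0, abs=1.0)

    def test_antisymmetry_and_path_additivity(self):
        cond = self.paper_conditions
        forward = tq.net_proton_import(7.0, 6.5, cond)
        assert forward == pytest.approx(-tq.net_proton_import(6.5, 7.0, cond), abs=1e-12)
        via = tq.net_proton_import(7.0, 6.8, cond) + tq.net_proton_import(6.8, 6.5, cond)
        assert via == pytest.approx(forward, abs=1e-12)

    def test_study_conditions_against_independent_scalar(self):
        # 0.5 mM buffer (pKa 7.20) + 150 µM dye (pKa 6.98), pH 7.0 → 6.8;
        # independent evaluation of the protonated-fraction difference per species
        def prot(total, pka, ph):
            return total * 10 ** (pka - ph) / (1 + 10 ** (pka - ph))

        expected = (prot(500.0, 7.20, 6.8) - prot(500.0, 7.20, 7.0)) + (
            prot(150.0, 6.98, 6.8) - prot(150.0, 6.98, 7.0)
        )
        got = tq.net_proton_import(7.0, 6.8, self.paper_conditions)
        assert got == pytest.approx(expected, abs=1e-9)
        assert got > 0  # acidification imports protons


class TestInitialRate:
    def test_constant_series_zero_slope(self):
        t = np.arange(0.0, 60.0)
        rate = tq.initial_rate(t, np.full_like(t, 3.3), t0=10.0, window=30.0)
        assert rate.slope == 0.0 and rate.stderr == 0.0

    def test_exact_line(self):
        t = np.arange(0.0, 60.0)
        rate = tq.initial_rate(t, 2.0 * t, t0=10.0, window=30.0)
        assert rate.slope == pytest.approx(2.0, abs=1e-12)
        assert rate.stderr == pytest.approx(0.0, abs=1e-9)

    def test_noiseless_simulated_uptake_within_2_percent(self):
        spec = syn.TraceSpec(mode="metal", KM=30.0, Vmax=0.05, S_uM=30.0, noise_sigma=0.0)
        trace, truth = syn.simulate_trace(spec)
        calib = FuraCalibration(Kd=0.2, Rmin=0.5, Rmax=5.0, beta=2.0)
        conc = tq.fura2_concentration(trace.ratio("ex340", "ex380"), calib)
        rate = tq.initial_rate(trace.time, conc, t0=spec.t_add, window=30.0)
        assert rate.slope == pytest.approx(truth["rate_uM_per_s"][0], rel=0.02)

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError, match="≥3"):
            tq.initial_rate(np.array([0.0, 1.0, 2.0, 50.0]), np.zeros(4), t0=10.0, window=30.0)


class TestMichaelisMenten:
    def test_noiseless_exact_recovery(self):
        S = np.array([3.0, 10.0, 30.0, 60.0, 100.0, 300.0])
        v = 5.0 * S / (30.0 + S)
        fit = tq.fit_michaelis_menten(S, v)
        assert fit.KM == pytest.approx(30.0, rel=1e-6)
        assert fit.Vmax == pytest.approx(5.0, rel=1e-6)

    def test_noisy_median_recovery_within_10_percent(self):
        # σ = 3% of Vmax, 8 concentrations KM/10..10·KM, 200 replicate fits
        true_km, true_vmax = 30.0, 5.0
        S = np.geomspace(3.0, 300.0, 8)
        kms = []
        rng = np.random.default_rng(2024)
        for _ in range(200):
            v = true_vmax * S / (true_km + S) + rng.normal(0, 0.03 * true_vmax, size=S.shape)
            kms.append(tq.fit_michaelis_menten(S, np.clip(v, 1e-9, None)).KM)
        assert abs(np.median(kms) - true_km) / true_km < 0.10

    def test_exclusion_restores_km_under_substrate_inhibition(self):
        true_km, true_vmax, ki = 30.0, 5.0, 2000.0
        S = np.array([3.0, 10.0, 30.0, 60.0, 100.0, 500.0, 1000.0])
        v = true_vmax * S / (true_km + S + S**2 / ki)
        biased = tq.fit_michaelis_menten(S, v)
        top_two = [len(S) - 2, len(S) - 1]
        cleaned = tq.fit_michaelis_menten(S, v, exclude=top_two)
        assert cleaned.excluded == top_two
        assert abs(cleaned.KM - true_km) < abs(biased.KM - true_km)
        assert cleaned.KM == pytest.approx(true_km, rel=0.10)

    def test_standard_errors_are_finite_and_nonnegative(self):
        rng = np.random.default_rng(5)
        S = np.geomspace(3.0, 300.0, 8)
        v = 5.0 * S / (30.0 + S) + rng.normal(0, 0.1, size=S.shape)
        fit = tq.fit_michaelis_menten(S, v)
        assert fit.KM_se >= 0 and np.isfinite(fit.KM_se)
        assert fit.Vmax_se >= 0 and np.isfinite(fit.Vmax_se)

    def test_too_few_concentrations_errors(self):
        with pytest.raises(ValueError, match="≥3 distinct"):
            tq.fit_michaelis_menten(np.array([1.0, 10.0]), np.array([0.1, 0.5]))


class TestTraceIO:
    def test_csv_round_trip_with_events(self, tmp_path):
        path = tmp_path / "trace.csv"
        path.write_text(
            "time_s,ex340,ex380,event_substrate\n"
            "0.0,100.0,200.0,30.0\n"
            "1.0,101.0,199.0,\n"
            "2.0,102.0,198.0,\n"
        )
        trace = tq.read_trace_csv(path)
        assert trace.channel_names == ("ex340", "ex380")
        assert trace.events == {"substrate": 30.0}
        assert np.allclose(trace.ratio("ex340", "ex380")[0], 0.5)

    def test_missing_time_column_errors(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("t,a,b\n0,1,2\n")
        with pytest.raises(ValueError, match="time_s"):
            tq.read_trace_csv(path)

    def test_nonincreasing_time_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            FluorescenceTrace(
                time=np.array([0.0, 1.0, 1.0]),
                channels={"a": np.zeros(3), "b": np.zeros(3)},
            )
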