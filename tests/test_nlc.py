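"""Two-sine admittance analysis, RC solve, and Boltzmann NLC fitting."""

import numpy as np
import pytest

from cochlear_aging import (
    BoltzmannParams,
    CircuitParams,
    SpectralLeakageError,
    TwoSineProtocol,
    boltzmann_capacitance,
    cm_voltage_series,
    fit_boltzmann,
    fourier_admittance,
    gen_voltage_clamp_recording,
    rc_admittance,
    solve_rc_from_admittance,
)
from cochlear_aging.errors import FitError, ModelMismatchError, ProtocolError
from cochlear_aging.nlc import fit_nlc_recording


class TestProtocol:
    def test_integer_cycles_by_construction(self, protocol):
        assert protocol.f1_cycles == 10
        # effective frequencies sit exactly on the analysis-window DFT grid
        n = protocol.n_segment_samples
        assert protocol.effective_f1 * n / protocol.sample_rate == pytest.approx(10.0)
        assert protocol.effective_f2 == pytest.approx(2 * protocol.effective_f1)

    def test_sample_rate_floor(self):
        with pytest.raises(ProtocolError):
            TwoSineProtocol(sample_rate=10_000.0)

    def test_frequency_ratio_enforced(self):
        with pytest.raises(ProtocolError):
            TwoSineProtocol(f1=390.6, f2=700.0)


class TestFourierAdmittance:
    def test_pure_resistor(self):
        # 100 MOhm resistor: Y = 0.01 uS real, no reactive part
        fs, f, n = 50_000.0, 500.0, 1000
        t = np.arange(n) / fs
        v = 10.0 * np.sin(2 * np.pi * f * t)
        y = fourier_admittance(v, v / 100.0, fs, f)
        assert y.real == pytest.approx(0.01, rel=1e-9)
        assert y.imag == pytest.approx(0.0, abs=1e-12)

    def test_forward_synthesis_recovers_complex_y(self):
        fs, f, n = 50_000.0, 781.25, 1280
        t = np.arange(n) / fs
        y_true = 0.004 * np.exp(1j * 0.7)
        v = 10.0 * np.sin(2 * np.pi * f * t)
        i = 10.0 * abs(y_true) * np.sin(2 * np.pi * f * t + np.angle(y_true))
        y = fourier_admittance(v, i, fs, f)
        assert abs(y - y_true) / abs(y_true) < 1e-9

    def test_amplitude_invariance_on_linear_circuit(self, circuit, short_protocol):
        bz = BoltzmannParams(qmax=0.0)
        ys = []
        for amp in (5.0, 10.0):
            proto = TwoSineProtocol(
                amplitude=amp, dc_levels=short_protocol.dc_levels
            )
            rec = gen_voltage_clamp_recording(circuit, bz, proto, 0.0, seed=0)
            seg = rec.segments[0]
            ys.append(
                fourier_admittance(
                    rec.vcmd_mV[seg.start:seg.stop],
                    rec.current_nA[seg.start:seg.stop],
                    rec.sample_rate,
                    proto.effective_f1,
                )
            )
        assert abs(ys[0] - ys[1]) / abs(ys[1]) < 1e-6

    def test_non_integer_cycles_raise(self):
        with pytest.raises(SpectralLeakageError):
            fourier_admittance(np.ones(1000), np.ones(1000), 50_000.0, 333.3)


class TestRCSolve:
    def test_rs_zero_closed_form(self):
        rm, cm = 200.0, 15.0
        f1, f2 = 390.625, 781.25
        y1, y2 = rc_admittance(0.0, rm, cm, f1), rc_admittance(0.0, rm, cm, f2)
        # with Rs = 0: Re Y = 1/Rm and Im Y = w*Cm at each frequency
        assert y1.real == pytest.approx(1 / rm)
        assert y1.imag / (2 * np.pi * f1 * 1e-6) == pytest.approx(cm)
        rs, rm_hat, cm_hat, res = solve_rc_from_admittance(y1, y2, f1, f2)
        assert rs == pytest.approx(0.0, abs=1e-6)
        assert rm_hat == pytest.approx(rm, rel=1e-9)
        assert cm_hat == pytest.approx(cm, rel=1e-9)

    def test_round_trip_exact(self):
        f1, f2 = 390.625, 781.25
        y1 = rc_admittance(10.0, 500.0, 25.0, f1)
        y2 = rc_admittance(10.0, 500.0, 25.0, f2)
        rs, rm, cm, res = solve_rc_from_admittance(y1, y2, f1, f2)
        assert rs == pytest.approx(10.0, rel=1e-6)
        assert rm == pytest.approx(500.0, rel=1e-6)
        assert cm == pytest.approx(25.0, rel=1e-6)
        assert res < 1e-9

    def test_inconsistent_pair_raises(self):
        f1, f2 = 390.625, 781.25
        y1 = rc_admittance(10.0, 500.0, 25.0, f1)
        y2 = rc_admittance(10.0, 500.0, 25.0, f2)
        with pytest.raises(ModelMismatchError):
            solve_rc_from_admittance(y1, np.conj(y2), f1, f2)


class TestSimulator:
    def test_resistive_divider_steady_state(self):
        # no NLC, no stimulus: the clamp sees a plain Rs + Rm divider
        circ = CircuitParams(rs=10.0, rm=500.0, clin=7.0)
        proto = TwoSineProtocol(amplitude=0.0, dc_levels=(-60.0,))
        rec = gen_voltage_clamp_recording(circ, BoltzmannParams(qmax=0.0), proto, 0.0)
        seg = rec.segments[0]
        np.testing.assert_allclose(
            rec.current_nA[seg.start:seg.stop], -60.0 / 510.0, rtol=1e-9
        )

    def test_rs_zero_membrane_follows_command(self):
        circ = CircuitParams(rs=0.0, rm=100.0, clin=10.0)
        proto = TwoSineProtocol(dc_levels=(-50.0,))
        rec = gen_voltage_clamp_recording(circ, BoltzmannParams(qmax=0.0), proto, 0.0)
        t_ms = rec.time_ms
        w1 = 2 * np.pi * proto.effective_f1 * 1e-3  # rad/ms
        w2 = 2 * np.pi * proto.effective_f2 * 1e-3
        dvc = 10.0 * (w1 * np.cos(w1 * t_ms) + w2 * np.cos(w2 * t_ms))  # mV/ms
        expected = rec.vcmd_mV / 100.0 + 10.0 * dvc * 1e-3  # nA
        np.testing.assert_allclose(rec.current_nA, expected, rtol=1e-9, atol=1e-12)

    def test_admittance_matches_closed_form_on_linear_cell(self, circuit):
        proto = TwoSineProtocol(dc_levels=(-70.0,))
        rec = gen_voltage_clamp_recording(circuit, BoltzmannParams(qmax=0.0), proto, 0.0)
        seg = rec.segments[0]
        for f in (proto.effective_f1, proto.effective_f2):
            y = fourier_admittance(
                rec.vcmd_mV[seg.start:seg.stop],
                rec.current_nA[seg.start:seg.stop],
                rec.sample_rate,
                f,
            )
            y_ref = rc_admittance(circuit.rs, circuit.rm, circuit.clin, f)
            assert abs(y - y_ref) / abs(y_ref) < 0.005

    def test_seed_determinism(self, circuit, boltzmann, short_protocol):
        a = gen_voltage_clamp_recording(circuit, boltzmann, short_protocol, 5.0, seed=9)
        b = gen_voltage_clamp_recording(circuit, boltzmann, short_protocol, 5.0, seed=9)
        np.testing.assert_array_equal(a.current_nA, b.current_nA)

    def test_linearity_without_nlc(self, circuit):
        # with Qmax = 0 the circuit is linear: doubling the stimulus doubles
        # the (noise-free) current deviation from its DC value
        recs = []
        for amp in (5.0, 10.0):
            proto = TwoSineProtocol(amplitude=amp, dc_levels=(-40.0,))
            recs.append(
                gen_voltage_clamp_recording(circuit, BoltzmannParams(qmax=0.0), proto, 0.0)
            )
        s = recs[0].segments[0]
        dev1 = recs[0].current_nA[s.start:s.stop] - recs[0].current_nA[s.start:s.stop].mean()
        dev2 = recs[1].current_nA[s.start:s.stop] - recs[1].current_nA[s.start:s.stop].mean()
        np.testing.assert_allclose(dev2, 2 * dev1, rtol=1e-6, atol=1e-12)


class TestCmVoltageSeries:
    def test_flat_capacitance_without_nlc(self, circuit):
        proto = TwoSineProtocol(dc_levels=(-100.0, -60.0, -20.0, 20.0, 60.0))
        rec = gen_voltage_clamp_recording(circuit, BoltzmannParams(qmax=0.0), proto, 0.0)
        points = cm_voltage_series(rec)
        for p in points:
            assert p.ok
            assert p.cm == pytest.approx(circuit.clin, rel=0.01)

    def test_peak_near_vpk(self, noisefree_recording, boltzmann):
        points = cm_voltage_series(noisefree_recording)
        best = max(points, key=lambda p: p.cm)
        dcs = sorted({s.dc_mV for s in noisefree_recording.segments})
        spacing = dcs[1] - dcs[0]
        assert abs(best.v - boltzmann.vpk) <= spacing

    def test_rs_zero_reports_dc_level_exactly(self):
        circ = CircuitParams(rs=0.0, rm=500.0, clin=7.0)
        proto = TwoSineProtocol(dc_levels=(-90.0, -70.0, -50.0, -30.0, -10.0))
        rec = gen_voltage_clamp_recording(circ, BoltzmannParams(qmax=0.0), proto, 0.0)
        for p, seg in zip(cm_voltage_series(rec), rec.segments):
            assert p.v == pytest.approx(seg.dc_mV, abs=1e-9)


class TestFitBoltzmann:
    def test_peak_height_identity(self):
        # at v = Vpk the NLC above Clin is exactly Qmax/(4*alpha)
        assert boltzmann_capacitance(-70.0, 800.0, 33.0, -70.0, 7.0) - 7.0 == pytest.approx(
            800.0 / (4 * 33.0)
        )

    def test_round_trip_on_exact_points(self):
        v = np.arange(-140.0, 61.0, 10.0)
        cm = boltzmann_capacitance(v, 800.0, 33.0, -70.0, 7.0)
        fit = fit_boltzmann((v, cm))
        assert fit.qmax == pytest.approx(800.0, rel=5e-3)
        assert fit.alpha == pytest.approx(33.0, rel=5e-3)
        assert fit.vpk == pytest.approx(-70.0, abs=0.5)
        assert fit.clin == pytest.approx(7.0, rel=5e-3)
        assert fit.charge_density == pytest.approx(800.0 / 7.0, rel=1e-2)

    def test_fitted_curve_symmetry_and_integral(self):
        v = np.arange(-140.0, 61.0, 10.0)
        cm = boltzmann_capacitance(v, 600.0, 28.0, -60.0, 6.0)
        fit = fit_boltzmann((v, cm))
        x = np.linspace(0.0, 120.0, 50)
        np.testing.assert_allclose(
            fit.curve(fit.vpk + x), fit.curve(fit.vpk - x), rtol=1e-12
        )
        grid = np.linspace(fit.vpk - 2000, fit.vpk + 2000, 400_001)
        integral = np.trapezoid(fit.curve(grid) - fit.clin, grid)
        assert integral == pytest.approx(fit.qmax, rel=1e-4)

    def test_charge_density_scale_invariance(self):
        v = np.arange(-140.0, 61.0, 10.0)
        fits = []
        for s in (1.0, 3.0):
            cm = boltzmann_capacitance(v, s * 500.0, 30.0, -65.0, s * 8.0)
            fits.append(fit_boltzmann((v, cm)))
        assert fits[0].charge_density == pytest.approx(fits[1].charge_density, rel=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError):
            fit_boltzmann((np.array([-80.0, -70, -60, -50]), np.array([7.0, 8, 7, 6])))

    def test_non_bracketing_span_warns(self):
        v = np.arange(0.0, 101.0, 10.0)
        cm = boltzmann_capacitance(v, 800.0, 33.0, -70.0, 7.0)
        with pytest.warns(UserWarning, match="voltage span"):
            fit_boltzmann((v, cm))


class TestFullWaveformFit:
    def test_recovery_degrades_monotonically_with_noise(self, circuit, boltzmann):
        proto = TwoSineProtocol()
        errs = []
        for noise in (0.0, 20.0, 100.0):
            per_seed = []
            for seed in (1, 2, 3):
                rec = gen_voltage_clamp_recording(circuit, boltzmann, proto, noise, seed=seed)
                fit = fit_nlc_recording(rec)
                per_seed.append(abs(fit.qmax - boltzmann.qmax) / boltzmann.qmax)
            errs.append(np.median(per_seed))
        assert errs[0] < errs[1] < errs[2]

    def test_recovers_circuit_parameters(self, noisefree_recording, circuit):
        fit = fit_nlc_recording(noisefree_recording)
        assert fit.rs == pytest.approx(circuit.rs, rel=1e-3)
        assert fit.rm == pytest.approx(circuit.rm, rel=1e-2)
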