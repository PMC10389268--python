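"""Forward-simulation signal equations, protocols, and noise model."""

import numpy as np
import pytest

import qmripipe as q
from qmripipe.acquire import spgr_signal
from qmripipe.epg import cpmg_echo_amplitudes, stimulated_echo_factors
from qmripipe.protocols import AcquisitionProtocol, default_protocol


class TestProtocols:
    def test_default_protocol_constants(self):
        se = default_protocol("multiecho_se")
        assert se.te_list == (13.0, 67.0, 93.0, 106.0) and se.n_repeats == 2
        vfa = default_protocol("vfa_ge")
        assert vfa.flip_angles == (4.0, 24.0) and vfa.tr == 16.4 and vfa.te_list == (6.7,)
        assert default_protocol("b1_pair").prep_angle_nominal == 45.0
        assert default_protocol("b0_pair").te_list == (4.89, 7.35)
        assert default_protocol("dualecho_ge").te_list == (4.3, 11.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(te_list=(20.0, 10.0)),  # non-increasing
            dict(te_list=(10.0, 20.0), tr=15.0),  # TE beyond TR
            dict(te_list=(10.0,), flip_angles=(200.0,)),
        ],
    )
    def test_invalid_protocols_rejected(self, kwargs):
        base = dict(sequence_kind="multiecho_se", te_list=(10.0, 20.0), tr=1000.0)
        with pytest.raises(ValueError):
            AcquisitionProtocol(**{**base, **kwargs})


class TestMultiechoSE:
    def test_echo_ratio_matches_closed_form(self, homogeneous_phantom):
        series = q.simulate_multiecho_se(homogeneous_phantom)
        cortex = homogeneous_phantom.mask("cortex")
        t2 = homogeneous_phantom.tissue_table["cortex"].t2
        ratio = series.volumes[0][cortex] / series.volumes[3][cortex]
        assert np.allclose(ratio, np.exp((106.0 - 13.0) / t2), rtol=1e-12)

    def test_near_zero_te_recovers_rx_pd(self, default_phantom):
        protocol = default_protocol("multiecho_se").with_updates(te_list=(1e-7, 13.0))
        series = q.simulate_multiecho_se(default_phantom, protocol)
        brain = default_phantom.brain_mask
        expected = (default_phantom.rx_profile * default_phantom.pd_map)[brain]
        assert np.allclose(series.volumes[0][brain], expected, rtol=1e-8)

    def test_signals_strictly_decreasing_in_te(self, default_phantom):
        series = q.simulate_multiecho_se(default_phantom)
        brain = default_phantom.brain_mask
        for earlier, later in zip(series.volumes[:3], series.volumes[1:4]):
            assert np.all(later[brain] < earlier[brain])

    def test_noiseless_repeats_bit_identical(self, default_phantom):
        series = q.simulate_multiecho_se(default_phantom)
        assert len(series.volumes) == 8  # 4 TE x 2 repeats
        for echo in range(4):
            assert np.array_equal(series.volumes[echo], series.volumes[echo + 4])

    def test_loglinear_slope_encodes_cortical_t2(self, homogeneous_phantom):
        """The log-signal slope over TE equals -1/T2 for the assigned cortical
        value (the patient-group cortical T2)."""
        series = q.simulate_multiecho_se(homogeneous_phantom)
        cortex = homogeneous_phantom.mask("cortex")
        tes = np.array(series.te_per_volume[:4])
        logs = np.log([v[cortex].mean() for v in series.volumes[:4]])
        slope = np.polyfit(tes, logs, 1)[0]
        assert -1.0 / slope == pytest.approx(80.97, rel=1e-9)


class TestVfaAndCalibrationScans:
    def test_ernst_saturation_limit(self):
        pd = np.full((2, 2, 2), 80.0)
        t1 = np.full((2, 2, 2), 1000.0)
        t2star = np.full((2, 2, 2), 45.0)
        b1 = np.ones((2, 2, 2))
        signal = spgr_signal(pd, t1, t2star, b1, alpha_deg=89.999, tr_ms=1e7, te_ms=6.7)
        assert np.allclose(signal, pd * np.exp(-6.7 / 45.0), rtol=1e-6)

    def test_vfa_signal_maximal_at_ernst_angle(self, homogeneous_phantom):
        tr = 16.4
        for tissue in ("wm", "cortex", "deep_gm"):
            params = homogeneous_phantom.tissue_table[tissue]
            e1 = np.exp(-tr / params.t1)
            angles = np.linspace(0.5, 80.0, 400)
            ones = np.ones((1, 1, 1))
            signals = [
                spgr_signal(ones, ones * params.t1, ones * params.t2star, ones, a, tr, 6.7)[0, 0, 0]
                for a in angles
            ]
            ernst = np.rad2deg(np.arccos(e1))
            assert abs(angles[int(np.argmax(signals))] - ernst) < 0.5

    def test_b1_pair_nominal_field_ratio_is_cos45(self, homogeneous_phantom):
        series = q.simulate_b1_pair(homogeneous_phantom, grid_scale=1)
        brain = homogeneous_phantom.brain_mask
        ratio = series.volumes[1][brain] / series.volumes[0][brain]
        assert np.allclose(ratio, np.cos(np.pi / 4), rtol=1e-12)
        assert ratio[0] == pytest.approx(0.70711, abs=5e-6)

    def test_b0_phase_evolution_at_50_hz(self, homogeneous_phantom):
        phantom = homogeneous_phantom
        phantom = q.make_phantom(shape=(32, 32, 32), seed=11, field_spec=q.FieldSpec(0, 0, 0))
        phantom.b0_map = np.full(phantom.shape, 50.0)
        series = q.simulate_b0_pair(phantom, grid_scale=1)
        dphi = series.phase_volumes[1] - series.phase_volumes[0]
        assert np.allclose(dphi, 2 * np.pi * 50.0 * 2.46e-3, rtol=1e-12)
        assert dphi.flat[0] == pytest.approx(0.77283, abs=5e-6)

    def test_b0_wrap_ambiguity_rejected(self):
        phantom = q.make_phantom(shape=(24, 24, 24), seed=0, field_spec=q.FieldSpec(0, 0, 0))
        phantom.b0_map = np.full(phantom.shape, 250.0)  # 2*pi*250*2.46ms > pi
        with pytest.raises(ValueError, match="wrap"):
            q.simulate_b0_pair(phantom)

    def test_dualecho_ratio_matches_t2star(self, homogeneous_phantom):
        series = q.simulate_dualecho_ge(homogeneous_phantom)
        wm = homogeneous_phantom.mask("wm")
        ratio = series.volumes[0][wm] / series.volumes[1][wm]
        assert np.allclose(ratio, np.exp(6.7 / 45.0), rtol=1e-12)
        assert ratio[0] == pytest.approx(1.16054, abs=1e-5)


class TestNoise:
    def test_infinite_snr_is_identity(self, default_phantom):
        series = q.simulate_multiecho_se(default_phantom)
        noisy = q.add_noise(series, np.inf, seed=1)
        for a, b in zip(series.volumes, noisy.volumes):
            assert np.array_equal(a, b)

    def test_high_snr_noise_sd_close_to_sigma(self, rng):
        from qmripipe.acquire import EchoSeries

        flat = np.full((40, 40, 40), 100.0)
        series = EchoSeries(
            volumes=[flat],
            protocol=default_protocol("multiecho_se"),
            te_per_volume=[13.0],
        )
        noisy = q.add_noise(series, snr=50.0, seed=7)
        assert noisy.noise_sigma == pytest.approx(2.0)
        assert noisy.volumes[0].std() == pytest.approx(noisy.noise_sigma, rel=0.05)

    def test_background_magnitude_follows_rayleigh_mean(self):
        from qmripipe.acquire import EchoSeries

        vol = np.zeros((40, 40, 40))
        vol[:2] = 100.0  # reference region for the SNR definition
        series = EchoSeries(
            volumes=[vol],
            protocol=default_protocol("multiecho_se"),
            te_per_volume=[13.0],
        )
        noisy = q.add_noise(series, snr=50.0, seed=3, reference_mask=vol > 0)
        background = noisy.volumes[0][vol == 0]
        expected = noisy.noise_sigma * np.sqrt(np.pi / 2.0)
        assert background.mean() == pytest.approx(expected, rel=0.01)

    def test_noise_deterministic_per_seed(self, default_phantom):
        series = q.simulate_vfa(default_phantom)
        n1 = q.add_noise(series, 30.0, seed=5)
        n2 = q.add_noise(series, 30.0, seed=5)
        n3 = q.add_noise(series, 30.0, seed=6)
        assert np.array_equal(n1.volumes[0], n2.volumes[0])
        assert not np.array_equal(n1.volumes[0], n3.volumes[0])


class TestEpgStimulatedEchoes:
    def test_ideal_refocusing_reduces_to_pure_exponential(self):
        t1 = np.array([900.0, 1500.0])
        t2 = np.array([60.0, 90.0])
        amps = cpmg_echo_amplitudes(t1, t2, esp_ms=13.3, n_echoes=6, refocus_deg=180.0)
        for k in range(6):
            assert np.allclose(amps[k], np.exp(-(k + 1) * 13.3 / t2), rtol=1e-12)

    def test_first_echo_amplitude_classic_formula(self):
        """First spin echo of a beta-refocused train: sin(alpha) sin^2(beta/2) E2."""
        t1, t2, beta = np.array([1e9]), np.array([80.0]), 160.0
        amps = cpmg_echo_amplitudes(t1, t2, esp_ms=13.3, n_echoes=1, refocus_deg=beta)
        expected = np.sin(np.pi / 2) * np.sin(np.deg2rad(beta) / 2) ** 2 * np.exp(-13.3 / 80.0)
        assert amps[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_contamination_factors_unity_at_180(self):
        f = stimulated_echo_factors(np.array([900.0]), np.array([62.0]), 13.3, 8, 180.0)
        assert np.allclose(f, 1.0, atol=1e-12)

    def test_simulator_contamination_mode_perturbs_late_echoes(self, homogeneous_phantom):
        clean = q.simulate_multiecho_se(homogeneous_phantom)
        contaminated = q.simulate_multiecho_se(homogeneous_phantom, stimulated_echoes=True)
        wm = homogeneous_phantom.mask("wm")
        assert not np.allclose(clean.volumes[3][wm], contaminated.volumes[3][wm])
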