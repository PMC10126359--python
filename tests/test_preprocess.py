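"""Optical-density conversion, Beer-Lambert inversion, filtering, and QC."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from nirsmci.preprocess import (
    MBLLParams,
    PreprocConfig,
    bandpass,
    butter_bandpass_gain,
    intensity_to_od,
    mbll_forward,
    mbll_invert,
    reject_noisy_channels,
    spatial_filter_eigen,
)

FS = 10.0


# ---------------------------------------------------------------------------
# Optical density
# ---------------------------------------------------------------------------


class TestIntensityToOD:
    def test_constant_intensity_gives_zero_od(self):
        od = intensity_to_od(np.full((2, 100), 5.0), FS, (0.0, 10.0))
        np.testing.assert_allclose(od, 0.0, atol=1e-15)

    def test_tenfold_drop_gives_unit_od(self):
        inten = np.full((1, 100), 2.0)
        inten[0, 50] = 0.2
        od = intensity_to_od(inten, FS, (0.0, 2.0))
        assert od[0, 50] == pytest.approx(1.0, abs=1e-12)

    def test_log10_closed_form(self):
        inten = np.full((1, 50), 3.0) * 10 ** (-0.02)
        inten[0, :10] = 3.0  # reference window
        od = intensity_to_od(inten, FS, (0.0, 1.0))
        np.testing.assert_allclose(od[0, 10:], 0.02, atol=1e-12)

    def test_non_positive_intensity_names_location(self):
        inten = np.ones((2, 10))
        inten[1, 3] = -1.0
        with pytest.raises(ValueError, match=r"\(1, 3\)"):
            intensity_to_od(inten, FS, (0.0, 1.0))


# ---------------------------------------------------------------------------
# Beer-Lambert
# ---------------------------------------------------------------------------


class TestMBLL:
    def test_zero_od_gives_zero_concentrations(self):
        hbo, hbr = mbll_invert(np.zeros((2, 5)), MBLLParams())
        np.testing.assert_array_equal(hbo, 0.0)
        np.testing.assert_array_equal(hbr, 0.0)

    @pytest.mark.parametrize("unit_mode", ["uM*mm", "uM"])
    def test_forward_then_invert_round_trip(self, unit_mode):
        params = MBLLParams(unit_mode=unit_mode)
        hbo_true = np.array([[1.0, -0.5, 2.0]])
        hbr_true = np.array([[-0.25, 0.1, -0.7]])
        od = mbll_forward(hbo_true, hbr_true, params)
        hbo, hbr = mbll_invert(od, params)
        np.testing.assert_allclose(hbo, hbo_true, atol=1e-10)
        np.testing.assert_allclose(hbr, hbr_true, atol=1e-10)

    def test_inversion_is_linear_in_od(self):
        rng = np.random.default_rng(0)
        od = rng.standard_normal((2, 4, 20)) * 0.01
        params = MBLLParams()
        hbo1, hbr1 = mbll_invert(od, params)
        hbo2, hbr2 = mbll_invert(2.0 * od, params)
        np.testing.assert_allclose(hbo2, 2.0 * hbo1, rtol=1e-12)
        np.testing.assert_allclose(hbr2, 2.0 * hbr1, rtol=1e-12)

    def test_singular_extinction_rejected(self):
        with pytest.raises(ValueError, match="ill-conditioned"):
            MBLLParams(extinction=np.array([[1.0, 2.0], [2.0, 4.0]]))

    def test_unit_mode_rescales_by_pathlength(self):
        od = np.full((2, 1, 3), 0.01)
        hbo_mm, _ = mbll_invert(od, MBLLParams(unit_mode="uM*mm"))
        hbo_um, _ = mbll_invert(od, MBLLParams(unit_mode="uM", distance=3.0))
        np.testing.assert_allclose(hbo_mm, hbo_um * 30.0, rtol=1e-12)


# ---------------------------------------------------------------------------
# Channel QC
# ---------------------------------------------------------------------------


class TestChannelRejection:
    def test_all_channels_within_threshold_kept(self):
        rng = np.random.default_rng(1)
        hbo = rng.standard_normal((8, 500)) * 10
        flags = reject_noisy_channels(hbo, threshold=300.0)
        assert all(v == "kept" for v in flags.values())

    def test_single_excursion_rejects_only_that_channel(self):
        rng = np.random.default_rng(2)
        hbo = rng.standard_normal((4, 500))
        hbo[2, 100] = hbo[2].mean() + 400.0
        flags = reject_noisy_channels(hbo, threshold=300.0)
        assert flags[3] == "rejected"
        assert [flags[c] for c in (1, 2, 4)] == ["kept"] * 3

    def test_sd_rule_ignores_brief_spikes(self):
        hbo = np.zeros((2, 1000))
        hbo[0, 10] = 400.0  # brief spike: huge peak, tiny SD
        flags_peak = reject_noisy_channels(hbo, threshold=300.0, rule="peak")
        flags_sd = reject_noisy_channels(hbo, threshold=300.0, rule="sd")
        assert flags_peak[1] == "rejected"
        assert flags_sd[1] == "kept"

    def test_all_rejected_raises(self):
        hbo = np.zeros((2, 100))
        hbo[:, 50] = 1000.0
        with pytest.raises(ValueError, match="unusable"):
            reject_noisy_channels(hbo, threshold=300.0)

    def test_qc_is_idempotent_and_order_independent(self):
        rng = np.random.default_rng(3)
        hbo = rng.standard_normal((6, 300)) * 50
        hbo[4, 10] = 500.0
        flags = reject_noisy_channels(hbo, threshold=300.0)
        again = reject_noisy_channels(hbo, threshold=300.0)
        assert flags == again
        perm = [3, 0, 5, 1, 4, 2]
        flags_perm = reject_noisy_channels(hbo[perm], threshold=300.0)
        assert [flags_perm[i + 1] for i in range(6)] == [flags[p + 1] for p in perm]


# ---------------------------------------------------------------------------
# Band-pass
# ---------------------------------------------------------------------------


class TestBandpass:
    def test_dc_is_rejected(self):
        out = bandpass(np.full(6000, 3.0), FS)
        assert np.abs(out).max() < 1e-6

    def _sine_gain(self, freq):
        # lock-in amplitude of the filtered sinusoid (transients trimmed),
        # isolating the response at the probe frequency from edge leakage
        t = np.arange(0, 2000, 1 / FS)
        out = bandpass(np.sin(2 * np.pi * freq * t), FS)
        core = slice(len(t) // 4, -len(t) // 4)
        phasor = np.exp(-2j * np.pi * freq * t[core])
        return 2 * np.abs(np.mean(out[core] * phasor))

    def test_cardiac_band_attenuated_40db(self):
        measured = self._sine_gain(1.1)
        oracle = butter_bandpass_gain(1.1, FS)[0]
        assert measured < 0.01  # >= 40 dB
        assert measured == pytest.approx(oracle, rel=0.05, abs=1e-8)

    def test_passband_gain_within_5_percent(self):
        measured = self._sine_gain(0.05)
        oracle = butter_bandpass_gain(0.05, FS)[0]
        assert 0.95 <= measured <= 1.05
        assert measured == pytest.approx(oracle, rel=0.02)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(np.zeros(5000), FS, band=(0.01, 6.0))
        with pytest.raises(ValueError, match="Nyquist"):
            PreprocConfig(band=(0.01, 6.0)).validate(FS)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="short"):
            bandpass(np.zeros(10), FS)

    def test_zero_phase_no_lag(self):
        # symmetric bump stays centered after filtering
        t = np.arange(0, 1000, 1 / FS)
        x = np.exp(-0.5 * ((t - 500) / 20) ** 2)
        out = bandpass(x, FS)
        assert abs(np.argmax(out) - np.argmax(x)) <= 1


# ---------------------------------------------------------------------------
# Spatial filter
# ---------------------------------------------------------------------------


class TestSpatialFilter:
    def test_rank_one_input_nulled(self):
        t = np.linspace(0, 100, 1000)
        matrix = np.tile(np.sin(0.3 * t), (8, 1))
        out = spatial_filter_eigen(matrix, k=1)
        assert np.abs(out).max() < 1e-10

    def test_global_component_removed_from_noisy_channels(self):
        rng = np.random.default_rng(4)
        t = np.arange(0, 600, 1 / FS)
        global_sig = np.sin(2 * np.pi * 0.1 * t) * 5
        matrix = rng.standard_normal((8, len(t))) + global_sig
        out = spatial_filter_eigen(matrix, k=1)
        for ch in range(8):
            r = np.corrcoef(out[ch], global_sig)[0, 1]
            assert abs(r) < 0.1

    def test_k_zero_is_identity(self):
        rng = np.random.default_rng(5)
        m = rng.standard_normal((4, 100))
        np.testing.assert_array_equal(spatial_filter_eigen(m, k=0), m)

    def test_k_at_least_n_channels_rejected(self):
        with pytest.raises(ValueError, match="k="):
            spatial_filter_eigen(np.zeros((3, 10)), k=3)

    def test_output_orthogonal_to_removed_component(self):
        rng = np.random.default_rng(6)
        m = rng.standard_normal((5, 400))
        centered = m - m.mean(axis=1, keepdims=True)
        u, _, _ = np.linalg.svd(centered, full_matrices=False)
        out = spatial_filter_eigen(m, k=2)
        proj = u[:, :2].T @ (out - out.mean(axis=1, keepdims=True))
        np.testing.assert_allclose(proj, 0.0, atol=1e-9)

    def test_rest_basis_preserves_task_pattern_orthogonal_to_interference(self):
        # interference lives on a fixed profile during rest; the task
        # pattern orthogonal to it must survive the projection
        rng = np.random.default_rng(7)
        t = np.arange(0, 600, 1 / FS)
        profile = np.array([1.0, -1.0, 0.5, -0.5])
        interference = np.outer(profile, np.sin(2 * np.pi * 0.1 * t) * 10)
        task_pattern = np.array([1.0, 1.0, 1.0, 1.0])  # orthogonal-ish
        task_pattern -= profile * (profile @ task_pattern) / (profile @ profile)
        task = np.outer(task_pattern, np.sin(2 * np.pi * 0.03 * t))
        noise = 0.01 * rng.standard_normal((4, len(t)))
        full = interference + task + noise
        basis = full[:, : len(t) // 3]  # task-free would be ideal; dominated by interference
        out = spatial_filter_eigen(full, k=1, basis=basis)
        # interference direction removed
        resid = profile @ (out - out.mean(axis=1, keepdims=True))
        assert np.abs(resid).max() < 0.5
        # task component retained
        kept = task_pattern @ out / (task_pattern @ task_pattern)
        r = np.corrcoef(kept, np.sin(2 * np.pi * 0.03 * t))[0, 1]
        assert r > 0.95

    def test_negligible_basis_skips_filtering(self):
        rng = np.random.default_rng(8)
        m = rng.standard_normal((4, 1000))
        basis = np.zeros((4, 100))
        np.testing.assert_array_equal(spatial_filter_eigen(m, k=1, basis=basis), m)


# ---------------------------------------------------------------------------
# Chain properties
# ---------------------------------------------------------------------------


@given(scale=st.floats(min_value=0.1, max_value=10.0))
def test_mbll_bandpass_chain_is_exactly_linear_in_od(scale):
    rng = np.random.default_rng(9)
    od = rng.standard_normal((2, 3, 2000)) * 1e-3
    params = MBLLParams()

    def chain(x):
        hbo, _ = mbll_invert(x, params)
        return bandpass(hbo, FS)

    base = chain(od)
    scaled = chain(scale * od)
    np.testing.assert_allclose(
        scaled, scale * base, rtol=0, atol=1e-10 * np.abs(scale * base).max()
    )


def test_full_intensity_chain_is_linear_to_leading_order():
    # the exp/log intensity step is only affinely linear; at physiological
    # OD magnitudes the deviation is second order and far below signal scale
    rng = np.random.default_rng(10)
    hbo = rng.standard_normal((3, 2000)) * 0.5
    hbr = -hbo / 3.0
    params = MBLLParams()

    def chain(h_o, h_r):
        od = mbll_forward(h_o, h_r, params)
        inten = np.power(10.0, -od)
        od2 = intensity_to_od(inten, FS, (0.0, 10.0))
        o, _ = mbll_invert(od2, params)
        return bandpass(o, FS)

    base = chain(hbo, hbr)
    scaled = chain(3.0 * hbo, 3.0 * hbr)
    np.testing.assert_allclose(scaled, 3.0 * base, atol=1e-6)
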