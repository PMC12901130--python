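"""Bias correction, tissue statistics, contrast/noise/CNR, QI, full QC."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from scipy import stats

from flairqc.core import TissueMasks, Volume
from flairqc.phantom import PhantomSpec, generate_phantom
from flairqc.qc_metrics import (
    QCConfig,
    compute_cnr,
    compute_contrast,
    compute_qc,
    compute_qi,
    correct_bias,
    estimate_bias_field,
    estimate_noise,
    tissue_stats,
)

SMALL = dict(matrix_size=(64, 64, 64), voxel_spacing_mm=(2.5, 2.5, 2.5), supersample=1)


class TestBiasCorrection:
    def test_bias_free_volume_is_almost_untouched_in_brain(self, default_phantom):
        _, vol, truth = default_phantom
        corrected = correct_bias(vol, truth.masks)
        brain = truth.masks.wm | truth.masks.gm | truth.masks.csf
        rel = np.abs(corrected.data[brain] - vol.data[brain]) / vol.data[brain]
        assert rel.max() < 0.01

    def test_wm_coefficient_of_variation_drops_below_5_percent(self, biased_phantom):
        _, vol, truth = biased_phantom
        corrected = correct_bias(vol, truth.masks)
        wm = truth.masks.wm
        cov = np.std(corrected.data[wm]) / np.mean(corrected.data[wm])
        assert cov < 0.05

    def test_recovered_field_correlates_with_injected_field(self, biased_phantom):
        _, vol, truth = biased_phantom
        field = estimate_bias_field(vol, truth.masks)
        brain = truth.masks.wm | truth.masks.gm | truth.masks.csf
        r = np.corrcoef(field[brain], truth.bias_field[brain])[0, 1]
        assert r > 0.95

    def test_empty_brain_mask_is_an_error(self, default_phantom):
        _, vol, truth = default_phantom
        z = np.zeros(vol.shape, bool)
        empty = TissueMasks(wm=z, gm=z, csf=z, head=truth.masks.head, background=z)
        with pytest.raises(ValueError, match="empty brain"):
            estimate_bias_field(vol, empty)


class TestTissueStats:
    def test_noise_free_medians_are_exact(self, default_phantom):
        _, vol, truth = default_phantom
        assert tissue_stats(vol, truth.masks) == (200.0, 300.0, 50.0)

    def test_rician_noise_medians_within_one_signal_unit(self):
        """Monte-Carlo: Rician noise sd 10 barely moves the tissue medians."""
        for seed in range(20):
            spec = PhantomSpec(**SMALL, noise_sd=10.0, seed=seed)
            vol, truth = generate_phantom(spec)
            mu = tissue_stats(vol, truth.masks)
            # Rician bias is expected at low SNR (CSF at 50: SNR 5), so
            # compare against the analytic Rician median per tissue
            for est, nu in zip(mu, (200.0, 300.0, 50.0)):
                true_med = stats.rice.median(nu / 10.0, scale=10.0)
                assert abs(est - true_med) < 1.0, (seed, nu)

    def test_empty_gm_mask_error_names_the_tissue(self, default_phantom):
        _, vol, truth = default_phantom
        m = truth.masks
        masks = TissueMasks(
            wm=m.wm, gm=np.zeros_like(m.gm), csf=m.csf, head=m.head,
            background=m.background,
        )
        with pytest.raises(ValueError, match="GM"):
            tissue_stats(vol, masks)


class TestContrastAndCNR:
    @pytest.mark.parametrize(
        "mu_gm, mu_wm, expected", [(300.0, 200.0, 0.2), (200.0, 200.0, 0.0)]
    )
    def test_michelson_contrast_arithmetic(self, mu_gm, mu_wm, expected):
        assert compute_contrast(mu_gm, mu_wm) == pytest.approx(expected)

    def test_zero_means_rejected(self):
        with pytest.raises(ValueError):
            compute_contrast(0.0, 0.0)

    def test_contrast_recovery_across_device_scaling(self):
        """Phantoms with scaled GM/WM separation recover the analytic
        Michelson contrast within 5% at noise <= 5% of the WM mean."""
        for c_scale in (0.6, 1.0, 1.4):
            m = 0.2 * c_scale
            gm = 200.0 * (1 + m) / (1 - m)
            spec = PhantomSpec(
                **SMALL,
                tissue_means={"WM": 200.0, "GM": gm, "CSF": 50.0, "background": 0.0},
                noise_sd=10.0,
                seed=31,
            )
            vol, truth = generate_phantom(spec)
            mu_wm, mu_gm, _ = tissue_stats(vol, truth.masks)
            assert abs(compute_contrast(mu_gm, mu_wm) / m - 1) < 0.05

    @pytest.mark.parametrize(
        "mu_gm, mu_wm, sd, expected",
        [(300.0, 200.0, 10.0, 10.0), (200.0, 300.0, 10.0, -10.0)],
    )
    def test_cnr_arithmetic_preserves_sign(self, mu_gm, mu_wm, sd, expected):
        assert compute_cnr(mu_gm, mu_wm, sd) == pytest.approx(expected)

    def test_cnr_with_zero_noise_points_to_the_flag(self):
        with pytest.raises(ValueError, match="noise-free"):
            compute_cnr(300.0, 200.0, 0.0)

    def test_cnr_slope_against_truth_across_noise_levels(self):
        """Estimated CNR tracks the analytic (GM-WM)/sigma within 10%."""
        est, true = [], []
        for sd in (5.0, 10.0, 20.0):
            spec = PhantomSpec(**SMALL, noise_sd=sd, seed=17)
            vol, truth = generate_phantom(spec)
            mu_wm, mu_gm, _ = tissue_stats(vol, truth.masks)
            est.append(compute_cnr(mu_gm, mu_wm, estimate_noise(vol, truth.masks)))
            true.append(100.0 / sd)
        slope = np.polyfit(true, est, 1)[0]
        assert 0.9 <= slope <= 1.1


class TestNoiseEstimate:
    def test_noise_free_phantom_estimates_zero(self, default_phantom):
        _, vol, truth = default_phantom
        assert estimate_noise(vol, truth.masks) < 1e-6

    def test_gaussian_noise_on_constant_block_within_10_percent(self, rng):
        shape = (48, 48, 48)
        m = np.zeros(shape, bool)
        m[8:-8, 8:-8, 8:-8] = True
        z = np.zeros(shape, bool)
        masks = TissueMasks(wm=m, gm=z, csf=z, head=m, background=~m)
        errs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            vol = Volume(200.0 + r.normal(0, 10.0, shape), (2.0, 2.0, 2.0))
            errs.append(estimate_noise(vol, masks) / 10.0 - 1.0)
        assert np.all(np.abs(errs) < 0.10)
        assert abs(np.mean(errs)) < 0.03  # calibrated, not just bounded

    def test_estimate_invariant_to_constant_offset(self):
        spec = PhantomSpec(**SMALL, noise_sd=8.0, seed=3)
        vol, truth = generate_phantom(spec)
        base = estimate_noise(vol, truth.masks)
        shifted = Volume(vol.data + 500.0, vol.spacing_mm)
        assert abs(estimate_noise(shifted, truth.masks) / base - 1) < 0.02


class TestQI:
    def test_clean_background_scores_at_least_099(self):
        spec = PhantomSpec(**SMALL, noise_sd=5.0, seed=41)
        vol, truth = generate_phantom(spec)
        assert compute_qi(vol, truth.masks) >= 0.99

    def test_qi_monotone_non_increasing_in_ghost_amplitude(self):
        qis = []
        for amp in (0.0, 0.05, 0.1, 0.2):
            spec = PhantomSpec(**SMALL, noise_sd=2.0, ghost_amplitude=amp, seed=42)
            vol, truth = generate_phantom(spec)
            qis.append(compute_qi(vol, truth.masks))
        assert all(a >= b for a, b in zip(qis, qis[1:])), qis
        assert qis[-1] < qis[0]  # a 20% ghost must actually be detected

    def test_zero_background_gives_exactly_one(self, default_phantom):
        _, vol, truth = default_phantom
        assert compute_qi(vol, truth.masks) == 1.0

    def test_too_small_background_is_an_error(self):
        spec = PhantomSpec(**SMALL, seed=1)
        vol, truth = generate_phantom(spec)
        cfg = QCConfig(qi_min_background=10**7)
        with pytest.raises(ValueError, match="background too small"):
            compute_qi(vol, truth.masks, cfg)


@pytest.fixture(scope="module")
def anisotropic_result():
    spec = PhantomSpec(
        matrix_size=(96, 96, 96),
        voxel_spacing_mm=(1.5, 1.5, 1.5),
        supersample=4,
        blur_fwhm_mm=(0.5 * 2.3548, 1.5 * 2.3548, 1.0 * 2.3548),
        noise_sd=3.0,
        seed=55,
    )
    vol, truth = generate_phantom(spec)
    return vol, truth


class TestComputeQC:
    def test_anisotropic_blur_orders_the_axis_mtfs(self, anisotropic_result):
        vol, truth = anisotropic_result
        res = compute_qc(vol, truth.masks)
        assert res.mtf50["FH"] > res.mtf50["RL"] > res.mtf50["AP"]
        for ax in ("FH", "AP", "RL"):
            assert res.mtf10[ax] >= res.mtf50[ax]
            assert res.n_edges_used[ax] >= 50

    def test_same_study_analysed_twice_gives_identical_results(self, anisotropic_result):
        vol, truth = anisotropic_result
        r1 = compute_qc(vol, truth.masks)
        r2 = compute_qc(vol, truth.masks)
        assert r1 == r2

    def test_partial_result_with_flags_on_stage_failure(self):
        spec = PhantomSpec(**SMALL, noise_sd=5.0, seed=6)
        vol, truth = generate_phantom(spec)
        # supersample=1 leaves no sub-voxel phase diversity, but the QC
        # must still deliver the non-MTF parameters with flags for the rest
        res = compute_qc(vol, truth.masks, QCConfig(mtf=dataclasses.replace(QCConfig().mtf, min_profiles=10**6)))
        assert res.contrast is not None
        assert res.noise_sd is not None
        assert res.qi is not None
        assert res.mtf50 == {}
        assert {"mtf_fh", "mtf_ap", "mtf_rl"} <= set(res.flags)
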