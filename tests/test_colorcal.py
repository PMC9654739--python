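"""Thin-plate-spline colour calibration: fitting, application, reporting."""

import numpy as np
import pytest
import yaml
from scipy.interpolate import RBFInterpolator

from olivesort import colorcal, synthgen
from olivesort.colorcal import (
    ChartObservation,
    DegenerateGeometryError,
    TPSColorMap,
    apply_tps,
    calibration_report,
    classic_reference,
    extract_patch_colors,
    fit_tps,
)


def _scalar_tps_eval(tps, color):
    """Independent per-colour evaluation: plain Python loop over control points."""
    out = []
    for ch in range(3):
        acc = tps.affine[ch, 0]
        for k in range(3):
            acc += tps.affine[ch, 1 + k] * color[k]
        for i, c in enumerate(tps.control_points):
            r = float(np.sqrt(sum((color[k] - c[k]) ** 2 for k in range(3))))
            if tps.kernel_id == "r3d":
                phi = r
            else:
                phi = r * r * np.log(r) if r > 0 else 0.0
            acc += tps.kernel_weights[i, ch] * phi
        out.append(acc)
    return np.array(out)


class TestExtractPatchColors:
    def test_constant_field_yields_constant_means(self):
        img = np.full((60, 80, 3), (10, 20, 30), dtype=np.uint8)
        rois = [(2 * i, 1, 2, 4) for i in range(24)]
        obs = extract_patch_colors(img, rois)
        assert np.allclose(obs.measured_rgb, (10, 20, 30))

    def test_matches_generator_truth_without_noise(self):
        img, truth_obs, rois = synthgen.make_distorted_chart(distortion="affine")
        obs = extract_patch_colors(img, rois)
        # rendered patches are constant, so means equal the rounded truth
        assert np.allclose(obs.measured_rgb, np.rint(truth_obs.measured_rgb))

    def test_noisy_patch_means_within_clt_bound(self):
        sigma = 2.0
        img, truth_obs, rois = synthgen.make_distorted_chart(
            distortion="identity", noise_sigma=sigma, seed=7, patch_size=20
        )
        obs = extract_patch_colors(img, rois)
        bound = 3 * sigma / np.sqrt(20 * 20)
        err = np.abs(obs.measured_rgb - truth_obs.measured_rgb)
        # half a grey level of quantisation on top of the sampling error
        assert (err <= bound + 0.5).all()

    def test_roi_outside_image_raises(self):
        img = np.zeros((50, 50, 3), dtype=np.uint8)
        rois = [(0, 0, 2, 2)] * 23 + [(49, 49, 4, 4)]
        with pytest.raises(IndexError, match="patch 24"):
            extract_patch_colors(img, rois)

    def test_empty_roi_raises(self):
        img = np.zeros((50, 50, 3), dtype=np.uint8)
        rois = [(0, 0, 2, 2)] * 23 + [(1, 1, 0, 3)]
        with pytest.raises(ValueError, match="empty ROI"):
            extract_patch_colors(img, rois)


class TestFitTPS:
    def test_identity_observation_gives_identity_map(self, rng):
        ref = classic_reference()
        obs = ChartObservation(ref.patch_rgb.copy(), ref)
        tps = fit_tps(obs)
        assert np.abs(tps.kernel_weights).max() < 1e-9
        assert np.allclose(tps.affine[:, 0], 0.0, atol=1e-6)
        assert np.allclose(tps.affine[:, 1:], np.eye(3), atol=1e-8)
        colors = rng.uniform(0, 255, (50, 3))
        assert np.abs(tps(colors) - colors).max() < 1e-6

    def test_affine_relation_absorbed_by_affine_block(self):
        ref = classic_reference()
        measured = 0.9 * ref.patch_rgb + 10.0
        tps = fit_tps(ChartObservation(measured, ref))
        assert np.abs(tps.kernel_weights).max() < 1e-6
        assert np.abs(tps(measured) - ref.patch_rgb).max() < 1e-6

    @pytest.mark.parametrize("kernel", ["r3d", "r2logr"])
    def test_nonlinear_distortion_interpolated_exactly(self, kernel):
        _, obs, _ = synthgen.make_distorted_chart(distortion="gamma_mix")
        tps = fit_tps(obs, kernel_id=kernel)
        resid = np.abs(tps(obs.measured_rgb) - obs.reference.patch_rgb)
        assert resid.max() < 1e-6

    def test_coincident_control_points_named(self):
        ref = classic_reference()
        measured = ref.patch_rgb.copy()
        measured[5] = measured[2]
        with pytest.raises(DegenerateGeometryError, match="3&6"):
            fit_tps(ChartObservation(measured, ref))

    def test_coplanar_control_points_rejected(self):
        ref = classic_reference()
        measured = ref.patch_rgb.copy()
        measured[:, 2] = measured[:, 0]  # all colours on the plane B = R
        with pytest.raises(DegenerateGeometryError, match="coplanar"):
            fit_tps(ChartObservation(measured, ref))

    def test_regularized_fit_tolerates_duplicates(self):
        ref = classic_reference()
        measured = ref.patch_rgb.copy()
        measured[5] = measured[2]
        tps = fit_tps(ChartObservation(measured, ref), regularization=1.0)
        assert np.isfinite(tps.kernel_weights).all()

    def test_matches_scipy_rbf_interpolant(self, rng):
        """Independent route: scipy's RBF interpolator with the same kernel
        and degree-1 polynomial tail defines the same unique interpolant."""
        _, obs, _ = synthgen.make_distorted_chart(distortion="gamma_mix")
        tps = fit_tps(obs, kernel_id="r3d")
        oracle = RBFInterpolator(
            obs.measured_rgb, obs.reference.patch_rgb, kernel="linear", degree=1
        )
        colors = rng.uniform(0, 255, (100, 3))
        assert np.abs(tps(colors) - oracle(colors)).max() < 1e-6


class TestApplyTPS:
    def test_identity_map_preserves_image(self, rng):
        ref = classic_reference()
        tps = fit_tps(ChartObservation(ref.patch_rgb.copy(), ref))
        img = rng.integers(0, 256, (40, 30, 3), dtype=np.uint8)
        assert np.array_equal(apply_tps(tps, img), img)

    def test_vectorized_equals_scalar_oracle(self, rng):
        _, obs, _ = synthgen.make_distorted_chart(distortion="gamma_mix")
        tps = fit_tps(obs)
        colors = rng.uniform(0, 255, (200, 3))
        expected = np.stack([_scalar_tps_eval(tps, c) for c in colors])
        assert np.abs(tps(colors) - expected).max() < 1e-6
        img = colors.reshape(10, 20, 3)
        assert np.array_equal(
            apply_tps(tps, img),
            np.clip(np.rint(expected), 0, 255).astype(np.uint8).reshape(10, 20, 3),
        )

    def test_saturating_offset_clips_everything(self):
        ref = classic_reference()
        obs = ChartObservation(ref.patch_rgb.copy(), ref)
        tps = TPSColorMap(
            control_points=ref.patch_rgb.copy(),
            affine=np.hstack([np.full((3, 1), 300.0), np.eye(3)]),
            kernel_weights=np.zeros((24, 3)),
        )
        img = np.full((8, 8, 3), 100, dtype=np.uint8)
        corrected, frac = apply_tps(tps, img, return_clip_fraction=True)
        assert (corrected == 255).all()
        assert frac == 1.0
        report = calibration_report(tps, obs, image=img)
        assert report.clipped_fraction == 1.0


class TestCalibrationReport:
    def test_exact_fit_has_zero_rmse(self):
        _, obs, _ = synthgen.make_distorted_chart(distortion="gamma_mix")
        report = calibration_report(fit_tps(obs), obs)
        assert report.rmse <= 1e-6
        assert np.isclose(
            report.rmse, np.sqrt(np.mean(report.per_patch_residual**2))
        )

    def test_identity_observation_zero_residuals(self):
        ref = classic_reference()
        obs = ChartObservation(ref.patch_rgb.copy(), ref)
        report = calibration_report(fit_tps(obs), obs)
        assert np.allclose(report.per_patch_residual, 0.0, atol=1e-9)

    def test_smoothing_increases_control_point_residual(self, rng):
        ref = classic_reference()
        measured = np.clip(
            synthgen.distort_colors(ref.patch_rgb, "gamma_mix")
            + rng.normal(0, 3, (24, 3)),
            0,
            255,
        )
        obs = ChartObservation(measured, ref)
        rmse0 = calibration_report(fit_tps(obs, regularization=0.0), obs).rmse
        rmse10 = calibration_report(fit_tps(obs, regularization=10.0), obs).rmse
        assert rmse10 > rmse0


def test_distortion_recovery_reduces_color_error_by_80_percent():
    """Calibrating a distorted scene via its chart must remove at least 80%
    of the RMS colour error on the olive pixels."""
    crops = [
        synthgen.make_crop(cls, seed=i)[0]
        for i, cls in enumerate(
            ["Bad Black", "Good Black", "Bad Green", "Good Green", "Top Green"]
        )
    ]
    original = np.concatenate([c.reshape(-1, 3) for c in crops]).astype(float)
    distorted = np.clip(
        np.rint(synthgen.distort_colors(original, "gamma_mix")), 0, 255
    )
    img, _, rois = synthgen.make_distorted_chart(distortion="gamma_mix")
    tps = fit_tps(extract_patch_colors(img, rois))
    corrected = apply_tps(tps, distorted.reshape(1, -1, 3)).reshape(-1, 3).astype(float)
    rmse_before = np.sqrt(np.mean((distorted - original) ** 2))
    rmse_after = np.sqrt(np.mean((corrected - original) ** 2))
    assert rmse_after <= 0.2 * rmse_before


def test_chart_roi_yaml_roundtrip(tmp_path):
    rois = [[i, 2 * i, 5, 6] for i in range(24)]
    path = tmp_path / "chart.yaml"
    path.write_text(yaml.safe_dump(rois))
    assert colorcal.load_chart_rois(path) == [tuple(r) for r in rois]
    path.write_text(yaml.safe_dump(rois[:23]))
    with pytest.raises(ValueError):
        colorcal.load_chart_rois(path)
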