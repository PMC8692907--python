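import math

import numpy as np
import pytest
from scipy import integrate, special

from vasoquant.imaging_io import RasterImage, VolumeScan, compute_mip
from vasoquant.phantom import (
    PhantomSpec,
    generate_phantom,
    score_against_truth,
    truth_metrics,
    kappa_for_turning_rate,
)
from vasoquant.metrics import turning_angles_deg
from vasoquant.pipeline import RunConfig, process_image


class TestSpecValidation:
    def test_requires_count_or_fill(self):
        with pytest.raises(ValueError):
            PhantomSpec(n_vessels=None, target_fill_pct=None)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_vessels": 1, "pixel_size_um": 0.0},
            {"target_fill_pct": 70.0},
            {"n_vessels": 1, "snr": -1.0},
            {"n_vessels": 1, "layout": "weird"},
        ],
    )
    def test_range_checks(self, kwargs):
        with pytest.raises(ValueError):
            PhantomSpec(**kwargs)


class TestKappaCalibration:
    def test_inverts_mean_abs_turning(self):
        # check E|vonmises(kappa)| equals the requested mean via quadrature
        for rate, step in [(1.0, 10.0), (2.44, 10.0), (3.84, 5.0)]:
            kappa = kappa_for_turning_rate(rate, step)
            target = math.radians(rate * step)
            got, _ = integrate.quad(
                lambda t: t * math.exp(kappa * (math.cos(t) - 1.0)), 0, math.pi
            )
            got /= math.pi * special.i0e(kappa)
            assert got == pytest.approx(target, rel=1e-6)

    def test_saturates_at_uniform(self):
        assert kappa_for_turning_rate(90.0, 1.0) == 0.0


class TestGeneratePhantom:
    def test_null_phantom(self):
        spec = PhantomSpec(n_vessels=0, snr=0.0, background=0.07, seed=0)
        img, truth = generate_phantom(spec)
        assert truth.vessel_count == 0
        assert truth.fill_fraction_pct == 0.0
        assert np.allclose(img.pixels, 0.07)

    def test_determinism_bit_identical(self):
        spec = PhantomSpec.vegf_like(seed=5)
        img1, t1 = generate_phantom(spec)
        img2, t2 = generate_phantom(PhantomSpec.vegf_like(seed=5))
        np.testing.assert_array_equal(img1.pixels, img2.pixels)
        np.testing.assert_array_equal(t1.mask, t2.mask)
        for a, b in zip(t1.centerlines_um, t2.centerlines_um):
            np.testing.assert_array_equal(a, b)

    def test_different_seeds_differ(self):
        img1, _ = generate_phantom(PhantomSpec.wt_like(seed=1))
        img2, _ = generate_phantom(PhantomSpec.wt_like(seed=2))
        assert not np.array_equal(img1.pixels, img2.pixels)

    def test_fill_target_reached_within_band(self):
        spec = PhantomSpec(target_fill_pct=15.0, seed=3)
        _, truth = generate_phantom(spec)
        assert 13.5 <= truth.fill_fraction_pct <= 16.5

    def test_infeasible_fill_reports_achieved(self):
        # every candidate vessel overshoots the small target, so the
        # fill can never enter the acceptance band
        spec = PhantomSpec(
            target_fill_pct=10.0, shape_px=(40, 40), width_median_um=300.0,
            width_sigma=0.0, seed=0,
        )
        with pytest.raises(ValueError, match="achieved"):
            generate_phantom(spec)

    def test_truth_tortuosity_consistent_with_polylines(self):
        _, truth = generate_phantom(PhantomSpec.wt_like(seed=2))
        for poly, tort, length in zip(
            truth.centerlines_um, truth.tortuosities_deg_per_um, truth.lengths_um
        ):
            seg = np.diff(poly, axis=0)
            L = np.hypot(seg[:, 0], seg[:, 1]).sum()
            assert L == pytest.approx(length, rel=1e-9)
            assert turning_angles_deg(poly).sum() / L == pytest.approx(tort, rel=1e-9)

    def test_turning_rate_monotonic_in_spec(self):
        means = []
        for rate in (0.5, 1.5, 3.0):
            _, truth = generate_phantom(
                PhantomSpec(n_vessels=8, turning_rate_deg_per_um=rate,
                            width_median_um=20.0, seed=11)
            )
            means.append(np.mean(truth.tortuosities_deg_per_um))
        assert means[0] < means[1] < means[2]

    def test_volume_phantom_mip_recovers_scene(self):
        spec = PhantomSpec(n_vessels=4, n_depth_layers=2, snr=0.0, seed=4)
        vol, truth = generate_phantom(spec)
        assert isinstance(vol, VolumeScan)
        mip = compute_mip(vol)
        # vessel pixels bright, background at the background level
        assert mip.pixels[truth.mask].mean() > 5 * spec.background
        assert abs(mip.pixels[~truth.mask].mean() - spec.background) < 0.05

    def test_image_pitch_recorded(self):
        img, _ = generate_phantom(PhantomSpec(n_vessels=1, pixel_size_um=20.0, seed=0))
        assert isinstance(img, RasterImage)
        assert img.pixel_size_um == 20.0


class TestScoreAgainstTruth:
    def test_truth_scored_against_itself_is_exact(self):
        _, truth = generate_phantom(PhantomSpec.wt_like(seed=6))
        rec = truth_metrics(truth)
        self_segments = [
            (truth.centerlines_um[i], truth.widths_um[i],
             truth.tortuosities_deg_per_um[i])
            for i in range(truth.vessel_count)
        ]
        score = score_against_truth(rec, truth, self_segments)
        assert score["count_error"] == 0
        assert score["fill_abs_error_pct"] == 0.0
        assert score["diameter_mae_um"] == pytest.approx(0.0, abs=1e-9)
        assert score["tortuosity_mae_deg_per_um"] == pytest.approx(0.0, abs=1e-9)

    def test_clean_separated_phantom_count_exact(self):
        spec = PhantomSpec(
            n_vessels=5, layout="parallel", fixed_widths_um=(25.0,),
            pixel_size_um=5.0, snr=0.0, seed=0,
        )
        img, truth = generate_phantom(spec)
        cfg = RunConfig(manifest="", output_dir="")
        rec, mask, graph, _ = process_image(img, cfg, {}, True)
        score = score_against_truth(rec, truth, graph)
        assert score["count_error"] == 0
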