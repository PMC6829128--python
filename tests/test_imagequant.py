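"""Projection, line-probe sampling, background subtraction, densitometry."""

import numpy as np
import pytest

from folliclescreen.imagequant import (
    DensitometryRecord,
    ImageStack,
    LineProbe,
    ProbeError,
    RegionProbe,
    corrected_membrane_intensity,
    densitometry_normalize,
    max_project,
    probe_mean,
    synth_follicle_image,
)


class TestMaxProject:
    def test_zero_slice_drops_out(self):
        a = np.full((4, 4), 7.0)
        stack = ImageStack(np.stack([np.zeros((4, 4)), a]))
        assert np.array_equal(max_project(stack), a)

    def test_single_slice_is_identity(self):
        a = np.arange(16.0).reshape(4, 4)
        stack = ImageStack(np.stack([a, a + 1]))
        assert np.array_equal(max_project(stack, (0, 1)), a)

    def test_invariant_to_slice_order(self):
        rng = np.random.default_rng(0)
        slices = rng.uniform(0, 10, (3, 5, 5))
        fwd = max_project(ImageStack(slices))
        rev = max_project(ImageStack(slices[::-1]))
        assert np.array_equal(fwd, rev)

    def test_empty_range_is_error(self):
        stack = ImageStack(np.zeros((2, 4, 4)))
        with pytest.raises(ValueError):
            max_project(stack, (1, 1))


class TestProbeMean:
    def test_constant_image_exact(self):
        img = np.full((20, 20), 3.25)
        probe = LineProbe(((2.3, 4.7), (15.1, 9.2)))
        assert probe_mean(img, probe) == pytest.approx(3.25, abs=1e-12)

    def test_step_edge_one_side(self):
        img = np.zeros((20, 20))
        img[:, 10:] = 42.0
        left = LineProbe(((1.0, 2.0), (8.0, 17.0)))
        right = LineProbe(((11.0, 2.0), (18.0, 17.0)))
        assert probe_mean(img, left) == pytest.approx(0.0)
        assert probe_mean(img, right) == pytest.approx(42.0)

    def test_out_of_bounds_vertex_named(self):
        img = np.zeros((10, 10))
        with pytest.raises(ProbeError, match="vertex 1"):
            probe_mean(img, LineProbe(((2.0, 2.0), (40.0, 2.0))))

    def test_translation_invariance(self):
        """Shifting image and probe together changes nothing (noiseless)."""
        rng = np.random.default_rng(1)
        img = np.pad(rng.uniform(0, 100, (20, 20)), 10)
        probe = LineProbe(((12.5, 14.2), (25.3, 22.8)))
        base = probe_mean(img, probe)
        shifted_img = np.roll(np.roll(img, 3, axis=0), 5, axis=1)
        shifted_probe = LineProbe(tuple((x + 5, y + 3) for x, y in probe.vertices))
        assert probe_mean(shifted_img, shifted_probe) == pytest.approx(base, abs=1e-6)

    def test_ridge_crest_within_tolerance(self):
        """Synthetic membrane ridge 150 AU above a 50 AU interior: the probe
        on the crest reads ~200 AU within the interpolation tolerance."""
        fix = synth_follicle_image(200.0, 50.0, seed=2, noise_sd=0.0)
        img = max_project(fix.stack)
        assert probe_mean(img, fix.membrane_probe) == pytest.approx(200.0, abs=2.0)


class TestCorrectedIntensity:
    def test_noiseless_recovery(self):
        fix = synth_follicle_image(200.0, 50.0, seed=3, noise_sd=0.0)
        ci = corrected_membrane_intensity(
            max_project(fix.stack), fix.membrane_probe, fix.cytoplasm_probe
        )
        assert ci.corrected == pytest.approx(150.0, abs=2.0)

    def test_membrane_equals_cytoplasm_gives_zero(self):
        fix = synth_follicle_image(80.0, 80.0, seed=4, noise_sd=0.0)
        ci = corrected_membrane_intensity(
            max_project(fix.stack), fix.membrane_probe, fix.cytoplasm_probe
        )
        assert ci.corrected == pytest.approx(0.0, abs=1e-9)

    def test_offset_invariance(self):
        """Adding a constant to the whole image leaves the corrected value
        unchanged: that cancellation is the point of the subtraction."""
        fix = synth_follicle_image(180.0, 60.0, seed=5, noise_sd=4.0)
        img = max_project(fix.stack)
        base = corrected_membrane_intensity(img, fix.membrane_probe, fix.cytoplasm_probe)
        offset = corrected_membrane_intensity(
            img + 37.5, fix.membrane_probe, fix.cytoplasm_probe
        )
        assert offset.corrected == pytest.approx(base.corrected, abs=1e-9)

    def test_negative_corrected_flagged_not_clipped(self):
        img = np.full((30, 30), 100.0)
        img[10:20, 10:20] = 200.0  # bright cytoplasm region
        probe = LineProbe(((2.0, 2.0), (8.0, 2.0)))
        region = RegionProbe(vertices=((10, 10), (19, 10), (19, 19), (10, 19)))
        ci = corrected_membrane_intensity(img, probe, region)
        assert ci.corrected < 0
        assert ci.negative

    def test_overlapping_probes_rejected(self):
        img = np.full((30, 30), 1.0)
        probe = LineProbe(((12.0, 15.0), (18.0, 15.0)))
        region = RegionProbe(vertices=((10, 10), (20, 10), (20, 20), (10, 20)))
        with pytest.raises(ProbeError, match="overlap"):
            corrected_membrane_intensity(img, probe, region)


class TestSyntheticFixture:
    def test_linearity_doubling_intensities(self):
        lo = synth_follicle_image(150.0, 50.0, seed=6, noise_sd=0.0)
        hi = synth_follicle_image(300.0, 100.0, seed=6, noise_sd=0.0)
        ci_lo = corrected_membrane_intensity(
            max_project(lo.stack), lo.membrane_probe, lo.cytoplasm_probe
        )
        ci_hi = corrected_membrane_intensity(
            max_project(hi.stack), hi.membrane_probe, hi.cytoplasm_probe
        )
        assert ci_hi.corrected == pytest.approx(2 * ci_lo.corrected, rel=1e-9)

    def test_fixed_seed_reproducible(self):
        a = synth_follicle_image(200.0, 50.0, seed=7, noise_sd=10.0)
        b = synth_follicle_image(200.0, 50.0, seed=7, noise_sd=10.0)
        assert np.array_equal(a.stack.slices, b.stack.slices)
        assert a.membrane_probe == b.membrane_probe

    def test_noise_error_propagation(self):
        """Empirical scatter of the corrected value matches the propagated
        error from independent per-pixel noise, within 20%.

        The oracle resamples the probe path itself (arc-length samples every
        0.5 px, bilinear weights) to accumulate the exact linear-functional
        weights, independent of the implementation's sampling code.
        """
        noise_sd = 10.0
        fix0 = synth_follicle_image(200.0, 50.0, seed=8, noise_sd=0.0, n_slices=1)
        img_shape = fix0.stack.slices[0].shape
        verts = np.asarray(fix0.membrane_probe.vertices)
        seg = np.diff(verts, axis=0)
        seg_len = np.hypot(seg[:, 0], seg[:, 1])
        total = seg_len.sum()
        m = int(np.ceil(total / 0.5))
        ts = np.linspace(0.0, 1.0, m + 1)
        pts = verts[0] + ts[:, None] * (verts[-1] - verts[0])  # single segment probe
        weights = np.zeros(img_shape)
        for x, y in pts:
            x0, y0 = int(np.floor(x)), int(np.floor(y))
            fx, fy = x - x0, y - y0
            weights[y0, x0] += (1 - fx) * (1 - fy)
            weights[y0, x0 + 1] += fx * (1 - fy)
            weights[y0 + 1, x0] += (1 - fx) * fy
            weights[y0 + 1, x0 + 1] += fx * fy
        weights /= len(pts)
        n_region = fix0.cytoplasm_probe.to_mask(img_shape).sum()
        propagated = noise_sd * np.sqrt((weights**2).sum() + 1.0 / n_region)

        vals = []
        for s in range(300):
            fix = synth_follicle_image(200.0, 50.0, seed=1000 + s, noise_sd=noise_sd, n_slices=1)
            ci = corrected_membrane_intensity(
                fix.stack.slices[0], fix.membrane_probe, fix.cytoplasm_probe
            )
            vals.append(ci.corrected)
        empirical = np.std(vals, ddof=1)
        assert empirical == pytest.approx(propagated, rel=0.2)

    def test_tiff_round_trip(self, tmp_path):
        fix = synth_follicle_image(120.0, 40.0, seed=9, noise_sd=5.0)
        path = tmp_path / "stack.tiff"
        fix.stack.to_tiff(path)
        back = ImageStack.from_tiff(path)
        assert np.allclose(back.slices, fix.stack.slices, atol=1e-4)


class TestDensitometry:
    def test_band_equals_loading_gives_unit_relatives(self):
        recs = [DensitometryRecord(f"lane{i}", 5.0, 5.0) for i in range(3)]
        out = densitometry_normalize(recs, ["lane0"])
        assert all(r.relative_to_control == pytest.approx(1.0) for r in out)

    def test_halving_loading_doubles_normalized(self):
        a = densitometry_normalize([DensitometryRecord("x", 10.0, 4.0)], ["x"])[0]
        b = densitometry_normalize([DensitometryRecord("x", 10.0, 2.0)], ["x"])[0]
        assert b.normalized == pytest.approx(2 * a.normalized)

    def test_mutant_at_eighty_percent_of_control(self):
        recs = [
            DensitometryRecord("wt", 10.0, 5.0),
            DensitometryRecord("het", 8.0, 5.0),
        ]
        out = densitometry_normalize(recs, ["wt"])
        assert out[1].relative_to_control == pytest.approx(0.8)

    def test_common_rescaling_invariance(self):
        recs = [DensitometryRecord("wt", 10.0, 5.0), DensitometryRecord("m", 6.0, 4.0)]
        base = densitometry_normalize(recs, ["wt"])
        scaled = densitometry_normalize(
            [DensitometryRecord(r.lane, 3.7 * r.band_intensity, 3.7 * r.loading_intensity)
             for r in recs],
            ["wt"],
        )
        for b, s in zip(base, scaled):
            assert s.relative_to_control == pytest.approx(b.relative_to_control)

    def test_zero_loading_is_error(self):
        with pytest.raises(ValueError, match="loading"):
            densitometry_normalize([DensitometryRecord("x", 1.0, 0.0)], ["x"])
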