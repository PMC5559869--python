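"""Symmetry-axis measurement: rasterization, ratio, profile, selection."""

import numpy as np
import pytest

import vertrot as vr
from vertrot.errors import EmptyInputError, GeometryError, ParameterError
from vertrot.symmetry import SymmetryProfile

from helpers import mirror_overlap_oracle, shoelace_area


class TestRasterize:
    def test_square_area(self):
        square = vr.EndplateOutline(
            [[0.0, 0.0], [10.0, 0.0], [10.0, 10.0], [0.0, 10.0]]
        )
        img = vr.rasterize_outline(square, 0.1)
        assert img.area_mm2 == pytest.approx(100.0, rel=0.02)

    def test_triangle_area(self):
        tri = vr.EndplateOutline([[0.0, 0.0], [4.0, 0.0], [0.0, 3.0]])
        img = vr.rasterize_outline(tri, 0.05)
        assert img.area_mm2 == pytest.approx(6.0, rel=0.02)

    def test_phantom_area_converges_to_shoelace(self, pedicled_params):
        """Raster area approaches the shoelace-formula area as spacing shrinks."""
        o = vr.generate_endplate_outline(pedicled_params, 57.0)
        target = shoelace_area([tuple(v) for v in o.vertices])
        errs = [
            abs(vr.rasterize_outline(o, sp).area_mm2 - target) / target
            for sp in (0.8, 0.4, 0.2)
        ]
        assert errs[-1] < errs[0]
        assert errs[-1] < 0.02
        assert abs(vr.rasterize_outline(o, 0.5).area_mm2 - target) / target < 0.02

    def test_self_intersecting_polygon_rejected(self):
        bowtie = vr.EndplateOutline([[0, 0], [2, 2], [2, 0], [0, 2]])
        with pytest.raises(GeometryError):
            vr.rasterize_outline(bowtie, 0.1)

    def test_bad_spacing(self):
        square = vr.EndplateOutline([[0, 0], [1, 0], [1, 1], [0, 1]])
        with pytest.raises(ParameterError):
            vr.rasterize_outline(square, 0.0)


class TestSymmetryRatio:
    def test_disc_symmetric_about_every_diameter(self, disc_params):
        img = vr.rasterize_outline(vr.generate_endplate_outline(disc_params, 0.0), 0.4)
        for angle in (0.0, 27.0, 90.0, 151.5):
            assert vr.symmetry_ratio(img, angle) == pytest.approx(1.0, abs=0.02)

    def test_mirror_union_is_fixed_point(self, rng):
        """A mask symmetrized about the vertical grid axis has ratio exactly 1 there."""
        m = rng.random((40, 50)) > 0.55
        m[0, :] = m[-1, :] = m[:, 0] = m[:, -1] = False
        m |= m[:, ::-1]
        if not m.any():
            m[20, 20] = m[20, 29] = True
        img = vr.BinaryEndplateImage(m, 0.5)
        assert vr.symmetry_ratio(img, 0.0) == pytest.approx(1.0, abs=1e-9)

    def test_exact_180_periodicity(self, pedicled_params):
        img = vr.rasterize_outline(vr.generate_endplate_outline(pedicled_params, 33.0), 0.5)
        for angle in (12.3, 61.0, 140.7):
            assert vr.symmetry_ratio(img, angle) == vr.symmetry_ratio(img, angle + 180.0)

    def test_off_axis_ratio_lower(self, pedicled_params):
        img = vr.rasterize_outline(vr.generate_endplate_outline(pedicled_params, 20.0), 0.5)
        assert vr.symmetry_ratio(img, 65.0) < vr.symmetry_ratio(img, 20.0)

    def test_oracle_equivalence_small_masks(self, rng):
        """Vectorized ratio matches the exhaustive per-pixel oracle to < 1 pixel-area."""
        for k in range(5):
            params = vr.ShapeParams(
                body_width=rng.uniform(34, 46),
                body_depth=rng.uniform(22, 30),
                pedicle_length=rng.uniform(6, 10),
                pedicle_width=rng.uniform(7, 11),
            )
            o = vr.generate_endplate_outline(params, rng.uniform(0, 180))
            extent = np.ptp(o.vertices, axis=0).max()
            img = vr.rasterize_outline(o, extent / 58.0)  # keeps the mask <= 64x64
            assert max(img.mask.shape) <= 64
            n_fg = img.mask.sum()
            for angle in rng.uniform(0, 180, size=2):
                got = vr.symmetry_ratio(img, float(angle))
                want = mirror_overlap_oracle(
                    img.mask, img.pixel_spacing, img.origin, float(angle)
                )
                assert abs(got - want) <= 1.0 / n_fg

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyInputError):
            vr.BinaryEndplateImage(np.zeros((5, 5), dtype=bool), 1.0)


class TestProfile:
    def test_ellipse_two_peaks_ambiguous(self, ellipse_params):
        img = vr.rasterize_outline(vr.generate_endplate_outline(ellipse_params, 40.0), 0.5)
        prof = vr.compute_symmetry_profile(img, 0.2)
        assert prof.ambiguous
        assert len(prof.peaks) == 2
        angles = sorted(a for a, _ in prof.peaks)
        assert angles[0] == pytest.approx(40.0, abs=1.0)
        assert angles[1] - angles[0] == pytest.approx(90.0, abs=2.0)

    def test_pedicled_single_dominant_peak(self, pedicled_params):
        img = vr.rasterize_outline(vr.generate_endplate_outline(pedicled_params, 75.0), 0.5)
        prof = vr.compute_symmetry_profile(img, 0.2)
        assert not prof.ambiguous
        assert prof.peaks[0][0] == pytest.approx(75.0, abs=0.7)

    def test_disc_flat_ambiguous(self, disc_params):
        img = vr.rasterize_outline(vr.generate_endplate_outline(disc_params, 0.0), 0.5)
        prof = vr.compute_symmetry_profile(img, 0.5)
        assert prof.ambiguous
        assert prof.peaks == []
        assert np.ptp(prof.ratios) < 0.02

    def test_profile_grid_and_bounds(self, pedicled_params):
        img = vr.rasterize_outline(vr.generate_endplate_outline(pedicled_params, 10.0), 0.6)
        prof = vr.compute_symmetry_profile(img, 0.5)
        assert prof.angles[0] == 0.0 and prof.angles[-1] < 180.0
        steps = np.diff(prof.angles)
        np.testing.assert_allclose(steps, steps[0])
        assert np.all((prof.ratios >= 0.0) & (prof.ratios <= 1.0))
        assert all(v <= prof.ratios.max() for _, v in prof.peaks)

    def test_bad_angle_step(self, pedicled_params):
        img = vr.rasterize_outline(vr.generate_endplate_outline(pedicled_params, 0.0), 0.8)
        with pytest.raises(ParameterError):
            vr.compute_symmetry_profile(img, 1.5)


def _made_profile(peaks):
    angles = np.arange(0.0, 180.0, 0.5)
    ratios = np.full_like(angles, 0.5)
    return SymmetryProfile(angles, ratios, peaks=peaks, ambiguous=len(peaks) > 1)


class TestSelection:
    def test_ambiguous_resolved_by_prior(self):
        """Three rival axes; the prior picks the anatomically plausible one."""
        prof = _made_profile([(100.3, 0.985), (45.4, 0.982), (142.1, 0.980)])
        angle, quality = vr.select_rotation_angle(prof, prior_angle=95.0)
        assert angle == pytest.approx(100.3)
        assert quality == "ambiguous_resolved"

    def test_single_peak_ok_without_prior(self):
        prof = _made_profile([(89.8, 0.99)])
        prof.ambiguous = False
        angle, quality = vr.select_rotation_angle(prof)
        assert angle == pytest.approx(89.8)
        assert quality == "ok"

    def test_ambiguous_without_prior_unmeasurable(self):
        prof = _made_profile([(40.0, 0.99), (130.0, 0.989)])
        angle, quality = vr.select_rotation_angle(prof)
        assert angle is None and quality == "unmeasurable"

    def test_flat_profile_unmeasurable(self):
        prof = _made_profile([])
        angle, quality = vr.select_rotation_angle(prof, prior_angle=50.0)
        assert angle is None and quality == "unmeasurable"

    def test_equidistant_tie_breaks_to_smaller_angle(self):
        prof = _made_profile([(40.0, 0.99), (120.0, 0.99)])
        angle, quality = vr.select_rotation_angle(prof, prior_angle=80.0)
        assert angle == pytest.approx(40.0)


class TestMeasurement:
    @pytest.mark.parametrize("true_angle", [0.0, 123.0])
    def test_recovers_truth(self, pedicled_params, true_angle):
        o = vr.generate_endplate_outline(pedicled_params, true_angle)
        rot = vr.measure_endplate_rotation(o, pixel_spacing=0.5, angle_step=0.2)
        assert rot.quality == "ok"
        assert vr.axial_distance(rot.phi, true_angle) <= 0.7  # angle_step + 0.5

    def test_equivariance_spot_checks(self, pedicled_params):
        base = 14.0
        o = vr.generate_endplate_outline(pedicled_params, base)
        phi0 = vr.measure_endplate_rotation(o, 0.5, 0.2).phi
        for delta in (30.0, 110.0):
            od = vr.generate_endplate_outline(pedicled_params, base + delta)
            phid = vr.measure_endplate_rotation(od, 0.5, 0.2).phi
            assert vr.axial_distance(phid - phi0, delta) <= 0.7

    def test_scale_invariance(self, pedicled_params):
        """Doubling the pixel spacing moves the answer by at most 2 angle steps."""
        o = vr.generate_endplate_outline(pedicled_params, 63.0)
        a = vr.measure_endplate_rotation(o, 0.4, 0.5).phi
        b = vr.measure_endplate_rotation(o, 0.8, 0.5).phi
        assert vr.axial_distance(a, b) <= 1.0

    def test_ellipse_unmeasurable_without_prior(self, ellipse_params):
        o = vr.generate_endplate_outline(ellipse_params, 70.0)
        rot = vr.measure_endplate_rotation(o, 0.6, 0.5)
        assert rot.quality == "unmeasurable" and rot.phi is None

    def test_metadata_propagates(self, pedicled_params):
        o = vr.generate_endplate_outline(
            pedicled_params, 90.0, level="T8", side="superior", timepoint="6m", patient="P01"
        )
        rot = vr.measure_endplate_rotation(o, 0.6, 0.5)
        assert (rot.level, rot.side, rot.timepoint, rot.patient) == ("T8", "superior", "6m", "P01")
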