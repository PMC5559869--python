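"""Synthetic-data generator: construction guarantees and determinism."""

import numpy as np
import pytest

import vertrot as vr
from vertrot.errors import ParameterError, ResolutionError

from helpers import circular_diff_oracle


class TestEndplateOutline:
    def test_mirror_symmetric_at_angle_zero(self, pedicled_params):
        """At true angle 0 the polygon is exactly mirror-symmetric about the AP (y) axis."""
        o = vr.generate_endplate_outline(pedicled_params, 0.0)
        v = o.vertices
        n = len(v)
        mirror_idx = (n // 2 - np.arange(n)) % n  # psi -> pi - psi on the vertex grid
        np.testing.assert_allclose(v[:, 0], -v[mirror_idx, 0], atol=1e-9)
        np.testing.assert_allclose(v[:, 1], v[mirror_idx, 1], atol=1e-9)

    def test_rotation_equivariance_by_construction(self, pedicled_params):
        """generate(30) equals the rigid 30-degree rotation of generate(0)."""
        o0 = vr.generate_endplate_outline(pedicled_params, 0.0)
        o30 = vr.generate_endplate_outline(pedicled_params, 30.0)
        from vertrot.geometry import cw_rotation_matrix

        rotated = o0.vertices @ cw_rotation_matrix(30.0).T
        np.testing.assert_allclose(o30.vertices, rotated, atol=1e-6)

    def test_ellipse_has_two_reflection_axes(self, ellipse_params):
        """asymmetry 0 + no pedicles: symmetric about both principal axes."""
        o = vr.generate_endplate_outline(ellipse_params, 0.0)
        v = o.vertices
        n = len(v)
        m1 = (n // 2 - np.arange(n)) % n  # about y axis
        m2 = (-np.arange(n)) % n  # about x axis (psi -> -psi)
        np.testing.assert_allclose(v[:, 0], -v[m1, 0], atol=1e-9)
        np.testing.assert_allclose(v[:, 1], v[m1, 1], atol=1e-9)
        np.testing.assert_allclose(v[:, 0], v[m2, 0], atol=1e-9)
        np.testing.assert_allclose(v[:, 1], -v[m2, 1], atol=1e-9)

    def test_deterministic_bytes(self, pedicled_params):
        a = vr.generate_endplate_outline(pedicled_params, 72.0, seed=5, noise_sd_mm=0.4)
        b = vr.generate_endplate_outline(pedicled_params, 72.0, seed=5, noise_sd_mm=0.4)
        assert a.vertices.tobytes() == b.vertices.tobytes()

    def test_noise_commutes_with_rotation(self, pedicled_params):
        """Radial noise with a fixed seed preserves rotation equivariance."""
        from vertrot.geometry import cw_rotation_matrix

        o0 = vr.generate_endplate_outline(pedicled_params, 0.0, seed=9, noise_sd_mm=0.5)
        o40 = vr.generate_endplate_outline(pedicled_params, 40.0, seed=9, noise_sd_mm=0.5)
        np.testing.assert_allclose(o40.vertices, o0.vertices @ cw_rotation_matrix(40.0).T, atol=1e-6)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"body_width": -1.0},
            {"posterior_flattening": 1.5},
            {"asymmetry_strength": -0.1},
            {"pedicle_present": True, "pedicle_width": 0.0},
        ],
    )
    def test_invalid_shape_params(self, kwargs):
        with pytest.raises(ParameterError):
            vr.generate_endplate_outline(vr.ShapeParams(**kwargs), 0.0)

    def test_angle_out_of_range(self, pedicled_params):
        with pytest.raises(ParameterError):
            vr.generate_endplate_outline(pedicled_params, 180.0)


def _spec(levels=None, injected=None, **kw):
    levels = levels or ["T5", "T6", "T7", "T8", "T9", "T10"]
    return vr.SyntheticSpineSpec(
        levels=levels,
        instrumented_range=(levels[1], levels[-2]),
        apex=kw.pop("apex", levels[len(levels) // 2]),
        injected_changes=injected or {},
        **kw,
    )


class TestSpineStudy:
    def test_no_injected_changes(self):
        study, truth = vr.generate_spine_study(_spec(seed=3))
        t1 = truth[truth.timepoint == "6m"].true_angle_deg.to_numpy()
        t2 = truth[truth.timepoint == "24m"].true_angle_deg.to_numpy()
        np.testing.assert_allclose(t1, t2, atol=1e-12)

    def test_single_intra_change_isolated(self):
        study, truth = vr.generate_spine_study(_spec(injected={"T7": 10.0}, seed=3))
        recs = vr.study_change_records(study, "6m", "24m", limit=8.2)
        changes = {r.level_key: r.change for r in recs}
        assert changes["T7"] == pytest.approx(10.0, abs=1e-9)
        for key, ch in changes.items():
            if key != "T7":
                assert ch == pytest.approx(0.0, abs=1e-9)

    def test_en_bloc_scenario_truth_table(self):
        """Rigid +10 of the construct: junction discs change by -/+10, construct by 0.

        Oracle: inter-endplate differences evaluated directly on the
        emitted ground-truth table, independent of the study object.
        """
        levels = ["T5", "T6", "T7", "T8", "T9", "T10"]
        inj = vr.en_bloc_changes(levels, ("T6", "T9"), 10.0)
        study, truth = vr.generate_spine_study(_spec(levels=levels, injected=inj, seed=11))

        def phi(level, side, tp):
            row = truth[(truth.level == level) & (truth.side == side) & (truth.timepoint == tp)]
            return float(row.true_angle_deg.iloc[0])

        def disc_change(upper, lower):
            d1 = circular_diff_oracle(phi(upper, "inferior", "6m"), phi(lower, "superior", "6m"))
            d2 = circular_diff_oracle(phi(upper, "inferior", "24m"), phi(lower, "superior", "24m"))
            return d2 - d1

        assert disc_change("T5", "T6") == pytest.approx(-10.0, abs=1e-9)
        assert disc_change("T9", "T10") == pytest.approx(10.0, abs=1e-9)
        for upper, lower in [("T6", "T7"), ("T7", "T8"), ("T8", "T9")]:
            assert disc_change(upper, lower) == pytest.approx(0.0, abs=1e-9)

    def test_truth_bookkeeping_random_changes(self, rng):
        inj = {"T6": 4.5, "T7/T8": -11.0, "T9": 2.25}
        study, truth = vr.generate_spine_study(_spec(injected=inj, seed=21))
        recs = vr.study_change_records(study, "6m", "24m", limit=8.2)
        changes = {r.level_key: r.change for r in recs}
        for key, want in inj.items():
            assert changes[key] == pytest.approx(want, abs=1e-9)

    def test_injected_change_at_unknown_entity(self):
        with pytest.raises(ParameterError):
            vr.generate_spine_study(_spec(injected={"L4": 5.0}))

    def test_outlines_carry_truth_angles(self):
        study, truth, outlines = vr.generate_spine_study(
            _spec(seed=2), include_outlines=True
        )
        for (lvl, side, tp), outline in outlines.items():
            row = truth[
                (truth.level == lvl) & (truth.side == side) & (truth.timepoint == tp)
            ]
            assert outline.true_angle_deg == pytest.approx(float(row.true_angle_deg.iloc[0]))


class TestRaterPairs:
    def test_zero_noise_reproduces_base(self):
        base = [3.0, -2.0, 5.5, 0.0]
        table = vr.generate_rater_pairs(vr.RaterPairSpec(4, 0.0, seed=1), base)
        np.testing.assert_allclose(table.alpha_n, base)
        np.testing.assert_allclose(table.alpha_m, base)

    def test_difference_sd_scales_sqrt2(self):
        """SD of signed replicate differences approaches sigma * sqrt(2)."""
        sigma = 3.0
        n = 40000
        table = vr.generate_rater_pairs(
            vr.RaterPairSpec(n, sigma, seed=7), np.zeros(n)
        )
        sd = np.std(table.alpha_n - table.alpha_m, ddof=1)
        assert sd == pytest.approx(sigma * np.sqrt(2.0), rel=0.03)

    def test_deterministic(self):
        a = vr.generate_rater_pairs(vr.RaterPairSpec(10, 2.0, seed=3), np.arange(10.0))
        b = vr.generate_rater_pairs(vr.RaterPairSpec(10, 2.0, seed=3), np.arange(10.0))
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_length_mismatch(self):
        with pytest.raises(ParameterError):
            vr.generate_rater_pairs(vr.RaterPairSpec(3, 1.0), [1.0, 2.0])


class TestTiltedVolume:
    def test_landmarks_on_plane(self, pedicled_params):
        tv = vr.generate_tilted_volume(pedicled_params, 30.0, tilt=(15.0, -10.0))
        # analytic plane through the origin with the stated normal
        dist = tv.landmarks @ tv.plane.normal
        assert np.max(np.abs(dist)) < 0.5 * tv.voxel_spacing[0]

    def test_identity_tilt_matches_2d_mask(self, pedicled_params):
        """With zero tilt the mid-solid axial voxel slice matches the rasterized outline."""
        tv = vr.generate_tilted_volume(pedicled_params, 25.0, tilt=(0.0, 0.0), voxel_size=1.0)
        outline = vr.generate_endplate_outline(pedicled_params, 25.0)
        img = vr.rasterize_outline(outline, 1.0)
        kz = int(round((-9.0 - tv.origin[2]) / tv.voxel_spacing[2]))
        vox = tv.volume[:, :, kz].T > 0.5  # [ix, iy] -> rows = y
        # compare foreground areas (same grid pitch)
        a1, a2 = vox.sum(), img.mask.sum()
        assert abs(a1 - a2) / a2 < 0.05

    def test_resolution_error(self, pedicled_params):
        with pytest.raises(ResolutionError):
            vr.generate_tilted_volume(pedicled_params, 0.0, voxel_size=5.0)

    def test_tilt_out_of_range(self, pedicled_params):
        with pytest.raises(ParameterError):
            vr.generate_tilted_volume(pedicled_params, 0.0, tilt=(50.0, 0.0))


class TestCohortGenerator:
    def test_counts_and_magnitudes(self):
        cohort = vr.generate_cohort(n_patients=32, n_with_significant=11, seed=5)
        assert cohort.n_patients == 32
        n_big = sum(
            1 for ch in cohort.injected.values() if any(abs(v) > 8.2 for v in ch.values())
        )
        assert n_big == 11
        for ch in cohort.injected.values():
            mags = sorted(abs(v) for v in ch.values())
            assert all(m <= 8.2 for m in mags[:-1])  # at most one supra-gate change

    def test_instrumented_span_in_range(self):
        cohort = vr.generate_cohort(n_patients=16, n_with_significant=4, seed=2)
        for study in cohort.studies:
            span = vr.vertebra_sequence(*study.instrumented_range)
            assert 6 <= len(span) <= 9
            assert len(study.levels) == len(span) + 2

    def test_deterministic(self):
        a = vr.generate_cohort(n_patients=8, n_with_significant=3, seed=9)
        b = vr.generate_cohort(n_patients=8, n_with_significant=3, seed=9)
        assert a.truth_table.to_csv(index=False) == b.truth_table.to_csv(index=False)
        assert a.injected == b.injected
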