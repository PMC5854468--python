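"""Track statistics: line fits, MSD models, filters, fold transforms, pair stats."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrebalign import (
    ContourScenario,
    FilterPolicy,
    Track,
    TrajectoryScenario,
    angle_to_midline,
    angle_width_binning,
    apply_filters,
    fit_msd,
    fit_track_line,
    fold_angle,
    generate_contour,
    generate_msd_fixture,
    generate_tracks,
    pairwise_statistics,
    pill_mesh,
    sigma90,
    summarize_track,
)


def straight_track(angle_deg, n=10, step=0.1, start=(0.0, 0.0), track_id=0):
    d = np.array([math.cos(math.radians(angle_deg)), math.sin(math.radians(angle_deg))])
    pos = np.asarray(start) + np.outer(np.arange(n) * step, d)
    return Track(track_id, np.arange(n), pos, 1.0)


class TestLineFit:
    def test_collinear_points_exact(self):
        s = fit_track_line(straight_track(30.0))
        assert s.line_angle == pytest.approx(30.0, abs=1e-9)
        assert s.r2_orth == pytest.approx(1.0)
        assert s.displacement == pytest.approx(0.9, rel=1e-9)

    def test_two_point_vertical_track(self):
        t = Track(0, [0, 1], [[0.0, 0.0], [0.0, 1.0]], 1.0)
        assert fit_track_line(t).line_angle == pytest.approx(90.0)

    def test_isotropic_cloud_r2_half(self):
        rng = np.random.default_rng(0)
        t = Track(0, np.arange(4000), rng.normal(0, 1, (4000, 2)), 1.0)
        assert fit_track_line(t).r2_orth == pytest.approx(0.5, abs=0.05)

    def test_zero_variance_rejected(self):
        t = Track(0, np.arange(5), np.zeros((5, 2)), 1.0)
        with pytest.raises(ValueError, match="zero-variance"):
            fit_track_line(t)

    def test_nonmonotone_frames_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            Track(0, [0, 2, 1], np.zeros((3, 2)), 1.0)


class TestMsdFit:
    def test_pure_drift_recovers_velocity(self):
        t = generate_msd_fixture("ballistic", speed=0.025, n_frames=40)
        s = fit_msd(t)
        assert s.velocity_msd == pytest.approx(0.025, rel=0.05)
        assert s.diffusion_D == pytest.approx(0.0, abs=1e-6)
        assert s.alpha == pytest.approx(2.0, abs=0.01)
        assert s.r2_loglog > 0.999

    def test_random_walk_recovers_diffusion(self):
        t = generate_msd_fixture("diffusive", diffusion_coeff=0.01, n_frames=10_000, seed=3)
        s = fit_msd(t)
        assert 0.9 <= s.alpha <= 1.1
        assert s.diffusion_D == pytest.approx(0.01, rel=0.25)  # single-trajectory scatter

    def test_stationary_with_noise_flat_msd(self):
        t = generate_msd_fixture("ballistic", speed=0.0, n_frames=200,
                                 localization_sigma=0.05, seed=5)
        s = fit_msd(t, model="drift_diffusion_locnoise")
        assert abs(s.alpha) < 0.15
        assert s.localization_sigma == pytest.approx(0.05, rel=0.15)

    def test_unknown_model_rejected(self):
        t = generate_msd_fixture("ballistic", n_frames=20)
        with pytest.raises(ValueError, match="model"):
            fit_msd(t, model="teleport")


class TestFilters:
    def test_random_field_tracks_all_retained(self, random_field_tracks):
        summaries = [summarize_track(t) for t in random_field_tracks[:100]]
        retained, attrition = apply_filters(summaries, FilterPolicy.filament())
        assert len(retained) == 100
        assert attrition == {}

    def test_short_displacement_dropped(self):
        s = summarize_track(straight_track(45.0, n=11, step=0.01))  # 0.1 um total
        retained, attrition = apply_filters([s], FilterPolicy.filament())
        assert retained == []
        assert attrition.get("displacement") == 1

    def test_disabled_thresholds_identity(self, random_field_tracks):
        permissive = FilterPolicy(r2_orth_min=None, displacement_min_um=None,
                                  velocity_min_um_s=None, r2_loglog_min=None,
                                  min_frames=None)
        summaries = [summarize_track(t) for t in random_field_tracks[:20]]
        retained, _ = apply_filters(summaries, permissive)
        assert len(retained) == 20

    def test_single_molecule_policy_bounds_track_length(self):
        pol = FilterPolicy.single_molecule()
        long = summarize_track(straight_track(10.0, n=150, step=0.02))
        short = summarize_track(straight_track(10.0, n=8, step=0.05))
        ok = summarize_track(straight_track(10.0, n=50, step=0.02))
        retained, _ = apply_filters([long, short, ok], pol)
        assert [s.n_frames for s in retained] == [50]

    @given(
        r2=st.floats(0.0, 0.99),
        disp=st.floats(0.0, 2.0),
        tighter=st.floats(0.0, 0.5),
    )
    @settings(max_examples=30, deadline=None)
    def test_tightening_never_grows_retained_set(self, r2, disp, tighter):
        summaries = [summarize_track(straight_track(a, n=20, step=0.05 + 0.01 * i))
                     for i, a in enumerate((0, 30, 60, 95, 140))]
        base = FilterPolicy(r2_orth_min=r2, displacement_min_um=disp)
        tight = FilterPolicy(r2_orth_min=min(r2 + tighter, 1.0),
                             displacement_min_um=disp + tighter)
        kept_base, _ = apply_filters(summaries, base)
        kept_tight, _ = apply_filters(summaries, tight)
        assert {s.track_id for s in kept_tight} <= {s.track_id for s in kept_base}


class TestAngleFolding:
    @pytest.mark.parametrize(
        "raw, folded",
        [(-30.0, 30.0), (0.0, 0.0), (90.0, 90.0), (150.0, 30.0), (-150.0, 30.0), (181.0, 1.0)],
    )
    def test_fold_transform_as_printed(self, raw, folded):
        assert fold_angle(raw) == pytest.approx(folded)

    @given(st.floats(-720, 720))
    @settings(max_examples=100, deadline=None)
    def test_fold_idempotent_and_in_range(self, raw):
        once = fold_angle(raw)
        assert 0.0 <= once <= 90.0
        assert fold_angle(once) == pytest.approx(once, abs=1e-9)

    def test_angle_to_midline_parallel_and_perpendicular(self, rod_contour):
        prof = pill_mesh(rod_contour)
        parallel = fit_track_line(straight_track(0.0, start=(0.0, 0.1)))
        perp = fit_track_line(straight_track(90.0, start=(0.0, -0.2)))
        assert angle_to_midline(parallel, prof) == pytest.approx(0.0, abs=1.0)
        assert angle_to_midline(perp, prof) == pytest.approx(90.0, abs=1.0)

    def test_round_cell_reports_none(self, circle_contour):
        prof = pill_mesh(circle_contour)
        s = fit_track_line(straight_track(15.0))
        assert angle_to_midline(s, prof) is None


class TestSigma90:
    def test_all_at_90_gives_zero(self):
        assert sigma90([90.0] * 7) == 0.0

    def test_hand_example(self):
        assert sigma90([60.0, 120.0]) == pytest.approx(30.0)

    def test_uniform_limit(self):
        rng = np.random.default_rng(12)
        val = sigma90(rng.uniform(0, 180, 100_000))
        assert val == pytest.approx(90 / math.sqrt(3), abs=0.5)

    def test_axial_symmetry(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0, 180, 500)
        assert sigma90(a) == pytest.approx(sigma90(180 - a))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sigma90([])


class TestPairwiseStatistics:
    def grid_summaries(self, angles, spacing=0.5):
        out = []
        n = math.ceil(math.sqrt(len(angles)))
        for i, a in enumerate(angles):
            start = ((i % n) * spacing, (i // n) * spacing)
            out.append(fit_track_line(straight_track(a, start=start, track_id=i)))
        return out

    def test_parallel_tracks(self):
        ps = pairwise_statistics(self.grid_summaries([25.0] * 16))
        assert ps.median_dtheta == pytest.approx(0.0, abs=1e-9)
        occupied = ps.binned[ps.binned.n_pairs > 0]
        np.testing.assert_allclose(occupied.mean_dp, 1.0, atol=1e-9)

    def test_orthogonal_pair(self):
        angs = [0.0, 90.0] * 8
        ps = pairwise_statistics(self.grid_summaries(angs))
        cross = ps.delta_theta[np.abs(ps.dot_products) < 1e-9]
        assert np.allclose(cross, 90.0)

    def test_null_median_near_45(self, random_field_tracks):
        summaries = [summarize_track(t) for t in random_field_tracks]
        ps = pairwise_statistics(summaries)
        assert ps.median_dtheta == pytest.approx(45.0, abs=2.5)

    def test_rotation_invariance_of_mean_dp(self):
        angles = [0.0, 30.0, 75.0, 120.0, 160.0] * 4
        base = pairwise_statistics(self.grid_summaries(angles))
        rot = pairwise_statistics(self.grid_summaries([(a + 50) % 180 for a in angles]))
        np.testing.assert_allclose(
            np.sort(np.abs(base.dot_products)), np.sort(np.abs(rot.dot_products)), atol=1e-9
        )

    def test_isolated_tracks_excluded(self):
        near = self.grid_summaries([10.0] * 8, spacing=0.4)
        far = fit_track_line(straight_track(80.0, start=(500.0, 500.0), track_id=99))
        ps = pairwise_statistics(near + [far])
        assert 99 not in {None}  # far track forms no pair
        assert len(ps.delta_theta) == len(pairwise_statistics(near).delta_theta)


class TestAngleWidthBinning:
    def test_rod_population_single_bin_near_90(self):
        rod = ContourScenario(kind="rod", width=1.0, length=4.0)
        tracks = generate_tracks(
            TrajectoryScenario(kind="circumferential", n_tracks=60, angular_noise=50.0, seed=6),
            rod,
        )
        contour = generate_contour(rod)
        prof = pill_mesh(contour)
        angles, widths = [], []
        for t in tracks:
            s = fit_track_line(t)
            a = angle_to_midline(s, prof)
            angles.append(a)
            widths.append(prof.local_width(np.asarray(s.mean_position)))
        table = angle_width_binning(angles, widths)
        assert len(table) == 1
        assert table.median_angle_deg.iloc[0] == pytest.approx(90.0, abs=5.0)

    def test_mixed_population_round_bins_less_aligned(self):
        rng = np.random.default_rng(8)
        aligned = list(rng.normal(88, 5, 80))
        isotropic = [float(fold_angle(a)) for a in rng.uniform(0, 180, 80)]
        widths = [1.0] * 80 + [2.5] * 80
        table = angle_width_binning(aligned + isotropic, widths)
        med = dict(zip(table.width_bin_center_um.round(2), table.median_angle_deg))
        narrow = [v for k, v in med.items() if k < 2]
        wide = [v for k, v in med.items() if k > 2]
        assert min(narrow) > 80.0
        assert 35.0 < np.mean(wide) < 60.0

    def test_sparse_bins_suppressed(self):
        table = angle_width_binning([90, 90, 90, 10], [1.0, 1.0, 1.0, 5.0], min_count=3)
        assert len(table) == 1
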