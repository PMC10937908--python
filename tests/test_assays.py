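"""DIS/FIS/SLA readouts, outlier exclusion and bin-size stabilization."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orgaswell import (
    LabelMask,
    OrganoidTrajectory,
    PlateLayout,
    SwellingRecord,
    bin_stability,
    condition_summary,
    exclude_outliers,
    fis_auc,
    sla,
    swelling_per_organoid,
    total_area_series,
)
from orgaswell.masks_io import ValidityError


def make_record(swelling, area_t0=500.0, well="A1", condition="ctrl", track=0):
    return SwellingRecord(
        well_id=well,
        condition=condition,
        track_id=track,
        area_t0=area_t0,
        area_t24=area_t0 * swelling,
        swelling=swelling,
    )


LAYOUT = PlateLayout(
    wells={
        "A1": ("ctrl", "DMSO", "P1"),
        "A2": ("ctrl", "DMSO", "P1"),
        "B1": ("treated", "VX-445/VX-661/VX-770", "P1"),
    }
)


class TestSwellingPerOrganoid:
    @pytest.mark.parametrize("a0,a1,expected", [(500, 500, 1.0), (150, 300, 2.0)])
    def test_printed_ratio(self, a0, a1, expected):
        traj = OrganoidTrajectory(track_id=1)
        traj.points = [(0.0, 1, a0, (0, 0)), (24.0, 1, a1, (0, 0))]
        rec = swelling_per_organoid(traj)
        assert rec.swelling == expected
        assert rec.area_t0 == a0 and rec.area_t24 == a1

    def test_missing_endpoint_raises(self):
        traj = OrganoidTrajectory(track_id=2)
        traj.points = [(0.0, 1, 100, (0, 0))]
        with pytest.raises(ValueError, match="endpoint"):
            swelling_per_organoid(traj)

    @given(
        a0=st.integers(min_value=1, max_value=10_000),
        a1=st.integers(min_value=1, max_value=10_000),
    )
    @settings(max_examples=50, derandomize=True)
    def test_ratio_agrees_with_exact_rational_arithmetic(self, a0, a1):
        traj = OrganoidTrajectory(track_id=0)
        traj.points = [(0.0, 1, a0, (0, 0)), (24.0, 1, a1, (0, 0))]
        rec = swelling_per_organoid(traj)
        assert rec.swelling == pytest.approx(float(Fraction(a1, a0)), rel=1e-12)


class TestExcludeOutliers:
    def test_tight_cluster_nothing_excluded(self):
        recs = [make_record(s, track=i) for i, s in enumerate([1.1, 1.2, 1.15, 1.18])]
        out = exclude_outliers(recs, min_area_t0=10)
        assert not any(r.excluded for r in out)

    def test_single_extreme_record_fenced(self):
        swellings = [1.1, 1.2, 1.15, 1.18, 9.0]
        recs = [make_record(s, track=i) for i, s in enumerate(swellings)]
        out = exclude_outliers(recs, min_area_t0=10, fence_k=1.5)
        # independent quartile/IQR oracle on the same values
        q1, q3 = np.percentile(swellings, [25, 75])
        hi = q3 + 1.5 * (q3 - q1)
        assert 9.0 > hi
        excluded = [r for r in out if r.excluded]
        assert len(excluded) == 1
        assert excluded[0].swelling == 9.0
        assert excluded[0].exclusion_reason == "tukey_fence"

    def test_small_t0_area_excluded_regardless_of_swelling(self):
        recs = [make_record(1.15, track=i) for i in range(4)]
        recs.append(make_record(1.15, area_t0=50, track=9))
        out = exclude_outliers(recs, min_area_t0=300)
        small = [r for r in out if r.area_t0 == 50]
        assert small[0].excluded and small[0].exclusion_reason == "min_area"

    def test_groups_below_four_records_skip_fence(self):
        recs = [make_record(s, track=i) for i, s in enumerate([1.0, 1.1, 99.0])]
        out = exclude_outliers(recs, min_area_t0=10)
        assert not any(r.excluded for r in out)

    def test_original_values_retained_and_inputs_untouched(self):
        recs = [make_record(s, track=i) for i, s in enumerate([1.1, 1.2, 1.15, 1.18, 9.0])]
        out = exclude_outliers(recs, min_area_t0=10)
        assert [r.swelling for r in out] == [r.swelling for r in recs]
        assert not any(r.excluded for r in recs)

    def test_order_invariance(self, rng):
        swellings = list(rng.normal(1.5, 0.3, size=30)) + [8.0, 0.01]
        recs = [make_record(s, track=i) for i, s in enumerate(swellings)]
        out1 = exclude_outliers(recs, min_area_t0=10)
        shuffled = list(recs)
        rng.shuffle(shuffled)
        out2 = exclude_outliers(shuffled, min_area_t0=10)
        flags1 = {r.track_id: r.excluded for r in out1}
        flags2 = {r.track_id: r.excluded for r in out2}
        assert flags1 == flags2


class TestConditionSummary:
    def test_mean_of_two(self):
        recs = [make_record(1.0, track=0), make_record(2.0, track=1)]
        (summ,) = condition_summary(recs, LAYOUT)
        assert summ.mean_swelling == 1.5
        assert summ.plate_id == "P1" and summ.condition == "ctrl"
        assert summ.n_included == 2 and summ.n_excluded == 0

    def test_all_excluded_reports_missing_mean(self):
        recs = [make_record(1.0, track=0)]
        recs[0].excluded = True
        recs[0].exclusion_reason = "min_area"
        (summ,) = condition_summary(recs, LAYOUT)
        assert summ.n_included == 0
        assert summ.mean_swelling is None and summ.sd_swelling is None

    def test_unknown_well_raises(self):
        recs = [make_record(1.0, well="Z9")]
        with pytest.raises(KeyError):
            condition_summary(recs, LAYOUT)

    def test_grouped_by_plate_and_condition(self):
        recs = [
            make_record(1.0, well="A1", track=0),
            make_record(1.2, well="A2", track=1),
            make_record(2.0, well="B1", condition="treated", track=2),
        ]
        summaries = condition_summary(recs, LAYOUT)
        byc = {s.condition: s for s in summaries}
        assert byc["ctrl"].mean_swelling == pytest.approx(1.1)
        assert byc["treated"].mean_swelling == 2.0


class TestSLA:
    @pytest.mark.parametrize("lum,tot,expected", [(25, 100, 25.0), (0, 500, 0.0), (500, 500, 100.0)])
    def test_printed_formula(self, lum, tot, expected):
        assert sla(lum, tot) == expected

    def test_luminal_exceeding_total_rejected(self):
        with pytest.raises(ValidityError):
            sla(101, 100)

    @given(
        lum=st.integers(min_value=0, max_value=1000),
        tot=st.integers(min_value=1, max_value=1000),
    )
    @settings(max_examples=50, derandomize=True)
    def test_agrees_with_rational_arithmetic(self, lum, tot):
        if lum > tot:
            return
        assert sla(lum, tot) == pytest.approx(float(Fraction(lum, tot) * 100), rel=1e-12)

    def test_generator_lumen_fraction_squared(self):
        from orgaswell import SceneSpec, ShapeParams, render_scene

        f = 0.5
        spec = SceneSpec(
            image_size=(128, 128),
            n_organoids=1,
            shape_params=ShapeParams(mean_radius=24, lumen_fraction=f),
            noise_sd=0.0,
            rng_seed=4,
        )
        scene = render_scene(spec)
        total = int((scene.truth.labels > 0).sum())
        luminal = int((scene.image.pixels == spec.lumen_level).sum())
        assert sla(luminal, total) == pytest.approx(100 * f**2, abs=3.0)


class TestFISAUC:
    def test_flat_series_scores_zero(self):
        curve = fis_auc([0, 10, 20, 30, 40, 50, 60], [800] * 7)
        assert curve.auc == 0.0
        assert curve.relative_area[0] == 100.0

    def test_linear_ramp_is_exact(self):
        # 100% -> 130% over 60 min: triangle area = 0.5 * 30 * 60 = 900
        t = [0, 10, 20, 30, 40, 50, 60]
        areas = [1000 * (1 + 0.3 * x / 60) for x in t]
        assert fis_auc(t, areas).auc == pytest.approx(900.0)

    def test_frame_count_invariance_on_linear_signal(self):
        t_fine = list(range(0, 61, 10))
        t_coarse = [0, 30, 60]
        ramp = lambda x: 1000 * (1 + 0.3 * x / 60)
        a1 = fis_auc(t_fine, [ramp(x) for x in t_fine]).auc
        a2 = fis_auc(t_coarse, [ramp(x) for x in t_coarse]).auc
        assert a1 == pytest.approx(a2)

    def test_shrinkage_is_negative(self):
        curve = fis_auc([0, 30, 60], [1000, 900, 800])
        assert curve.auc < 0

    @given(scale=st.floats(min_value=0.1, max_value=5.0))
    @settings(max_examples=30, derandomize=True)
    def test_auc_linear_in_deviation(self, scale):
        t = [0.0, 10.0, 20.0, 30.0]
        base = np.array([1000.0, 1100.0, 1250.0, 1300.0])
        dev = base - 1000.0
        scaled = 1000.0 + scale * dev
        assert fis_auc(t, scaled).auc == pytest.approx(scale * fis_auc(t, base).auc, rel=1e-9)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ZeroDivisionError):
            fis_auc([0, 10], [0, 100])

    def test_must_start_at_zero(self):
        with pytest.raises(ValueError):
            fis_auc([10, 20], [100, 120])


class TestTotalAreaSeries:
    def test_identical_masks_all_ones(self, easy_scene):
        series = total_area_series([easy_scene.truth] * 3)
        np.testing.assert_allclose(series, 1.0)

    def test_doubled_mask(self):
        a = np.zeros((20, 20), dtype=np.int64)
        a[0:5, 0:5] = 1
        b = np.zeros((20, 20), dtype=np.int64)
        b[0:5, 0:10] = 1
        series = total_area_series([LabelMask(labels=a), LabelMask(labels=b)])
        np.testing.assert_allclose(series, [1.0, 2.0])

    def test_consistent_with_per_trajectory_sum(self):
        from orgaswell import SceneSpec, build_trajectories, extract_instances, interpolate_masks, render_scene

        s0 = render_scene(SceneSpec(image_size=(256, 256), n_organoids=5, rng_seed=77))
        frames = interpolate_masks(s0, {r.label_id: 1.6 for r in s0.per_organoid}, 4)
        sets = [extract_instances(f, timepoint=float(i)) for i, f in enumerate(frames)]
        trajs = build_trajectories(sets, frames)
        series = total_area_series(frames)
        for k in range(4):
            per_traj = sum(t.points[k][2] for t in trajs if t.complete)
            total0 = sum(t.points[0][2] for t in trajs if t.complete)
            assert series[k] == pytest.approx(per_traj / total0)


class TestBinStability:
    def test_constant_records_give_zero_sd(self):
        values = [1.3] * 300
        table = bin_stability(values, rng_seed=0)
        np.testing.assert_allclose(table.sd_of_means, 0.0, atol=1e-12)
        np.testing.assert_allclose(table.means.to_numpy(), 1.3, rtol=1e-12)

    def test_default_protocol_shape(self):
        values = list(np.random.default_rng(0).normal(1.5, 0.3, size=300))
        table = bin_stability(values, rng_seed=1)
        assert table.bin_sizes == (2, 4, 8, 16, 32, 64, 128, 256)
        assert table.means.shape == (10, 8)

    def test_sd_scales_like_sqrt_bin_size(self):
        sigma = 0.4
        values = list(np.random.default_rng(5).normal(1.5, sigma, size=2000))
        table = bin_stability(values, rng_seed=2)
        for b in (8, 16, 32, 64, 128, 256):
            expected = sigma / np.sqrt(b)
            assert expected / 2 <= table.sd_of_means[b] <= expected * 2

    def test_oversized_bin_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            bin_stability([1.0] * 10, bin_sizes=[16], rng_seed=0)

    def test_excluded_records_ignored(self):
        recs = [make_record(1.0, track=i) for i in range(10)]
        recs.append(make_record(100.0, track=99))
        recs[-1].excluded = True
        table = bin_stability(recs, bin_sizes=[10], repeats=5, rng_seed=3)
        assert np.all(table.means.to_numpy() == 1.0)
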