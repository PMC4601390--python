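"""Tip-pool signatures, dark-state control, integrated density."""

import warnings

import numpy as np
import pytest

from frapdyn import (
    AcquisitionSchedule,
    RegionSpec,
    SyntheticCellSpec,
    TipTraces,
    classify_recovery_speed,
    dark_state_recovery_fraction,
    estimate_background,
    final_unbleached_minus_bleached,
    fractional_recovery,
    generate_tip_experiment,
    generate_whole_cell_bleach,
    generate_zstack_sum,
    integrated_density_summary,
    lateral_mobility_profiles,
    tip_metrics,
)

TIP_STRIP = RegionSpec(30, 20, 120, 20, role="bleach_strip")


def analyze_tip_movie(spec, **kw):
    series, man = generate_tip_experiment(spec, **kw)
    sched = AcquisitionSchedule.fast_slow()
    regs = man["regions"]
    bg = estimate_background(series, regs["background"])
    traces = TipTraces.from_series(series, sched, regs["bleached_tip"],
                                   regs["unbleached_tip"], regs["cytoplasm"], bg)
    return traces, man, series, bg


def synthetic_traces(bleached, unbleached, cytoplasm):
    sched = AcquisitionSchedule.fast_slow()
    n = sched.n_frames

    def expand(v):
        return np.full(n, float(v)) if np.isscalar(v) else np.asarray(v, float)

    return TipTraces(expand(bleached), expand(unbleached), expand(cytoplasm),
                     sched)


class TestFractionalRecovery:
    def test_arithmetic(self):
        sched = AcquisitionSchedule.fast_slow()
        tr = np.full(sched.n_frames, 60.0)
        tr[20] = 40.0
        tr[-1] = 52.0
        assert fractional_recovery(tr, sched) == pytest.approx(0.2)

    def test_zero_when_final_equals_first_postbleach(self):
        sched = AcquisitionSchedule.fast_slow()
        tr = np.full(sched.n_frames, 60.0)
        tr[20:] = 40.0
        assert fractional_recovery(tr, sched) == pytest.approx(0.0)

    def test_nonpositive_prebleach_flagged(self):
        sched = AcquisitionSchedule.fast_slow()
        tr = np.zeros(sched.n_frames)
        with pytest.warns(UserWarning, match="over-subtracted"):
            assert np.isnan(fractional_recovery(tr, sched))


class TestFinalDifference:
    def test_identical_traces_give_zero(self):
        t = synthetic_traces(50.0, 50.0, 10.0)
        assert final_unbleached_minus_bleached(t) == pytest.approx(0.0)

    def test_constant_normalized_gap(self):
        # normalized unbleached stays 1.0; bleached drops to 0.8 after bleach
        sched = AcquisitionSchedule.fast_slow()
        bl = np.full(sched.n_frames, 50.0)
        bl[20:] = 40.0
        t = synthetic_traces(bl, 50.0, 10.0)
        assert final_unbleached_minus_bleached(t) == pytest.approx(0.2)

    def test_matches_generator_bookkeeping(self):
        """Immobile-only tip: the analysis value equals the value computed
        directly from the generator's per-pool per-frame manifest."""
        spec = SyntheticCellSpec(cytoplasm_concentration=10.0,
                                 immobile_bound_density=30.0,
                                 mobile_bound_density=0.0, noise=None,
                                 quantize_8bit=False)
        traces, man, _, _ = analyze_tip_movie(spec, bleach_depth=1.0)
        measured = final_unbleached_minus_bleached(traces)
        sched = traces.sched
        pre, fin = sched.prebleach_indices(), sched.final_indices()
        free = man["free_per_frame"]
        bl = free + man["immobile_per_frame"][:, 0] + man["mobile_per_frame"][:, 0]
        un = free + man["immobile_per_frame"][:, 1] + man["mobile_per_frame"][:, 1]
        expected = (un[fin] / un[pre].mean() - bl[fin] / bl[pre].mean()).mean()
        assert measured == pytest.approx(expected, abs=0.01)


class TestRecoveryClassification:
    def test_step_at_first_slow_frame(self):
        sched = AcquisitionSchedule.fast_slow()
        d = np.zeros(sched.n_frames)
        d[175:] = 1.0
        t = synthetic_traces(10.0, d + 5.0, 5.0)
        assert classify_recovery_speed(t) == "<10 s"

    def test_flat_after_transition_is_no_recovery(self):
        t = synthetic_traces(10.0, 5.0, 5.0)
        assert classify_recovery_speed(t) == "no recovery"

    @pytest.mark.parametrize("k,label", [(2, "<20 s"), (3, "<30 s"),
                                         (4, "<40 s"), (5, "<60 s"),
                                         (6, "<60 s"), (7, ">30 s")])
    def test_step_at_kth_slow_frame(self, k, label):
        sched = AcquisitionSchedule.fast_slow()
        d = np.zeros(sched.n_frames)
        d[175 + k - 1:] = 1.0
        t = synthetic_traces(10.0, d + 5.0, 5.0)
        assert classify_recovery_speed(t) == label

    def test_schedule_without_slow_phase_rejected(self):
        sched = AcquisitionSchedule.uniform(200)
        n = sched.n_frames
        t = TipTraces(np.full(n, 1.0), np.full(n, 1.0), np.full(n, 1.0), sched)
        with pytest.raises(ValueError):
            classify_recovery_speed(t)


class TestSyntheticSignatures:
    def test_pure_immobile_tip(self):
        spec = SyntheticCellSpec(cytoplasm_concentration=0.0,
                                 immobile_bound_density=60.0,
                                 mobile_bound_density=0.0, noise=None,
                                 quantize_8bit=False)
        traces, _, _, _ = analyze_tip_movie(spec)
        m = tip_metrics(traces)
        assert m.recovery_class == "no recovery"
        assert abs(m.fractional_recovery) < 0.1

    def test_mobile_pool_switches_class_to_fast(self):
        spec = SyntheticCellSpec(cytoplasm_concentration=10.0,
                                 immobile_bound_density=60.0 * 0.3,
                                 mobile_bound_density=60.0 * 0.7, k_off=1.0,
                                 noise=None, quantize_8bit=False)
        traces, _, _, _ = analyze_tip_movie(spec)
        assert classify_recovery_speed(traces) == "<10 s"

    def test_final_difference_monotone_in_immobile_fraction(self):
        vals = []
        for f in (0.0, 0.15, 0.3, 0.6):
            spec = SyntheticCellSpec(cytoplasm_concentration=10.0,
                                     immobile_bound_density=60.0 * f,
                                     mobile_bound_density=60.0 * (1 - f),
                                     k_off=1.0, noise=None, quantize_8bit=False)
            traces, _, _, _ = analyze_tip_movie(spec)
            vals.append(final_unbleached_minus_bleached(traces))
        assert np.all(np.diff(vals) > 0)


class TestLateralMobility:
    def run_case(self, d_lateral, k_off, seed=3):
        spec = SyntheticCellSpec(cytoplasm_concentration=10.0,
                                 immobile_bound_density=10.0,
                                 mobile_bound_density=40.0, k_off=k_off,
                                 mobile_lateral_D=d_lateral, seed=seed)
        series, man = generate_tip_experiment(spec, beta=0.004)
        bg = estimate_background(series, man["regions"]["background"])
        return lateral_mobility_profiles(series, TIP_STRIP, (10, 21, 199), bg,
                                         unbleached_interval_px=(90, 150),
                                         toward_bleached="left", seed=1)

    def test_exchange_only_pool_shows_no_gradient(self):
        res = self.run_case(d_lateral=0.0, k_off=1.0)
        assert not res["significant"]

    def test_laterally_diffusing_bound_pool_shows_negative_gradient(self):
        res = self.run_case(d_lateral=0.05, k_off=0.001)
        assert res["significant"]
        assert res["slope"] < 0

    def test_uniform_recovery_slope_near_zero(self):
        rng = np.random.default_rng(0)
        data = np.clip(50 + rng.normal(0, 1, (200, 60, 300)), 0, 255)
        from frapdyn import ImageSeries
        series = ImageSeries(data)
        res = lateral_mobility_profiles(series, TIP_STRIP, (10, 21, 199), 0.0,
                                        unbleached_interval_px=(90, 150),
                                        seed=2)
        assert abs(res["slope"]) < 0.05
        assert not res["significant"]


class TestDarkState:
    def test_arithmetic_fraction(self):
        sched = AcquisitionSchedule.fast_slow()
        tr = np.full(sched.n_frames, 100.0)
        tr[20:] = 20.6
        tr[20] = 20.0
        assert dark_state_recovery_fraction(tr, sched) == pytest.approx(0.006)

    def test_no_recovery_gives_zero(self):
        sched = AcquisitionSchedule.fast_slow()
        tr = np.full(sched.n_frames, 100.0)
        tr[20:] = 20.0
        assert dark_state_recovery_fraction(tr, sched) == pytest.approx(0.0)

    @pytest.mark.parametrize("f,tol", [(0.0, 0.002), (0.005, 0.002),
                                       (0.04, 0.005)])
    def test_generator_dark_fraction_recovered(self, f, tol):
        spec = SyntheticCellSpec(cytoplasm_concentration=150.0,
                                 dark_state_fraction=f, seed=9)
        series, man = generate_whole_cell_bleach(spec)
        sched = AcquisitionSchedule.fast_slow()
        bg = estimate_background(series, man["regions"]["background"])
        tr = series.region_trace(man["regions"]["cell_strip"], bg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert dark_state_recovery_fraction(tr, sched) == pytest.approx(f, abs=tol)

    def test_still_rising_trace_warns(self):
        sched = AcquisitionSchedule.fast_slow()
        tr = np.full(sched.n_frames, 100.0)
        tr[20:] = 20.0 + 0.3 * np.arange(sched.n_frames - 20)
        with pytest.warns(UserWarning, match="still rising"):
            dark_state_recovery_fraction(tr, sched)


class TestIntegratedDensity:
    def test_uniform_image_at_background_gives_zero_sums(self):
        img = np.full((60, 300), 10.0)
        out = integrated_density_summary(
            img, RegionSpec(30, 20, 120, 20, role="bleached_tip"),
            RegionSpec(180, 20, 60, 20, role="cytoplasm"), background=10.0)
        assert out["tip_sum"] == pytest.approx(0.0)
        assert out["cytoplasm_sum"] == pytest.approx(0.0)

    def test_half_area_correction_arithmetic(self):
        """Tip of 100 px at 50/px above background, cytoplasm 10/px above:
        corrected tip sum = 100*50 - 10*50 = 4500."""
        img = np.zeros((60, 300))
        tip = RegionSpec(0, 0, 20, 5, role="bleached_tip")
        cyto = RegionSpec(100, 0, 20, 5, role="cytoplasm")
        img[tip.y_slice, tip.x_slice] = 50.0
        img[cyto.y_slice, cyto.x_slice] = 10.0
        out = integrated_density_summary(img, tip, cyto, background=0.0)
        assert out["tip_sum"] == pytest.approx(4500.0)

    def test_overlapping_regions_rejected(self):
        img = np.zeros((60, 300))
        with pytest.raises(ValueError):
            integrated_density_summary(
                img, RegionSpec(0, 0, 20, 5, role="bleached_tip"),
                RegionSpec(10, 0, 20, 5, role="cytoplasm"), background=0.0)

    def test_recovers_generator_voxel_ratio(self):
        spec = SyntheticCellSpec(cytoplasm_concentration=40.0, seed=8)
        img, man = generate_zstack_sum(spec, ratio=3.7)
        out = integrated_density_summary(img, man["tip_region"],
                                         man["cytoplasm_region"],
                                         background=man["background"],
                                         n_z=man["n_z"])
        assert out["ratio"] == pytest.approx(3.7, rel=0.02)

    def test_decomposition_is_additive(self):
        """tip_sum + cytoplasm_sum + reassigned overlap equals the total
        background-corrected signal of the two regions."""
        spec = SyntheticCellSpec(cytoplasm_concentration=40.0, seed=8)
        img, man = generate_zstack_sum(spec, ratio=3.7)
        tip, cyto = man["tip_region"], man["cytoplasm_region"]
        out = integrated_density_summary(img, tip, cyto,
                                         background=man["background"],
                                         n_z=man["n_z"])
        bg = man["background"] * man["n_z"]
        total = (img[tip.y_slice, tip.x_slice].sum()
                 - bg * tip.width * tip.height
                 + img[cyto.y_slice, cyto.x_slice].sum()
                 - bg * cyto.width * cyto.height)
        overlap = out["cyto_per_voxel"] * man["n_z"] * tip.width * tip.height / 2
        assert out["tip_sum"] + out["cytoplasm_sum"] + overlap \
            == pytest.approx(total, rel=0.01)
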