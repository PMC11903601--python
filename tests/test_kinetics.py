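"""Kinetic descriptors: onset, TTE, maximum slope, IER, U phases, CAD map."""

import numpy as np
import pytest

from ufrad.images import DceSeries
from ufrad.kinetics import (
    TimeSignalCurve,
    cad_kinetics,
    compute_ier,
    compute_max_slope,
    compute_tte,
    compute_u_phases,
    extract_curve,
    find_hotspot,
    onset_phase,
    ultrafast_kinetics,
)
from ufrad.schedules import standard_schedule, ultrafast_schedule
from ufrad.synthetic import PhantomSpec, TissueKinetics, generate_phantom


def _curve(signal, times=None, n_pre=1):
    signal = np.asarray(signal, dtype=float)
    if times is None:
        times = 4.2 * np.arange(len(signal))
    return TimeSignalCurve(times, signal, n_pre)


class TestOnset:
    def test_rule_arithmetic(self):
        # baseline 100; first frame strictly above 110 wins
        c = _curve([100, 105, 109, 111, 130])
        assert onset_phase(c) == 3

    def test_never_enhances_returns_sentinel(self):
        assert onset_phase(_curve([100, 101, 102, 103])) is None

    def test_boundary_not_inclusive(self):
        assert onset_phase(_curve([100, 110, 115])) == 2

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            onset_phase(_curve([0, 10, 20]))


class TestTte:
    def test_formula_arithmetic(self):
        tumor = _curve([100] * 5 + [150] * 10)  # onset phase 5
        aorta = _curve([100] * 2 + [150] * 13)  # onset phase 2
        assert compute_tte(tumor, aorta) == pytest.approx(3 * 4.2)

    def test_equal_onsets_zero(self):
        c = _curve([100, 90, 150, 160])
        assert compute_tte(c, c) == 0.0

    def test_missing_onset_nan(self):
        flat = _curve([100, 101, 102, 100])
        enh = _curve([100, 150, 160, 170])
        assert np.isnan(compute_tte(enh, flat))

    def test_invariant_to_signal_rescaling(self):
        tumor = _curve([100, 102, 118, 140, 150])
        aorta = _curve([80, 95, 120, 130, 135])
        base = compute_tte(tumor, aorta)
        tumor2 = _curve(tumor.signal * 3.7)
        aorta2 = _curve(aorta.signal * 0.2)
        assert compute_tte(tumor2, aorta2) == base

    def test_planted_onset_offsets_recovered_noiseless(self):
        # aorta onset at 4.2 s; tumor onsets yielding 1/2/3-frame offsets
        sched = ultrafast_schedule()
        aorta = TissueKinetics(120.0, 4.2, 0.15, 21.0, 0.0)
        expected = []
        got = []
        for k_frames, onset in [(1, 6.0), (2, 10.2), (3, 14.4)]:
            tumor = TissueKinetics(100.0, onset, 0.10, 50.0, 0.0)
            from ufrad.synthetic import enhancement_curve

            tc = enhancement_curve(tumor, sched)
            ac = enhancement_curve(aorta, sched)
            t_on, a_on = onset_phase(tc), onset_phase(ac)
            got.append(compute_tte(tc, ac))
            expected.append((t_on - a_on) * 4.2)
        assert got == expected
        assert np.all(np.diff(got) > 0)  # later planted onset, larger TTE


class TestMaxSlope:
    def test_constant_curve_zero(self):
        assert compute_max_slope(_curve([100] * 6)) == 0.0

    def test_single_step_arithmetic(self):
        # baseline 100, one step to 142 over 4.2 s -> 10 %/s
        assert compute_max_slope(_curve([100, 142])) == pytest.approx(10.0)

    def test_matches_consecutive_segment_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            sig = 100 + np.abs(rng.normal(0, 30, size=15)).cumsum() * rng.choice(
                [0.2, 1.0]
            )
            c = _curve(sig)
            base = sig[0]
            oracle = max(
                (100 * (sig[i + 1] - base) / base - 100 * (sig[i] - base) / base)
                / 4.2
                for i in range(len(sig) - 1)
            )
            assert compute_max_slope(c) == pytest.approx(oracle, rel=1e-12)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            compute_max_slope(_curve([-1, 10, 20]))


class TestIer:
    def test_no_enhancement_identity(self):
        assert compute_ier(_curve([100, 100, 100]), 2) == pytest.approx(1.0)

    def test_both_conventions(self):
        c = _curve([100, 200, 250])
        assert compute_ier(c, 1, "as_printed") == pytest.approx(0.5)
        assert compute_ier(c, 1, "relative_change") == pytest.approx(1.0)

    def test_as_printed_in_unit_interval_for_enhancing_curves(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            sig = 100 + np.cumsum(rng.uniform(0, 30, size=10))
            sig[0] = 100
            v = compute_ier(_curve(sig), early_phase=rng.integers(1, 10))
            assert 0 < v <= 1


class TestUPhases:
    def test_u2_follows_u1(self, uf_schedule):
        sig = [100] * 3 + [120] * 12
        u1, u2, t2 = compute_u_phases(_curve(sig, uf_schedule.times), uf_schedule)
        assert (u1, u2) == (3, 4)
        assert t2 == pytest.approx(uf_schedule.times[4])

    def test_onset_never_sentinel(self, uf_schedule):
        sig = [100] * 15
        u1, u2, t2 = compute_u_phases(_curve(sig, uf_schedule.times), uf_schedule)
        assert u1 is None and u2 is None and np.isnan(t2)

    def test_onset_at_final_frame_clamps(self, uf_schedule):
        sig = [100] * 14 + [150]
        with pytest.warns(UserWarning, match="clamping"):
            u1, u2, _ = compute_u_phases(_curve(sig, uf_schedule.times), uf_schedule)
        assert (u1, u2) == (14, 14)

    def test_u2_time_increases_with_planted_onset(self, uf_schedule):
        from ufrad.synthetic import enhancement_curve

        times = []
        for onset in [4.0, 12.0, 20.0, 28.0]:
            k = TissueKinetics(100.0, onset, 0.2, onset + 15, 0.0)
            _, _, t2 = compute_u_phases(enhancement_curve(k, uf_schedule), uf_schedule)
            times.append(t2)
        assert np.all(np.diff(times) > 0)


class TestHotspot:
    def _series(self, data):
        return DceSeries(data, (1.0, 1.0, 1.0), ultrafast_schedule())

    def test_planted_bright_spot_found(self):
        # bright peak with a dimmer halo: the disc centered on the peak is
        # the unique maximizer (a lone voxel ties every disc containing it)
        data = np.full((15, 6, 20, 20), 100.0)
        data[-1, 3, 9:12, 11:14] = 300.0
        data[-1, 3, 10, 12] = 500.0
        mask = np.zeros((6, 20, 20), dtype=bool)
        mask[2:5, 5:16, 5:16] = True
        roi = find_hotspot(self._series(data), mask)
        assert roi.slice_index == 3 and roi.center == (10, 12)
        assert [3, 10, 12] in roi.voxels.tolist()

    def test_uniform_enhancement_tie_breaks_lowest_index(self):
        data = np.full((15, 4, 10, 10), 100.0)
        data[-1] = 200.0
        mask = np.zeros((4, 10, 10), dtype=bool)
        mask[1:3, 4:8, 4:8] = True
        roi = find_hotspot(self._series(data), mask)
        assert (roi.slice_index, *roi.center) == (1, 4, 4)

    def test_matches_brute_force_disc_search(self):
        rng = np.random.default_rng(5)
        nz, ny, nx = 4, 16, 16
        data = np.full((15, nz, ny, nx), 100.0)
        zz, yy, xx = np.mgrid[:nz, :ny, :nx]
        bump = 200 * np.exp(-(((yy - 7.3) ** 2 + (xx - 9.1) ** 2) / 8.0))
        data[-1] += bump * (zz == 2) + rng.normal(0, 1.0, size=(nz, ny, nx))
        mask = np.zeros((nz, ny, nx), dtype=bool)
        mask[1:4, 2:14, 2:14] = True
        series = self._series(data)
        roi = find_hotspot(series, mask)

        # brute force over every mask voxel as disc center
        offs = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)]
        rel = (data[-1] - data[0]) / data[0]
        best, best_score = None, -np.inf
        for z, y, x in np.argwhere(mask):
            vals = [
                rel[z, y + dy, x + dx]
                for dy, dx in offs
                if 0 <= y + dy < ny and 0 <= x + dx < nx
            ]
            score = np.mean(vals)
            if score > best_score + 1e-12:
                best, best_score = (z, y, x), score
        assert (roi.slice_index, *roi.center) == best

    def test_small_mask_shrinks_roi_with_warning(self):
        data = np.full((15, 4, 8, 8), 100.0)
        data[-1] = 140.0
        mask = np.zeros((4, 8, 8), dtype=bool)
        mask[2, 4, 4] = True
        mask[2, 4, 5] = True
        with pytest.warns(UserWarning, match="shrinking"):
            roi = find_hotspot(self._series(data), mask)
        assert all(mask[tuple(v)] for v in roi.voxels)


class TestExtractCurve:
    def test_constant_image_constant_curve(self, uf_schedule):
        data = np.full((15, 4, 8, 8), 7.0)
        series = DceSeries(data, (1.0, 1.0, 1.0), uf_schedule)
        from ufrad.kinetics import HotspotRoi

        roi = HotspotRoi(2, (4, 4), 3.0, np.array([[2, 4, 4], [2, 4, 5]]))
        assert np.allclose(extract_curve(series, roi).signal, 7.0)

    def test_disc_mean_equals_explicit_average(self, phantom):
        roi = find_hotspot(phantom.ultrafast, phantom.tumor_mask)
        curve = extract_curve(phantom.ultrafast, roi)
        z, y, x = roi.voxels[:, 0], roi.voxels[:, 1], roi.voxels[:, 2]
        oracle = np.array(
            [phantom.ultrafast.data[t, z, y, x].mean() for t in range(15)]
        )
        assert np.allclose(curve.signal, oracle)

    def test_single_voxel_roi(self, phantom):
        from ufrad.kinetics import HotspotRoi

        roi = HotspotRoi(16, (22, 22), 3.0, np.array([[16, 22, 22]]))
        curve = extract_curve(phantom.ultrafast, roi)
        assert np.allclose(curve.signal, phantom.ultrafast.data[:, 16, 22, 22])


class TestCadKinetics:
    def _series(self, pre, init, delayed):
        data = np.stack([pre, init, (init + delayed) / 2, (init + delayed) / 2, delayed])
        return DceSeries(data, (1.0, 1.0, 1.0), standard_schedule())

    def test_pure_washout(self):
        shape = (4, 6, 6)
        pre = np.full(shape, 100.0)
        init = np.full(shape, 200.0)  # +100%
        delayed = init * 0.8  # -20%
        mask = np.ones(shape, dtype=bool)
        kin = cad_kinetics(self._series(pre, init, delayed), mask)
        assert kin.washout_pct == 100.0
        assert kin.plateau_pct == 0.0 and kin.persistent_pct == 0.0
        assert kin.peak_enhancement_pct == pytest.approx(100.0)

    def test_exact_boundary_is_plateau(self):
        shape = (2, 4, 4)
        pre = np.full(shape, 100.0)
        init = np.full(shape, 200.0)
        delayed = np.full(shape, 220.0)  # (220-200)/200 == the 0.1 boundary
        kin = cad_kinetics(self._series(pre, init, delayed), np.ones(shape, bool))
        assert kin.plateau_pct == 100.0

    def test_voxel_count_oracle(self):
        # 50 washout, 30 plateau, 20 persistent voxels
        nvox = 100
        pre = np.full((1, 10, 10), 100.0)
        init = np.full((1, 10, 10), 200.0)
        change = np.concatenate(
            [np.full(50, -0.2), np.full(30, 0.0), np.full(20, 0.2)]
        ).reshape(1, 10, 10)
        delayed = init * (1 + change)
        kin = cad_kinetics(self._series(pre, init, delayed), np.ones((1, 10, 10), bool))
        assert (kin.washout_pct, kin.plateau_pct, kin.persistent_pct) == (50, 30, 20)
        assert kin.washout_pct + kin.plateau_pct + kin.persistent_pct == pytest.approx(
            100.0
        )

    def test_no_evaluated_voxels_sentinel(self):
        shape = (2, 4, 4)
        pre = np.full(shape, 100.0)
        init = np.full(shape, 120.0)  # +20% < 50% threshold
        kin = cad_kinetics(self._series(pre, init, init), np.ones(shape, bool))
        assert np.isnan(kin.washout_pct)
        assert kin.peak_enhancement_pct == pytest.approx(20.0)


class TestRoundTrip:
    def test_planted_kinetics_recovered_on_phantom_sweep(self):
        # shorter planted tumor onset => smaller TTE, exact at zero noise.
        # threshold crossing is onset + 0.1/slope = onset + 1 s, and the
        # first frame strictly past it sets the phase: aorta crosses at
        # 4.87 s -> phase 2; tumor onsets below cross at phases 3/4/5.
        ttes = []
        for onset, want in [(8.4, 4.2), (12.6, 8.4), (16.8, 12.6)]:
            spec = PhantomSpec(
                seed=30,
                noise_sd=0.0,
                tumor_kinetics=TissueKinetics(100.0, onset, 0.10, 50.0, -0.0005),
                aorta_kinetics=TissueKinetics(120.0, 4.2, 0.15, 21.0, 0.0),
            )
            rec = generate_phantom(spec)
            kin = ultrafast_kinetics(rec.ultrafast, rec.tumor_mask, rec.aorta_mask)
            ttes.append(kin.tte_s)
            assert kin.tte_s == pytest.approx(want)
        assert np.all(np.diff(ttes) > 0)
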