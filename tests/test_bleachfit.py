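import numpy as np
import pytest

from memtirf.bleachfit import (
    BleachTrace,
    cell_trace,
    compare_conditions,
    default_background_region,
    fit_photobleach_global,
    fits_to_frame,
    read_traces_csv,
    write_traces_csv,
)
from memtirf.optics import ImageStack, LabelMask


def two_phase(t, a, kf, ks):
    return a * np.exp(-kf * t) + (100.0 - a) * np.exp(-ks * t)


def make_trace(t, values, cell_id=0, condition="c"):
    values = np.array(values, dtype=float)
    values[0] = 100.0
    return BleachTrace(cell_id, condition, t, values)


@pytest.fixture
def disk_stack():
    """A synthetic stack: one square cell over a flat background."""
    h = w = 40
    labels = np.zeros((h, w), dtype=np.int32)
    labels[15:25, 15:25] = 1
    t = np.arange(20) * 0.1
    frames = np.empty((20, h, w))
    decay = 50.0 * np.exp(-0.5 * t)
    for f in range(20):
        frames[f] = 100.0
        frames[f, labels == 1] += decay[f]
    return ImageStack(frames, 0.08, 0.1), LabelMask(labels)


class TestCellTrace:
    def test_first_value_exactly_100(self, disk_stack):
        stack, mask = disk_stack
        tr = cell_trace(stack, mask, 1)
        assert tr.normalized_intensity[0] == 100.0

    def test_scale_invariance(self, disk_stack):
        stack, mask = disk_stack
        scaled = ImageStack(stack.frames * 3.7, stack.pixel_size, stack.frame_interval)
        np.testing.assert_allclose(
            cell_trace(scaled, mask, 1).normalized_intensity,
            cell_trace(stack, mask, 1).normalized_intensity,
            rtol=1e-12,
        )

    def test_constant_offset_stack_gives_flat_100(self):
        labels = np.zeros((30, 30), dtype=np.int32)
        labels[12:20, 12:20] = 1
        frames = np.full((8, 30, 30), 80.0)
        frames[:, labels == 1] += 50.0
        stack = ImageStack(frames, 0.08, 0.1)
        tr = cell_trace(stack, LabelMask(labels), 1)
        np.testing.assert_allclose(tr.normalized_intensity, 100.0)

    def test_background_subtraction_uses_decay(self, disk_stack):
        stack, mask = disk_stack
        tr = cell_trace(stack, mask, 1)
        np.testing.assert_allclose(
            tr.normalized_intensity, 100.0 * np.exp(-0.5 * tr.times), rtol=1e-9
        )

    def test_nonpositive_frame0_rejected(self):
        labels = np.zeros((30, 30), dtype=np.int32)
        labels[12:20, 12:20] = 1
        frames = np.full((5, 30, 30), 100.0)  # cell not brighter than background
        with pytest.raises(ValueError, match="cannot normalize"):
            cell_trace(ImageStack(frames, 0.08, 0.1), LabelMask(labels), 1)

    def test_background_region_must_avoid_cells(self, disk_stack):
        stack, mask = disk_stack
        bad = np.ones(mask.labels.shape, dtype=bool)
        with pytest.raises(ValueError, match="overlaps"):
            cell_trace(stack, mask, 1, background_region=bad)

    def test_default_background_margin(self, disk_stack):
        _, mask = disk_stack
        bg = default_background_region(mask, margin_px=5)
        assert not (bg & (mask.labels > 0)).any()
        assert bg.sum() > 0


class TestGlobalFit:
    def test_noiseless_recovery_to_1e6(self):
        t = np.arange(0, 12, 0.1)
        tr = make_trace(t, two_phase(t, 40.0, 0.5, 0.05))
        fits = fit_photobleach_global([tr])
        f = fits["c"]
        assert f.k_fast == pytest.approx(0.5, rel=1e-6)
        assert f.K == pytest.approx(0.05, rel=1e-6)
        assert f.A_fast == pytest.approx(40.0, rel=1e-6)
        assert f.R2 == pytest.approx(1.0, abs=1e-9)

    def test_pure_slow_exponential_closed_form(self):
        t_half = 3.0
        k = np.log(2) / t_half
        t = np.arange(0, 15, 0.25)
        tr = make_trace(t, 100.0 * np.exp(-k * t))
        f = fit_photobleach_global([tr])["c"]
        assert f.K == pytest.approx(k, rel=1e-7)

    def test_two_conditions_shared_fast_rate_with_noise(self):
        rng = np.random.default_rng(12)
        t = np.arange(0, 12, 0.1)
        traces = []
        for cond, k_slow in (("a", 0.08), ("b", 0.03)):
            clean = two_phase(t, 40.0, 0.5, k_slow)
            for cell in range(6):
                noisy = clean * (1 + 0.01 * rng.standard_normal(t.size))
                traces.append(make_trace(t, noisy, cell, cond))
        fits = fit_photobleach_global(traces)
        assert fits["a"].k_fast == fits["b"].k_fast
        assert fits["a"].k_fast == pytest.approx(0.5, rel=0.05)
        assert fits["a"].K == pytest.approx(0.08, rel=0.05)
        assert fits["b"].K == pytest.approx(0.03, rel=0.05)
        assert fits["a"].K > fits["b"].K
        assert fits["a"].n == 6

    def test_time_unit_equivariance(self):
        t = np.arange(0, 12, 0.1)
        tr_s = make_trace(t, two_phase(t, 0.5, 0.5, 0.05))
        tr_min = make_trace(t / 60.0, two_phase(t, 0.5, 0.5, 0.05))
        f_s = fit_photobleach_global([tr_s])["c"]
        f_min = fit_photobleach_global([tr_min])["c"]
        assert f_min.K == pytest.approx(f_s.K * 60.0, rel=1e-4)
        assert f_min.R2 == pytest.approx(f_s.R2, abs=1e-6)

    def test_too_few_time_points_rejected(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        tr = make_trace(t, 100 * np.exp(-0.1 * t))
        with pytest.raises(ValueError, match="fewer than 5"):
            fit_photobleach_global([tr])

    def test_mismatched_grids_within_condition_rejected(self):
        t1 = np.arange(0, 5, 0.5)
        t2 = np.arange(0, 5, 0.25)
        traces = [
            make_trace(t1, 100 * np.exp(-0.1 * t1), 0),
            make_trace(t2, 100 * np.exp(-0.1 * t2), 1),
        ]
        with pytest.raises(ValueError, match="time grids"):
            fit_photobleach_global(traces)

    def test_pooled_target_agrees_with_mean_on_balanced_data(self):
        rng = np.random.default_rng(3)
        t = np.arange(0, 12, 0.1)
        traces = []
        for cond, ks in (("a", 0.08), ("b", 0.03)):
            clean = two_phase(t, 40.0, 0.5, ks)
            for cell in range(5):
                traces.append(make_trace(t, clean * (1 + 0.01 * rng.standard_normal(t.size)), cell, cond))
        f_mean = fit_photobleach_global(traces, target="mean")
        f_pool = fit_photobleach_global(traces, target="pooled")
        for c in ("a", "b"):
            assert f_pool[c].K == pytest.approx(f_mean[c].K, rel=1e-3)

    def test_unknown_target_rejected(self):
        t = np.arange(0, 10, 0.2)
        tr = make_trace(t, two_phase(t, 40, 0.5, 0.05))
        with pytest.raises(ValueError, match="target"):
            fit_photobleach_global([tr], target="median")

    def test_k_fast_never_below_k_slow(self):
        t = np.arange(0, 10, 0.2)
        tr = make_trace(t, two_phase(t, 20.0, 1.0, 0.02))
        f = fit_photobleach_global([tr])["c"]
        assert f.k_fast >= f.K


class TestCompare:
    def _fit(self, cond, K, sem=1e-4):
        from memtirf.bleachfit import BleachFit

        t = np.arange(0, 10, 0.5)
        return BleachFit(cond, K, 0.5, 40.0, sem, 0.99, 10, times=t)

    def test_forced_ratio(self):
        df = compare_conditions([self._fit("ref", 0.08), self._fit("rif", 0.03)])
        row = df[df.condition == "rif"].iloc[0]
        assert row.K_ratio_to_ref == pytest.approx(0.375)
        assert row.verdict == "faster diffusion"

    def test_identical_fits_no_change(self):
        df = compare_conditions([self._fit("a", 0.05), self._fit("b", 0.05)])
        assert df[df.condition == "b"].iloc[0].verdict == "no change"

    def test_single_fit_rejected(self):
        with pytest.raises(ValueError):
            compare_conditions([self._fit("a", 0.05)])

    def test_mismatched_grids_rejected(self):
        from memtirf.bleachfit import BleachFit

        f1 = self._fit("a", 0.05)
        f2 = BleachFit("b", 0.03, 0.5, 40.0, 1e-4, 0.99, 10, times=np.arange(0, 5, 0.5))
        with pytest.raises(ValueError, match="time grids"):
            compare_conditions([f1, f2])


class TestTraceCsv:
    def test_round_trip(self, tmp_path):
        t = np.arange(0, 5, 0.5)
        traces = [
            make_trace(t, two_phase(t, 30, 0.6, 0.04), cell_id=i, condition=c)
            for c in ("x", "y")
            for i in range(3)
        ]
        p = tmp_path / "traces.csv"
        write_traces_csv(traces, p)
        back = read_traces_csv(p)
        assert len(back) == 6
        orig = {(tr.condition, tr.cell_id): tr for tr in traces}
        for tr in back:
            ref = orig[(tr.condition, tr.cell_id)]
            np.testing.assert_allclose(tr.times, ref.times)
            np.testing.assert_allclose(tr.normalized_intensity, ref.normalized_intensity, rtol=1e-9)

    def test_fits_frame_columns(self):
        t = np.arange(0, 10, 0.2)
        fits = fit_photobleach_global([make_trace(t, two_phase(t, 40, 0.5, 0.05))])
        df = fits_to_frame(fits)
        assert {"condition", "K", "SEM_K", "R2", "n", "k_fast", "A_fast"} <= set(df.columns)


class TestTraceValidation:
    def test_first_value_must_be_100(self):
        t = np.arange(0, 5, 0.5)
        with pytest.raises(ValueError):
            BleachTrace(0, "c", t, np.full(t.size, 99.0))

    def test_times_must_start_at_zero(self):
        t = np.arange(1, 6, 0.5)
        vals = np.full(t.size, 100.0)
        with pytest.raises(ValueError):
            BleachTrace(0, "c", t, vals)
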