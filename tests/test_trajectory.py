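"""Schedule generation, timing models, windows, sliding-window bookkeeping."""

import numpy as np
import pytest

from epikit import (
    SamplingSchedule,
    Scheme,
    SequenceParams,
    TimingModel,
    effective_line_times,
    make_epi_schedule,
    make_epik_schedule,
    make_schedule,
    periphery_update_rate,
    sampling_window,
    schedule_to_frame,
    sliding_window_sources,
)
from epikit.trajectory import Region, ScheduleEntry, keyhole_bounds

from conftest import random_valid_params


class TestSequenceParams:
    def test_preset_derived_quantities(self, epi64, epik96):
        assert epi64.lines_per_shot == 64
        assert epik96.keyhole_lines == 24
        assert epik96.periphery_lines == 72
        assert epik96.lines_per_shot == 48  # half of the 96-line matrix
        assert epik96.effective_echo_spacing_ms == pytest.approx(0.445)

    @pytest.mark.parametrize(
        "kw",
        [
            dict(keyhole_fraction=0.0),
            dict(keyhole_fraction=1.5),
            dict(te_ms=-1.0),
            dict(matrix_py=64, keyhole_fraction=0.3),  # 19.2 keyhole lines
            dict(
                scheme=Scheme.EPIK, matrix_py=96, keyhole_fraction=0.25,
                n_interleaves=5,
            ),  # 72 peripheral lines not divisible by 5
        ],
    )
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValueError):
            SequenceParams(**kw)


class TestEpiSchedule:
    def test_protocol_window_arithmetic(self, epi64):
        sched = make_epi_schedule(epi64)
        times = [e.acq_time_ms for e in sched.entries]
        assert times[0] == pytest.approx(13.68)
        assert times[-1] == pytest.approx(46.32 - 0.510)
        assert times[0] + 64 * 0.510 == pytest.approx(46.32)

    def test_center_line_at_te(self, epi64):
        sched = make_epi_schedule(epi64)
        assert sched.times_by_line()[32] == pytest.approx(30.0)

    def test_eight_line_arithmetic_sequence(self):
        p = SequenceParams(matrix_py=8, echo_spacing_ms=1.0, te_ms=10.0)
        sched = make_epi_schedule(p)
        assert [e.acq_time_ms for e in sched.entries] == pytest.approx(
            [6, 7, 8, 9, 10, 11, 12, 13]
        )
        assert all(e.region is Region.KEYHOLE for e in sched.entries)

    def test_rejects_epik_params(self, epik96):
        with pytest.raises(ValueError):
            make_epi_schedule(epik96)


class TestEpikSchedule:
    def test_interleave_offsets_cycle(self, epik96):
        """Peripheral offsets run 0,1,2 over shots 0-2 and wrap at shot 3."""
        def first_peripheral_line(shot):
            sched = make_epik_schedule(epik96, shot)
            return next(
                e.line_index for e in sched.entries if e.region is Region.PERIPHERY
            )

        assert [first_peripheral_line(s) for s in range(4)] == [0, 1, 2, 0]

    def test_entries_per_shot_halved(self, epik96):
        sched = make_epik_schedule(epik96, 0)
        assert len(sched.entries) == 48
        kh = [e for e in sched.entries if e.region is Region.KEYHOLE]
        assert len(kh) == 24

    def test_nyquist_coverage_over_three_shots(self, epik96):
        lines = []
        for s in range(3):
            lines += [
                e.line_index
                for e in make_epik_schedule(epik96, s).entries
                if e.region is Region.PERIPHERY
            ]
        lines += [
            e.line_index
            for e in make_epik_schedule(epik96, 0).entries
            if e.region is Region.KEYHOLE
        ]
        assert sorted(lines) == list(range(96))

    def test_keyhole_contains_central_line(self, epik96):
        lo, hi = keyhole_bounds(epik96)
        assert (lo, hi) == (36, 60)
        assert lo <= 48 < hi

    def test_acquisition_order_monotone_in_ky(self, epik96):
        sched = make_epik_schedule(epik96, 1)
        lines = sched.line_indices
        assert lines == sorted(lines)

    def test_ets_makes_shared_periphery_smooth(self, epik96):
        """Combined peripheral time map increases strictly with k_y."""
        by_line = {}
        for s in range(3):
            for e in make_epik_schedule(epik96, s).entries:
                if e.region is Region.PERIPHERY:
                    by_line[e.line_index] = e.acq_time_ms
        bottom = [by_line[j] for j in range(36)]
        assert np.all(np.diff(bottom) > 0)
        assert np.allclose(np.diff(bottom), 0.890 / 3)

    def test_degenerate_epik_equals_epi(self, epi64):
        """keyhole_fraction=1, n_interleaves=1 EPIK is bit-identical EPI."""
        epik_degenerate = epi64.with_(scheme=Scheme.EPIK)
        a = make_epi_schedule(epi64)
        b = make_epik_schedule(epik_degenerate, 0)
        assert a.line_indices == b.line_indices
        assert [e.acq_time_ms for e in a.entries] == pytest.approx(
            [e.acq_time_ms for e in b.entries]
        )

    def test_strictly_increasing_times_enforced(self, epi64):
        entries = (
            ScheduleEntry(0, 5.0, Region.KEYHOLE),
            ScheduleEntry(1, 5.0, Region.KEYHOLE),
        )
        with pytest.raises(ValueError):
            SamplingSchedule(0, entries, epi64)


class TestEffectiveLineTimes:
    def test_uniform_matches_protocol_spacing(self, epik96):
        tm = effective_line_times(epik96, TimingModel.UNIFORM_EFFECTIVE)
        diffs = np.diff(tm.times_ms)
        assert np.allclose(diffs, 0.445)
        assert tm.times_ms[48] == pytest.approx(30.0)
        assert tm.times_ms[0] == pytest.approx(8.64)

    def test_epi_equals_schedule_times(self, epi64):
        tm = effective_line_times(epi64, TimingModel.UNIFORM_EFFECTIVE)
        sched = make_epi_schedule(epi64)
        by_line = sched.times_by_line()
        assert list(tm.times_ms) == pytest.approx(
            [by_line[j] for j in range(64)]
        )

    def test_piecewise_span_identity(self, epik96):
        """Piecewise and uniform maps span the same readout duration."""
        tm = effective_line_times(epik96, TimingModel.PHYSICAL_PIECEWISE)
        d_per = 0.890 / 3
        span = (tm.times_ms[-1] + d_per) - tm.times_ms[0]
        assert span == pytest.approx(48 * 0.890)
        assert span == pytest.approx(96 * 0.445)
        assert tm.times_ms[48] == pytest.approx(30.0)

    def test_piecewise_region_spacings(self, epik96):
        tm = effective_line_times(epik96, TimingModel.PHYSICAL_PIECEWISE)
        t = np.asarray(tm.times_ms)
        assert np.allclose(np.diff(t[:36]), 0.890 / 3)  # bottom periphery
        assert np.allclose(np.diff(t[36:60]), 0.890)  # keyhole
        assert np.allclose(np.diff(t[60:]), 0.890 / 3)  # top periphery

    def test_monotone_nondecreasing(self, epik96):
        for model in TimingModel:
            t = np.asarray(effective_line_times(epik96, model).times_ms)
            assert np.all(np.diff(t) > 0)

    def test_unknown_model_rejected(self, epik96):
        with pytest.raises(ValueError):
            effective_line_times(epik96, "bogus")


class TestWindowsAndRates:
    def test_protocol_sampling_windows(self, epi64, epik96):
        assert sampling_window(epi64) == pytest.approx((13.68, 46.32))
        assert sampling_window(epik96) == pytest.approx((8.64, 51.36))

    def test_window_width_difference(self, epi64, epik96):
        w_epi = np.diff(sampling_window(epi64))[0]
        w_epik = np.diff(sampling_window(epik96))[0]
        assert w_epik - w_epi == pytest.approx(10.08)

    def test_window_symmetric_about_te(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = random_valid_params(rng)
            lo, hi = sampling_window(p)
            assert (lo + hi) / 2 == pytest.approx(p.te_ms)

    def test_periphery_update_rate(self, epik96, epi64):
        assert periphery_update_rate(epik96) == pytest.approx(1 / 6.6)
        assert round(periphery_update_rate(epik96), 2) == 0.15
        assert periphery_update_rate(epi64) == pytest.approx(1000 / 2200)
        p = epik96.with_(tr_ms=1000.0)
        assert periphery_update_rate(p) == pytest.approx(1 / 3)


class TestSlidingWindowSources:
    def test_keyhole_from_current_scan(self, epik96):
        src = sliding_window_sources(5, epik96)
        for j in range(36, 60):
            assert src[j] == 5

    def test_scan2_partition(self, epik96):
        src = sliding_window_sources(2, epik96)
        for j in list(range(36)) + list(range(60, 96)):
            assert src[j] == j % 3

    def test_oldest_scan_discarded(self, epik96):
        src = sliding_window_sources(3, epik96)
        assert set(src.values()) <= {1, 2, 3}
        assert 0 not in src.values()

    def test_bootstrap_threshold(self, epik96):
        with pytest.raises(ValueError):
            sliding_window_sources(1, epik96)
        sliding_window_sources(2, epik96)  # first reconstructable

    def test_source_map_totality_random_params(self):
        """Total single-valued map with bounded source ages, over many
        random valid parameterizations."""
        rng = np.random.default_rng(42)
        for _ in range(300):
            p = random_valid_params(rng)
            scan = int(rng.integers(p.n_interleaves - 1, p.n_interleaves + 10))
            src = sliding_window_sources(scan, p)
            assert sorted(src) == list(range(p.matrix_py))
            ages = {scan - s for s in src.values()}
            assert ages <= set(range(p.n_interleaves))
            lo, hi = keyhole_bounds(p)
            assert all(src[j] == scan for j in range(lo, hi))

    def test_coverage_matches_schedules(self):
        """The source map's claims agree with what the shots acquire."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            p = random_valid_params(rng)
            scan = p.n_interleaves - 1 + int(rng.integers(0, 5))
            src = sliding_window_sources(scan, p)
            acquired = {
                s: set(make_schedule(p, s).line_indices)
                for s in range(scan - p.n_interleaves + 1, scan + 1)
            }
            for j, s in src.items():
                assert j in acquired[s]


def test_schedule_csv_export(tmp_path, epik96):
    scheds = [make_epik_schedule(epik96, s) for s in range(3)]
    df = schedule_to_frame(scheds)
    assert list(df.columns) == [
        "shot_index", "acq_order", "line_index", "region", "acq_time_ms"
    ]
    assert len(df) == 3 * 48
    out = tmp_path / "sched.csv"
    df.to_csv(out, index=False)
    assert out.exists()
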