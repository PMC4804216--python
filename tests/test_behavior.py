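"""Tests for the behavioural indices, including brute-force oracles.

The oracle recomputes maintenance/accuracy from a millisecond-resolution
boolean key-state raster and perseverance by direct scanning; interval
arithmetic must agree exactly (maintenance, accuracy) or within one
millisecond quantum (perseverance).
"""

import numpy as np
import pytest

from bgcircuit.behavior import (
    BehaviorIndices,
    KeypressLog,
    SynthProfile,
    accuracy,
    compute_indices,
    maintenance,
    perseverance,
    read_log,
    selection_to_log,
    switches,
    synth_log,
    write_log,
)
from bgcircuit.task import KEYS, SelectionTrace, make_sim_schedule


def simple_schedule(n_windows=4, win_s=5.0):
    from bgcircuit.task import StimulusSchedule
    vals = []
    base = np.array([0.5, 0.45, 0.4, 0.35])
    for i in range(n_windows):
        vals.append(np.roll(base, i))
    return StimulusSchedule(onsets=np.arange(n_windows) * win_s,
                            offsets=np.arange(1, n_windows + 1) * win_s,
                            values=np.stack(vals),
                            trial_id=np.zeros(n_windows, dtype=int))


class TestMaintenance:
    def test_union_of_two_holds(self):
        sched = simple_schedule()
        log = KeypressLog([(2.0, "up", "press"), (5.0, "up", "release"),
                           (7.0, "left", "press"), (15.0, "left", "release")],
                          end_s=20.0)
        assert maintenance(log, sched) == pytest.approx(11000.0)

    def test_no_press_is_zero(self):
        assert maintenance(KeypressLog([], end_s=20.0), simple_schedule()) == 0.0

    def test_simultaneous_holds_counted_once(self):
        sched = simple_schedule()
        log = KeypressLog([(0.0, "up", "press"), (0.0, "down", "press"),
                           (1.0, "up", "release"), (1.0, "down", "release")],
                          end_s=20.0)
        assert maintenance(log, sched) == pytest.approx(1000.0)


class TestPerseverance:
    def test_direct_latency(self):
        sched = simple_schedule()
        log = KeypressLog([(3.0, "up", "press"), (6.2, "up", "release")], end_s=20.0)
        mean, n = perseverance(log, sched, min_rt_ms=300)
        assert n == 1 and mean == pytest.approx(1200.0)

    def test_fast_release_excluded(self):
        sched = simple_schedule()
        log = KeypressLog([(3.0, "up", "press"), (5.1, "up", "release")], end_s=20.0)
        mean, n = perseverance(log, sched, min_rt_ms=300)
        assert n == 0 and np.isnan(mean)

    def test_no_key_held_is_empty_not_zero(self):
        sched = simple_schedule()
        log = KeypressLog([(5.5, "up", "press"), (6.0, "up", "release")], end_s=20.0)
        mean, n = perseverance(log, sched, min_rt_ms=300)
        assert n == 0 and np.isnan(mean)


class TestSwitches:
    def test_same_key_repress_not_counted(self):
        sched = simple_schedule(1)
        log = KeypressLog([
            (0.5, "up", "press"), (1.0, "up", "release"),
            (1.5, "up", "press"), (2.0, "up", "release"),   # re-press: ignored
            (2.5, "left", "press"), (4.0, "left", "release"),
        ], end_s=5.0)
        assert switches(log, sched, min_rt_ms=300) == pytest.approx(2.0)

    def test_single_hold_scores_entry_switch(self):
        sched = simple_schedule(1)
        log = KeypressLog([(0.5, "up", "press"), (4.5, "up", "release")], end_s=5.0)
        assert switches(log, sched) == pytest.approx(1.0)
        assert switches(log, sched, count_entry_switch=False) == 0.0

    def test_empty_window_is_zero(self):
        assert switches(KeypressLog([], end_s=5.0), simple_schedule(1)) == 0.0

    def test_press_within_rt_window_excluded(self):
        sched = simple_schedule(1)
        log = KeypressLog([(0.1, "up", "press"), (4.5, "up", "release")], end_s=5.0)
        assert switches(log, sched, min_rt_ms=300) == 0.0


class TestAccuracy:
    def test_perfect_hold_scores_100(self):
        sched = simple_schedule(1)  # brightest channel 0 = "up"
        log = KeypressLog([(0.0, "up", "press"), (5.0, "up", "release")], end_s=5.0)
        assert accuracy(log, sched) == pytest.approx(100.0)

    def test_half_hold_scores_50(self):
        sched = simple_schedule(1)
        log = KeypressLog([(0.0, "up", "press"), (2.5, "up", "release")], end_s=5.0)
        assert accuracy(log, sched) == pytest.approx(50.0, abs=1.0)

    def test_wrong_key_scores_0(self):
        sched = simple_schedule(1)
        log = KeypressLog([(0.0, "down", "press"), (5.0, "down", "release")], end_s=5.0)
        assert accuracy(log, sched) == 0.0

    def test_multikey_bins_incorrect(self):
        sched = simple_schedule(1)
        log = KeypressLog([(0.0, "up", "press"), (0.0, "down", "press"),
                           (5.0, "up", "release"), (5.0, "down", "release")],
                          end_s=5.0)
        assert accuracy(log, sched) == 0.0


# -- brute-force oracle -------------------------------------------------


def _raster(log: KeypressLog, t_end_ms: int) -> np.ndarray:
    """(t_end_ms, 4) boolean key-state raster at 1-ms resolution."""
    r = np.zeros((t_end_ms, 4), dtype=bool)
    for key, ivs in log.intervals_ms().items():
        k = KEYS.index(key)
        for a, b in ivs:
            r[max(a, 0):min(b, t_end_ms), k] = True
    return r


def oracle_maintenance(log, sched):
    r = _raster(log, int(round(sched.duration * 1000)))
    any_down = r.any(axis=1)
    per_trial = []
    for _, t0, t1 in sched.trials:
        per_trial.append(any_down[int(round(t0 * 1000)):int(round(t1 * 1000))].sum())
    return float(np.mean(per_trial))


def oracle_perseverance(log, sched, min_rt_ms):
    r = _raster(log, int(round(sched.duration * 1000)) + 1)
    end = int(round(log.end_s * 1000))
    lats = []
    for tc in sched.change_times():
        t = int(round(tc * 1000))
        held = np.flatnonzero(r[t])
        if len(held) == 0:
            continue
        # disengagement of one key = first ms it goes up after the change
        rels = []
        for k in held:
            rel = t
            while rel < end and r[rel, k]:
                rel += 1
            rels.append(rel)
        rel = max(rels)
        if rel >= end:
            continue
        if rel - t >= min_rt_ms:
            lats.append(rel - t)
    return (float(np.mean(lats)), len(lats)) if lats else (float("nan"), 0)


def oracle_accuracy(log, sched, bin_ms=17.0):
    r = _raster(log, int(round(sched.duration * 1000)) + 1)
    ok = n = 0
    for _, t0, t1 in sched.trials:
        for lo in np.arange(t0 * 1000, t1 * 1000, bin_ms):
            mid = lo + bin_ms / 2
            if mid > t1 * 1000:
                break
            n += 1
            pat = sched.pattern_at(mid / 1000)
            if pat is None:
                continue
            down = np.flatnonzero(r[int(mid)])
            if len(down) == 1 and down[0] == sched.brightest[pat]:
                ok += 1
    return 100.0 * ok / n if n else 0.0


def random_log(rng, t_end=20.0):
    """A random (possibly messy) log: random holds per key, overlaps allowed."""
    events = []
    for key in KEYS:
        t = rng.uniform(0, 3)
        while t < t_end - 0.2:
            dur = rng.uniform(0.05, 3.0)
            t1 = min(t + dur, t_end)
            events.append((round(t, 3), key, "press"))
            events.append((round(t1, 3), key, "release"))
            t = t1 + rng.uniform(0.05, 4.0)
    events.sort(key=lambda e: (e[0], e[2] == "press"))
    return KeypressLog(events, end_s=t_end)


class TestOracleEquivalence:
    def test_interval_arithmetic_matches_ms_scan(self):
        """On 1000 random synthetic logs the interval-based indices equal
        the millisecond-scan oracle (perseverance within one quantum)."""
        rng = np.random.default_rng(42)
        sched = simple_schedule(4)
        for _ in range(1000):
            log = random_log(rng)
            assert maintenance(log, sched) == pytest.approx(
                oracle_maintenance(log, sched), abs=1e-9)
            om, on = oracle_perseverance(log, sched, 300)
            pm, pn = perseverance(log, sched, 300)
            assert pn == on
            if on:
                assert pm == pytest.approx(om, abs=1.0)
            assert accuracy(log, sched) == pytest.approx(
                oracle_accuracy(log, sched), abs=1e-9)

    def test_switch_conservation(self):
        """total switches = presses - same-key re-presses - excluded presses
        (on a schedule whose windows tile the log's whole extent)."""
        rng = np.random.default_rng(7)
        sched = simple_schedule(4)
        for _ in range(200):
            log = random_log(rng)
            total = switches(log, sched, min_rt_ms=300) * sched.n_patterns
            n_press = n_recount = n_excl = 0
            for on, off in zip(sched.onsets, sched.offsets):
                w0, w1 = on * 1000, off * 1000
                last = None
                for t, ch in log.presses():
                    if not (w0 <= t < w1):
                        continue
                    if t < w0 + 300:
                        n_excl += 1
                        continue
                    n_press += 1
                    if last is not None and ch == last:
                        n_recount += 1
                    last = ch
            out_of_window = len(log.presses()) - n_press - n_excl
            assert total == pytest.approx(n_press - n_recount)
            assert out_of_window == 0  # windows tile [0, 20)


class TestMonotonicity:
    def test_delaying_releases_never_decreases_indices(self):
        sched = simple_schedule(4)
        prof = SynthProfile(perseverance_ms=800, rt_ms=500, switches_per_pattern=1)
        log = synth_log(prof, sched, seed=1)
        delayed_events = [(t + (0.2 if a == "release" else 0.0), k, a)
                          for t, k, a in log.events]
        delayed_events.sort(key=lambda e: e[0])
        delayed = KeypressLog(delayed_events, end_s=log.end_s + 0.2)
        assert maintenance(delayed, sched) >= maintenance(log, sched)
        p0, _ = perseverance(log, sched, 300)
        p1, _ = perseverance(delayed, sched, 300)
        assert p1 >= p0


class TestSynthLog:
    def test_profile_recovery(self):
        sched = simple_schedule(8)
        prof = SynthProfile(perseverance_ms=1500, rt_ms=450, switches_per_pattern=1)
        for seed in (1, 2):
            log = synth_log(prof, sched, seed=seed)
            idx = compute_indices(log, sched, min_rt_ms=300)
            assert idx.perseverance_ms == pytest.approx(1500, abs=50)
            assert idx.switches == pytest.approx(1.0)

    def test_two_seeds_differ_but_match_profile(self):
        sched = simple_schedule(8)
        prof = SynthProfile(perseverance_ms=1200, rt_ms=500, switches_per_pattern=2)
        a = synth_log(prof, sched, seed=1)
        b = synth_log(prof, sched, seed=2)
        assert a.events != b.events
        for log in (a, b):
            idx = compute_indices(log, sched, min_rt_ms=300)
            assert idx.switches == pytest.approx(2.0, abs=0.2)

    def test_zero_press_profile(self):
        sched = simple_schedule(4)
        log = synth_log(SynthProfile(switches_per_pattern=0), sched, seed=0)
        idx = compute_indices(log, sched)
        assert idx.maintenance_ms == 0 and idx.switches == 0
        assert np.isnan(idx.perseverance_ms)

    def test_infeasible_profile_named(self):
        sched = simple_schedule(4)
        with pytest.raises(ValueError, match="perseverance_ms"):
            synth_log(SynthProfile(perseverance_ms=6000), sched, seed=0)
        with pytest.raises(ValueError, match="min_rt"):
            synth_log(SynthProfile(rt_ms=250, rt_jitter_ms=0), sched, seed=0)


class TestLogPlumbing:
    def test_file_round_trip(self, tmp_path):
        sched = simple_schedule(4)
        log = synth_log(SynthProfile(), sched, seed=3)
        p = tmp_path / "keys.log"
        write_log(log, p)
        back = read_log(p)
        assert back.events == [(pytest.approx(t), k, a) for t, k, a in log.events]
        assert back.end_s == pytest.approx(log.end_s)

    def test_validation_rejects_double_press(self):
        with pytest.raises(ValueError, match="already down"):
            KeypressLog([(0.0, "up", "press"), (1.0, "up", "press")])
        with pytest.raises(ValueError, match="not down"):
            KeypressLog([(0.0, "up", "release")])
        with pytest.raises(ValueError, match="non-decreasing"):
            KeypressLog([(1.0, "up", "press"), (0.5, "up", "release")])

    def test_selection_trace_to_log(self):
        sel = SelectionTrace(t=(np.arange(10) + 1) * 0.01,
                             channel=np.array([-1, 0, 0, 0, 1, 1, -1, -1, 2, 2]))
        log = selection_to_log(sel)
        keys = [(k, a) for _, k, a in log.events]
        assert keys == [("up", "press"), ("up", "release"), ("down", "press"),
                        ("down", "release"), ("left", "press"), ("left", "release")]
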