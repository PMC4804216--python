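"""Behavioural indices of the luminance-discrimination task.

Three indices quantify motor flexibility from keypress records (human-style
logs or discretized simulation output):

* **maintenance** -- time per trial spent holding any key, correct or not,
  regardless of pattern changes (simultaneous holds counted once, union
  semantics);
* **perseverance** -- latency to disengage from whatever is held when the
  luminance pattern changes (latencies faster than the reaction-time
  exclusion threshold are dropped as involuntary);
* **switches** -- distinct-key selection changes per stable luminance
  pattern; re-pressing the same key never counts, while the obligatory
  first response after a change counts as the window's first switch.

An accuracy score (percent of trial time holding exactly the correct key,
evaluated on ~17-ms bins) mirrors the task's feedback score.

All computations quantize timestamps to 1 ms and operate on half-open
hold intervals ``[t_press, t_release)``, which makes the interval
arithmetic exactly equivalent to a brute-force millisecond scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .task import KEYS, SelectionTrace, StimulusSchedule

__all__ = [
    "KeypressLog",
    "BehaviorIndices",
    "SynthProfile",
    "selection_to_log",
    "maintenance",
    "perseverance",
    "switches",
    "accuracy",
    "compute_indices",
    "synth_log",
    "write_log",
    "read_log",
]

_MS = 1000  # quantization: 1 ms


def _ms(t: float) -> int:
    return int(round(t * _MS))


@dataclass
class KeypressLog:
    """Ordered press/release events.

    ``events`` is a list of ``(t_s, key, action)`` with key in
    :data:`~bgcircuit.task.KEYS` and action ``press``/``release``.
    Holds may overlap across keys; an unmatched press is implicitly
    released at ``end_s``.
    """

    events: list
    end_s: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        last_t = -np.inf
        down = set()
        for t, key, action in self.events:
            if key not in KEYS:
                raise ValueError(f"unknown key {key!r}")
            if action not in ("press", "release"):
                raise ValueError(f"unknown action {action!r}")
            if t < last_t:
                raise ValueError("event timestamps must be non-decreasing")
            last_t = t
            if action == "press":
                if key in down:
                    raise ValueError(f"key {key!r} pressed while already down at t={t}")
                down.add(key)
            else:
                if key not in down:
                    raise ValueError(f"key {key!r} released while not down at t={t}")
                down.discard(key)
        if self.end_s is None:
            self.end_s = float(last_t) if self.events else 0.0

    def intervals_ms(self) -> dict:
        """Per-key hold intervals in integer ms, half-open [t0, t1)."""
        out = {k: [] for k in KEYS}
        open_at = {}
        for t, key, action in self.events:
            if action == "press":
                open_at[key] = _ms(t)
            else:
                t0 = open_at.pop(key)
                t1 = _ms(t)
                if t1 > t0:
                    out[key].append((t0, t1))
        end = _ms(self.end_s)
        for key, t0 in open_at.items():
            if end > t0:
                out[key].append((t0, end))
        return out

    def presses(self) -> list:
        """(t_ms, channel) of every press event, in order."""
        return [(_ms(t), KEYS.index(k)) for t, k, a in self.events if a == "press"]

    @property
    def n_events(self) -> int:
        return len(self.events)


def selection_to_log(sel: SelectionTrace) -> KeypressLog:
    """Convert a discrete selection trace into press/release events.

    Each engaged sample extends a hold of the corresponding key; a change
    of channel releases the old key and presses the new one at the sample
    time.
    """
    events = []
    prev = -1
    t_prev = 0.0
    for t, ch in zip(sel.t, sel.channel):
        if ch != prev:
            if prev >= 0:
                events.append((t, KEYS[prev], "release"))
            if ch >= 0:
                events.append((t, KEYS[ch], "press"))
            prev = ch
        t_prev = t
    if prev >= 0:
        events.append((t_prev + sel.dt, KEYS[prev], "release"))
    return KeypressLog(events=events, end_s=float(sel.t[-1] + sel.dt),
                       meta={"source": sel.source})


def _union_length_ms(intervals, lo: int, hi: int) -> int:
    """Length of the union of [t0, t1) intervals clipped to [lo, hi)."""
    clipped = sorted((max(t0, lo), min(t1, hi)) for t0, t1 in intervals
                     if t1 > lo and t0 < hi)
    total = 0
    cur_lo = cur_hi = None
    for t0, t1 in clipped:
        if cur_hi is None or t0 > cur_hi:
            if cur_hi is not None:
                total += cur_hi - cur_lo
            cur_lo, cur_hi = t0, t1
        else:
            cur_hi = max(cur_hi, t1)
    if cur_hi is not None:
        total += cur_hi - cur_lo
    return total


def maintenance(log: KeypressLog, schedule: StimulusSchedule) -> float:
    """Mean per-trial total key-hold time, ms (union over keys)."""
    trials = schedule.trials
    if not trials:
        raise ValueError("schedule has no trials")
    ivals = [iv for key_ivs in log.intervals_ms().values() for iv in key_ivs]
    per_trial = [_union_length_ms(ivals, _ms(t0), _ms(t1)) for _, t0, t1 in trials]
    return float(np.mean(per_trial))


def _held_at(intervals_by_key: dict, t: int) -> list:
    """Keys down at time t with their release times: [(key, t_release)]."""
    out = []
    for key, ivs in intervals_by_key.items():
        for t0, t1 in ivs:
            if t0 <= t < t1:
                out.append((key, t1))
    return out


def perseverance(log: KeypressLog, schedule: StimulusSchedule,
                 min_rt_ms: float = 300.0) -> tuple:
    """Mean disengage latency after pattern changes, ms.

    For each pattern-to-pattern change at which at least one key is held,
    the latency is the time until every key held at the change has been
    released.  Latencies below ``min_rt_ms`` are excluded (involuntary),
    as are changes where the hold persists to the end of the record
    (disengagement unobserved).  Returns ``(mean_ms, n_contributing)``
    with mean NaN when no change contributes -- an empty result, distinct
    from zero.
    """
    if min_rt_ms < 0:
        raise ValueError("min_rt_ms must be >= 0")
    ivals = log.intervals_ms()
    latencies = []
    end = _ms(log.end_s)
    for tc in schedule.change_times():
        tc_ms = _ms(tc)
        held = _held_at(ivals, tc_ms)
        if not held:
            continue
        release = max(t1 for _, t1 in held)
        if release >= end:
            continue
        lat = release - tc_ms
        if lat >= min_rt_ms:
            latencies.append(lat)
    if not latencies:
        return float("nan"), 0
    return float(np.mean(latencies)), len(latencies)


def switches(log: KeypressLog, schedule: StimulusSchedule,
             min_rt_ms: float = 300.0, count_entry_switch: bool = True) -> float:
    """Mean distinct-key selection changes per luminance pattern.

    Within each stable-pattern window, a press counts when the pressed
    key differs from the most recently pressed key of that window;
    same-key re-presses never count.  The first press of a window (the
    required response) counts when ``count_entry_switch`` is true, so an
    ideal subject scores 1 per pattern.  Presses within ``min_rt_ms`` of
    the window's start are excluded as involuntary.
    """
    presses = log.presses()
    counts = []
    for on, off in zip(schedule.onsets, schedule.offsets):
        w0, w1 = _ms(on), _ms(off)
        last = None
        n = 0
        for t, ch in presses:
            if not (w0 <= t < w1) or t < w0 + min_rt_ms:
                continue
            if last is None:
                if count_entry_switch:
                    n += 1
            elif ch != last:
                n += 1
            last = ch
        counts.append(n)
    return float(np.mean(counts))


def accuracy(log: KeypressLog, schedule: StimulusSchedule, bin_ms: float = 17.0) -> float:
    """Percent of trial time holding exactly the correct key.

    Each trial is divided into ``bin_ms`` bins; a bin scores when, at its
    midpoint, the key of the currently brightest position -- and no other
    key -- is held.  Bins with several keys down are incorrect (the
    task's feedback disappears under multi-key presses).
    """
    if not bin_ms > 0:
        raise ValueError("bin_ms must be > 0")
    ivals = log.intervals_ms()
    n_ok = 0
    n_bins = 0
    for _, t0, t1 in schedule.trials:
        edges = np.arange(_ms(t0), _ms(t1), bin_ms)
        for lo in edges:
            mid = lo + bin_ms / 2.0
            if mid > _ms(t1):
                break
            n_bins += 1
            pat = schedule.pattern_at(mid / _MS)
            if pat is None:
                continue
            held = [k for k, ivs in ivals.items()
                    for a, b in ivs if a <= mid < b]
            if len(held) == 1 and held[0] == KEYS[int(schedule.brightest[pat])]:
                n_ok += 1
    return 100.0 * n_ok / n_bins if n_bins else 0.0


@dataclass
class BehaviorIndices:
    """The index vector of one run/session."""

    maintenance_ms: float
    perseverance_ms: float  # NaN when no change contributed
    n_perseverance: int
    switches: float
    accuracy_pct: float
    n_excluded: int = 0

    def as_dict(self) -> dict:
        return {"maintenance_ms": self.maintenance_ms,
                "perseverance_ms": self.perseverance_ms,
                "n_perseverance": self.n_perseverance,
                "switches": self.switches,
                "accuracy_pct": self.accuracy_pct,
                "n_excluded": self.n_excluded}


def compute_indices(log: KeypressLog | SelectionTrace, schedule: StimulusSchedule,
                    min_rt_ms: float = 300.0, bin_ms: float = 17.0,
                    count_entry_switch: bool = True) -> BehaviorIndices:
    """All behavioural indices of one record against one schedule."""
    if isinstance(log, SelectionTrace):
        log = selection_to_log(log)
    maint = maintenance(log, schedule)
    pers, n_pers = perseverance(log, schedule, min_rt_ms)
    sw = switches(log, schedule, min_rt_ms, count_entry_switch)
    acc = accuracy(log, schedule, bin_ms)
    # bookkeeping: sub-threshold disengage latencies dropped by the RT rule
    n_excl = 0
    ivals = log.intervals_ms()
    end = _ms(log.end_s)
    for tc in schedule.change_times():
        held = _held_at(ivals, _ms(tc))
        if held:
            release = max(t1 for _, t1 in held)
            if release < end and release - _ms(tc) < min_rt_ms:
                n_excl += 1
    return BehaviorIndices(maintenance_ms=maint, perseverance_ms=pers,
                           n_perseverance=n_pers, switches=sw, accuracy_pct=acc,
                           n_excluded=n_excl)


@dataclass(frozen=True)
class SynthProfile:
    """Target behavioural profile for the synthetic keypress generator.

    ``rt_ms`` is the latency from pattern change to the (correct) new
    press; ``perseverance_ms`` the latency from change to release of the
    previous key; ``switches_per_pattern`` the number of distinct-key
    presses per stable window (0 = never press at all); ``extra_switch_gap_ms``
    spaces any switches beyond the first.  Jitters are uniform
    half-widths.
    """

    perseverance_ms: float = 1500.0
    perseverance_jitter_ms: float = 40.0
    rt_ms: float = 450.0
    rt_jitter_ms: float = 60.0
    switches_per_pattern: float = 1.0
    extra_switch_gap_ms: float = 600.0
    min_rt_ms: float = 300.0


def synth_log(profile: SynthProfile, schedule: StimulusSchedule, seed: int = 0) -> KeypressLog:
    """Generate a keypress log realizing a requested behavioural profile.

    The synthetic agent presses the correct key ``rt_ms`` after each
    pattern appears, holds it until ``perseverance_ms`` after the next
    change, and inserts extra distinct-key switches when
    ``switches_per_pattern`` exceeds one.  Raises for infeasible
    profiles (e.g. a perseverance longer than the shortest pattern).
    """
    min_gap_ms = 1000.0 * float(np.min(schedule.offsets - schedule.onsets))
    if profile.switches_per_pattern < 0:
        raise ValueError("infeasible profile: switches_per_pattern < 0")
    if profile.switches_per_pattern > 0:
        if profile.perseverance_ms + profile.perseverance_jitter_ms >= min_gap_ms:
            raise ValueError(
                "infeasible profile: perseverance_ms exceeds the shortest "
                f"stable pattern ({min_gap_ms:.0f} ms)")
        if profile.rt_ms - profile.rt_jitter_ms <= profile.min_rt_ms:
            raise ValueError(
                "infeasible profile: rt_ms - rt_jitter_ms must exceed min_rt_ms "
                "or presses would be excluded by the reaction-time rule")
        n_extra = int(round(profile.switches_per_pattern)) - 1
        need = (profile.rt_ms + profile.rt_jitter_ms
                + n_extra * profile.extra_switch_gap_ms)
        if need >= min_gap_ms:
            raise ValueError(
                "infeasible profile: rt_ms plus extra switches do not fit in "
                f"the shortest stable pattern ({min_gap_ms:.0f} ms)")
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0xB19)))
    if profile.switches_per_pattern == 0:
        return KeypressLog(events=[], end_s=schedule.duration)

    events = []
    held = None  # (key, planned release time s)
    pending = None  # (key, release_time_s) of the perseverative hold
    n_pat = schedule.n_patterns
    change_set = set(np.round(schedule.change_times(), 6))
    for i in range(n_pat):
        on = schedule.onsets[i]
        off = schedule.offsets[i]
        correct = KEYS[int(schedule.brightest[i])]
        pending = None
        if held is not None:
            key, _ = held
            if round(float(on), 6) in change_set:
                lat = profile.perseverance_ms + rng.uniform(
                    -profile.perseverance_jitter_ms, profile.perseverance_jitter_ms)
                t_rel = on + lat / 1000.0
                events.append((t_rel, key, "release"))
                pending = (key, t_rel)
            else:  # blank gap before this pattern: release at previous offset
                events.append((float(schedule.offsets[i - 1]), key, "release"))
            held = None
        t_press = on + (profile.rt_ms + rng.uniform(
            -profile.rt_jitter_ms, profile.rt_jitter_ms)) / 1000.0
        key = correct
        # the key held into the next pattern must differ from that
        # pattern's correct key, or its perseverative hold would collide
        # with the next entry press
        next_correct = (KEYS[int(schedule.brightest[i + 1])]
                        if i + 1 < n_pat else None)
        n_extra = int(round(profile.switches_per_pattern)) - 1
        for j in range(n_extra):
            t_next = t_press + profile.extra_switch_gap_ms / 1000.0
            events.append((t_press, key, "press"))
            events.append((t_next, key, "release"))
            others = [k for k in KEYS if k != key
                      and (j < n_extra - 1 or k != next_correct)
                      and not (pending and k == pending[0] and t_next < pending[1])]
            key = others[int(rng.integers(len(others)))]
            t_press = t_next
        events.append((t_press, key, "press"))
        held = (key, off)
    if held is not None:
        events.append((float(schedule.offsets[-1]), held[0], "release"))
    events.sort(key=lambda e: e[0])
    return KeypressLog(events=events, end_s=schedule.duration,
                       meta={"synthetic": True, "seed": int(seed)})


# -- log file round-trip -----------------------------------------------

_LOG_HEADER = "# bgcircuit-keypress-log v1"


def write_log(log: KeypressLog, path) -> None:
    """Write a keypress log as tab-separated text (t_s, key, action)."""
    with open(path, "w") as fh:
        fh.write(_LOG_HEADER + "\n")
        fh.write(f"# end_s={log.end_s:.6f}\n")
        fh.write("t_s\tkey\taction\n")
        for t, key, action in log.events:
            fh.write(f"{t:.6f}\t{key}\t{action}\n")


def read_log(path) -> KeypressLog:
    """Read a log written by :func:`write_log` (validates order/pairing)."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or lines[0] != _LOG_HEADER:
        raise ValueError(f"{path}: not a bgcircuit keypress log")
    end_s = None
    if len(lines) > 1 and lines[1].startswith("# end_s="):
        end_s = float(lines[1].split("=", 1)[1])
    events = []
    for ln in lines[3:]:
        if not ln.strip():
            continue
        t, key, action = ln.split("\t")
        events.append((float(t), key, action))
    return KeypressLog(events=events, end_s=end_s)
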