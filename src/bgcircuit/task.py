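"""Luminance-discrimination task: stimulus schedules and selection readout.

A *luminance pattern* assigns four brightness/saliency values to the four
screen positions (up, down, left, right -- channels 0..3).  Schedules are
sequences of timed patterns: the simulator uses fixed 5-s intervals, the
two behavioural-experiment layouts use variable intervals grouped into
trials separated by blank gaps.  Every pattern change moves the brightest
position, so each change demands exactly one selection switch.

The readout side discretizes continuous channel activity into a
:class:`SelectionTrace` by threshold-plus-margin winner-take-all with tie
hysteresis.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KEYS",
    "HIGH_SALIENCY",
    "LOW_SALIENCY",
    "StimulusSchedule",
    "SelectionTrace",
    "make_sim_schedule",
    "make_task_schedule",
    "schedule_to_input",
    "read_selection",
    "write_schedule",
    "read_schedule",
]

#: channel order convention used everywhere in the package
KEYS = ("up", "down", "left", "right")

#: the two saliency vectors of the simulated task
HIGH_SALIENCY = (0.5, 0.45, 0.4, 0.35)
LOW_SALIENCY = (0.4, 0.35, 0.3, 0.25)

_SCHEDULE_HEADER = "# bgcircuit-schedule v1"


@dataclass(frozen=True)
class StimulusSchedule:
    """A timed sequence of luminance patterns.

    Attributes
    ----------
    onsets, offsets : ndarray, seconds
        Start and end of each stable pattern (strictly increasing onsets;
        gaps between a pattern's offset and the next onset are blank
        screen).
    values : ndarray, shape (n, 4)
        The four luminance values per pattern, one column per channel in
        :data:`KEYS` order; each row is a permutation of the same base
        vector with a unique maximum.
    trial_id : ndarray of int
        Trial each pattern belongs to.
    reward : tuple of str or None
        Optional per-trial saliency/reward tag ("low"/"high").
    """

    onsets: np.ndarray
    offsets: np.ndarray
    values: np.ndarray
    trial_id: np.ndarray
    reward: tuple | None = None

    def __post_init__(self):
        onsets = np.asarray(self.onsets, dtype=float)
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "offsets", np.asarray(self.offsets, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "trial_id", np.asarray(self.trial_id, dtype=int))
        if len(onsets) == 0:
            raise ValueError("empty schedule")
        if not np.all(np.diff(onsets) > 0):
            raise ValueError("onsets must be strictly increasing")
        if not np.all(self.offsets > self.onsets):
            raise ValueError("each offset must exceed its onset")
        if self.values.shape != (len(onsets), 4):
            raise ValueError("values must be (n_patterns, 4)")
        for row in self.values:
            if np.sum(row == row.max()) != 1:
                raise ValueError("each pattern needs a unique brightest channel")

    @property
    def n_patterns(self) -> int:
        return len(self.onsets)

    @property
    def brightest(self) -> np.ndarray:
        """Index of the brightest channel per pattern."""
        return np.argmax(self.values, axis=1)

    @property
    def duration(self) -> float:
        return float(self.offsets[-1])

    @property
    def trials(self) -> list:
        """Per-trial (trial_id, t_start, t_end) tuples."""
        out = []
        for tid in np.unique(self.trial_id):
            m = self.trial_id == tid
            out.append((int(tid), float(self.onsets[m].min()), float(self.offsets[m].max())))
        return out

    def change_times(self) -> np.ndarray:
        """Times of pattern-to-pattern transitions (contiguous onsets only).

        A transition exists where a pattern starts exactly when the
        previous one ends; trial-initial onsets after a blank gap are
        appearances, not changes.
        """
        prev_off = self.offsets[:-1]
        nxt_on = self.onsets[1:]
        return nxt_on[np.isclose(prev_off, nxt_on)]

    def pattern_at(self, t: float):
        """Index of the pattern covering time ``t``, or None (blank)."""
        i = int(np.searchsorted(self.onsets, t, side="right")) - 1
        if i >= 0 and t < self.offsets[i]:
            return i
        return None


def _permute_no_repeat(base: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Stack of n permutations of ``base`` with no consecutive repeat of
    the brightest channel (so every change demands a switch)."""
    rows = []
    prev_best = -1
    for _ in range(n):
        while True:
            perm = rng.permutation(4)
            row = base[perm]
            best = int(np.argmax(row))
            if best != prev_best:
                break
        rows.append(row)
        prev_best = best
    return np.stack(rows)


def make_sim_schedule(saliency: str, n_intervals: int, interval_s: float = 5.0,
                      seed: int = 0, intervals_per_trial: int = 4) -> StimulusSchedule:
    """Fixed-interval schedule for the simulator.

    The base vector is the high-saliency [0.5 0.45 0.4 0.35] or the
    low-saliency [0.4 0.35 0.3 0.25] set, randomly re-assigned to the
    four positions every ``interval_s`` (default 5 s) such that the
    brightest position always moves.  Consecutive groups of
    ``intervals_per_trial`` intervals form one simulated trial.
    """
    vectors = {"high": HIGH_SALIENCY, "low": LOW_SALIENCY}
    if saliency not in vectors:
        raise ValueError(f"unknown saliency {saliency!r}; expected 'high' or 'low'")
    if n_intervals < 1:
        raise ValueError("n_intervals must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0x5EED)))
    values = _permute_no_repeat(np.asarray(vectors[saliency]), n_intervals, rng)
    onsets = np.arange(n_intervals) * interval_s
    return StimulusSchedule(
        onsets=onsets, offsets=onsets + interval_s, values=values,
        trial_id=np.arange(n_intervals) // intervals_per_trial)


def make_task_schedule(experiment: int, n_trials: int, seed: int = 0,
                       saliency: str | None = None) -> StimulusSchedule:
    """Schedule with the trial structure of the two behavioural layouts.

    Experiment 1: six patterns per trial (initial + five changes), gaps
    uniform in [2, 4] s resampled until the trial lasts 15-20 s,
    inter-trial blank of 3 s.  Experiment 2: seven patterns per trial,
    gaps uniform in [1.25, 2] s, inter-trial blank of 6 s and balanced
    pseudo-random low/high reward tags (half of each per 8-trial block).

    ``saliency`` picks the base luminance vector (defaults to high for
    experiment 1 and per-trial high/low by reward tag for experiment 2).
    """
    if experiment not in (1, 2):
        raise ValueError("experiment must be 1 or 2")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0x7A5C, experiment)))

    if experiment == 1:
        n_pat, lo, hi, gap, bounds = 6, 2.0, 4.0, 3.0, (15.0, 20.0)
        rewards = None
    else:
        n_pat, lo, hi, gap, bounds = 7, 1.25, 2.0, 6.0, None
        rewards = []
        for blk in range(0, n_trials, 8):
            half = min(8, n_trials - blk)
            tags = ["low", "high"] * ((half + 1) // 2)
            rng.shuffle(tags)
            rewards.extend(tags[:half])

    onsets, offsets, values, trial_id = [], [], [], []
    t = 0.0
    prev_best = -1
    for tr in range(n_trials):
        for _ in range(1000):
            durs = rng.uniform(lo, hi, n_pat)
            if bounds is None or bounds[0] <= durs.sum() <= bounds[1]:
                break
        else:  # pragma: no cover - bounds are easily satisfiable
            raise RuntimeError("could not sample trial durations within bounds")
        if experiment == 1:
            base = np.asarray(HIGH_SALIENCY if saliency in (None, "high") else LOW_SALIENCY)
        else:
            tag = saliency or rewards[tr]
            base = np.asarray(HIGH_SALIENCY if tag == "high" else LOW_SALIENCY)
        for d in durs:
            while True:
                row = base[rng.permutation(4)]
                best = int(np.argmax(row))
                if best != prev_best:
                    break
            onsets.append(t)
            offsets.append(t + d)
            values.append(row)
            trial_id.append(tr)
            prev_best = best
            t += d
        t += gap
    return StimulusSchedule(
        onsets=np.array(onsets), offsets=np.array(offsets), values=np.stack(values),
        trial_id=np.array(trial_id),
        reward=tuple(rewards) if rewards is not None else None)


def schedule_to_input(schedule: StimulusSchedule, n_steps: int, dt: float) -> np.ndarray:
    """Rasterize a schedule into the per-step external cortical input.

    Returns (n_steps, 4); blank-screen periods (and times past the end of
    the schedule) are zero.
    """
    out = np.zeros((n_steps, 4))
    for on, off, row in zip(schedule.onsets, schedule.offsets, schedule.values):
        k0 = int(round(on / dt))
        k1 = min(int(round(off / dt)), n_steps)
        if k0 < n_steps:
            out[k0:k1] = row
    return out


@dataclass
class SelectionTrace:
    """Discrete action engagement over time.

    ``channel[i]`` is the engaged channel (0..3) at ``t[i]``, or -1 when
    nothing is selected.  Samples are evenly spaced.
    """

    t: np.ndarray
    channel: np.ndarray
    source: str = "simulated"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.channel = np.asarray(self.channel, dtype=int)
        if len(self.t) != len(self.channel):
            raise ValueError("t and channel must have equal length")
        if np.any(np.diff(self.t) < 0):
            raise ValueError("timestamps must be non-decreasing")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def coverage(self, t0: float, t1: float) -> float:
        """Fraction of [t0, t1) with some channel engaged."""
        m = (self.t >= t0) & (self.t < t1)
        if not m.any():
            return 0.0
        return float(np.mean(self.channel[m] >= 0))


def read_selection(trace, threshold: float | None = None, margin: float | None = None,
                   readout_nucleus: str | None = None,
                   hysteresis: float | None = None) -> SelectionTrace:
    """Discretize a simulation trace into channel selections.

    Engagement: the readout channel with maximal activity is selected
    when it reaches ``threshold`` and exceeds the runner-up by
    ``margin``; on an exact tie among super-threshold leaders the
    previous winner, if among them, is retained; an unresolved tie
    selects nothing.  Release: an engaged channel is held until its
    activity falls below ``threshold - hysteresis`` or another channel
    overtakes it by ``margin`` (Schmitt-trigger hold, so brief noise
    dips do not register as key releases).  Defaults come from the
    trace's embedded readout metadata.
    """
    ro = trace.meta.get("readout", {})
    nucleus = readout_nucleus or ro.get("nucleus", "cortex")
    threshold = ro.get("threshold", 0.3) if threshold is None else threshold
    margin = ro.get("margin", 0.02) if margin is None else margin
    hysteresis = ro.get("hysteresis", 0.1) if hysteresis is None else hysteresis
    thr_release = threshold - hysteresis

    y = trace.nucleus(nucleus)  # raises KeyError if missing
    n = y.shape[0]
    sel = np.full(n, -1, dtype=int)
    prev = -1
    for i in range(n):
        row = y[i]
        top = float(row.max())
        cur = -1
        if prev >= 0 and row[prev] >= thr_release and top - row[prev] < margin:
            cur = prev  # hold the engaged key through small dips
        elif top >= threshold:
            winners = np.flatnonzero(row == top)
            if len(winners) > 1:
                cur = prev if prev in winners else -1
            else:
                w = int(winners[0])
                runner = float(np.partition(row, -2)[-2])
                if (top - runner) >= margin or prev == w:
                    cur = w
        sel[i] = cur
        prev = cur
    return SelectionTrace(t=trace.t.copy(), channel=sel, source="simulated",
                          meta={"nucleus": nucleus, "threshold": threshold,
                                "margin": margin, "hysteresis": hysteresis})


# -- schedule file round-trip ------------------------------------------


def write_schedule(schedule: StimulusSchedule, path) -> None:
    """Write a schedule as versioned tab-separated text."""
    buf = io.StringIO()
    buf.write(_SCHEDULE_HEADER + "\n")
    buf.write("onset_s\toffset_s\tup\tdown\tleft\tright\ttrial_id\treward_label\n")
    for i in range(schedule.n_patterns):
        tid = int(schedule.trial_id[i])
        tag = schedule.reward[tid] if schedule.reward is not None else "."
        vals = "\t".join(f"{v:.6g}" for v in schedule.values[i])
        buf.write(f"{schedule.onsets[i]:.6f}\t{schedule.offsets[i]:.6f}\t{vals}\t{tid}\t{tag}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_schedule(path) -> StimulusSchedule:
    """Read a schedule written by :func:`write_schedule`."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or lines[0] != _SCHEDULE_HEADER:
        raise ValueError(f"{path}: not a bgcircuit schedule file")
    onsets, offsets, values, trial_id, tags = [], [], [], [], {}
    for ln in lines[2:]:
        if not ln.strip():
            continue
        parts = ln.split("\t")
        onsets.append(float(parts[0]))
        offsets.append(float(parts[1]))
        values.append([float(v) for v in parts[2:6]])
        tid = int(parts[6])
        trial_id.append(tid)
        tags[tid] = parts[7]
    reward = None
    if any(v != "." for v in tags.values()):
        reward = tuple(tags[t] for t in sorted(tags))
    return StimulusSchedule(onsets=np.array(onsets), offsets=np.array(offsets),
                            values=np.array(values), trial_id=np.array(trial_id),
                            reward=reward)
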