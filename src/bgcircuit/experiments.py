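"""Simulated studies: regime case studies, the paired virtual experiment
and the dopamine x pallidal-connectivity regime map.

The virtual experiment mirrors a within-subject clinical design: each
random seed is one simulated Parkinsonian subject (low dopaminergic
drive) tested four times -- simulated subthalamic DBS on/off crossed
with high/low input value -- with the *same* cortical noise series in
all four conditions, so condition contrasts isolate the manipulation.
Behavioural indices per run feed paired t-tests and the 2x2
repeated-measures ANOVA.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats as bgstats
from .behavior import compute_indices, selection_to_log
from .config import ModelConfig, simulate
from .task import SelectionTrace, StimulusSchedule, make_sim_schedule, read_selection

__all__ = [
    "RegimeLabel",
    "ConditionResult",
    "classify_regime",
    "run_virtual_experiment",
    "sweep_regimes",
    "reproduce_fig4",
    "RegimeReproductionError",
    "selection_change_rate",
]

REGIMES = ("maintenance", "suppression", "switching", "repetition")


@dataclass(frozen=True)
class RegimeLabel:
    """Outcome of the regime decision tree with its supporting evidence."""

    label: str
    coverage: float        # fraction of stable-window time with a selection
    switch_rate: float     # distinct-key switches per stable window
    cycle_rate: float      # same-key press/release cycles per stable window

    def __post_init__(self):
        if self.label not in REGIMES:
            raise ValueError(f"unknown regime label {self.label!r}")


@dataclass(frozen=True)
class ConditionResult:
    """One run of the virtual experiment."""

    seed_id: int
    dbs: str               # "on" | "off"
    value: str             # "high" | "low"
    indices: dict
    config_hash: str
    noise_checksum: str


def _window_stats(sel: SelectionTrace, schedule: StimulusSchedule):
    """Per-stable-window coverage / distinct-switch / same-key-cycle means."""
    if schedule.n_patterns < 2:
        raise ValueError("need >= 2 stable-input windows to classify")
    if schedule.onsets[0] < sel.t[0] - sel.dt or schedule.offsets[-1] > sel.t[-1] + sel.dt:
        raise ValueError("selection trace does not cover the schedule")
    # global run-length encoding: a hold carried over a window boundary was
    # "pressed" in the window where the run started, not re-pressed anew
    ch_all = sel.channel
    starts = np.flatnonzero(np.r_[True, np.diff(ch_all) != 0])
    press_t = sel.t[starts]
    press_ch = ch_all[starts]
    cov, sw, cyc = [], [], []
    for on, off in zip(schedule.onsets, schedule.offsets):
        m = (sel.t >= on) & (sel.t < off)
        ch = ch_all[m]
        cov.append(float(np.mean(ch >= 0)) if len(ch) else 0.0)
        in_win = (press_t >= on) & (press_t < off) & (press_ch >= 0)
        n_sw, n_cyc, last = 0, 0, None
        for k in press_ch[in_win]:
            if last is None or k != last:
                n_sw += 1
            else:
                n_cyc += 1
            last = int(k)
        sw.append(n_sw)
        cyc.append(n_cyc)
    return float(np.mean(cov)), float(np.mean(sw)), float(np.mean(cyc))


def classify_regime(sel: SelectionTrace, schedule: StimulusSchedule,
                    c_low: float = 0.15, s_hi: float = 2.0,
                    r_hi: float = 2.0) -> RegimeLabel:
    """Label a run's motor regime by a fixed decision tree.

    suppression -- the agent is almost entirely disengaged (coverage <
    ``c_low``); switching -- distinct-key changes per stable window >= ``s_hi``
    (ambitendency among competitors); repetition -- the same key is
    cyclically released and re-pressed (>= ``r_hi`` cycles per window
    without excessive distinct switching); otherwise input-driven
    maintenance.
    """
    cov, sw, cyc = _window_stats(sel, schedule)
    if cov < c_low:
        label = "suppression"
    elif sw >= s_hi:
        label = "switching"
    elif cyc >= r_hi:
        label = "repetition"
    else:
        label = "maintenance"
    return RegimeLabel(label=label, coverage=cov, switch_rate=sw, cycle_rate=cyc)


def selection_change_rate(sel: SelectionTrace, schedule: StimulusSchedule) -> float:
    """Distinct-key selection changes per second within stable windows.

    Counts transitions where the engaged key changes to a different key
    (entry into the first selection of a window included), divided by
    the total stable-window time: the behavioural face of the
    switching-band oscillation.
    """
    _, sw, _ = _window_stats(sel, schedule)
    window_s = float(np.mean(schedule.offsets - schedule.onsets))
    return sw / window_s


def _derive_seed(master_seed: int, k: int) -> int:
    """Stable per-subject sub-seed below 2**31."""
    return int(np.random.SeedSequence((int(master_seed), int(k))).generate_state(1)[0]
               % (2 ** 31))


def run_virtual_experiment(config: ModelConfig, n_seeds: int = 12,
                           master_seed: int = 0, n_trials: int = 4,
                           interval_s: float = 5.0, min_rt_ms: float = 300.0,
                           out_dir=None) -> tuple:
    """The paired 2x2 virtual experiment: ``4 * n_seeds`` simulations.

    Every seed (simulated subject, low dopaminergic drive) is run under
    DBS on/off crossed with high/low input value; the four runs of a
    seed share the identical cortical-noise series (asserted via stream
    checksums).  Each run covers ``n_trials`` trials of four
    ``interval_s`` luminance intervals.

    Returns ``(index_table, stats_report)``: the long-format per-run
    index table and a dict of paired t-tests (pooled across value,
    df = 2n-1, and within value, df = n-1) plus the 2x2 RM-ANOVA per
    index.  Perseverance values of runs where no pattern change caught
    a held key (fully suppressed runs) enter the statistics as 0 ms.
    """
    if n_seeds < 2:
        raise ValueError("n_seeds must be >= 2 for inferential statistics")
    low = config.with_dopamine("low")
    n_intervals = 4 * n_trials
    duration = n_intervals * interval_s

    rows = []
    results = []
    for i in range(n_seeds):
        seed = _derive_seed(master_seed, i)
        checksums = set()
        for dbs_on in (False, True):
            cfg = low.with_dbs(dbs_on)
            for value in ("high", "low"):
                sched = make_sim_schedule(value, n_intervals, interval_s, seed=seed)
                trace = simulate(cfg, sched, duration, seed=seed)
                checksums.add(trace.meta["noise_checksum"])
                sel = read_selection(trace)
                idx = compute_indices(sel, sched, min_rt_ms=min_rt_ms)
                results.append(ConditionResult(
                    seed_id=i, dbs="on" if dbs_on else "off", value=value,
                    indices=idx.as_dict(), config_hash=cfg.config_hash,
                    noise_checksum=trace.meta["noise_checksum"]))
                rows.append({
                    "id": i, "dbs": "on" if dbs_on else "off", "value": value,
                    "maintenance_ms": idx.maintenance_ms,
                    "perseverance_ms": (0.0 if math.isnan(idx.perseverance_ms)
                                        else idx.perseverance_ms),
                    "switches": idx.switches,
                    "accuracy_pct": idx.accuracy_pct,
                })
        if len(checksums) != 1:
            raise AssertionError(
                f"seed {i}: conditions consumed different noise streams")
    table = pd.DataFrame(rows)

    report = {"n_seeds": n_seeds, "n_runs": len(rows), "master_seed": master_seed}
    for index in ("maintenance_ms", "perseverance_ms", "switches"):
        piv = table.pivot_table(index=["id", "value"], columns="dbs",
                                values=index).reset_index()
        pooled = bgstats.paired_t(piv["on"], piv["off"])
        by_value = {}
        for val in ("high", "low"):
            sub = piv[piv["value"] == val]
            by_value[val] = bgstats.paired_t(sub["on"], sub["off"])
        anova = bgstats.rm_anova_2x2(table, index, subject="id",
                                     factor_a="dbs", factor_b="value")
        report[index] = {
            "paired_t_on_vs_off_pooled": vars(pooled),
            "paired_t_on_vs_off_by_value": {k: vars(v) for k, v in by_value.items()},
            "anova": {k: vars(v) for k, v in anova.items()},
        }

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        bgstats.write_index_table(table, os.path.join(out_dir, "index_table.tsv"))
        with open(os.path.join(out_dir, "stats_report.json"), "w") as fh:
            json.dump(report, fh, indent=2)
    return table, report


def sweep_regimes(config: ModelConfig, da_levels, gpe_gpi_weights,
                  saliencies=("high", "low"), seeds=(1, 2, 3),
                  duration: float = 40.0, interval_s: float = 5.0,
                  **classify_kw) -> pd.DataFrame:
    """Regime map over dopaminergic drive x GPe->GPi (short-indirect) strength.

    Each grid cell is classified per seed and labelled by majority vote
    ("mixed" on ties).  Returns a long DataFrame with per-cell vote
    counts.
    """
    da_levels = list(da_levels)
    gpe_gpi_weights = list(gpe_gpi_weights)
    if not da_levels or not gpe_gpi_weights or not list(saliencies):
        raise ValueError("empty sweep grid")
    n_intervals = int(duration // interval_s)
    rows = []
    for da in da_levels:
        for w in gpe_gpi_weights:
            cfg = config.with_dopamine(da).with_projection_weight("GPe", "GPi", w)
            for sal in saliencies:
                votes = []
                for seed in seeds:
                    sched = make_sim_schedule(sal, n_intervals, interval_s, seed=seed)
                    trace = simulate(cfg, sched, n_intervals * interval_s, seed=seed)
                    votes.append(classify_regime(read_selection(trace), sched,
                                                 **classify_kw).label)
                counts = {r: votes.count(r) for r in REGIMES}
                top = max(counts.values())
                winners = [r for r, c in counts.items() if c == top]
                rows.append({"da_level": da, "gpe_gpi_weight": w, "saliency": sal,
                             "label": winners[0] if len(winners) == 1 else "mixed",
                             **{f"votes_{r}": c for r, c in counts.items()}})
    return pd.DataFrame(rows)


class RegimeReproductionError(RuntimeError):
    """A case-study run did not land in its expected motor regime."""


def reproduce_fig4(config: ModelConfig, seed: int = 1, duration: float = 40.0,
                   interval_s: float = 5.0, out_dir=None,
                   min_rt_ms: float = 300.0) -> dict:
    """The four canonical case studies on one shared seed.

    Runs control/high-saliency (expected: input-driven maintenance),
    low-DA/low (motor suppression), low-DA/high (dysfunctional
    switching) and low-DA/high with simulated DBS (restored maintenance
    with raised perseverance), asserts every regime label and that
    perseverance under DBS exceeds the matched DBS-off run.  Raises
    :class:`RegimeReproductionError` with a diagnostic report on any
    mismatch; returns the report on success.
    """
    cases = {
        "control_high": (config.with_dopamine("control"), "high", "maintenance"),
        "lowda_low": (config.with_dopamine("low"), "low", "suppression"),
        "lowda_high": (config.with_dopamine("low"), "high", "switching"),
        "lowda_dbs_high": (config.with_dopamine("low").with_dbs(True), "high",
                           "maintenance"),
    }
    n_intervals = int(duration // interval_s)
    report = {"seed": seed, "duration_s": duration}
    failures = []
    pers = {}
    for name, (cfg, sal, expected) in cases.items():
        sched = make_sim_schedule(sal, n_intervals, interval_s, seed=seed)
        trace = simulate(cfg, sched, n_intervals * interval_s, seed=seed)
        sel = read_selection(trace)
        label = classify_regime(sel, sched)
        idx = compute_indices(sel, sched, min_rt_ms=min_rt_ms)
        report[name] = {"expected": expected, "label": label.label,
                        "coverage": label.coverage, "switch_rate": label.switch_rate,
                        "cycle_rate": label.cycle_rate,
                        "indices": idx.as_dict()}
        pers[name] = idx.perseverance_ms
        if label.label != expected:
            failures.append(f"{name}: expected {expected}, got {label.label} "
                            f"(cov={label.coverage:.2f}, sw={label.switch_rate:.2f}, "
                            f"cyc={label.cycle_rate:.2f})")
        if out_dir is not None:
            os.makedirs(out_dir, exist_ok=True)
            from .behavior import write_log
            write_log(selection_to_log(sel),
                      os.path.join(out_dir, f"fig4_{name}_selections.log"))
    # a fully transient DBS-off disengagement (every latency under the RT
    # exclusion) is an empty perseverance; for the direction check it
    # counts as 0 ms
    if math.isnan(pers["lowda_high"]):
        pers["lowda_high"] = 0.0
    if not (pers["lowda_dbs_high"] > pers["lowda_high"]) or \
            math.isnan(pers["lowda_dbs_high"]):
        failures.append(
            f"perseverance under DBS ({pers['lowda_dbs_high']:.0f} ms) does not "
            f"exceed the matched DBS-off run ({pers['lowda_high']:.0f} ms)")
    report["perseverance_dbs_vs_off"] = {
        "dbs_on_ms": pers["lowda_dbs_high"], "dbs_off_ms": pers["lowda_high"]}
    if out_dir is not None:
        with open(os.path.join(out_dir, "fig4_report.json"), "w") as fh:
            json.dump(report, fh, indent=2)
    if failures:
        raise RegimeReproductionError("; ".join(failures))
    return report
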