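# Methods

## The model

`bgcircuit` simulates action selection in the sensorimotor
cortico-basal-ganglia-thalamo-cortical loop with population ("rate")
units.  Seven nuclei are modelled — cortex, the D1- and D2-receptor
striatal populations, external and internal globus pallidus (GPe, GPi),
subthalamic nucleus (STN) and thalamus — each split into four parallel
*channels*, one per candidate action (the four arrow keys of the
luminance-discrimination task).

Each unit j of nucleus g is a leaky integrator,

    tau_g du_j/dt = -u_j + b_j + (eps_g + lam_g d_g) * sum_i s_i w_ji y_i ,
    y_j = [tanh(u_j - theta_g)]+ ,

so every output lies in [0, 1).  `b_j` is the basal activation, `d_g`
the dopaminergic drive in [0, 1], `s_i` the sign of the afferent
projection (negative for GABAergic sources: striatum, GPe, GPi) and
`theta_g` a transfer threshold, positive only in cortex.  The dopamine
coefficients are (eps, lam) = (0.2, 1) for D1 units, (0.6, -0.5) for D2
units and (1, 0) everywhere else, so dopamine facilitates
cortico-striatal transmission through the direct pathway and suppresses
it through the indirect pathway.  The gain multiplies the *summed
synaptic input* of the nucleus, the only placement consistent with a
differential dopaminergic effect on cortico-striatal transmission.

Pathways follow the standard channelized architecture:

* direct: cortex -> striatum-D1 -> GPi (channel-wise inhibition of the
  output gate; selection and maintenance);
* short indirect: cortex -> striatum-D2 -> GPe -> GPi (triple
  channel-wise inhibition; delivers the *opposite* saliency pattern to
  GPi and acts as a pattern generator / switching circuit);
* long indirect & hyperdirect: striatum-D2 -> GPe -> STN -> GPi and
  cortex -> STN -> GPi, with diffuse STN efferents (undifferentiated
  excitation of the whole GPi: global motor suppression) and a diffuse
  GPe -> STN leg closing the pallido-subthalamic homeostatic loop;
* closure: GPi -| thalamus <-> cortex (channel-wise re-entrant loop).

Whether cortex -> STN is channel-wise or diffuse is not constrained by
the anatomy we model at this grain; we use channel-wise (the diffusion
to all channels happens in STN -> GPi anyway).  Diffuse projections
spread `weight / n_source` per connection so `weight` is the total
drive at full source activation.

### Simulated DBS

Subthalamic deep brain stimulation is modelled as a tonic increment
(default +0.3) of the basal activations of STN, GPe and GPi.  Raising
pallidal baselines pushes GPe units toward tanh saturation, compressing
the channel-specific signal they convey: the *signal-to-baseline ratio*
of the indirect pathway falls, switching is suppressed, and the
input-driven attractor (maintenance) survives.  The same mechanism
slows disengagement after a pattern change, which is measured as raised
perseverance.  Millisecond pulse trains, antidromic effects and
spiking-level phenomena are out of scope of a rate model.

### Noise and seeds

Cortical units receive "differentiated noise" as a perturbation of
their basal activation, uniform on ±0.1 (the amplitude is a config
key), redrawn every 50 ms and held in between.  Per-step white noise
would be filtered out by the leak; a held baseline perturbation is the
reading consistent with noise acting on b_j.  Each (nucleus, unit) pair
draws from its own substream keyed by `(seed, crc32(nucleus), unit)`,
so the noise series is a pure function of the master seed and never
depends on dopamine, DBS or input condition — the virtual experiment
verifies this with stream checksums, making within-seed condition
contrasts noise-identical by construction.

### Default parameters

Connection weights, time constants, thresholds and baselines are a
hand-tuned set shipped in `src/bgcircuit/data/default_model.yaml`.
They were tuned (by scored search over the qualitative constraints, not
to any numeric target) to satisfy, simultaneously:

1. under low dopamine, slightly greater transmission in the indirect
   than the direct pathway (this requires d_low < 0.267 given the
   striatal coefficients; the shipped low preset is d = 0.2, control
   d = 0.8);
2. balance among the three GPi afferents (striatum-D1, STN, GPe) such
   that all four motor regimes are reachable from one parameter set by
   varying only dopamine, input saliency and DBS;
3. a closed-loop switching period inside the slow band (0.5–2 Hz).

Time constants are 100 ms (cortex, thalamus) and 150 ms (all BG
nuclei); with a five-stage loop this bounds channel phase changes below
~2 Hz, the model's stated frequency ceiling.  Integration is explicit
Euler at dt = 1 ms (stability-guarded against dt >= min tau; the pure
leak matches the analytic exponential within 1% at this step and 0.1%
at 0.1 ms), output downsampled to 10 ms.

## Task and readout

The luminance-discrimination task presents four brightness values in a
cross layout; the simulated input vectors are [0.5 0.45 0.4 0.35]
(high saliency) and [0.4 0.35 0.3 0.25] (low), re-assigned to positions
every 5 s such that the brightest position always moves (so every
change demands exactly one switch).  Channel order is fixed as
(up, down, left, right) = (0, 1, 2, 3).  The experiment-style schedules
reproduce the human trial structure: six patterns per trial with 2–4 s
gaps (trial length constrained to 15–20 s by rejection sampling) and
3-s inter-trial blanks, or seven patterns with 1.25–2 s gaps, 6-s
blanks and balanced low/high reward tags (gap distributions are uniform
within the stated ranges; the distribution itself is a modelling choice).

A continuous trace becomes a discrete selection by threshold-plus-margin
winner-take-all on the cortical layer: the maximal channel is engaged
when it reaches `threshold` and beats the runner-up by `margin`; exact
ties retain the previous winner; an engaged channel is *held* until its
activity drops below `threshold - hysteresis` or another channel
overtakes it by `margin`.  The release hysteresis (Schmitt trigger) is
deliberate: the 50-ms noise redraws cause brief sub-threshold dips that
a memoryless rule would report as key releases, which no human
keypress record would contain.  All four readout values are config keys
tuned jointly with the network.

## Behavioural indices

* **maintenance** — mean per-trial time any key is held (union over
  keys, so simultaneous holds count once), irrespective of pattern
  changes.
* **perseverance** — mean latency from a pattern-to-pattern change to
  the release of whatever was held at the change (the end of the hold
  interval covering the change; max over simultaneously held keys).
  Latencies below the reaction-time threshold (300 ms for
  experiment-1-style records, 200 ms for experiment-2-style) are
  excluded as involuntary; a change with nothing held contributes
  nothing; a record with no contributing change yields an *empty*
  result (NaN, n=0), distinct from zero.
* **switches** — distinct-key selection changes per stable pattern;
  same-key re-presses never count; the obligatory first response after
  a change counts as the window's first switch (so an ideal agent
  scores 1 per pattern; `count_entry_switch=False` gives the other
  reading); presses within the RT threshold of a change are excluded.
* **accuracy** — percent of 17-ms bins (the task software's grain) in
  which exactly the correct key is down; multi-key bins are incorrect.

Timestamps are quantized to 1 ms and holds are half-open intervals, so
the interval arithmetic is provably identical to a millisecond-scan;
the test suite asserts this equivalence on 1000 random logs.  The scope
of the RT exclusion is read as: it removes involuntary *events* from
perseverance and switch counting, but key-hold time still counts toward
maintenance (which is defined irrespective of events).

The synthetic keypress generator (`synth_log`) realizes a requested
profile (reaction time, perseverance, switches per pattern, with
uniform jitters) on any schedule.  It emulates a subject who always
finds the correct key and whose latencies are independent across
changes; it does not emulate tremor, drift, error corrections or
fatigue, so tests passing on synthetic logs validate the *index
arithmetic*, not robustness to messy clinical records (a separate
random-log generator exercises overlapping and disordered holds).

## Statistics

Paired t-tests are standard two-sided tests on within-subject
differences (zero difference variance raises rather than returning an
infinite statistic).  The 2x2 fully-within ANOVA is computed through
per-subject contrasts, each effect's F being the squared paired-t of
its contrast with df = (1, n-1); this is algebraically identical to the
classical partitioned-SS formulation for balanced 2x2 designs and is
tested against an independent SS implementation to 1e-10 relative
error.  The Bayes factor for null evidence marginalizes a normal
likelihood over a half-normal alternative prior (mean 0, SD 0.2 by
default, one-tailed in a caller-specified direction — the Dienes
convention; `tails=2` keeps the full normal).  Integration is adaptive
quadrature over ±12 prior SDs at 1e-8 relative tolerance, tested within
1% of a 400k-point trapezoid grid.  The effect scale of the prior SD is
the caller's responsibility.  No multiple-comparison correction is
applied by default (a Bonferroni alpha of 0.016 for three indices is
the relevant conventional correction, noted here for users who want it).

## Oscillation analysis

Band powers integrate Welch periodograms (Hann windows, segment length
half the analysis window, 50% overlap) of mean-removed activity `y`
(the transmitted signal — `u` would double-count the transfer
nonlinearity).  Band presets: slow 0.5–2 Hz and ultraslow 0.017–0.5 Hz
(the presets the oscillation case studies use); a 0.3–2 Hz literature preset also ships.  The
0.017 Hz floor excludes DC and trends.  A plain-periodogram estimator is
available where exact Parseval accounting matters; short windows raise
the effective floor to their own frequency resolution.  Slow power
tracks the switching function of the short indirect pathway, ultraslow
power the maintenance function of the direct pathway; simulated DBS
shifts GPi power from the slow toward the ultraslow band.

## Experiments

`classify_regime` reduces a run to one of four labels by a decision
tree on per-window evidence: suppression if selected-time coverage
< 0.15; else switching if distinct-key switches per window >= 2; else
repetition if same-key press/release cycles per window >= 2; else
maintenance.  Thresholds are config keys; the defaults separate the
four case studies under the shipped parameter set.  A key held across
a window boundary belongs to the window where it was pressed.

The virtual experiment runs each of `n_seeds` (default 12) simulated
low-dopamine subjects four times — DBS on/off x high/low input value —
on identical noise, computes indices per run (one simulated trial =
four consecutive 5-s intervals; runs default to 4 trials = 80 s), and
emits pooled (df 2n-1) and per-value (df n-1) paired t-tests plus the
2x2 RM-ANOVA.  Pooling value conditions treats 24 correlated
observations as independent pairs; we reproduce that convention for
comparability and flag it here.  Fully suppressed runs can yield an
empty perseverance; such runs enter the group statistics as 0 ms (the
agent demonstrably never perseverated), a choice that only weakens the
DBS-raises-perseverance contrast.

`sweep_regimes` maps regimes over dopaminergic drive x GPe->GPi weight
(the short-indirect strength) with majority vote across seeds ("mixed"
on ties).  `reproduce_fig4` asserts the four case-study regimes and the
DBS-raises-perseverance direction on a shared seed and exits nonzero on
any mismatch.

## Problem sizes

Defaults were chosen so a full check runs comfortably on a laptop: the
acceptance quantities use 60-s runs (3 seeds) and one 25-s case study;
the virtual experiment uses 12 seeds x 4 conditions x 80 s.  All are
config/argument keys and scale linearly.

## Known limitations

* The published architecture's exact numeric parameters are not
  reproduced; the shipped set is constraint-tuned, so simulated F/t
  statistics match the reference pattern directionally, not numerically.
* Four channels and a single motor loop; no learning or plasticity of
  cortico-striatal weights; no spiking dynamics, conductances or
  millisecond DBS pulse structure; no beta-band (15–25 Hz) phenomena —
  unreachable by construction in a rate model whose phase changes cap
  at ~2 Hz.
* The low-saliency suppression regime depends on the input values
  staying near the cortical threshold; inputs far outside the
  calibrated [0.25, 0.5] range are not meaningful without retuning.
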