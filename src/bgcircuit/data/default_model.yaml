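# Canonical hand-tuned model of the sensorimotor basal-ganglia loop.
#
# Weights, time constants, thresholds and baselines are tuned to satisfy
# the model's qualitative constraints: (i) slightly greater indirect- than
# direct-pathway transmission under low dopamine, (ii) balanced GPi
# afferents (striatum-D1, STN, GPe) so that maintenance, suppression,
# switching and repetition are all reachable, and (iii) a closed-loop
# switching period in the 0.5-2 Hz band.  See docs/methods.md.
dopamine: 0.8
dopamine_presets:
  control: 0.8
  low: 0.2
noise:
  amplitude: 0.1
  refresh_interval: 0.05
  nuclei: [cortex]
dbs:
  enabled: false
  delta_b: {STN: 0.3, GPe: 0.3, GPi: 0.3}
readout:
  nucleus: cortex
  threshold: 0.6000
  margin: 0.0297
  hysteresis: 0.0328
nuclei:
  - {name: cortex,      n_units: 4, tau: 0.10, theta: 0.1720, baseline: 0.0}
  - {name: striatum_D1, n_units: 4, tau: 0.15, theta: 0.0, baseline: 0.0, epsilon: 0.2, lam: 1.0}
  - {name: striatum_D2, n_units: 4, tau: 0.15, theta: 0.0, baseline: 0.0, epsilon: 0.6, lam: -0.5}
  - {name: GPe,         n_units: 4, tau: 0.15, theta: 0.0, baseline: 0.6978}
  - {name: GPi,         n_units: 4, tau: 0.15, theta: 0.0, baseline: 1.0000}
  - {name: STN,         n_units: 4, tau: 0.15, theta: 0.0, baseline: 0.4562}
  - {name: thalamus,    n_units: 4, tau: 0.10, theta: 0.0, baseline: 0.0000}
projections:
  - {source: cortex,      target: striatum_D1, weight: 1.2839, topology: channel_wise}
  - {source: cortex,      target: striatum_D2, weight: 0.9723, topology: channel_wise}
  - {source: cortex,      target: STN,         weight: 0.9210, topology: channel_wise}
  - {source: striatum_D1, target: GPi,         weight: 1.5558, topology: channel_wise}
  - {source: striatum_D2, target: GPe,         weight: 2.1000, topology: channel_wise}
  - {source: GPe,         target: GPi,         weight: 2.3800, topology: channel_wise}
  - {source: GPe,         target: STN,         weight: 1.4000, topology: diffuse}
  - {source: STN,         target: GPe,         weight: 0.6000, topology: diffuse}
  - {source: STN,         target: GPi,         weight: 1.1028, topology: diffuse}
  - {source: GPi,         target: thalamus,    weight: 1.2131, topology: channel_wise}
  - {source: thalamus,    target: cortex,      weight: 1.0633, topology: channel_wise}
  - {source: cortex,      target: thalamus,    weight: 0.8132, topology: channel_wise}
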