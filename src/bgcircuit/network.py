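"""Leaky-integrator rate network of the basal ganglia motor loop.

The circuit is built from population ("rate") units grouped into nuclei.
Each unit j obeys

    tau_g * du_j/dt = -u_j + b_j + (eps_g + lam_g * d_g) * sum_i s_i w_ji y_i

where ``b_j`` is the basal activation (perturbed by noise in the cortical
layers, and raised by simulated deep brain stimulation in STN/GPe/GPi),
``d_g`` is the dopaminergic drive reaching the nucleus and ``s_i`` the sign
of the afferent projection.  The transfer function is a rectified
hyperbolic tangent,

    y_j = [tanh(u_j - theta_g)]+          (so 0 <= y_j < 1 always),

with a positive threshold ``theta_g`` only in cortical layers.

Four parallel channels thread every nucleus, one per candidate action
(up/down/left/right); channel-wise projections preserve the saliency
pattern while diffuse projections (the STN efferents and the GPe->STN
leg of the homeostatic loop) spread it uniformly.
"""

from __future__ import annotations

import hashlib
import zlib
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "NUCLEI",
    "CORTICAL_NUCLEI",
    "INHIBITORY_NUCLEI",
    "NucleusGroup",
    "Projection",
    "NoiseSpec",
    "DBSSpec",
    "NetworkState",
    "Network",
    "SimulationTrace",
    "transfer",
    "dopamine_gain",
    "euler_step",
]

#: canonical nucleus names of the modelled sensorimotor loop
NUCLEI = ("cortex", "striatum_D1", "striatum_D2", "GPe", "GPi", "STN", "thalamus")

#: nuclei treated as cortical layers (positive transfer threshold, noisy baseline)
CORTICAL_NUCLEI = frozenset({"cortex"})

#: GABAergic nuclei -- every projection they originate is inhibitory
INHIBITORY_NUCLEI = frozenset({"striatum_D1", "striatum_D2", "GPe", "GPi"})

# dopamine-gain coefficients pinned by the model definition:
# (epsilon, lambda); all non-striatal nuclei use (1, 0)
_STRIATAL_COEFFS = {"striatum_D1": (0.2, 1.0), "striatum_D2": (0.6, -0.5)}


def transfer(u, theta):
    """Rectified-tanh transfer function ``[tanh(u - theta)]+``.

    Zero for ``u <= theta``, strictly increasing above threshold and
    asymptotically approaching (never reaching) 1.

    Parameters
    ----------
    u : float or ndarray
        Activation potential(s).
    theta : float or ndarray
        Transfer threshold (broadcast against ``u``).

    Returns
    -------
    float or ndarray in [0, 1)
    """
    u = np.asarray(u, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(theta))):
        raise ValueError("transfer() requires finite u and theta")
    out = np.maximum(np.tanh(u - theta), 0.0)
    return float(out) if out.ndim == 0 else out


def dopamine_gain(epsilon, lam, d):
    """Multiplicative input gain ``epsilon + lam * d`` of a nucleus.

    ``d`` is the dopaminergic drive in [0, 1].  With the model's striatal
    coefficients the gain rises with dopamine in D1 units
    (epsilon=0.2, lam=1) and falls in D2 units (epsilon=0.6, lam=-0.5);
    everywhere else (epsilon=1, lam=0) it is identically 1.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0) or np.any(d > 1) or not np.all(np.isfinite(d)):
        raise ValueError(f"dopamine level must lie in [0, 1], got {d}")
    out = epsilon + lam * d
    return float(out) if np.ndim(out) == 0 else out


@dataclass(frozen=True)
class NucleusGroup:
    """One modelled nucleus: a group of identical leaky-integrator units.

    Attributes
    ----------
    name:
        One of :data:`NUCLEI`.
    n_units:
        Number of action channels (default 4).
    tau:
        Time constant of the leak, seconds.
    theta:
        Transfer threshold; positive only for cortical layers.
    baseline:
        Basal activation b_j, scalar (shared) or per-unit vector.
    epsilon, lam:
        Dopamine-gain coefficients (pinned per nucleus, see module docs).
    da_level:
        Dopaminergic drive d_g in [0, 1] reaching this nucleus.
    """

    name: str
    tau: float
    theta: float = 0.0
    baseline: float | tuple = 0.0
    n_units: int = 4
    epsilon: float = 1.0
    lam: float = 0.0
    da_level: float = 0.0

    def __post_init__(self):
        if self.name not in NUCLEI:
            raise ValueError(f"unknown nucleus {self.name!r}; expected one of {NUCLEI}")
        if not (self.tau > 0 and np.isfinite(self.tau)):
            raise ValueError(f"{self.name}: tau must be > 0")
        if self.n_units < 1:
            raise ValueError(f"{self.name}: n_units must be >= 1")
        if not np.all(np.isfinite(self.baseline_vector)):
            raise ValueError(f"{self.name}: baseline must be finite")
        if self.name not in CORTICAL_NUCLEI and self.theta != 0.0:
            raise ValueError(f"{self.name}: theta > 0 is reserved for cortical layers")
        expect = _STRIATAL_COEFFS.get(self.name, (1.0, 0.0))
        if (self.epsilon, self.lam) != expect:
            raise ValueError(
                f"{self.name}: dopamine coefficients must be eps={expect[0]}, lam={expect[1]}"
            )
        if not 0.0 <= self.da_level <= 1.0:
            raise ValueError(f"{self.name}: da_level must lie in [0, 1]")

    @property
    def baseline_vector(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.baseline, dtype=float), (self.n_units,))

    @property
    def gain(self) -> float:
        """Dopamine-modulated input gain of this nucleus."""
        return dopamine_gain(self.epsilon, self.lam, self.da_level)

    def with_da(self, d: float) -> "NucleusGroup":
        return replace(self, da_level=float(d))


@dataclass(frozen=True)
class Projection:
    """A signed, weighted connection between two nuclei.

    ``channel_wise`` topology connects unit i to unit i (requires equal
    channel counts); ``diffuse`` connects all to all with uniform weight
    ``weight / n_source`` so that ``weight`` is the total drive delivered
    when every source unit is fully active.
    """

    source: str
    target: str
    weight: float
    topology: str = "channel_wise"

    def __post_init__(self):
        for nm in (self.source, self.target):
            if nm not in NUCLEI:
                raise ValueError(f"unknown nucleus {nm!r} in projection")
        if self.weight < 0:
            raise ValueError(f"{self.source}->{self.target}: weight must be >= 0")
        if self.topology not in ("channel_wise", "diffuse"):
            raise ValueError(f"unknown topology {self.topology!r}")

    @property
    def sign(self) -> int:
        """-1 for GABAergic sources, +1 for glutamatergic ones."""
        return -1 if self.source in INHIBITORY_NUCLEI else +1


@dataclass(frozen=True)
class NoiseSpec:
    """Uniform baseline perturbation of the cortical layers.

    Noise is drawn uniformly in ``[-amplitude, +amplitude]`` independently
    per cortical unit, redrawn every ``refresh_interval`` seconds and held
    in between (a perturbation of b_j, not an injected white current).
    The series for a given master seed is bit-reproducible and independent
    of every other model parameter, so runs differing only in dopamine or
    DBS consume identical noise.
    """

    amplitude: float = 0.1
    refresh_interval: float = 0.05
    nuclei: tuple = ("cortex",)

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("noise amplitude must be >= 0")
        if not self.refresh_interval > 0:
            raise ValueError("noise refresh_interval must be > 0")

    def series(self, seed: int, nucleus: str, n_units: int, n_steps: int, dt: float) -> np.ndarray:
        """Precompute the (n_steps, n_units) noise series for one nucleus.

        Each (nucleus, unit) pair owns an independent substream keyed by
        ``(seed, crc32(nucleus), unit)``, so adding or removing a nucleus
        never perturbs the noise of the others.
        """
        if nucleus not in self.nuclei or self.amplitude == 0:
            return np.zeros((n_steps, n_units))
        hold = max(1, int(round(self.refresh_interval / dt)))
        n_blocks = -(-n_steps // hold)
        out = np.empty((n_steps, n_units))
        tag = zlib.crc32(nucleus.encode())
        for j in range(n_units):
            rng = np.random.default_rng(np.random.SeedSequence((int(seed), tag, j)))
            draws = rng.uniform(-self.amplitude, self.amplitude, n_blocks)
            out[:, j] = np.repeat(draws, hold)[:n_steps]
        return out


@dataclass(frozen=True)
class DBSSpec:
    """Simulated subthalamic deep brain stimulation.

    Modelled as a tonic increment of the basal activations of the STN and
    both pallidal segments, raising baseline activity and thereby lowering
    the signal-to-baseline ratio of pallidal transmission.
    """

    enabled: bool = False
    delta_b: dict = field(default_factory=lambda: {"STN": 0.3, "GPe": 0.3, "GPi": 0.3})

    def __post_init__(self):
        allowed = {"STN", "GPe", "GPi"}
        bad = set(self.delta_b) - allowed
        if bad:
            raise ValueError(f"DBS increments only apply to {sorted(allowed)}, got {sorted(bad)}")
        if any(v < 0 for v in self.delta_b.values()):
            raise ValueError("DBS increments must be >= 0")

    def increment(self, nucleus: str) -> float:
        return float(self.delta_b.get(nucleus, 0.0)) if self.enabled else 0.0


@dataclass
class NetworkState:
    """Instantaneous state of the network: potentials, outputs, time."""

    u: np.ndarray  # stacked activation potentials, shape (n_total,)
    y: np.ndarray  # stacked transfer outputs in [0, 1)
    t: float = 0.0


class Network:
    """Compiled rate network: stacked state vectors and one weight matrix.

    Units of all nuclei are concatenated (in the order the nuclei were
    given) into single ``u``/``y`` vectors; projections become blocks of
    a dense signed weight matrix so an integration step is a single
    matrix-vector product.
    """

    def __init__(self, nuclei, projections, noise: NoiseSpec | None = None,
                 dbs: DBSSpec | None = None):
        names = [n.name for n in nuclei]
        if len(set(names)) != len(names):
            raise ValueError("duplicate nucleus names")
        self.nuclei = {n.name: n for n in nuclei}
        self.projections = list(projections)
        self.noise = noise if noise is not None else NoiseSpec()
        self.dbs = dbs if dbs is not None else DBSSpec()

        referenced = {p.source for p in self.projections} | {p.target for p in self.projections}
        missing = sorted(referenced - set(names))
        if missing:
            raise ValueError(f"projections reference undefined nuclei: {missing}")

        self.slices: dict[str, slice] = {}
        off = 0
        for n in nuclei:
            self.slices[n.name] = slice(off, off + n.n_units)
            off += n.n_units
        self.n_total = off

        self.tau = np.concatenate([np.full(n.n_units, n.tau) for n in nuclei])
        self.theta = np.concatenate([np.full(n.n_units, n.theta) for n in nuclei])
        self.b = np.concatenate([n.baseline_vector for n in nuclei])
        self.gain = np.concatenate([np.full(n.n_units, n.gain) for n in nuclei])

        self.W = np.zeros((self.n_total, self.n_total))
        for p in self.projections:
            src, tgt = self.slices[p.source], self.slices[p.target]
            ns = src.stop - src.start
            nt = tgt.stop - tgt.start
            if p.topology == "channel_wise":
                if ns != nt:
                    raise ValueError(
                        f"channel_wise projection {p.source}->{p.target} "
                        f"requires equal n_units ({ns} != {nt})")
                self.W[tgt, src] += p.sign * p.weight * np.eye(ns)
            else:
                self.W[tgt, src] += p.sign * (p.weight / ns) * np.ones((nt, ns))

    @property
    def b_effective(self) -> np.ndarray:
        """Basal activations including any DBS increment."""
        b = self.b.copy()
        for name in self.nuclei:
            inc = self.dbs.increment(name)
            if inc:
                b[self.slices[name]] += inc
        return b

    def initial_state(self) -> NetworkState:
        u = np.zeros(self.n_total)
        return NetworkState(u=u, y=transfer(u, self.theta), t=0.0)

    def noise_series(self, seed: int, n_steps: int, dt: float) -> np.ndarray:
        """Stacked (n_steps, n_total) baseline-noise series (cortex only)."""
        out = np.zeros((n_steps, self.n_total))
        for name, nuc in self.nuclei.items():
            out[:, self.slices[name]] = self.noise.series(seed, name, nuc.n_units, n_steps, dt)
        return out

    def noise_checksum(self, seed: int, n_steps: int, dt: float) -> str:
        """SHA1 of the noise series; used to assert seed-pairing across conditions."""
        return hashlib.sha1(
            np.ascontiguousarray(self.noise_series(seed, n_steps, dt)).tobytes()
        ).hexdigest()

    # -- integration ----------------------------------------------------

    def _check_dt(self, dt: float):
        if not dt > 0:
            raise ValueError("dt must be > 0")
        if dt >= self.tau.min():
            raise ValueError(
                f"dt={dt} >= min tau={self.tau.min()}: explicit Euler would be unstable")

    def step(self, state: NetworkState, external: np.ndarray, noise: np.ndarray,
             dt: float, b_eff: np.ndarray | None = None) -> NetworkState:
        """Advance one explicit-Euler step (functional; returns a new state)."""
        self._check_dt(dt)
        if b_eff is None:
            b_eff = self.b_effective
        cx = self.slices.get("cortex")
        syn = self.W @ state.y
        if cx is not None and external is not None:
            syn[cx] = syn[cx] + np.asarray(external, dtype=float)
        drive = b_eff + noise - state.u + self.gain * syn
        u = state.u + (dt / self.tau) * drive
        if not np.all(np.isfinite(u)):
            raise FloatingPointError("non-finite activation potential")
        return NetworkState(u=u, y=transfer(u, self.theta), t=state.t + dt)

    def run(self, external: np.ndarray, duration: float, seed: int,
            dt: float = 1e-3, output_dt: float = 1e-2) -> "SimulationTrace":
        """Integrate for ``duration`` seconds under a per-step cortical input.

        Parameters
        ----------
        external : ndarray, shape (n_steps, n_cortex_units)
            Cortical input at every integration step (use
            :func:`bgcircuit.task.schedule_to_input` to rasterize a
            stimulus schedule).
        duration : float
            Simulated time, seconds.
        seed : int
            Master seed for the cortical baseline noise.
        dt, output_dt : float
            Integration step and output sampling period, seconds.

        Returns
        -------
        SimulationTrace
            Transfer outputs ``y`` of every unit sampled at ``output_dt``.
        """
        self._check_dt(dt)
        n_steps = int(round(duration / dt))
        if external.shape[0] < n_steps:
            raise ValueError("external input shorter than the simulation")
        every = max(1, int(round(output_dt / dt)))
        n_out = n_steps // every

        noise = self.noise_series(seed, n_steps, dt)
        b_eff = self.b_effective
        cx = self.slices["cortex"]
        inv_tau_dt = dt / self.tau
        W, gain, theta = self.W, self.gain, self.theta

        u = np.zeros(self.n_total)
        y = np.maximum(np.tanh(u - theta), 0.0)
        out = np.empty((n_out, self.n_total))
        t_out = (np.arange(n_out) + 1.0) * every * dt
        k_out = 0
        for k in range(n_steps):
            syn = W @ y
            syn[cx] += external[k]
            u += inv_tau_dt * (b_eff + noise[k] - u + gain * syn)
            y = np.maximum(np.tanh(u - theta), 0.0)
            if (k + 1) % every == 0:
                out[k_out] = y
                k_out += 1
        if not np.all(np.isfinite(u)):
            raise FloatingPointError("non-finite activation potential")
        return SimulationTrace(t=t_out, y=out, slices=dict(self.slices),
                               meta={"seed": int(seed), "dt": dt, "output_dt": output_dt,
                                     "duration": duration})


def euler_step(state: NetworkState, network: Network, external_input,
               dt: float, noise=None) -> NetworkState:
    """One explicit-Euler step of the network ODE (see module docstring).

    ``external_input`` is added to the summed synaptic input of the
    cortical units; ``noise`` (stacked, optional) perturbs the basal
    activations.  Raises if ``dt`` is not well below the smallest time
    constant.
    """
    if noise is None:
        noise = np.zeros(network.n_total)
    return network.step(state, np.asarray(external_input, dtype=float), noise, dt)


@dataclass
class SimulationTrace:
    """Sampled transfer outputs of a simulation run.

    ``y`` is (n_samples, n_total) with nuclei located by ``slices``;
    ``meta`` records seed, step sizes and (when produced through
    :func:`bgcircuit.config.simulate`) the config hash, noise checksum
    and the stimulus-schedule change times.
    """

    t: np.ndarray
    y: np.ndarray
    slices: dict
    meta: dict = field(default_factory=dict)

    @property
    def fs(self) -> float:
        """Output sampling rate, Hz."""
        return 1.0 / float(self.t[1] - self.t[0])

    def nucleus(self, name: str) -> np.ndarray:
        """(n_samples, n_units) activity of one nucleus."""
        if name not in self.slices:
            raise KeyError(f"nucleus {name!r} not in trace (have {sorted(self.slices)})")
        return self.y[:, self.slices[name]]

    def window(self, t0: float, t1: float) -> "SimulationTrace":
        """Restrict the trace to ``t0 <= t < t1``."""
        if not (t0 < t1):
            raise ValueError("empty window")
        m = (self.t >= t0) & (self.t < t1)
        if not m.any():
            raise ValueError(f"window [{t0}, {t1}) outside trace")
        return SimulationTrace(t=self.t[m], y=self.y[m], slices=self.slices, meta=self.meta)

    def to_frame(self):
        """Long-format DataFrame with columns time_s, nucleus, channel, y."""
        import pandas as pd

        frames = []
        for name, sl in self.slices.items():
            block = self.y[:, sl]
            for ch in range(block.shape[1]):
                frames.append(pd.DataFrame({
                    "time_s": self.t, "nucleus": name, "channel": ch, "y": block[:, ch]}))
        return pd.concat(frames, ignore_index=True)
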