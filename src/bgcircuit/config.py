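"""Model configuration: YAML round-trip and the canonical default model.

A configuration file fully determines a simulation condition: nuclei
(time constants, thresholds, baselines), projections, the global
dopaminergic drive, the DBS spec, the cortical-noise spec and the
selection-readout parameters.  The shipped ``default_model.yaml`` is the
hand-tuned parameter set used by every high-level experiment; named
dopamine presets (``control`` / ``low``) and the DBS toggle derive the
four study conditions from it.
"""

from __future__ import annotations

import hashlib
import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .network import DBSSpec, Network, NoiseSpec, NucleusGroup, Projection

__all__ = ["ReadoutSpec", "ModelConfig", "load_config", "load_default_model", "simulate"]


@dataclass(frozen=True)
class ReadoutSpec:
    """How a continuous trace becomes a discrete selection (see task module)."""

    nucleus: str = "cortex"
    threshold: float = 0.3
    margin: float = 0.02
    hysteresis: float = 0.1


@dataclass(frozen=True)
class ModelConfig:
    """A complete, condition-resolved model description."""

    nuclei: tuple
    projections: tuple
    dopamine: float
    noise: NoiseSpec = NoiseSpec()
    dbs: DBSSpec = DBSSpec()
    readout: ReadoutSpec = ReadoutSpec()
    dopamine_presets: dict = field(default_factory=lambda: {"control": 0.8, "low": 0.2})

    def build(self) -> Network:
        """Compile to a :class:`~bgcircuit.network.Network` with the global
        dopamine level applied to every nucleus."""
        nuclei = tuple(n.with_da(self.dopamine) for n in self.nuclei)
        return Network(nuclei, self.projections, noise=self.noise, dbs=self.dbs)

    # -- condition variants --------------------------------------------

    def with_dopamine(self, level) -> "ModelConfig":
        """Return a copy at a numeric dopamine level or a named preset."""
        if isinstance(level, str):
            if level not in self.dopamine_presets:
                raise KeyError(f"unknown dopamine preset {level!r}")
            level = self.dopamine_presets[level]
        return replace(self, dopamine=float(level))

    def with_dbs(self, enabled: bool) -> "ModelConfig":
        return replace(self, dbs=replace(self.dbs, enabled=bool(enabled)))

    def with_projection_weight(self, source: str, target: str, weight: float) -> "ModelConfig":
        """Copy with one projection's weight replaced (used by regime sweeps)."""
        hit = False
        projs = []
        for p in self.projections:
            if p.source == source and p.target == target:
                p = replace(p, weight=float(weight))
                hit = True
            projs.append(p)
        if not hit:
            raise KeyError(f"no projection {source}->{target} in config")
        return replace(self, projections=tuple(projs))

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "dopamine": self.dopamine,
            "dopamine_presets": dict(self.dopamine_presets),
            "noise": {"amplitude": self.noise.amplitude,
                      "refresh_interval": self.noise.refresh_interval,
                      "nuclei": list(self.noise.nuclei)},
            "dbs": {"enabled": self.dbs.enabled, "delta_b": dict(self.dbs.delta_b)},
            "readout": {"nucleus": self.readout.nucleus,
                        "threshold": self.readout.threshold,
                        "margin": self.readout.margin,
                        "hysteresis": self.readout.hysteresis},
            "nuclei": [
                {"name": n.name, "n_units": n.n_units, "tau": n.tau, "theta": n.theta,
                 "baseline": (list(np.atleast_1d(n.baseline))
                              if np.ndim(n.baseline) else float(n.baseline)),
                 "epsilon": n.epsilon, "lam": n.lam}
                for n in self.nuclei],
            "projections": [
                {"source": p.source, "target": p.target, "weight": p.weight,
                 "topology": p.topology}
                for p in self.projections],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        try:
            nuclei = tuple(
                NucleusGroup(name=n["name"], tau=n["tau"], theta=n.get("theta", 0.0),
                             baseline=(tuple(n["baseline"])
                                       if isinstance(n["baseline"], (list, tuple))
                                       else n["baseline"]),
                             n_units=n.get("n_units", 4),
                             epsilon=n.get("epsilon", 1.0), lam=n.get("lam", 0.0))
                for n in d["nuclei"])
            projections = tuple(
                Projection(source=p["source"], target=p["target"], weight=p["weight"],
                           topology=p.get("topology", "channel_wise"))
                for p in d["projections"])
        except KeyError as e:
            raise ValueError(f"config missing required key: {e}") from e
        noise = d.get("noise", {})
        dbs = d.get("dbs", {})
        ro = d.get("readout", {})
        return cls(
            nuclei=nuclei, projections=projections, dopamine=float(d["dopamine"]),
            noise=NoiseSpec(amplitude=noise.get("amplitude", 0.1),
                            refresh_interval=noise.get("refresh_interval", 0.05),
                            nuclei=tuple(noise.get("nuclei", ("cortex",)))),
            dbs=DBSSpec(enabled=dbs.get("enabled", False),
                        delta_b=dict(dbs.get("delta_b", {"STN": 0.3, "GPe": 0.3, "GPi": 0.3}))),
            readout=ReadoutSpec(nucleus=ro.get("nucleus", "cortex"),
                                threshold=ro.get("threshold", 0.3),
                                margin=ro.get("margin", 0.02),
                                hysteresis=ro.get("hysteresis", 0.1)),
            dopamine_presets=dict(d.get("dopamine_presets", {"control": 0.8, "low": 0.2})),
        )

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @property
    def config_hash(self) -> str:
        """SHA1 of the canonical YAML form; identifies the condition."""
        return hashlib.sha1(self.to_yaml().encode()).hexdigest()


def load_config(path) -> ModelConfig:
    """Load a model configuration from a YAML file."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ValueError(f"{path}: not a mapping")
    return ModelConfig.from_dict(d)


def load_default_model() -> ModelConfig:
    """The canonical hand-tuned model shipped with the package."""
    ref = importlib.resources.files("bgcircuit").joinpath("data/default_model.yaml")
    return ModelConfig.from_dict(yaml.safe_load(ref.read_text()))


def simulate(config: ModelConfig, schedule, duration: float, seed: int,
             dt: float = 1e-3, output_dt: float = 1e-2):
    """Run one simulation under a config and stimulus schedule.

    Thin orchestration over :meth:`Network.run`: rasterizes the schedule
    into the per-step cortical input, integrates, and attaches schedule
    change times, config hash and noise checksum to the trace metadata.
    """
    from .task import schedule_to_input

    net = config.build()
    n_steps = int(round(duration / dt))
    ext = schedule_to_input(schedule, n_steps, dt)
    trace = net.run(ext, duration, seed=seed, dt=dt, output_dt=output_dt)
    trace.meta.update({
        "config_hash": config.config_hash,
        "noise_checksum": net.noise_checksum(seed, n_steps, dt),
        "change_times": [float(t) for t in schedule.onsets],
        "readout": {"nucleus": config.readout.nucleus,
                    "threshold": config.readout.threshold,
                    "margin": config.readout.margin,
                    "hysteresis": config.readout.hysteresis},
    })
    return trace
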