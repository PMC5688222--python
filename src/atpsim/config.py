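"""Configuration: model parameters, protocol specs, YAML loading, manifests.

Every numeric constant of the critic and actor equations, every trial
timing, and every protocol quantity is reachable from here; the engine reads
them from these dataclasses only.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .encoding import TrialClock

__all__ = [
    "CriticConfig",
    "ActorConfig",
    "MetaConfig",
    "LesionConfig",
    "ModelConfig",
    "ProtocolSpec",
    "ConfigError",
    "load_config",
    "dump_config",
    "write_manifest",
]


class ConfigError(ValueError):
    """Invalid or incomplete configuration."""


@dataclass
class CriticConfig:
    """Critic parameters.

    ``kappa``/``tau`` set the eligibility-trace and discount time constants
    (steps); ``beta_m``/``beta_o`` the magnitude and omission learning rates
    (the omission rate defaults faster than magnitude, the regime in which
    omission probability is tracked flexibly on top of a stable magnitude
    estimate). ``td_gain`` scales the temporal-difference term of both
    prediction errors; 1.0 is plain discrete TD(0) so that value converges
    to reinforcer magnitude / omission probability. ``reward_lag`` is the
    one-step delay with which the reward signal enters the magnitude error.
    """

    kappa: float = 9.6
    tau: float = 10.0
    beta_m: float = 0.06
    beta_o: float = 0.10
    td_gain: float = 1.0
    reward_lag: int = 1
    trace_mode: str = "kappa"
    literal_reward_onset_traces: bool = False

    def validate(self) -> None:
        if self.trace_mode not in ("kappa", "lambda_gamma"):
            raise ConfigError(
                "critic.trace_mode must be 'kappa' or 'lambda_gamma'"
            )
        for name in ("beta_m", "beta_o"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ConfigError(f"critic.{name} must be in [0, 1), got {v}")
        if self.tau <= 1.0:
            raise ConfigError("critic.tau must exceed the timestep")
        if self.kappa <= 1.0:
            raise ConfigError("critic.kappa must exceed the timestep")


@dataclass
class ActorConfig:
    """Actor node dynamics, response selection and Hebbian learning rates."""

    tau_r: float = 5.0
    h_r: float = -1.0
    C_r: float = 1.2
    beta_r: float = 4.0
    beta_sr: float = 0.105
    beta_er: float = 0.06
    gate_mode: str = "omission"
    learn_step: str = "eval"
    er_unlearn_factor: float = 0.2
    weight_floor: float = 0.0
    beta_om: float = 10.0
    th_om: float = 0.29
    decision_threshold: float = 0.525
    exec_input: float = 2.2
    stimulus_input: float = 1.0
    rew_outer_sigmoid: bool = False
    target_input_both: bool = False

    def validate(self) -> None:
        for name in ("beta_sr", "beta_er"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ConfigError(f"actor.{name} must be in [0, 1), got {v}")
        if self.tau_r <= 0:
            raise ConfigError("actor.tau_r must be positive")
        if self.gate_mode not in ("omission", "magnitude"):
            raise ConfigError("actor.gate_mode must be 'omission' or 'magnitude'")
        if self.learn_step not in ("eval", "all"):
            raise ConfigError("actor.learn_step must be 'eval' or 'all'")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ConfigError("actor.decision_threshold must be in (0, 1)")


@dataclass
class MetaConfig:
    """Bounds, initial values and rate of the expectancy meta-parameters."""

    n_slope: float = 0.5
    a_slope: float = 20.0
    n_th: float = 0.0
    a_th: float = 1.0
    C_j: float = 3.0
    update_mode: str = "congruent"
    init_slope: float = 4.2
    init_th: float = 0.5

    def validate(self) -> None:
        if self.update_mode not in ("congruent", "signed"):
            raise ConfigError("meta.update_mode must be 'congruent' or 'signed'")
        if not self.n_slope <= self.init_slope <= self.a_slope:
            raise ConfigError("meta.init_slope outside [n_slope, a_slope]")
        if not self.n_th <= self.init_th <= self.a_th:
            raise ConfigError("meta.init_th outside [n_th, a_th]")
        if self.C_j <= 0:
            raise ConfigError("meta.C_j must be positive")


@dataclass
class LesionConfig:
    """Route lesions and ablations.

    ``s_r`` zeroes and freezes the stimulus-response route (the
    prospective-only, mediational-theory model); ``e_r`` zeroes and freezes
    the expectancy-response route (a plain actor-critic);
    ``mutual_inhibition=False`` removes the Rew/Om competition.
    """

    s_r: bool = False
    e_r: bool = False
    mutual_inhibition: bool = True

    def validate(self) -> None:
        pass


@dataclass
class ModelConfig:
    trial: TrialClock = field(default_factory=TrialClock)
    critic: CriticConfig = field(default_factory=CriticConfig)
    actor: ActorConfig = field(default_factory=ActorConfig)
    meta: MetaConfig = field(default_factory=MetaConfig)
    lesion: LesionConfig = field(default_factory=LesionConfig)

    def validate(self) -> "ModelConfig":
        self.critic.validate()
        self.actor.validate()
        self.meta.validate()
        self.lesion.validate()
        return self

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ProtocolSpec:
    """Declarative description of a two-phase discrimination experiment.

    ``schedules`` maps 1-based stimulus id to ``(correct_response,
    reward_probability)`` with responses 1-based as well. ``kind`` selects
    the undriven-guess baseline: ``two_lever`` guesses uniformly,
    ``single_rule`` hits the rewarded rule with probability 0.25.
    """

    name: str
    kind: str
    schedules: dict[int, tuple[int, float]]
    acquisition_trials: int
    extinction_trials: int
    acquisition_block: int
    extinction_block: int
    n_runs: int = 50
    seed_base: int = 1
    max_same_type_run: int = 3

    def validate(self) -> "ProtocolSpec":
        if self.kind not in ("two_lever", "single_rule"):
            raise ConfigError(f"protocol.kind invalid: {self.kind!r}")
        if not self.schedules:
            raise ConfigError("protocol.schedules must not be empty")
        for stim, (resp, p) in self.schedules.items():
            if stim not in (1, 2) or resp not in (1, 2):
                raise ConfigError("stimulus/response ids must be 1 or 2")
            if not 0.0 <= p <= 1.0:
                raise ConfigError(
                    f"reward probability for stimulus {stim} must be in [0, 1]"
                )
        for name in (
            "acquisition_trials",
            "extinction_trials",
            "acquisition_block",
            "extinction_block",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"protocol.{name} must be positive")
        if self.n_runs <= 0:
            raise ConfigError("protocol.n_runs must be positive")
        n_stim = len(self.schedules)
        for name in ("acquisition_block", "extinction_block"):
            if getattr(self, name) % n_stim:
                raise ConfigError(f"protocol.{name} must be divisible by the stimulus count")
        if n_stim > 1 and self.max_same_type_run < 1:
            raise ConfigError("max_same_type_run must be >= 1")
        return self


_SECTIONS = {
    "trial": TrialClock,
    "critic": CriticConfig,
    "actor": ActorConfig,
    "meta": MetaConfig,
    "lesion": LesionConfig,
}

_REQUIRED_PROTOCOL_KEYS = (
    "name",
    "kind",
    "schedules",
    "acquisition_trials",
    "extinction_trials",
    "acquisition_block",
    "extinction_block",
)


def _build_section(cls, data: dict, section: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        warnings.warn(
            f"unknown keys in [{section}] ignored: {sorted(unknown)}", stacklevel=3
        )
    return cls(**{k: v for k, v in data.items() if k in known})


def load_config(path: str | Path) -> tuple[ProtocolSpec, ModelConfig]:
    """Load and validate a protocol + model configuration from YAML.

    The file must contain a ``protocol`` section naming the experiment;
    model sections (``trial``, ``critic``, ``actor``, ``meta``, ``lesion``)
    are optional and default-filled. Unknown keys warn; out-of-range values
    raise :class:`ConfigError` naming the offending key.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    proto_raw = raw.get("protocol")
    if not isinstance(proto_raw, dict):
        missing = ", ".join(f"protocol.{k}" for k in _REQUIRED_PROTOCOL_KEYS)
        raise ConfigError(f"missing required keys: {missing}")
    missing = [k for k in _REQUIRED_PROTOCOL_KEYS if k not in proto_raw]
    if missing:
        raise ConfigError(
            "missing required keys: " + ", ".join(f"protocol.{k}" for k in missing)
        )
    schedules = {
        int(k): (int(v[0]), float(v[1])) for k, v in proto_raw["schedules"].items()
    }
    known = {f.name for f in fields(ProtocolSpec)}
    extra = {
        k: v for k, v in proto_raw.items() if k in known and k != "schedules"
    }
    unknown = set(proto_raw) - known
    if unknown:
        warnings.warn(f"unknown keys in [protocol] ignored: {sorted(unknown)}")
    spec = ProtocolSpec(schedules=schedules, **extra).validate()

    sections = {}
    for name, cls in _SECTIONS.items():
        sections[name] = _build_section(cls, raw.get(name, {}) or {}, name)
    model = ModelConfig(**sections).validate()
    return spec, model


def dump_config(spec: ProtocolSpec, model: ModelConfig, path: str | Path) -> None:
    """Write a protocol + model configuration back to YAML."""
    doc = {"protocol": asdict(spec), **model.to_dict()}
    doc["protocol"]["schedules"] = {
        int(k): [int(v[0]), float(v[1])] for k, v in spec.schedules.items()
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def write_manifest(
    out_dir: str | Path,
    spec: ProtocolSpec,
    model: ModelConfig,
    seeds: list[int],
    outputs: list[str | Path],
) -> Path:
    """Write a reproducibility manifest (config snapshot, seeds, checksums)."""
    from . import __version__

    out_dir = Path(out_dir)
    checksums = {}
    for f in outputs:
        f = Path(f)
        checksums[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    manifest = {
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "protocol": asdict(spec),
        "model": model.to_dict(),
        "seeds": seeds,
        "checksums": checksums,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
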