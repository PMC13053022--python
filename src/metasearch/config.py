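"""Run configuration: validated parameter bundles and deterministic seeding.

Every stochastic stage of a pipeline receives a child seed derived from the
global seed and the stage name, so a whole run is reproducible from one
integer while stages stay statistically independent.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .metamdp import MetaMDPParams

#: Threshold used when simulating the reference experiment configuration.
THETA_EXPERIMENT_PRESET = 0.998


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic child seed for a named stage (stable across runs)."""
    return int(np.random.SeedSequence([global_seed, zlib.crc32(stage.encode())]).generate_state(1)[0] % (2**31))


@dataclass
class GeneratorSettings:
    n_scenes: int = 50
    n_objects_min: int = 56
    n_objects_max: int = 113
    n_features: int = 6
    distractor_similarity: float = 0.0
    cap_half_angle_deg: float = 60.0
    deadline_s: float = 8.0


@dataclass
class AblationSettings:
    spaces: list[str] = field(default_factory=lambda: ["embedding"])
    pcs: list[int] = field(default_factory=lambda: [1, 2, 3, 4, 5, 6, 7])
    n_agents: int = 20
    n_sims_opt: int = 500


@dataclass
class EvaluationSettings:
    n_perm: int = 999
    simulations_per_scene: int = 20


@dataclass
class RunConfig:
    """Top-level configuration for the end-to-end pipeline."""

    seed: int = 0
    out_dir: str = "runs"
    log_level: str = "INFO"
    theta: float | None = None  # no silent default; set or request the optimizer
    optimize_theta: bool = False
    mdp: MetaMDPParams = field(default_factory=MetaMDPParams)
    generator: GeneratorSettings = field(default_factory=GeneratorSettings)
    ablation: AblationSettings = field(default_factory=AblationSettings)
    evaluation: EvaluationSettings = field(default_factory=EvaluationSettings)

    def require_theta(self) -> float:
        if self.theta is None and not self.optimize_theta:
            raise ValueError(
                "theta has no default: set 'theta' explicitly (preset "
                f"{THETA_EXPERIMENT_PRESET} matches the experiment simulation) "
                "or set optimize_theta: true"
            )
        return self.theta


def _build(cls, payload: dict, path: str):
    known = {f.name: f for f in fields(cls)}
    unknown = set(payload) - set(known)
    if unknown:
        raise ValueError(f"unknown config key(s) at {path}: {sorted(unknown)}")
    kwargs = {}
    for key, value in payload.items():
        f = known[key]
        if f.name == "mdp":
            kwargs[key] = MetaMDPParams(**value)
        elif f.name == "generator":
            kwargs[key] = _build(GeneratorSettings, value, f"{path}.generator")
        elif f.name == "ablation":
            kwargs[key] = _build(AblationSettings, value, f"{path}.ablation")
        elif f.name == "evaluation":
            kwargs[key] = _build(EvaluationSettings, value, f"{path}.evaluation")
        else:
            kwargs[key] = value
    return cls(**kwargs)


def validate_config(path) -> RunConfig:
    """Load a YAML/JSON config file, fill defaults, reject unknown keys.

    Range violations surface with the offending field path. An empty file
    yields the full default configuration (with ``theta`` still unset).
    """
    text = Path(path).read_text()
    payload = yaml.safe_load(text) or {}
    if not isinstance(payload, dict):
        raise ValueError("config root must be a mapping")
    cfg = _build(RunConfig, payload, "config")
    if cfg.theta is not None and not 0.0 < cfg.theta < 1.0:
        raise ValueError(f"config.theta: must lie in (0, 1), got {cfg.theta}")
    if cfg.mdp.cost <= 0:
        raise ValueError("config.mdp.cost: must be positive")
    if cfg.generator.n_scenes < 1:
        raise ValueError("config.generator.n_scenes: must be >= 1")
    return cfg


def config_to_dict(cfg: RunConfig) -> dict:
    return asdict(cfg)
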