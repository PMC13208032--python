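"""YAML run configuration with committed defaults and leakage guards.

An empty file (or missing blocks) yields the full default configuration:
the committed training hyperparameters (constant lr 2e-4, Adam beta1 0.5 /
beta2 0.999, 40 epochs, batch 16, 256 input, 9 residual blocks, loss
weights 1.0 / 0.1 / 0.2 / 15.0 / 2.0), registration defaults (pyramid
100/70/20, refinement 1000 iterations at lr 3.0, smooth weight 2.0) and
phantom defaults. Validation collects *every* violation before raising,
and subject splits (pretrain / finetune / eval) must be pairwise disjoint
— a subject appearing in two cohorts would leak information between
training and evaluation.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace

import yaml

from .phantom import PhantomSpec
from .registration import RegistrationConfig
from .translator import LossWeights, TrainConfig

__all__ = ["RunConfig", "ConfigError", "load_config", "dump_config"]

_TUPLE_FIELDS = {"betas", "pyramid_iterations", "scale_weights"}


class ConfigError(ValueError):
    """Carries the full list of validation problems."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n" + "\n".join(f"- {p}" for p in problems))


@dataclass
class RunConfig:
    paths: dict = field(default_factory=lambda: {"data": "data", "output": "out"})
    seed: int = 0
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    train_phase1: TrainConfig = field(default_factory=lambda: TrainConfig(phase=1))
    train_phase2: TrainConfig = field(default_factory=lambda: TrainConfig(phase=2))
    loss_weights: LossWeights = field(default_factory=LossWeights)
    evaluation: dict = field(default_factory=lambda: {
        "embedder": "random_projection", "backbone": "seeded_conv",
        "metrics": ["psnr", "mse", "ms_ssim", "fid", "lpips", "cnr",
                    "distribution", "profile"]})
    split: dict = field(default_factory=lambda: {
        "pretrain": ["S00", "S01", "S02"], "finetune": ["S10", "S11"],
        "eval": ["S20"]})
    dose_levels: dict = field(default_factory=lambda: {
        "Pre": 0.0, "Post40": 0.4, "Post100": 1.0})


def _coerce(dc_type, block: dict, errors: list[str], ctx: str):
    known = {f.name for f in fields(dc_type)}
    kwargs = {}
    for key, val in (block or {}).items():
        if key not in known:
            errors.append(f"{ctx}: unknown key {key!r}")
            continue
        if key in _TUPLE_FIELDS and isinstance(val, list):
            val = tuple(val)
        kwargs[key] = val
    try:
        return dc_type(**kwargs)
    except (TypeError, ValueError) as exc:
        errors.append(f"{ctx}: {exc}")
        return dc_type()


def load_config(path: str | None = None, data: dict | None = None) -> RunConfig:
    """Load and validate a YAML run configuration (defaults applied)."""
    if data is None:
        if path is None:
            data = {}
        else:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError([f"top level must be a mapping, got {type(data).__name__}"])
    errors: list[str] = []
    cfg = RunConfig()
    simple = {"paths": dict, "seed": int, "evaluation": dict, "split": dict,
              "dose_levels": dict}
    for key, typ in simple.items():
        if key in data:
            val = data[key]
            if not isinstance(val, typ):
                errors.append(f"{key}: expected {typ.__name__}")
            else:
                setattr(cfg, key, val)
    cfg.phantom = _coerce(PhantomSpec, data.get("phantom", {}), errors, "phantom")
    cfg.registration = _coerce(RegistrationConfig, data.get("registration", {}),
                               errors, "registration")
    p1 = dict(data.get("train_phase1", {}))
    p1.setdefault("phase", 1)
    p2 = dict(data.get("train_phase2", {}))
    p2.setdefault("phase", 2)
    cfg.train_phase1 = _coerce(TrainConfig, p1, errors, "train_phase1")
    cfg.train_phase2 = _coerce(TrainConfig, p2, errors, "train_phase2")
    cfg.loss_weights = _coerce(LossWeights, data.get("loss_weights", {}),
                               errors, "loss_weights")

    # semantic validation — collect everything
    for name, obj in (("phantom", cfg.phantom), ("registration", cfg.registration),
                      ("train_phase1", cfg.train_phase1),
                      ("train_phase2", cfg.train_phase2),
                      ("loss_weights", cfg.loss_weights)):
        try:
            obj.validate()
        except ValueError as exc:
            errors.append(f"{name}: {exc}")
    # leakage guard: splits pairwise disjoint
    names = list(cfg.split)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            overlap = sorted(set(cfg.split[a]) & set(cfg.split[b]))
            for sid in overlap:
                errors.append(
                    f"split: subject {sid!r} appears in both {a!r} and {b!r} "
                    "(subject-level leakage)")
    if errors:
        raise ConfigError(errors)
    return cfg


def dump_config(cfg: RunConfig, path: str | None = None) -> dict:
    """Serialize a RunConfig back to plain YAML-able data (and optionally a file)."""
    doc = {
        "paths": dict(cfg.paths),
        "seed": cfg.seed,
        "phantom": asdict(cfg.phantom),
        "registration": asdict(cfg.registration),
        "train_phase1": asdict(cfg.train_phase1),
        "train_phase2": asdict(cfg.train_phase2),
        "loss_weights": asdict(cfg.loss_weights),
        "evaluation": dict(cfg.evaluation),
        "split": {k: list(v) for k, v in cfg.split.items()},
        "dose_levels": dict(cfg.dose_levels),
    }
    for block in ("registration", "train_phase1", "train_phase2", "loss_weights"):
        for key, val in doc[block].items():
            if isinstance(val, tuple):
                doc[block][key] = list(val)
    if path is not None:
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)
    return doc
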