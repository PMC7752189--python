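"""Pipeline configuration: a small YAML key/value schema.

Schema (all keys optional unless noted):

    seed: 0                  # root seed for every source of randomness
    outdir: results          # where stages write their artifacts
    mcmc:                    # preset name or explicit sampler settings
      preset: desk           # desk | paper
      # or: n_chains, iterations, burn_in, thinning, rhat_threshold
    purge_rule: positive     # positive | two-sided
    purge_level: physician   # physician | population
    activation: intercept    # intercept | raw_mean
    model_selection: dic     # dic | random | fixed
    dic_threshold: 3.0
    figures: false           # render matplotlib figures (headless-safe off)
    inputs:                  # existing data; omit when simulating
      patient_ratings: path/to/patient.csv
      observer_ratings: path/to/observer.csv
    simulate:                # synthetic study; omit when inputs given
      n_physicians: 29
      patients_per_physician: 10
      recorded_consultations_per_physician: 3
      raters_per_consultation: 2
      rater_pool_size: 4
    instruments:             # override instrument item counts/ranges
      OPTION-12: {n_items: 12, item_min: 0, item_max: 4}

Unknown keys are rejected so typos fail loudly instead of silently using a
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .inference import MCMC_PRESETS, McmcConfig
from .observer import DEFAULT_INSTRUMENTS, InstrumentSpec
from .simulate import StudyDesign

__all__ = ["PipelineConfig", "load_config"]

_SIMULATE_KEYS = {
    "n_physicians",
    "patients_per_physician",
    "recorded_consultations_per_physician",
    "raters_per_consultation",
    "rater_pool_size",
}
_MCMC_KEYS = {"preset", "n_chains", "iterations", "burn_in", "thinning", "rhat_threshold"}


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: Path = Path("results")
    mcmc: McmcConfig = field(default_factory=lambda: MCMC_PRESETS["desk"])
    purge_rule: str = "positive"
    purge_level: str = "physician"
    activation: str = "intercept"
    model_selection: str = "dic"
    dic_threshold: float = 3.0
    figures: bool = False
    patient_ratings_path: Path | None = None
    observer_ratings_path: Path | None = None
    simulate: StudyDesign | None = field(default_factory=StudyDesign)
    instruments: dict[str, InstrumentSpec] = field(
        default_factory=lambda: dict(DEFAULT_INSTRUMENTS)
    )

    def __post_init__(self) -> None:
        if self.purge_rule not in ("positive", "two-sided"):
            raise ValueError("purge_rule must be 'positive' or 'two-sided'")
        if self.purge_level not in ("physician", "population"):
            raise ValueError("purge_level must be 'physician' or 'population'")
        if self.activation not in ("intercept", "raw_mean"):
            raise ValueError("activation must be 'intercept' or 'raw_mean'")
        if self.model_selection not in ("dic", "random", "fixed"):
            raise ValueError("model_selection must be 'dic', 'random' or 'fixed'")
        self.outdir = Path(self.outdir)
        if self.simulate is None and self.patient_ratings_path is None:
            raise ValueError("either a simulate block or inputs.patient_ratings is required")

    def validate_inputs(self) -> None:
        """Check referenced input paths resolve before any computation."""
        for name, path in (
            ("patient_ratings", self.patient_ratings_path),
            ("observer_ratings", self.observer_ratings_path),
        ):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"inputs.{name}: no such file: {path}")


def _reject_unknown(mapping: dict, allowed: set[str], context: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"unknown {context} keys: {sorted(unknown)}")


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a YAML config file; keyword overrides win over file values."""
    raw: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    _reject_unknown(
        raw,
        {
            "seed",
            "outdir",
            "mcmc",
            "purge_rule",
            "purge_level",
            "activation",
            "model_selection",
            "dic_threshold",
            "figures",
            "inputs",
            "simulate",
            "instruments",
        },
        "config",
    )

    kwargs: dict = {}
    for key in (
        "seed",
        "outdir",
        "purge_rule",
        "purge_level",
        "activation",
        "model_selection",
        "dic_threshold",
        "figures",
    ):
        if key in raw:
            kwargs[key] = raw[key]

    if "mcmc" in raw:
        block = raw["mcmc"]
        if isinstance(block, str):
            block = {"preset": block}
        _reject_unknown(block, _MCMC_KEYS, "mcmc")
        base = MCMC_PRESETS[block.get("preset", "desk")]
        mcmc_kwargs = {k: v for k, v in block.items() if k != "preset"}
        kwargs["mcmc"] = (
            McmcConfig(
                **{
                    f.name: mcmc_kwargs.get(f.name, getattr(base, f.name))
                    for f in fields(McmcConfig)
                }
            )
            if mcmc_kwargs
            else base
        )

    if "inputs" in raw:
        block = raw["inputs"] or {}
        _reject_unknown(block, {"patient_ratings", "observer_ratings"}, "inputs")
        if "patient_ratings" in block:
            kwargs["patient_ratings_path"] = Path(block["patient_ratings"])
        if "observer_ratings" in block:
            kwargs["observer_ratings_path"] = Path(block["observer_ratings"])
        kwargs.setdefault("simulate", None)

    if "simulate" in raw:
        block = raw["simulate"] or {}
        _reject_unknown(block, _SIMULATE_KEYS, "simulate")
        kwargs["simulate"] = StudyDesign(seed=raw.get("seed", 0), **block)

    if "instruments" in raw:
        instruments = dict(DEFAULT_INSTRUMENTS)
        for name, spec in (raw["instruments"] or {}).items():
            _reject_unknown(spec, {"n_items", "item_min", "item_max"}, f"instruments.{name}")
            base_spec = instruments.get(name)
            instruments[name] = InstrumentSpec(
                name=name,
                n_items=spec.get("n_items", base_spec.n_items if base_spec else None),
                item_min=spec.get("item_min", base_spec.item_min if base_spec else 0),
                item_max=spec.get("item_max", base_spec.item_max if base_spec else 4),
            )
        kwargs["instruments"] = instruments

    for key, value in overrides.items():
        if value is not None:
            kwargs[key] = value

    cfg = PipelineConfig(**kwargs)
    if "seed" in kwargs and cfg.simulate is not None and cfg.simulate.seed != cfg.seed:
        cfg.simulate = StudyDesign(
            **{
                **{f.name: getattr(cfg.simulate, f.name) for f in fields(StudyDesign)},
                "seed": cfg.seed,
            }
        )
    return cfg
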