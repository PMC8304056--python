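"""Run configuration: schema-validated YAML, shared by the CLI subcommands."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .assembly import DisorderSpec, SubstrateSpec
from .io import GroupingRules

__all__ = ["RunConfig", "load_config"]

_TOP_KEYS = {
    "input",
    "bin_width",
    "grouping",
    "contrasts",
    "substrate",
    "water_gap",
    "multilayer",
    "instrument",
    "output",
    "verbosity",
}

_SUBSTRATE_KEYS = {"fronting_sld", "oxide_thickness", "oxide_sld",
                   "oxide_roughness", "sample_roughness"}
_MULTILAYER_KEYS = {"n_repeats", "jitter_width", "jitter_distribution",
                    "n_realizations", "seed"}
_INSTRUMENT_KEYS = {"dq_over_q", "q_min", "q_max", "n_q", "scale", "background"}
_GROUPING_KEYS = {"rules", "isotopes", "implicit_h"}


def _check_keys(section: Mapping, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(
            f"unknown config key(s) in {where}: {sorted(unknown)} "
            f"(allowed: {sorted(allowed)})"
        )


@dataclass
class InstrumentBlock:
    dq_over_q: float = 0.0
    q_min: float = 0.005
    q_max: float = 0.3
    n_q: int = 500
    scale: float = 1.0
    background: float = 0.0


@dataclass
class MultilayerBlock:
    n_repeats: int = 1
    jitter_width: float = 0.0
    jitter_distribution: str = "uniform"
    n_realizations: int = 64
    seed: int = 0

    def disorder(self) -> DisorderSpec:
        return DisorderSpec(
            width=self.jitter_width,
            distribution=self.jitter_distribution,
            n_realizations=self.n_realizations,
            seed=self.seed,
        )


@dataclass
class RunConfig:
    """Validated run configuration (unknown keys are rejected up front)."""

    input: str | None = None
    bin_width: float = 0.13
    grouping: GroupingRules = field(default_factory=GroupingRules)
    contrasts: list[float] = field(default_factory=lambda: [1.0])
    substrate: SubstrateSpec | None = None
    water_gap: float = 10.0
    multilayer: MultilayerBlock = field(default_factory=MultilayerBlock)
    instrument: InstrumentBlock = field(default_factory=InstrumentBlock)
    output: str | None = None
    verbosity: str = "info"

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        _check_keys(raw, _TOP_KEYS, "top level")
        kwargs: dict[str, Any] = {}
        for key in ("input", "bin_width", "water_gap", "output", "verbosity"):
            if key in raw:
                kwargs[key] = raw[key]
        if "contrasts" in raw:
            contrasts = [float(f) for f in raw["contrasts"]]
            if any(not 0.0 <= f <= 1.0 for f in contrasts):
                raise ValueError("contrast fractions must be in [0, 1]")
            kwargs["contrasts"] = contrasts
        if "grouping" in raw:
            g = raw["grouping"]
            _check_keys(g, _GROUPING_KEYS, "grouping")
            kwargs["grouping"] = GroupingRules(
                rules=[tuple(r) for r in g.get("rules", [])],
                isotopes=dict(g.get("isotopes", {})),
                implicit_h={
                    (res, atom): int(n)
                    for (res, atom), n in (
                        ((e["resname"], e["atomname"]), e["count"])
                        for e in g.get("implicit_h", [])
                    )
                },
            )
        if "substrate" in raw:
            s = raw["substrate"]
            _check_keys(s, _SUBSTRATE_KEYS, "substrate")
            kwargs["substrate"] = SubstrateSpec(**s)
        if "multilayer" in raw:
            m = raw["multilayer"]
            _check_keys(m, _MULTILAYER_KEYS, "multilayer")
            kwargs["multilayer"] = MultilayerBlock(**m)
        if "instrument" in raw:
            i = raw["instrument"]
            _check_keys(i, _INSTRUMENT_KEYS, "instrument")
            kwargs["instrument"] = InstrumentBlock(**i)
        cfg = cls(**kwargs)
        if cfg.verbosity not in ("quiet", "info", "debug"):
            raise ValueError("verbosity must be quiet/info/debug")
        return cfg


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return RunConfig.from_dict(raw)
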