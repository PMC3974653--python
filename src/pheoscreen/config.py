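"""Pipeline configuration: thresholds, stage toggles, seeds.

A :class:`PipelineConfig` collects every tunable of the end-to-end run —
triage/efficacy cuts, the fold-change and CI bands, top-N sizes, the seed,
and the synthetic-stage parameters — and round-trips stably through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .qhts import ScreenConfig

__all__ = ["PipelineConfig", "ScreenStage", "MetaStage", "NetworkStage",
           "SynergyStage"]

ALL_STAGES = ("simulate", "screen", "enrich", "meta", "network", "synergy")


@dataclass
class ScreenStage:
    n_compounds: int = 400
    noise_sd: float = 3.0          # percent of the control window
    top_n: int = 50
    active_efficacy_pct: float = 60.0
    high_efficacy_pct: float = 80.0
    poor_fit_r2: float = 0.5
    noise_multiplier: float = 3.0

    def screen_config(self) -> ScreenConfig:
        return ScreenConfig(
            active_efficacy_pct=self.active_efficacy_pct,
            high_efficacy_pct=self.high_efficacy_pct,
            poor_fit_r2=self.poor_fit_r2,
            noise_multiplier=self.noise_multiplier,
        )


@dataclass
class MetaStage:
    n_genes: int = 600
    n_divergent: int = 100
    n_samples_a: int = 3
    n_samples_b: int = 12
    rho: float = 0.86
    fold_threshold: float = 2.0
    n_drugs: int = 22
    min_targets: int = 3


@dataclass
class NetworkStage:
    connect_targets_to_all_drugs: bool = True
    top_n: int = 20


@dataclass
class SynergyStage:
    dm1: float = 5.0               # nM, drug 1 median-effect dose
    dm2: float = 1000.0            # nM, drug 2
    m1: float = 1.0
    m2: float = 1.0
    ratio: float = 200.0           # dose2 : dose1
    ci_true: float = 0.55
    noise_sd: float = 0.01
    ci_lo: float = 0.8
    ci_hi: float = 1.2


@dataclass
class PipelineConfig:
    """Full pipeline configuration; serializable to/from YAML."""

    seed: int = 1
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    concentration_unit: str = "uM"
    screen: ScreenStage = field(default_factory=ScreenStage)
    meta: MetaStage = field(default_factory=MetaStage)
    network: NetworkStage = field(default_factory=NetworkStage)
    synergy: SynergyStage = field(default_factory=SynergyStage)

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s) {sorted(unknown)}")
        if not 0 < self.screen.active_efficacy_pct < self.screen.high_efficacy_pct:
            raise ValueError("need 0 < active efficacy cut < high-efficacy cut")
        if self.meta.fold_threshold <= 1:
            raise ValueError("fold_threshold must be > 1")
        if not 0 < self.synergy.ci_lo < self.synergy.ci_hi:
            raise ValueError("CI bands must satisfy 0 < lo < hi")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for name, sub in (("screen", ScreenStage), ("meta", MetaStage),
                          ("network", NetworkStage), ("synergy", SynergyStage)):
            if name in d and isinstance(d[name], dict):
                known = {f.name for f in fields(sub)}
                extra = set(d[name]) - known
                if extra:
                    raise ValueError(f"unknown {name} option(s) {sorted(extra)}")
                d[name] = sub(**d[name])
        return cls(**d)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source.read())
        else:
            try:
                with open(source) as fh:
                    data = yaml.safe_load(fh)
            except (OSError, TypeError):
                data = yaml.safe_load(source)
        return cls.from_dict(data or {})
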