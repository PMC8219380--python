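"""Pipeline configuration: one structured (YAML) file, every constant overridable.

The defaults encode the analysis conventions: the 2.5x saturation rule for
admitting SPR fits into the W6/32 standard curve, the 20 uM switch for
reporting constrained vs free KD, activation thresholds of 15% (CD69) and
10% (IL-2) for potency, the KD < 1 uM exclusion floor and p = 0.05
significance filter for the power law, the annealed Metropolis-Hastings
settings of the kinetic-proofreading fit, and the phase-map scenario sizes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class UnitsConfig:
    concentration: str = "uM"
    dose: str = "uM"
    response: str = "RU"
    activation: str = "percent"


@dataclass
class SPRConfig:
    #: max(T)/KD ratio a free fit must exceed to enter the standard curve
    saturation_ratio: float = 2.5
    #: constrained KD above this (uM) is reported; below it the free KD is
    kd_switch_threshold: float = 20.0
    w632_note: str = "W6/32 injected at a single fixed concentration (10 ug/ml)"


@dataclass
class PotencyConfig:
    #: % activation defining potency, per readout
    threshold_percent: dict = field(
        default_factory=lambda: {"CD69": 15.0, "IL2": 10.0})


@dataclass
class PowerLawConfig:
    kd_exclusion_floor: float = 1.0   # uM; saturation regime below this
    significance_alpha: float = 0.05  # slope p-value filter


@dataclass
class SynthConfig:
    n_experiments: int = 12
    sigma_log: float = 0.1       # lognormal potency noise SD (log10 units)
    sigma_ru: float = 2.0        # SPR response noise SD (RU)
    n_spr_replicates: int = 3
    hill_emin: float = 0.0
    hill_emax: float = 60.0
    hill_coeff: float = 1.0


@dataclass
class KPFitConfig:
    prior_set: str = "plate"          # "plate" or "cell"
    schedule: str = "synthetic"       # "plate", "cell" or "synthetic"
    sigma_log: float = 0.1            # noise scale for the synthetic schedule
    n_chains: int = 1000
    max_steps: int = 5_000_000
    kon: float = 0.0447               # uM^-1 s^-1


@dataclass
class HeatmapConfig:
    n_values: list = field(default_factory=lambda: [0, 1, 2, 3, 4])
    tau_values: list = field(default_factory=lambda: [0.5, 1.0, 2.0, 5.0, 10.0, 20.0])
    n_realisations: int = 250
    t_end: float = 100.0
    lambda_threshold: float = 0.1
    L_high: float = 10000.0
    R0: float = 30000.0
    koff1: float = 1.0
    alpha: float = 2.0
    #: per-molecule kon chosen so kon*R0 = kon_occupancy_factor*koff1
    kon_occupancy_factor: float = 100.0


@dataclass
class PipelineConfig:
    seed: int = 0
    units: UnitsConfig = field(default_factory=UnitsConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)
    spr: SPRConfig = field(default_factory=SPRConfig)
    potency: PotencyConfig = field(default_factory=PotencyConfig)
    powerlaw: PowerLawConfig = field(default_factory=PowerLawConfig)
    kpfit: KPFitConfig = field(default_factory=KPFitConfig)
    heatmap: HeatmapConfig = field(default_factory=HeatmapConfig)

    def validate(self) -> "PipelineConfig":
        if self.seed < 0:
            raise ValueError("seed must be >= 0")
        if self.spr.saturation_ratio <= 0 or self.spr.kd_switch_threshold <= 0:
            raise ValueError("SPR thresholds must be > 0")
        sy = self.synth
        if sy.n_experiments < 1 or sy.sigma_log < 0 or sy.sigma_ru < 0:
            raise ValueError("invalid synth block")
        if not sy.hill_emin < sy.hill_emax or sy.hill_coeff <= 0:
            raise ValueError("invalid synth Hill shape")
        if any(v <= 0 for v in self.potency.threshold_percent.values()):
            raise ValueError("potency thresholds must be > 0")
        if self.powerlaw.kd_exclusion_floor <= 0:
            raise ValueError("kd_exclusion_floor must be > 0")
        if not 0 < self.powerlaw.significance_alpha < 1:
            raise ValueError("significance_alpha must be in (0, 1)")
        if self.kpfit.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        hm = self.heatmap
        if hm.n_realisations < 1 or hm.t_end <= 0 or hm.lambda_threshold <= 0:
            raise ValueError("invalid heatmap block")
        if hm.alpha <= 0 or hm.L_high <= 0 or hm.R0 <= 0:
            raise ValueError("invalid heatmap block")
        return self

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs: dict = {}
        sub = {"units": UnitsConfig, "synth": SynthConfig, "spr": SPRConfig,
               "potency": PotencyConfig, "powerlaw": PowerLawConfig,
               "kpfit": KPFitConfig, "heatmap": HeatmapConfig}
        for key, val in d.items():
            if key in sub:
                kwargs[key] = sub[key](**val)
            else:
                kwargs[key] = val
        return cls(**kwargs).validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def content_hash(self) -> str:
        """Stable hash of the full configuration, recorded in run metadata."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
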