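"""Run configuration: YAML round-trip and validation for the CLI stages."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .deconv import AcquisitionParams, ConfigurationError, FitConfig


@dataclass
class OxygenBlock:
    p50_mmHg: float = 26.0
    hill_h: float = 2.8
    b_total: float = 0.1943
    ca_o2: float = 0.19
    cmro2_target: float = 2.5
    nawm_cbf_anchor: float = 22.0  # mL/100 mL/min mapped to the NAWM-mean rCBF
    reference_state: dict = field(
        default_factory=lambda: {
            "mtt_s": 1.4, "cth_s": 1.33, "pto2_mmHg": 25.0, "oef_target": 0.30
        }
    )


@dataclass
class RoiBlock:
    vessel_fraction: float = 0.08
    pve_threshold: float = 0.5
    size_filter: bool = True
    min_voxels: int = 3
    min_extent_mm: float = 3.0
    connectivity: int = 26


@dataclass
class RunConfig:
    acq: AcquisitionParams = field(
        default_factory=lambda: AcquisitionParams(te=0.040, dt=1.2, baseline=(0, 8))
    )
    fit: FitConfig = field(default_factory=FitConfig)
    oxygen: OxygenBlock = field(default_factory=OxygenBlock)
    roi: RoiBlock = field(default_factory=RoiBlock)
    seed: int = 0

    def validate(self) -> "RunConfig":
        r = self.roi
        if not 0.0 < r.vessel_fraction < 1.0:
            raise ConfigurationError("roi.vessel_fraction must be in (0, 1)")
        if not 0.0 < r.pve_threshold <= 1.0:
            raise ConfigurationError("roi.pve_threshold must be in (0, 1]")
        if r.connectivity not in (6, 26):
            raise ConfigurationError("roi.connectivity must be 6 or 26")
        o = self.oxygen
        for name in ("p50_mmHg", "hill_h", "b_total", "ca_o2", "cmro2_target",
                     "nawm_cbf_anchor"):
            if not getattr(o, name) > 0:
                raise ConfigurationError(f"oxygen.{name} must be positive")
        if not o.ca_o2 < o.b_total:
            raise ConfigurationError("oxygen.ca_o2 must be below oxygen.b_total")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["acq"]["baseline"] = list(self.acq.baseline)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = {}
        if "acq" in d:
            a = dict(d["acq"])
            a["baseline"] = tuple(a.get("baseline", (0, 8)))
            kwargs["acq"] = AcquisitionParams(**a)
        if "fit" in d:
            f = dict(d["fit"])
            for key in ("alpha_bounds", "beta_bounds", "k_leak_bounds",
                        "delay_bounds", "alpha_starts", "delay_starts"):
                if key in f:
                    f[key] = tuple(f[key])
            kwargs["fit"] = FitConfig(**f)
        if "oxygen" in d:
            kwargs["oxygen"] = OxygenBlock(**d["oxygen"])
        if "roi" in d:
            kwargs["roi"] = RoiBlock(**d["roi"])
        if "seed" in d:
            kwargs["seed"] = int(d["seed"])
        return cls(**kwargs).validate()


def load_config(path: str | Path) -> RunConfig:
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    try:
        return RunConfig.from_dict(raw)
    except TypeError as e:
        raise ConfigurationError(f"invalid configuration {path}: {e}") from e


def save_config(cfg: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        yaml.safe_dump(cfg.to_dict(), f, sort_keys=False)
    return path
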