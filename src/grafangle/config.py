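"""Run configuration: one YAML-serializable tree covering every stage.

CLI flags override config-file values; the effective configuration is
embedded verbatim in every JSON output for provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .detect import DetectorParams
from .geometry import MeasureParams, ScreenParams
from .phantom import DriftModel, NoiseConfig
from .pipeline import GateParams


@dataclass
class SynthConfig:
    alpha_deg: float = 70.0
    inclination_deg: float = 0.0
    n_frames: int = 1
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    drift: DriftModel = field(default_factory=DriftModel)


@dataclass
class RunConfig:
    synth: SynthConfig = field(default_factory=SynthConfig)
    detector: DetectorParams = field(default_factory=DetectorParams)
    measure: MeasureParams = field(default_factory=MeasureParams)
    gates: GateParams = field(default_factory=GateParams)
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synth"]["drift"]["offplane_frames"] = sorted(
            self.synth.drift.offplane_frames
        )
        return d

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        synth = d.get("synth", {})
        noise = NoiseConfig(**synth.get("noise", {}))
        drift_d = dict(synth.get("drift", {}))
        if "offplane_frames" in drift_d:
            drift_d["offplane_frames"] = frozenset(drift_d["offplane_frames"])
        if "translation_per_frame" in drift_d:
            drift_d["translation_per_frame"] = tuple(drift_d["translation_per_frame"])
        drift = DriftModel(**drift_d)
        synth_kwargs = {k: v for k, v in synth.items() if k not in {"noise", "drift"}}

        def build(cls_, key):
            sub = dict(d.get(key, {}))
            if "screen" in sub:
                sub["screen"] = ScreenParams(**sub["screen"])
            return cls_(**sub)

        return cls(
            synth=SynthConfig(noise=noise, drift=drift, **synth_kwargs),
            detector=build(DetectorParams, "detector"),
            measure=build(MeasureParams, "measure"),
            gates=GateParams(**d.get("gates", {})),
            seed=int(d.get("seed", 0)),
        )
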