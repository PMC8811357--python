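"""Pipeline configuration: one nested, YAML-round-trippable source of truth.

Every random operation in the pipeline (phantom generation, k-means
initialization, negative-voxel sampling, SVM probability calibration) reads
its seed from here, derived deterministically from the single global seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields, replace

import yaml

from .candidates import FeatureConfig
from .shapes import ShapeCriteria
from .subjects import SubjectThreshold
from .vessels import FrangiParams


def _to_plain(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _to_plain(v) for k, v in asdict(obj).items()}
    if isinstance(obj, tuple):
        return list(obj)
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


def _from_plain(cls, d):
    kwargs = {}
    for f in fields(cls):
        if f.name not in d:
            continue
        v = d[f.name]
        if isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


@dataclass(frozen=True)
class VesselRemovalConfig:
    frangi: FrangiParams = field(default_factory=FrangiParams)
    sigma_grad: float = 1.0
    sigma_window: float = 3.0
    feature_weights: tuple[float, float, float] = (1.0, 0.25, 2.0)


@dataclass(frozen=True)
class PipelineConfig:
    """Top-level configuration for the preselection pipeline."""

    modality: str = "SWI"
    vessel_removal: VesselRemovalConfig = field(default_factory=VesselRemovalConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    shape: ShapeCriteria = field(default_factory=ShapeCriteria)
    subject: SubjectThreshold = field(default_factory=SubjectThreshold)
    seed: int = 0
    log_level: str = "INFO"

    def stage_seed(self, stage: str, index: int = 0) -> int:
        """Deterministic per-stage, per-subject sub-seed below 2**31."""
        digest = hashlib.sha256(f"{int(self.seed)}:{stage}:{int(index)}".encode()).digest()
        return int.from_bytes(digest[:4], "little") % (2**31 - 1)

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "modality": self.modality,
            "seed": self.seed,
            "log_level": self.log_level,
            "vessel_removal": {
                "frangi": _to_plain(self.vessel_removal.frangi),
                "sigma_grad": self.vessel_removal.sigma_grad,
                "sigma_window": self.vessel_removal.sigma_window,
                "feature_weights": list(self.vessel_removal.feature_weights),
            },
            "features": _to_plain(self.features),
            "shape": _to_plain(self.shape),
            "subject": _to_plain(self.subject),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        vr = d.get("vessel_removal", {})
        return cls(
            modality=d.get("modality", "SWI"),
            seed=int(d.get("seed", 0)),
            log_level=d.get("log_level", "INFO"),
            vessel_removal=VesselRemovalConfig(
                frangi=_from_plain(FrangiParams, vr.get("frangi", {})),
                sigma_grad=vr.get("sigma_grad", 1.0),
                sigma_window=vr.get("sigma_window", 3.0),
                feature_weights=tuple(vr.get("feature_weights", (1.0, 0.25, 2.0))),
            ),
            features=_from_plain(FeatureConfig, d.get("features", {})),
            shape=_from_plain(ShapeCriteria, d.get("shape", {})),
            subject=_from_plain(SubjectThreshold, d.get("subject", {})),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def with_th_ncmb(self, th: int) -> "PipelineConfig":
        return replace(self, subject=SubjectThreshold(th))
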