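"""Schema-validated run configuration.

Every number the pipeline depends on — smoothing kernels, thresholds, the
area gate, proportion cut-offs, primers, enzyme, the expected product
length, the gel band resolution and the random seed — lives in one YAML/JSON
document validated before any work starts.  Defaults are the screening
protocol's values, held as data rather than code constants.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from .genotyping import ENZYMES, PrimerPair, RestrictionEnzyme
from .hcs import ClassifierConfig, SmoothingSpec

SCHEMA_VERSION = "1"

__all__ = ["RunConfig", "SCHEMA_VERSION"]


class SmoothingModel(BaseModel):
    kernel_size: int = Field(ge=1)
    sigma: float = Field(gt=0)


class ClassifierModel(BaseModel):
    red_spec: SmoothingModel = SmoothingModel(kernel_size=21, sigma=7.0)
    greenblue_spec: SmoothingModel = SmoothingModel(kernel_size=60, sigma=20.0)
    red_threshold: float = Field(default=125.0, ge=0)
    green_threshold: float = Field(default=200.0, ge=0)
    blue_threshold: float = Field(default=200.0, ge=0)
    min_clone_area: int = Field(default=20_000, gt=0)
    ap_high: float = 0.9
    ap_low: float = 0.1

    def build(self) -> ClassifierConfig:
        return ClassifierConfig(
            red_spec=SmoothingSpec(self.red_spec.kernel_size, self.red_spec.sigma),
            greenblue_spec=SmoothingSpec(
                self.greenblue_spec.kernel_size, self.greenblue_spec.sigma
            ),
            red_threshold=self.red_threshold,
            green_threshold=self.green_threshold,
            blue_threshold=self.blue_threshold,
            min_clone_area=self.min_clone_area,
            ap_high=self.ap_high,
            ap_low=self.ap_low,
        )


class PrimerModel(BaseModel):
    forward: str = "CCCCGAAAGTTCTCATTCAA"
    reverse: str = "GCGAATCCGTCGCTGTGCAT"
    expected_product_length: int = 314

    def build(self) -> PrimerPair:
        return PrimerPair(self.forward, self.reverse, self.expected_product_length)


class EnzymeModel(BaseModel):
    name: str = "MvaI"
    recognition: str = "CCWGG"
    cut_offset: int = 2

    @field_validator("recognition")
    @classmethod
    def _valid_pattern(cls, v: str) -> str:
        RestrictionEnzyme("probe", v, 0)  # raises on invalid IUPAC codes
        return v.upper()

    def build(self) -> RestrictionEnzyme:
        if self.name in ENZYMES and self.recognition == ENZYMES[self.name].recognition:
            return ENZYMES[self.name]
        return RestrictionEnzyme(self.name, self.recognition, self.cut_offset)


class RunConfig(BaseModel):
    """Top-level pipeline configuration."""

    classifier: ClassifierModel = ClassifierModel()
    primers: PrimerModel = PrimerModel()
    enzyme: EnzymeModel = EnzymeModel()
    band_resolution: int = Field(default=10, ge=1)
    channel_order: tuple[str, str, str] = ("blue", "green", "red")
    seed: int = 0
    log_level: str = "INFO"

    @field_validator("channel_order")
    @classmethod
    def _channels(cls, v: tuple[str, str, str]) -> tuple[str, str, str]:
        if sorted(v) != ["blue", "green", "red"]:
            raise ValueError("channel_order must be a permutation of blue/green/red")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def config_hash(self) -> str:
        """Stable digest identifying this configuration (stamped on artifacts)."""
        canonical = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]
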