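"""Run configuration: validated settings for the whole pipeline."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["ConfigError", "RunConfig"]


class ConfigError(ValueError):
    pass


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class FingerprintSettings(_Strict):
    scheme: Literal["structural_keys", "hashed_path"] = "structural_keys"
    n_bits: int = Field(1024, ge=2)
    max_depth: int = Field(6, ge=1)
    key_file: Optional[str] = None


class EnumerationSettings(_Strict):
    prune_level: Optional[int] = Field(4, ge=1)
    max_bits: int = Field(20, ge=1)


class FragmentationSettings(_Strict):
    max_depth: Optional[int] = Field(None, ge=1)
    unit_cap: int = Field(25, ge=1)
    unit_smarts_file: Optional[str] = None


class DomainSettings(_Strict):
    min_occurrence: int = Field(4, ge=1)


class RunConfig(_Strict):
    """Top-level configuration; unknown keys are rejected on load."""

    approach: Literal["fragment", "bitset"] = "fragment"
    fingerprint: FingerprintSettings = Field(default_factory=FingerprintSettings)
    enumeration: EnumerationSettings = Field(default_factory=EnumerationSettings)
    fragmentation: FragmentationSettings = Field(default_factory=FragmentationSettings)
    domain: DomainSettings = Field(default_factory=DomainSettings)
    condense: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            data = yaml.safe_load(Path(path).read_text()) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"invalid YAML in {path}: {exc}") from exc
        try:
            return cls.model_validate(data)
        except Exception as exc:
            raise ConfigError(f"invalid configuration in {path}: {exc}") from exc

    def fingerprint_hash(self) -> str:
        """Stable digest of the descriptor settings, used to refuse running a
        model against fingerprints it was not trained on."""
        payload = json.dumps(self.fingerprint.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
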