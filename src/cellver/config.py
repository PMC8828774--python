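"""Application-level configuration: one validated object wiring all modules.

``AppConfig`` aggregates the store path, barcode codec spec, site-selection
thresholds, analyzer settings, logging and the global random seed.  It loads
from YAML or JSON, rejects unknown keys, and re-validates every sub-config
against the owning module's own constraints (the pydantic layer is a typed
shell; the dataclasses in :mod:`cellver.codec` and :mod:`cellver.recovery`
remain the source of truth for domain invariants).
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from . import codec
from .recovery import AnalyzerConfig

__all__ = ["AppConfig", "BarcodeSpecConfig", "SiteConfig", "AnalyzerSettings", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class BarcodeSpecConfig(_Strict):
    payload_bits: int = 40
    checksum_bits: int = 16
    seed_bits: int = 8
    gc_min: float = 0.40
    gc_max: float = 0.60
    max_homopolymer: int = 3
    forbidden_motifs: list[str] | None = None
    flank_5p: str = codec.DEFAULT_FLANK_5P
    flank_3p: str = codec.DEFAULT_FLANK_3P
    max_correct: int = 2

    def build(self) -> codec.BarcodeSpec:
        kwargs = self.model_dump()
        motifs = kwargs.pop("forbidden_motifs")
        if motifs is not None:
            kwargs["forbidden_motifs"] = frozenset(motifs)
        return codec.BarcodeSpec(**kwargs)


class SiteConfig(_Strict):
    min_len: int = 50
    max_len: int = 1000
    max_intervening: int = 3
    conservation_k: int = 15
    conservation_coverage_min: float = 0.9
    conservation_identity_min: float = 0.9
    arm_len: int = 40
    target_len: int = 200

    @field_validator("min_len", "max_len", "arm_len", "conservation_k", "target_len")
    @classmethod
    def _positive(cls, v: int) -> int:
        if v < 1:
            raise ValueError("must be >= 1")
        return v


class AnalyzerSettings(_Strict):
    min_variant_frequency: float = 0.5
    min_overlap: int = 20
    max_flank_mismatch: int = 2
    match_score: float = 1.0
    mismatch_score: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0
    min_overlap_identity: float = 0.75

    def build(self) -> AnalyzerConfig:
        return AnalyzerConfig(**self.model_dump())


class AppConfig(_Strict):
    store_path: str = "./cellver-store"
    barcode: BarcodeSpecConfig = BarcodeSpecConfig()
    sites: SiteConfig = SiteConfig()
    analyzer: AnalyzerSettings = AnalyzerSettings()
    log_level: str = "INFO"
    seed: int = 0

    @field_validator("log_level")
    @classmethod
    def _log_level(cls, v: str) -> str:
        if v.upper() not in {"DEBUG", "INFO", "WARNING", "ERROR"}:
            raise ValueError(f"unknown log level {v!r}")
        return v.upper()

    def barcode_spec(self) -> codec.BarcodeSpec:
        return self.barcode.build()

    def analyzer_config(self) -> AnalyzerConfig:
        return self.analyzer.build()


def load_config(path: str | Path) -> AppConfig:
    """Load and validate an AppConfig from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    cfg = AppConfig.model_validate(data or {})
    cfg.barcode_spec()  # fail fast on domain-level violations
    cfg.analyzer_config()
    return cfg
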