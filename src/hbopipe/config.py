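"""Validated pipeline configuration with the study's analysis constants.

Every tunable of the pipeline lives here with its default: the 19,754 Hz
sampling rate, the 100-sample recalibration excision border, the
150-3000 Hz spike band, the 5xSD / 5 ms detection rule, top-30 channel
selection with the 0.5 Hz organoid floor and 5 Hz channel ceiling, the
7-of-20 / >0.1 TPM expression filter, the (diff > 4, FC > 2, p < 0.05) DEG
conjunction, and the enrichment thresholds.  Configs load from YAML;
unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

STUDY_DESIGN = {
    # organoids per experimental arm of the emulated study
    "mea": 32,
    "rnaseq": 20,
    "propofol_concentration": 8,
    "lactate": 8,
}


@dataclass
class PipelineConfig:
    # acquisition / signal
    fs: float = 19754.0
    excision_border: int = 100
    band_low_hz: float = 150.0
    band_high_hz: float = 3000.0
    filter_numtaps: int = 513
    saturation_frac: float = 0.9
    flash_channel_frac: float = 0.5
    flash_pad: int = 0
    # spike detection
    detect_k: float = 5.0
    detect_window_ms: float = 5.0
    refractory_ms: float = 1.0
    # channel / organoid selection
    top_n_channels: int = 30
    max_channel_hz: float = 5.0
    min_mean_hz: float = 0.5
    # expression filtering and DEG calling
    expr_min_valid: int = 7
    expr_min_value: float = 0.1
    deg_min_diff: float = 4.0
    deg_min_fc: float = 2.0
    deg_alpha: float = 0.05
    # enrichment
    enrich_fdr: float = 0.05
    enrich_alpha: float = 0.05
    gsea_n_perm: int = 1000
    # synthetic-study scale (per-organoid recording size kept modest so a
    # full run stays desk-scale; generator waveform/noise defaults apply)
    seed: int = 0
    sim_n_organoids_per_group: int = 8
    sim_n_channels: int = 16
    sim_duration_s: float = 20.0
    sim_rate_hz: float = 2.0
    sim_n_genes: int = 4000

    def validate(self) -> "PipelineConfig":
        def req(cond, name, msg):
            if not cond:
                raise ValueError(f"config field {name}: {msg}")

        req(self.fs > 0, "fs", "must be positive")
        req(self.excision_border >= 0, "excision_border", "must be >= 0")
        req(0 < self.band_low_hz < self.band_high_hz < self.fs / 2,
            "band_low_hz/band_high_hz", "need 0 < low < high < fs/2")
        req(self.filter_numtaps >= 3 and self.filter_numtaps % 2 == 1,
            "filter_numtaps", "must be an odd integer >= 3")
        req(0 < self.saturation_frac <= 1, "saturation_frac", "must be in (0, 1]")
        req(0 < self.flash_channel_frac <= 1, "flash_channel_frac", "must be in (0, 1]")
        req(self.detect_k > 0, "detect_k", "must be positive")
        req(self.detect_window_ms > 0, "detect_window_ms", "must be positive")
        req(self.top_n_channels >= 1, "top_n_channels", "must be >= 1")
        req(self.max_channel_hz > 0, "max_channel_hz", "must be positive")
        req(self.min_mean_hz >= 0, "min_mean_hz", "must be >= 0")
        req(self.expr_min_valid >= 0, "expr_min_valid", "must be >= 0")
        req(self.deg_min_fc >= 1, "deg_min_fc", "must be >= 1")
        req(0 < self.deg_alpha < 1, "deg_alpha", "must be in (0, 1)")
        req(0 < self.enrich_fdr < 1, "enrich_fdr", "must be in (0, 1)")
        req(self.gsea_n_perm >= 10, "gsea_n_perm", "must be >= 10")
        req(self.sim_n_organoids_per_group >= 1, "sim_n_organoids_per_group", "must be >= 1")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        return cls(**raw).validate()

    def to_yaml(self, path: str | Path):
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def hash(self) -> str:
        """Stable short hash of the full configuration (run provenance)."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
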