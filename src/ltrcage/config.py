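"""Run configuration: every tunable threshold of the pipeline in one place.

The defaults reproduce the published analysis settings: Paraclu clustering at
10 tags / 2-fold density / 500 bp, a ±100 bp coding-TSS window, a 5 kb proximal
radius, FDR 0.05 for the up-regulated call, the stringent signature criteria
(FDR < 1e-10, fold > 8, expression in ≥30 tumor samples), the −600..+400 bp
TF-binding window, and a Jaccard threshold of 0.5 for the cobinding network.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    # tss_clustering
    cluster_min_tags: int = 10
    cluster_min_fold: float = 2.0
    cluster_max_length: int = 500
    working_min_tpm: float = 1.0
    working_min_samples: int = 2
    # peak_classification
    coding_window_bp: int = 100
    proximal_kb: float = 5.0
    # differential_expression
    de_alpha: float = 0.05
    fold_pseudocount: float = 0.001
    # repeat_enrichment
    exclude_internal: bool = True
    metaelement_min_length: int = 5000
    metaelement_bins: int = 100
    # signature_stratification
    signature_fdr_max: float = 1e-10
    signature_fold_min: float = 8.0
    signature_min_tumor_samples: int = 30
    signature_prefix: str = "LTR"
    cluster_k: int = 3
    log_pseudocount: float = 0.005
    # regulatory_integration
    open_chromatin_max_distance: int = 1000
    tf_window_upstream: int = 600
    tf_window_downstream: int = 400
    tf_alpha: float = 0.05
    jaccard_min: float = 0.5
    profile_halfwidth: int = 2000
    profile_bin: int = 100
    # run plumbing
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        positive = [
            "cluster_min_tags", "cluster_min_fold", "cluster_max_length",
            "working_min_samples", "coding_window_bp", "proximal_kb",
            "signature_fold_min", "signature_min_tumor_samples", "cluster_k",
            "open_chromatin_max_distance", "metaelement_min_length",
            "metaelement_bins", "profile_halfwidth", "profile_bin",
        ]
        for key in positive:
            if getattr(self, key) <= 0:
                raise ConfigError(f"{key} must be positive, got {getattr(self, key)}")
        for key in ("de_alpha", "tf_alpha", "jaccard_min"):
            v = getattr(self, key)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{key} must be in [0, 1], got {v}")
        for key in ("signature_fdr_max", "working_min_tpm", "fold_pseudocount",
                    "log_pseudocount"):
            if getattr(self, key) < 0:
                raise ConfigError(f"{key} must be non-negative")
        if self.seed < 0:
            raise ConfigError("seed must be non-negative")
        return self

    @property
    def proximal_bp(self) -> int:
        return int(round(self.proximal_kb * 1000))


_FIELDS = {f.name: f for f in dataclasses.fields(PipelineConfig)}


def _coerce(name: str, raw: str):
    ftype = _FIELDS[name].type
    raw = raw.strip()
    if ftype == "bool":
        if raw.lower() in ("1", "true", "yes"):
            return True
        if raw.lower() in ("0", "false", "no"):
            return False
        raise ConfigError(f"{name}: cannot parse boolean from {raw!r}")
    if ftype == "int":
        return int(raw)
    if ftype == "float":
        return float(raw)
    return raw


def read_config(path: str | Path) -> PipelineConfig:
    """Parse a flat ``key = value`` text file into a PipelineConfig.

    Unknown keys are rejected; an empty file yields the full default
    configuration; out-of-range values raise ConfigError naming the key.
    """
    cfg = PipelineConfig()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected key=value, got {line!r}")
        key, _, raw = line.partition("=")
        key = key.strip()
        if key not in _FIELDS:
            raise ConfigError(f"line {lineno}: unknown configuration key {key!r}")
        try:
            setattr(cfg, key, _coerce(key, raw))
        except ConfigError:
            raise
        except ValueError as exc:
            raise ConfigError(f"line {lineno}: bad value for {key}: {exc}") from exc
    return cfg.validate()


def write_config(cfg: PipelineConfig, path: str | Path) -> None:
    lines = [f"{f.name} = {getattr(cfg, f.name)}" for f in dataclasses.fields(PipelineConfig)]
    Path(path).write_text("\n".join(lines) + "\n")
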