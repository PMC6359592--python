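"""Run configuration: a validated, fully-defaulted parameter tree.

Unknown keys are rejected (misspelled parameters must fail loudly, not
silently fall back to defaults), and the effective configuration — every
parameter actually used, defaulted or not — is echoed into the output
directory at run time.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ConfigError


def _require_keys(d: Mapping, allowed: set[str], context: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {context}: {sorted(unknown)}")


@dataclass
class InputPaths:
    locus_fasta: str = ""
    plate_3c: str = ""
    digestion_qc: str = ""
    anchor_map: str = ""
    expression_plate: str = ""
    chip_wells: str = ""
    ddpcr_wells: str = ""


@dataclass
class LocusParams:
    motif: str = "AAGCTT"
    cut_offset: int = 0
    tss_position: int = 0
    gene_strand: str = "+"


@dataclass
class ThreeCParams:
    library_id: str = ""
    normalizer_assay: str = "ERCC3_junction"
    proximal_window_kb: float = 4.0
    min_fold_background: float = 3.0
    min_fold_proximal: float = 1.5
    iterative_background: bool = True
    background_z_threshold: float = 2.0
    digestion_threshold_percent: float = 85.0
    require_digestion_qc: bool = True


@dataclass
class ExpressionParams:
    target_assay: str = "PTBP3"
    reference_assays: list[str] = field(default_factory=lambda: ["GAPDH", "PBGD"])
    calibrator_sample: str = "fibroblast"
    test_samples: list[str] = field(default_factory=list)
    star_thresholds: list[float] = field(default_factory=lambda: [0.05, 0.01, 0.001])


@dataclass
class ChipParams:
    antibody: str = "H3K27ac"
    star_thresholds: list[float] = field(default_factory=lambda: [0.05, 0.01, 0.001])


@dataclass
class DdpcrParams:
    target_assay: str = "PTBP3"
    reference_assay: str = "PBGD"
    calibrator_sample: str = "fibroblast"
    test_samples: list[str] = field(default_factory=list)


@dataclass
class RunConfig:
    inputs: InputPaths = field(default_factory=InputPaths)
    locus: LocusParams = field(default_factory=LocusParams)
    threec: ThreeCParams = field(default_factory=ThreeCParams)
    expression: ExpressionParams = field(default_factory=ExpressionParams)
    chip: ChipParams = field(default_factory=ChipParams)
    ddpcr: DdpcrParams = field(default_factory=DdpcrParams)
    output_dir: str = "loop3c_out"
    log_level: str = "INFO"
    seed: int = 0

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        _require_keys(d, set(cls.__dataclass_fields__), "run config")
        sections = {
            "inputs": InputPaths,
            "locus": LocusParams,
            "threec": ThreeCParams,
            "expression": ExpressionParams,
            "chip": ChipParams,
            "ddpcr": DdpcrParams,
        }
        kwargs = {}
        for key, klass in sections.items():
            sub = dict(d.get(key, {}) or {})
            _require_keys(sub, set(klass.__dataclass_fields__), key)
            kwargs[key] = klass(**sub)
        return cls(
            output_dir=str(d.get("output_dir", "loop3c_out")),
            log_level=str(d.get("log_level", "INFO")),
            seed=int(d.get("seed", 0)),
            **kwargs,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: run config must be a YAML mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)

    def write_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
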