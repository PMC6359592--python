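"""Plain-text readers and writers.

All formats are line-oriented text: CSV for plates and wells, TSV for
results and anchor maps, BED for intervals, YAML for configuration, JSON
for run summaries.  Plate parsing is strict: the header must carry exactly
the expected columns, malformed rows are rejected with their line number,
blank Cq wells are dropped with a warning, and a duplicated
(sample, assay, replicate) key keeps the last row (warned).
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import FormatError

logger = logging.getLogger(__name__)

PLATE_COLUMNS = ["sample", "assay", "replicate", "cq"]
PLATE_OPTIONAL = ["efficiency"]
CHIP_COLUMNS = ["cell_line", "region", "antibody", "experiment", "cq", "input_fraction"]
DDPCR_COLUMNS = ["sample", "assay", "positives", "total"]
DDPCR_OPTIONAL = ["droplet_volume_nl"]
QC_COLUMNS = [
    "library",
    "site",
    "cq_site_digested",
    "cq_ctrl_digested",
    "cq_site_undigested",
    "cq_ctrl_undigested",
]


def _check_header(
    path: Path, header: Sequence[str], required: Sequence[str], optional: Sequence[str]
) -> None:
    missing = [c for c in required if c not in header]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in header if c not in [*required, *optional]]
    if extra:
        raise FormatError(f"{path}: unexpected column(s) {extra}")


def read_plate_csv(path: str | Path) -> pd.DataFrame:
    """Read a qPCR plate CSV (sample, assay, replicate, cq[, efficiency])."""
    path = Path(path)
    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, no header")
        _check_header(path, reader.fieldnames, PLATE_COLUMNS, PLATE_OPTIONAL)
        has_eff = "efficiency" in reader.fieldnames
        for lineno, row in enumerate(reader, start=2):
            raw_cq = (row.get("cq") or "").strip()
            if not raw_cq:
                logger.warning("%s:%d: blank cq, row dropped", path, lineno)
                continue
            try:
                cq = float(raw_cq)
                replicate = int(row["replicate"])
                eff = float(row["efficiency"]) if has_eff and (row.get("efficiency") or "").strip() else 1.0
            except (TypeError, ValueError):
                logger.warning("%s:%d: malformed row rejected: %r", path, lineno, row)
                continue
            rows.append(
                {
                    "sample": row["sample"],
                    "assay": row["assay"],
                    "replicate": replicate,
                    "cq": cq,
                    "efficiency": eff,
                }
            )
    df = pd.DataFrame(rows, columns=[*PLATE_COLUMNS, "efficiency"])
    dup = df.duplicated(subset=["sample", "assay", "replicate"], keep="last")
    if dup.any():
        logger.warning(
            "%s: %d duplicated (sample, assay, replicate) key(s); keeping last",
            path,
            int(dup.sum()),
        )
        df = df[~dup].reset_index(drop=True)
    return df


def write_plate_csv(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in [*PLATE_COLUMNS, "efficiency"] if c in df.columns]
    df.to_csv(path, columns=cols, index=False)


def read_chip_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _check_header(path, list(df.columns), CHIP_COLUMNS, [])
    return df


def read_ddpcr_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _check_header(path, list(df.columns), DDPCR_COLUMNS, DDPCR_OPTIONAL)
    return df


def read_digestion_qc_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _check_header(path, list(df.columns), QC_COLUMNS, [])
    return df


def read_anchor_map(path: str | Path) -> pd.DataFrame:
    """Anchor map TSV: assay plus fragment_id and/or position (one needed)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if "assay" not in df.columns:
        raise FormatError(f"{path}: anchor map needs an 'assay' column")
    if "fragment_id" not in df.columns and "position" not in df.columns:
        raise FormatError(
            f"{path}: anchor map needs a 'fragment_id' or 'position' column"
        )
    return df


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_fasta(name: str, sequence: str, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i : i + width] + "\n")
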