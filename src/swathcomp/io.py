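"""Readers and writers for the pipeline's plain-text formats.

Everything is tab-separated UTF-8 with '.' decimals: the peptide report
(one row per sample x precursor observation), the design table, abundance
matrices, differential-abundance tables, plus FASTA for proteomes, JSON for
QC/enrichment/manifest and YAML for pipeline configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .digestion import Proteome
from .filtering import Design, PRECURSOR_COLS
from .quantify import AbundanceMatrix, LINEAR

logger = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "sample_id",
    "species",
    "sequence",
    "modifications",
    "charge",
    "genes",
    "intensity",
    "q_value",
]

DESIGN_COLUMNS = ["sample_id", "species", "group"]


def read_quant_report(path: str | Path) -> pd.DataFrame:
    """Read and validate a peptide-level quantification report."""
    df = pd.read_csv(path, sep="\t", dtype={"modifications": str}, keep_default_na=False)
    missing = [c for c in REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"report {path} is missing columns: {missing}")
    if df.empty:
        raise ValueError(f"report {path} contains no observations")
    for col in ("intensity", "q_value"):
        values = pd.to_numeric(df[col], errors="coerce")
        if values.isna().any():
            line = int(df.index[values.isna()][0]) + 2  # header + 1-based
            raise ValueError(f"non-numeric {col} at line {line} of {path}")
        df[col] = values
    df["charge"] = pd.to_numeric(df["charge"], errors="raise").astype(int)
    if ((df["q_value"] < 0) | (df["q_value"] > 1)).any():
        line = int(df.index[(df["q_value"] < 0) | (df["q_value"] > 1)][0]) + 2
        raise ValueError(f"q_value outside [0, 1] at line {line} of {path}")
    dup = df.duplicated(subset=["sample_id"] + PRECURSOR_COLS)
    if dup.any():
        line = int(df.index[dup][0]) + 2
        raise ValueError(f"duplicate (sample, precursor) observation at line {line} of {path}")
    return df[REPORT_COLUMNS]


def write_quant_report(report: pd.DataFrame, path: str | Path) -> None:
    report[REPORT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_design(path: str | Path, contrast: tuple[str, str] | None = None) -> Design:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"design {path} is missing columns: {missing}")
    return Design(table=df[DESIGN_COLUMNS], contrast=contrast)


def write_design(design: Design | pd.DataFrame, path: str | Path) -> None:
    table = design.table if isinstance(design, Design) else design
    table[DESIGN_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gene_set(path: str | Path) -> set[str]:
    """One symbol per line (or first TSV column); upper-cased, de-duplicated."""
    symbols: set[str] = set()
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            token = line.split("\t")[0].strip()
            if token and not token.startswith("#"):
                symbols.add(token.upper())
    if not symbols:
        raise ValueError(f"gene-set file {path} is empty")
    return symbols


def write_fasta(proteome: Proteome, path: str | Path, width: int = 60) -> None:
    """UniProt-style headers: >sp|ACC|ACC GN=GENE OS=species."""
    with open(path, "w", encoding="utf-8") as handle:
        for entry in proteome.entries:
            handle.write(
                f">sp|{entry.accession}|{entry.accession} GN={entry.gene} OS={proteome.species}\n"
            )
            seq = entry.sequence
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def write_matrix(matrix: AbundanceMatrix | pd.DataFrame, path: str | Path) -> None:
    data = matrix.data if isinstance(matrix, AbundanceMatrix) else matrix
    if isinstance(data.index, pd.MultiIndex):
        data = data.copy()
        data.index = ["/".join(str(part) for part in key) for key in data.index]
    data.to_csv(path, sep="\t", index_label="feature")


def read_matrix(path: str | Path, scale: str = LINEAR) -> AbundanceMatrix:
    data = pd.read_csv(path, sep="\t", index_col="feature")
    return AbundanceMatrix(data, scale=scale)


def write_json(payload: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(payload, handle, indent=2, sort_keys=True, default=_json_default)
        handle.write("\n")


def _json_default(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, np.ndarray):
        return value.tolist()
    raise TypeError(f"cannot serialize {type(value)!r}")


def sha256_file(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def load_yaml_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as handle:
        payload = yaml.safe_load(handle)
    if not isinstance(payload, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return payload
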