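"""TSV readers/writers for the pipeline's matrices and annotation tables.

Conventions
-----------
All matrices are plain UTF-8 TSV: a header row of sample ids and a first
column of feature ids. Missing values are forbidden — the longitudinal
design assumes a complete (feature x timepoint) grid, so an ``NA`` in the
input is a format error, not a value. Coordinates are 1-based.

In memory every matrix is a :class:`pandas.DataFrame`:

* expression — genes x timepoints, FPKM (non-negative)
* methylation — CpG probes x timepoints, beta values in [0, 1]
* composition — timepoints x cell types, proportions
* signature   — signature CpGs x cell types, mean beta per cell type
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("methdyn")

GENE_ANNOTATION_COLUMNS = ["gene_id", "chromosome", "tss", "strand"]
CPG_ANNOTATION_COLUMNS = ["probe_id", "chromosome", "position", "snp_overlap"]


class FormatError(ValueError):
    """Malformed input file or matrix."""


def _read_tsv_matrix(path: str | Path, what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    df.columns.name = None
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate {what} ids {dups[:5]}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate sample ids {dups[:5]}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric cell in matrix body ({exc})") from exc
    if df.isna().any().any():
        r, c = np.argwhere(df.isna().to_numpy())[0]
        raise FormatError(
            f"{path}: missing value at feature {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    return df


def validate_expression(df: pd.DataFrame, origin: str = "expression matrix") -> pd.DataFrame:
    """Check the invariants of an expression matrix (FPKM >= 0, unique ids)."""
    if df.index.has_duplicates:
        raise FormatError(f"{origin}: duplicate gene ids")
    if df.columns.has_duplicates:
        raise FormatError(f"{origin}: duplicate sample ids")
    vals = df.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise FormatError(f"{origin}: missing values are not allowed")
    if (vals < 0).any():
        r, c = np.argwhere(vals < 0)[0]
        raise FormatError(
            f"{origin}: negative FPKM {vals[r, c]} at gene {df.index[r]!r}, "
            f"sample {df.columns[c]!r}"
        )
    return df


def validate_methylation(df: pd.DataFrame, origin: str = "methylation matrix") -> pd.DataFrame:
    """Check the invariants of a methylation matrix (beta in [0, 1], unique ids)."""
    if df.index.has_duplicates:
        raise FormatError(f"{origin}: duplicate probe ids")
    if df.columns.has_duplicates:
        raise FormatError(f"{origin}: duplicate sample ids")
    vals = df.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise FormatError(f"{origin}: missing values are not allowed")
    if (vals < 0).any() or (vals > 1).any():
        bad = np.argwhere((vals < 0) | (vals > 1))[0]
        r, c = bad
        raise FormatError(
            f"{origin}: beta {vals[r, c]} outside [0, 1] at probe {df.index[r]!r}, "
            f"sample {df.columns[c]!r}"
        )
    return df


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes x timepoints FPKM matrix from TSV."""
    df = _read_tsv_matrix(path, "gene")
    validate_expression(df, origin=str(path))
    logger.info("read expression matrix %s: %d genes x %d samples", path, *df.shape)
    return df


def write_expression_matrix(df: pd.DataFrame, path: str | Path) -> None:
    validate_expression(df)
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_methylation_matrix(path: str | Path) -> pd.DataFrame:
    """Read a probes x timepoints beta-value matrix from TSV."""
    df = _read_tsv_matrix(path, "probe")
    validate_methylation(df, origin=str(path))
    logger.info("read methylation matrix %s: %d probes x %d samples", path, *df.shape)
    return df


def write_methylation_matrix(df: pd.DataFrame, path: str | Path) -> None:
    validate_methylation(df)
    df.to_csv(path, sep="\t", index_label="probe_id")


def read_composition_matrix(path: str | Path) -> pd.DataFrame:
    """Read a timepoints x cell types composition matrix from TSV."""
    df = _read_tsv_matrix(path, "sample")
    if (df.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative proportion")
    return df


def write_composition_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_signature_matrix(path: str | Path) -> pd.DataFrame:
    """Read a signature-CpGs x cell-types reference methylation matrix."""
    df = _read_tsv_matrix(path, "probe")
    validate_methylation(df, origin=str(path))
    if df.shape[1] < 2:
        raise FormatError(f"{path}: a reference signature needs >= 2 cell types")
    return df


def write_signature_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="probe_id")


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Read a gene annotation table (gene_id, chromosome, tss, strand)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chromosome": str})
    missing = set(GENE_ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    df = df[GENE_ANNOTATION_COLUMNS].copy()
    if df["gene_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate gene ids")
    if (df["tss"] < 1).any():
        raise FormatError(f"{path}: tss positions must be >= 1 (1-based)")
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise FormatError(f"{path}: strand must be '+' or '-' ({df.loc[bad, 'gene_id'].iloc[0]})")
    return df


def write_gene_annotation(df: pd.DataFrame, path: str | Path) -> None:
    df[GENE_ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_cpg_annotation(path: str | Path) -> pd.DataFrame:
    """Read a CpG annotation table (probe_id, chromosome, position, snp_overlap)."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chromosome": str})
    missing = set(CPG_ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    df = df[CPG_ANNOTATION_COLUMNS].copy()
    df["snp_overlap"] = df["snp_overlap"].astype(bool)
    if df["probe_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate probe ids")
    if (df["position"] < 1).any():
        raise FormatError(f"{path}: probe positions must be >= 1 (1-based)")
    return df


def write_cpg_annotation(df: pd.DataFrame, path: str | Path) -> None:
    df[CPG_ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_detection_p(path: str | Path) -> pd.DataFrame:
    """Read a probes x samples detection p-value matrix."""
    df = _read_tsv_matrix(path, "probe")
    vals = df.to_numpy()
    if (vals < 0).any() or (vals > 1).any():
        raise FormatError(f"{path}: detection p-values must lie in [0, 1]")
    return df
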