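"""Readers and writers for the tab-separated interchange formats.

All on-disk artifacts are plain text: the FPKM matrix and the normalized
matrix are gene x sample TSV tables whose first column is ``gene_id``; the
group file is a two-column TSV mapping sample identifiers to ``control`` or
``treated``; gene sets use the standard GMT dialect; run manifests are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

GROUP_LABELS = ("control", "treated")

_NORM_HEADER = "# permde normalized expression matrix (log2(FPKM+1) scale)"


def read_fpkm(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample FPKM matrix; first column is the gene identifier."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    if df.empty:
        raise ValueError(f"{path}: no genes found")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"{path}: non-numeric entries in expression matrix")
    if np.isnan(values).any():
        raise ValueError(f"{path}: missing values are not supported")
    if (values < 0).any():
        raise ValueError(f"{path}: negative FPKM values")
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicated gene identifiers")
    return df


def write_fpkm(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_groups(path: str | Path) -> pd.Series:
    """Read the sample -> group assignment (two columns: sample_id, group)."""
    table = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "group"],
                        dtype=str, comment="#")
    groups = pd.Series(table["group"].to_numpy(), index=table["sample_id"], name="group")
    labels = set(groups.unique())
    if not labels.issubset(set(GROUP_LABELS)) or len(labels) != 2:
        raise ValueError(
            f"{path}: groups must use exactly the labels {GROUP_LABELS}, got {sorted(labels)}"
        )
    return groups


def write_groups(groups: pd.Series, path: str | Path) -> None:
    groups.rename("group").to_csv(path, sep="\t", header=False, index_label="sample_id")


def read_truth(path: str | Path) -> pd.DataFrame:
    truth = pd.read_csv(path, sep="\t", index_col=0)
    truth.index = truth.index.astype(str)
    for col in ("is_de", "is_silent"):
        truth[col] = truth[col].astype(bool)
    return truth


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index_label="gene_id")


def write_normalized(df: pd.DataFrame, path: str | Path, steps: list[str]) -> None:
    """Write the normalized matrix with a provenance header recording applied steps."""
    with open(path, "w") as fh:
        fh.write(_NORM_HEADER + "\n")
        fh.write("# steps: " + ",".join(steps) + "\n")
        df.to_csv(fh, sep="\t", index_label="gene_id")


def read_normalized(path: str | Path) -> tuple[pd.DataFrame, list[str]]:
    """Read a normalized matrix, returning the values and the provenance steps."""
    steps: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# steps:"):
                steps = [s for s in line.split(":", 1)[1].strip().split(",") if s]
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    return df, steps


def write_de_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="gene_id")


def read_de_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index = table.index.astype(str)
    table["is_deg"] = table["is_deg"].astype(bool)
    return table


def write_enrichment(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
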