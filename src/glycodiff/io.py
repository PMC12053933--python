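"""Readers and writers for the delimited-text formats the pipelines consume.

Supported inputs: per-sample glycopeptide quantification tables (GlycReSoft-
style CSV/TSV), a sample sheet mapping sample ids to tumor/adjacent groups
(optionally with per-sample table paths), MaxQuant-style ``proteinGroups``
tables and a generic protein intensity dialect, and GMT gene-set files.
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import pandas as pd

from .glyco import RECORD_COLUMNS, GlycopeptideMatrix
from .proteomics import ProteinGroupTable

__all__ = [
    "read_sample_sheet",
    "read_glycopeptide_table",
    "read_glycopeptide_tables",
    "read_protein_groups",
    "read_gmt",
    "write_matrix",
]


def _read_delimited(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


def read_sample_sheet(path) -> pd.DataFrame:
    """Sample sheet: columns ``sample``, ``group`` and optionally ``path``."""
    sheet = _read_delimited(path)
    for col in ("sample", "group"):
        if col not in sheet.columns:
            raise ValueError(f"sample sheet lacks required column {col!r}")
    if sheet["sample"].duplicated().any():
        dupes = sheet.loc[sheet["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"duplicate sample ids in sample sheet: {dupes}")
    bad = set(sheet["group"]) - {"tumor", "adjacent"}
    if bad:
        raise ValueError(f"groups must be tumor/adjacent, got {sorted(bad)}")
    return sheet


def read_glycopeptide_table(path) -> pd.DataFrame:
    """One per-sample glycopeptide quantification table."""
    t = _read_delimited(path)
    missing = [c for c in RECORD_COLUMNS if c not in t.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return t


def read_glycopeptide_tables(sheet: pd.DataFrame, base_dir=None) -> dict[str, pd.DataFrame]:
    """Load every per-sample table referenced by a sample sheet's ``path``."""
    if "path" not in sheet.columns:
        raise ValueError("sample sheet has no 'path' column")
    tables = {}
    for _, row in sheet.iterrows():
        p = row["path"]
        if base_dir is not None and not os.path.isabs(p):
            p = os.path.join(base_dir, p)
        tables[row["sample"]] = read_glycopeptide_table(p)
    return tables


def read_protein_groups(
    path, groups: Mapping[str, str], dialect: str = "auto"
) -> ProteinGroupTable:
    """Read a protein-group intensity table.

    ``dialect="maxquant"`` expects the MaxQuant ``proteinGroups`` columns
    ("Majority protein IDs", "Gene names", per-sample "LFQ intensity <id>",
    and "+"-flagged "Reverse" / "Potential contaminant"); zero LFQ intensities
    are missing by MaxQuant convention. ``dialect="generic"`` expects columns
    ``protein``, ``gene``, ``reverse``, ``contaminant`` plus one column per
    sample id. ``"auto"`` sniffs the header.
    """
    t = pd.read_csv(path, sep="\t")
    if dialect == "auto":
        dialect = "maxquant" if "Majority protein IDs" in t.columns else "generic"
    groups = dict(groups)
    if dialect == "maxquant":
        proteins = t["Majority protein IDs"].astype(str).str.split(";").str[0]
        gene = (
            t["Gene names"].astype(str).str.split(";").str[0]
            if "Gene names" in t.columns
            else proteins
        )
        meta = pd.DataFrame(
            {
                "gene": gene.values,
                "reverse": (t.get("Reverse", "") == "+").values,
                "contaminant": (t.get("Potential contaminant", "") == "+").values,
            },
            index=proteins.values,
        )
        cols = {}
        for s in groups:
            col = f"LFQ intensity {s}"
            if col not in t.columns:
                raise ValueError(f"{path}: no column {col!r} for sample {s!r}")
            v = t[col].astype(float).replace(0.0, np.nan)
            cols[s] = v.values
        intens = pd.DataFrame(cols, index=proteins.values)
    elif dialect == "generic":
        t = t.set_index("protein")
        meta = pd.DataFrame(
            {
                "gene": t["gene"],
                "reverse": t["reverse"].astype(bool),
                "contaminant": t["contaminant"].astype(bool),
            }
        )
        intens = t[list(groups)].astype(float)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    meta.index.name = intens.index.name = "protein"
    return ProteinGroupTable(intensities=intens, meta=meta, groups=pd.Series(groups))


def read_gmt(path) -> dict[str, list[str]]:
    """GMT gene sets: one set per line, tab-separated name, description, genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, _desc, *genes = fields
            sets[name] = [g for g in genes if g]
    return sets


def write_matrix(m: GlycopeptideMatrix, path) -> None:
    """Write a merged glycopeptide matrix as TSV with a group header row."""
    out = m.abundance.copy()
    out.columns = pd.MultiIndex.from_tuples(
        [(c, m.groups[c]) for c in out.columns], names=["sample", "group"]
    )
    out.to_csv(path, sep="\t")
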