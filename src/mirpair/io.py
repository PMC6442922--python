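"""Readers and writers for the pipeline's plain-text interchange formats.

TSV with a header row is the table dialect throughout (counts, targets,
DE results, edges); the sample sheet is CSV; gene sets use the standard
GMT layout (set name, description, then member genes, tab-separated);
ortholog maps are two-column TSV.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .de import validate_sample_sheet
from .errors import ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "read_counts_tsv", "write_counts_tsv",
    "read_sample_sheet", "write_sample_sheet",
    "read_gmt", "write_gmt",
    "read_orthologs", "write_orthologs",
    "read_targets_tsv", "write_targets_tsv",
]


def read_counts_tsv(path) -> pd.DataFrame:
    """Read a miRNA x sample count matrix; entries must be non-negative integers.

    Errors name the offending cell (row label, column, line number).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"{path}: duplicate miRNA id {dup!r}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round()) | (vals < 0)
        if bad.any():
            i = int(bad.to_numpy().argmax())
            raise ValidationError(
                f"{path}: non-integer or negative count at row {df.index[i]!r}, "
                f"column {col!r} (line {i + 2})"
            )
    return df.astype(int)


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="mirna_id")


def read_sample_sheet(path) -> pd.DataFrame:
    """Read and validate the paired 2x2 sample sheet (CSV)."""
    sheet = pd.read_csv(path, dtype=str)
    return validate_sample_sheet(sheet)


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, index=False)


def read_gmt(path) -> dict[str, set[str]]:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValidationError(
                f"{path}: line {lineno}: GMT rows need name, description and >=1 gene"
            )
        name, genes = fields[0], [g for g in fields[2:] if g]
        if name in sets:
            raise ValidationError(f"{path}: line {lineno}: duplicate set name {name!r}")
        unique = set(genes)
        if len(unique) < len(genes):
            log.warning("%s: set %r has %d duplicate gene ids (collapsed)",
                        path, name, len(genes) - len(unique))
        sets[name] = unique
    return sets


def write_gmt(sets: dict[str, set[str]], path, description: str = "mirpair") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *sorted(genes)]) + "\n")


def read_orthologs(path) -> dict[str, str]:
    """Read a two-column TSV mapping species-A gene ids to species-B ids."""
    omap: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2 or not all(fields):
            raise ValidationError(f"{path}: line {lineno}: expected exactly two columns")
        a, b = fields
        if a in omap and omap[a] != b:
            raise ValidationError(
                f"{path}: line {lineno}: gene {a!r} mapped to both {omap[a]!r} and {b!r}"
            )
        omap[a] = b
    return omap


def write_orthologs(omap: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(omap.items()):
            fh.write(f"{a}\t{b}\n")


def read_targets_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_targets_tsv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False)
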