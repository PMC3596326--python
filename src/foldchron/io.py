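"""File formats: abundance TSV, NEXUS character blocks, Newick trees,
age/calibration tables.

The NEXUS writer emits a DATA block with the 24-symbol ordered alphabet
and an ASSUMPTIONS block recording the all-'N' ancestral states, so the
matrix remains usable in external parsimony software that polarizes
characters the same way.
"""

from __future__ import annotations

import re
from pathlib import Path

import dendropy
import pandas as pd

from .chronology import AgeTable
from .coding import (
    AbundanceMatrix,
    CharacterMatrix,
    SYMBOLS,
    parse_symbols,
    render_symbols,
)


# -- abundance matrices ------------------------------------------------------


def read_abundance_tsv(path) -> AbundanceMatrix:
    """Read a family x proteome count matrix.

    First column = family IDs, header row = proteome IDs, integer cells.
    Ragged rows, non-integer or negative cells and duplicate IDs are
    rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.isna().any().any():
        raise ValueError(f"{path}: ragged or missing cells in abundance matrix")
    try:
        values = df.astype(int)
    except ValueError as exc:
        raise ValueError(f"{path}: non-integer abundance cell ({exc})") from None
    neg = (values < 0)
    if neg.any().any():
        fam = values.index[neg.any(axis=1)][0]
        col = values.columns[neg.any(axis=0)][0]
        raise ValueError(f"{path}: negative count at family {fam!r}, proteome {col!r}")
    return AbundanceMatrix.from_dataframe(values)


def write_abundance_tsv(matrix: AbundanceMatrix, path) -> None:
    df = matrix.to_dataframe()
    df.index.name = "family"
    df.to_csv(path, sep="\t")


# -- NEXUS character matrices ------------------------------------------------


def write_nexus(cm: CharacterMatrix, path) -> None:
    """Write the polarized matrix as a NEXUS DATA + ASSUMPTIONS document."""
    rows = render_symbols(cm)
    width = max((len(t) for t in cm.taxa), default=0) + 2
    lines = [
        "#NEXUS",
        "",
        "BEGIN DATA;",
        f"    DIMENSIONS NTAX={cm.n_taxa} NCHAR={cm.n_characters};",
        f'    FORMAT DATATYPE=STANDARD SYMBOLS="{SYMBOLS}" MISSING=? GAP=-;',
        "    MATRIX",
    ]
    for taxon, row in zip(cm.taxa, rows):
        lines.append(f"        {_nexus_token(taxon):<{width}} {row}")
    lines += [
        "    ;",
        "END;",
        "",
        "BEGIN ASSUMPTIONS;",
        "    OPTIONS DEFTYPE=ORD POLYTCOUNT=MINSTEPS;",
        f"    ANCSTATES * polarized = N : 1-{cm.n_characters};",
        "END;",
        "",
    ]
    Path(path).write_text("\n".join(lines))


def _nexus_token(label: str) -> str:
    if re.fullmatch(r"[\w.]+", label):
        return label
    return "'" + label.replace("'", "''") + "'"


def read_nexus(path) -> CharacterMatrix:
    """Read back a NEXUS matrix written by :func:`write_nexus`."""
    text = Path(path).read_text()
    m = re.search(r"DIMENSIONS\s+NTAX=(\d+)\s+NCHAR=(\d+)\s*;", text, re.I)
    if not m:
        raise ValueError(f"{path}: missing DIMENSIONS line")
    ntax, nchar = int(m.group(1)), int(m.group(2))
    m = re.search(r"MATRIX(.*?);", text, re.S | re.I)
    if not m:
        raise ValueError(f"{path}: missing MATRIX block")
    taxa, rows = [], []
    for line in m.group(1).strip().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("'"):
            qm = re.match(r"'((?:[^']|'')*)'\s+(\S+)", line)
            if not qm:
                raise ValueError(f"{path}: malformed matrix row {line!r}")
            taxa.append(qm.group(1).replace("''", "'"))
            rows.append(qm.group(2))
        else:
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}: malformed matrix row {line!r}")
            taxa.append(parts[0])
            rows.append(parts[1])
    if len(taxa) != ntax or any(len(r) != nchar for r in rows):
        raise ValueError(f"{path}: matrix does not match declared dimensions")
    characters = [f"char{i + 1}" for i in range(nchar)]
    return parse_symbols(rows, taxa, characters)


# -- Newick trees ------------------------------------------------------------


def write_newick(tree: dendropy.Tree, path) -> None:
    Path(path).write_text(
        tree.as_string(schema="newick", suppress_rooting=False)
    )


def read_newick(path) -> dendropy.Tree:
    """Read a rooted tree; quoted labels (e.g. ccs with dots) are preserved."""
    text = Path(path).read_text()
    if text.count("(") != text.count(")"):
        pos = len(text)
        raise ValueError(f"{path}: unbalanced parentheses (scanned {pos} chars)")
    return dendropy.Tree.get(
        data=text,
        schema="newick",
        rooting="force-rooted",
        preserve_underscores=True,
    )


# -- age and calibration tables ---------------------------------------------


def write_age_table(ages: AgeTable, path) -> None:
    ages.to_dataframe().to_csv(path, sep="\t", index=False)


def read_age_table(path) -> AgeTable:
    df = pd.read_csv(path, sep="\t", dtype={"family": str})
    if "family" not in df.columns or "nd" not in df.columns:
        raise ValueError(f"{path}: age table needs 'family' and 'nd' columns")
    prov = (
        dict(zip(df["family"], df["provenance"]))
        if "provenance" in df.columns
        else None
    )
    return AgeTable(dict(zip(df["family"], df["nd"])), prov)


def read_calibration_tsv(path) -> pd.DataFrame:
    """Read (nd, age_gy[, label]) calibration pairs."""
    df = pd.read_csv(path, sep="\t")
    if "nd" not in df.columns or "age_gy" not in df.columns:
        raise ValueError(f"{path}: calibration needs 'nd' and 'age_gy' columns")
    return df
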