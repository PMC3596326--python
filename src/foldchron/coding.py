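"""Polarized multistate coding of fold-family abundance censuses.

A genomic census of domain structure yields a matrix of nonnegative
counts: how many copies of each fold family (FF) occur in each proteome.
For tree inference the matrix is recoded so that each proteome becomes a
single ordered multistate character with 24 states, written with the
symbols ``0``–``9`` then ``A``–``N``.  The maximal state ``N`` is the
plesiomorphic (ancestral) condition: the evolutionary model polarizes
change from high genomic abundance toward absence, so a hypothetical
all-``N`` ancestor roots the tree without an outgroup.
"""

from __future__ import annotations

import dataclasses
import re
from typing import Sequence

import numpy as np
import pandas as pd

#: 24-symbol ordered alphabet: digits 0-9 then letters A-N.
SYMBOLS = "0123456789ABCDEFGHIJKLMN"
#: Integer value of the ancestral (plesiomorphic) state, symbol 'N'.
ANCESTRAL_STATE = 23
#: Reserved taxon label of the hypothetical all-ancestral terminal.
ANCESTOR_LABEL = "ANCESTOR"

_CCS_RE = re.compile(r"^([a-z])\.(\d+)\.(\d+)\.(\d+)$")


@dataclasses.dataclass(frozen=True)
class ConciseClassification:
    """A SCOP concise classification string (ccs), e.g. ``c.23.16.1``.

    The four dot-separated fields name the protein class, fold (F), fold
    superfamily (FSF) and fold family (FF).
    """

    scop_class: str
    fold_id: int
    fsf_id: int
    ff_id: int

    @classmethod
    def parse(cls, text: str) -> "ConciseClassification":
        m = _CCS_RE.match(text.strip())
        if m is None:
            raise ValueError(
                f"not a concise classification string (class.F.FSF.FF): {text!r}"
            )
        return cls(m.group(1), int(m.group(2)), int(m.group(3)), int(m.group(4)))

    def __str__(self) -> str:
        return f"{self.scop_class}.{self.fold_id}.{self.fsf_id}.{self.ff_id}"

    @property
    def fsf(self) -> str:
        """The enclosing fold superfamily, e.g. ``c.23.16`` for ``c.23.16.1``."""
        return f"{self.scop_class}.{self.fold_id}.{self.fsf_id}"


def fsf_of(ccs: str) -> str:
    """Return the FSF prefix of a ccs, e.g. ``c.23.16.1`` -> ``c.23.16``."""
    return ConciseClassification.parse(ccs).fsf


class AbundanceMatrix:
    """Nonnegative fold-family x proteome copy-number counts.

    Rows are fold families (the phylogenetic taxa), columns are proteomes
    (the phylogenetic characters).
    """

    def __init__(
        self,
        counts: np.ndarray | Sequence[Sequence[int]],
        family_ids: Sequence[str],
        proteome_ids: Sequence[str],
    ):
        counts = np.asarray(counts, dtype=np.int64)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if counts.shape != (len(family_ids), len(proteome_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(family_ids)} families x {len(proteome_ids)} proteomes"
            )
        if (counts < 0).any():
            f, p = map(int, np.argwhere(counts < 0)[0])
            raise ValueError(
                f"negative count for family {family_ids[f]!r}, proteome {proteome_ids[p]!r}"
            )
        for kind, ids in (("family", family_ids), ("proteome", proteome_ids)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {kind} IDs")
        self.counts = counts
        self.family_ids = list(family_ids)
        self.proteome_ids = list(proteome_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "AbundanceMatrix":
        return cls(df.to_numpy(), [str(i) for i in df.index], [str(c) for c in df.columns])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.family_ids, columns=self.proteome_ids)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, AbundanceMatrix)
            and self.family_ids == other.family_ids
            and self.proteome_ids == other.proteome_ids
            and np.array_equal(self.counts, other.counts)
        )

    def __repr__(self) -> str:
        return f"<AbundanceMatrix {self.shape[0]} families x {self.shape[1]} proteomes>"


class CharacterMatrix:
    """24-state polarized character matrix; taxa = fold families.

    ``states`` holds integers in [0, 23] with shape (n_taxa, n_characters).
    The hypothetical ancestor (all states 23, symbol 'N') is implicit: it
    is attached by the tree-inference machinery and is never counted as a
    data taxon here.
    """

    def __init__(
        self,
        states: np.ndarray,
        taxa: Sequence[str],
        characters: Sequence[str],
    ):
        states = np.asarray(states, dtype=np.int16)
        if states.shape != (len(taxa), len(characters)):
            raise ValueError("states shape does not match taxa x characters")
        if states.size and (states.min() < 0 or states.max() > ANCESTRAL_STATE):
            raise ValueError("states must lie in [0, 23]")
        self.states = states
        self.taxa = list(taxa)
        self.characters = list(characters)

    @property
    def n_taxa(self) -> int:
        return self.states.shape[0]

    @property
    def n_characters(self) -> int:
        return self.states.shape[1]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CharacterMatrix)
            and self.taxa == other.taxa
            and self.characters == other.characters
            and np.array_equal(self.states, other.states)
        )

    def __repr__(self) -> str:
        return f"<CharacterMatrix {self.n_taxa} taxa x {self.n_characters} characters>"


def encode_abundance(matrix: AbundanceMatrix, scale: str = "log") -> CharacterMatrix:
    """Recode counts into 24 ordered states, normalized per proteome.

    With the default ``scale="log"`` a count ``n`` in proteome ``p`` maps to
    ``round(23 * ln(n + 1) / ln(n_max(p) + 1))`` where ``n_max(p)`` is the
    largest count in that proteome; ``scale="linear"`` uses
    ``round(23 * n / n_max(p))``.  Absent families (n = 0) get state 0 and
    the most abundant family in each proteome gets the maximal state 23.
    Rounding is half-up, so the map is monotone in ``n`` within a column.

    Raises ``ValueError`` for an all-zero proteome column, whose
    normalization would be undefined.
    """
    if scale not in ("log", "linear"):
        raise ValueError(f"unknown scale {scale!r}; use 'log' or 'linear'")
    counts = matrix.counts
    col_max = counts.max(axis=0)
    zero_cols = np.flatnonzero(col_max == 0)
    if zero_cols.size:
        raise ValueError(
            f"proteome {matrix.proteome_ids[int(zero_cols[0])]!r} has no fold "
            "family occurrences; per-proteome normalization is undefined"
        )
    if scale == "log":
        scaled = np.log1p(counts) / np.log1p(col_max)
    else:
        scaled = counts / col_max
    states = np.floor(ANCESTRAL_STATE * scaled + 0.5).astype(np.int16)
    return CharacterMatrix(states, matrix.family_ids, matrix.proteome_ids)


def drop_empty_proteomes(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Drop proteome columns in which no fold family occurs.

    Real censuses never contain such proteomes (every proteome is made of
    domains); they arise in simulations that track only a small subset of
    families.  Removing them restores the encoding precondition without
    touching any informative column.
    """
    keep = matrix.counts.max(axis=0) > 0
    if keep.all():
        return matrix
    return AbundanceMatrix(
        matrix.counts[:, keep],
        matrix.family_ids,
        [p for p, k in zip(matrix.proteome_ids, keep) if k],
    )


def state_to_symbol(state: int) -> str:
    if not 0 <= state <= ANCESTRAL_STATE:
        raise ValueError(f"state {state} outside [0, 23]")
    return SYMBOLS[state]


def symbol_to_state(symbol: str) -> int:
    try:
        return SYMBOLS.index(symbol.upper())
    except ValueError:
        raise ValueError(f"unknown state symbol {symbol!r}") from None


def render_symbols(cm: CharacterMatrix) -> list[str]:
    """Render each taxon's states as a string over the 24-symbol alphabet."""
    lut = np.array(list(SYMBOLS))
    return ["".join(lut[row]) for row in cm.states]


def parse_symbols(rows: Sequence[str], taxa: Sequence[str], characters: Sequence[str]) -> CharacterMatrix:
    """Inverse of :func:`render_symbols`."""
    states = np.array([[symbol_to_state(s) for s in row] for row in rows], dtype=np.int16)
    return CharacterMatrix(states, taxa, characters)
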