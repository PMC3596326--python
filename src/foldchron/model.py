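"""Model/Results interface over the chronology pipeline.

:class:`FoldChronology` wraps an abundance census the way statistical
modelling packages wrap a dataset: construct it from a matrix (or TSV),
call :meth:`~FoldChronology.fit` to run the polarized encoding and the
maximum-parsimony search, and read estimates off the returned
:class:`ChronologyResults` — the tree, its parsimony score, the
node-distance age of every fold family, and geological ages under a
structure clock.
"""

from __future__ import annotations

import pandas as pd

from . import atlas
from .chronology import (
    AgeTable,
    FOLD_CLOCK,
    MolecularClock,
    clock_age,
    node_distances,
)
from .coding import AbundanceMatrix, CharacterMatrix, encode_abundance
from .parsimony import SearchConfig, SearchResult, search_mp


class FoldChronology:
    """Chronology model for a fold-family x proteome abundance census.

    Parameters
    ----------
    abundance:
        The census matrix (families x proteomes, nonnegative counts).
    scale:
        Count-to-state transform, ``"log"`` (default) or ``"linear"``.
    """

    def __init__(self, abundance: AbundanceMatrix, scale: str = "log"):
        self.abundance = abundance
        self.scale = scale
        self.character_matrix: CharacterMatrix = encode_abundance(abundance, scale)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, scale: str = "log") -> "FoldChronology":
        return cls(AbundanceMatrix.from_dataframe(df), scale)

    @classmethod
    def from_tsv(cls, path, scale: str = "log") -> "FoldChronology":
        from .io import read_abundance_tsv

        return cls(read_abundance_tsv(path), scale)

    def fit(
        self,
        search: SearchConfig | None = None,
        normalization: str = "minmax",
    ) -> "ChronologyResults":
        """Infer the rooted tree and node-distance ages.

        ``search`` configures the parsimony search (seed included);
        ``normalization`` selects the depth rescaling of
        :func:`~foldchron.chronology.node_distances`.
        """
        result = search_mp(self.character_matrix, search)
        ages = node_distances(result.tree, normalization)
        return ChronologyResults(self, result, ages)

    def __repr__(self) -> str:
        a = self.abundance
        return f"<FoldChronology {a.shape[0]} families x {a.shape[1]} proteomes, scale={self.scale}>"


class ChronologyResults:
    """Fitted chronology: tree, score, and relative/geological ages."""

    def __init__(self, model: FoldChronology, search_result: SearchResult, ages: AgeTable):
        self.model = model
        self.tree = search_result.tree
        self.score = search_result.score
        self.n_cooptimal = search_result.n_cooptimal
        self.newick = search_result.newick
        self.ages = ages

    def ages_gy(self, clock: MolecularClock = FOLD_CLOCK) -> pd.DataFrame:
        """Age table with geological ages appended under ``clock``."""
        df = self.ages.to_dataframe()
        df["age_gy"] = [clock_age(nd, clock) for nd in df["nd"]]
        return df

    def timeline(self, network: atlas.EnzymeNetwork, clock: MolecularClock = FOLD_CLOCK):
        """Per-pathway first-appearance/completion timelines on this fit's ages."""
        return atlas.build_timeline(network, self.ages, clock)

    def paint(self, network: atlas.EnzymeNetwork):
        """Age-painted network graph using this fit's ages."""
        return atlas.paint_network(network, self.ages)

    def summary(self, clock: MolecularClock = FOLD_CLOCK) -> str:
        a = self.model.abundance
        df = self.ages_gy(clock).sort_values(["nd", "family"]).reset_index(drop=True)
        lines = [
            "Fold-family chronology (maximum parsimony, polarized abundance characters)",
            "=" * 74,
            f"Families (taxa):        {a.shape[0]}",
            f"Proteomes (characters): {a.shape[1]}",
            f"Coding scale:           {self.model.scale}",
            f"Tree length (steps):    {self.score}",
            f"Co-optimal trees seen:  {self.n_cooptimal}",
            f"Clock: t = {clock.slope:+.3f} nd {clock.intercept:+.3f} Gy ({clock.level})",
            "-" * 74,
            f"{'family':<20} {'nd':>8} {'age_gy':>8}  provenance",
        ]
        for _, row in df.iterrows():
            lines.append(
                f"{row['family']:<20} {row['nd']:>8.3f} {row['age_gy']:>8.3f}  {row['provenance']}"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<ChronologyResults score={self.score}, "
            f"{len(self.ages)} dated families, {self.n_cooptimal} co-optimal>"
        )
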