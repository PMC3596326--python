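"""Packaged purine-metabolism fixture.

Ships the node-distance ages of the 11 fold families that build the core
of purine metabolism (KEGG NUC 00230) together with a small enzymatic
network linking them, via EC numbers, to the nucleotide interconversion
(INT), biosynthesis (BIO) and catabolism-and-salvage (CAT) pathways.
The ages come from a published chronology of fold families censused in
free-living proteomes; the network records which steps share domains
across and within pathways.  Two peripheral entries are carried for
context: PRPP synthetase (pentose phosphate, label CAR) and the
adenylosuccinate branch.  The EC of the GMP/GDP kinase step is the
canonical guanylate kinase number, chosen editorially: the source
chronology names only the fold family and its role.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .atlas import EnzymeNetwork
from .chronology import AgeTable

#: nd interval over which the BIO enzymatic repertoire was established.
BIO_ESTABLISHMENT_WINDOW = (0.057, 0.367)

#: nd at which all central BIO enzymes are in place (reported completion;
#: the youngest central BIO family, SAICAR synthase d.143.1.1, sits at 0.188 —
#: the two differ by printed rounding and both are carried).
BIO_COMPLETION_ND = 0.187


def _data_path(name: str):
    return resources.files("foldchron.data").joinpath(name)


def load_purine_fixture() -> tuple[AgeTable, EnzymeNetwork]:
    """Load the packaged purine-metabolism ages and enzyme network.

    Returns the 11-family age table (e.g. ``c.23.16.1`` -> 0.057,
    ``d.143.1.1`` -> 0.188) and the EC/pathway/ccs network.
    """
    with resources.as_file(_data_path("purine_ages.tsv")) as p:
        ages_df = pd.read_csv(p, sep="\t", dtype={"family": str, "nd": float})
    ages = AgeTable(dict(zip(ages_df["family"], ages_df["nd"])))
    with resources.as_file(_data_path("purine_network.tsv")) as p:
        net = EnzymeNetwork.from_tsv(p)
    return ages, net
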