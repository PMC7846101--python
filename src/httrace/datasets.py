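"""Built-in example data: the sea-snake HTT survey.

A dated elapid phylogeny (ages in Ma, within the ranges reported for
the group: sea kraits diverging ~25 Ma, the sea snake radiation inside
the last ~18 Ma) and the presence/absence of the seven
horizontally transferred LINE subfamilies found in the olive sea snake
(Aipysurus laevis) across seven elapid genomes, as established by
reciprocal screening: RTE-Snek_1 restricted to A. laevis; Proto2-Snek
shared with Emydocephalus ijimae; Rex1-Snek_1H1, Rex1-Snek_2 and
RTE-Snek_2 shared with E. ijimae and Hydrophis melanocephalus;
Rex1-Snek_1H2 and Rex1-Snek_1H3 in A. laevis and H. melanocephalus but
not E. ijimae (hence two independent transfers each).  Gain parsimony
on this matrix yields nine transfer events.
"""
from __future__ import annotations

from .io_formats import DatedTree

ELAPID_TREE_NEWICK = (
    "(Ophiophagus_hannah:30,(Laticauda_colubrina:25,"
    "((Notechis_scutatus:10,Pseudonaja_textilis:10):6,"
    "(Hydrophis_melanocephalus:8,"
    "(Emydocephalus_ijimae:5,Aipysurus_laevis:5):3):8):9):5):0;"
)

ELAPID_SPECIES = [
    "Ophiophagus_hannah", "Laticauda_colubrina", "Pseudonaja_textilis",
    "Notechis_scutatus", "Hydrophis_melanocephalus", "Emydocephalus_ijimae",
    "Aipysurus_laevis",
]

_AIP = "Aipysurus_laevis"
_EMY = "Emydocephalus_ijimae"
_HYD = "Hydrophis_melanocephalus"

SEA_SNAKE_PRESENCE: dict[str, set[str]] = {
    "Rex1-Snek_1H1": {_AIP, _EMY, _HYD},
    "Rex1-Snek_1H2": {_AIP, _HYD},
    "Rex1-Snek_1H3": {_AIP, _HYD},
    "Rex1-Snek_2": {_AIP, _EMY, _HYD},
    "RTE-Snek_1": {_AIP},
    "RTE-Snek_2": {_AIP, _EMY, _HYD},
    "Proto2-Snek": {_AIP, _EMY},
}


def elapid_tree() -> DatedTree:
    return DatedTree.from_newick(ELAPID_TREE_NEWICK)


def sea_snake_presence_matrix() -> dict[str, dict[str, bool]]:
    """Family -> species -> present (the high-identity presence calls)."""
    return {fam: {sp: sp in present for sp in ELAPID_SPECIES}
            for fam, present in SEA_SNAKE_PRESENCE.items()}
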