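"""The canonical 37-gene vocabulary of bilaterian mitochondrial genomes.

Gene symbols follow the conventional abbreviation scheme for animal mt
genomes: 13 protein-coding genes (PCGs), two rRNA genes, and 22 tRNA genes
named by the single-letter code of their amino acid.  The two leucine and
two serine tRNAs are disambiguated by anticodon family: L1 carries a NAG
anticodon, L2 a YAA anticodon, S1 a NCU anticodon and S2 a NGA anticodon.
"""

from __future__ import annotations

PROTEIN_CODING: tuple[str, ...] = (
    "atp6", "atp8", "cob", "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
)

RRNA: tuple[str, ...] = ("rrnS", "rrnL")

#: anticodons of the 22 mt tRNAs of the rat lice (RNA alphabet)
TRNA_ANTICODON: dict[str, str] = {
    "trnA": "UGC",
    "trnC": "GCA",
    "trnD": "GUC",
    "trnE": "UUC",
    "trnF": "GAA",
    "trnG": "UCC",
    "trnH": "GUG",
    "trnI": "GAU",
    "trnK": "UUU",
    "trnL1": "UAG",
    "trnL2": "UAA",
    "trnM": "CAU",
    "trnN": "GUU",
    "trnP": "UGG",
    "trnQ": "UUG",
    "trnR": "UCG",
    "trnS1": "UCU",
    "trnS2": "UGA",
    "trnT": "UGU",
    "trnV": "UAC",
    "trnW": "UCA",
    "trnY": "GUA",
}

TRNA: tuple[str, ...] = tuple(sorted(TRNA_ANTICODON))

#: the closed 37-symbol vocabulary
CANONICAL_GENES: frozenset[str] = frozenset(PROTEIN_CODING) | frozenset(RRNA) | frozenset(TRNA)

PSEUDO_PREFIX = "pseudo-"

#: paralogous tRNA families whose members can exchange identities
TRNA_FAMILY: dict[str, str] = {"trnL1": "L", "trnL2": "L", "trnS1": "S", "trnS2": "S"}


def category_of(name: str) -> str:
    """Return the category (PCG / rRNA / tRNA / pseudogene) of a gene symbol."""
    if name.startswith(PSEUDO_PREFIX):
        return "pseudogene"
    if name in PROTEIN_CODING:
        return "PCG"
    if name in RRNA:
        return "rRNA"
    if name in TRNA_ANTICODON:
        return "tRNA"
    raise ValueError(f"unknown gene symbol: {name!r}")


def is_canonical(name: str) -> bool:
    return name in CANONICAL_GENES


def is_trna(name: str) -> bool:
    return name in TRNA_ANTICODON


def is_valid_symbol(name: str) -> bool:
    """True for canonical symbols and ``pseudo-`` forms of them."""
    if name.startswith(PSEUDO_PREFIX):
        return name[len(PSEUDO_PREFIX):] in CANONICAL_GENES
    return name in CANONICAL_GENES
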