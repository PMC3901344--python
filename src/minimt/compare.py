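"""Cross-species comparison of minichromosome arrangements.

Compares arrangement catalogs (identical minichromosomes, tRNA
distribution differences), reconstructs ancestral presence of junction
characters on the fixed louse phylogeny under Dollo parsimony (a derived
arrangement arises once and can only be lost), and classifies the
rearrangement events separating an ancestral catalog from a derived one
into translocations, identity swaps and pseudogenisations.

A tRNA's "distribution" is keyed by its host minichromosome, identified by
the set of protein-coding and rRNA genes it carries; position changes
within an unchanged host do not count as distribution differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib

from . import genes as _genes
from .model import (ArrangementCatalog, FragmentedGenome, Phylogeny,
                    canonical_rotation)


@dataclass
class JunctionCharacter:
    """Presence/absence of a gene adjacency or whole-minichromosome state."""

    name: str
    kind: str  # adjacency | arrangement | minichromosome
    state: str
    present_in: frozenset[str]


def characters_from_table(df) -> list[JunctionCharacter]:
    """Build characters from the packaged junction table."""
    return [
        JunctionCharacter(
            name=r.name, kind=r.kind, state=r.state,
            present_in=frozenset(r.present_in.split(",")))
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# catalog comparison

@dataclass
class CatalogComparison:
    identical_minichromosomes: list[tuple[str, str]]
    differing_trnas: frozenset[str]
    differing_pcg_rrna: frozenset[str]

    @property
    def n_identical(self) -> int:
        return len(self.identical_minichromosomes)


def compare_catalogs(cat_a: ArrangementCatalog, cat_b: ArrangementCatalog
                     ) -> CatalogComparison:
    """Identical minichromosomes and genes whose host minichromosome differs.

    Minichromosomes count as identical when they have the same gene
    content, circular order and orientation (rotation-invariant).  A gene's
    host is keyed by the PCG/rRNA content of its minichromosome, so both
    members of an identity swap count as differing.
    """
    for cat in (cat_a, cat_b):
        if not cat.is_complete:
            raise ValueError(f"{cat.species}: catalog is not complete (37 genes)")

    canon_b = {canonical_rotation(e): mid for mid, e in cat_b.entries.items()}
    identical = [
        (mid, canon_b[canonical_rotation(e)])
        for mid, e in sorted(cat_a.entries.items())
        if canonical_rotation(e) in canon_b
    ]

    def hosts(cat: ArrangementCatalog) -> dict[str, frozenset[str]]:
        return {g: cat.host_key(mid)
                for mid, entry in cat.entries.items() for g, _ in entry}

    ha, hb = hosts(cat_a), hosts(cat_b)
    moved = frozenset(g for g in ha if ha[g] != hb[g])
    return CatalogComparison(
        identical_minichromosomes=identical,
        differing_trnas=frozenset(g for g in moved if _genes.is_trna(g)),
        differing_pcg_rrna=frozenset(g for g in moved if not _genes.is_trna(g)),
    )


# ---------------------------------------------------------------------------
# Dollo ancestral-state inference

def infer_ancestral_states(
    characters: list[JunctionCharacter],
    tree: Phylogeny,
) -> dict[str, dict[str, str]]:
    """Per character and internal node: present / absent / ambiguous.

    Dollo reconstruction: the state arises once, at the MRCA of the leaves
    showing it, and every node on a path from that gain to a present leaf
    is present.  A node whose subtree contains the state in only one child
    and which is not below the gain (including the single-leaf case, where
    the gain cannot be localised) is ambiguous; a node with no present
    leaves below it is absent.
    """
    leaf_set = set(tree.leaf_names)
    out: dict[str, dict[str, str]] = {}
    for ch in characters:
        unknown = ch.present_in - leaf_set
        if unknown:
            raise ValueError(f"{ch.name}: unknown species {sorted(unknown)}")
        present = ch.present_in
        states: dict[str, str] = {}
        gain = tree.tree.common_ancestor(list(present)) if present else None
        gain_leaves = tree.leaves_under(gain) if gain is not None else frozenset()
        for i, node in enumerate(tree.internal_nodes()):
            name = node.name or f"node{i}"
            below = tree.leaves_under(node)
            hit_children = sum(
                1 for child in node.clades
                if tree.leaves_under(child) & present)
            if not below & present:
                states[name] = "absent"
            elif hit_children >= 2:
                states[name] = "present"
            elif gain is not None and below < gain_leaves:
                # pass-through node inside the spanning subtree of the gain
                states[name] = "present"
            else:
                states[name] = "ambiguous"
        out[ch.name] = states
    return out


# ---------------------------------------------------------------------------
# rearrangement-event classification

@dataclass
class RearrangementEvent:
    """A classified difference between an ancestral and a derived arrangement."""

    type: str  # translocation | identity_swap | pseudogenization
    genes: tuple[str, ...]
    source_context: tuple | None = None
    dest_context: tuple | None = None
    evidence: str = "arrangement_only"
    lineage: str = "unassigned"

    def key(self) -> tuple[str, frozenset[str]]:
        """Identity of the event irrespective of context details."""
        return (self.type, frozenset(self.genes))


def _neighbors(entry, i: int) -> tuple[str, str]:
    n = len(entry)
    return entry[(i - 1) % n][0], entry[(i + 1) % n][0]


def _positions(cat: ArrangementCatalog) -> dict[str, tuple[str, int]]:
    return {g: (mid, i)
            for mid, entry in cat.entries.items()
            for i, (g, _) in enumerate(entry)}


def _edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def classify_events(
    ancestral: ArrangementCatalog,
    derived: ArrangementCatalog,
    ancestral_genome: FragmentedGenome | None = None,
    derived_genome: FragmentedGenome | None = None,
    lineage: str = "unassigned",
) -> list[RearrangementEvent]:
    """Classify the per-gene differences between two complete catalogs.

    tRNAs whose host minichromosome (PCG/rRNA key) changed are candidate
    moves.  Two same-family tRNAs that exactly exchange contexts — each
    derived gene sits where the other sat ancestrally — are one
    identity-swap event (confirmed, when genomes are supplied, by each
    derived gene being more similar to the ancestral occupant of its site
    than to its own ancestral copy); remaining moves are translocations,
    with blocks of genes that stay adjacent moving as one event.  A
    pseudogene remnant at the ancestral site attaches remnant evidence.
    """
    for cat in (ancestral, derived):
        if not cat.is_complete:
            raise ValueError(f"{cat.species}: catalog is not complete")

    pos_a, pos_d = _positions(ancestral), _positions(derived)
    host_a = {g: ancestral.host_key(mid) for g, (mid, _) in pos_a.items()}
    host_d = {g: derived.host_key(mid) for g, (mid, _) in pos_d.items()}
    moved = sorted(g for g in host_a
                   if _genes.is_trna(g) and host_a[g] != host_d[g])

    events: list[RearrangementEvent] = []

    def ctx(cat: ArrangementCatalog, positions, gene: str) -> tuple:
        mid, i = positions[gene]
        return (cat.host_key(mid), _neighbors(cat.entries[mid], i))

    # identity swaps: exact context exchange between same-family genes
    swapped: set[str] = set()
    for a in list(moved):
        if a in swapped or a not in _genes.TRNA_FAMILY:
            continue
        fam = _genes.TRNA_FAMILY[a]
        for b in moved:
            if b <= a or b in swapped or _genes.TRNA_FAMILY.get(b) != fam:
                continue
            if ctx(derived, pos_d, a) == ctx(ancestral, pos_a, b) and \
               ctx(derived, pos_d, b) == ctx(ancestral, pos_a, a):
                evidence = "arrangement_only"
                if ancestral_genome is not None and derived_genome is not None:
                    def seq(genome: FragmentedGenome, gene: str) -> str:
                        mc, ann = genome.find_gene(gene)
                        return mc.gene_sequence(ann)
                    ok = (
                        _edit_distance(seq(derived_genome, a), seq(ancestral_genome, b))
                        < _edit_distance(seq(derived_genome, a), seq(ancestral_genome, a))
                        and
                        _edit_distance(seq(derived_genome, b), seq(ancestral_genome, a))
                        < _edit_distance(seq(derived_genome, b), seq(ancestral_genome, b))
                    )
                    if not ok:
                        continue  # contexts exchanged but sequences disagree
                    evidence = "sequence_similarity"
                events.append(RearrangementEvent(
                    type="identity_swap", genes=(a, b),
                    evidence=evidence, lineage=lineage))
                swapped.update((a, b))
                break
    moved = [g for g in moved if g not in swapped]

    # group remaining moves into blocks adjacent in both catalogs
    blocks: list[list[str]] = []
    used: set[str] = set()
    for g in moved:
        if g in used:
            continue
        mid_a, i_a = pos_a[g]
        block = [g]
        entry_a = ancestral.entries[mid_a]
        j = i_a
        while True:  # extend rightwards through co-moving adjacent genes
            j += 1
            if j >= len(entry_a):
                break
            nxt = entry_a[j][0]
            if nxt not in moved or nxt in used:
                break
            mid_d, i_d = pos_d[block[-1]]
            mid_d2, i_d2 = pos_d[nxt]
            if mid_d2 != mid_d or i_d2 != i_d + 1:
                break
            block.append(nxt)
        used.update(block)
        blocks.append(block)

    pseudo_names = {p for ps in derived.pseudogenes.values() for p in ps}
    for block in blocks:
        first, last = block[0], block[-1]
        mid_a, i_first = pos_a[first]
        _, i_last = pos_a[last]
        src = (_neighbors(ancestral.entries[mid_a], i_first)[0],
               _neighbors(ancestral.entries[mid_a], i_last)[1])
        mid_d, i_d = pos_d[first]
        _, j_d = pos_d[last]
        dst = (_neighbors(derived.entries[mid_d], i_d)[0],
               _neighbors(derived.entries[mid_d], j_d)[1])
        evidence = "arrangement_only"
        if f"{_genes.PSEUDO_PREFIX}{first}" in pseudo_names:
            evidence = "pseudogene_remnant"
        elif ancestral_genome is not None and derived_genome is not None:
            evidence_hit = _remnant_at_source(
                ancestral_genome, derived_genome, first, src)
            if evidence_hit:
                evidence = "pseudogene_remnant"
        events.append(RearrangementEvent(
            type="translocation", genes=tuple(block),
            source_context=src, dest_context=dst,
            evidence=evidence, lineage=lineage))

    events.sort(key=lambda e: (e.type, e.genes))
    return events


def _remnant_at_source(
    ancestral_genome: FragmentedGenome,
    derived_genome: FragmentedGenome,
    gene: str,
    src_flanks: tuple[str | None, str | None],
) -> bool:
    """Look for a remnant of ``gene`` between its ancestral flanks."""
    from .annotate import detect_pseudogene  # deferred: avoids import cycle

    left, right = src_flanks
    if left is None or right is None:
        return False
    try:
        mc_l, ann_l = derived_genome.find_gene(left)
        mc_r, ann_r = derived_genome.find_gene(right)
    except KeyError:
        return False
    if mc_l.id != mc_r.id:
        return False
    lo, hi = sorted((ann_l.end, ann_r.start)) if ann_l.end <= ann_r.start \
        else sorted((ann_r.end, ann_l.start))
    if hi - lo < 20:
        return False
    intergenic = mc_l.fetch(lo, hi)
    mc_g, ann_g = ancestral_genome.find_gene(gene)
    return bool(detect_pseudogene(intergenic, mc_g.gene_sequence(ann_g)))
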