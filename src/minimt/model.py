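"""Domain types for fragmented mitochondrial genomes.

A fragmented mt genome is a set of small circular chromosomes
("minichromosomes"), each carrying a subset of the 37 canonical mt genes in
a coding region, plus a non-coding region (NCR) that is well conserved
across the minichromosomes of one species.  Coordinates are 0-based
half-open on the circle; ``end`` may exceed the sequence length to encode
origin-spanning features (positions are taken modulo the length).  The
origin is fixed at the first base of the coding region's first gene on the
reference strand, and the reference strand is the strand on which the
majority of genes are transcribed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Iterable, Iterator

from Bio import Phylo, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import genes as _genes

Span = tuple[int, int]

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneAnnotation:
    """One gene feature on a circular minichromosome.

    ``orientation`` is '+' or '-' relative to the reference strand of the
    non-coding region.  tRNA annotations carry a non-empty (RNA-alphabet)
    anticodon; all other categories carry none.
    """

    name: str
    category: str
    start: int
    end: int
    orientation: str
    anticodon: str = ""

    def __post_init__(self) -> None:
        if not _genes.is_valid_symbol(self.name):
            raise ValueError(f"unknown gene symbol: {self.name!r}")
        expected = _genes.category_of(self.name)
        if self.category != expected:
            raise ValueError(
                f"{self.name}: category {self.category!r}, expected {expected!r}")
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"{self.name}: bad interval [{self.start}, {self.end})")
        if self.orientation not in ("+", "-"):
            raise ValueError(f"{self.name}: orientation must be '+' or '-'")
        if self.category == "tRNA" and not self.anticodon:
            raise ValueError(f"{self.name}: tRNA annotation requires an anticodon")
        if self.category != "tRNA" and self.anticodon:
            raise ValueError(f"{self.name}: only tRNAs carry an anticodon")

    @property
    def length(self) -> int:
        return self.end - self.start

    def validate_on(self, seq_len: int) -> None:
        if self.start >= seq_len:
            raise ValueError(f"{self.name}: start {self.start} >= length {seq_len}")
        if self.length > seq_len:
            raise ValueError(f"{self.name}: feature longer than the circle")


@dataclass
class Minichromosome:
    """A circular minichromosome: sequence (optional) plus ordered gene list.

    ``coding_span`` and ``noncoding_span``, when both set, partition the
    circle.  Pseudogene features are kept in ``genes`` but are excluded from
    the canonical gene order.
    """

    id: str
    sequence: str | None = None
    genes: list[GeneAnnotation] = field(default_factory=list)
    coding_span: Span | None = None
    noncoding_span: Span | None = None

    @property
    def length(self) -> int:
        if self.sequence is None:
            raise ValueError(f"{self.id}: no sequence")
        return len(self.sequence)

    def canonical_genes(self) -> list[GeneAnnotation]:
        return [g for g in self.genes if g.category != "pseudogene"]

    def fetch(self, start: int, end: int) -> str:
        """Subsequence on the circle (end may exceed the length)."""
        if self.sequence is None:
            raise ValueError(f"{self.id}: no sequence")
        L = self.length
        n = end - start
        if n > L:
            raise ValueError("span longer than the circle")
        start %= L
        return (self.sequence + self.sequence)[start:start + n]

    def gene_sequence(self, ann: GeneAnnotation) -> str:
        s = self.fetch(ann.start, ann.end)
        return revcomp(s) if ann.orientation == "-" else s

    def rotated(self, offset: int) -> "Minichromosome":
        """Same circle with the origin shifted by ``offset`` bases."""
        L = self.length
        offset %= L
        seq = self.sequence[offset:] + self.sequence[:offset]

        def shift(span: Span) -> Span:
            s = (span[0] - offset) % L
            return (s, s + (span[1] - span[0]))

        new_genes = [
            dataclasses.replace(g, start=(g.start - offset) % L,
                                end=(g.start - offset) % L + g.length)
            for g in self.genes
        ]
        return Minichromosome(
            id=self.id, sequence=seq, genes=new_genes,
            coding_span=shift(self.coding_span) if self.coding_span else None,
            noncoding_span=shift(self.noncoding_span) if self.noncoding_span else None,
        )

    def validate(self) -> None:
        if self.sequence is not None:
            L = self.length
            for g in self.genes:
                g.validate_on(L)
            if self.coding_span and self.noncoding_span:
                cs, ce = self.coding_span
                ns, ne = self.noncoding_span
                if (ce - cs) + (ne - ns) != L:
                    raise ValueError(f"{self.id}: spans do not partition the circle")
                if ce % L != ns % L or ne % L != cs % L:
                    raise ValueError(f"{self.id}: spans are not adjacent on the circle")


@dataclass
class FragmentedGenome:
    """A species' mitochondrial genome as a set of circular minichromosomes."""

    species: str
    minichromosomes: list[Minichromosome] = field(default_factory=list)

    def __iter__(self) -> Iterator[Minichromosome]:
        return iter(self.minichromosomes)

    def __len__(self) -> int:
        return len(self.minichromosomes)

    def get(self, mid: str) -> Minichromosome:
        for mc in self.minichromosomes:
            if mc.id == mid:
                return mc
        raise KeyError(mid)

    def gene_names(self) -> list[str]:
        return [g.name for mc in self for g in mc.canonical_genes()]

    def find_gene(self, name: str) -> tuple[Minichromosome, GeneAnnotation]:
        for mc in self:
            for g in mc.canonical_genes():
                if g.name == name:
                    return mc, g
        raise KeyError(name)

    def validate(self) -> None:
        """Check the no-gene-content-overlap invariant and per-circle rules."""
        seen: dict[str, str] = {}
        for mc in self.minichromosomes:
            mc.validate()
            for g in mc.canonical_genes():
                if g.name in seen:
                    raise ValueError(
                        f"gene {g.name} on both {seen[g.name]} and {mc.id}")
                seen[g.name] = mc.id

    @property
    def is_complete(self) -> bool:
        return set(self.gene_names()) == _genes.CANONICAL_GENES and \
            len(self.gene_names()) == 37


Entry = tuple[tuple[str, str], ...]  # ordered ((gene, orientation), ...)


def canonical_rotation(entry: Entry) -> Entry:
    """Lexicographically smallest rotation of a circular gene order.

    Circular gene orders are compared rotation-invariantly; reflection is
    NOT an equality because orientation is meaningful.
    """
    if not entry:
        return entry
    rotations = [entry[i:] + entry[:i] for i in range(len(entry))]
    return min(rotations)


@dataclass
class ArrangementCatalog:
    """Sequence-free gene order/orientation per minichromosome for one species."""

    species: str
    entries: dict[str, Entry] = field(default_factory=dict)
    pseudogenes: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ArrangementCatalog):
            return NotImplemented
        if self.species != other.species:
            return False
        if set(self.entries) != set(other.entries):
            return False
        return all(
            canonical_rotation(self.entries[k]) == canonical_rotation(other.entries[k])
            for k in self.entries
        )

    def gene_names(self) -> list[str]:
        return [g for e in self.entries.values() for g, _ in e]

    @property
    def n_minichromosomes(self) -> int:
        return len(self.entries)

    @property
    def is_complete(self) -> bool:
        names = self.gene_names()
        return len(names) == 37 and set(names) == _genes.CANONICAL_GENES

    def host_key(self, mid: str) -> frozenset[str]:
        """The set of PCG + rRNA gene names on a minichromosome.

        Used as a sequence-free, rearrangement-stable identifier of the
        minichromosome when tRNAs move between minichromosomes.
        """
        return frozenset(
            g for g, _ in self.entries[mid]
            if _genes.category_of(g) in ("PCG", "rRNA"))

    def host_of(self, gene: str) -> str:
        for mid, entry in self.entries.items():
            if any(g == gene for g, _ in entry):
                return mid
        raise KeyError(gene)

    def validate(self) -> None:
        seen: dict[str, str] = {}
        for mid, entry in self.entries.items():
            for g, o in entry:
                if not _genes.is_canonical(g):
                    raise ValueError(f"unknown gene symbol: {g!r}")
                if o not in ("+", "-"):
                    raise ValueError(f"{g}: bad orientation {o!r}")
                if g in seen:
                    raise ValueError(f"duplicate gene {g} on {seen[g]} and {mid}")
                seen[g] = mid


def load_catalog(path: str | Path, species: str | None = None) -> ArrangementCatalog | dict[str, ArrangementCatalog]:
    """Read an arrangement-catalog TSV.

    Columns: species, minichrom_id, ordinal, gene, orientation; ``#``
    comments allowed.  Returns one catalog when the file holds a single
    species (or ``species`` is given), else a dict keyed by species.
    """
    rows: dict[str, dict[str, list[tuple[int, str, str]]]] = {}
    pseudo: dict[str, dict[str, list[tuple[int, str]]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
            sp, mid, ordinal, gene, orient = parts
            try:
                o = int(ordinal)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: bad ordinal {ordinal!r}") from None
            if orient not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: bad orientation {orient!r}")
            if not _genes.is_valid_symbol(gene):
                raise ValueError(f"{path}:{lineno}: unknown gene symbol {gene!r}")
            if gene.startswith(_genes.PSEUDO_PREFIX):
                pseudo.setdefault(sp, {}).setdefault(mid, []).append((o, gene))
            else:
                rows.setdefault(sp, {}).setdefault(mid, []).append((o, gene, orient))

    catalogs: dict[str, ArrangementCatalog] = {}
    for sp, by_mid in rows.items():
        entries = {
            mid: tuple((g, o) for _, g, o in sorted(triples))
            for mid, triples in by_mid.items()
        }
        cat = ArrangementCatalog(
            species=sp, entries=entries,
            pseudogenes={
                mid: tuple(g for _, g in sorted(lst))
                for mid, lst in pseudo.get(sp, {}).items()
            })
        cat.validate()
        catalogs[sp] = cat
    if species is not None:
        return catalogs[species]
    if len(catalogs) == 1:
        return next(iter(catalogs.values()))
    return catalogs


def write_catalog(catalogs: ArrangementCatalog | Iterable[ArrangementCatalog],
                  path: str | Path, header: str | None = None) -> None:
    """Write catalogs as TSV in canonical (sorted) order.

    ``write(load(x))`` reproduces ``x`` byte-for-byte once ``x`` is itself
    in canonical order.
    """
    if isinstance(catalogs, ArrangementCatalog):
        catalogs = [catalogs]
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for cat in sorted(catalogs, key=lambda c: c.species):
            for mid in sorted(cat.entries):
                for i, (g, o) in enumerate(cat.entries[mid], 1):
                    fh.write(f"{cat.species}\t{mid}\t{i}\t{g}\t{o}\n")
                for j, g in enumerate(cat.pseudogenes.get(mid, ()), 1):
                    fh.write(f"{cat.species}\t{mid}\t{100 + j}\t{g}\t+\n")


def genome_to_catalog(genome: FragmentedGenome) -> ArrangementCatalog:
    """Drop sequence: gene order by increasing start along the coding region.

    Pseudogenes are excluded from the canonical order but retained in the
    catalog's ``pseudogenes`` side list.
    """
    entries: dict[str, Entry] = {}
    pseudo: dict[str, tuple[str, ...]] = {}
    any_genes = any(mc.genes for mc in genome)
    if genome.minichromosomes and not any_genes:
        raise ValueError(f"{genome.species}: genome is not annotated")
    for mc in genome:
        ordered = sorted(mc.genes, key=lambda g: (g.start, g.name))
        entries[mc.id] = tuple(
            (g.name, g.orientation) for g in ordered if g.category != "pseudogene")
        ps = tuple(g.name for g in ordered if g.category == "pseudogene")
        if ps:
            pseudo[mc.id] = ps
    return ArrangementCatalog(species=genome.species, entries=entries, pseudogenes=pseudo)


# ---------------------------------------------------------------------------
# FASTA round-trip, header: species|minichrom_id|circular=true|length=N

def write_genome_fasta(genome: FragmentedGenome, path: str | Path,
                       circular: bool = True) -> None:
    records = []
    for mc in genome:
        if mc.sequence is None:
            raise ValueError(f"{mc.id}: no sequence to write")
        head = f"{genome.species}|{mc.id}|circular={'true' if circular else 'false'}|length={mc.length}"
        records.append(SeqRecord(Seq(mc.sequence), id=head, description=""))
    SeqIO.write(records, str(path), "fasta")


def read_genome_fasta(path: str | Path) -> FragmentedGenome:
    species = None
    mcs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.id.split("|")
        if len(fields) < 2:
            raise ValueError(f"bad FASTA header: {rec.id}")
        sp, mid = fields[0], fields[1]
        if species is None:
            species = sp
        elif sp != species:
            raise ValueError("FASTA mixes species")
        mcs.append(Minichromosome(id=mid, sequence=str(rec.seq).upper()))
    return FragmentedGenome(species=species or "unknown", minichromosomes=mcs)


# ---------------------------------------------------------------------------
# Phylogeny

@dataclass
class Phylogeny:
    """A rooted tree over species labels with named internal nodes."""

    tree: "Phylo.BaseTree.Tree"

    @classmethod
    def from_newick(cls, source: str | Path) -> "Phylogeny":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        tree = Phylo.read(StringIO(text), "newick")
        tree.rooted = True
        return cls(tree)

    @property
    def leaf_names(self) -> list[str]:
        return [t.name for t in self.tree.get_terminals()]

    def internal_nodes(self):
        return self.tree.get_nonterminals()

    def leaves_under(self, clade) -> frozenset[str]:
        return frozenset(t.name for t in clade.get_terminals())


@dataclass
class LifeHistoryRecord:
    """Body length and life-cycle ranges for one louse species."""

    species: str
    body_length_mm: tuple[float, float]
    life_cycle_days: tuple[float, float] | None
    genes_per_minichromosome: float

    def __post_init__(self) -> None:
        for lo, hi in filter(None, (self.body_length_mm, self.life_cycle_days)):
            if not (0 < lo <= hi):
                raise ValueError(f"{self.species}: bad range ({lo}, {hi})")
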