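"""Synthetic fragmented mt genomes with known ground truth.

The generator emulates the architecture observed in sucking-louse mt
genomes: a configurable number of circular minichromosomes (default 11),
each with a distinct coding region (a subset of the 37 canonical genes,
default partition = the *Po. asiatica* arrangement) and one shared
non-coding region (NCR) template, copied to every minichromosome with a
small per-copy divergence.  The NCR carries an AT-rich motif immediately
upstream of the coding 5' end and a GC-rich motif immediately downstream
of the coding 3' end, each containing a fully conserved core (101 bp
upstream, 44 bp downstream by default).  tRNA genes are synthesised from a
parameterised cloverleaf template so the secondary-structure folder has a
recoverable ground truth.

Derived sister genomes apply known rearrangement events (tRNA
translocations with optional pseudogene remnants, anticodon identity
swaps, pseudogenisations); planted identical stretches between gene pairs
give the shared-stretch scanner a known positive.  All randomness flows
from a single integer seed through numpy's splittable generators.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import fixtures
from . import genes as _genes
from .annotate import fold_trna
from .compare import RearrangementEvent
from .model import (ArrangementCatalog, Entry, FragmentedGenome,
                    GeneAnnotation, Minichromosome, genome_to_catalog, revcomp)

#: default plus-strand lengths of the protein-coding and rRNA genes (bp),
#: chosen so coding-region sizes fall in the observed 0.8-1.8 kb range
DEFAULT_GENE_LENGTHS: dict[str, int] = {
    "atp8": 160, "atp6": 680, "cob": 1140, "cox1": 1540, "cox2": 680,
    "cox3": 790, "nad1": 910, "nad2": 960, "nad3": 350, "nad4": 1340,
    "nad4L": 290, "nad5": 1690, "nad6": 470, "rrnS": 740, "rrnL": 1150,
}

# guard segments inside the NCR give the maximal-window motif detector a
# well-defined stopping point (see docs/methods.md)
_AT_GUARD = 50   # all-A/T segment following the GC-rich motif
_GC_GUARD = 40   # all-G/C segment preceding the AT-rich motif

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _default_partition() -> dict[str, Entry]:
    return dict(fixtures.pa_catalog().entries)


def _default_arms() -> dict[str, tuple[int, int]]:
    df = fixtures.trna_arm_values()
    return {r.trna: (int(r.pa_tstem), int(r.pa_tloop)) for r in df.itertuples()}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic genome generator."""

    n_minichromosomes: int = 11
    gene_partition: dict[str, Entry] = field(default_factory=_default_partition)
    ncr_length: int = 1300
    at_motif: tuple[int, float] = (140, 0.64)
    gc_motif: tuple[int, float] = (76, 0.71)
    upstream_conserved_len: int = 101
    downstream_conserved_len: int = 44
    ncr_divergence: float = 0.02
    coding_base_composition: dict[str, float] = field(
        default_factory=lambda: {"A": 0.30, "C": 0.18, "G": 0.17, "T": 0.35})
    gene_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GENE_LENGTHS))
    trna_arms: dict[str, tuple[int, int]] = field(default_factory=_default_arms)
    read_length: int = 90
    coverage: float = 30.0
    error_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        genes_seen: list[str] = []
        for entry in self.gene_partition.values():
            genes_seen.extend(g for g, _ in entry)
        if sorted(genes_seen) != sorted(_genes.CANONICAL_GENES):
            missing = _genes.CANONICAL_GENES - set(genes_seen)
            dupes = {g for g in genes_seen if genes_seen.count(g) > 1}
            raise ValueError(
                f"gene_partition must cover the 37 genes exactly once "
                f"(missing={sorted(missing)}, duplicated={sorted(dupes)})")
        if len(self.gene_partition) != self.n_minichromosomes:
            raise ValueError("n_minichromosomes does not match the partition")
        for _, frac in (self.at_motif, self.gc_motif):
            if not 0 < frac < 1:
                raise ValueError("motif fractions must be in (0, 1)")
        if abs(sum(self.coding_base_composition.values()) - 1) > 1e-9:
            raise ValueError("coding_base_composition must sum to 1")
        floor = (self.gc_motif[0] + _AT_GUARD + _GC_GUARD + self.at_motif[0] + 50)
        if self.ncr_length < floor:
            raise ValueError(f"ncr_length must be >= {floor}")
        if not (self.upstream_conserved_len <= self.at_motif[0]
                and self.downstream_conserved_len <= self.gc_motif[0]):
            raise ValueError("conserved cores must fit inside the boundary motifs")


@dataclass
class PlantedStretch:
    """Record of an identical stretch copied between two genes."""

    gene_a: str
    gene_b: str
    length: int
    pos_a: int  # offset within the plus-strand sequence of gene_a
    pos_b: int


@dataclass
class GroundTruth:
    """Everything the generator knows about an emitted genome."""

    catalog: ArrangementCatalog
    coding_spans: dict[str, tuple[int, int]]
    noncoding_spans: dict[str, tuple[int, int]]
    gene_sequences: dict[str, str]  # plus-strand reference set
    trna_arms: dict[str, tuple[int, int]]
    ncr_template: str
    planted: list[PlantedStretch] = field(default_factory=list)
    events: list[RearrangementEvent] = field(default_factory=list)


def _rand_seq(rng: np.random.Generator, n: int, comp: Mapping[str, float]) -> str:
    probs = [comp.get(b, 0.0) for b in "ACGT"]
    arr = rng.choice(_BASES, size=n, p=probs)
    return arr.tobytes().decode()


def _motif_seq(rng: np.random.Generator, length: int, fraction: float,
               rich: str, poor: str) -> str:
    """Sequence with an exact count of ``rich`` bases (= round(frac*len))."""
    n_rich = round(fraction * length)
    out = np.empty(length, dtype="U1")
    pos = rng.permutation(length)
    out[pos[:n_rich]] = rng.choice(list(rich), size=n_rich)
    out[pos[n_rich:]] = rng.choice(list(poor), size=length - n_rich)
    return "".join(out)


def synthesize_trna(rng: np.random.Generator, anticodon_rna: str,
                    t_stem: int, t_loop: int, max_tries: int = 200) -> str:
    """A cloverleaf-folding tRNA gene with the configured T-arm.

    Template: acceptor 7 bp, 2 nt spacer, D-arm 4 bp + 5 nt loop, 1 nt
    spacer, anticodon arm 5 bp + 7 nt loop (anticodon at the centre),
    variable region 4 nt, T-arm per the arguments.  Stems are strict
    Watson-Crick so the exhaustive folder recovers the template; candidates
    are resampled until the folder returns exactly the configured arms.
    """
    anticodon = anticodon_rna.replace("U", "T")
    wc = {"A": "T", "T": "A", "G": "C", "C": "G"}

    def stem(n: int) -> tuple[str, str]:
        s5 = _rand_seq(rng, n, {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25})
        return s5, "".join(wc[b] for b in reversed(s5))

    uniform = {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
    for _ in range(max_tries):
        acc5, acc3 = stem(7)
        d5, d3 = stem(4)
        ac5, ac3 = stem(5)
        t5, t3 = stem(t_stem)
        seq = (acc5 + _rand_seq(rng, 2, uniform)
               + d5 + _rand_seq(rng, 5, uniform) + d3 + _rand_seq(rng, 1, uniform)
               + ac5 + _rand_seq(rng, 2, uniform) + anticodon + _rand_seq(rng, 2, uniform) + ac3
               + _rand_seq(rng, 4, uniform)
               + t5 + _rand_seq(rng, t_loop, uniform) + t3 + acc3)
        st = fold_trna(seq)
        if (st is not None and st.t_stem == t_stem and st.t_loop == t_loop
                and st.anticodon == anticodon_rna):
            return seq
    raise RuntimeError(f"could not synthesise a recoverable tRNA ({anticodon_rna})")


def _build_ncr_template(rng: np.random.Generator, cfg: SimulationConfig
                        ) -> tuple[str, np.ndarray]:
    """NCR template plus a boolean mask of fully conserved positions.

    Layout 5'->3' (the NCR follows the coding region on the circle):
    GC-rich motif | all-AT guard | filler | all-GC guard | AT-rich motif.
    The conserved cores are the NCR prefix (downstream motif core) and
    suffix (upstream core); one deliberately variable site flanks each core
    so conserved-flank lengths are exactly recoverable.
    """
    N = cfg.ncr_length
    at_len, at_frac = cfg.at_motif
    gc_len, gc_frac = cfg.gc_motif
    filler_len = N - gc_len - _AT_GUARD - _GC_GUARD - at_len
    uniform = {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
    template = (
        _motif_seq(rng, gc_len, gc_frac, "GC", "AT")
        + _motif_seq(rng, _AT_GUARD, 1.0, "AT", "GC")
        + _rand_seq(rng, filler_len, uniform)
        + _motif_seq(rng, _GC_GUARD, 1.0, "GC", "AT")
        + _motif_seq(rng, at_len, at_frac, "AT", "GC")
    )
    conserved = np.zeros(N, dtype=bool)
    conserved[:cfg.downstream_conserved_len] = True
    conserved[N - cfg.upstream_conserved_len:] = True
    return template, conserved


def _ncr_copy(rng: np.random.Generator, template: str, conserved: np.ndarray,
              rate: float, copy_index: int, cfg: SimulationConfig) -> str:
    arr = np.frombuffer(template.encode(), dtype=np.uint8).copy()
    mutable = ~conserved
    hit = (rng.random(len(arr)) < rate) & mutable
    for p in np.nonzero(hit)[0]:
        choices = _BASES[_BASES != arr[p]]
        arr[p] = rng.choice(choices)
    # forced variable sites just outside each conserved core
    N = cfg.ncr_length
    for p in (cfg.downstream_conserved_len, N - cfg.upstream_conserved_len - 1):
        arr[p] = _BASES[copy_index % 4]
    return arr.tobytes().decode()


def generate_genome(config: SimulationConfig | None = None,
                    species: str = "synthetic",
                    ) -> tuple[FragmentedGenome, GroundTruth]:
    """Generate a fragmented mt genome and its ground truth.

    Deterministic under ``config.seed``: the same config yields
    byte-identical sequences on every run.
    """
    cfg = config or SimulationConfig()
    cfg.validate()
    master = np.random.default_rng(cfg.seed)
    genes_rng, ncr_rng, copies_rng = master.spawn(3)

    gene_seqs: dict[str, str] = {}
    for name in sorted(_genes.CANONICAL_GENES):
        if _genes.is_trna(name):
            stem, loop = cfg.trna_arms[name]
            gene_seqs[name] = synthesize_trna(
                genes_rng, _genes.TRNA_ANTICODON[name], stem, loop)
        else:
            gene_seqs[name] = _rand_seq(
                genes_rng, cfg.gene_lengths[name], cfg.coding_base_composition)

    template, conserved = _build_ncr_template(ncr_rng, cfg)

    mcs: list[Minichromosome] = []
    coding_spans: dict[str, tuple[int, int]] = {}
    noncoding_spans: dict[str, tuple[int, int]] = {}
    for i, mid in enumerate(sorted(cfg.gene_partition)):
        entry = cfg.gene_partition[mid]
        parts: list[str] = []
        anns: list[GeneAnnotation] = []
        pos = 0
        for gname, orient in entry:
            seq = gene_seqs[gname]
            parts.append(revcomp(seq) if orient == "-" else seq)
            anns.append(GeneAnnotation(
                name=gname, category=_genes.category_of(gname),
                start=pos, end=pos + len(seq), orientation=orient,
                anticodon=_genes.TRNA_ANTICODON.get(gname, "")))
            pos += len(seq)
        ncr = _ncr_copy(copies_rng, template, conserved, cfg.ncr_divergence, i, cfg)
        mc = Minichromosome(id=mid, sequence="".join(parts) + ncr, genes=anns,
                            coding_span=(0, pos),
                            noncoding_span=(pos, pos + len(ncr)))
        mc.validate()
        mcs.append(mc)
        coding_spans[mid] = (0, pos)
        noncoding_spans[mid] = (pos, pos + len(ncr))

    genome = FragmentedGenome(species=species, minichromosomes=mcs)
    genome.validate()
    truth = GroundTruth(
        catalog=genome_to_catalog(genome),
        coding_spans=coding_spans,
        noncoding_spans=noncoding_spans,
        gene_sequences=gene_seqs,
        trna_arms=dict(cfg.trna_arms),
        ncr_template=template,
    )
    return genome, truth


# ---------------------------------------------------------------------------
# rearrangement events

@dataclass
class Translocation:
    """Move a gene (or block of adjacent genes) next to an anchor gene."""

    genes: tuple[str, ...]
    dest_anchor: str
    side: str = "after"  # before | after
    leave_pseudogene: bool = False
    pseudogene_length: int = 55
    pseudogene_identity: float = 0.8
    orientation: str = "+"


@dataclass
class IdentitySwap:
    """Exchange the anticodon triplets of two same-family tRNA genes."""

    gene_a: str
    gene_b: str


@dataclass
class Pseudogenization:
    """Degrade a gene in place into a truncated, mutated remnant."""

    gene: str
    remnant_length: int = 55
    remnant_identity: float = 0.8


EventSpec = Translocation | IdentitySwap | Pseudogenization


@dataclass
class _Unit:
    name: str | None  # None = anonymous spacer
    orient: str
    seq: str  # plus-strand
    category: str | None


def _units_of(mc: Minichromosome) -> list[_Unit]:
    """Symbolic view of a coding region: ordered gene/spacer units."""
    cs, ce = mc.coding_span
    if cs != 0:
        raise ValueError("expected generator layout with coding region at origin")
    units: list[_Unit] = []
    pos = cs
    for g in sorted(mc.genes, key=lambda a: a.start):
        if g.start > pos:
            units.append(_Unit(None, "+", mc.sequence[pos:g.start], None))
        units.append(_Unit(g.name, g.orientation,
                           mc.gene_sequence(g), g.category))
        pos = g.end
    if pos < ce:
        units.append(_Unit(None, "+", mc.sequence[pos:ce], None))
    return units


def _mutate(rng: np.random.Generator, seq: str, identity: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n_mut = round((1 - identity) * len(arr))
    for p in rng.choice(len(arr), size=n_mut, replace=False):
        arr[p] = rng.choice(_BASES[_BASES != arr[p]])
    return arr.tobytes().decode()


def _flanks(units: list[_Unit], idx_lo: int, idx_hi: int) -> tuple[str | None, str | None]:
    left = next((u.name for u in reversed(units[:idx_lo]) if u.name), None)
    right = next((u.name for u in units[idx_hi + 1:] if u.name), None)
    return left, right


def derive_sister(
    genome: FragmentedGenome,
    events: Sequence[EventSpec],
    seed: int = 0,
    species: str | None = None,
) -> tuple[FragmentedGenome, GroundTruth]:
    """Apply rearrangement events to a copy of an annotated genome.

    Events are applied in order at the sequence level; the returned ground
    truth records each applied event.  A translocation with
    ``leave_pseudogene`` keeps a truncated, mutated remnant of the (first)
    moved gene at the ancestral site; an identity swap exchanges only the
    anticodon triplets of the two genes in place and renames them.
    """
    rng = np.random.default_rng(seed)
    units_by_mc: dict[str, list[_Unit]] = {}
    ncr_by_mc: dict[str, str] = {}
    for mc in genome:
        if mc.coding_span is None:
            raise ValueError(f"{mc.id}: genome must carry spans and annotations")
        units_by_mc[mc.id] = _units_of(mc)
        ncr_by_mc[mc.id] = mc.fetch(*mc.noncoding_span)

    def locate(gene: str) -> tuple[str, int]:
        for mid, units in units_by_mc.items():
            for i, u in enumerate(units):
                if u.name == gene:
                    return mid, i
        raise ValueError(f"gene {gene!r} not found in the genome")

    applied: list[RearrangementEvent] = []
    for ev in events:
        if isinstance(ev, Translocation):
            mids = {locate(g)[0] for g in ev.genes}
            if len(mids) != 1:
                raise ValueError(f"block {ev.genes} spans minichromosomes")
            src_mid = mids.pop()
            units = units_by_mc[src_mid]
            idxs = sorted(locate(g)[1] for g in ev.genes)
            if idxs != list(range(idxs[0], idxs[0] + len(idxs))):
                raise ValueError(f"block {ev.genes} is not adjacent")
            lo, hi = idxs[0], idxs[-1]
            src_left, src_right = _flanks(units, lo, hi)
            block = units[lo:hi + 1]
            remnant = None
            if ev.leave_pseudogene:
                head = block[0]
                rem_seq = _mutate(rng, head.seq[:ev.pseudogene_length],
                                  ev.pseudogene_identity)
                remnant = _Unit(f"{_genes.PSEUDO_PREFIX}{head.name}",
                                head.orient, rem_seq, "pseudogene")
            units_by_mc[src_mid] = units[:lo] + ([remnant] if remnant else []) + units[hi + 1:]

            dst_mid, anchor_idx = locate(ev.dest_anchor)  # after removal
            dst_units = units_by_mc[dst_mid]
            moved = [dataclasses.replace(u, orient=ev.orientation) for u in block]
            if ev.orientation == "-":
                moved = moved[::-1]
            at = anchor_idx + 1 if ev.side == "after" else anchor_idx
            units_by_mc[dst_mid] = dst_units[:at] + moved + dst_units[at:]
            applied.append(RearrangementEvent(
                type="translocation", genes=tuple(ev.genes),
                source_context=(src_left, src_right),
                dest_context=(ev.dest_anchor, ev.side),
                evidence="pseudogene_remnant" if ev.leave_pseudogene else "arrangement_only"))
        elif isinstance(ev, IdentitySwap):
            fam_a = _genes.TRNA_FAMILY.get(ev.gene_a)
            fam_b = _genes.TRNA_FAMILY.get(ev.gene_b)
            if fam_a is None or fam_a != fam_b or ev.gene_a == ev.gene_b:
                raise ValueError(
                    f"identity swap requires two distinct same-family tRNAs, "
                    f"got {ev.gene_a}/{ev.gene_b}")
            (mid_a, i_a), (mid_b, i_b) = locate(ev.gene_a), locate(ev.gene_b)
            ua, ub = units_by_mc[mid_a][i_a], units_by_mc[mid_b][i_b]

            def swap_anticodon(u: _Unit, new_ac_rna: str) -> str:
                st = fold_trna(u.seq)
                if st is None:
                    raise ValueError(f"{u.name}: does not fold, cannot swap anticodon")
                s = st.anticodon_start
                return u.seq[:s] + new_ac_rna.replace("U", "T") + u.seq[s + 3:]

            ac_a = _genes.TRNA_ANTICODON[ev.gene_a]
            ac_b = _genes.TRNA_ANTICODON[ev.gene_b]
            new_a = _Unit(ev.gene_b, ua.orient, swap_anticodon(ua, ac_b), ua.category)
            new_b = _Unit(ev.gene_a, ub.orient, swap_anticodon(ub, ac_a), ub.category)
            units_by_mc[mid_a][i_a] = new_a
            units_by_mc[mid_b][i_b] = new_b
            applied.append(RearrangementEvent(
                type="identity_swap", genes=(ev.gene_a, ev.gene_b),
                source_context=None, dest_context=None,
                evidence="sequence_similarity"))
        elif isinstance(ev, Pseudogenization):
            mid, i = locate(ev.gene)
            u = units_by_mc[mid][i]
            rem = _mutate(rng, u.seq[:ev.remnant_length], ev.remnant_identity)
            units_by_mc[mid][i] = _Unit(f"{_genes.PSEUDO_PREFIX}{u.name}",
                                        u.orient, rem, "pseudogene")
            applied.append(RearrangementEvent(
                type="pseudogenization", genes=(ev.gene,),
                source_context=None, dest_context=None,
                evidence="pseudogene_remnant"))
        else:
            raise TypeError(f"unknown event spec: {ev!r}")

    # re-render
    mcs: list[Minichromosome] = []
    coding_spans: dict[str, tuple[int, int]] = {}
    noncoding_spans: dict[str, tuple[int, int]] = {}
    for mid in sorted(units_by_mc):
        parts: list[str] = []
        anns: list[GeneAnnotation] = []
        pos = 0
        for u in units_by_mc[mid]:
            rendered = revcomp(u.seq) if u.orient == "-" else u.seq
            if u.name is not None:
                anns.append(GeneAnnotation(
                    name=u.name, category=u.category or _genes.category_of(u.name),
                    start=pos, end=pos + len(rendered), orientation=u.orient,
                    anticodon=_genes.TRNA_ANTICODON.get(u.name, "")))
            parts.append(rendered)
            pos += len(rendered)
        seq = "".join(parts) + ncr_by_mc[mid]
        mc = Minichromosome(id=mid, sequence=seq, genes=anns,
                            coding_span=(0, pos), noncoding_span=(pos, len(seq)))
        mcs.append(mc)
        coding_spans[mid] = (0, pos)
        noncoding_spans[mid] = (pos, len(seq))

    sister = FragmentedGenome(species=species or f"{genome.species}_sister",
                              minichromosomes=mcs)
    sister.validate()
    gene_seqs = {u.name: u.seq for us in units_by_mc.values() for u in us
                 if u.name and not u.name.startswith(_genes.PSEUDO_PREFIX)}
    truth = GroundTruth(
        catalog=genome_to_catalog(sister),
        coding_spans=coding_spans,
        noncoding_spans=noncoding_spans,
        gene_sequences=gene_seqs,
        trna_arms={},
        ncr_template="",
        events=applied,
    )
    return sister, truth


def plant_shared_stretch(
    genome: FragmentedGenome,
    gene_a: str,
    gene_b: str,
    length: int,
    seed: int = 0,
) -> tuple[FragmentedGenome, PlantedStretch]:
    """Copy a random window of gene_a over a random window of gene_b.

    Both windows are on the plus strands of the genes; the returned record
    carries the planted length and in-gene offsets.  ``length`` 0 returns
    an unchanged copy.
    """
    out = copy.deepcopy(genome)
    mc_a, ann_a = out.find_gene(gene_a)
    mc_b, ann_b = out.find_gene(gene_b)
    if length >= min(ann_a.length, ann_b.length):
        raise ValueError("planted length must be shorter than both genes")
    if length == 0:
        return out, PlantedStretch(gene_a, gene_b, 0, 0, 0)
    rng = np.random.default_rng(seed)
    sa = mc_a.gene_sequence(ann_a)
    sb = mc_b.gene_sequence(ann_b)
    pos_a = int(rng.integers(0, len(sa) - length + 1))
    pos_b = int(rng.integers(0, len(sb) - length + 1))
    new_b = sb[:pos_b] + sa[pos_a:pos_a + length] + sb[pos_b + length:]
    rendered = revcomp(new_b) if ann_b.orientation == "-" else new_b
    if ann_b.end > mc_b.length:
        raise ValueError("origin-spanning genes are not supported for planting")
    mc_b.sequence = mc_b.sequence[:ann_b.start] + rendered + mc_b.sequence[ann_b.end:]
    return out, PlantedStretch(gene_a, gene_b, length, pos_a, pos_b)


# ---------------------------------------------------------------------------
# read simulation

def simulate_reads(
    genome: FragmentedGenome,
    read_length: int = 90,
    coverage: float = 30.0,
    error_rate: float = 0.0,
    seed: int = 0,
    region: str = "circle",
) -> list[tuple[str, str]]:
    """Uniform single-end reads from each minichromosome.

    ``region='circle'`` samples the whole circle with positions wrapping
    the origin; ``region='coding'`` samples the coding region only,
    mirroring amplicon sequencing of the coding span (requires spans).
    Read counts are Poisson around coverage * span / read_length; strands
    are random; substitution errors are applied at ``error_rate``.
    Deterministic under ``seed``.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if region not in ("circle", "coding"):
        raise ValueError(f"unknown region {region!r}")
    rng = np.random.default_rng(seed)
    reads: list[tuple[str, str]] = []
    for mc in genome:
        if region == "coding":
            if mc.coding_span is None:
                raise ValueError(f"{mc.id}: coding span not set")
            span = mc.fetch(*mc.coding_span)
            wrap = False
        else:
            span = mc.sequence
            wrap = True
        if read_length > len(span):
            raise ValueError(f"{mc.id}: read length {read_length} exceeds template")
        n = int(rng.poisson(coverage * len(span) / read_length))
        template = span + span[:read_length] if wrap else span
        hi = len(span) if wrap else len(span) - read_length + 1
        starts = rng.integers(0, hi, size=n)
        strands = rng.random(n) < 0.5
        for i, (s, flip) in enumerate(zip(starts, strands)):
            seq = template[s:s + read_length]
            if error_rate > 0:
                arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
                for p in np.nonzero(rng.random(read_length) < error_rate)[0]:
                    arr[p] = rng.choice(_BASES[_BASES != arr[p]])
                seq = arr.tobytes().decode()
            if flip:
                seq = revcomp(seq)
            reads.append((f"{mc.id}:{i}", seq))
    return reads


def write_fastq(reads: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    reads = []
    with open(path) as fh:
        while True:
            head = fh.readline()
            if not head:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            reads.append((head[1:].strip(), seq))
    return reads
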