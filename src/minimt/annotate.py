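"""Annotation of minichromosome sequences.

Stages: partition each circle into its coding region and the shared
non-coding region (NCR) by cross-minichromosome k-mer conservation; locate
the compositional motifs that flank the coding region (an AT-rich motif
upstream of the coding 5' end, a GC-rich motif downstream of the 3' end);
identify genes by best-hit similarity against a reference gene set; fold
tRNA genes into cloverleaf secondary structures and tabulate T-arm metrics;
and detect pseudogene remnants in intergenic sequence.

Louse mt tRNAs are structurally aberrant, so the cloverleaf search uses
wider arm bounds than standard tRNA models (T-stems of 3-8 pairs, T-loops
of 3-11 nt span the observed range).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import edlib
import numpy as np
import pandas as pd

from . import genes as _genes
from .model import FragmentedGenome, GeneAnnotation, Minichromosome, revcomp
from .util import round_half_up

# Watson-Crick plus G.U wobble (DNA alphabet)
_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


# ---------------------------------------------------------------------------
# coding / non-coding partition

def partition_coding_noncoding(
    genome: FragmentedGenome,
    k: int = 15,
    merge_gap: int = 120,
    min_block: int = 200,
    min_coding: int = 200,
) -> FragmentedGenome:
    """Set coding/noncoding spans on every minichromosome, in place.

    A position is an NCR anchor when its k-mer occurs in at least half of
    the minichromosomes; anchors closer than ``merge_gap`` are merged
    (ungapped extension across the occasional diverged site), and the
    largest merged block on each circle is taken as its NCR.
    """
    n = len(genome.minichromosomes)
    if n < 2:
        raise ValueError("need at least 2 minichromosomes to find the shared NCR")
    threshold = max(2, math.ceil(n / 2))

    kmer_sources: dict[str, set[int]] = {}
    for i, mc in enumerate(genome):
        doubled = mc.sequence + mc.sequence
        for p in range(mc.length):
            kmer_sources.setdefault(doubled[p:p + k], set()).add(i)

    for i, mc in enumerate(genome):
        L = mc.length
        doubled = mc.sequence + mc.sequence
        marked = [p for p in range(L) if len(kmer_sources[doubled[p:p + k]]) >= threshold]
        if not marked:
            raise ValueError(f"{mc.id}: no shared non-coding region")

        # circular merge of anchor starts
        blocks: list[list[int]] = [[marked[0], marked[0]]]
        for p in marked[1:]:
            if p - blocks[-1][1] <= merge_gap:
                blocks[-1][1] = p
            else:
                blocks.append([p, p])
        if len(blocks) > 1 and (marked[0] + L) - blocks[-1][1] <= merge_gap:
            first = blocks.pop(0)
            blocks[-1][1] = first[1] + L

        spans = [(s, e + k) for s, e in blocks]
        ns, ne = max(spans, key=lambda se: (se[1] - se[0], -se[0]))
        ncr_len = min(ne - ns, L)
        if ncr_len < min_block:
            raise ValueError(f"{mc.id}: no shared non-coding region")
        if L - ncr_len < min_coding:
            raise ValueError(f"{mc.id}: no distinct coding region")
        cs = ne % L
        mc.noncoding_span = (ns % L, ns % L + ncr_len)
        mc.coding_span = (cs, cs + (L - ncr_len))
    return genome


# ---------------------------------------------------------------------------
# compositional motifs

@dataclass
class MotifHit:
    """A compositional or conserved motif interval on the circle."""

    start: int
    end: int  # may exceed the sequence length (wraps)
    fraction: float
    side: str  # upstream_AT | downstream_GC | conserved_upstream | conserved_downstream

    @property
    def length(self) -> int:
        return self.end - self.start


def _longest_flank_window(seq: str, bases: str, threshold: float,
                          min_len: int, from_end: bool) -> tuple[int, float] | None:
    """Longest prefix (or suffix) window with composition >= threshold."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    wanted = np.zeros(256, dtype=bool)
    for b in bases:
        wanted[ord(b)] = True
    hits = wanted[arr]
    if from_end:
        hits = hits[::-1]
    csum = np.cumsum(hits)
    lengths = np.arange(1, len(seq) + 1)
    ok = csum >= threshold * lengths
    ok[: min_len - 1] = False
    if not ok.any():
        return None
    w = int(np.nonzero(ok)[0][-1]) + 1
    return w, float(csum[w - 1] / w)


def find_compositional_motifs(
    mc: Minichromosome,
    at_threshold: float = 0.60,
    gc_threshold: float = 0.55,
    min_len: int = 50,
) -> list[MotifHit]:
    """AT-rich motif touching the coding 5' boundary, GC-rich one at the 3'.

    Thresholds default to values that admit the weakest observed motifs
    (AT 64%, GC down to 57%); a side with no qualifying window of at least
    ``min_len`` is simply absent from the result.
    """
    if mc.noncoding_span is None:
        raise ValueError(f"{mc.id}: spans not set; run partition first")
    ns, ne = mc.noncoding_span
    ncr = mc.fetch(ns, ne)
    hits: list[MotifHit] = []
    up = _longest_flank_window(ncr, "AT", at_threshold, min_len, from_end=True)
    if up is not None:
        w, frac = up
        hits.append(MotifHit(start=ne - w, end=ne, fraction=frac, side="upstream_AT"))
    down = _longest_flank_window(ncr, "GC", gc_threshold, min_len, from_end=False)
    if down is not None:
        w, frac = down
        hits.append(MotifHit(start=ns, end=ns + w, fraction=frac, side="downstream_GC"))
    return hits


def conserved_flank_motifs(genome: FragmentedGenome) -> tuple[MotifHit, MotifHit]:
    """Longest NCR flanks identical across all minichromosomes.

    Returns the conserved upstream motif (common NCR suffix, abutting each
    coding 5' end) and the conserved downstream motif (common NCR prefix),
    in the coordinates of the first minichromosome.
    """
    ncrs = []
    for mc in genome:
        if mc.noncoding_span is None:
            raise ValueError(f"{mc.id}: spans not set; run partition first")
        ncrs.append(mc.fetch(*mc.noncoding_span))
    m = min(len(s) for s in ncrs)

    def common_prefix() -> int:
        for i in range(m):
            if len({s[i] for s in ncrs}) > 1:
                return i
        return m

    def common_suffix() -> int:
        for i in range(1, m + 1):
            if len({s[-i] for s in ncrs}) > 1:
                return i - 1
        return m

    ns, ne = genome.minichromosomes[0].noncoding_span
    up, down = common_suffix(), common_prefix()
    return (
        MotifHit(start=ne - up, end=ne, fraction=1.0, side="conserved_upstream"),
        MotifHit(start=ns, end=ns + down, fraction=1.0, side="conserved_downstream"),
    )


# ---------------------------------------------------------------------------
# gene identification by best-hit similarity

def assign_gene_identity(
    sequence: str,
    reference: Mapping[str, str],
    circular: bool = False,
    min_identity: float = 0.7,
    min_coverage: float = 0.6,
) -> list[GeneAnnotation]:
    """Annotate genes by best-hit similarity against a reference gene set.

    Each reference gene aligning at >= ``min_identity`` (edit identity over
    the reference length) and covering >= ``min_coverage`` of it is placed
    at its best-scoring location and strand; overlapping calls are resolved
    by score.  On circles the search runs on the doubled sequence and
    coordinates are reported modulo the length (``end`` may exceed it).
    """
    if not reference:
        raise ValueError("empty reference gene set")
    L = len(sequence)
    target = sequence + sequence if circular else sequence
    rc_target = revcomp(target)
    max_hits: list[tuple[float, int, str, str, int, int]] = []

    for name, ref in reference.items():
        best = None  # (dist, start, end, strand)
        max_dist = int(len(ref) * (1 - min_identity))
        for strand, tgt in (("+", target), ("-", rc_target)):
            res = edlib.align(ref, tgt, mode="HW", task="locations", k=max_dist)
            if res["editDistance"] < 0:
                continue
            for s, e in res["locations"]:
                if strand == "-":
                    s, e = len(tgt) - 1 - e, len(tgt) - 1 - s
                if circular and s >= L:
                    continue
                span = e - s + 1
                if span < min_coverage * len(ref):
                    continue
                cand = (res["editDistance"], s, e + 1, strand)
                if best is None or cand < best:
                    best = cand
        if best is not None:
            dist, s, e, strand = best
            score = len(ref) - dist
            max_hits.append((score, len(ref), name, strand, s, e))

    # overlap resolution by score (then name for determinism)
    max_hits.sort(key=lambda h: (-h[0], h[2]))
    accepted: list[GeneAnnotation] = []
    occupied: list[tuple[int, int]] = []

    def overlaps(s: int, e: int) -> bool:
        for os, oe in occupied:
            for shift in ((0,) if not circular else (-L, 0, L)):
                lo, hi = max(s + shift, os), min(e + shift, oe)
                if hi - lo > 0.5 * min(e - s, oe - os):
                    return True
        return False

    for score, _reflen, name, strand, s, e in max_hits:
        if overlaps(s, e):
            continue
        occupied.append((s, e))
        accepted.append(GeneAnnotation(
            name=name,
            category=_genes.category_of(name),
            start=s, end=e,
            orientation=strand,
            anticodon=_genes.TRNA_ANTICODON.get(name, ""),
        ))
    accepted.sort(key=lambda g: (g.start, g.name))
    return accepted


# ---------------------------------------------------------------------------
# tRNA cloverleaf folding

@dataclass
class TrnaStructure:
    """Cloverleaf decomposition of a tRNA gene with per-arm stem/loop sizes."""

    acceptor_pairs: int
    d_stem: int
    d_loop: int
    ac_stem: int
    ac_loop: int
    var_len: int
    t_stem: int
    t_loop: int
    anticodon: str
    anticodon_start: int  # offset of the anticodon triplet in the sequence
    total_pairs: int
    wc_pairs: int

    @property
    def t_arm(self) -> int:
        """T-arm length in nt: 2 * stem pairs + loop nt."""
        return 2 * self.t_stem + self.t_loop

    @property
    def d_arm(self) -> int:
        return 2 * self.d_stem + self.d_loop


def fold_trna(seq: str) -> TrnaStructure | None:
    """Exhaustive cloverleaf search; ``None`` when no decomposition folds.

    Grammar (5'->3'): acceptor stem 6-7 pairs, 0-3 nt spacer, D-stem 3-4
    pairs with a 3-10 nt loop, 0-2 nt spacer, anticodon stem 4-5 pairs with
    a 7-nt loop (anticodon at its center), variable region 3-6 nt, T-stem
    3-8 pairs with a 3-11 nt loop, then the acceptor 3' strand.  All stem
    positions must form Watson-Crick or G.U pairs.  Among valid
    decompositions the one with the most pairs wins; ties prefer more
    Watson-Crick pairs, then the smallest T-stem.
    """
    seq = seq.upper()
    L = len(seq)
    if not 50 <= L <= 90:
        raise ValueError(f"tRNA fold expects 50-90 nt, got {L}")

    def stem_ok(p5: int, p3_end: int, n: int) -> int | None:
        """Return WC-pair count if positions pair, else None.

        The 5' strand starts at ``p5``; the 3' strand ENDS at ``p3_end``
        (exclusive) and is read backwards.
        """
        wc = 0
        for i in range(n):
            pair = (seq[p5 + i], seq[p3_end - 1 - i])
            if pair not in _PAIRS:
                return None
            if pair in _WC:
                wc += 1
        return wc

    best: tuple | None = None
    for a in (7, 6):
        wc_a = stem_ok(0, L, a)
        if wc_a is None:
            continue
        for s1 in range(0, 4):
            d5 = a + s1
            for d in (4, 3):
                for dloop in range(3, 11):
                    wc_d = stem_ok(d5, d5 + 2 * d + dloop, d)
                    if wc_d is None:
                        continue
                    d_end = d5 + 2 * d + dloop
                    for s2 in range(0, 3):
                        c5 = d_end + s2
                        for c in (5, 4):
                            ac_end = c5 + 2 * c + 7
                            if ac_end > L - a:
                                continue
                            wc_c = stem_ok(c5, ac_end, c)
                            if wc_c is None:
                                continue
                            for t in range(3, 9):
                                for tloop in range(3, 12):
                                    var = L - a - ac_end - 2 * t - tloop
                                    if not 3 <= var <= 6:
                                        continue
                                    t5 = ac_end + var
                                    wc_t = stem_ok(t5, t5 + 2 * t + tloop, t)
                                    if wc_t is None:
                                        continue
                                    total = a + d + c + t
                                    wc = wc_a + wc_d + wc_c + wc_t
                                    key = (total, wc, -t, a, -s1, d, -dloop, -s2, c)
                                    if best is None or key > best[0]:
                                        ac_start = c5 + c + 2
                                        best = (key, TrnaStructure(
                                            acceptor_pairs=a, d_stem=d, d_loop=dloop,
                                            ac_stem=c, ac_loop=7, var_len=var,
                                            t_stem=t, t_loop=tloop,
                                            anticodon=seq[ac_start:ac_start + 3].replace("T", "U"),
                                            anticodon_start=ac_start,
                                            total_pairs=total, wc_pairs=wc))
    return None if best is None else best[1]


def tarm_table(values: Mapping[str, tuple[int, int]] | Mapping[str, TrnaStructure]
               | Iterable[tuple[str, int, int]]) -> pd.DataFrame:
    """Per-tRNA T-stem/T-loop/T-arm rows plus Total and Mean rows.

    Accepts a mapping from tRNA name to (stem pairs, loop nt) or to a
    :class:`TrnaStructure`, or an iterable of (name, stem, loop) rows.
    Requires exactly one row per canonical tRNA; arm = 2*stem + loop,
    Total = column sums, Mean = Total/22 rounded half-up to one decimal.
    """
    rows: dict[str, tuple[int, int]] = {}
    if isinstance(values, Mapping):
        items: Iterable[tuple[str, object]] = values.items()
        for name, v in items:
            if isinstance(v, TrnaStructure):
                rows[name] = (v.t_stem, v.t_loop)
            else:
                rows[name] = tuple(v)  # type: ignore[assignment]
    else:
        for name, stem, loop in values:
            if name in rows:
                raise ValueError(f"duplicate tRNA name: {name}")
            rows[name] = (stem, loop)
    if set(rows) != set(_genes.TRNA):
        missing = set(_genes.TRNA) - set(rows)
        extra = set(rows) - set(_genes.TRNA)
        raise ValueError(f"need one row per tRNA; missing={sorted(missing)} extra={sorted(extra)}")

    df = pd.DataFrame(
        [(name, s, l, 2 * s + l) for name, (s, l) in sorted(rows.items())],
        columns=["trna", "stem_pairs", "loop_nt", "arm_nt"],
    ).set_index("trna")
    totals = df.sum()
    means = {c: round_half_up(totals[c] / 22, 1) for c in df.columns}
    df.loc["Total"] = totals
    df.loc["Mean"] = pd.Series(means)
    return df


# ---------------------------------------------------------------------------
# pseudogene detection

@dataclass
class PseudogeneHit:
    """A degenerate gene remnant found in intergenic sequence."""

    start: int
    end: int
    identity: float  # matches / alignment columns

    @property
    def length(self) -> int:
        return self.end - self.start


def detect_pseudogene(
    intergenic: str,
    gene: str,
    min_len: int = 40,
    min_identity: float = 0.65,
    search_revcomp: bool = True,
) -> list[PseudogeneHit]:
    """Glocal alignment of a functional gene against intergenic sequence.

    The whole gene is aligned against the best-matching window (edlib HW);
    identity is matches over alignment columns, so both the truncation and
    the divergence of a remnant count against it.  Hits shorter than
    ``min_len`` or below ``min_identity`` are dropped.  The identity
    default sits between the best chance alignments of unrelated sequences
    (<= ~0.65) and the weakest genuine remnants (>= ~0.72 for a 55 bp
    remnant at 80% sequence identity).
    """
    if not intergenic or not gene:
        raise ValueError("both sequences must be non-empty")
    hits: list[PseudogeneHit] = []
    for strand, g in (("+", gene), ("-", revcomp(gene))) if search_revcomp else (("+", gene),):
        res = edlib.align(g, intergenic, mode="HW", task="path")
        if res["editDistance"] < 0 or not res["locations"]:
            continue
        s, e = res["locations"][0]
        # extended cigar: '=' match, 'X' mismatch, 'I'/'D' indel
        cols = matches = 0
        num = ""
        for ch in res["cigar"]:
            if ch.isdigit():
                num += ch
            else:
                cols += int(num)
                if ch == "=":
                    matches += int(num)
                num = ""
        identity = matches / cols if cols else 0.0
        span = e + 1 - s
        if span >= min_len and identity >= min_identity:
            hits.append(PseudogeneHit(start=s, end=e + 1, identity=identity))
    hits.sort(key=lambda h: (-h.identity * h.length, h.start))
    return hits


# ---------------------------------------------------------------------------
# GFF3 output

_GFF_TYPE = {"PCG": "gene", "rRNA": "rRNA", "tRNA": "tRNA",
             "pseudogene": "pseudogene"}


def write_gff3(genome: FragmentedGenome, path) -> None:
    """Write annotations as GFF3 with circular region directives."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for mc in genome:
            fh.write(f"##sequence-region {mc.id} 1 {mc.length}\n")
            fh.write(f"{mc.id}\tminimt\tregion\t1\t{mc.length}\t.\t+\t.\t"
                     f"ID={mc.id};Is_circular=true\n")
            for g in sorted(mc.genes, key=lambda a: a.start):
                attrs = f"ID={g.name};Name={g.name}"
                if g.anticodon:
                    attrs += f";anticodon={g.anticodon}"
                # GFF is 1-based inclusive; origin-spanning ends stay >length
                fh.write(f"{mc.id}\tminimt\t{_GFF_TYPE[g.category]}\t"
                         f"{g.start + 1}\t{g.end}\t.\t{g.orientation}\t.\t{attrs}\n")


# ---------------------------------------------------------------------------
# genome-level convenience

def contigs_to_catalog(
    contigs,
    reference: Mapping[str, str],
    species: str = "assembly",
    **thresholds,
):
    """Annotate assembled contigs and derive an arrangement catalog.

    Each contig is oriented so that the majority of its genes sit on the
    plus strand (the reference-strand convention: all but one or two genes
    are transcribed on the same strand), then genes are ordered by start
    position.  Contigs with no gene call are dropped.
    """
    from .model import ArrangementCatalog  # local: keeps module deps one-way

    entries = {}
    for i, contig in enumerate(contigs):
        anns = assign_gene_identity(contig.sequence, reference,
                                    circular=contig.circular, **thresholds)
        if not anns:
            continue
        n_minus = sum(1 for a in anns if a.orientation == "-")
        if n_minus * 2 > len(anns):
            L = len(contig.sequence)
            flipped = []
            for a in anns:
                ns = (L - a.end) % L
                flipped.append(GeneAnnotation(
                    name=a.name, category=a.category,
                    start=ns, end=ns + a.length,
                    orientation="+" if a.orientation == "-" else "-",
                    anticodon=a.anticodon))
            anns = flipped
        anns.sort(key=lambda g: (g.start, g.name))
        key = "-".join(g.name for g in anns
                       if g.category in ("PCG", "rRNA")) or f"contig{i}"
        entries[key] = tuple((g.name, g.orientation) for g in anns)
    return ArrangementCatalog(species=species, entries=entries)


def annotate_genome(
    genome: FragmentedGenome,
    reference: Mapping[str, str],
    partition: bool = True,
    **thresholds,
) -> FragmentedGenome:
    """Partition (optionally) and assign gene identities on every circle."""
    if partition:
        partition_coding_noncoding(genome)
    for mc in genome:
        mc.genes = assign_gene_identity(mc.sequence, reference, circular=True,
                                        **thresholds)
    return genome
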