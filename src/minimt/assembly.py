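"""Greedy overlap-layout-consensus assembly of short reads at desk scale.

Re-implements the assembly step used for minichromosome amplicon reads:
reads are merged greedily, longest qualifying overlap first, where an
overlap must be at least ``min_overlap`` bases long at ``min_identity``
ungapped identity (defaults 50 bp / 98%).  Both strands are considered;
consensus is by per-column majority vote.  Circles are recovered by
trimming the terminal redundancy of a contig whose ends overlap.

This is deliberately not a general-purpose assembler: no repeat
resolution, no scaffolding, no quality-aware consensus.  Minichromosomes
sharing a non-coding region assemble correctly only when reads cover the
distinct coding regions (the amplicon design this mirrors).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import revcomp

_ANCHOR_K = 21
_ANCHOR_STRIDE = 5
_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
_IDX_BASE = "ACGT"
_COMP_PERM = (3, 2, 1, 0)  # A<->T, C<->G in profile columns


@dataclass
class Contig:
    """An assembled sequence with read support."""

    sequence: str
    circular: bool = False
    n_reads: int = 1


class _WorkingContig:
    __slots__ = ("cid", "seq", "profile", "n_reads", "fwd", "rev", "alive")

    def __init__(self, cid: int, seq: str, n_reads: int = 1,
                 fwd: int = 1, rev: int = 0) -> None:
        self.cid = cid
        self.seq = seq
        self.profile = [[0, 0, 0, 0] for _ in seq]
        for i, ch in enumerate(seq):
            self.profile[i][_BASE_IDX[ch]] = n_reads
        self.n_reads = n_reads
        self.fwd = fwd
        self.rev = rev
        self.alive = True


def _canonical(kmer: str) -> tuple[str, bool]:
    rc = revcomp(kmer)
    return (kmer, True) if kmer <= rc else (rc, False)


def _hamming(a: str, b: str, limit: int) -> int:
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > limit:
                return mism
    return mism


def _assemble_working(reads: Sequence[str] | Sequence[tuple[str, str]],
                      min_overlap: int = 50,
                      min_identity: float = 0.98) -> list[_WorkingContig]:
    seqs = [r[1] if isinstance(r, tuple) else r for r in reads]
    if not seqs:
        raise ValueError("empty read set")
    if not 0 < min_identity <= 1:
        raise ValueError("min_identity must be in (0, 1]")
    if min_overlap >= max(len(s) for s in seqs):
        raise ValueError("min_overlap must be shorter than the reads")

    # collapse exact duplicates (same strand) into multiplicities
    counts: dict[str, int] = {}
    for s in seqs:
        counts[s.upper()] = counts.get(s.upper(), 0) + 1
    contigs: dict[int, _WorkingContig] = {}
    for i, s in enumerate(sorted(counts)):
        contigs[i] = _WorkingContig(i, s, n_reads=counts[s],
                                    fwd=counts[s], rev=0)
    next_id = len(contigs)

    # anchor index: canonical k-mer -> [(contig id, pos, same-as-canonical)]
    index: dict[str, list[tuple[int, int, bool]]] = {}

    def index_contig(wc: _WorkingContig) -> None:
        s = wc.seq
        for p in range(0, len(s) - _ANCHOR_K + 1):
            canon, same = _canonical(s[p:p + _ANCHOR_K])
            index.setdefault(canon, []).append((wc.cid, p, same))

    heap: list[tuple] = []
    push_count = 0

    def try_push(a: _WorkingContig, b: _WorkingContig, flip: bool, off: int) -> None:
        # arrangement: a forward at 0, b (flipped or not) starting at off,
        # which may be negative when b overhangs to the left
        nonlocal push_count
        la, lb = len(a.seq), len(b.seq)
        start_a = max(0, off)
        o = min(la, off + lb) - start_a
        if o < min_overlap:
            return
        b_or = revcomp(b.seq) if flip else b.seq
        limit = int((1 - min_identity) * o)
        if _hamming(a.seq[start_a:start_a + o],
                    b_or[start_a - off:start_a - off + o], limit) > limit:
            return
        push_count += 1
        heapq.heappush(heap, (-o, a.cid, b.cid, flip, off, push_count))

    def find_candidates(wc: _WorkingContig) -> None:
        s = wc.seq
        seen: set[tuple[int, bool, int]] = set()
        for p in range(0, len(s) - _ANCHOR_K + 1, _ANCHOR_STRIDE):
            canon, same = _canonical(s[p:p + _ANCHOR_K])
            for oid, q, osame in index.get(canon, ()):  # noqa: B909
                other = contigs.get(oid)
                if other is None or not other.alive or oid == wc.cid:
                    continue
                flip = same != osame
                if flip:
                    q = len(other.seq) - _ANCHOR_K - q
                off = p - q
                key = (oid, flip, off)
                if key in seen:
                    continue
                seen.add(key)
                try_push(wc, other, flip, off)

    for wc in list(contigs.values()):
        index_contig(wc)
    for wc in list(contigs.values()):
        find_candidates(wc)

    def merge(a: _WorkingContig, b: _WorkingContig, flip: bool, off: int) -> _WorkingContig:
        nonlocal next_id
        b_prof = [[col[i] for i in _COMP_PERM] for col in reversed(b.profile)] \
            if flip else b.profile
        shift_a, shift_b = max(0, -off), max(0, off)
        span = max(shift_a + len(a.profile), shift_b + len(b_prof))
        new = _WorkingContig.__new__(_WorkingContig)
        new.cid = next_id
        next_id += 1
        new.profile = [[0, 0, 0, 0] for _ in range(span)]
        for shift, prof in ((shift_a, a.profile), (shift_b, b_prof)):
            for i, col in enumerate(prof):
                tgt = new.profile[shift + i]
                for t in range(4):
                    tgt[t] += col[t]
        new.seq = "".join(
            _IDX_BASE[max(range(4), key=lambda t: (col[t], -t))]
            for col in new.profile)
        new.n_reads = a.n_reads + b.n_reads
        new.fwd = a.fwd + (b.rev if flip else b.fwd)
        new.rev = a.rev + (b.fwd if flip else b.rev)
        new.alive = True
        return new

    while heap:
        nego, aid, bid, flip, off, _ = heapq.heappop(heap)
        a, b = contigs.get(aid), contigs.get(bid)
        if a is None or b is None or not a.alive or not b.alive:
            continue
        a.alive = False
        b.alive = False
        del contigs[aid], contigs[bid]
        new = merge(a, b, flip, off)
        contigs[new.cid] = new
        index_contig(new)
        find_candidates(new)

    return sorted(contigs.values(), key=lambda w: (-len(w.seq), w.seq))


def _finalize(wc: _WorkingContig, circular: bool = False) -> Contig:
    seq = revcomp(wc.seq) if wc.rev > wc.fwd else wc.seq
    return Contig(sequence=seq, circular=circular, n_reads=wc.n_reads)


def assemble(reads: Sequence[str] | Sequence[tuple[str, str]],
             min_overlap: int = 50,
             min_identity: float = 0.98) -> list[Contig]:
    """Greedy overlap-layout assembly with majority-vote consensus.

    Repeatedly merges the pair of contigs with the longest suffix-prefix
    (or containment) overlap of length >= ``min_overlap`` at ungapped
    identity >= ``min_identity``, both strands considered, until no merge
    qualifies.  Deterministic: overlaps of equal length are merged in a
    fixed order.  Each contig is reported on the strand matching the
    majority of the reads it absorbed.
    """
    return [_finalize(wc) for wc in _assemble_working(reads, min_overlap, min_identity)]


def circularize(contig: Contig, min_overlap: int = 50,
                min_identity: float = 0.95) -> Contig:
    """Trim terminal redundancy and mark circular when the ends overlap.

    If the contig's prefix and suffix overlap by at least ``min_overlap``
    bases at ``min_identity`` ungapped identity, the redundant suffix copy
    is removed and the contig marked circular; otherwise it is returned
    unchanged.  The longest qualifying end-overlap is used, so a contig
    equal to a doubled circle collapses to one circle length.
    """
    if contig.circular:
        return contig
    s = contig.sequence
    o = _end_overlap(s, min_overlap, min_identity)
    if o:
        return Contig(sequence=s[:len(s) - o], circular=True,
                      n_reads=contig.n_reads)
    return contig


def _end_overlap(seq: str, min_overlap: int, min_identity: float) -> int:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    for o in range(len(seq) - 1, min_overlap - 1, -1):
        limit = int((1 - min_identity) * o)
        if int((arr[:o] != arr[-o:]).sum()) <= limit:
            return o
    return 0


def assemble_circular(reads, min_overlap: int = 50,
                      min_identity: float = 0.98,
                      end_join_identity: float = 0.95) -> list[Contig]:
    """Assemble, then circularize contigs whose ends overlap.

    Circularization is profile-aware: the read support of the redundant
    terminal copy is folded back onto the contig start before the final
    consensus, so the thinly covered end columns are polished by the
    full-depth evidence.  The end join uses a relaxed identity
    (``end_join_identity``) because the redundant copies are each
    single-read-deep at their tips.
    """
    out: list[Contig] = []
    for wc in _assemble_working(reads, min_overlap, min_identity):
        o = _end_overlap(wc.seq, min_overlap, end_join_identity)
        if o == 0:
            out.append(_finalize(wc))
            continue
        L = len(wc.seq)
        folded = [list(col) for col in wc.profile[:L - o]]
        for i in range(o):
            src = wc.profile[L - o + i]
            for t in range(4):
                folded[i][t] += src[t]
        wc.profile = folded
        wc.seq = "".join(
            _IDX_BASE[max(range(4), key=lambda t: (col[t], -t))]
            for col in folded)
        out.append(_finalize(wc, circular=True))
    return out


def is_rotation_of(contig: Contig, truth: str) -> bool:
    """Is the contig a rotation (or reverse-complement rotation) of a circle?"""
    if len(contig.sequence) != len(truth):
        return False
    doubled = truth + truth
    return contig.sequence in doubled or revcomp(contig.sequence) in doubled
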