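# Methods

This note documents the models and procedures implemented in `minimt`,
the parameter choices behind them, and what the synthetic-data tests do
and do not establish about real data.

## The genome model

A fragmented mt genome is a set of circular minichromosomes.  Each circle
partitions into a **coding region** (a subset of the 37 canonical animal
mt genes, abutting, in a fixed circular order and orientation) and a
**non-coding region (NCR)** that is highly similar across the
minichromosomes of one species.  Coordinates are 0-based half-open on the
circle with the origin at the first base of the coding region's first
gene; a feature's `end` may exceed the circle length to encode
origin-spanning intervals.  The reference strand is the strand carrying
the majority of genes (in the rat lice all genes but one or two).
Arrangement equality is rotation-invariant and orientation-sensitive:
reflection is *not* equality.

Gene vocabulary: 13 protein-coding genes, `rrnS`/`rrnL`, and 22 tRNAs
named by amino-acid letter, with the leucine pair disambiguated by
anticodon family (L1 = NAG, L2 = YAA) and likewise the serine pair
(S1 = NCU, S2 = NGA).  Each canonical gene occurs on at most one
minichromosome; a complete genome carries all 37 exactly once.

## Synthetic genomes (the study conditions)

`SimulationConfig` defaults describe the system the package targets:

| parameter | default | meaning |
|---|---|---|
| `n_minichromosomes` | 11 | circles per genome |
| `gene_partition` | the *Po. asiatica* arrangement | gene → circle map with orientations |
| `ncr_length` | 1300 bp | shared NCR template length |
| `at_motif` | (140 bp, 0.64) | AT-rich motif abutting the coding 5′ end |
| `gc_motif` | (76 bp, 0.71) | GC-rich motif abutting the coding 3′ end |
| `upstream_conserved_len` | 101 bp | fully conserved NCR suffix |
| `downstream_conserved_len` | 44 bp | fully conserved NCR prefix |
| `ncr_divergence` | 0.02 | per-copy substitution rate from the template (≈96% pairwise NCR identity) |
| `read_length` / `coverage` / `error_rate` | 90 bp / 30× / 0 | read simulation |

Protein/rRNA gene sequences are i.i.d. draws from a mildly AT-rich
composition with realistic per-gene lengths (coding regions come out at
0.8–1.8 kb and whole circles at 2.1–3.1 kb).  tRNA genes are synthesised
from a cloverleaf template — acceptor 7 bp, D-arm 4 bp + 5 nt loop,
anticodon arm 5 bp + 7 nt loop with the anticodon at the centre, 4 nt
variable region, T-arm per the packaged per-tRNA stem/loop values — with
strict Watson-Crick stems, and each candidate is re-folded until the
exhaustive folder returns exactly the configured arms, so structure
recovery has an unambiguous ground truth.

Two generator-specific design choices make detection quantities exactly
recoverable rather than approximately so.  First, fixed-composition guard
segments (50 bp all-A/T after the GC motif, 40 bp all-G/C before the AT
motif) separate the boundary motifs from the 50/50 NCR filler; without
them the maximal-window motif detector would drift tens of bases into a
filler whose composition sits near the threshold.  Second, one
deliberately variable site (base cycling with the copy index) flanks each
fully conserved boundary core, pinning the cross-minichromosome conserved
flank lengths at exactly 101/44 bp; otherwise the common flank would
extend stochastically by a few bases.  Both are emulations of variable
sites observed next to conserved motifs, and both are documented rather
than load-bearing: the motif tests allow ±20 bp regardless.

Derived sisters apply events in order at the sequence level.
Translocations move a gene (or a block of adjacent genes) next to an
anchor gene on another circle, optionally leaving a truncated remnant at
the source (default 55 bp at 80% identity, between the observed 54 and
57 bp remnants).  Identity swaps exchange only the anticodon triplets of
two same-family tRNAs and rename them — the sequences differ from the
parent only inside the two triplets.  Planted stretches copy a random
window of one gene over a random window of another, recording both
offsets.  All randomness descends from one integer seed through numpy's
splittable generators; identical configs are byte-identical across runs.

Read simulation draws Poisson(read count) uniform positions, random
strands, and i.i.d. substitution errors.  `region="circle"` samples whole
circles (positions wrap the origin); `region="coding"` samples the coding
region only, mirroring amplicon sequencing between conserved NCR primers.
The end-to-end recovery pipeline uses coding-region reads: whole-genome
reads from circles sharing a near-identical NCR are not separable by any
overlap assembler without long-range information, and the sequencing
design this package models avoided exactly that.

## Assembly

Greedy overlap-layout-consensus: all candidate overlaps ≥ 50 bp at ≥ 98%
ungapped identity (both strands; candidates found via shared 21-mers) go
into a priority queue; the longest is merged first, consensus is
per-column majority vote over the read profile, and merging repeats until
no overlap qualifies.  Ties between equal-length overlaps resolve in a
fixed insertion order, making the output deterministic and invariant to
read order (tested by permutation).  Circularization trims the terminal
redundancy when a contig's ends overlap; it is profile-aware — the
redundant terminal columns' read support is folded back onto the contig
start before the final consensus — because contig tips are single-read
deep and would otherwise both fail the strict identity check and retain
isolated errors.  The end join uses a relaxed 95% identity for the same
reason.  Limitations: ungapped overlaps only (substitution-only reads),
no repeat resolution, no quality awareness.

## Annotation

*Partition.*  A position is an NCR anchor when its 15-mer occurs in at
least half of the minichromosomes; anchors within 120 bp merge, and the
largest merged block per circle is its NCR (minimum 200 bp; a genome of
near-identical circles has no distinct coding region and errors out).
At 2% NCR divergence the recovered spans match the truth essentially
exactly (Jaccard ≥ 0.95 asserted, 1.0 typical) because conserved flanks
abut the coding boundaries.  Recovered boundary offsets of a few bases
are tolerated in tests.

*Motifs.*  The AT-rich (GC-rich) motif is the longest window touching the
coding 5′ (3′) boundary with AT ≥ 0.60 (GC ≥ 0.55), minimum 50 bp.
Thresholds admit the weakest observed motifs (GC 57%) while rejecting
ordinary NCR background.  Conserved flank motifs are the longest NCR
suffix/prefix identical across all minichromosomes.

*Gene identity.*  Each reference gene is aligned (edlib, glocal) against
both strands of the doubled circle; a call requires edit identity ≥ 0.70
over ≥ 0.60 of the reference length, the best-scoring location wins, and
overlapping calls resolve by score.  With the generator's own reference
set recovery is exact to the base.  The 70%/60% defaults are pragmatic:
they reject the 55 bp/80% pseudogene remnants (≈0.65 identity against the
full gene) while accepting moderately diverged orthologs.

*tRNA folding.*  Exhaustive cloverleaf search over acceptor 6–7 bp,
0–3 nt spacer, D-stem 3–4 bp (loop 3–10), 0–2 nt spacer, anticodon stem
4–5 bp with a 7 nt loop, variable region 3–6 nt, and T-stem 3–8 bp (loop
3–11) — bounds spanning the aberrant arm sizes these lice actually show.
Watson-Crick and G·U pairs are allowed, every stem position must pair,
and the decomposition maximising total pairs wins (ties: more
Watson-Crick pairs, then the smallest T-stem).  The T-arm table reports
stem pairs, loop nt and arm = 2·stem + loop per tRNA with Total and Mean
(half-up, one decimal) rows.

*Pseudogenes.*  The functional gene is glocally aligned against the
intergenic window; a remnant call needs an aligned span ≥ 40 bp and
identity (matches / alignment columns) ≥ 0.65.  The identity floor sits
between the best chance alignments of unrelated sequences (≤ ~0.65,
measured) and the weakest genuine remnants (≥ ~0.72), giving ≥ 95% clean
calls on random sequence while detecting every simulated remnant.

## Shared stretches and the chance baseline

`longest_shared_stretch` is an exact longest-common-substring search
(suffix automaton over one gene, scan of the other), with positions and a
smallest-(posA,posB) tie-break, verified against an all-substrings oracle.
Reverse-complement search is an explicit flag; the default is
forward-strand only, matching how same-strand identities are reported in
this system.  Secondary stretches come from re-running the search with
the primary match masked.

The chance baseline is Monte-Carlo: independent random sequences of the
same lengths and base composition (composition-matched rather than
shuffled — composition is the dominant determinant of chance match
lengths), longest stretch per replicate, reported as mean and 95th
percentile.  The simulator computes stretch lengths by binary search over
exact 2-bit k-mer codes (falling back to the automaton above 31 bp,
unreachable by chance at these scales) and was checked against exhaustive
enumeration at length 4.  A pair is **flagged** when observed ≥ 2× the
null mean or observed > the null 95th percentile; the 2× rule is
calibrated so that stretches described as "2–3 times longer than
chance" flag, and the q95 rule contributes its nominal ≤ 5% chance-level
flags — on 666 pairs a handful of isolated q95 flags is expected
background, which is why ranking by fold-over-chance, not the flag bit
alone, identifies the real signal.  Inside the genome-wide scan, gene
lengths are bucketed on a geometric grid (ratio 1.45) and null
distributions cached per bucket pair; the standalone null function is
exact per-lengths.

## Comparative analysis

Minichromosomes are **identical** across species when gene content,
circular order and orientation all match (rotation-invariant).  A gene's
**distribution** is keyed by its host minichromosome's set of
protein-coding/rRNA genes; a tRNA "differs" between species when that key
differs, so position changes within an unchanged host do not count, and
both members of an identity swap count.  This is the definition under
which the rat-louse comparison yields exactly 8 differing tRNAs.

Ancestral states of junction characters (gene adjacencies, whole
arrangements, whole minichromosomes, each with a presence vector over
species) are inferred by **Dollo parsimony**: the state arises once, at
the MRCA of the species showing it, and every node on a path from that
gain to a present leaf is present.  A node containing the state in only
one child subtree and not inside the gain's spanning subtree is
ambiguous (including the single-species case, where the gain cannot be
localised); nodes with no present descendants are absent.  On the seven
packaged junction characters this equals exhaustive single-gain
minimal-change parsimony node for node.

Event classification compares a complete ancestral catalog with a derived
one.  tRNAs whose host key changed are candidate moves; two same-family
tRNAs that exactly exchange contexts (host key and flanking genes) — and,
when sequences are available, where each derived gene is closer to the
ancestral occupant of its site than to its own ancestral copy — are one
**identity swap**, encoding the in-place-exchange preference as a rule
rather than a likelihood (no probabilistic model is attempted).
Remaining moves group into **translocations**, with genes adjacent in
both catalogs moving as one block.  A pseudogene remnant at the ancestral
site (from the catalog's pseudogene list or by remnant detection in the
sequences) attaches remnant evidence.  Recovery is exact (precision =
recall = 1.0 over 20 seeded replicates) for non-interacting event
programs; events stacked on the same junction are not identifiable from
arrangements alone and are outside what the classifier claims.

## Fragmentation vs life history

Fragmentation extent is genes per minichromosome, rounded half-up to one
decimal (the rule reproducing every derivable published value: 37/11 →
3.4, 37/9 → 4.1, 34/14 → 2.4).  The *Pediculus* value 2.1 is carried as a
catalog constant and never recomputed (37/20 would round to 1.9); the
packaged table marks it `catalog_constant`.  Life-history ranges become
midpoints; the association is Spearman's rank correlation with average
ranks for ties plus a weak-monotonicity flag.  With five species and tied
metrics no p-value is attached — the output is descriptive.  On the
packaged table: life cycle ρ ≈ 0.97 and concordant; body length
non-concordant (ρ ≈ 0.05).

## Problem sizes and determinism

The test suite and acceptance script run entirely on synthetic data and
packaged fixtures: end-to-end recovery uses the default 11-circle genome
at 30× error-free coverage (≈4,700 reads) over 5 seeds in the tests and
3 in the acceptance script; event recovery uses 20 and 10 seeded
replicates respectively; the pair scan uses 200 Monte-Carlo replicates
per length bucket.  All stages are deterministic under their seeds;
pipeline runs with the same configuration produce byte-identical
summaries.

## Limitations

Substitution-only reads and ungapped overlaps; no indel realism, no
paired ends, no quality model.  Whole-genome assembly of circles sharing
an NCR is out of scope (amplicon design assumed).  Gene identification
requires a per-gene reference set — there is no ab initio gene finding,
no covariance-model tRNA scoring, no ORF validation.  Synthetic coding
sequence is i.i.d.; real genes have codon structure and conserved domains
that make chance shared stretches slightly longer than the i.i.d. null,
so real-data fold-over-chance values should be read comparatively, not as
calibrated significance.  The phylogeny is fixed input; no dating, no
tree estimation, and no model of the fragmentation process itself.
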