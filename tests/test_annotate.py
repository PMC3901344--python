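"""Partitioning, motifs, gene identification, tRNA folding, pseudogenes."""

from __future__ import annotations

import copy

import numpy as np
import pytest

from minimt import (FragmentedGenome, Minichromosome, SimulationConfig,
                    assign_gene_identity, detect_pseudogene,
                    find_compositional_motifs, fold_trna, generate_genome,
                    partition_coding_noncoding, tarm_table)
from minimt.annotate import conserved_flank_motifs
from minimt.model import revcomp
from minimt import fixtures as fx


def _bare(genome):
    g = copy.deepcopy(genome)
    for mc in g:
        mc.coding_span = mc.noncoding_span = None
        mc.genes = []
    return g


class TestPartition:
    def test_recovers_truth_spans(self, default_sim):
        genome, truth = default_sim
        g = _bare(genome)
        partition_coding_noncoding(g)
        for mc in g:
            ts, te = truth.noncoding_spans[mc.id]
            rs, re = mc.noncoding_span
            inter = max(0, min(te, re) - max(ts, rs))
            union = (te - ts) + (re - rs) - inter
            assert inter / union >= 0.95

    def test_recovered_ncr_length_near_configured(self, default_sim):
        genome, _ = default_sim
        g = _bare(genome)
        partition_coding_noncoding(g)
        for mc in g:
            ns, ne = mc.noncoding_span
            assert abs((ne - ns) - 1300) <= 50

    def test_identical_sequences_are_degenerate(self):
        seq = "".join(np.random.default_rng(0).choice(list("ACGT"), 2000))
        g = FragmentedGenome("x", [Minichromosome("a", sequence=seq),
                                   Minichromosome("b", sequence=seq)])
        with pytest.raises(ValueError, match="no distinct coding region"):
            partition_coding_noncoding(g)

    def test_unrelated_sequences_have_no_shared_ncr(self):
        rng = np.random.default_rng(1)
        mcs = [Minichromosome(f"m{i}",
                              sequence="".join(rng.choice(list("ACGT"), 2000)))
               for i in range(3)]
        with pytest.raises(ValueError, match="no shared non-coding region"):
            partition_coding_noncoding(FragmentedGenome("x", mcs))


class TestMotifs:
    def test_upstream_at_motif_near_planted_size(self, default_sim):
        genome, _ = default_sim
        for mc in genome:
            hits = {h.side: h for h in find_compositional_motifs(mc)}
            up = hits["upstream_AT"]
            assert abs(up.length - 140) <= 20
            assert up.fraction >= 0.60
            assert up.end == mc.noncoding_span[1]  # touches the coding 5' end

    def test_downstream_gc_motif_detected(self, default_sim):
        genome, _ = default_sim
        for mc in genome:
            hits = {h.side: h for h in find_compositional_motifs(mc)}
            down = hits["downstream_GC"]
            assert 76 <= down.length <= 101
            assert down.fraction >= 0.55

    def test_all_g_ncr_has_no_at_hit(self):
        mc = Minichromosome("m", sequence="A" * 500 + "G" * 400,
                            coding_span=(0, 500), noncoding_span=(500, 900))
        hits = {h.side: h for h in find_compositional_motifs(mc)}
        assert "upstream_AT" not in hits
        assert hits["downstream_GC"].length == 400  # spans the whole NCR

    def test_weak_gc_motif_is_still_admitted(self):
        """A 65 bp motif at 57% GC (the weakest case this system shows)
        passes the default GC threshold."""
        rng = np.random.default_rng(5)
        n_gc = round(0.57 * 65)
        motif = ["G" if i < n_gc else "A" for i in range(65)]
        rng.shuffle(motif)
        ncr = "".join(motif) + "AT" * 120  # AT tail stops the window
        mc = Minichromosome("m", sequence="C" * 300 + ncr,
                            coding_span=(0, 300), noncoding_span=(300, 300 + len(ncr)))
        hits = {h.side: h for h in find_compositional_motifs(mc)}
        assert "downstream_GC" in hits
        assert hits["downstream_GC"].length >= 60

    def test_conserved_flanks_recovered_exactly(self, default_sim):
        genome, _ = default_sim
        up, down = conserved_flank_motifs(genome)
        assert up.length == 101
        assert down.length == 44


class TestGeneIdentity:
    def test_exact_recovery_on_own_reference(self, default_sim):
        genome, truth = default_sim
        for mc in genome:
            anns = assign_gene_identity(mc.sequence, truth.gene_sequences,
                                        circular=True)
            got = [(a.name, a.start, a.end, a.orientation) for a in anns]
            want = [(a.name, a.start, a.end, a.orientation) for a in mc.genes]
            assert got == want

    def test_strand_symmetry(self, default_sim):
        genome, truth = default_sim
        mc = genome.get("atp8-atp6")
        anns = assign_gene_identity(revcomp(mc.sequence), truth.gene_sequences,
                                    circular=True)
        assert {a.name for a in anns} == {"atp8", "atp6"}
        assert all(a.orientation == "-" for a in anns)

    def test_absent_gene_not_called(self, default_sim):
        genome, truth = default_sim
        mc = genome.get("atp8-atp6")
        anns = assign_gene_identity(mc.sequence, truth.gene_sequences,
                                    circular=True)
        assert {a.name for a in anns} == {"atp8", "atp6"}

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="empty reference"):
            assign_gene_identity("ACGT" * 100, {})


class TestFoldTrna:
    def test_recovers_configured_arms_for_all_22(self, default_sim):
        genome, truth = default_sim
        for name, (stem, loop) in truth.trna_arms.items():
            mc, ann = genome.find_gene(name)
            st = fold_trna(mc.gene_sequence(ann))
            assert st is not None, name
            assert (st.t_stem, st.t_loop) == (stem, loop), name
            assert st.anticodon == ann.anticodon
            assert st.t_arm == 2 * stem + loop

    def test_large_t_arm_architecture(self):
        """A template with T-stem 8 / T-loop 9 folds to a 25 nt T-arm
        (the alanine architecture of the more derived rat louse)."""
        from minimt.simulate import synthesize_trna
        rng = np.random.default_rng(11)
        seq = synthesize_trna(rng, "UGC", 8, 9)
        st = fold_trna(seq)
        assert st.t_arm == 25
        assert st.anticodon == "UGC"

    def test_homopolymer_does_not_fold(self):
        assert fold_trna("A" * 70) is None

    def test_out_of_range_length_errors(self):
        with pytest.raises(ValueError, match="50-90"):
            fold_trna("ACGT" * 30)


class TestTarmTable:
    @pytest.mark.parametrize("species,total,mean", [("pa", 332, 15.1),
                                                    ("ps", 285, 13.0)])
    def test_published_totals_and_means(self, species, total, mean):
        df = fx.trna_arm_values()
        rows = {r.trna: (int(getattr(r, f"{species}_tstem")),
                         int(getattr(r, f"{species}_tloop")))
                for r in df.itertuples()}
        table = tarm_table(rows)
        assert table.loc["Total", "arm_nt"] == total
        assert table.loc["Mean", "arm_nt"] == mean

    @pytest.mark.parametrize("species", ["pa", "ps"])
    def test_arm_arithmetic_holds_for_every_row(self, species):
        df = fx.trna_arm_values()
        rows = {r.trna: (int(getattr(r, f"{species}_tstem")),
                         int(getattr(r, f"{species}_tloop")))
                for r in df.itertuples()}
        table = tarm_table(rows)
        body = table.drop(["Total", "Mean"])
        assert len(body) == 22
        assert (body["arm_nt"] == 2 * body["stem_pairs"] + body["loop_nt"]).all()

    def test_all_zero_rows_give_zero_totals(self):
        from minimt.genes import TRNA
        table = tarm_table({t: (0, 0) for t in TRNA})
        assert table.loc["Total", "arm_nt"] == 0

    def test_duplicate_name_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            tarm_table([("trnA", 5, 7), ("trnA", 4, 6)])

    def test_missing_trna_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            tarm_table({"trnA": (5, 7)})


class TestDetectPseudogene:
    def test_synthetic_remnant_found_at_expected_length(self, default_sim):
        genome, truth = default_sim
        from minimt.simulate import Translocation, derive_sister
        sister, _ = derive_sister(
            genome, [Translocation(("trnP",), dest_anchor="trnK", side="before",
                                   leave_pseudogene=True)], seed=9)
        mc = next(m for m in sister if any(a.category == "pseudogene"
                                           for a in m.genes))
        ann = next(a for a in mc.genes if a.category == "pseudogene")
        pad = 20  # flanking context around the remnant
        inter = mc.fetch(max(0, ann.start - pad), ann.end + pad)
        hits = detect_pseudogene(inter, truth.gene_sequences["trnP"])
        assert hits
        assert abs(hits[0].length - 55) <= 5

    def test_false_positive_rate_on_random_sequence(self):
        rng = np.random.default_rng(0)
        clean = 0
        for _ in range(100):
            inter = "".join(rng.choice(list("ACGT"), 150))
            gene = "".join(rng.choice(list("ACGT"), 68))
            clean += not detect_pseudogene(inter, gene)
        assert clean >= 95

    def test_identical_remnant_scores_perfectly(self, default_sim):
        _, truth = default_sim
        gene = truth.gene_sequences["trnT"]
        hits = detect_pseudogene("TTTT" + gene + "AAAA", gene)
        assert hits[0].identity == 1.0
        assert hits[0].length == len(gene)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            detect_pseudogene("", "ACGT")


class TestGff3Output:
    def test_circular_directives_and_features(self, default_sim, tmp_path):
        from minimt.annotate import write_gff3
        genome, _ = default_sim
        p = tmp_path / "out.gff3"
        write_gff3(genome, p)
        text = p.read_text()
        assert text.startswith("##gff-version 3")
        assert text.count("Is_circular=true") == 11
        assert sum(1 for line in text.splitlines()
                   if "\ttRNA\t" in line) == 22
        # minus-strand gene carries its strand
        nad1 = next(line for line in text.splitlines() if "ID=nad1" in line)
        assert "\t-\t" in nad1
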