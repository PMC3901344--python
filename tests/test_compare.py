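"""Catalog comparison, Dollo ancestral states, event classification."""

from __future__ import annotations

from itertools import product

import numpy as np
import pytest

from minimt import (classify_events, compare_catalogs, infer_ancestral_states)
from minimt.compare import JunctionCharacter, characters_from_table
from minimt.simulate import IdentitySwap, Translocation, derive_sister
from minimt import fixtures as fx


class TestCompareCatalogs:
    def test_pa_vs_ps_identical_minichromosomes(self, pa_catalog, ps_catalog):
        cmp = compare_catalogs(pa_catalog, ps_catalog)
        assert cmp.n_identical == 2
        assert {a for a, _ in cmp.identical_minichromosomes} == \
            {"atp8-atp6", "trnE-cob-trnI"}

    def test_pa_vs_ps_differing_trnas(self, pa_catalog, ps_catalog):
        cmp = compare_catalogs(pa_catalog, ps_catalog)
        assert cmp.differing_trnas == frozenset(
            {"trnL1", "trnL2", "trnT", "trnA", "trnP", "trnF", "trnS1", "trnS2"})
        assert len(cmp.differing_pcg_rrna) == 0

    def test_self_comparison(self, pa_catalog):
        cmp = compare_catalogs(pa_catalog, pa_catalog)
        assert cmp.n_identical == 11
        assert not cmp.differing_trnas and not cmp.differing_pcg_rrna

    def test_counts_are_symmetric(self, pa_catalog, ps_catalog):
        ab = compare_catalogs(pa_catalog, ps_catalog)
        ba = compare_catalogs(ps_catalog, pa_catalog)
        assert ab.n_identical == ba.n_identical
        assert ab.differing_trnas == ba.differing_trnas

    def test_incomplete_catalog_rejected(self, pa_catalog):
        from minimt import ArrangementCatalog
        partial = ArrangementCatalog("partial", dict(list(
            pa_catalog.entries.items())[:5]))
        with pytest.raises(ValueError, match="not complete"):
            compare_catalogs(partial, pa_catalog)


def dollo_oracle(tree, present: frozenset[str]) -> dict[str, str]:
    """Exhaustive single-gain parsimony over all internal-state assignments.

    Scores every {present, absent} assignment to the internal nodes,
    keeps assignments with at most one origin (root presence or an
    absent-to-present edge) and the minimal number of changes, and
    reports per node the consensus over minimal scenarios.
    """
    internals = list(tree.internal_nodes())
    leaves = tree.leaf_names
    scenarios = []
    best = None
    for bits in product((True, False), repeat=len(internals)):
        state = {id(n): b for n, b in zip(internals, bits)}
        for leaf in tree.tree.get_terminals():
            state[id(leaf)] = leaf.name in present
        gains = losses = 0
        root = tree.tree.root
        if state[id(root)]:
            gains += 1
        stack = [root]
        while stack:
            node = stack.pop()
            for child in node.clades:
                if state[id(node)] and not state[id(child)]:
                    losses += 1
                elif not state[id(node)] and state[id(child)]:
                    gains += 1
                stack.append(child)
        if gains > 1:
            continue
        cost = gains + losses
        if best is None or cost < best:
            best = cost
            scenarios = [bits]
        elif cost == best:
            scenarios.append(bits)
    out = {}
    for i, node in enumerate(internals):
        vals = {s[i] for s in scenarios}
        out[node.name] = ("present" if vals == {True}
                          else "absent" if vals == {False} else "ambiguous")
    return out


class TestDolloInference:
    def test_all_seven_junctions_ancestral_at_root(self):
        chars = characters_from_table(fx.junction_table())
        states = infer_ancestral_states(chars, fx.louse_tree())
        assert len(states) == 7
        for name, st in states.items():
            assert st["anoplura"] == "present", name

    def test_matches_exhaustive_single_gain_parsimony(self):
        """Dollo states equal the brute-force minimal single-gain
        reconstruction for every packaged junction character."""
        tree = fx.louse_tree()
        chars = characters_from_table(fx.junction_table())
        states = infer_ancestral_states(chars, tree)
        for ch in chars:
            assert states[ch.name] == dollo_oracle(tree, ch.present_in), ch.name

    def test_rrns_trnc_pass_through_nodes_present(self):
        tree = fx.louse_tree()
        ch = JunctionCharacter("x", "minichromosome", "rrnS+,trnC+",
                               frozenset({"Polyplax_asiatica",
                                          "Haematopinus_suis",
                                          "Haematopinus_apri"}))
        st = infer_ancestral_states([ch], tree)["x"]
        assert st["anoplura"] == "present"
        assert st["rat_human_lice"] == "present"  # on the path to Pa
        assert st["rat_lice"] == "present"
        assert st["pig_lice"] == "present"
        assert st["human_lice"] == "absent"

    def test_single_leaf_state_is_ambiguous(self):
        tree = fx.louse_tree()
        ch = JunctionCharacter("y", "adjacency", "a+,b+",
                               frozenset({"Polyplax_asiatica"}))
        st = infer_ancestral_states([ch], tree)["y"]
        assert st["rat_lice"] == "ambiguous"
        assert st["anoplura"] == "ambiguous"
        assert st["pig_lice"] == "absent"
        assert "present" not in st.values()

    def test_unknown_species_rejected(self):
        tree = fx.louse_tree()
        ch = JunctionCharacter("z", "adjacency", "a+,b+",
                               frozenset({"Rattus_norvegicus"}))
        with pytest.raises(ValueError, match="unknown species"):
            infer_ancestral_states([ch], tree)


class TestClassifyEvents:
    def test_ancestor_to_pa_fixture(self, pa_catalog):
        events = classify_events(fx.ancestral_catalog(), pa_catalog)
        keys = {e.key() for e in events}
        assert keys == {("translocation", frozenset({"trnP"})),
                        ("translocation", frozenset({"trnF"}))}

    def test_ancestor_to_ps_fixture(self, ps_catalog):
        events = classify_events(fx.ancestral_catalog(), ps_catalog)
        keys = {e.key() for e in events}
        assert keys == {("translocation", frozenset({"trnT"})),
                        ("translocation", frozenset({"trnA"})),
                        ("translocation", frozenset({"trnS1", "trnS2"})),
                        ("identity_swap", frozenset({"trnL1", "trnL2"}))}

    def test_swap_evidence_uses_sequences(self, ancestral_sim):
        genome, truth = ancestral_sim
        sister, st = derive_sister(genome, [IdentitySwap("trnL1", "trnL2")],
                                   seed=2)
        events = classify_events(truth.catalog, st.catalog, genome, sister)
        assert len(events) == 1
        assert events[0].type == "identity_swap"
        assert events[0].evidence == "sequence_similarity"

    def test_remnant_evidence_attached(self, ancestral_sim):
        genome, truth = ancestral_sim
        sister, st = derive_sister(
            genome,
            [Translocation(("trnT",), dest_anchor="trnD", side="before",
                           leave_pseudogene=True)], seed=2)
        # classify from sequences alone: hide the catalog's pseudogene list
        cat = st.catalog
        cat.pseudogenes = {}
        events = classify_events(truth.catalog, cat, genome, sister)
        assert events[0].key() == ("translocation", frozenset({"trnT"}))
        assert events[0].evidence == "pseudogene_remnant"


def random_event_program(rng: np.random.Generator, catalog):
    """Random, non-interacting event specs with their expected keys.

    Moves are constrained to keep events independent: each source and
    destination minichromosome is used once, and when an identity swap is
    injected the minichromosomes hosting the swapped pair are left
    untouched so the swap's context signature stays intact.
    """
    host = {g: mid for mid, entry in catalog.entries.items() for g, _ in entry}
    do_swap = rng.random() < 0.5
    protected = {host["trnL1"], host["trnL2"]} if do_swap else set()
    anchors = [(mid, g) for mid, entry in catalog.entries.items()
               for g, _ in entry
               if g in catalog.host_key(mid) and mid not in protected]
    movable = sorted(g for g in host
                     if g.startswith("trn") and g not in ("trnL1", "trnL2")
                     and host[g] not in protected)
    events, keys = [], set()
    used_mids: set[str] = set(protected)
    n_moves = int(rng.integers(1, 4))
    rng.shuffle(movable)
    for g in movable:
        if len(events) >= n_moves:
            break
        if host[g] in used_mids:
            continue
        choices = [(mid, a) for mid, a in anchors
                   if mid not in used_mids and mid != host[g]]
        if not choices:
            break
        used_mids.add(host[g])
        mid, anchor = choices[int(rng.integers(0, len(choices)))]
        used_mids.add(mid)
        side = "after" if rng.random() < 0.5 else "before"
        events.append(Translocation((g,), dest_anchor=anchor, side=side,
                                    leave_pseudogene=bool(rng.random() < 0.5)))
        keys.add(("translocation", frozenset({g})))
    if do_swap:
        events.append(IdentitySwap("trnL1", "trnL2"))
        keys.add(("identity_swap", frozenset({"trnL1", "trnL2"})))
    return events, keys


class TestEventRecovery:
    def test_perfect_recovery_over_20_seeds(self, ancestral_sim):
        """Arrangement-level precision and recall both 1.0 on synthetic
        sister pairs with randomly injected events."""
        genome, truth = ancestral_sim
        for seed in range(20):
            rng = np.random.default_rng(seed)
            events, expected = random_event_program(rng, truth.catalog)
            sister, st = derive_sister(genome, events, seed=seed)
            got = {e.key() for e in classify_events(truth.catalog, st.catalog,
                                                    genome, sister)}
            assert got == expected, f"seed {seed}"
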