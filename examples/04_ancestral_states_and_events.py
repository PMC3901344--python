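"""Which arrangements are ancestral, and what happened on each lineage?

Runs Dollo parsimony on the seven diagnostic junction characters over the
fixed louse phylogeny, then classifies the rearrangement events separating
the reconstructed ancestor from each rat-louse species.
"""

from minimt import classify_events, infer_ancestral_states
from minimt.compare import characters_from_table
from minimt import fixtures as fx

tree = fx.louse_tree()
chars = characters_from_table(fx.junction_table())
states = infer_ancestral_states(chars, tree)
print("ancestral at the root of the sampled lice:")
for ch in chars:
    print(f"  {ch.name}: {states[ch.name]['anoplura']}")

anc = fx.ancestral_catalog()
for cat in (fx.pa_catalog(), fx.ps_catalog()):
    print(f"\nevents on the lineage to {cat.species}:")
    for e in classify_events(anc, cat):
        print(f"  {e.type}: {'+'.join(e.genes)}")
# Pa: trnP and trnF translocated; Ps: trnT, trnA and the trnS1-trnS2 block
# translocated plus the leucine tRNAs swapping identities in place.
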