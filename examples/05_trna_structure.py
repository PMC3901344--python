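"""tRNA cloverleaf folding and the T-arm table.

Folds the generator's synthetic tRNA genes back into cloverleaves and
prints the published-style T-arm table (stem pairs, loop nt, arm nt with
Total and Mean rows) for both rat-louse species from the packaged values.
"""

from minimt import SimulationConfig, fold_trna, generate_genome, tarm_table
from minimt import fixtures as fx

genome, truth = generate_genome(SimulationConfig(seed=1))
mc, ann = genome.find_gene("trnA")
st = fold_trna(mc.gene_sequence(ann))
print(f"trnA folds: acceptor {st.acceptor_pairs} bp, D-arm {st.d_arm} nt, "
      f"anticodon {st.anticodon}, T-arm {st.t_arm} nt "
      f"({st.t_stem} pairs + {st.t_loop} nt loop)")

arms = fx.trna_arm_values()
for sp, label in (("pa", "Polyplax asiatica"), ("ps", "Polyplax spinulosa")):
    table = tarm_table({r.trna: (int(getattr(r, f"{sp}_tstem")),
                                 int(getattr(r, f"{sp}_tloop")))
                        for r in arms.itertuples()})
    total, mean = int(table.loc["Total", "arm_nt"]), table.loc["Mean", "arm_nt"]
    print(f"{label}: T-arm total {total} nt, mean {mean} nt")
# Long T-arms (alanine/cysteine in the more derived species) coincide with
# the recombination-length stretch those two genes share.
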