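"""Does fragmentation extent track life history?

Computes genes-per-minichromosome for five louse species and relates it
to body size and life-cycle length (range midpoints, Spearman with
average ranks).
"""

from minimt import life_history_association
from minimt.fragstats import fragmentation_records_from_table
from minimt import fixtures as fx

pairs = fragmentation_records_from_table(fx.life_history_table())
print("species                genes/minichromosome  life cycle (d)  body (mm)")
for frag, life in pairs:
    print(f"{frag.species:<22} {frag.genes_per_minichromosome:>6}"
          f"          {life.life_cycle_days}   {life.body_length_mm}")

rho, conc = life_history_association(pairs, "life_cycle")
print(f"\nlife cycle:  spearman rho = {rho:.4f}, concordant ordering = {conc}")
rho_b, conc_b = life_history_association(pairs, "body_length")
print(f"body length: spearman rho = {rho_b:.4f}, concordant ordering = {conc_b}")
# Less fragmented genomes (more genes per minichromosome) go with longer
# life cycles; body size shows no such ordering.
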