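"""Compare the mt gene arrangements of the two rat-louse species.

Loads the packaged arrangement catalogs of Polyplax asiatica and
Polyplax spinulosa and reports which minichromosomes are identical and
which tRNA genes sit on different host minichromosomes.
"""

from minimt import compare_catalogs, genes_per_minichromosome
from minimt import fixtures as fx

pa, ps = fx.pa_catalog(), fx.ps_catalog()
print(f"{pa.species}: {len(pa.gene_names())} genes on "
      f"{pa.n_minichromosomes} minichromosomes "
      f"({genes_per_minichromosome(pa).genes_per_minichromosome} genes each on average)")

cmp = compare_catalogs(pa, ps)
print(f"\nidentical minichromosomes ({cmp.n_identical}):")
for a, b in cmp.identical_minichromosomes:
    print(f"  {a}")
print(f"\ntRNAs on different host minichromosomes ({len(cmp.differing_trnas)}):")
print(" ", ", ".join(sorted(cmp.differing_trnas)))
print(f"protein-coding/rRNA genes on different hosts: {len(cmp.differing_pcg_rrna)}")

# The two species share the PCG/rRNA distribution entirely; the 8 differing
# tRNAs are the footprint of post-speciation translocations plus the
# leucine identity swap.
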