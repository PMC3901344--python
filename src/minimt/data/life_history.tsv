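# Adult body length (mm), life-cycle length (days) and genes per
# minichromosome of five blood-sucking louse species.
species	body_lo	body_hi	cycle_lo	cycle_hi	genes_per_mc	n_genes	n_minichromosomes	source
Haematopinus_suis	4	6	29	48	4.1	37	9	computed
Polyplax_spinulosa	0.6	1.5	25	28	3.4	37	11	computed
Pthirus_pubis	1.3	2.0	16	25	2.4	34	14	computed
Pediculus_humanus	2.3	3.6	14	20	2.1	37	20	catalog_constant
Pediculus_capitis	2.1	3.3	13	17	2.1	37	20	catalog_constant
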