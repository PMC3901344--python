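# Reconstructed arrangement of the most recent common ancestor of the
# Polyplax rat lice (ancestral junctions shared with pig/human lice).
# columns: species, minichrom_id, ordinal, gene, orientation
Polyplax_MRCA	atp8-atp6	1	atp8	+
Polyplax_MRCA	atp8-atp6	2	atp6	+
Polyplax_MRCA	cox1-trnL2	1	cox1	+
Polyplax_MRCA	cox1-trnL2	2	trnL2	+
Polyplax_MRCA	rrnS-trnC	1	rrnS	+
Polyplax_MRCA	rrnS-trnC	2	trnC	+
Polyplax_MRCA	trnD-trnY-cox2-nad6	1	trnD	+
Polyplax_MRCA	trnD-trnY-cox2-nad6	2	trnY	+
Polyplax_MRCA	trnD-trnY-cox2-nad6	3	cox2	+
Polyplax_MRCA	trnD-trnY-cox2-nad6	4	nad6	+
Polyplax_MRCA	trnE-cob-trnI	1	trnE	+
Polyplax_MRCA	trnE-cob-trnI	2	cob	+
Polyplax_MRCA	trnE-cob-trnI	3	trnI	+
Polyplax_MRCA	trnH-nad5-trnF	1	trnH	+
Polyplax_MRCA	trnH-nad5-trnF	2	nad5	+
Polyplax_MRCA	trnH-nad5-trnF	3	trnF	+
Polyplax_MRCA	trnK-nad4	1	trnK	+
Polyplax_MRCA	trnK-nad4	2	nad4	+
Polyplax_MRCA	trnM-trnL1-rrnL-trnV	1	trnM	+
Polyplax_MRCA	trnM-trnL1-rrnL-trnV	2	trnL1	+
Polyplax_MRCA	trnM-trnL1-rrnL-trnV	3	rrnL	+
Polyplax_MRCA	trnM-trnL1-rrnL-trnV	4	trnV	+
Polyplax_MRCA	trnQ-nad2-trnN	1	trnQ	+
Polyplax_MRCA	trnQ-nad2-trnN	2	nad2	+
Polyplax_MRCA	trnQ-nad2-trnN	3	trnN	+
Polyplax_MRCA	trnR-nad4L-trnP-cox3-trnA	1	trnR	+
Polyplax_MRCA	trnR-nad4L-trnP-cox3-trnA	2	nad4L	+
Polyplax_MRCA	trnR-nad4L-trnP-cox3-trnA	3	trnP	+
Polyplax_MRCA	trnR-nad4L-trnP-cox3-trnA	4	cox3	+
Polyplax_MRCA	trnR-nad4L-trnP-cox3-trnA	5	trnA	+
Polyplax_MRCA	trnS1-trnS2-nad1-trnT-trnG-nad3-trnW	1	trnS1	+
Polyplax_MRCA	trnS1-trnS2-nad1-trnT-trnG-nad3-trnW	2	trnS2	+
Polyplax_MRCA	trnS1-trnS2-nad1-trnT-trnG-nad3-trnW	3	nad1	-
Polyplax_MRCA	trnS1-trnS2-nad1-trnT-trnG-nad3-trnW	4	trnT	-
Polyplax_MRCA	trnS1-trnS2-nad1-trnT-trnG-nad3-trnW	5	trnG	+
Polyplax_MRCA	trnS1-trnS2-nad1-trnT-trnG-nad3-trnW	6	nad3	+
Polyplax_MRCA	trnS1-trnS2-nad1-trnT-trnG-nad3-trnW	7	trnW	+
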