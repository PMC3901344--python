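# Arrangement catalogs of the two Polyplax rat-louse mt genomes.
# columns: species, minichrom_id, ordinal, gene, orientation
Polyplax_asiatica	atp8-atp6	1	atp8	+
Polyplax_asiatica	atp8-atp6	2	atp6	+
Polyplax_asiatica	cox1-trnL2	1	cox1	+
Polyplax_asiatica	cox1-trnL2	2	trnL2	+
Polyplax_asiatica	rrnS-trnC	1	rrnS	+
Polyplax_asiatica	rrnS-trnC	2	trnC	+
Polyplax_asiatica	trnD-trnY-cox2-nad6	1	trnD	+
Polyplax_asiatica	trnD-trnY-cox2-nad6	2	trnY	+
Polyplax_asiatica	trnD-trnY-cox2-nad6	3	cox2	+
Polyplax_asiatica	trnD-trnY-cox2-nad6	4	nad6	+
Polyplax_asiatica	trnE-cob-trnI	1	trnE	+
Polyplax_asiatica	trnE-cob-trnI	2	cob	+
Polyplax_asiatica	trnE-cob-trnI	3	trnI	+
Polyplax_asiatica	trnH-nad5	1	trnH	+
Polyplax_asiatica	trnH-nad5	2	nad5	+
Polyplax_asiatica	trnK-nad4-trnF	1	trnK	+
Polyplax_asiatica	trnK-nad4-trnF	2	nad4	+
Polyplax_asiatica	trnK-nad4-trnF	3	trnF	+
Polyplax_asiatica	trnM-trnL1-rrnL-trnV	1	trnM	+
Polyplax_asiatica	trnM-trnL1-rrnL-trnV	2	trnL1	+
Polyplax_asiatica	trnM-trnL1-rrnL-trnV	3	rrnL	+
Polyplax_asiatica	trnM-trnL1-rrnL-trnV	4	trnV	+
Polyplax_asiatica	trnQ-nad2-trnN-trnP	1	trnQ	+
Polyplax_asiatica	trnQ-nad2-trnN-trnP	2	nad2	+
Polyplax_asiatica	trnQ-nad2-trnN-trnP	3	trnN	+
Polyplax_asiatica	trnQ-nad2-trnN-trnP	4	trnP	+
Polyplax_asiatica	trnR-nad4L-cox3-trnA	1	trnR	+
Polyplax_asiatica	trnR-nad4L-cox3-trnA	2	nad4L	+
Polyplax_asiatica	trnR-nad4L-cox3-trnA	3	cox3	+
Polyplax_asiatica	trnR-nad4L-cox3-trnA	4	trnA	+
Polyplax_asiatica	trnS1-trnS2-nad1-trnT-trnG-nad3-trnW	1	trnS1	+
Polyplax_asiatica	trnS1-trnS2-nad1-trnT-trnG-nad3-trnW	2	trnS2	+
Polyplax_asiatica	trnS1-trnS2-nad1-trnT-trnG-nad3-trnW	3	nad1	-
Polyplax_asiatica	trnS1-trnS2-nad1-trnT-trnG-nad3-trnW	4	trnT	-
Polyplax_asiatica	trnS1-trnS2-nad1-trnT-trnG-nad3-trnW	5	trnG	+
Polyplax_asiatica	trnS1-trnS2-nad1-trnT-trnG-nad3-trnW	6	nad3	+
Polyplax_asiatica	trnS1-trnS2-nad1-trnT-trnG-nad3-trnW	7	trnW	+
Polyplax_spinulosa	atp8-atp6	1	atp8	+
Polyplax_spinulosa	atp8-atp6	2	atp6	+
Polyplax_spinulosa	cox1-trnL1	1	cox1	+
Polyplax_spinulosa	cox1-trnL1	2	trnL1	+
Polyplax_spinulosa	nad1-trnG-nad3-trnW	1	nad1	-
Polyplax_spinulosa	nad1-trnG-nad3-trnW	2	trnG	+
Polyplax_spinulosa	nad1-trnG-nad3-trnW	3	nad3	+
Polyplax_spinulosa	nad1-trnG-nad3-trnW	4	trnW	+
Polyplax_spinulosa	trnE-cob-trnI	1	trnE	+
Polyplax_spinulosa	trnE-cob-trnI	2	cob	+
Polyplax_spinulosa	trnE-cob-trnI	3	trnI	+
Polyplax_spinulosa	trnH-nad5-trnF	1	trnH	+
Polyplax_spinulosa	trnH-nad5-trnF	2	nad5	+
Polyplax_spinulosa	trnH-nad5-trnF	3	trnF	+
Polyplax_spinulosa	trnK-nad4	1	trnK	+
Polyplax_spinulosa	trnK-nad4	2	nad4	+
Polyplax_spinulosa	trnM-trnL2-rrnL-trnV	1	trnM	+
Polyplax_spinulosa	trnM-trnL2-rrnL-trnV	2	trnL2	+
Polyplax_spinulosa	trnM-trnL2-rrnL-trnV	3	rrnL	+
Polyplax_spinulosa	trnM-trnL2-rrnL-trnV	4	trnV	+
Polyplax_spinulosa	trnQ-nad2-trnN	1	trnQ	+
Polyplax_spinulosa	trnQ-nad2-trnN	2	nad2	+
Polyplax_spinulosa	trnQ-nad2-trnN	3	trnN	+
Polyplax_spinulosa	trnR-nad4L-trnP-cox3	1	trnR	+
Polyplax_spinulosa	trnR-nad4L-trnP-cox3	2	nad4L	+
Polyplax_spinulosa	trnR-nad4L-trnP-cox3	3	trnP	+
Polyplax_spinulosa	trnR-nad4L-trnP-cox3	4	cox3	+
Polyplax_spinulosa	trnS1-trnS2-rrnS-trnC	1	trnS1	+
Polyplax_spinulosa	trnS1-trnS2-rrnS-trnC	2	trnS2	+
Polyplax_spinulosa	trnS1-trnS2-rrnS-trnC	3	rrnS	+
Polyplax_spinulosa	trnS1-trnS2-rrnS-trnC	4	trnC	+
Polyplax_spinulosa	trnT-trnD-trnY-cox2-nad6-trnA	1	trnT	+
Polyplax_spinulosa	trnT-trnD-trnY-cox2-nad6-trnA	2	trnD	+
Polyplax_spinulosa	trnT-trnD-trnY-cox2-nad6-trnA	3	trnY	+
Polyplax_spinulosa	trnT-trnD-trnY-cox2-nad6-trnA	4	cox2	+
Polyplax_spinulosa	trnT-trnD-trnY-cox2-nad6-trnA	5	nad6	+
Polyplax_spinulosa	trnT-trnD-trnY-cox2-nad6-trnA	6	trnA	+
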