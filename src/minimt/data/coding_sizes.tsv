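# Coding-region sizes (bp) and Illumina read counts per minichromosome
minichromosome	pa_coding_bp	ps_coding_bp	pa_reads	ps_reads
atp8-atp6	838	832	73276	143560
trnE-cob-trnI	1242	1228	47008	50108
cox1-trnL	1626	1599	49653	49675
trnD-trnY-cox2-nad6	1292	1399	35911	41691
trnR-nad4L-cox3	1268	1190	36763	64203
nad1-trnG-nad3-trnW	1602	1419	21705	66380
trnQ-nad2-trnN	1385	1134	24989	46412
trnK-nad4	1465	1331	38589	78061
trnH-nad5	1756	1816	39554	44417
rrnS-trnC	802	904	121142	165740
trnM-rrnL-trnV	1333	1237	57476	96783
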