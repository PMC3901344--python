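# T-stem pairs and T-loop nt of the 22 mt tRNAs (arm = 2*stem + loop)
trna	anticodon	pa_tstem	ps_tstem	pa_tloop	ps_tloop
trnA	UGC	5	8	7	9
trnC	GCA	4	7	5	9
trnD	GUC	4	4	3	4
trnE	UUC	5	3	11	4
trnF	GAA	5	4	6	4
trnG	UCC	5	3	5	6
trnH	GUG	4	5	4	3
trnI	GAU	5	3	6	4
trnK	UUU	5	3	3	3
trnL1	UAG	5	4	4	3
trnL2	UAA	5	4	6	4
trnM	CAU	3	4	10	3
trnN	GUU	5	3	4	3
trnP	UGG	4	4	4	3
trnQ	UUG	5	5	6	6
trnR	UCG	5	3	6	4
trnS1	UCU	5	5	8	10
trnS2	UGA	5	5	6	4
trnT	UGU	3	4	5	3
trnV	UAC	5	3	9	4
trnW	UCA	6	5	8	4
trnY	GUA	3	3	4	4
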