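# Gene-adjacency / whole-minichromosome characters and the louse
# species in which each arrangement is observed.
name	kind	state	present_in
rrnS-trnC_minichromosome	minichromosome	rrnS+,trnC+	Polyplax_asiatica,Haematopinus_suis,Haematopinus_apri
nad1-trnT-trnG-nad3-trnW_arrangement	arrangement	nad1-,trnT-,trnG+,nad3+,trnW+	Polyplax_asiatica,Haematopinus_suis,Haematopinus_apri
cox3-trnA_adjacency	adjacency	cox3+,trnA+	Polyplax_asiatica,Haematopinus_suis,Haematopinus_apri,Pediculus_humanus,Pediculus_capitis,Pthirus_pubis
trnP-cox3_adjacency	adjacency	trnP+,cox3+	Polyplax_spinulosa,Haematopinus_suis,Haematopinus_apri
nad5-trnF_adjacency	adjacency	nad5+,trnF+	Polyplax_spinulosa,Haematopinus_suis,Haematopinus_apri
cox1-trnL2_adjacency	adjacency	cox1+,trnL2+	Polyplax_asiatica,Haematopinus_suis,Haematopinus_apri
trnL1-rrnL_adjacency	adjacency	trnL1+,rrnL+	Polyplax_asiatica,Haematopinus_suis,Haematopinus_apri,Pediculus_humanus,Pediculus_capitis
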