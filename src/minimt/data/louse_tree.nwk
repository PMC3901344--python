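(((Polyplax_asiatica,Polyplax_spinulosa)rat_lice,(Pediculus_humanus,Pediculus_capitis,Pthirus_pubis)human_lice)rat_human_lice,(Haematopinus_suis,Haematopinus_apri)pig_lice)anoplura;
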