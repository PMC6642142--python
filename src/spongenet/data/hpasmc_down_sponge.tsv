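lnc_id	lnc_fc	lnc_p	mirna_id	binding_sites	mirna_fc	mirna_p
ENST00000596769	-2.8621	0.0043	hsa-miR-133a-3p	7	1.6677	0.0919
ENST00000596769	-2.8621	0.0043	hsa-miR-130b-5p	4	1.7023	0.0386
ENST00000603037	-1.5199	0.0208	hsa-let-7a-5p	4	2.1128	0.0011
TCONS_00014969	-3.2602	0.0194	hsa-miR-125b-5p	4	1.5854	0.0032
ENST00000589511	-2.6857	0.0467	hsa-miR-125b-5p	4	1.5854	0.0032
TCONS_00012168	-1.6284	0.0000	hsa-miR-130b-5p	4	1.7023	0.0386
TCONS_00026830	-4.1484	0.0010	hsa-let-7a-5p	3	2.1128	0.0011
ENST00000412149	-1.5780	0.0134	hsa-miR-10b-5p	3	1.6354	0.0038
ENST00000412149	-1.5780	0.0134	hsa-miR-125b-5p	3	1.5854	0.0032
ENST00000603095	-1.7070	0.0282	hsa-miR-133a-3p	3	1.6677	0.0919
ENST00000596769	-2.8621	0.0043	hsa-miR-10b-5p	2	1.6354	0.0038
TCONS_00026830	-4.1484	0.0010	hsa-miR-130b-5p	2	1.7023	0.0386
ENST00000595853	-2.6963	0.0011	hsa-miR-130b-5p	2	1.7023	0.0386
ENST00000569618	-2.0383	0.0213	hsa-miR-98-3p	2	1.7129	0.0391
ENST00000521148	-1.5589	0.0243	hsa-miR-10b-5p	1	1.6354	0.0038
ENST00000549516	-2.2653	0.0242	hsa-miR-125b-5p	1	1.5854	0.0032
ENST00000518355	-1.7250	0.0039	hsa-miR-125b-5p	1	1.5854	0.0032
ENST00000570084	-1.8786	0.0116	hsa-miR-130b-5p	1	1.7023	0.0386
ENST00000422345	-2.2413	0.0100	hsa-miR-133a-3p	1	1.6677	0.0919
TCONS_00013442	-1.8486	0.0223	hsa-miR-133a-3p	1	1.6677	0.0919
TCONS_00013442	-1.8486	0.0223	hsa-miR-454-3p	1	2.2159	0.0003
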