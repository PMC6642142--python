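lnc_id	lnc_fc	lnc_p	mirna_id	binding_sites	mirna_fc	mirna_p
TCONS_00001909	1.631	0.037	hsa-miR-376b-5p	22	-3.855	0.029
TCONS_00001909	1.631	0.037	hsa-miR-193a-3p	7	-3.381	0.002
TCONS_00001909	1.631	0.037	hsa-miR-370-3p	6	-2.299	0.001
TCONS_00028198	1.552	0.018	hsa-miR-376b-5p	15	-3.855	0.029
TCONS_00028198	1.552	0.018	hsa-miR-33a-3p	13	-2.98	0.012
TCONS_00028198	1.552	0.018	hsa-miR-185-5p	21	-2.865	0.007
ENST00000585387	1.735	0.011	hsa-miR-491-5p	2	-2.585	0.041
ENST00000585387	1.735	0.011	hsa-miR-185-5p	2	-2.865	0.007
ENST00000585387	1.735	0.011	hsa-miR-654-5p	1	-1.787	0.019
TCONS_00022282	1.573	0.017	hsa-miR-185-5p	3	-2.865	0.007
TCONS_00025369	2.04	0.007	hsa-miR-491-5p	1	-2.585	0.041
TCONS_00012383	1.73	0.013	hsa-miR-185-5p	1	-2.865	0.007
TCONS_00012383	1.73	0.013	hsa-miR-503-5p	1	-4.321	0.0035
ENST00000595383	1.78	0.007	hsa-miR-1277-5p	1	-1.709	0.0145
ENST00000595383	1.78	0.007	hsa-miR-33a-3p	1	-2.98	0.012
TCONS_00024430	1.77	0.015	hsa-miR-324-3p	2	-2.066	0.0391
ENST00000412357	1.54	0.048	hsa-miR-33a-5p	2	-3.541	0.0001
ENST00000429843	1.83	0.015	hsa-miR-146a-5p	1	-3.066	0.0023
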