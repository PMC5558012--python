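# Published characterization of a nine-antibody anti-NGF panel (mAb1-mAb9):
# predicted solubility scores (a.u.) for the VH domain, VL domain and the
# combined VH-VL complex; measured PEG_half (% PEG w/v) and apparent
# solubility (mg/mL) with 95% bootstrap confidence bounds; thermal
# stability metadata Tm1 (DSC) and TH (DSF), degrees C.
variant	score_vh	score_vl	score_combined	peg_half	peg_half_lo	peg_half_hi	apparent_solubility	apparent_solubility_lo	apparent_solubility_hi	tm1	th
mAb1	0.383	0.696	0.025	4.9	4.5	5.1	18.8	9.7	36.9	65.9	59.8
mAb2	-0.304	0.708	-0.465	0.4	0.32	0.47	0.78	0.7	0.86	55	50.6
mAb3	0.287	0.751	-0.008	0.44	0.41	0.48	0.89	0.78	1.01	54.8	51.3
mAb4	0.42	0.645	0.017	5	4.8	5.1	29.3	12.5	68.3	55.3	51.5
mAb5	0.488	0.645	0.067	6.9	6.8	7.2	78.2	27.6	207.8	55.4	50
mAb6	0.007	0.696	-0.248	2	1.9	2	2.9	2.2	3.7	54.1	48.7
mAb7	0.38	0.775	0.076	5.5	5.3	5.8	23.3	5.8	97.1	55.3	51.6
mAb8	0.282	0.557	-0.142	4.8	4.6	5	27.2	16.5	44	55.5	51.5
mAb9	0.378	0.584	-0.053	5.7	5.5	5.8	50.6	26.9	94.7	55.8	51.3
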