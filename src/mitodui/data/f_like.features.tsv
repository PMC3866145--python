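label	kind	start	end	strand	wraps_origin	incomplete_stop
cox1	PCG	0	1545	1	0	0
trnV	tRNA	1591	1656	1	0	0
cox2	PCG	1681	2362	1	0	0
trnE	tRNA	2387	2452	1	0	0
FORF	ORF	2477	2738	1	0	0
trnW	tRNA	2763	2828	1	0	0
nad2	PCG	2853	3816	1	0	0
trnS1	tRNA	3841	3906	1	0	0
nad3	PCG	3931	4288	1	0	0
trnM	tRNA	4313	4378	1	0	0
rrnS	rRNA	4378	5235	1	0	0
trnK	tRNA	5235	5300	1	0	0
trnT	tRNA	5300	5365	1	0	0
trnY	tRNA	5365	5430	1	0	0
rrnL	rRNA	5430	6726	1	0	0
trnL1	tRNA	6726	6787	1	0	0
cob	PCG	6812	7973	1	0	0
trnP	tRNA	7972	8037	1	0	0
nad5	PCG	8062	9796	1	0	0
trnQ	tRNA	10845	10910	1	0	0
trnC	tRNA	10935	11000	-1	0	0
nad1	PCG	11025	11922	-1	0	0
trnI	tRNA	11947	12012	-1	0	0
nad6	PCG	12037	12526	1	0	0
trnN	tRNA	12551	12616	1	0	0
nad4	PCG	12641	13991	-1	0	0
nad4L	PCG	13983	14280	-1	0	0
trnD	tRNA	14305	14370	-1	0	0
atp8	PCG	14370	14568	-1	0	0
trnA	tRNA	14593	14667	1	0	0
atp6	PCG	14667	15375	-1	0	0
trnR	tRNA	15400	15465	1	0	0
cox3	PCG	15465	16245	-1	0	0
trnG	tRNA	16270	16331	1	0	0
trnL2	tRNA	16356	16421	1	0	0
trnF	tRNA	16446	16511	1	0	0
trnS2	tRNA	16536	16601	-1	0	0
trnH	tRNA	16626	16691	-1	0	0
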