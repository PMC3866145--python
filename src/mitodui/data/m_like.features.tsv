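label	kind	start	end	strand	wraps_origin	incomplete_stop
cox1	PCG	0	1602	1	0	0
trnV	tRNA	1633	1698	1	0	0
cox2	PCG	1716	2940	1	0	0
trnE	tRNA	2958	3023	1	0	0
trnW	tRNA	3041	3106	1	0	0
nad3	PCG	3124	3484	1	0	0
trnS1	tRNA	3502	3567	1	0	0
nad2	PCG	3585	4581	1	0	0
trnM	tRNA	4579	4644	1	0	0
rrnS	rRNA	4644	5501	1	0	0
trnK	tRNA	5501	5566	1	0	0
trnT	tRNA	5566	5631	1	0	0
trnY	tRNA	5631	5693	1	0	0
rrnL	rRNA	5693	7006	1	0	0
trnL1	tRNA	7006	7071	1	0	0
cob	PCG	7089	8238	1	0	0
trnN	tRNA	8256	8321	1	0	0
trnP	tRNA	8320	8385	1	0	0
nad5	PCG	8403	10167	1	0	0
trnH	tRNA	10185	10256	-1	0	0
trnQ	tRNA	11104	11169	1	0	0
trnC	tRNA	11168	11233	-1	0	0
nad1	PCG	11251	12160	-1	0	0
trnI	tRNA	12178	12243	-1	0	0
nad6	PCG	12261	12942	1	0	0
nad4	PCG	12774	14148	-1	0	0
nad4L	PCG	14141	14441	-1	0	0
MORF	ORF	14459	14894	-1	0	0
atp8	PCG	14912	15089	-1	0	0
trnD	tRNA	15089	15154	-1	0	0
trnA	tRNA	15172	15237	1	0	0
atp6	PCG	15237	15921	-1	0	0
trnR	tRNA	15939	16004	1	0	0
trnG	tRNA	16004	16069	1	0	0
trnL2	tRNA	16087	16152	1	0	0
trnF	tRNA	16170	16235	1	0	0
trnS2	tRNA	16253	16318	-1	0	0
cox3	PCG	16336	8	-1	1	0
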