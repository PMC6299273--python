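# Published annotation of the Melarhaphe neritoides mitogenome (GenBank MH119311).
# Genome length 15676 bp, circular. Coordinates 1-based inclusive.
gene	kind	strand	start	end	start_codon	stop_codon
cox1	PCG	+	1	1536	ATG	TAA
cox2	PCG	+	1548	2234	ATG	TAA
trnD(gtc)	tRNA	+	2240	2307
atp8	PCG	+	2309	2467	ATG	TAA
atp6	PCG	+	2470	3165	ATT	TAA
trnM(cat)	tRNA	-	3204	3271
trnY(gta)	tRNA	-	3273	3340
trnC(gca)	tRNA	-	3342	3407
trnW(tca)	tRNA	-	3409	3474
trnQ(ttg)	tRNA	-	3477	3533
trnG(tcc)	tRNA	-	3541	3607
trnE(ttc)	tRNA	-	3608	3672
rrnS	rRNA	+	3751	4632
trnV(tac)	tRNA	+	4630	4696
rrnL	rRNA	+	4674	6087
trnL2(taa)	tRNA	+	6052	6121
trnL1(tag)	tRNA	+	6124	6191
nad1	PCG	+	6192	7133	ATG	TAG
trnP(tgg)	tRNA	+	7134	7200
nad6	PCG	+	7202	7705	ATG	TAA
cob	PCG	+	7714	8853	ATG	TAG
trnS2(tga)	tRNA	+	8863	8929
trnT(tgt)	tRNA	-	8930	8999
nad4l	PCG	+	9008	9304	ATG	TAA
nad4	PCG	+	9298	10668	ATG	TAA
trnH(gtg)	tRNA	+	10669	10732
nad5	PCG	+	10733	12454	ATG	TAA
trnF(gaa)	tRNA	+	12454	12520
CR	control_region	+	12521	12994
cox3	PCG	+	12995	13774	ATG	TAA
trnK(ttt)	tRNA	+	13807	13878
trnA(tgc)	tRNA	+	13890	13957
trnR(tcg)	tRNA	+	13959	14027
trnN(gtt)	tRNA	+	14038	14104
trnI(gat)	tRNA	+	14120	14186
nad3	PCG	+	14190	14543	ATG	TAA
trnS1(gct)	tRNA	+	14544	14611
nad2	PCG	+	14612	15673	ATG	TAG
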