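# Published per-region nucleotide composition of the Melarhaphe neritoides
# mitogenome (GenBank MH119311); percentages as printed (1 decimal).
region	A_pct	C_pct	G_pct	T_pct
whole_mitogenome	28.9	16.6	17.1	37.4
cox1	26.0	17.3	19.3	37.4
cox2	29.1	17.5	18.5	34.9
atp8	30.2	15.7	15.1	39.0
atp6	24.9	17.1	15.5	42.5
rrnS	30.7	13.8	37.5	17.9
rrnL	36.1	12.5	36.4	15.0
nad1	25.7	16.8	17.1	40.4
nad6	26.8	15.7	16.1	41.5
cob	24.6	18.7	17.7	39.0
nad4l	27.9	15.8	17.2	39.1
nad4	26.4	19.0	15.2	39.4
nad5	25.7	20.1	15.9	38.3
CR	32.7	19.8	15.8	31.6
cox3	24.4	18.6	22.2	34.9
nad3	28.2	15.0	19.5	37.3
nad2	27.7	13.2	17.5	41.6
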