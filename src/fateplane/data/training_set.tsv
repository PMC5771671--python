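# Training proportions for the geometric vulval model: percent of animals in
# which each cell adopts fate 1/2/3, per experiment.  Sources: classical
# EGF/Notch genetics (mosaics, half doses, Notch nulls, lin-15), measured and
# fitted EGF-overexpression lines, anchor-cell ablations at successive stages
# (mapped to evenly spaced model times), and the low-EGF x Notch epistasis
# lines.  scored=0 marks cells not scored in that experiment.  The lin-15
# phenotype (all cells induced, alternating 1/2 fates, with or without the
# anchor cell) has no per-cell percentages and is flagged kind=alternating.
# Rows may sum to 99-101 because the sources print rounded percents; the
# reader renormalizes.
experiment	cell	kind	p1	p2	p3	scored
WT	P4.p	proportions	0	0	100	1
WT	P5.p	proportions	0	100	0	1
WT	P6.p	proportions	100	0	0	1
WT	P7.p	proportions	0	100	0	1
WT	P8.p	proportions	0	0	100	1
let-23-mosaic	P4.p	proportions	0	0	100	1
let-23-mosaic	P5.p	proportions	0	100	0	1
let-23-mosaic	P6.p	proportions	100	0	0	1
let-23-mosaic	P7.p	proportions	0	100	0	1
let-23-mosaic	P8.p	proportions	0	0	100	1
half-dose-EGF	P4.p	proportions	0	0	100	1
half-dose-EGF	P5.p	proportions	0	100	0	1
half-dose-EGF	P6.p	proportions	100	0	0	1
half-dose-EGF	P7.p	proportions	0	100	0	1
half-dose-EGF	P8.p	proportions	0	0	100	1
half-dose-Notch	P4.p	proportions	0	0	100	1
half-dose-Notch	P5.p	proportions	0	100	0	1
half-dose-Notch	P6.p	proportions	100	0	0	1
half-dose-Notch	P7.p	proportions	0	100	0	1
half-dose-Notch	P8.p	proportions	0	0	100	1
Notch-null	P4.p	proportions	0	0	100	1
Notch-null	P5.p	proportions	0	0	100	1
Notch-null	P6.p	proportions	100	0	0	1
Notch-null	P7.p	proportions	0	0	100	1
Notch-null	P8.p	proportions	0	0	100	1
Notch-null-2AC	P4.p	proportions	0	0	100	1
Notch-null-2AC	P5.p	proportions	100	0	0	1
Notch-null-2AC	P6.p	proportions	100	0	0	1
Notch-null-2AC	P7.p	proportions	100	0	0	1
Notch-null-2AC	P8.p	proportions	0	0	100	1
lin-15	P4.p	alternating	0	0	0	1
lin-15	P5.p	alternating	0	0	0	1
lin-15	P6.p	alternating	0	0	0	1
lin-15	P7.p	alternating	0	0	0	1
lin-15	P8.p	alternating	0	0	0	1
JU1107	P4.p	proportions	2	16	82	1
JU1107	P5.p	proportions	22	78	0	1
JU1107	P6.p	proportions	100	0	0	1
JU1107	P7.p	proportions	16	84	0	1
JU1107	P8.p	proportions	3	13	84	1
JU1100	P4.p	proportions	24	54	21	1
JU1100	P5.p	proportions	54	46	0	1
JU1100	P6.p	proportions	96	4	0	1
JU1100	P7.p	proportions	37	63	0	1
JU1100	P8.p	proportions	12	39	49	1
ablation-L2-lethargus	P4.p	proportions	0	0	0	0
ablation-L2-lethargus	P5.p	proportions	0	0	100	1
ablation-L2-lethargus	P6.p	proportions	0	0	100	1
ablation-L2-lethargus	P7.p	proportions	0	0	100	1
ablation-L2-lethargus	P8.p	proportions	0	0	0	0
ablation-early-L3	P4.p	proportions	0	0	0	0
ablation-early-L3	P5.p	proportions	3	24	74	1
ablation-early-L3	P6.p	proportions	18	19	64	1
ablation-early-L3	P7.p	proportions	0	20	80	1
ablation-early-L3	P8.p	proportions	0	0	0	0
ablation-DU-divided	P4.p	proportions	0	0	0	0
ablation-DU-divided	P5.p	proportions	0	59	41	1
ablation-DU-divided	P6.p	proportions	31	37	32	1
ablation-DU-divided	P7.p	proportions	0	53	47	1
ablation-DU-divided	P8.p	proportions	0	0	0	0
ablation-VU-divided	P4.p	proportions	0	0	0	0
ablation-VU-divided	P5.p	proportions	0	95	5	1
ablation-VU-divided	P6.p	proportions	53	48	0	1
ablation-VU-divided	P7.p	proportions	8	86	6	1
ablation-VU-divided	P8.p	proportions	0	0	0	0
ablation-3-divided	P4.p	proportions	0	0	0	0
ablation-3-divided	P5.p	proportions	3	98	0	1
ablation-3-divided	P6.p	proportions	65	35	0	1
ablation-3-divided	P7.p	proportions	0	100	0	1
ablation-3-divided	P8.p	proportions	0	0	0	0
ablation-two-cell	P4.p	proportions	0	0	0	0
ablation-two-cell	P5.p	proportions	1	99	0	1
ablation-two-cell	P6.p	proportions	93	7	0	1
ablation-two-cell	P7.p	proportions	1	99	0	1
ablation-two-cell	P8.p	proportions	0	0	0	0
CB1417	P4.p	proportions	0	0	100	1
CB1417	P5.p	proportions	0	10	90	1
CB1417	P6.p	proportions	54	0	46	1
CB1417	P7.p	proportions	0	10	90	1
CB1417	P8.p	proportions	0	0	100	1
JU2064	P4.p	proportions	0	1	99	1
JU2064	P5.p	proportions	0	100	0	1
JU2064	P6.p	proportions	100	0	0	1
JU2064	P7.p	proportions	0	100	0	1
JU2064	P8.p	proportions	1	2	97	1
JU2095	P4.p	proportions	0	0	100	1
JU2095	P5.p	proportions	1	14	86	1
JU2095	P6.p	proportions	72	1	28	1
JU2095	P7.p	proportions	0	16	84	1
JU2095	P8.p	proportions	0	2	98	1
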