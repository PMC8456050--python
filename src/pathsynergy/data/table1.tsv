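compound	cell_line	single_or_comb	score_type	comb_score	single_score	gi50_nM	gi90_nM	loewe_combenefit	bliss_combenefit
Semagacestat	PANC-1	C	PC	NA	NA	>10000	>10000	27.40	8.90
Gemcitabine	PANC-1	S	PC	NA	-0.45	152	>10000	3.40	0.00
Scriptaid	PANC-1	S&C	Res	-0.89	-0.33	3218	>10000	33.30	10.40
Tacedinaline	PANC-1	S&C	Res	-0.84	-0.39	>10000	>10000	26.50	8.00
Salmeterol	PANC-1	S&C	Res	-0.84	-0.33	4248	>10000	14.20	2.10
Triclosan	PANC-1	C	Res	-1.00	-0.28	>10000	>10000	13.10	5.20
Entinostat	PANC-1	S&C	Res/Score1	-0.78	-0.45	11007	16626	51.50	26.70
Entinostat	HPAF2	C	NA	NA	NA	NA	NA	NA	NA
Entinostat	K8484	C	NA	NA	NA	NA	NA	NA	NA
Entinostat	MIA PaCa2	C	NA	NA	NA	NA	NA	NA	NA
Entinostat	TB32048	C	NA	NA	NA	NA	NA	NA	NA
Saracatinib	PANC-1	S&C	Score1	-0.66	-0.33	>10000	>10000	40.00	22.10
Thioridazine	PANC-1	C	Score1	-0.73	-0.21	9318	16163	34.10	20.30
Loperamide	PANC-1	S&C	Score1	-0.71	-0.36	3200	>10000	23.20	12.10
RS-17053	PANC-1	S&C	Score1	-0.83	-0.39	3154	5275	1.60	0.50
TW-37	PANC-1	C	Score2	-0.81	-0.26	3722	3761	15.10	1.20
Digoxin	PANC-1	C	Score2	-0.83	-0.21	25	66	6.70	5.30
Maprotiline	PANC-1	S&C	Selected CM	NA	-0.35	>10000	>10000	12.10	5.30
Racecadotril	PANC-1	S&C	Selected CM&FoM	NA	-0.36	>10000	>10000	31.30	24.00
Y-134	PANC-1	S&C	Selected CM&SS	NA	-0.41	>10000	>10000	18.40	6.00
Dibenzazepine	PANC-1	S&C	Selected HS&FrM	NA	-0.45	8975	13108	20.60	7.30
Palbociclib	PANC-1	S&C	Selected MK&AB&HS	NA	-0.45	6285	>10000	7.00	2.90
Actinomycin D	PANC-1	S	NA	NA	-0.31	<1	4	18.70	1.30
L-168	PANC-1	S	NA	NA	-0.28	>10000	>10000	17.20	5.00
Clofarabine	PANC-1	S	NA	NA	-0.40	>10000	>10000	15.40	8.40
BX-795	PANC-1	S	NA	NA	-0.40	1619	9207	13.80	0.30
Teniposide	PANC-1	S	NA	NA	-0.45	546	4371	11.60	1.80
Ciclopirox	PANC-1	S	NA	NA	-0.40	1002	1134	11.00	3.90
Ursolic acid	PANC-1	S	NA	NA	-0.16	>10000	>10000	11.00	2.30
Phloretin	PANC-1	S	NA	NA	-0.40	>10000	>10000	8.10	8.10
BMS-387032	PANC-1	S	NA	NA	-0.38	114	218	7.70	1.90
Serdemetan	PANC-1	S	NA	NA	-0.42	3094	>10000	7.70	3.00
Leelamine	PANC-1	S	NA	NA	-0.31	7567	9462	7.20	3.50
STK525924	PANC-1	S	NA	NA	-0.43	6684	11519	7.20	1.40
Medroxyprogesterone	PANC-1	S	NA	NA	-0.36	>10000	>10000	2.10	0.10
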