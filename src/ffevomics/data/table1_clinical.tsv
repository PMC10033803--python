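variable	units	control_1	control_2	control_3	case_1	case_2	case_3	printed_p
Age	years	28.5	27.3	29.2	25.3	26.5	28.6	0.240209
BMI	kg/m^2	23.3	24.9	22.0	19.9	23.0	24.7	0.624407
LH	IU/L	6.1	8.1	5.1	10.1	12.3	14.9	0.0217718
FSH	IU/L	7.0	6.0	7.8	6.4	6.0	5.1	0.164435
E2	pmol/L	119.7	106.3	132.5	168.6	158.3	159.6	0.00658136
T	nmol/L	1.0	0.5	1.3	3.5	2.9	2.3	0.0092485
FBG	mmol/L	5.1	5.2	5.0	5.0	5.2	5.3	0.561437
Infertility	years	3.9	3.6	4.1	2.9	2.6	3.5	0.0454128
PRL	ng/mL	19.8	25.3	15.4	31.6	36.5	42.9	0.0179693
AMH	ng/mL	4.1	5.6	6.8	9.2	11.9	13.5	0.0150721
Follicles	count	12	11	12	22	22	21	<0.0001
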