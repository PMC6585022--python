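family	gene	cytoband	accession
AZIN	AZIN2	1p35.1	Q96A70
AZIN	ODC1	2p25	P11926
AZIN	AZIN1	8q22.3	O14977
CHRN	CHRNB2	1q21.3	P17787
CHRN	CHRNG	2q37.1	P07510
CHRN	CHRND	2q37.1	Q07001
CHRN	CHRNA1	2q31.1	P02708
CHRN	CHRNA2	8p21	Q15822
CHRN	CHRNA6	8p11.21	Q15825
CHRN	CHRNB3	8p11.2	Q05901
CHRN	CHRNA4	20q13.33	P43681
CHRN	CHRNA3	15q24	P32297
CHRN	CHRNB4	15q24	P30926
CHRN	CHRNB1	17p13.1	P11230
CHRN	CHRNE	17p13.2	Q04844
CHRN	CHRNA5	15q24	P30532
CRO	CROCC	1p36.13	Q5TZA2
CRO	CROCC2	2q37.3	H7BZ55
CRO	CEP250	20q11.22	Q9BV73
DLGAP	DLGAP3	1p35.3-p34.1	O95886
DLGAP	DLGAP1	18p11.31	O14490
DLGAP	DLGAP5	14q22.3	Q15398
DLGAP	DLGAP2	8p23	Q9P1A6
DLGAP	DLGAP4	20q11.23	Q9Y2H0
E2F	E2F2	1p36	Q14209
E2F	E2F6	2p25.1	O75461
E2F	E2F5	8q21.2	Q15329
E2F	E2F1	20q11.2	Q01094
E2F	E2F3	6p22	O00716
E2F	E2F4	16q22.1	Q16254
FAM110	FAM110D	1p36.11	Q8TAY7
FAM110	FAM110C	2p25.3	Q1W6H9
FAM110	FAM110B	8q12.1	Q8TC76
FAM110	FAM110A	20p13	Q9BQ89
GRHL	GRHL3	1p36.11	Q8TE85
GRHL	TFCP2L1	2q14	Q9NZI6
GRHL	GRHL1	2p25.1	Q9NZI5
GRHL	GRHL2	8q22.3	Q6ISB3
GRHL	TFCP2	12q13	Q12800
GRHL	UBP1	3p22.3	Q9NZI7
ID	ID3	1p36.13-p36.12	Q02535
ID	ID2	2p25	Q02363
ID	ID1	20q11	P41134
ID	ID4	6p22.3	P47928
MROH	MROH9	1q24.3	Q5TGP6
MROH	MROH7	1p32.3	Q68CQ1
MROH	MROH6	8q24.3	A6NGR9
MROH	MROH5	8q24.3	Q6ZUA9
MROH	MROH8	20q11.22	Q9H579
MYT	MYT1L	2p25.3	Q9UL68
MYT	ST18	8q11.23	O60284
MYT	MYT1	20q13.33	Q01538
NCOA	NCOA1	2p23	Q15788
NCOA	NCOA2	8q13.3	Q15596
NCOA	NCOA3	20q12	Q9Y6Q9
NKAIN	NKAIN1	1p35.2	Q4KMZ8
NKAIN	NKAIN3	8q12.3	Q8N8D7
NKAIN	NKAIN4	20q13.33	Q8IVV8
NKAIN	NKAIN2	6q21	Q5VXU1
KCNQ	KCNQ4	1p34	P56696
KCNQ	KCNQ3	8q24	O43525
KCNQ	KCNQ2	20q13.3	O43526
KCNQ	KCNQ5	6q14	Q9NR82
KCNQ	KCNQ1	11p15.5	P51787
RGS	RGS13	1q31.2	O14921
RGS	RGS8	1q25	P57771
RGS	RGS1	1q31	Q08116
RGS	RGS18	1q31.2	Q9NS28
RGS	RGS16	1q25-q31	O15492
RGS	RGS21	1q31.2	Q2M5E4
RGS	RGS4	1q23.3	P49798
RGS	RGS2	1q31	P41220
RGS	RGS20	8q11.23	O76081
RGS	RGS19	20q13.33	P49795
RGS	RGS17	6q25.3	Q9UGC6
RGS	RGS3	9q32	P49796
RGS	RGS5	1q23.1	O15539
RIMS	RIMS3	1p34.2	Q9UJD0
RIMS	RIMS2	8q22.3	Q9UQ26
RIMS	RIMS4	20q13.12	Q9H426
RIMS	RIMS1	6q12-q13	Q86UR5
RSPO	RSPO1	1p34.3	Q2MKA7
RSPO	RSPO2	8q23.1	Q6UXX9
RSPO	RSPO4	20p13	Q2I0M5
RSPO	RSPO3	6q22.33	Q9BXY4
SLC	SLC30A2	1p35.3	Q9BRI3
SLC	SLC30A10	1q41	Q6XR72
SLC	SLC30A1	1q32.3	Q9Y6M5
SLC	SLC30A3	2p23.3	Q99726
SLC	SLC30A8	8q24.11	Q8IWU4
SLC	SLC30A4	15q21.1	O14863
SNT	SNTG2	2p25.3	Q9NY99
SNT	SNTG1	8q11.21	Q9NSN8
SNT	SNTB1	8q23-q24	Q13884
SNT	SNTA1	20q11.2	Q13424
SNT	SNTB2	16q22.1	P49711
SNT	GOPC	6q21	Q9HD26
SNX	SNX27	1q21.3	Q96L92
SNX	SNX17	2p23.3	Q15036
SNX	SNX31	8q22.3	Q8N9S9
STMN	STMN1	1p36.11	P16949
STMN	STMN2	8q21.13	Q93045
STMN	STMN4	8p21.2	Q9H169
STMN	STMN3	20q13.3	Q9NZ72
STK	STK25	2q37.3	O00506
STK	STK3	8q22.2	Q13188
STK	STK4	20q11.2-q13.2	Q13043
STK	STK24	13q31.2-q32.3	Q9Y6E0
STK	STK26	Xq26.2	Q9P289
TCEA	TCEA3	1p36.12	O75764
TCEA	TCEA1	8q11.2	P23193
TCEA	TCEA2	20q13.33	Q15560
TCEA	TCEANC	Xp22.2	Q8N8B7
UBXN	UBXN2A	2p23.3	P68543
UBXN	UBXN2B	8q12.1	Q14CS0
UBXN	NSFL1C	20p13	Q9UNZ2
XKR	XKR8	1p35.3	Q9H6D3
XKR	XKR9	8q13.3	Q5GH70
XKR	XKR6	8p23.1	Q5GH73
XKR	XKR4	8q12.1	Q5GH76
XKR	XKR5	8p23.1	Q6UX68
XKR	XKR7	20q11.21	Q5GH72
YTHDF	YTHDF2	1p35	Q9Y5A9
YTHDF	YTHDF3	8q12.3	Q7Z739
YTHDF	YTHDF1	20q13.33	Q9BYJ9
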