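family	block	schematic	allowance
MROH	a	((20,1),8);	3
STK	a	((2,13),X);	3
E2F	b	((1,6),20);	2
EYA	b	((6,8),20);	2
STMN	b	((1,8),20);	2
HCK	c	((20,8),(1,2));	5
DLGAP	c	((20,18),(1,8));	5
NKAIN	c	((20,8),(1,6));	5
KCNQ	c	((20,8),(1,6));	5
MATN	c	((20,8),(1,2));	5
FAM110	d	((20,8),2);	4
NCOA	d	((20,8),2);	4
KCNS	d	((20,8),2);	4
MYT	d	((20,8),2);	4
YTHDF	d	((20,8),1);	4
XKR	d	((20,8),1);	4
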