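novel_dbtf	function	core_dbtf	target_gene	ar42j_expressed	gastrin_responsive
CREM	Activator	CREB1	JUN	Yes	Yes
FOXP3	Repressor	CREB1	IFNG	No	No
FOXP3	Repressor	CREB1	IL10	No	No
FOXP3	Repressor	CREB1	BCL2	No	No
FOXP3	Repressor	CREB1	MALAT1	No	No
TCF7L2	Repressor	CREB1	MYOD1	No	No
FOXP3	Repressor	NFkB1	PIGR	No	No
FOXP3	Repressor	NFkB1	CXCL5	No	No
FOXP3	Repressor	NFkB1	VCAM1	No	No
FOXP3	Repressor	NFkB1	VWF	No	No
FOXP3	Repressor	NFkB1	IFNG	No	No
FOXP3	Repressor	NFkB1	IL8	No	No
FOXP3	Repressor	NFkB1	BCL2A1	No	No
FOXP3	Repressor	NFkB1	NFKB1	Yes	Yes
FOXP3	Repressor	NFkB1	IER3	Yes	Yes
FOXP3	Repressor	NFkB1	CD40LG	No	No
FOXP3	Repressor	NFkB1	SELE	No	No
FOXP3	Repressor	NFkB1	ALOX5AP	Yes	Yes
SMAD3	Repressor	NFkB1	MMP9	No	No
PARP1	Activator	NFkB1	BRCA2	Yes	Yes
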