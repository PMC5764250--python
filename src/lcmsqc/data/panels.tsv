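peptide	panel	charge	expected_rt
LVNELTEFAK	QC1	2
HLVDEPQNLIK	QC1	2
VPQVSTPTLVEVSR	QC1	2
EAC(CAM)FAVEGPK	QC1	2
EYEATLEEC(CAM)C(CAM)AK	QC1	2
EC(CAM)C(CAM)HGDLLEC(CAM)ADDR	QC1	2
SLHTLFGDELC(CAM)K	QC1	2
TC(CAM)VADESHAGC(CAM)EK	QC1	2
YIC(CAM)DNQDTISSK	QC1	2
NEC(CAM)FLSHK	QC1	2
YAEAVTR	QC2	2
TPAQFDADELR	QC2	2
STLTDSLVC(CAM)K	QC2	2
SLADELALVDVLEDK	QC2	2
NPDDITNEEYGEFYK	QC2	2
LGDLYEEEMR	QC2	2
LAVDEEENADNNTK	QC2	2
FEELNMDLFR	QC2	2
EAALSTALSEK	QC2	2
DDVAQTDLLQIDPNFGSK	QC2	2
RFPGYDSESK	QC2	2
EVSTYIK	QC2	2
EATTEFSVDAR	QC2	2
FAFQAEVNR	QC2	2
EQFLDGDGWTSR	QC2	2
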