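gene	status	expressed_allele
THAP3	imprinted	paternal
DNMT1	imprinted	maternal
SIAH1	imprinted	maternal
RHOBTB3	imprinted	paternal
CDKN1C	imprinted	maternal
KLHDC10	imprinted	maternal
ZFAT	imprinted	paternal
ADTRP	imprinted	maternal
ATP10A	imprinted	maternal
FGF12	imprinted	maternal
JMJD1C	imprinted	maternal
IGF2	imprinted	paternal
H19	imprinted	maternal
MEG3	imprinted	maternal
PEG3	imprinted	paternal
SNRPN	imprinted	paternal
PLAGL1	imprinted	paternal
GRB10	imprinted	maternal
MEST	imprinted	paternal
KCNQ1	imprinted	maternal
NDN	imprinted	paternal
MKRN3	imprinted	paternal
UBE3A	imprinted	maternal
PEG10	imprinted	paternal
NNAT	imprinted	paternal
GNAS	imprinted	maternal
DLK1	imprinted	paternal
RTL1	imprinted	paternal
IGF2R	imprinted	maternal
PHLDA2	imprinted	maternal
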