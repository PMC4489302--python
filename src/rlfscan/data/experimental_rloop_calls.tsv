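# Literature-curated experimental R-loop detection outcomes at 22 gene loci
# (R-loop foot-printing, electron microscopy, DRIP-qPCR, DRIP-seq, RNase H
# assays) paired with the structural-model prediction at each locus.
# Columns: locus, experimental signal, predicted RLFS ('+' present, '-' absent).
locus	experimental	predicted
IGH_switch_region	+	+
MYC	+	+
BCL6	+	+
RHOH	+	+
ACTB	+	+
FMR1	+	+
SNRPN	+	+
HK2	+	+
CHTF8	+	+
CIRH1A	+	+
APOE	+	+
FHIT	+	+
FLC	+	-
Pkd2l1	+	+
Foxo4	+	+
Airn	+	+
C9orf72	+	+
JTB	-	-
PPM1D	-	-
TP53	-	-
PBX1	-	+
PTEN	+	+
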