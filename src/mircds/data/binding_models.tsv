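model	length	unpaired	insertions	expected	note
CDS1	22	3,4,5	-	not_repressed	seed mismatched, miRNA 3' end fully paired
CDS1a	22	3,4,5,20,21,22	-	not_repressed	seed mismatched, 3' end unpaired
CDS2	22	-	5:1	not_repressed	minor seed imperfection (1-nt target bulge in seed), 3' end paired
CDS2a	22	20,21,22	5:1	not_repressed	minor seed imperfection, 3' end unpaired
CDS3	22	-	-	repressed	perfect complementarity
CDS3a	22	12	-	repressed	seed paired, single central mismatch
CDS3b	22	21,22	-	repressed	seed paired, two bases mismatched at the 3' end
CDS3c	22	20,21,22	-	repressed	seed paired, 3' terminal bases unpaired
C-miR2	21	12	-	repressed	single base bulge at miRNA position 12
C-miR2/11	21	11	-	repressed	single base bulge at miRNA position 11
C-miR2/10	21	10	-	repressed	single base bulge at miRNA position 10
C-miR2-11-12	21	11,12	-	weak	central bulge widened to 2 bases
C-miR2-10-13	21	10,11,12,13	-	not_repressed	central bulge widened to 4 bases
C-miR2-20-21	21	12,20,21	-	repressed	central bulge 1 plus two 3'-terminal mismatches
C-miR2-19-21	21	12,19,20,21	-	repressed	central bulge 1 plus three 3'-terminal mismatches
C-miR2-21-23	23	12,21,22,23	-	repressed	longer miRNA, three 3'-terminal mismatches, supplementary retained
siR2	21	-	-	repressed	fully complementary siRNA
siR2-20-21	21	20,21	-	repressed	siRNA with two 3'-terminal mismatches
siR2-19-21	21	19,20,21	-	repressed	siRNA with three 3'-terminal mismatches
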