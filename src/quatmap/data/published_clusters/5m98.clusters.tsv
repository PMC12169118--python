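# Reported quaternary-epitope clusters on uricase structure PDB 5M98
# (Danio rerio urate oxidase).  Format: see 4d12.clusters.tsv.
LEU.163.D, LYS.164.D, THR.165.D, ALA.223.D, HIS.129.A, ALA.130.A
GLY.167.C, PHE.168.C, LEU.169.C, ASN.57.A, SER.58.A, ASP.59.A, ILE.60.A
ASN.57.C, SER.58.C, ASP.59.C, ILE.60.C, ILEU.61.C, GLY.167.A, PHE.168.A, LEU.169.A
VAL.23.D, LEU.24.D, HIS.25.D, ILE.26.D, LYS.75.D, GLU.274.A, VAL.275.A, TYR.276.A, LEU.277.A
SER.228.C, GLN.230.C, LYS.231.C, TYR.234.C, ASP.51.A, TYR.52.A, GLY.55.A
THR.65.C, ILE.267.B, THR.174.A, PHE.173.A
LYS.159.D, THR.160.D, HIS.124.A
LYS.22.D, PRO.278.A
GLU.274.D, ILEU.26.A
TYR.220.D, HIS.122.A
HIS.122.D, TYR.220.A
PHE.173.B, ILE.276.A
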