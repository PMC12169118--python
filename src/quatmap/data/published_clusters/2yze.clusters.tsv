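# Reported quaternary-epitope clusters on uricase structure PDB 2YZE
# (Arthrobacter globiformis urate oxidase).  Format: see 4d12.clusters.tsv.
ARG.26.D, LEU.27.D, VAL.28.D, PHE.269.A, TYR.270.A, ALA.271.A
LEU.220.B, ALA.221.B, GLN.223.B, GLN.224.B, TYR.227.B, HIS.56.A, THRR.57.A, GLY.59.A
LEU.156.D, LYS.157.D, SER.158.D, ALA.215.D, HIS.123.A, ALA.124.A
LYS.29.D, VAL.30.D, GLU.267.A, VAL.268.A
THR.69.B, TYR.171.A, THR.172.A
GLY.165.B, PHE.166.B, PRO.167.B, ASN.61.A, ALA.62.A, VAL.64.A
ASN.61.B, ALA.62.B, VAL.64.B, GLY.165.A, PHE.166.A, PRO.167.A
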