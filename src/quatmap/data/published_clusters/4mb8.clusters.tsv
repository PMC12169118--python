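# Reported quaternary-epitope clusters on uricase structure PDB 4MB8
# (mammalian urate oxidase).  Format: see 4d12.clusters.tsv.
PRO.233.C, SER.234.C, GLN.236.C, LYS.237.C, TYR.240.C, ASP.56.A, TYR.57.A, GLY.60.A
VAL.28.D, LEU.29.D, HIS.30.D, ILE.31.D, GLU..280.A, VAL.281.A, LEU.282.A, LEU.283.A
ASN.62.C, SER.63.C, ILE.65.C, ILE.66.C, GLY.172.A, PHE.173.A, ILE.174.A
GLY.172.C, PHE.173.C, ILE.174.C, ASN.62.A, SER.63.A, ILE.65.A, ILE.66.A
ASP.24.C, MET.25.C, VAL.26.C, ASN.287.A, PRO.288.A
THR.70.C, PHE.178.A, THR.179.A
HIS.127.D, TYR.226.D, HIS.127.A, TYR.226.A
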