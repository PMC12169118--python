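# Reported quaternary-epitope clusters on uricase structure PDB 4D12
# (Aspergillus flavus urate oxidase).  One cluster per line, labels
# NAME.number.chain transcribed verbatim from the published listing,
# including its typos; residues resolve by chain + author number, names
# are advisory.  Labels lacking a chain inherit the next labelled chain
# in the row.
TYR.69.D, LYS.17.D, VAL.18.D, GLU.276.A, VAL.277.A, PHE.278.A
VAL.151.D, LEU.152.D, LYS.153.D, SER.154.D, ALA.220.D, HIS.118.A, SER.119.A, PHE.120.A, ILE.121.A
ALA.225, GLN.228, ALA.229, TYR.232.C, TYR.46.A, ALA.49.A
GLY.161.C, PHE.162.C, LEU.163.C, ASN.51.A, SER.52.C, ILE.154.C
ASN.51.C, SER.52.C, ILE.54.C, VSL.55.C, GLY.161.A, PHE.162.A, LEU.163.A
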