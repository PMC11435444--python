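# swallowpfas default detection limits (ng/g wet wt.).
# '*' wildcards: a row applies to every matrix/year without a more specific entry.
# Bands: 0.10 ng/g for perfluoroalkyl carboxylates, sulfonates and the FOSAA
# acids (the published site tables print 0.05 = DL/2 for all-non-detect cells);
# 1.0 for PFBA, fluorotelomer sulfonates,
# sulfonamides/derivatives and ether acids (reported band 0.26-1.50);
# 3.0 for fluorotelomer carboxylates (reported band 2.5-4.0).
analyte,matrix,year,dl
PFBA,*,*,1.0
PFPeA,*,*,0.10
PFHxA,*,*,0.10
PFHpA,*,*,0.10
PFOA,*,*,0.10
PFNA,*,*,0.10
PFDA,*,*,0.10
PFUnA,*,*,0.10
PFDoA,*,*,0.10
PFTrDA,*,*,0.10
PFTeDA,*,*,0.10
PFBS,*,*,0.10
PFPeS,*,*,0.10
PFHxS,*,*,0.10
PFHpS,*,*,0.10
PFOS,*,*,0.10
PFNS,*,*,0.10
PFDS,*,*,0.10
PFDoS,*,*,0.10
PFOSA,*,*,1.0
N-MeFOSA,*,*,1.0
N-EtFOSA,*,*,1.0
N-MeFOSAA,*,*,0.10
N-EtFOSAA,*,*,0.10
N-MeFOSE,*,*,1.0
N-EtFOSE,*,*,1.0
4:2 FTS,*,*,1.0
6:2 FTS,*,*,1.0
8:2 FTS,*,*,1.0
3:3 FTCA,*,*,3.0
5:3 FTCA,*,*,3.0
7:3 FTCA,*,*,3.0
PFEESA,*,*,1.0
PFMPA,*,*,1.0
PFMBA,*,*,1.0
NFDHA,*,*,1.0
HFPO-DA,*,*,1.0
ADONA,*,*,1.0
9Cl-PF3ONS,*,*,1.0
11Cl-PF3OUdS,*,*,1.0
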