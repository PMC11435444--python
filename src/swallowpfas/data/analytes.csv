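# swallowpfas default analyte registry: 40 targeted PFAS (commercial panel, 2021).
# panels: semicolon-separated memberships; PFAS13 = original 13-analyte panel (2019),
# PFAS33 = 2020 panel, PFAS40 = full 2021 panel. Panel sets are nested.
name,chem_class,panels,carbon_count
PFBA,perfluorocarboxylate,PFAS13;PFAS33;PFAS40,4
PFPeA,perfluorocarboxylate,PFAS13;PFAS33;PFAS40,5
PFHxA,perfluorocarboxylate,PFAS13;PFAS33;PFAS40,6
PFHpA,perfluorocarboxylate,PFAS13;PFAS33;PFAS40,7
PFOA,perfluorocarboxylate,PFAS13;PFAS33;PFAS40,8
PFNA,perfluorocarboxylate,PFAS13;PFAS33;PFAS40,9
PFDA,perfluorocarboxylate,PFAS13;PFAS33;PFAS40,10
PFUnA,perfluorocarboxylate,PFAS13;PFAS33;PFAS40,11
PFDoA,perfluorocarboxylate,PFAS13;PFAS33;PFAS40,12
PFTrDA,perfluorocarboxylate,PFAS33;PFAS40,13
PFTeDA,perfluorocarboxylate,PFAS33;PFAS40,14
PFBS,perfluorosulfonate,PFAS13;PFAS33;PFAS40,4
PFPeS,perfluorosulfonate,PFAS33;PFAS40,5
PFHxS,perfluorosulfonate,PFAS13;PFAS33;PFAS40,6
PFHpS,perfluorosulfonate,PFAS33;PFAS40,7
PFOS,perfluorosulfonate,PFAS13;PFAS33;PFAS40,8
PFNS,perfluorosulfonate,PFAS33;PFAS40,9
PFDS,perfluorosulfonate,PFAS33;PFAS40,10
PFDoS,perfluorosulfonate,PFAS33;PFAS40,12
PFOSA,sulfonamide,PFAS13;PFAS33;PFAS40,8
N-MeFOSA,sulfonamide,PFAS33;PFAS40,
N-EtFOSA,sulfonamide,PFAS33;PFAS40,
N-MeFOSAA,sulfonamide_derivative,PFAS33;PFAS40,
N-EtFOSAA,sulfonamide_derivative,PFAS33;PFAS40,
N-MeFOSE,sulfonamide_derivative,PFAS33;PFAS40,
N-EtFOSE,sulfonamide_derivative,PFAS33;PFAS40,
4:2 FTS,fluorotelomer_sulfonate,PFAS33;PFAS40,
6:2 FTS,fluorotelomer_sulfonate,PFAS33;PFAS40,
8:2 FTS,fluorotelomer_sulfonate,PFAS33;PFAS40,
3:3 FTCA,fluorotelomer_carboxylate,PFAS33;PFAS40,
5:3 FTCA,fluorotelomer_carboxylate,PFAS33;PFAS40,
7:3 FTCA,fluorotelomer_carboxylate,PFAS33;PFAS40,
PFEESA,ether_acid,PFAS33;PFAS40,
PFMPA,ether_acid,PFAS40,
PFMBA,ether_acid,PFAS40,
NFDHA,ether_acid,PFAS40,
HFPO-DA,ether_acid,PFAS40,
ADONA,ether_acid,PFAS40,
9Cl-PF3ONS,other,PFAS40,
11Cl-PF3OUdS,other,PFAS40,
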