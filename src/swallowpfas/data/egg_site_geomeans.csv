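# Published per-site geometric means (ng/g wet wt.) for PFAS detected in >50%
# of tree swallow egg samples, Duluth MN study area, 2020-2021; plus the
# published detect-only panel totals. Blank geo_mean = not available (analyte
# not quantified at that site). Used as worked-example inputs.
site,region,n,analyte,geo_mean
Thomson Reservoir,StLouisRiver,9,PFOS,10.49
Thomson Reservoir,StLouisRiver,9,PFHxS,0.23
Thomson Reservoir,StLouisRiver,9,PFOA,0.25
Thomson Reservoir,StLouisRiver,9,PFNA,1.50
Thomson Reservoir,StLouisRiver,9,PFDA,0.81
Thomson Reservoir,StLouisRiver,9,PFUnA,1.29
Thomson Reservoir,StLouisRiver,9,PFDoA,0.61
Thomson Reservoir,StLouisRiver,9,PFTrDA,0.47
Thomson Reservoir,StLouisRiver,9,PFTeDA,0.27
Thomson Reservoir,StLouisRiver,9,PFDS,0.40
Thomson Reservoir,StLouisRiver,9,N-EtFOSE,1.23
Thomson Reservoir,StLouisRiver,9,7:3 FTCA,4.10
Thomson Reservoir,StLouisRiver,9,Total_PFAS13,15.51
Thomson Reservoir,StLouisRiver,9,Total_PFAS40,19.84
Boy Scout Landing,StLouisRiver,6,PFOS,34.80
Boy Scout Landing,StLouisRiver,6,PFHxS,1.52
Boy Scout Landing,StLouisRiver,6,PFOA,0.28
Boy Scout Landing,StLouisRiver,6,PFNA,1.40
Boy Scout Landing,StLouisRiver,6,PFDA,0.96
Boy Scout Landing,StLouisRiver,6,PFUnA,1.51
Boy Scout Landing,StLouisRiver,6,PFDoA,0.86
Boy Scout Landing,StLouisRiver,6,PFTrDA,1.13
Boy Scout Landing,StLouisRiver,6,PFTeDA,0.29
Boy Scout Landing,StLouisRiver,6,PFDS,0.47
Boy Scout Landing,StLouisRiver,6,N-EtFOSE,2.22
Boy Scout Landing,StLouisRiver,6,7:3 FTCA,15.04
Boy Scout Landing,StLouisRiver,6,Total_PFAS13,42.46
Boy Scout Landing,StLouisRiver,6,Total_PFAS40,57.97
Munger Landing,StLouisRiver,6,PFOS,16.31
Munger Landing,StLouisRiver,6,PFHxS,0.39
Munger Landing,StLouisRiver,6,PFOA,0.17
Munger Landing,StLouisRiver,6,PFNA,1.03
Munger Landing,StLouisRiver,6,PFDA,0.96
Munger Landing,StLouisRiver,6,PFUnA,1.05
Munger Landing,StLouisRiver,6,PFDoA,0.60
Munger Landing,StLouisRiver,6,PFTrDA,0.33
Munger Landing,StLouisRiver,6,PFTeDA,0.24
Munger Landing,StLouisRiver,6,PFDS,0.36
Munger Landing,StLouisRiver,6,N-EtFOSE,1.47
Munger Landing,StLouisRiver,6,7:3 FTCA,4.04
Munger Landing,StLouisRiver,6,Total_PFAS13,20.58
Munger Landing,StLouisRiver,6,Total_PFAS40,27.57
Erie Ponds,StLouisRiver,3,PFOS,18.25
Erie Ponds,StLouisRiver,3,PFHxS,0.50
Erie Ponds,StLouisRiver,3,PFOA,0.12
Erie Ponds,StLouisRiver,3,PFNA,0.51
Erie Ponds,StLouisRiver,3,PFDA,0.63
Erie Ponds,StLouisRiver,3,PFUnA,0.68
Erie Ponds,StLouisRiver,3,PFDoA,0.70
Erie Ponds,StLouisRiver,3,PFTrDA,0.33
Erie Ponds,StLouisRiver,3,PFTeDA,0.37
Erie Ponds,StLouisRiver,3,PFDS,1.57
Erie Ponds,StLouisRiver,3,N-EtFOSE,0.71
Erie Ponds,StLouisRiver,3,7:3 FTCA,19.95
Erie Ponds,StLouisRiver,3,Total_PFAS13,21.36
Erie Ponds,StLouisRiver,3,Total_PFAS40,45.43
Miller Creek,StLouisRiver,5,PFOS,6.52
Miller Creek,StLouisRiver,5,PFHxS,0.26
Miller Creek,StLouisRiver,5,PFOA,0.10
Miller Creek,StLouisRiver,5,PFNA,0.60
Miller Creek,StLouisRiver,5,PFDA,0.62
Miller Creek,StLouisRiver,5,PFUnA,0.62
Miller Creek,StLouisRiver,5,PFDoA,0.65
Miller Creek,StLouisRiver,5,PFTrDA,0.63
Miller Creek,StLouisRiver,5,PFTeDA,0.21
Miller Creek,StLouisRiver,5,PFDS,0.26
Miller Creek,StLouisRiver,5,N-EtFOSE,0.72
Miller Creek,StLouisRiver,5,7:3 FTCA,7.57
Miller Creek,StLouisRiver,5,Total_PFAS13,9.51
Miller Creek,StLouisRiver,5,Total_PFAS40,38.19
ANG,North,4,PFOS,136.90
ANG,North,4,PFHxS,11.00
ANG,North,4,PFOA,1.24
ANG,North,4,PFNA,2.63
ANG,North,4,PFDA,1.27
ANG,North,4,PFUnA,1.12
ANG,North,4,PFDoA,1.63
ANG,North,4,PFTrDA,1.23
ANG,North,4,PFTeDA,0.61
ANG,North,4,PFDS,0.57
ANG,North,4,N-EtFOSE,1.75
ANG,North,4,7:3 FTCA,25.32
ANG,North,4,Total_PFAS13,157.4
ANG,North,4,Total_PFAS40,208.2
Martin Road,North,3,PFOS,92.08
Martin Road,North,3,PFHxS,4.47
Martin Road,North,3,PFOA,0.44
Martin Road,North,3,PFNA,0.82
Martin Road,North,3,PFDA,0.68
Martin Road,North,3,PFUnA,0.98
Martin Road,North,3,PFDoA,0.65
Martin Road,North,3,PFTrDA,0.75
Martin Road,North,3,PFTeDA,0.14
Martin Road,North,3,PFDS,0.16
Martin Road,North,3,N-EtFOSE,2.13
Martin Road,North,3,7:3 FTCA,8.78
Martin Road,North,3,Total_PFAS13,100.4
Martin Road,North,3,Total_PFAS40,109.9
Rice Lake North,North,3,PFOS,469.7
Rice Lake North,North,3,PFHxS,31.74
Rice Lake North,North,3,PFOA,11.70
Rice Lake North,North,3,PFNA,11.03
Rice Lake North,North,3,PFDA,2.39
Rice Lake North,North,3,PFUnA,2.03
Rice Lake North,North,3,PFDoA,0.88
Rice Lake North,North,3,PFTrDA,0.64
Rice Lake North,North,3,PFTeDA,0.35
Rice Lake North,North,3,PFDS,0.19
Rice Lake North,North,3,N-EtFOSE,2.19
Rice Lake North,North,3,7:3 FTCA,35.89
Rice Lake North,North,3,Total_PFAS13,534.7
Rice Lake North,North,3,Total_PFAS40,600.6
UMD,Reference,2,PFOS,26.64
UMD,Reference,2,PFHxS,1.14
UMD,Reference,2,PFOA,1.11
UMD,Reference,2,PFNA,1.47
UMD,Reference,2,PFDA,0.73
UMD,Reference,2,PFUnA,0.89
UMD,Reference,2,PFDoA,0.71
UMD,Reference,2,PFTrDA,0.82
UMD,Reference,2,PFTeDA,0.25
UMD,Reference,2,PFDS,0.28
UMD,Reference,2,N-EtFOSE,1.07
UMD,Reference,2,7:3 FTCA,8.12
UMD,Reference,2,Total_PFAS13,32.74
UMD,Reference,2,Total_PFAS40,43.52
Boulder Lake,Reference,5,PFOS,6.08
Boulder Lake,Reference,5,PFHxS,0.12
Boulder Lake,Reference,5,PFOA,0.37
Boulder Lake,Reference,5,PFNA,1.02
Boulder Lake,Reference,5,PFDA,0.64
Boulder Lake,Reference,5,PFUnA,1.35
Boulder Lake,Reference,5,PFDoA,0.51
Boulder Lake,Reference,5,PFTrDA,0.74
Boulder Lake,Reference,5,PFTeDA,0.31
Boulder Lake,Reference,5,PFDS,0.20
Boulder Lake,Reference,5,N-EtFOSE,1.24
Boulder Lake,Reference,5,7:3 FTCA,
Boulder Lake,Reference,5,Total_PFAS13,10.13
Boulder Lake,Reference,5,Total_PFAS40,13.71
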