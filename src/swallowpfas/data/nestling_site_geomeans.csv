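# Published per-site geometric means (ng/g wet wt.) for PFAS detected in >50%
# of tree swallow nestling carcass samples, Duluth MN study area, 2019-2021;
# plus the published detect-only panel totals. Blank geo_mean = not available
# (all non-detect or not analyzed at that site).
site,region,n,analyte,geo_mean
Thomson Reservoir,StLouisRiver,14,PFOS,8.86
Thomson Reservoir,StLouisRiver,14,PFHxS,0.28
Thomson Reservoir,StLouisRiver,14,PFOA,1.08
Thomson Reservoir,StLouisRiver,14,PFNA,2.05
Thomson Reservoir,StLouisRiver,14,PFDA,0.53
Thomson Reservoir,StLouisRiver,14,PFUnA,0.57
Thomson Reservoir,StLouisRiver,14,PFDoA,0.11
Thomson Reservoir,StLouisRiver,14,PFDS,0.17
Thomson Reservoir,StLouisRiver,14,N-EtFOSAA,0.10
Thomson Reservoir,StLouisRiver,14,Total_PFAS13,13.57
Thomson Reservoir,StLouisRiver,14,Total_PFAS40,14.26
Boy Scout Landing,StLouisRiver,6,PFOS,12.76
Boy Scout Landing,StLouisRiver,6,PFHxS,1.29
Boy Scout Landing,StLouisRiver,6,PFOA,0.30
Boy Scout Landing,StLouisRiver,6,PFNA,0.91
Boy Scout Landing,StLouisRiver,6,PFDA,0.33
Boy Scout Landing,StLouisRiver,6,PFUnA,0.22
Boy Scout Landing,StLouisRiver,6,PFDoA,0.08
Boy Scout Landing,StLouisRiver,6,PFDS,0.09
Boy Scout Landing,StLouisRiver,6,N-EtFOSAA,0.18
Boy Scout Landing,StLouisRiver,6,Total_PFAS13,16.15
Boy Scout Landing,StLouisRiver,6,Total_PFAS40,16.53
Munger Landing,StLouisRiver,17,PFOS,11.63
Munger Landing,StLouisRiver,17,PFHxS,0.55
Munger Landing,StLouisRiver,17,PFOA,0.59
Munger Landing,StLouisRiver,17,PFNA,1.12
Munger Landing,StLouisRiver,17,PFDA,0.42
Munger Landing,StLouisRiver,17,PFUnA,0.43
Munger Landing,StLouisRiver,17,PFDoA,0.16
Munger Landing,StLouisRiver,17,PFDS,0.18
Munger Landing,StLouisRiver,17,N-EtFOSAA,0.25
Munger Landing,StLouisRiver,17,Total_PFAS13,15.06
Munger Landing,StLouisRiver,17,Total_PFAS40,17.35
Stryker Bay,StLouisRiver,5,PFOS,7.63
Stryker Bay,StLouisRiver,5,PFHxS,
Stryker Bay,StLouisRiver,5,PFOA,0.48
Stryker Bay,StLouisRiver,5,PFNA,0.85
Stryker Bay,StLouisRiver,5,PFDA,0.23
Stryker Bay,StLouisRiver,5,PFUnA,0.31
Stryker Bay,StLouisRiver,5,PFDoA,
Stryker Bay,StLouisRiver,5,PFDS,
Stryker Bay,StLouisRiver,5,N-EtFOSAA,
Stryker Bay,StLouisRiver,5,Total_PFAS13,9.40
Stryker Bay,StLouisRiver,5,Total_PFAS40,9.40
Erie Ponds,StLouisRiver,14,PFOS,11.42
Erie Ponds,StLouisRiver,14,PFHxS,0.39
Erie Ponds,StLouisRiver,14,PFOA,0.31
Erie Ponds,StLouisRiver,14,PFNA,0.94
Erie Ponds,StLouisRiver,14,PFDA,0.44
Erie Ponds,StLouisRiver,14,PFUnA,0.30
Erie Ponds,StLouisRiver,14,PFDoA,0.27
Erie Ponds,StLouisRiver,14,PFDS,0.57
Erie Ponds,StLouisRiver,14,N-EtFOSAA,1.08
Erie Ponds,StLouisRiver,14,Total_PFAS13,14.63
Erie Ponds,StLouisRiver,14,Total_PFAS40,20.57
Miller Creek,StLouisRiver,5,PFOS,6.08
Miller Creek,StLouisRiver,5,PFHxS,0.26
Miller Creek,StLouisRiver,5,PFOA,0.09
Miller Creek,StLouisRiver,5,PFNA,0.44
Miller Creek,StLouisRiver,5,PFDA,0.67
Miller Creek,StLouisRiver,5,PFUnA,0.08
Miller Creek,StLouisRiver,5,PFDoA,0.17
Miller Creek,StLouisRiver,5,PFDS,0.22
Miller Creek,StLouisRiver,5,N-EtFOSAA,0.23
Miller Creek,StLouisRiver,5,Total_PFAS13,8.06
Miller Creek,StLouisRiver,5,Total_PFAS40,30.88
ANG,North,5,PFOS,36.73
ANG,North,5,PFHxS,5.48
ANG,North,5,PFOA,1.18
ANG,North,5,PFNA,0.69
ANG,North,5,PFDA,0.33
ANG,North,5,PFUnA,0.08
ANG,North,5,PFDoA,0.12
ANG,North,5,PFDS,0.09
ANG,North,5,N-EtFOSAA,0.05
ANG,North,5,Total_PFAS13,45.24
ANG,North,5,Total_PFAS40,54.64
Martin Road,North,5,PFOS,82.10
Martin Road,North,5,PFHxS,7.00
Martin Road,North,5,PFOA,3.81
Martin Road,North,5,PFNA,1.02
Martin Road,North,5,PFDA,0.39
Martin Road,North,5,PFUnA,0.05
Martin Road,North,5,PFDoA,0.05
Martin Road,North,5,PFDS,0.05
Martin Road,North,5,N-EtFOSAA,0.05
Martin Road,North,5,Total_PFAS13,94.82
Martin Road,North,5,Total_PFAS40,96.37
Rice Lake North,North,6,PFOS,121.9
Rice Lake North,North,6,PFHxS,8.24
Rice Lake North,North,6,PFOA,3.88
Rice Lake North,North,6,PFNA,1.73
Rice Lake North,North,6,PFDA,0.76
Rice Lake North,North,6,PFUnA,0.24
Rice Lake North,North,6,PFDoA,0.06
Rice Lake North,North,6,PFDS,0.05
Rice Lake North,North,6,N-EtFOSAA,0.05
Rice Lake North,North,6,Total_PFAS13,138.23
Rice Lake North,North,6,Total_PFAS40,139.5
UMD,Reference,1,PFOS,3.72
UMD,Reference,1,PFHxS,0.24
UMD,Reference,1,PFOA,0.13
UMD,Reference,1,PFNA,0.05
UMD,Reference,1,PFDA,0.05
UMD,Reference,1,PFUnA,0.05
UMD,Reference,1,PFDoA,0.05
UMD,Reference,1,PFDS,0.05
UMD,Reference,1,N-EtFOSAA,0.05
UMD,Reference,1,Total_PFAS13,4.09
UMD,Reference,1,Total_PFAS40,4.09
Boulder Lake,Reference,5,PFOS,1.06
Boulder Lake,Reference,5,PFHxS,0.17
Boulder Lake,Reference,5,PFOA,0.76
Boulder Lake,Reference,5,PFNA,1.40
Boulder Lake,Reference,5,PFDA,0.34
Boulder Lake,Reference,5,PFUnA,0.42
Boulder Lake,Reference,5,PFDoA,0.11
Boulder Lake,Reference,5,PFDS,0.05
Boulder Lake,Reference,5,N-EtFOSAA,0.05
Boulder Lake,Reference,5,Total_PFAS13,5.04
Boulder Lake,Reference,5,Total_PFAS40,5.58
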