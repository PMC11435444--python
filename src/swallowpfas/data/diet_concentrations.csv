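# Published PFAS concentrations (ng/g wet wt.) in composited tree swallow diet
# (stomach-content) samples, one composite per site, Duluth MN area 2020-2021.
# Blank value = below detection limit. Total_PFAS13 / Total_PFAS40 rows carry
# the published detect-only panel totals.
site,region,analyte,value
Thomson Reservoir,StLouisRiver,PFOS,15.5
Thomson Reservoir,StLouisRiver,PFHxS,0.29
Thomson Reservoir,StLouisRiver,PFOA,0.86
Thomson Reservoir,StLouisRiver,PFNA,2.84
Thomson Reservoir,StLouisRiver,PFDA,0.61
Thomson Reservoir,StLouisRiver,PFUnA,0.55
Thomson Reservoir,StLouisRiver,6:2 FTS,
Thomson Reservoir,StLouisRiver,8:2 FTS,
Thomson Reservoir,StLouisRiver,Total_PFAS13,20.6
Thomson Reservoir,StLouisRiver,Total_PFAS40,20.6
Boy Scout Landing,StLouisRiver,PFOS,5.10
Boy Scout Landing,StLouisRiver,PFHxS,0.31
Boy Scout Landing,StLouisRiver,PFOA,0.12
Boy Scout Landing,StLouisRiver,PFNA,0.39
Boy Scout Landing,StLouisRiver,PFDA,
Boy Scout Landing,StLouisRiver,PFUnA,
Boy Scout Landing,StLouisRiver,6:2 FTS,2.24
Boy Scout Landing,StLouisRiver,8:2 FTS,
Boy Scout Landing,StLouisRiver,Total_PFAS13,5.92
Boy Scout Landing,StLouisRiver,Total_PFAS40,8.15
Erie Ponds,StLouisRiver,PFOS,4.86
Erie Ponds,StLouisRiver,PFHxS,
Erie Ponds,StLouisRiver,PFOA,0.7
Erie Ponds,StLouisRiver,PFNA,0.46
Erie Ponds,StLouisRiver,PFDA,
Erie Ponds,StLouisRiver,PFUnA,
Erie Ponds,StLouisRiver,6:2 FTS,1.91
Erie Ponds,StLouisRiver,8:2 FTS,152
Erie Ponds,StLouisRiver,Total_PFAS13,6.02
Erie Ponds,StLouisRiver,Total_PFAS40,160
Miller Creek,StLouisRiver,PFOS,2.92
Miller Creek,StLouisRiver,PFHxS,
Miller Creek,StLouisRiver,PFOA,0.22
Miller Creek,StLouisRiver,PFNA,0.25
Miller Creek,StLouisRiver,PFDA,
Miller Creek,StLouisRiver,PFUnA,
Miller Creek,StLouisRiver,6:2 FTS,1.74
Miller Creek,StLouisRiver,8:2 FTS,
Miller Creek,StLouisRiver,Total_PFAS13,3.32
Miller Creek,StLouisRiver,Total_PFAS40,5.13
ANG,North,PFOS,29.0
ANG,North,PFHxS,3.01
ANG,North,PFOA,0.94
ANG,North,PFNA,0.37
ANG,North,PFDA,
ANG,North,PFUnA,
ANG,North,6:2 FTS,
ANG,North,8:2 FTS,0.65
ANG,North,Total_PFAS13,33.3
ANG,North,Total_PFAS40,34.0
Martin Road,North,PFOS,44.7
Martin Road,North,PFHxS,0.54
Martin Road,North,PFOA,1.13
Martin Road,North,PFNA,0.68
Martin Road,North,PFDA,
Martin Road,North,PFUnA,
Martin Road,North,6:2 FTS,43.9
Martin Road,North,8:2 FTS,1.03
Martin Road,North,Total_PFAS13,47.0
Martin Road,North,Total_PFAS40,92.0
Rice Lake North,North,PFOS,90.0
Rice Lake North,North,PFHxS,1.73
Rice Lake North,North,PFOA,1.50
Rice Lake North,North,PFNA,1.33
Rice Lake North,North,PFDA,0.47
Rice Lake North,North,PFUnA,0.27
Rice Lake North,North,6:2 FTS,1.02
Rice Lake North,North,8:2 FTS,0.72
Rice Lake North,North,Total_PFAS13,95.30
Rice Lake North,North,Total_PFAS40,97.0
Boulder Lake,Reference,PFOS,2.95
Boulder Lake,Reference,PFHxS,
Boulder Lake,Reference,PFOA,0.451
Boulder Lake,Reference,PFNA,1.51
Boulder Lake,Reference,PFDA,0.322
Boulder Lake,Reference,PFUnA,0.283
Boulder Lake,Reference,6:2 FTS,
Boulder Lake,Reference,8:2 FTS,
Boulder Lake,Reference,Total_PFAS13,5.52
Boulder Lake,Reference,Total_PFAS40,5.52
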