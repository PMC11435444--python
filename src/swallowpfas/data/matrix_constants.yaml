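# Mean moisture / lipid composition used to convert wet-weight concentrations
# to dry-weight or lipid-normalized bases, by tissue matrix.
#
# NOTE on egg pct_lipid: the source reports 87.3% lipid for egg homogenate,
# which is physiologically implausible for fresh eggs (~8-9% is typical; the
# printed value looks like a transposed 8.73).  The printed value is kept here
# so that conversions reproduce the published constants; override it if you
# need a realistic egg lipid basis.
egg:
  pct_moisture: 82.4
  pct_lipid: 87.3
nestling:
  pct_moisture: 69.9
  pct_lipid: 8.44
diet:
  pct_moisture: 71.1
  pct_lipid: 2.38
liver:
  pct_moisture: 71.7
  pct_lipid: null
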