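# Bundled panel-conversion coefficients between the 13-analyte and 40-analyte
# total PFAS panels, fitted on 2021 samples where both panels were measured in
# the same tissue (total correlation r = 0.997 in eggs, r = 0.910 in nestlings).
# forward: PFAS40 estimate = slope * PFAS13 + intercept
# reverse: PFAS13 estimate = slope * PFAS40 + intercept
# Forward and reverse are separate least-squares fits, not algebraic inverses.
egg:
  forward: {slope: 1.216, intercept: 24.48}
  reverse: {slope: 0.820, intercept: -19.017}
  r: 0.997
nestling:
  forward: {slope: 1.039, intercept: 7.005}
  reverse: {slope: 0.876, intercept: -2.433}
  r: 0.910
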