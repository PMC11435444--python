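# Methods

This note records the statistical model behind `swallowpfas`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical choices a maintainer would want written
down.

## Data model and censoring

All concentrations are stored wet-weight (ng/g wet wt.); dry-weight and
lipid-normalized bases are presentation-only conversions dividing by the
solids fraction (1 − %moisture/100) or the lipid fraction (%lipid/100).
The bundled matrix constants are the study means (moisture 82.4 / 69.9 /
71.1 / 71.7% and lipid 87.3 / 8.44 / 2.38% for egg / nestling / diet, and
liver moisture). The egg lipid constant of 87.3% is physiologically
implausible for fresh egg homogenate (8–9% is typical; the figure looks
like a transposed 8.73) but is kept as published so conversions reproduce
the source constants; the bundled YAML documents the doubt and the value
is trivially overridden.

Censoring is handled by substitution, not by survival-type estimators
(Kaplan–Meier / MLE are out of scope because the workflow being
reproduced uses substitution):

- **Detect-only rule** for panel totals: Total PFAS₁₃/₃₃/₄₀ sums analytes
  with concentrations above the DL; non-detects contribute zero. An
  all-non-detect sample totals 0.
- **Half-DL rule** for per-analyte statistics: DL/2 replaces non-detects,
  but only for analytes passing the detection gate (strictly more than
  50% of samples detected). The gate threshold is a config parameter
  because it is genuinely ambiguous whether substitution should extend to
  analytes below the gate; the default applies it only above.

The registry defines 40 analytes in three nested reporting panels
(PFAS13 ⊆ PFAS33 ⊆ PFAS40) that mirror the growth of the commercial
analyte list across study years. The 13-analyte panel is taken as the nine
C4–C12 carboxylates, PFBS, PFHxS, PFOS and PFOSA — the only subset
consistent with the published panel totals; the 33-panel excludes the
seven ether/emerging acids added last (HFPO-DA, ADONA, 9Cl-PF3ONS,
11Cl-PF3OUdS, PFMPA, PFMBA, NFDHA). Default DLs are banded: 0.10 ng/g for
the perfluoroalkyl carboxylates (except PFBA), sulfonates and FOSAA acids
(the published site tables print DL/2 = 0.05 for all-non-detect cells,
pinning the typical DL), 1.0 ng/g for PFBA, fluorotelomer sulfonates,
sulfonamides/derivatives and ether acids, 3.0 ng/g for fluorotelomer
carboxylates. A detected-flag column, when present, overrides the
value-vs-DL inference — laboratory qualifier flags are authoritative.

## Summary statistics

Geometric means and 95% CIs are computed as t-intervals on the natural-log
scale, exponentiated back. The evidence for this choice: the published
CIs are asymmetric around the geometric means exactly as back-transformed
log-scale intervals are. n = 1 yields the value with absent bounds.

One-way ANOVA runs on log₁₀ concentrations (biomarker-style quantities and
accumulation rates are analyzed untransformed via a flag). Letter displays
come from pairwise two-sample t-tests at a Bonferroni-adjusted alpha;
groups sharing a letter are not significantly different. Letters are the
maximal cliques of the non-significance graph (equivalent to the
insert-and-absorb algorithm); the clique cover is computed exactly with
networkx. Nonstandard "forced separation" alphas seen in published
footnotes (0.075–0.25) are supported only as an override knob.

TEQ is the TEF-weighted sum over congeners; the WHO TEF table is
user-supplied configuration (it is cited, not reprinted, in the sources
this package follows), and a missing factor is an error naming the
congener.

## Fingerprinting

Ratio orientation follows the field's "1:x" convention: the reported
`n_value` x is the denominator-side dominance factor, so PFHxS:PFOS = 1:x
has x = PFOS/PFHxS and carboxylate:sulfonate = 1:x has
x = Σsulfonates/Σcarboxylates. Orientation was verified by reproducing all
six published ratio endpoints from the bundled site tables. Ratios are
computed from half-DL-substituted values so a censored PFHxS still yields
a finite ratio (the reference-lake egg ratio of 1:50.7 requires exactly
this). Reported ratios round to one decimal; classifications use
unrounded values, and the 1:20 boundary itself classes as non-AFFF.

Class sums default to the seven carboxylates {PFOA, PFNA, PFDA, PFUnA,
PFDoA, PFTrDA, PFTeDA} and three sulfonates {PFOS, PFHxS, PFDS} — the
members detected in >50% of egg or nestling samples in the source study —
and can be recomputed from any dataset's own detection gate.

`call_source` votes three AFFF indicators: PFHxS:PFOS x < 20,
carb:sulf x > 10, and a concentrated-composition rule (PFOS ≥ 70% of
Total₄₀, PFHxS ≥ 5%, at most one other analyte ≥ 2%). Two or more votes
give *AFFF-like*. Failing that, a profile with sulfonate dominance below
the matrix-specific background bound (x < 1 nestlings, < 1.5 eggs) and at
least four minor analytes ≥ 2% is *background-like*; a single stray vote
is *indeterminate*; none, *non-AFFF*. The background test is checked
before the single-vote case deliberately: at genuinely diffuse background
sites PFHxS:PFOS can fall below 1:20 (both analytes near the DL), and the
broad-spectrum evidence should outrank that one unreliable vote — the
known failure mode of the PFHxS:PFOS rule in low-exposure nestlings. The
composition-rule thresholds are calibrated to the preset signatures and
exposed in `CompositionRule`; they are package conventions, not field
constants.

Panel conversion is ordinary least squares in each direction separately
(forward and reverse fits are *not* algebraic inverses; their slopes
multiply to r², an identity the tests check to 1e−10). Bundled
coefficients: eggs 1.216/24.48 forward, 0.820/−19.017 reverse; nestlings
1.039/7.005 and 0.876/−2.433. Negative estimates (the reverse egg
equation crosses zero near 23 ng/g) are warned about, never clamped.

## Accumulation rates

rate = (m_nestling − m_egg)/age with masses in ng (concentration × wet
sample mass) and age in days as recorded per nestling (11–13 d). Negative
rates are retained — elimination can exceed intake. Sibling eggs are
matched by nest identifier; otherwise the *arithmetic mean of per-egg
masses* at the site substitutes (the procedure is defined on masses, not
concentrations, so masses are averaged). Per-site aggregation defaults to
the mean of per-pair rates; a zero-intercept regression of mass gain on
age ("slope of the line") is available as `method="regression"` — the two
agree exactly at zero noise and differ only in weighting when ages vary.
Site comparisons use one-way ANOVA on untransformed rates.

## Ordination

Profiles are percent of Total PFAS₄₀ with zeros (not DL/2) for
non-detects — substitution would fabricate composition where there is no
signal. Analytes detected in fewer than two samples across the data set
are dropped to limit zero inflation. "Standardize then log-transform" is
undefined at zero, so the transform is ln(x + 1) on percent values
(ln(x + c) with user c is available). Bray–Curtis dissimilarities are
computed by scipy's pdist; the package's own `bray_curtis` implements the
formula and the two are held equal to 1e−12 in tests.

ANOSIM ranks all pairwise distances once (average ranks on ties — the
standard convention) and computes R = (r̄_B − r̄_W)/(M/2), M = n(n−1)/2.
The permutation null relabels samples; the p-value uses the add-one
estimator (1 + #{R_perm ≥ R_obs})/(1 + n_permutations), which can never
be zero and makes the test slightly conservative when permutations tie
the observed partition. 9999 permutations by default; the seed is
mandatory in the CLI and results are bit-reproducible given (seed,
n_permutations). Pairwise statistics re-run the test on each group pair's
submatrix and are reported unadjusted (a Bonferroni option exists, off by
default). Interpretation bands: R ≥ 0.4 evident, 0.3–0.4 some support,
< 0.3 little evidence.

NMDS is backed by scikit-learn's nonmetric MDS (20 random restarts,
max 500 iterations, stress tolerance 1e−6, k = 2) with the final
configuration centered, rotated to principal axes, and its quality
recomputed as Kruskal stress-1 against an isotonic
(pool-adjacent-violators) regression of configuration distances on input
ranks — so the reported stress is exactly the classical statistic
regardless of the optimizer's internal objective.

## Synthetic data

The generator emulates the *statistical* structure the analysis assumes,
not food-web mechanism: per-sample Total₄₀ is lognormal (site/region
structure enters through the signature and a per-matrix multiplier),
per-analyte concentrations are Total₄₀ × a Dirichlet draw around the
signature percentages, censoring applies the DL table, and egg/nestling
pairs obey m_nestling = m_egg + rate × age + Gaussian noise truncated at
zero. Defaults, chosen once as field-plausible: Dirichlet concentration
500 (per-analyte log-scale spread ≲ 0.3 for minor analytes), nestling
Total₄₀ medians 120 / 16 / 5.6 ng/g for AFFF / urban / background with
σ_log = 0.5, egg totals 4× and diet 0.7× the nestling level, egg sample
mass 1.5 g and nestling 20 g with 10% lognormal spread (only the
mass × concentration product matters to the estimator), ages uniform on
{11, 12, 13}, year effects off. Diet composites are emitted one per
site-year, with an option to spike extra fluorotelomer sulfonate mass to
mimic diet-only FTS occurrences.

What passing tests show — and do not. The generator reproduces
compositional separation, censoring behaviour and the mass-balance
relation, so green tests demonstrate the *estimators* are correct and
well-calibrated under the stated model. Real tissue data add analyte-level
correlation beyond the Dirichlet's, toxicokinetic differences between
matrices, spatial/temporal autocorrelation and laboratory batch effects,
none of which are modelled; accuracy figures on synthetic data are not
field error rates.

## Numerical choices and degenerate inputs

Zero-variance ANOVA groups return F = 0, p = 1 with a shared letter.
Zero denominators in ratios return an infinite-ratio sentinel with a
warning rather than raising, because an all-censored PFHxS is an expected
condition at clean sites. Profile rows with zero totals are dropped with
a warning; an all-zero data set is an error. Distance matrices validate
symmetry (1e−12), zero diagonal and non-negativity. Seeds below 2³¹ are
drawn from a single `numpy.random.default_rng` stream wherever a
procedure needs several.

Problem sizes in the bundled acceptance computation were chosen to give
stable Monte-Carlo estimates at interactive run times: 1000 null
simulations × 199 permutations for the type-I calibration, 1000
replicates × 10 pairs for estimator bias, 12 sites per source label × 10
samples for site classification.

## Known limitations

- Substitution-based censoring biases low-detection-frequency summaries;
  the >50% gate limits but does not remove this.
- The composition-rule thresholds in `call_source` are calibrated to
  legacy (sulfonate-based) AFFF; fluorotelomer-based foams do not carry
  the PFHxS marker and will not be flagged.
- Panel-conversion coefficients are study-specific; refit before applying
  them to other regions or species.
- ANOSIM assumes exchangeability under the null; strong within-site
  dependence (siblings) mildly inflates significance.
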