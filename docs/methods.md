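# Methods

This note records the models, assumptions and numerical choices behind
`edakit`, in the spirit of a statistics package's methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Exact-mass arithmetic

Monoisotopic masses are summed from a CODATA/IUPAC table of the most
abundant isotopes (C = 12 exactly, H = 1.0078250319, N = 14.0030740052,
O = 15.9949146221, …). Protonation and deprotonation use the
**electron-corrected proton mass** 1.0072765 Da (an H atom minus its
electron), not the H atomic mass: for small molecules the 0.55 mDa
electron term is visible at the fourth decimal of m/z, and only the
corrected value reproduces reference [M+H]⁺ values to 10⁻⁴ Da. The
implementation is cross-checked in the test suite against an independent
mass library (pyteomics) to 2 × 10⁻⁵ Da.

## Peak picking

A trace is scanned for strict local maxima at or above `min_intensity`
(default 10 counts). The noise floor is the MAD-based sigma
(1.4826 × median absolute deviation) of the trace **outside** candidate
peak regions (± 2 estimated widths around each apex); a peak is kept if
apex/noise ≥ `sn` (default 3) and its full width at half maximum lies in
`width_bounds` (default 5–60 s). MAD was chosen over the residual RMS
because it is insensitive to the peaks themselves and makes the S/N rule
testable on constructed traces. Flat traces return an empty list rather
than an error. Apex times are reported in minutes; widths assume an
approximately uniform sampling interval (the median Δt is used).

## Library matching and confidence levels

A feature matches a library entry when |Δm/z| ≤ 10 mDa (MS1) and
|ΔRT| ≤ 1 min. Identification confidence follows the community 1–5
scale: exact-mass/formula agreement alone → level 4; feature MS2 present
but no usable library spectrum (or a spectrum matching below threshold)
→ level 3; at least 50 % of the entry's MS2 peaks matched within 15 mDa
→ level 2; the same backed by a reference standard → level 1. The 0.5
match-score threshold is a package default — tolerances are standard,
but no published match-count rule exists for this workflow, so the rule
is fixed and documented to keep level assignment deterministic.

## Feature alignment and the prioritization cascade

Alignment between two tables is one-to-one: candidate pairs within
tolerance are consumed in order of ascending |Δm/z|, ties broken by
|ΔRT|, then by lower index. The cascade applies, in narrative order:

1. keep 5×-extract features also detected in the 1× extract
   (presence/absence with tolerance matching);
2. restrict to the upper and lower fraction separately (reported as the
   union of the two restricted sets);
3. drop features whose 1× intensity exceeds the 5× intensity —
   enrichment must not be inverted;
4. subtract the process blank (removal on **any** match, regardless of
   intensity ratio — the strictest reading, deliberately conservative);
5. keep features present in *both* fraction-restricted sets;
6. keep features with intensity > 1 % of the summed 5×-table intensity.
   The 5× extract is used as the denominator because it is the cascade's
   reference sample; the threshold is configurable.

Counts are non-increasing by construction and are asserted as such. On
every fixture the cascade is compared against an independent brute-force
oracle (naive all-pairs matching, explicit set operations) that lives in
the test suite only.

## Dose–response

The four-parameter logistic r(c) = floor + (ceiling − floor) / (1 +
(EC50/c)^hill) is fitted by weighted least squares in the parameters
(floor, ceiling, log EC50, hill), weights 1/response — a constant-CV
error model appropriate for reporter assays whose noise scales with the
signal. Starting values are fixed (floor = min response, ceiling = max
response, EC50 = geometric mid-dose, hill = 1) so fits are deterministic.
Effect concentrations use the analytic inverse
EC_p = EC50 · (p/(100 − p))^(1/hill); their 95 % CIs come from the
first-order delta method on log EC_p with a t-quantile at the residual
degrees of freedom. The package validates the delta CIs against
parametric-bootstrap refits (within 10 %) and checks frequentist
coverage (≥ 90 % over 200 simulations) in the test suite.

E2 equivalents: the sample's dilution series (dose axis = relative
concentration, 1 = undiluted) gets its own 4PL fit; the relative
concentration x at which it crosses the positive control's 10 % effect
response is interpolated from that fit, and E2-EQ = EC10(PC)/x. A sample
whose fitted curve never reaches that response level within the tested
range raises "below effect threshold". The CI combines the relative
half-widths of both curve inversions in quadrature (the two fits are
independent experiments).

## Standard addition

Ordinary least squares of response on spike level (the unspiked sample
is spike 0 with its own replicates); the in-assay concentration is the
magnitude of the x-intercept a/b. Its 95 % CI uses first-order
(Fieller-type) propagation of the (a, b) covariance with the residual
t-quantile; the test suite checks it against a leverage-corrected
residual bootstrap and checks coverage over 200 simulations. Dilution
correction multiplies the point estimate and half-width by
total/aliquot volume. LOD and LOQ assume S/N proportional to
concentration: LOD = c·3/SN, LOQ = c·10/SN, hence LOQ/LOD = 10/3
identically.

## Effect balance and error propagation

REP, E2-EQ(analyte) and the percent contribution are pure products and
ratios, so first-order Gaussian propagation reduces exactly to adding
relative half-widths in quadrature; the chained evaluation therefore
equals the single-formula evaluation, and the propagation is validated
against 100,000-draw Monte-Carlo quantile intervals (inputs as
independent Gaussians with sd = half-width/1.96; agreement within 5 %
for relative errors ≤ 20 %). The 95 % half-widths are propagated
directly — equivalent to treating them as proportional to standard
deviations under equal coverage — and inputs are treated as independent
because they come from four separate experiments. All concentrations
enter in ng/L; conversions happen only at I/O boundaries.

## Redox speciation kinetics

The reduced-species fraction follows f(t) = plateau + (f0 − plateau) ·
e^(−kt) with an effective first-order rate k (1/h). Far from equilibrium
(k·t ≪ 1) this is indistinguishable from a line of slope
−k(f0 − plateau), so slow (low-pH) series are fitted linearly and fast
(high-pH) series with the exponential model; `auto` fits both and keeps
the higher R², ties going to linear. Fractions are carried internally on
the 0–1 scale (percent input is rescaled), so slopes are in fraction
units per hour. Exponential starts are deterministic: f0 = first value,
plateau = last value, k = 3/t_max; f0 is left free rather than pinned to
the first observation. A constant series is reported as degenerate
(slope 0, R² undefined) rather than an error. Mass balance compares each
timepoint's summed normalized areas against the series mean; the default
4 % tolerance flags side reactions. Acid–base speciation is plain
Henderson–Hasselbalch; the pKa is a required input, not an assumed
constant.

## Synthetic data: what it emulates and what it does not

Generators mirror the study conditions so recovery tests are meaningful:

* **Feature scenario** — default 100 background features + 2 planted
  drivers, multiplicative log-normal intensity noise (CV 0.05), m/z laid
  on a 0.5 Da grid with 2 mDa/0.02 min jitter between tables so
  tolerance matching is exercised but distinct features can never
  collide. Drivers scale exactly with the enrichment factor before
  noise, appear in both fractions, are absent from the blank and exceed
  the 1 % share; each background feature is constructed to violate
  exactly one cascade criterion, recorded in the truth object.
* **YES plates** — 4PL responses with induction ratio spanning 1–10,
  analyte EC50 820,000 ng/L with hill 2.4 (chosen to match an
  EC10:EC50 ratio of ≈ 330:820), positive control EC50 82 ng/L with
  hill 1.5 (EC10 ≈ 19 ng/L), seven 1:2 dilutions from 6 × EC50,
  triplicates, log-normal noise CV 0.1; the PC grid is ten doubling
  steps from 0.66 ng/L.
* **Standard addition** — spikes 0/210/420/630/840 µg/L around a true
  in-assay concentration of 500 µg/L (×6 dilution → 3000 µg/L in the
  sample), slope 1, log-normal noise CV 0.05.
* **Kinetics** — the printed 14-timepoint grid to 173 h; per-pH
  (f0, k, plateau) defaults produce a slow near-linear decline from
  ≈ 92 % at pH 5–6, a faster decline at pH 7, and plateaus of 58 %/53 %
  at pH 8/9 reached within ~100 h. Fraction noise is additive Gaussian
  (sd 0.01); the two species' summed area is perturbed only by a 1 % CV
  factor, so the < 4 % mass-balance criterion holds by construction.

Not emulated: chromatographic peak shapes beyond what peak-picking
tests need, adduct/isotope multiplicity of real features, matrix-driven
heteroscedasticity beyond the constant-CV model, replicate-to-replicate
plate drift, and any pH dependence *within* a kinetics series. Passing
recovery tests therefore demonstrates correctness of the estimators
under the stated noise models, not robustness to every artefact of real
LC-HRMS or assay data.

## Problem sizes and determinism

Simulation studies in the tests use 200 replicates (coverage checks),
50 scenarios (cascade/oracle agreement), 2000 bootstrap refits and
100,000 Monte-Carlo draws — sizes at which the checked frequentist
properties stabilize while the whole suite runs in seconds. All
randomness flows from `numpy.random.SeedSequence` forked per stage, so
identical seeds give bit-identical outputs regardless of stage order.

## Known limitations

* The cascade treats features as points; co-eluting isomers within
  tolerance merge into one match.
* Delta-method CIs are symmetric; for strongly skewed EC sampling
  distributions a profile-likelihood or log-scale interval would be
  more faithful at small n.
* The two-state kinetic model books no intermediate species; a drifting
  mass balance is detected but not modelled.
* Standard-addition pooling assumes replicate series share one slope;
  per-series fits can be obtained by calling the fitter per replicate.
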