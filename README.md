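# edakit

Effect-directed analysis (EDA) asks a deceptively simple question about a
complex environmental sample: *which* of the thousands of compounds in it
actually causes the biological effect you measure? `edakit` implements the
computational side of one such study design — identifying the driver of
estrogenic activity in aqueous leachates of rubber/elastomer materials —
as a tested, reusable Python pipeline:

* **Nontarget screening helpers** — monoisotopic mass and adduct m/z
  arithmetic with an electron-corrected proton mass, chromatographic peak
  picking (minimum intensity, S/N against a MAD noise floor, peak-width
  window), and spectral-library matching with identification-confidence
  levels 1–5.
* **Feature prioritization cascade** — reduces an LC-HRMS feature table to
  candidate toxicity drivers using a fractionation design: presence in both
  enrichment levels (1× / 5× REF) of the extract, presence in both
  bioactive plate fractions, enrichment-consistent intensities, process-blank
  subtraction, and a >1 %-of-total-intensity filter.
* **Dose–response modelling** — four-parameter logistic fits of yeast
  estrogen screen (YES) plates, EC10/EC50 with delta-method 95 % CIs, and
  17β-estradiol equivalents (E2-EQ) of samples against a fitted positive
  control.
* **Standard-addition quantification** — x-intercept concentration with a
  Fieller-type CI, dilution correction, and S/N-based LOD/LOQ.
* **Redox speciation kinetics** — a phenol/quinone-imine couple
  (4-hydroxydiphenylamine ⇌ *N*-phenyl-*p*-benzoquinone monoimine)
  interconverting pH-dependently; internal-standard normalization, species
  fractions, mass-balance diagnostics, linear and exponential-plateau fits,
  and Henderson–Hasselbalch speciation.
* **Effect balance** — the chain

  ```
  REP            = EC10,E2 / EC10,analyte
  E2-EQ_analyte  = REP × C
  % estrogenicity = E2-EQ_analyte / E2-EQ_sample × 100
  ```

  with Gaussian propagation of the 95 % confidence half-widths.
* **Synthetic data with ground truth** — generators for every input the
  pipeline needs (feature tables with planted drivers, YES plates,
  spike series, kinetics), so every stage is testable end to end.

## Worked example

The headline calculation: how much of a leachate's total estrogenicity does
one analyte explain? Feed in the four measured quantities (EC10 of the E2
positive control, EC10 of the analyte, the analyte concentration from
standard addition, the sample's total E2-EQ — concentrations in ng/L):

```bash
edakit balance \
  --ec10-e2 19 3 \
  --ec10-analyte 329000 59000 \
  --conc 3000000 170000 \
  --e2eq-sample 140 7
```

prints

```
REP                = 5.77508e-05 ± 1.37987e-05
E2-EQ(analyte)     = 173.252 ± 42.5445 ng/L
percent of sample  = 123.752 ± 31.0125 %
```

i.e. a relative potency of ≈ 5.8 × 10⁻⁵, an analyte estradiol equivalent of
≈ 173 ng/L, and — to two significant figures — **120 ± 30 %** of the
observed estrogenicity explained by the analyte alone: the compound is the
main effect driver, with the >100 % point estimate consistent with 100 %
within its propagated uncertainty.

The full synthetic pipeline (feature cascade → dose–response → E2-EQ →
standard addition → effect balance → kinetics) runs with one seed:

```bash
edakit --seed 1 --out-dir out run-all
```

Its `summary.json` reports, among other things, the cascade's per-step
feature counts (102 → 75 → 75 → 61 → 44 → 17 → 2: exactly the two planted
driver features survive), the recovered sample E2-EQ (≈ 139 ng/L against a
simulated truth of 140), the dilution-corrected analyte concentration
(≈ 3080 µg/L against a truth of 3000), and per-pH kinetic fits with their
mass-balance diagnostics.

## Layout

```
src/edakit/
  types.py           shared domain types (features, plates, ValueWithCI)
  io.py              CSV dialects for all tabular formats
  nts.py             exact masses, peak picking, library matching
  cascade.py         feature-prioritization cascade
  dose_response.py   4PL fits, EC levels, E2 equivalents
  quantification.py  standard addition, dilution, LOD/LOQ
  balance.py         effect-balance chain with error propagation
  kinetics.py        redox speciation kinetics
  synthetic.py       ground-truth data generators
  pipeline.py        stage orchestration
  cli.py             command-line interface
docs/methods.md      modelling assumptions and numerical choices
```
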