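# Methods

## The physiological quantities

All metrics are defined over an aerobic glucose batch culture sampled
at discrete times for dry weight (DW, gDW/L), OD₆₀₀, extracellular
metabolites (g/L) and cumulative off-gas (mol/L of culture).

**Specific growth rate μ** is the OLS slope of ln(DW) against time over
the exponential window on glucose. DW is the default basis; OD₆₀₀ is
available and gives the same slope whenever OD is proportional to DW.

**Exponential window.** Candidate samples need positive biomass,
glucose > 1 g/L, and must precede the ethanol maximum of a fermenting
run (growth "on glucose solely"). Among all contiguous stretches of at
least `min_points = 4` samples whose log-linear fit reaches
`r² ≥ 0.995`, the longest wins; ties go to the higher slope. The window
was chosen by eye in classical practice, so a manual override is part
of the interface; the automatic rule exists to make pipelines
reproducible.

**Endpoint.** Fermenting runs (max ethanol ≥ 0.5 g/L) are evaluated at
the earliest sample attaining the ethanol maximum; non-fermenting runs
when glucose first reaches 0.1 g/L (a typical HPLC detection scale),
linearly interpolated between the bracketing samples. A run whose
ethanol peak arrives while > 0.1 g/L glucose remains is flagged as
mixed metabolism instead of being rejected — such species exist.

**Yields** `Y_p/S = (c_p(t_end) − c_p(t_0)) / (S(t_0) − S(t_end))` in
g/g, endpoint concentrations linearly interpolated; negative numerators
(noise) clip to zero with the clip visible in QC. **Specific rates**
`q_p = (Δc_p/ΔX)·μ` use the first and last window samples; this equals
the exponential-phase yield ratio times μ, so the two textbook
formulations coincide (a unit test asserts it).

**Respiration ratio** is cumulative ΔCO₂ / ΔO₂ (mol/mol) from the first
sample to the end of the glucose phase; < 10⁻⁶ mol/L of O₂ consumed is
reported as an infinite ratio rather than a large noisy number.

**Carbon balance** is C-mol out / C-mol in at the endpoint with
per-C-mol masses (g/C-mol): glucose 30.03, ethanol 23.03, glycerol
30.70, acetate 30.03, pyruvate 29.35, succinate 29.52, lactate 30.03,
biomass 24.6. Biomass uses the standard ash-free yeast composition
CH₁.₈O₀.₅N₀.₂; no strain-specific composition is attempted. Balances
outside [0.9, 1.1] raise a QC flag.

## The synthetic-data generator

The simulator is a Sonnleitner–Käppeli-style respiratory-bottleneck
model — the simplest mechanism that spans the observed phenotype range
from fully respiratory to strongly fermentative:

* glucose uptake `q_S = q_S,max · S/(K_S+S)` (Monod, `K_S = 0.1 g/L`);
* oxidation up to the respiratory capacity `resp_cap`, biomass yield
  `Y_XS,ox`; the overflow `q_S − resp_cap` ferments with biomass yield
  `Y_XS,ferm` and ethanol yield `Y_ES,ferm ≤ 0.511 g/g` (the
  stoichiometric maximum of C₆H₁₂O₆ → 2 EtOH + 2 CO₂);
* CO₂ is all substrate carbon not fixed in biomass or excreted
  products, so closure is exact by construction; fermentation adds one
  CO₂ per ethanol and consumes no O₂, while the respiratory remainder
  runs at RQ 1.0 (pure carbohydrate oxidation) — the observed RQ
  gradient across phenotypes is therefore emergent, not imposed;
* below 0.05 g/L glucose, phenotypes with `ethanol_growth` switch to
  respiring the accumulated ethanol (Monod in ethanol, `μ = Y_XE·q_E`,
  O₂ from the electron balance with degrees of reduction 6 per C-mol
  ethanol and 4.2 per C-mol biomass);
* integration is fixed-step RK4 at 0.01 h; a step that would drive
  glucose negative is linearly blended to the depletion point, keeping
  closure error well below 1%.

Default conditions mirror a standard screen: 2% glucose (20 g/L),
inoculum 500-fold below final biomass (`X0 = S0·Y_XS,ox/500`), 0.5 h
sampling, 36–48 h duration. The three presets bracket the phenotype
space: `strong_positive` (S. cerevisiae-like: q_S,max 1.9, strong
overflow, Y_E/S ≈ 0.40, Y_X/S ≈ 0.15, μ ≈ 0.29), `intermediate`
(Lachancea-like: Y_X/S ≈ 0.29, Y_E/S ≈ 0.24, μ ≈ 0.32) and `negative`
(K. lactis-like: no overflow, Y_X/S = 0.55, μ ≈ 0.30). Preset rate and
yield constants were picked once to land inside the three published
phenotype ranges at realistic growth rates.

Measurement noise is multiplicative lognormal with mean 1 and a chosen
coefficient of variation, independent per sample and channel —
appropriate for HPLC and gravimetric errors that scale with signal.
Cumulative gas channels are perturbed on their increments and
re-accumulated, since gas analyzers integrate continuously.

**What the generator does not emulate:** oxygen transfer limitation
(dissolved O₂ is assumed non-limiting, as maintained by a stirrer
cascade in practice), pH and temperature dynamics, by-product spectra
beyond optional trace glycerol/acetate fluxes, lag phases, and
autocorrelated sensor drift. Passing recovery tests therefore shows the
extractor is unbiased against this error model, not against every
failure mode of real reactors.

## The packaged dataset and its repair

The reference table ships verbatim: 66 runs, one row per cultivation.
`build_analysis_set` averages biological replicates per metric
(arithmetic mean of run-level values — replicates were separate
cultivations, so run-level averaging, not pooled refitting, is the
faithful operation), excludes the fructophilic *Zygosaccharomyces*
species, the gut isolate *T. blattae* and the five
non-*Saccharomycetaceae* controls, and yields 37 strains
(groups 1–4: 10, 8, 4, 15). Two same-species strains of *L. kluyverii*
and three of *K. marxianus* are distinct data points, which the strain
key (species + primary collection id) preserves.

Two printed rows fail the table's own internal identity
μ ≈ q_S·Y_X/S (it holds to ~3% median everywhere else):

* *Tor. franciscae* A1/A2 print consumption rates (0.25/0.27) below
  their production rates (1.03/0.95); swapping the two columns restores
  the identity.
* *Kaz. exiguus* prints (0.43, 0.43, 0.18, 1.75, 0.740) — readable as a
  one-column rightward shift whose true (Y_E/S, Y_X/S, q_S, q_E) is
  (0.43, 0.18, 1.75, 0.74), with the growth rate lost; it is
  reconstructed from the same identity as 1.75 × 0.18 = 0.315.

The default remains as-printed; `repaired=True` applies this
reconstruction. Under the repaired variant every grouped statistic
agrees with the reference analysis to a few percent; as printed, the
biomass-yield ANOVA F is ~40% low — strong evidence the original
analysis used unscrambled data. The `reproduce` command emits per-cell
deviations for either variant so the choice stays visible. One
reference cell (Pearson r for ethanol yield vs growth rate, printed
0.38, identical to the row above it, while its Spearman counterpart is
−0.10) appears to be a copy error; the computed value is ≈ 0.04 and is
reported as such, not forced.

## Crabtree classification

Categories follow the published yield cuts: strong positive
(Y_X/S < 0.18 **and** Y_E/S > 0.33 — conjunctive, matching every listed
member), negative-like (Y_X/S > 0.33 and Y_E/S < 0.15), intermediate
(0.18 ≤ Y_X/S ≤ 0.33). These bounds do not tile the yield plane; points
in the gaps get the nearest category by yield distance plus an
`outside published bounds` flag, because the original grouping was
explicitly arbitrary and silent reassignment would hide that.

## Statistics

Distribution functions and rank tests come from scipy; sums of squares,
R² = SS_between/SS_total, the regression F = r²(n−2)/(1−r²) and the
Welch–Satterthwaite df are computed explicitly so the reported
quantities are defined by this package, and brute-force oracles in the
test suite pin them (two-group F = pooled t², hand-ranked
Kruskal–Wallis, hand-evaluated Welch df, R² ≡ r² to 1e−12). All tests
are two-sided at α = 0.05 with raw pairwise p-values, mirroring the
reference analysis; a Holm step-down option exists for users who want
family-wise control over the six pairwise comparisons per parameter.
Spearman p-values use the t approximation (the R default for these
sample sizes). Group summaries are mean ± t₍ₙ₋₁,0.975₎·s/√n.

## Numerical choices and degenerate inputs

* Glucose "depleted" at 0.1 g/L, ethanol "detected" at 0.5 g/L, window
  needs glucose > 1 g/L — all configurable; they are absolute
  concentrations, so rescaled data require rescaled thresholds (the
  scale-invariance property test rescales them alongside).
* Ethanol maximum is the raw earliest-maximum sample; an optional
  3-point median filter handles very noisy traces, off by default.
* Flat biomass fails the window r² criterion and errors with advice to
  supply a manual window; zero glucose consumption, non-increasing
  biomass and sub-minimum samples are errors, not NaNs.
* Welch with two zero-variance samples reports t = 0, p = 1 rather than
  dividing by zero; ANOVA with zero within-group variance and equal
  means reports F = 0.
* The closed-form oracle for noiseless yield recovery integrates the
  model's yield ODE in the substrate coordinate between the run's
  actual endpoints (Monod log-term included), since the
  saturation-limit formula is itself ~1% off for presets with a high
  respiratory fraction.

## Problem sizes

The shipped analyses are small by nature: the reference dataset is 66
rows; simulations integrate ≤ 48 h at 0.01 h steps (≤ 4800 RK4 steps)
sampled half-hourly; recovery ensembles use 50 noise seeds per preset
at cv = 0.02, at which the Monte-Carlo error of ensemble means is well
under the tolerances being checked. The full test suite and the
acceptance script each run in seconds on one CPU.

## Known limitations

* The repair of the two inconsistent reference rows is a documented
  reconstruction, not an erratum; one number (*Kaz. exiguus* growth
  rate) is inferred, and the growth-rate ANOVA is the statistic most
  sensitive to it.
* The simulator's phenotypes are caricatures: single bottleneck
  parameter, fixed yields, no regulation dynamics (no gradual glucose
  repression release, no lag after the diauxic shift).
* Specific rates use window-endpoint samples (Δ-quotients), not
  regression through all window samples; with noiseless data the two
  agree, with noisy data the Δ-quotient is slightly noisier.
* No phylogenetically independent contrasts: group comparisons treat
  strains as independent, as in the reference analysis, although
  related species are not statistically independent samples of the
  trait.
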