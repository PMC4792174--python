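# Methods

## Model and assumptions

The pipeline analyzes continuous ²H₂O-labeling experiments in intact
animals. Its observable is A₀(t), the fractional abundance of a peptide's
monoisotopic isotopomer over labeling time. Three assumptions carry the
analysis:

1. **First-order replacement.** Each protein pool turns over with a single
   rate constant k (1/day); all peptides of a protein share it. Biphasic or
   multi-compartment kinetics are out of scope.
2. **Non-steady-state precursor.** Body water equilibrates with first-order
   kinetics p(t) = p_ss(1 − e^(−k_p t)) rather than instantaneously, so a
   peptide synthesized early carries fewer labels. The precursor's
   0th-isotopomer fraction is A₀,max(t) = a(1 − p(t))^N. This retards the
   initial descent of the decay curve without shifting it rightward.
3. **Sequence-determined constants.** a follows from elemental composition
   and natural isotope abundances (shipped IUPAC table, user-overridable);
   N is the sum of per-residue deuterium-accessible site counts from the
   Commerford-lineage in vivo exchange literature (shipped table,
   user-overridable). Neither is fitted.

Combining 1–3 gives dA₀/dt = k(a(1 − p_ss(1 − e^(−k_p t)))^N − A₀) with
A₀(0) = a. For integer N the binomial expansion of the precursor term
yields the closed form

A₀(t) = a e^(−kt) + a k Σᵢ C(N,i)(1−p_ss)^(N−i) p_ss^i (e^(−i k_p t) − e^(−kt))/(k − i k_p),

with the i-th summand replaced by its limit a k bᵢ t e^(−kt) when
|k − i·k_p| < 10⁻⁹·k_p. An independent oracle integrates the ODE with an
8th-order adaptive Runge–Kutta method (rtol 10⁻¹², atol 10⁻¹⁴); the two
routes agree below 10⁻⁸ across the tested parameter grid. The oracle also
handles real-valued N exactly, whereas the analytic path rounds N to the
nearest integer: rounding shifts the plateau a(1−p_ss)^N by the factor
(1−p_ss)^(−ΔN) — about 2.3% of the plateau per half site at p_ss = 0.045 —
and the transient deviation stays below that shift. Analyses that need
exactness under fractional N should use the ODE path.

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| p_ss | 0.045 (synthetic) | fraction | body-water plateau enrichment; calibrated per experiment from GC-MS |
| k_p | 2.0 (synthetic) | 1/day | body-water equilibration rate; bounded to (0, 50] when fitted |
| k search bounds | [10⁻⁴, 20] | 1/day | turnover-rate search interval |
| k starts | 0.1, with restarts 0.01 and 1.0 | 1/day | lowest-SS restart wins |
| n_peaks | 5 | — | isotopomer envelope truncation (>99.9% of envelope mass for tryptic peptides) |
| filter | DP ≥ 4; R² ≥ 0.8 or s.e. ≤ 0.05 | — | stringency acceptance rule (OR of the two branches) |
| ppm window | 60 | ppm | XIC extraction half-width, half-open interval |
| smoothing | Savitzky-Golay, 7 points, order 2 | — | preserves constant and linear traces exactly |
| digest | after K/R, not before P; 0 missed cleavages; 6–30 aa | — | quantifiable-peptide count for XIC normalization |

The body-water defaults are plausible mouse values for an 8% v/v drinking
supply with a priming bolus (body water equilibrates to roughly half the
supply level within half a day); they are stated as synthetic-generator
conventions, not measured constants, and every fitted analysis calibrates
them from its own GC-MS data.

Fit statistics: R² = 1 − SS/TSS (kept as computed, so flat or poor fits go
negative — required for faithful filter behavior); s.e. = √(SS/(DP−1)) in
A₀ units, the denominator configurable to DP or DP−2; dk is the linearized
one-parameter standard error s.e./√Σ(∂A₀/∂k)². A series with zero total
variance is assigned R² = 0 and flagged via the at-bound indicator. Where
the two criteria interact, the s.e. branch deliberately rescues
slow-turnover peptides whose nearly flat curves bound R² from above.

## The synthetic-data generator

`synth.generate_experiment` emulates the structure the analysis assumes:
six mouse strains × two conditions with sampling days {0,1,3,5,7,10,14}
(six days, dropping day 14, for the treated condition), 18 runs per sample
group and 2 animals per group-day in the bookkeeping; per-protein rates
shared by member peptides; A₀ series from the exact forward model plus
i.i.d. Gaussian noise (default sd 0.01) clamped to [0,1]; body-water
measurements from the enrichment curve plus noise (sd 0.002); peptide
sequences as random tryptic fragments whose a and N are computed exactly
as the analysis computes them.

Rate constants are drawn from a two-piece, quantile-spliced log-normal:
K = median·e^(σ(z)·z) with z standard normal and separate log-scales below
and above the median chosen so the 10th/90th percentiles land exactly on
the target interdecile bounds (0.037 and 0.30/day around a median of
0.094/day). A single log-normal cannot match a median and two
geometrically asymmetric deciles simultaneously; the spliced form reduces
to a plain log-normal when the bounds are symmetric.

What the generator does **not** emulate: chromatographic peak-shape
irregularities, missing time points, heteroscedastic or correlated A₀
noise, mis-identifications, shared peptides between proteins, isotopomer
envelopes beyond Gaussian elution, or run-to-run intensity drift. Passing
recovery tests therefore demonstrate correctness of the estimator under
the model's own assumptions, not robustness to real-data pathologies.

## Numerical choices and degenerate inputs

- Nelder-Mead runs on the scalar SS(k) with a smooth quadratic penalty
  outside the search interval; the quasi-Newton cross-check uses L-BFGS-B
  with box bounds. Multiple starts guard against the shallow-SS ridge at
  small k.
- Flat series (A₀ ≈ constant) drive k to the lower bound and are flagged;
  the filter rejects them through DP/R² regardless.
- Fractional synthesis FS = (a − A₀)/(a − a(1−p_ss)^N) is exact for
  overlaying peptides that differ in a; peptides differing in N retain a
  small early-transient spread under finite k_p that vanishes in the
  fast-enrichment limit. FS is undefined (and rejected) for N = 0 or
  p_ss = 0.
- Enrichment fitting on saturated data (constant p at all t > 0) sits on a
  residual-flat ridge in k_p; any large value below the 50/day bound is an
  equivalent optimum and the plateau remains identifiable.
- XIC extraction uses the half-open window [mz(1−δ), mz(1+δ)); envelope
  areas are trapezoidal over retention time with negative smoothed values
  clipped at zero before integration.
- The within-sample closure of XIC abundance (stage 3) is applied per time
  point, so each intensity column sums to 1.

## Design choices where the design was open

- The R² and s.e. filter criteria combine with OR, matching the two
  accepted populations the filter-sweep diagnostic exposes.
- MAD is unscaled (no 1.4826 normal-consistency factor); even-sized
  medians average the two central values.
- Modifications change elemental composition (hence a) but not N: no
  modification-specific site counts exist in the exchange literature, and
  side-chain/backbone sites dominate.
- The theoretical tryptic-peptide count uses zero missed cleavages:
  "possible tryptic peptides" parses most simply as fully cleaved
  products. Configurable.
- Peptide identity is (sequence including modifications, charge).
- Elution windows for envelope integration are supplied externally (from
  identification retention times); peak detection is out of scope.

## Known limitations

- Single-pool, single-rate model: proteins with biphasic kinetics or
  partially exported pools violate assumption 1 and will show elevated
  intra-protein variability rather than a model error.
- No mzML reader: spectra enter through the in-memory `SpectrumSlice`
  container (the synthetic generator produces them); converting vendor or
  mzML data to that container is the caller's responsibility.
- The analytic path's integer-N rounding (documented above) is a bias, not
  a noise term; it cancels in within-study comparisons but matters for
  absolute rates when N is near a half-integer and p_ss is large.
- Acceptance-scale simulations use 500 peptide series, a 1,000-point
  model-validation grid, 10⁵ rate draws, and a 30-protein pipeline run —
  sizes chosen to make Monte-Carlo error small relative to the tested
  tolerances while keeping the suite fast.
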