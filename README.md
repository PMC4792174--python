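# turnoverkit

Protein turnover kinetics from heavy-water (²H₂O) metabolic labeling.

When an animal drinks deuterated water, newly synthesized proteins
incorporate deuterium at metabolically accessible hydrogen sites. In mass
spectra this appears as a gradual decay of each peptide's monoisotopic
(0th) isotopomer fraction A₀, and the decay rate is the protein's turnover
rate constant *k*. `turnoverkit` implements the full analysis for such
experiments — for proteomics researchers fitting peptide isotopomer time
series, and for methods developers who need a transparent, testable
reference pipeline with a synthetic-data generator.

## The model

Body-water enrichment follows first-order kinetics with plateau p_ss and
rate k_p (both calibrated from GC-MS acetone-exchange measurements):

    p(t) = p_ss · (1 − e^(−k_p t))

The 0th-isotopomer fraction of a peptide with natural-abundance value *a*
and *N* accessible labeling sites obeys the non-steady-state rate equation

    dA₀/dt = k · ( a·(1 − p(t))^N − A₀ ),    A₀(0) = a,

whose closed form (binomial expansion of the precursor term) is fitted to
each peptide's time series by Nelder-Mead simplex, minimizing the residual
sum of squares over *k* alone; a quasi-Newton option cross-checks every
fit. Series pass the stringency filter when quantified at ≥4 time points
with R² ≥ 0.8 or standard error of estimate ≤ 0.05 (the second branch
rescues slow-turnover peptides whose flat curves cannot achieve high R²).
Protein turnover is the median ± median absolute deviation of accepted
member-peptide rates; half-life is ln 2 / k. Label-free abundance comes
from three-stage-normalized XIC envelope areas and from NSAF spectral
counting.

## Worked example

`python examples/single_peptide_fit.py` prints:

```
peptide ALTDTDLTGHGQK: composition C56H93N17O22, a = 0.4826, N = 21.07
true k = 0.094/d; fitted k = 0.0939 ± 0.0036/d
R2 = 0.9906, s.e. = 0.0081 -> half-life 7.38 d
```

Reading: from the sequence alone the pipeline derives *a* (the chance that
a peptide molecule contains no heavy isotope, 48.3% here) and *N* (≈21
deuterium-accessible sites). A simulated 14-day time course with 1% A₀
noise is fitted back to within half a percent of the true rate; ln 2/k
converts the rate to a 7.4-day half-life. The other scripts in `examples/`
cover body-water calibration, the full experiment-level pipeline, envelope
integration from spectra, and abundance quantification.

A thin CLI mirrors the pipeline stages:

```sh
turnoverkit simulate --seed 1 --out-dir exp
turnoverkit fit exp/hl-data.out exp/peptides.csv --pss 0.045 --kp 2.0 --out exp/hl.out
turnoverkit filter exp/hl.out --out exp/hl-accepted.out
turnoverkit aggregate exp/hl-accepted.out --out exp/proteins.csv
```

File formats follow the field's conventions: `hl.out` (14 columns of
per-peptide fits), `hl-data.out` (ID, t, A₀), `intensity.txt` (per-protein
relative intensity at days 0–14).

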