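# Methods

## Spectral model

Each replicate spectrum is a Beer–Lambert mixture on a shared descending
wavenumber grid (default 4000 → 650 cm⁻¹ at 4 cm⁻¹ point spacing; an
8 cm⁻¹ nominal instrument resolution implies denser point spacing, and the
final point is clamped to exactly 650 when the spacing does not divide the
span):

    A(ν) = a · Σᵢ cᵢ εᵢ(ν) + b₀ + b₁·s(ν) + e(ν)

with component concentrations cᵢ in g/dL (IgG mg/dL ÷ 1000), absorptivities
εᵢ built from fixed Gaussian bands, film-thickness factor
a ~ lognormal(0, scatter_sd), a linear baseline drift term, white detector
noise e, and extra noise confined to 2200–1900 cm⁻¹ (emulating the diamond
coating of the ATR element). Three components keep the inverse problem
non-trivial at low rank: IgG and albumin share the amide A/I/II triplet but
differ in relative intensities and band positions (amide II 1550 vs
1544 cm⁻¹; albumin adds a 1400 cm⁻¹ carboxylate band), and a lumped
"matrix" component carries the low-wavenumber salt/metabolite envelope. All
components are essentially zero in the 4000–3800 cm⁻¹ region, which is a
true baseline. No evanescent-wave optics are modelled.

Gross replicate anomalies (mis-spread or contaminated films) are injected
with probability `outlier_rate` per replicate as an additive offset of 10×
the noise SD plus a 20% multiplicative scale error, with random signs; the
flags are kept as ground truth. All randomness flows from a single
`numpy.random.Generator` seeded by the config; identical configs give
bit-identical datasets.

## Reference-IgG distribution

Truth values are drawn from a lognormal (log-median ln 1150, σ = 0.9)
truncated by rejection to the configured range (default 5–3000 mg/dL).
These constants put ≈51% of the truncated mass below the 1000 mg/dL FTPI
cut-off, matching a calf/cow population with about half the animals
IgG-deficient; this makes the downstream diagnostic evaluation meaningful
rather than degenerate. Pre-colostral animals (3.2% of samples, tagged with
the ultra-low RID kit, working range 10–100 mg/dL) are drawn uniformly at
the bottom of the range.

## Study conditions

Two named configurations are fixed:

* `study_config()` — the realistic design: 250 samples × 5 replicates,
  noise_sd 0.001 AU (32 co-added scans), scatter_sd 0.10 (hand-spread dried
  films vary ~10% in effective thickness), baseline drift 0.001 AU,
  diamond-band noise 0.01 AU, outlier rate 1%, albumin 3.5 ± 0.15 g/dL
  (serum albumin is homeostatically tight, CV ≈ 4%), matrix 1.5 ± 0.30 g/dL.
* `recovery_config()` — the parameter-recovery regime: every nuisance term
  at or near zero (noise_sd 0.001, scatter_sd 0.01, no baseline drift,
  composition SDs 0.05 g/dL). Its purpose is to verify that the calibration
  machinery is unbiased when the linear model assumptions hold, so the
  measured error reflects the pipeline, not the simulator's nuisance
  magnitudes.

Recovery runs use the un-normalized smoothing variant deliberately: SNV and
vector normalization are affine-invariant per spectrum, so they erase
absolute-intensity (thickness × concentration) information and map the
concentration simplex onto a curved manifold; under SNV, absolute IgG is
identifiable only through the albumin/matrix composition prior, which
bounds attainable RMSEP at roughly the IgG-weighted albumin CV regardless
of the calibration. That information loss is a property of the
normalization, not a defect of the pipeline, and is visible in the
acceptance output as the gap between the recovery metrics (r ≈ 0.9999)
and the SNV study metrics (r ≈ 0.99).

The same affine-invariance means SNV exactly nulls the simulator's
offset-plus-scale outlier model, so the Dixon screen's operating
characteristics are likewise measured under the non-normalizing spec, where
such an anomaly is observable.

## Preprocessing

Savitzky–Golay filters use window 9, polynomial order 2, with mirror
padding so output length equals input length; interior points reproduce any
polynomial of degree ≤ 2 exactly. Derivatives use the same window/order via
SG convolution and are taken with respect to *increasing* wavenumber
regardless of storage order (one sign flip per derivative order on the
descending grid). Normalization operates on the full-span spectrum before
region selection, matching the stated processing order. SNV uses the
sample (n−1) standard deviation.

The Dixon screen applies the two-tailed r₁₀ statistic (gap over range) at
both extremes of the 3–7 replicate values at each retained wavenumber,
compares the larger statistic to the Rorabacher critical table (n = 5,
95% → 0.710), and flags at most one replicate per point (ties go to the
high end). A replicate flagged at strictly more than 50% of points is
excluded whole, in a single pass (no re-screen of the survivors), and at
least two replicates must survive. Note that with one flag per point the
flag fractions sum to ≤ 1, so the default >50% rule can exclude at most one
replicate per sample; lower thresholds can exclude more. Zero-range points
contribute no flag.

## Calibration

NIPALS PLS1 with deflation of both X and y; X columns are centered but not
variance-scaled (per-spectrum normalization already conditions the data,
and variance scaling is not standard for spectra). The regression vector is
b = W(PᵀW)⁻¹q, so prediction is affine; at k = rank the fit coincides with
the minimum-norm least-squares solution (tested against a pseudoinverse
oracle and against scikit-learn's PLSRegression as an independent
implementation). Factor extraction stops early if the residual covariance
collapses below 1e-12 of its initial norm; further factors reuse the last
regression vector.

MCCV recomputes centering on every training split (the statistically
correct choice), pools squared errors over repeats — RMMCCV(k) =
√(Σ e² ⁄ (N·n_val)) — and breaks ties toward the smallest k (parsimony).
Splits are drawn without replacement from one seeded generator stream.
The default is 10,000 repeats with 67/66 splits of a 133-sample calibration
set; tests and the acceptance script run 200–500 repeats, which is enough
to stabilize the argmin at the simulated signal-to-noise (the RMMCCV
standard error scales as 1/√N).

## Splitting and exclusion

Kit working ranges are closed intervals. The every-third rule sorts
ascending by reference IgG with ties broken by sample id and assigns
1-based ranks 1, 4, 7, … to the prediction set; this offset yields
67 prediction / 133 calibration from 200 retained samples and guarantees
the prediction set spans the extremes. Because all preprocessing is
per-replicate, no statistic computed on the prediction set can reach the
model; this is asserted by perturbing prediction spectra and observing
bit-identical coefficients.

## Evaluation conventions

* Bland–Altman: differences are test − reference; limits mean ± 1.96 ×
  sample SD.
* CCC: population (1/n) moments, per Lin's original definition; |CCC| ≤ |r|
  always, with equality when means and variances agree.
* RPD numerator: population SD of the prediction-set reference values (the
  definition used for this assay family); the sample SD is reported
  alongside. Interpretation bands: RPD < 2 poor; 2–2.5 screening; > 2.5 or
  RER > 10 quantification; > 3 or RER > 20 accurate quantification.
* CV\* = CV(1 + 1/(4n)) with sample SD; assay-side precision predicts each
  surviving replicate spectrum separately with the final model.
* FTPI classification is strict: positive iff IgG < cutoff (default
  1000 mg/dL). Undefined diagnostic rates (zero denominator) are NaN,
  never zero.

## What the simulation does and does not show

Passing tests demonstrate that the pipeline is algorithmically correct
(filters, screen, PLS/MCCV, statistics all verified against independent
oracles) and that it recovers known truth under its own generative model.
The simulator does not reproduce everything in real dried-film spectra:
water-vapor/CO₂ lines, Mie-type scatter curvature, detector nonlinearity,
film cracking, inter-animal variation beyond three components, or
reference-assay (RID) measurement error — the simulated truth is exact,
which is why simulated agreement statistics are optimistic relative to a
field study. Conclusions about real-instrument performance require real
spectra.

## Known limitations

* The Dixon table covers 3–7 replicates; larger replicate groups are
  rejected rather than approximated.
* PLS1 only (single response); no variable selection or nonlinear
  calibration.
* The exclusion step is strictly range-driven; samples outside every kit's
  range are dropped even if their spectra are informative.
* MCCV cost grows linearly in repeats × k_max; the 10,000-repeat default is
  minutes-scale on one core at the study size.
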