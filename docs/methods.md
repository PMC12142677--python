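# Methods

This note documents the models implemented in `cimccs`, the defaults and
why they were chosen, what the simulators do and do not emulate, and the
numerical choices that matter.

## Mass and m/z arithmetic

Monoisotopic masses come from a versioned table of CODATA/AME values shipped
with the package (`cimccs/data/atomic_masses.json`). Adduct m/z is computed
as (M + k·m_atom)/z with the added H/Na/K counted as **neutral atoms** and
the electron mass ignored. This convention — rather than adding proton
masses — is the one under which TOF instruments calibrated against
neutral-atom reference tables report m/z; it reproduces the leucine-
enkephalin lock mass (556.2771) and self-consistent sub-ppm mass errors for
pre-charged quaternary-ammonium cations observed as [M]⁺ and [M+H]²⁺. A
`electron_correction=True` switch subtracts z electron masses for data
processed under the other convention.

Isotopologue spacing uses the single parameter Δ(¹³C–¹²C) = 1.003355 Da.
For organic ions the first isotopologue is carbon-dominated, so charge
inference from spacing (z = round(1.003355/Δm)) is accurate for z ≤ 4; the
residual against the ideal spacing is returned so callers can reject poor
fits. Full isotopic fine structure is out of scope.

Reduced mass is μ = m_ion·m_gas/(m_ion + m_gas). The default drift gas is
N₂ at its monoisotopic mass 28.00615 Da; this is overridable because
vendor pipelines sometimes use the average molecular mass (28.0134 Da) —
the difference shifts all CCS values by < 0.02% and cancels in calibrated
workflows.

## Instrument-default calibration

The single-pass chain is

1. t_d(ms) = t_d(bins) · V_ADC / 1000 (V_ADC = ADC pusher period, μs),
2. t_c* = t_d(ms) − C·√(m/z) (EDC transfer-time correction),
3. Ω_c = m·t_c* + b (linear map fitted to calibrant tables by OLS),
4. Ω = Ω_c · z · √(1/μ).

The EDC coefficient C is applied as read from instrument metadata with a
configurable `edc_unit_factor` (default 1.0), since the metadata field's
scale is vendor-defined. A corrected drift time ≤ 0 is treated as an error
(non-physical) rather than clamped. The inverse chain is provided and used
by the simulator; the forward∘inverse round trip is exact to machine
precision and tested at < 1e−9 relative error.

## Multipass calibration

Arrival-time distributions recorded at several (n, t_s) settings are
reduced to apexes by nonlinear least-squares Gaussian fits (initialised at
the max-intensity bin, σ from FWHM, window ±3 initial σ). The periodic
drift time is then the intercept of the OLS regression

    (t_nd − t_s)/n  =  t_pp − (v_u/v_p) · (t_s/n),

with velocity ratio v_u/v_p = −slope. This regression arrangement is the
reading that makes a linear fit well posed (response and regressor both
scale as 1/n); it is isolated in `fit_tpp` so an alternative arrangement is
a one-function change. At least two settings with distinct t_s/n are
required; acquisition schedules should spread t_s/n (the shipped default
settings span 20–32.5 ms) or the intercept is poorly determined.

Calibration against reference CCS uses a power law Ω_c = A·t_pp^B fitted by
OLS in log–log space: deterministic, initialisation-free, with residuals
reported in both spaces. The power law is fitted to **corrected** CCS
(reference CCS divided by z√(1/μ)) and back-transformed per ion, so one
curve serves all charge states; fitting raw CCS instead would fold the
charge/reduced-mass factor into the curve and break for mixed-z calibrant
sets.

## CCS prediction

One support-vector regressor (RBF kernel) per adduct, trained on a 2-D
RDKit descriptor panel (22 constitutional/topological/polarity descriptors;
configurable by name). Structures are canonicalised before featurization so
equivalent SMILES/InChI encodings give identical vectors. The split is
ceil(0.7·n) training / rest validation, shuffled by an explicit seed;
descriptors and the CCS target are standardised with training-fold
statistics only, and hyperparameters (C, γ, ε) are selected by 3-fold
cross-validated grid search within the training fold. Reported metrics
(median relative error, RMSE) come from the held-out fold only. Adducts
without enough records fall back, with a warning and a flag, to the
protonated model. Numerical parity with any external predictor is not a
goal; the contract is the training protocol and the recovery behaviour on
data with a known generative law.

## Feature processing

Alignment is greedy centroid clustering: features are visited in descending
intensity (ties by ascending m/z) and join the nearest cluster within both
0.03 Da and 2 drift bins of the intensity-weighted centroid, else seed a
new cluster. The greedy-by-intensity order makes strong features anchor the
centroids and is deterministic. Under per-run jitter σ_mz = 0.005 Da /
σ_drift = 0.4 bins, the probability that some member of a 50-feature,
3-run study falls outside the drift tolerance of its anchor is analytically
≈ 4% per study (2·(1−Φ(2/(0.4√2))) per extra member), so occasional single
splits are expected and observed; merges of well-separated features are
not.

Isotope flagging requires the m/z spacing (within 20 ppm of 1.003355/z),
drift agreement (2 bins) and an abundance ratio inside (0.01, 1.0); chains
are capped at depth 2 so flags stay acyclic. Doubly-charged linking tests
|ppm(mz_low, (mz_high + m_H)/2)| ≤ 5 ppm. Background removal is list-based
(m/z exclusion list with ppm tolerance), mirroring a manual curation step.

Differential statistics use the fold change oriented control/case and a
two-sided Welch t-test on per-sample intensity summaries — Welch because
group variances cannot be assumed equal at n = 4 per group. The default
keep rule is (FC ≥ 1.5 or ≤ 1/1.5) and p ≤ 0.1, with no multiple-testing
correction by design (the workflow is a feature-triage step, not an
inference claim); a correction can be layered on by the caller. Both the
fold change and the t statistic are invariant to global intensity
rescaling.

## Annotation

Database matching computes adduct m/z for every (entry, adduct) pair and
keeps hits within ±0.005 Da or ±5 ppm (both bounds inclusive — "±" is read
inclusively throughout). Candidate filtering removes |Δ CCS %| strictly
greater than the threshold (default 1%), so kept ∪ removed is always a
partition and lowering the threshold removes a superset. Isobar
adjudication ranks candidates by |Δ CCS %|; a winner is declared only when
the best two differ by more than 0.05 percentage points — below the
demonstrated measurement accuracy (~0.4%), such ties are genuinely
unresolvable and are flagged instead. Sum-composition agreement is
implemented as elemental-formula + adduct equality, a format-free proxy
that avoids parsing lipid shorthand out of SMILES; a class-tag comparison
is available when both sides carry labels. De novo candidates pass through
filtering identically to database candidates but keep their source label so
reports can segregate them.

## Simulators

All simulators take one explicit seed (numpy `default_rng`; derived seeds
stay below 2³¹) and attach a JSON-serializable truth sidecar; recovery
tests always compare against that truth.

- **Multipass**: true Ω_c follows A = 225, B = 0.55, v_u/v_p = 1.05 —
  values placing lipid-range singly charged ions (CCS 150–330 Å², m/z
  350–950) at t_pp ≈ 10–40 ms. Arrival peaks are Gaussians of width
  0.01·√t_nd ms (diffusion-like broadening) with optional apex jitter and
  additive intensity noise. Not emulated: ion losses, peak tailing, space
  charge, partial pass-count selection.
- **Method comparison**: both calibration routes see the same noisy drift
  measurements; the default route uses only the n = 1 observation (plus
  EDC term added and removed, as on the instrument) with a linear
  calibration, the multipass route regresses all six settings and fits the
  power law. The multipass advantage in this simulation comes from the
  correct curve family and noise averaging over settings — the mechanism,
  not the magnitude, of the real-data advantage, which depends on tissue
  data unavailable here. The shipped study sizes (10 calibrants, 13
  analytes, σ = 0.02 ms, 20 seeds) give mean errors ≈ 1.8% (default) vs
  ≈ 0.1% (multipass).
- **Feature study**: log-normal multiplicative intensity noise with
  σ_log = 0.25 (a ~25% intensity CV, typical for MS intensities), m/z and
  drift jitter per run, planted fold changes of alternating direction,
  isotope partners at +1.003355/z with ratios 0.15–0.45, and doubly
  charged partners satisfying the (M + m_H)/2 relation. Every feature is
  present in every run — no dropout — so passing tests say nothing about
  missingness handling. Under the null, Welch's t on these skewed
  intensities at n = 4 is slightly conservative: the fraction of features
  with p ≤ 0.1 is ≈ 0.084, within Monte-Carlo tolerance of nominal.
- **Candidate lists**: offsets between predicted and experimental CCS are
  drawn from stated distributions (decoys a few percent off, matching the
  mismatch scale of structurally wrong candidates), or placed exactly into
  |offset| bands when a scenario with fixed counts is needed. Structures
  are homologous-series SMILES placeholders; no structure–CCS physics is
  claimed.

## Problem sizes and determinism

The shipped tests and the acceptance script use 500-replicate Monte-Carlo
loops for regression-recovery checks, 100-seed loops for alignment/isotope/
null-statistics rates, 20 seeds for the method comparison, and 500-record
training sets for the predictor — sizes at which the checked quantities'
Monte-Carlo error is comfortably below the asserted margins while the whole
suite runs in well under a minute. Fixed seeds make every simulated dataset
and every trained model bit-reproducible; `GridSearchCV` uses unshuffled
K-fold, and SVR fitting is deterministic.

## Known limitations

- No vendor raw-file parsing; inputs are delimited text exported upstream.
- No Mason–Schamp first-principles CCS (pressure/temperature are not
  modelled); everything is calibration-relative.
- Negative-mode adducts and isotopic fine structure are unsupported.
- The EDC coefficient's physical units are treated as opaque (unit factor
  configurable); only the functional form t − C√(m/z) is assumed.
- The CCS predictor is a protocol implementation, not a replication of any
  published model's numbers; its accuracy statements hold for data with a
  learnable descriptor→CCS law.
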