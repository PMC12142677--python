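# cimccs

Collision-cross-section (CCS) calibration, machine-learning CCS prediction
and CCS-based annotation filtering for cyclic ion mobility (cIM) spatial
metabolomics.

## The problem

In mass spectrometry imaging (MSI), most features never get MS² spectra, so
annotation rests on MS1 m/z matching — which cannot separate isobars and
leaves many features unknown. Traveling-wave cyclic ion mobility adds a
drift-time dimension: with an accurate calibration, drift times become CCS
values (Ω, Å²), a structure-dependent quantity that can be *predicted* from
a candidate structure and compared with the measurement. When CCS accuracy
reaches a few tenths of a percent, a ±1% agreement window between predicted
and experimental CCS becomes a sharp filter on candidate structures and can
adjudicate between isobaric database matches.

`cimccs` implements that workflow end to end for users of cIM-MSI data:

- **`cimccs.masscalc`** — exact-mass/adduct arithmetic: monoisotopic masses
  from a shipped atomic-mass table, adduct m/z ([M+H]⁺, [M+Na]⁺, [M+K]⁺,
  [M+2H]²⁺, plus [M]⁺ / [M+H]²⁺ for pre-charged cations), ppm errors,
  ¹³C-spacing charge inference, ion–gas reduced mass μ.
- **`cimccs.calibration`** — two drift→CCS routes.
  *Instrument default* (single pass):
  t_d(ms) = t_d(bins)·V_ADC/1000, t_c* = t_d − C√(m/z),
  Ω_c = m·t_c* + b, Ω = Ω_c·z·√(1/μ).
  *Multipass*: Gaussian apexes of arrival distributions at several pass
  counts n and separation times t_s, the regression
  (t_nd − t_s)/n = t_pp − (v_u/v_p)(t_s/n) to extract the periodic drift
  time t_pp per ion, and a power-law calibration Ω_c = A·t_pp^B fitted in
  log–log space against reference CCS values.
- **`cimccs.predictor`** — per-adduct support-vector regression over an
  RDKit 2-D descriptor panel, 70/30 train/validation split, cross-validated
  hyperparameter search on the training fold only.
- **`cimccs.features`** — cross-run feature alignment (0.03 Da / 2-bin
  tolerances), isotope flagging, doubly-charged linking, ion-image Pearson
  correlation, and control/tumor differential statistics (fold change +
  Welch t-test, 1.5-FC / 0.1-p defaults).
- **`cimccs.annotate`** — m/z database matching (±0.005 Da or ±5 ppm),
  ±1% CCS candidate filtering, isobar adjudication by smallest |Δ CCS %|,
  sum-composition consistency, SIRIUS-style candidate-file ingestion.
- **`cimccs.simulate`** — seeded ground-truth generators for all of the
  above (arrival histograms, two-group feature studies, candidate lists,
  predictor training data).

## Worked example

Check a measured m/z against a pre-charged cation's formula (a
quaternary-ammonium drug observed as [M]⁺):

```bash
$ cimccs masscheck --formula C32H53N2O4 --adduct "[M]+" --measured 529.3989
{
  "formula": "C32H53N2O4",
  "adduct": "[M]+",
  "z": 1,
  "theoretical_mz": 529.4005,
  "measured_mz": 529.3989,
  "ppm_error": -3.1
}
```

The theoretical cation mass is 529.4005 Da (neutral-atom monoisotopic
masses, no electron correction) and the measurement is 3.1 ppm low — well
inside the agreement expected for an identification.

Simulate a multipass acquisition and calibrate it back:

```bash
$ cimccs simulate --kind multipass --seed 5 --out simdata
$ cimccs calibrate --arrivals simdata/arrivals.csv --ions simdata/ions.csv --out ccs.csv
```

`ccs.csv` then holds, per ion, the fitted periodic drift time `t_pp_ms`,
the calibrated `ccs`, and `percent_error` against the reference value
(≈ 0.1% at the simulated noise level — the accuracy regime in which a ±1%
candidate filter is meaningful).

The same steps are available as library calls (`simulate.simulate_multipass`,
`calibration.estimate_tpp`, `calibration.fit_multipass_calibration`,
`annotate.filter_candidates`, …); see `docs/methods.md` for the model
details and parameter choices.

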