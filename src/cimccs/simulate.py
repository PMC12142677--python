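"""Ground-truth simulators for the whole workflow.

Every simulator draws all randomness from one explicit seed and ships a
:class:`SimulationTruth` sidecar, so downstream recovery tests always compare
against known truth rather than hard-coded numbers.

What is emulated (and what is not): multipass arrival-time distributions are
ideal Gaussians whose apex follows the periodic-drift-time model with
diffusion-like sqrt(t) broadening -- no ion losses, space charge or peak
tailing; feature studies use log-normal multiplicative intensity noise with
every feature present in every run -- no dropout or matrix effects; candidate
lists carry CCS offsets drawn from stated distributions rather than real
structure--CCS physics.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import calibration as cal
from .annotate import Candidate
from .masscalc import C13_C12_SPACING, MONOISOTOPIC_MASS, N2, DriftGas, reduced_mass

__all__ = [
    "SimulationTruth",
    "make_ion_set",
    "MultipassDataset",
    "simulate_multipass",
    "simulate_default_method",
    "CalibrationComparison",
    "simulate_calibration_study",
    "FeatureStudy",
    "simulate_feature_study",
    "study_intensity_table",
    "simulate_ion_images",
    "simulate_candidates",
    "IsobarCase",
    "simulate_isobar_pairs",
    "simulate_predictor_data",
    "simulate_structure_dataset",
]

#: Default multipass acquisition settings: (pass count, separation time ms).
#: Separation times grow super-linearly with pass count so that t_s/n spans a
#: range and the periodic-drift regression is well conditioned.
DEFAULT_PASS_SETTINGS: Tuple[Tuple[int, float], ...] = (
    (1, 20.0),
    (2, 45.0),
    (3, 75.0),
    (4, 110.0),
    (5, 150.0),
    (6, 195.0),
)

# Default power-law calibration truth: Omega_c = A * t_pp**B with t_pp in ms.
# Chosen so that singly charged lipid-range ions (CCS ~ 150-330 A^2,
# m/z ~ 350-950) land at periodic drift times of ~10-40 ms.
DEFAULT_A = 225.0
DEFAULT_B = 0.55
DEFAULT_VELOCITY_RATIO = 1.05


@dataclass
class SimulationTruth:
    """Ground truth serialized alongside every simulated dataset."""

    seed: int
    params: dict = field(default_factory=dict)
    values: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        def _default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, pd.DataFrame):
                return o.to_dict(orient="list")
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(f"not JSON-serializable: {type(o)}")

        text = json.dumps(
            {"seed": self.seed, "params": self.params, "values": self.values},
            indent=2,
            default=_default,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def make_ion_set(
    n: int,
    ccs_range: Tuple[float, float] = (150.0, 330.0),
    mz_range: Tuple[float, float] = (350.0, 950.0),
    seed: int = 0,
    prefix: str = "ion",
) -> pd.DataFrame:
    """A set of singly charged ions with CCS loosely correlated with m/z.

    Returns columns name, mz, z, mass (ion mass, Da) and ccs (A^2).
    """
    rng = np.random.default_rng(seed)
    mz = np.sort(rng.uniform(*mz_range, size=n))
    frac = (mz - mz_range[0]) / (mz_range[1] - mz_range[0])
    ccs = ccs_range[0] + frac * (ccs_range[1] - ccs_range[0])
    ccs = ccs * (1.0 + rng.normal(0, 0.02, size=n))  # compound-class scatter
    ccs = np.clip(ccs, ccs_range[0] * 0.9, ccs_range[1] * 1.1)
    return pd.DataFrame(
        {
            "name": [f"{prefix}{i:02d}" for i in range(n)],
            "mz": mz,
            "z": 1,
            "mass": mz - MONOISOTOPIC_MASS["H"],  # treat as [M+H]+ species
            "ccs": ccs,
        }
    )


def _true_tpp(
    ions: pd.DataFrame, A: float, B: float, gas: DriftGas
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-ion corrected CCS and periodic drift time under the true power law."""
    omega_c = np.array(
        [
            cal.ccs_to_corrected(c, int(z), reduced_mass(m, gas.mass))
            for c, z, m in zip(ions["ccs"], ions["z"], ions["mass"])
        ]
    )
    t_pp = (omega_c / A) ** (1.0 / B)
    return omega_c, t_pp


def _t_nd(t_pp: float, n: int, t_s: float, velocity_ratio: float) -> float:
    # inverse of the periodic-drift regression model:
    # (t_nd - t_s)/n = t_pp - (v_u/v_p) * t_s/n
    return t_s + n * t_pp - velocity_ratio * t_s


@dataclass
class MultipassDataset:
    ions: pd.DataFrame
    pass_settings: Sequence[Tuple[int, float]]
    #: ion name -> {(n, t_s): (times ms, intensities)}
    histograms: Dict[str, Dict[Tuple[int, float], Tuple[np.ndarray, np.ndarray]]]
    truth: SimulationTruth

    def to_long_table(self) -> pd.DataFrame:
        """Long-format arrival data (ion, n, t_s, time_ms, intensity)."""
        rows = []
        for name, per_setting in self.histograms.items():
            for (n, t_s), (t, y) in per_setting.items():
                rows.append(
                    pd.DataFrame(
                        {"ion": name, "n": n, "t_s": t_s, "time_ms": t, "intensity": y}
                    )
                )
        return pd.concat(rows, ignore_index=True)


def simulate_multipass(
    ions: pd.DataFrame,
    pass_settings: Sequence[Tuple[int, float]] = DEFAULT_PASS_SETTINGS,
    noise_sigma_ms: float = 0.0,
    seed: int = 0,
    *,
    A: float = DEFAULT_A,
    B: float = DEFAULT_B,
    velocity_ratio: float = DEFAULT_VELOCITY_RATIO,
    drift_gas: DriftGas = N2,
    peak_width_coeff: float = 0.01,
    points_per_peak: int = 81,
    intensity_noise: float = 0.0,
) -> MultipassDataset:
    """Generate multipass arrival-time histograms for ions of known CCS.

    For each ion the true periodic drift time follows the inverted power law
    ``t_pp = (Omega_c/A)**(1/B)``; for each (n, t_s) setting the total drift
    time follows the inverted periodic-drift model, jittered by
    ``noise_sigma_ms``.  The arrival distribution is a Gaussian of width
    ``peak_width_coeff * sqrt(t_nd)`` (diffusion-like broadening) sampled on
    a regular grid, with optional additive intensity noise (fraction of the
    amplitude).
    """
    if noise_sigma_ms < 0 or intensity_noise < 0:
        raise ValueError("noise parameters must be non-negative")
    rng = np.random.default_rng(seed)
    omega_c, t_pp = _true_tpp(ions, A, B, drift_gas)
    histograms: Dict[str, Dict[Tuple[int, float], Tuple[np.ndarray, np.ndarray]]] = {}
    for i, name in enumerate(ions["name"]):
        per_setting = {}
        for n, t_s in pass_settings:
            if n < 1:
                raise ValueError("pass count must be >= 1")
            center_true = _t_nd(t_pp[i], n, t_s, velocity_ratio)
            if center_true <= 0:
                raise ValueError(
                    f"non-physical drift time for {name} at (n={n}, t_s={t_s})"
                )
            center = center_true + rng.normal(0, noise_sigma_ms) if noise_sigma_ms else center_true
            width = peak_width_coeff * np.sqrt(center_true)
            t = np.linspace(center - 4 * width, center + 4 * width, points_per_peak)
            y = 100.0 * np.exp(-0.5 * ((t - center) / width) ** 2)
            if intensity_noise:
                y = y + rng.normal(0, intensity_noise * 100.0, size=y.size)
            per_setting[(n, t_s)] = (t, y)
        histograms[name] = per_setting
    truth = SimulationTruth(
        seed=seed,
        params={
            "A": A,
            "B": B,
            "velocity_ratio": velocity_ratio,
            "noise_sigma_ms": noise_sigma_ms,
            "peak_width_coeff": peak_width_coeff,
            "intensity_noise": intensity_noise,
            "pass_settings": list(map(list, pass_settings)),
            "drift_gas_mass": drift_gas.mass,
        },
        values={
            "ions": ions.to_dict(orient="list"),
            "omega_c": omega_c,
            "t_pp": t_pp,
        },
    )
    return MultipassDataset(
        ions=ions, pass_settings=list(pass_settings), histograms=histograms, truth=truth
    )


def simulate_default_method(
    ions: pd.DataFrame,
    model: cal.LinearCalModel,
    noise_sigma_bins: float = 0.0,
    seed: int = 0,
    *,
    drift_gas: DriftGas = N2,
) -> Tuple[pd.DataFrame, SimulationTruth]:
    """Single-pass drift-bin readings generated by inverting the default
    calibration chain from known CCS values."""
    rng = np.random.default_rng(seed)
    bins = np.array(
        [
            cal.invert_default_ccs(
                row.ccs, row.mz, int(row.z), row.mass, model, drift_gas=drift_gas
            )
            for row in ions.itertuples()
        ]
    )
    observed = bins + rng.normal(0, noise_sigma_bins, size=bins.size) if noise_sigma_bins else bins
    table = ions.copy()
    table["t_d_bins"] = observed
    truth = SimulationTruth(
        seed=seed,
        params={
            "slope": model.slope,
            "intercept": model.intercept,
            "edc_coefficient": model.edc_coefficient,
            "pusher_period_us": model.pusher_period_us,
            "noise_sigma_bins": noise_sigma_bins,
        },
        values={"true_bins": bins, "ions": ions.to_dict(orient="list")},
    )
    return table, truth


# --------------------------------------------------------------------------
# method-comparison study
# --------------------------------------------------------------------------

@dataclass
class CalibrationComparison:
    per_ion: pd.DataFrame  # name, ccs_true, ccs_default, ccs_multipass, errors (%)
    mean_error_default_pct: float
    mean_error_multipass_pct: float
    truth: SimulationTruth


def simulate_calibration_study(
    n_calibrants: int = 10,
    n_analytes: int = 13,
    noise_sigma_ms: float = 0.02,
    seed: int = 0,
    *,
    pass_settings: Sequence[Tuple[int, float]] = DEFAULT_PASS_SETTINGS,
    A: float = DEFAULT_A,
    B: float = DEFAULT_B,
    velocity_ratio: float = DEFAULT_VELOCITY_RATIO,
    edc_coefficient: float = 1.41,
    drift_gas: DriftGas = N2,
) -> CalibrationComparison:
    """Head-to-head comparison of the two calibration routes on one noisy
    synthetic acquisition.

    The generative truth is the multipass world: drift behaviour follows a
    power law in the periodic drift time, and the single-pass (n=1)
    observation -- the only one the default method sees -- is calibrated with
    the default linear model, while the multipass route regresses all pass
    settings.  Identical per-measurement noise feeds both routes, so any
    accuracy difference reflects the calibration models themselves (linear
    approximation of a curved response, and noise averaging over settings).
    """
    rng = np.random.default_rng(seed)
    cal_seed, ana_seed, noise_seed = rng.integers(0, 2**31 - 1, size=3)
    calibrants = make_ion_set(n_calibrants, seed=int(cal_seed), prefix="cal")
    analytes = make_ion_set(n_analytes, seed=int(ana_seed), prefix="ana")
    ions = pd.concat([calibrants, analytes], ignore_index=True)

    _, t_pp_true = _true_tpp(ions, A, B, drift_gas)
    nrng = np.random.default_rng(int(noise_seed))

    # every ion observed at every pass setting; the n=1 row doubles as the
    # single-pass acquisition used by the default route
    t_nd_obs = {}
    for i in range(len(ions)):
        t_nd_obs[i] = {
            (n, t_s): _t_nd(t_pp_true[i], n, t_s, velocity_ratio)
            + nrng.normal(0, noise_sigma_ms)
            for n, t_s in pass_settings
        }

    n1_setting = min(pass_settings, key=lambda s: s[0])
    mus = np.array([reduced_mass(m, drift_gas.mass) for m in ions["mass"]])
    zs = ions["z"].to_numpy(dtype=int)
    omega_c_ref = np.array(
        [cal.ccs_to_corrected(c, int(z), mu) for c, z, mu in zip(ions["ccs"], zs, mus)]
    )

    is_cal = np.arange(len(ions)) < n_calibrants

    # --- default route: linear fit of corrected CCS vs single-pass drift ---
    # (the EDC term is added when "acquiring" and removed when calibrating,
    # exactly as the instrument chain does)
    t_single = np.array(
        [
            t_nd_obs[i][n1_setting] + edc_coefficient * np.sqrt(ions["mz"][i])
            for i in range(len(ions))
        ]
    )
    t_corrected = np.array(
        [
            cal.edc_correct(t_single[i], edc_coefficient, ions["mz"][i])
            for i in range(len(ions))
        ]
    )
    linear = cal.fit_linear_calibration(
        list(zip(t_corrected[is_cal], omega_c_ref[is_cal])),
        edc_coefficient=edc_coefficient,
    )
    ccs_default = np.array(
        [
            cal.corrected_to_ccs(
                max(linear.ccs_corrected(t_corrected[i]), 1e-9), int(zs[i]), mus[i]
            )
            for i in range(len(ions))
        ]
    )

    # --- multipass route: per-ion t_pp regression + power-law calibration ---
    t_pp_est = np.array(
        [
            cal.fit_tpp(
                [cal.MultipassObservation(n, t_s, t_nd_obs[i][(n, t_s)]) for n, t_s in pass_settings]
            ).t_pp
            for i in range(len(ions))
        ]
    )
    power = cal.fit_multipass_calibration(
        t_pp_est[is_cal], ions["ccs"][is_cal], zs[is_cal], mus[is_cal]
    )
    ccs_multipass = np.array(
        [
            cal.multipass_ccs(t_pp_est[i], int(zs[i]), ions["mass"][i], power, drift_gas=drift_gas).ccs
            for i in range(len(ions))
        ]
    )

    analyte_mask = ~is_cal
    err_default = np.abs(ccs_default - ions["ccs"]) / ions["ccs"] * 100.0
    err_multipass = np.abs(ccs_multipass - ions["ccs"]) / ions["ccs"] * 100.0
    per_ion = pd.DataFrame(
        {
            "name": ions["name"],
            "is_calibrant": is_cal,
            "ccs_true": ions["ccs"],
            "ccs_default": ccs_default,
            "ccs_multipass": ccs_multipass,
            "error_default_pct": err_default,
            "error_multipass_pct": err_multipass,
        }
    )
    truth = SimulationTruth(
        seed=seed,
        params={
            "n_calibrants": n_calibrants,
            "n_analytes": n_analytes,
            "noise_sigma_ms": noise_sigma_ms,
            "A": A,
            "B": B,
            "velocity_ratio": velocity_ratio,
            "edc_coefficient": edc_coefficient,
        },
        values={"t_pp_true": t_pp_true, "t_pp_estimated": t_pp_est},
    )
    return CalibrationComparison(
        per_ion=per_ion,
        mean_error_default_pct=float(err_default[analyte_mask].mean()),
        mean_error_multipass_pct=float(err_multipass[analyte_mask].mean()),
        truth=truth,
    )


# --------------------------------------------------------------------------
# feature studies
# --------------------------------------------------------------------------

@dataclass
class FeatureStudy:
    runs: Dict[str, pd.DataFrame]  # sample name -> (mz, drift_bins, intensity)
    groups: Dict[str, str]  # sample name -> group label
    truth: SimulationTruth


def simulate_feature_study(
    n_features: int = 300,
    n_per_group: int = 4,
    effect_fraction: float = 0.1,
    effect_size: float = 4.0,
    isotope_fraction: float = 0.0,
    n_doubly_charged_pairs: int = 0,
    seed: int = 0,
    *,
    mz_jitter_sd: float = 0.005,
    drift_jitter_sd: float = 0.4,
    intensity_sigma: float = 0.25,
    mz_range: Tuple[float, float] = (150.0, 1100.0),
    drift_range: Tuple[float, float] = (20.0, 180.0),
    min_mz_spacing: float = 0.15,
) -> FeatureStudy:
    """Two-group imaging-style feature study with planted ground truth.

    Emulates a tumor-vs-control tissue comparison: each of the
    ``2 * n_per_group`` samples yields a feature list whose m/z and drift
    positions are jittered per run and whose intensities are log-normal
    around group means.  A fraction of features carries a planted fold
    change (alternating direction, FC oriented control/case); optional
    first-isotopologue partners sit at +1.003355/z with a fixed abundance
    ratio, and optional doubly charged partners satisfy the
    (M + m_H)/2 relation, each with its own isotope for charge inference.
    """
    if not 0 <= effect_fraction <= 1 or not 0 <= isotope_fraction <= 1:
        raise ValueError("fractions must lie in [0, 1]")
    if n_features < 1 or n_per_group < 1:
        raise ValueError("sizes must be >= 1")
    rng = np.random.default_rng(seed)

    # base analyte features on a jittered grid so true features stay apart
    grid = np.linspace(*mz_range, n_features)
    spacing = grid[1] - grid[0] if n_features > 1 else 1.0
    jit = rng.uniform(-0.3, 0.3, size=n_features) * max(spacing - min_mz_spacing, 0)
    mz = grid + jit
    drift = rng.uniform(*drift_range, size=n_features)
    base = rng.lognormal(mean=10.0, sigma=1.0, size=n_features)

    n_effect = int(round(effect_fraction * n_features))
    effect_idx = rng.choice(n_features, size=n_effect, replace=False)
    fc = np.ones(n_features)
    for j, idx in enumerate(np.sort(effect_idx)):
        fc[idx] = effect_size if j % 2 == 0 else 1.0 / effect_size

    records = pd.DataFrame(
        {
            "mz": mz,
            "drift_bins": drift,
            "base_intensity": base,
            "true_fc": fc,
            "is_effect": np.isin(np.arange(n_features), effect_idx),
            "role": "analyte",
            "parent": -1,
            "charge": 1,
        }
    )

    # planted isotopologues
    n_iso = int(round(isotope_fraction * n_features))
    iso_parents = rng.choice(n_features, size=n_iso, replace=False)
    iso_rows = []
    for p in iso_parents:
        ratio = rng.uniform(0.15, 0.45)
        iso_rows.append(
            {
                "mz": records.at[p, "mz"] + C13_C12_SPACING,
                "drift_bins": records.at[p, "drift_bins"],
                "base_intensity": records.at[p, "base_intensity"] * ratio,
                "true_fc": records.at[p, "true_fc"],
                "is_effect": False,
                "role": "isotope",
                "parent": p,
                "charge": 1,
            }
        )

    # planted doubly charged partners (plus their own isotopes)
    dc_rows = []
    for _ in range(n_doubly_charged_pairs):
        p = int(rng.integers(0, n_features))
        mz2 = (records.at[p, "mz"] + MONOISOTOPIC_MASS["H"]) / 2.0
        inten2 = records.at[p, "base_intensity"] * rng.uniform(0.3, 0.8)
        dc_rows.append(
            {
                "mz": mz2,
                "drift_bins": records.at[p, "drift_bins"] * 0.55,
                "base_intensity": inten2,
                "true_fc": records.at[p, "true_fc"],
                "is_effect": False,
                "role": "doubly_charged",
                "parent": p,
                "charge": 2,
            }
        )
        dc_rows.append(
            {
                "mz": mz2 + C13_C12_SPACING / 2.0,
                "drift_bins": records.at[p, "drift_bins"] * 0.55,
                "base_intensity": inten2 * 0.3,
                "true_fc": records.at[p, "true_fc"],
                "is_effect": False,
                "role": "isotope",
                "parent": p,
                "charge": 2,
            }
        )
    all_features = pd.concat(
        [records, pd.DataFrame(iso_rows), pd.DataFrame(dc_rows)], ignore_index=True
    )

    samples = [f"control{i+1}" for i in range(n_per_group)] + [
        f"tumor{i+1}" for i in range(n_per_group)
    ]
    groups = {s: ("control" if s.startswith("control") else "tumor") for s in samples}
    runs: Dict[str, pd.DataFrame] = {}
    intensities: Dict[str, np.ndarray] = {}
    nf = len(all_features)
    for s in samples:
        group_mean = all_features["base_intensity"].to_numpy().copy()
        if groups[s] == "control":
            group_mean = group_mean * all_features["true_fc"].to_numpy()
        inten = group_mean * rng.lognormal(0.0, intensity_sigma, size=nf)
        intensities[s] = inten
        runs[s] = pd.DataFrame(
            {
                "mz": all_features["mz"].to_numpy() + rng.normal(0, mz_jitter_sd, nf),
                "drift_bins": all_features["drift_bins"].to_numpy()
                + rng.normal(0, drift_jitter_sd, nf),
                "intensity": inten,
            }
        )

    truth = SimulationTruth(
        seed=seed,
        params={
            "n_features": n_features,
            "n_per_group": n_per_group,
            "effect_fraction": effect_fraction,
            "effect_size": effect_size,
            "isotope_fraction": isotope_fraction,
            "n_doubly_charged_pairs": n_doubly_charged_pairs,
            "mz_jitter_sd": mz_jitter_sd,
            "drift_jitter_sd": drift_jitter_sd,
            "intensity_sigma": intensity_sigma,
        },
        values={
            "features": all_features,
            "intensities": {s: v for s, v in intensities.items()},
        },
    )
    return FeatureStudy(runs=runs, groups=groups, truth=truth)


def study_intensity_table(study: FeatureStudy) -> pd.DataFrame:
    """Per-sample intensity matrix assembled from the study's ground truth.

    Bypasses alignment (the simulator knows the feature correspondence), so
    statistical behaviour can be tested independently of clustering.
    """
    feats = study.truth.values["features"]
    table = pd.DataFrame(
        {
            "mz": feats["mz"].to_numpy(),
            "drift_bins": feats["drift_bins"].to_numpy(),
        }
    )
    for s, inten in study.truth.values["intensities"].items():
        table[s] = inten
    return table


def simulate_ion_images(
    shape: Tuple[int, int] = (40, 40),
    snr: float = 10.0,
    n_images: int = 2,
    seed: int = 0,
) -> Tuple[List[np.ndarray], np.ndarray]:
    """Noisy renderings of one spatial abundance pattern (two blobs).

    Noise is additive Gaussian with sigma = pattern std / snr.  Returns the
    renderings and the noiseless pattern.
    """
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    cy, cx = shape[0] * 0.35, shape[1] * 0.3
    pattern = np.exp(-(((yy - cy) / (shape[0] * 0.15)) ** 2 + ((xx - cx) / (shape[1] * 0.15)) ** 2))
    pattern += 0.7 * np.exp(
        -(((yy - shape[0] * 0.7) / (shape[0] * 0.2)) ** 2 + ((xx - shape[1] * 0.75) / (shape[1] * 0.2)) ** 2)
    )
    sigma = pattern.std() / snr
    images = [pattern + rng.normal(0, sigma, size=shape) for _ in range(n_images)]
    return images, pattern


# --------------------------------------------------------------------------
# candidate lists
# --------------------------------------------------------------------------

def _alkane(k: int) -> Tuple[str, str]:
    return "C" * k, f"C{k}H{2 * k + 2}"


def simulate_candidates(
    n_database: int = 8,
    n_de_novo: int = 100,
    experimental_ccs: float = 229.0,
    true_offset_sd: float = 0.2,
    decoy_offset_mean: float = 3.0,
    decoy_offset_sd: float = 1.0,
    band_counts: Optional[Sequence[Tuple[float, float, int]]] = None,
    seed: int = 0,
) -> Tuple[List[Candidate], SimulationTruth]:
    """A structure-candidate list with known CCS offsets.

    Default mode: rank 1 is the planted truth with a small offset
    (N(0, true_offset_sd) %); all other candidates are decoys with |offset|
    ~ N(decoy_offset_mean, decoy_offset_sd) %, the mismatch scale typical of
    structurally wrong candidates (a few percent).

    ``band_counts`` mode: pass ``[(lo, hi, count), ...]`` to draw exactly
    ``count`` absolute offsets uniformly from each (lo, hi] percent band
    (signs random, positions shuffled); the planted-truth convention then
    does not apply.  Total candidates = n_database + n_de_novo, and band
    counts must sum to that total.
    """
    rng = np.random.default_rng(seed)
    total = n_database + n_de_novo
    if band_counts is not None:
        if sum(c for _, _, c in band_counts) != total:
            raise ValueError("band counts must sum to n_database + n_de_novo")
        offsets = []
        for lo, hi, count in band_counts:
            mags = rng.uniform(np.nextafter(lo, hi), hi, size=count)
            offsets.extend(mags)
        offsets = np.array(offsets) * rng.choice([-1.0, 1.0], size=total)
        rng.shuffle(offsets)
        true_index = None
    else:
        offsets = np.abs(rng.normal(decoy_offset_mean, decoy_offset_sd, size=total))
        offsets = np.maximum(offsets, 1.2)  # decoys stay clearly off
        offsets *= rng.choice([-1.0, 1.0], size=total)
        offsets[0] = rng.normal(0.0, true_offset_sd)
        true_index = 0

    candidates = []
    for i in range(total):
        smiles, formula = _alkane(i + 1)
        candidates.append(
            Candidate(
                rank=i + 1,
                structure=smiles,
                formula=formula,
                adduct="[M+H]+",
                source="database" if i < n_database else "de novo",
                predicted_ccs=experimental_ccs * (1.0 + offsets[i] / 100.0),
                percent_diff=float(offsets[i]),
            )
        )
    truth = SimulationTruth(
        seed=seed,
        params={
            "n_database": n_database,
            "n_de_novo": n_de_novo,
            "experimental_ccs": experimental_ccs,
            "band_counts": list(map(list, band_counts)) if band_counts else None,
        },
        values={"offsets_pct": offsets, "true_index": true_index},
    )
    return candidates, truth


@dataclass
class IsobarCase:
    experimental_ccs: float
    candidates: List[Candidate]
    true_adduct: str


def simulate_isobar_pairs(
    n_pairs: int = 5,
    truth_within_pct: float = 0.5,
    decoy_beyond_pct: float = 1.5,
    decoy_max_pct: float = 4.0,
    seed: int = 0,
) -> Tuple[List[IsobarCase], SimulationTruth]:
    """Isobaric candidate pairs where the true structure's predicted CCS sits
    within ``truth_within_pct`` of the experimental value and the decoy's
    beyond ``decoy_beyond_pct``.

    Mirrors the sodiated-vs-protonated isobar situation: the true candidate
    is the [M+Na]+ species and the decoy the [M+H]+ species.
    """
    rng = np.random.default_rng(seed)
    cases = []
    truth_offsets, decoy_offsets = [], []
    for i in range(n_pairs):
        ccs = rng.uniform(200.0, 320.0)
        off_t = rng.uniform(0.0, truth_within_pct) * rng.choice([-1.0, 1.0])
        off_d = rng.uniform(decoy_beyond_pct, decoy_max_pct) * rng.choice([-1.0, 1.0])
        truth_offsets.append(off_t)
        decoy_offsets.append(off_d)
        smiles_t, formula_t = _alkane(14 + i)
        smiles_d, formula_d = _alkane(15 + i)
        cases.append(
            IsobarCase(
                experimental_ccs=ccs,
                candidates=[
                    Candidate(
                        rank=1,
                        structure=smiles_t,
                        formula=formula_t,
                        adduct="[M+Na]+",
                        predicted_ccs=ccs * (1 + off_t / 100.0),
                    ),
                    Candidate(
                        rank=2,
                        structure=smiles_d,
                        formula=formula_d,
                        adduct="[M+H]+",
                        predicted_ccs=ccs * (1 + off_d / 100.0),
                    ),
                ],
                true_adduct="[M+Na]+",
            )
        )
    truth = SimulationTruth(
        seed=seed,
        params={
            "n_pairs": n_pairs,
            "truth_within_pct": truth_within_pct,
            "decoy_beyond_pct": decoy_beyond_pct,
        },
        values={"truth_offsets_pct": truth_offsets, "decoy_offsets_pct": decoy_offsets},
    )
    return cases, truth


# --------------------------------------------------------------------------
# predictor training data
# --------------------------------------------------------------------------

def default_generative(X: np.ndarray) -> np.ndarray:
    """Smooth default CCS surface over descriptors: linear + interaction."""
    return 200.0 + 25.0 * X[:, 0] + 12.0 * X[:, 1] + 5.0 * X[:, 0] * X[:, 1]


def simulate_predictor_data(
    n: int = 500,
    descriptor_dim: int = 6,
    noise_sigma: float = 1.0,
    generative: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    seed: int = 0,
) -> Tuple[pd.DataFrame, np.ndarray, SimulationTruth]:
    """Descriptor vectors with CCS = f(descriptors) + Gaussian noise.

    The default generative surface depends on the first two descriptors only
    (linear + interaction, CCS around 200 A^2); the remaining dimensions are
    distractors.
    """
    if n < 20:
        raise ValueError("need n >= 20")
    rng = np.random.default_rng(seed)
    X = rng.normal(0.0, 1.0, size=(n, descriptor_dim))
    f = generative or default_generative
    y_clean = f(X)
    y = y_clean + rng.normal(0.0, noise_sigma, size=n)
    frame = pd.DataFrame(X, columns=[f"d{i}" for i in range(descriptor_dim)])
    truth = SimulationTruth(
        seed=seed,
        params={"n": n, "descriptor_dim": descriptor_dim, "noise_sigma": noise_sigma},
        values={
            "generative": getattr(f, "__name__", "custom"),
            "y_clean": y_clean,
        },
    )
    return frame, y, truth


def simulate_structure_dataset(
    n: int = 80,
    adduct: str = "[M+H]+",
    noise_sigma: float = 1.0,
    seed: int = 0,
) -> Tuple[pd.DataFrame, SimulationTruth]:
    """A structure-level training set (SMILES + CCS) with known generative law.

    Structures are homologous series (alkanes, primary alcohols, primary
    amines) and the CCS is a smooth function of heavy-atom count and H-bond
    donors plus noise -- enough structure--property signal for the descriptor
    panel to learn from, without claiming real CCS physics.
    """
    rng = np.random.default_rng(seed)
    rows = []
    k = 2
    heads = ("", "O", "N")
    while len(rows) < n:
        for head in heads:
            if len(rows) >= n:
                break
            smiles = "C" * k + head
            heavy = k + (1 if head else 0)
            donors = 1 if head else 0
            ccs = 60.0 + 6.5 * heavy + 4.0 * donors + rng.normal(0.0, noise_sigma)
            rows.append(
                {"id": f"cmpd{len(rows):03d}", "structure": smiles, "adduct": adduct, "ccs": ccs}
            )
        k += 1
    frame = pd.DataFrame(rows)
    truth = SimulationTruth(
        seed=seed,
        params={"n": n, "adduct": adduct, "noise_sigma": noise_sigma},
        values={"law": "ccs = 60 + 6.5*heavy_atoms + 4.0*donors + noise"},
    )
    return frame, truth
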