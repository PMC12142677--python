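"""MSI feature-table processing.

Cross-run alignment of (m/z, drift) feature lists, background removal,
isotopologue flagging, charge-state linking of doubly/singly charged pairs,
spatial correlation of ion images, and two-group differential statistics
(fold change + Welch t-test).

A feature table is a pandas DataFrame with one row per aligned feature and
columns ``mz``, ``drift_bins``, ``n_members``, ``role`` (one of ``analyte``,
``isotope``, ``background``), ``parent_id``, ``charge`` plus one intensity
column per run/sample.
"""

from __future__ import annotations

from typing import Mapping, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .masscalc import MONOISOTOPIC_MASS, isotope_mz, ppm_error

__all__ = [
    "align_features",
    "remove_background",
    "flag_isotopes",
    "link_multiply_charged",
    "LinkResult",
    "spatial_correlation",
    "differential_filter",
    "volcano_data",
]

_META_COLS = ("mz", "drift_bins", "n_members", "total_intensity", "role", "parent_id", "charge")


def intensity_columns(table: pd.DataFrame) -> list:
    """Names of the per-run/per-sample intensity columns of a feature table."""
    return [c for c in table.columns if c not in _META_COLS]


def align_features(
    runs: Sequence[pd.DataFrame],
    mz_tol: float = 0.03,
    drift_tol: float = 2.0,
    run_names: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Greedy centroid clustering of per-run feature lists into one table.

    Features are visited in order of descending intensity (ties broken by
    ascending m/z) and join the nearest existing cluster whose
    intensity-weighted centroid lies within both ``mz_tol`` (Da) and
    ``drift_tol`` (bins); otherwise they seed a new cluster.  Every input
    feature joins exactly one cluster.

    Each run DataFrame needs columns ``mz``, ``drift_bins`` and
    ``intensity``.
    """
    if len(runs) < 1:
        raise ValueError("need at least one run")
    if run_names is None:
        run_names = [f"run{i}" for i in range(len(runs))]
    if len(run_names) != len(runs):
        raise ValueError("run_names length must match runs")

    mzs, drifts, intens, run_idx = [], [], [], []
    for i, run in enumerate(runs):
        for col in ("mz", "drift_bins", "intensity"):
            if col not in run.columns:
                raise ValueError(f"run {run_names[i]!r} is missing column {col!r}")
        mzs.append(run["mz"].to_numpy(dtype=float))
        drifts.append(run["drift_bins"].to_numpy(dtype=float))
        intens.append(run["intensity"].to_numpy(dtype=float))
        run_idx.append(np.full(len(run), i))
    mz = np.concatenate(mzs)
    drift = np.concatenate(drifts)
    inten = np.concatenate(intens)
    ridx = np.concatenate(run_idx)

    order = np.lexsort((mz, -inten))  # intensity desc, mz asc tie-break
    n = mz.size
    c_mz = np.empty(n)
    c_drift = np.empty(n)
    c_weight = np.empty(n)
    c_members = np.zeros(n, dtype=int)
    c_run_int = np.zeros((n, len(runs)))
    k = 0
    for j in order:
        m, d, w, r = mz[j], drift[j], inten[j], ridx[j]
        target = -1
        if k:
            dmz = np.abs(c_mz[:k] - m)
            ok = (dmz <= mz_tol) & (np.abs(c_drift[:k] - d) <= drift_tol)
            if ok.any():
                cand = np.flatnonzero(ok)
                target = cand[np.argmin(dmz[cand])]
        if target < 0:
            target = k
            c_mz[k] = m
            c_drift[k] = d
            c_weight[k] = 0.0
            k += 1
            w_old = 0.0
        else:
            w_old = c_weight[target]
        # intensity-weighted centroid update
        w_new = w_old + w
        c_mz[target] = (c_mz[target] * w_old + m * w) / w_new if w_new > 0 else m
        c_drift[target] = (c_drift[target] * w_old + d * w) / w_new if w_new > 0 else d
        c_weight[target] = w_new
        c_members[target] += 1
        c_run_int[target, r] += w

    table = pd.DataFrame(
        {
            "mz": c_mz[:k],
            "drift_bins": c_drift[:k],
            "n_members": c_members[:k],
            "total_intensity": c_weight[:k],
            "role": "analyte",
            "parent_id": -1,
            "charge": 0,
        }
    )
    for i, name in enumerate(run_names):
        table[name] = c_run_int[:k, i]
    table = table.sort_values("mz", kind="stable").reset_index(drop=True)
    table.index.name = "feature_id"
    return table


def remove_background(
    table: pd.DataFrame, exclusion_mzs: Sequence[float], ppm_tol: float = 10.0
) -> pd.DataFrame:
    """Flag features matching a user-supplied m/z exclusion list as background.

    Mirrors a manual removal of non-endogenous ions: any feature within
    ``ppm_tol`` of a listed m/z gets ``role == "background"``.
    """
    out = table.copy()
    mz = out["mz"].to_numpy(dtype=float)
    mask = np.zeros(len(out), dtype=bool)
    for ex in exclusion_mzs:
        mask |= np.abs(mz - ex) / ex * 1e6 <= ppm_tol
    out.loc[mask, "role"] = "background"
    return out


def flag_isotopes(
    table: pd.DataFrame,
    drift_tol: float = 2.0,
    ratio_bounds: Tuple[float, float] = (0.01, 1.0),
    ppm_tol: float = 20.0,
    z_max: int = 4,
    max_depth: int = 2,
) -> pd.DataFrame:
    """Flag first-isotopologue partners based on m/z spacing, drift and ratio.

    Feature B is flagged as the isotope of feature A when B's m/z matches
    ``isotope_mz(A.mz, z, 1)`` within ``ppm_tol`` for some charge z <= z_max,
    their drift positions agree within ``drift_tol`` bins, and the intensity
    ratio B/A falls inside ``ratio_bounds``.  Chains are limited to
    ``max_depth`` (an isotope's isotope is allowed once; deeper chains are
    not), so flags stay acyclic.
    """
    out = table.copy()
    mz = out["mz"].to_numpy(dtype=float)
    drift = out["drift_bins"].to_numpy(dtype=float)
    inten = out["total_intensity"].to_numpy(dtype=float)
    role = out["role"].to_numpy(dtype=object)
    parent = out["parent_id"].to_numpy().copy()
    charge = out["charge"].to_numpy().copy()
    depth = np.zeros(len(out), dtype=int)

    order = np.argsort(mz, kind="stable")
    lo, hi = ratio_bounds
    for ai in order:  # candidate parents, ascending m/z
        if role[ai] == "background" or depth[ai] >= max_depth:
            continue
        for z in range(1, z_max + 1):
            target = isotope_mz(mz[ai], z, 1)
            tol_da = target * ppm_tol * 1e-6
            hits = np.flatnonzero(
                (np.abs(mz - target) <= tol_da)
                & (np.abs(drift - drift[ai]) <= drift_tol)
                & (role != "background")
                & (role != "isotope")
            )
            for bi in hits:
                if bi == ai:
                    continue
                ratio = inten[bi] / inten[ai] if inten[ai] > 0 else np.inf
                if not (lo <= ratio <= hi):
                    continue
                role[bi] = "isotope"
                parent[bi] = ai
                charge[bi] = z
                if charge[ai] == 0:
                    charge[ai] = z
                depth[bi] = depth[ai] + 1
                break  # one isotope partner per (parent, z)
    out["role"] = role
    out["parent_id"] = parent
    out["charge"] = charge
    return out


class LinkResult(NamedTuple):
    is_pair: bool
    ppm_residual: float


def link_multiply_charged(
    mz_high: float, mz_low: float, ppm_tol: float = 5.0
) -> LinkResult:
    """Test whether a low-m/z feature is the doubly charged, protonated form
    of a high-m/z singly charged feature.

    The expected doubly charged m/z is ``(mz_high + m_H) / 2`` (neutral-atom
    hydrogen mass); the pair links when the observed low m/z is within
    ``ppm_tol`` of it.
    """
    if mz_high <= mz_low:
        raise ValueError("mz_high must exceed mz_low")
    expected = (mz_high + MONOISOTOPIC_MASS["H"]) / 2.0
    residual = ppm_error(mz_low, expected)
    return LinkResult(is_pair=abs(residual) <= ppm_tol, ppm_residual=residual)


def spatial_correlation(image1, image2) -> float:
    """Pearson correlation of two ion images over their common pixel grid."""
    a = np.asarray(image1, dtype=float)
    b = np.asarray(image2, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"pixel grids differ: {a.shape} vs {b.shape}")
    a, b = a.ravel(), b.ravel()
    if a.size < 2:
        raise ValueError("need at least 2 pixels")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant image; correlation undefined")
    return float(stats.pearsonr(a, b).statistic)


def differential_filter(
    table: pd.DataFrame,
    groups: Mapping[str, str],
    fc_threshold: float = 1.5,
    p_threshold: float = 0.1,
    control_label: str = "control",
    case_label: str = "tumor",
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Two-group differential filtering on per-sample intensity summaries.

    ``groups`` maps intensity column names to group labels.  The fold change
    is oriented control/case, and the p-value comes from a two-sided Welch
    t-test (unequal variances) on the per-sample values.  A feature is kept
    iff (FC >= fc_threshold or FC <= 1/fc_threshold) and p <= p_threshold.

    Returns ``(filtered_table, stats)`` where ``stats`` has one row per
    input feature.
    """
    control_cols = [c for c, g in groups.items() if g == control_label]
    case_cols = [c for c, g in groups.items() if g == case_label]
    if len(control_cols) < 2 or len(case_cols) < 2:
        raise ValueError("need at least 2 samples per group")
    for c in control_cols + case_cols:
        if c not in table.columns:
            raise ValueError(f"sample column {c!r} not in table")

    a = table[control_cols].to_numpy(dtype=float)
    b = table[case_cols].to_numpy(dtype=float)
    mean_control = a.mean(axis=1)
    mean_case = b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(mean_case > 0, mean_control / mean_case, np.inf)
    t = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isnan(t.pvalue), 1.0, t.pvalue)
    keep = ((fc >= fc_threshold) | (fc <= 1.0 / fc_threshold)) & (p <= p_threshold)

    stat = pd.DataFrame(
        {
            "mz": table["mz"] if "mz" in table.columns else np.nan,
            "mean_control": mean_control,
            "mean_case": mean_case,
            "fold_change": fc,
            "p_value": p,
            "n_control": len(control_cols),
            "n_case": len(case_cols),
            "keep": keep,
        },
        index=table.index,
    )
    return table[keep], stat


def volcano_data(
    stats_table: pd.DataFrame, p_cut: float = 0.05, fc_cut: float = 2.0
) -> pd.DataFrame:
    """log2 fold change, -log10 p and a significance class per feature.

    Classes: ``up`` (up in control: FC >= fc_cut, p <= p_cut), ``down``
    (FC <= 1/fc_cut, p <= p_cut), else ``ns``.
    """
    fc = stats_table["fold_change"].to_numpy(dtype=float)
    p = stats_table["p_value"].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log2_fc = np.log2(fc)
        neg_log10_p = -np.log10(np.maximum(p, 1e-300))
    cls = np.full(len(fc), "ns", dtype=object)
    cls[(fc >= fc_cut) & (p <= p_cut)] = "up"
    cls[(fc <= 1.0 / fc_cut) & (p <= p_cut)] = "down"
    return pd.DataFrame(
        {"log2_fc": log2_fc, "neg_log10_p": neg_log10_p, "significance": cls},
        index=stats_table.index,
    )
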