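"""Per-adduct machine-learning CCS prediction from molecular structure.

A support-vector regression (RBF kernel) is trained per adduct on a panel of
2-D molecular descriptors computed with RDKit.  70% of the records go to
training (hyperparameters selected by cross-validated grid search on the
training fold only) and the held-out 30% provide the validation metrics
(median relative error and RMSE).  Descriptors and the CCS target are
standardised using training-fold statistics only.

The descriptor panel is configuration-driven (any RDKit ``Descriptors``
name), so alternative panels can be swapped in without code changes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence, Union

import joblib
import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors
from sklearn.model_selection import GridSearchCV
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

__all__ = [
    "DEFAULT_DESCRIPTORS",
    "featurize",
    "PredictorModel",
    "train",
    "train_from_descriptors",
    "percent_difference",
    "predict_with_fallback",
    "save_model",
    "load_model",
]

#: Default 2-D descriptor panel: constitutional, topological and
#: polarity-related descriptors, all conformer-free.
DEFAULT_DESCRIPTORS: tuple = (
    "MolWt",
    "ExactMolWt",
    "HeavyAtomCount",
    "NumHAcceptors",
    "NumHDonors",
    "NumHeteroatoms",
    "NumRotatableBonds",
    "RingCount",
    "NumAromaticRings",
    "FractionCSP3",
    "TPSA",
    "MolLogP",
    "MolMR",
    "LabuteASA",
    "BertzCT",
    "Chi0v",
    "Chi1v",
    "Chi2v",
    "Kappa1",
    "Kappa2",
    "Kappa3",
    "HallKierAlpha",
)

_DEFAULT_GRID: Mapping[str, Sequence] = {
    "C": [1.0, 10.0, 100.0],
    "gamma": ["scale", 0.03, 0.3],
    "epsilon": [0.01, 0.05, 0.1],
}


def _mol_from_structure(structure: str) -> Chem.Mol:
    s = structure.strip()
    if s.startswith("InChI="):
        mol = Chem.MolFromInchi(s)
    else:
        mol = Chem.MolFromSmiles(s)
    if mol is None:
        raise ValueError(f"unparseable structure: {structure!r}")
    # round-trip through canonical SMILES so equivalent encodings collapse
    mol = Chem.MolFromSmiles(Chem.MolToSmiles(mol))
    return mol


def featurize(
    structure: str, descriptor_names: Sequence[str] = DEFAULT_DESCRIPTORS
) -> pd.Series:
    """Compute the named RDKit descriptors for a SMILES or InChI string.

    The structure is canonicalised first, so equivalent encodings of the
    same molecule yield identical vectors.
    """
    mol = _mol_from_structure(structure)
    values = {}
    for name in descriptor_names:
        fn = getattr(Descriptors, name, None)
        if fn is None:
            raise ValueError(f"unknown RDKit descriptor: {name!r}")
        values[name] = float(fn(mol))
    return pd.Series(values, name=Chem.MolToSmiles(mol))


@dataclass
class PredictorModel:
    """A trained per-adduct CCS regressor with its scaling and metrics."""

    adduct: Optional[str]
    descriptor_names: Sequence[str]
    scaler: StandardScaler
    y_mean: float
    y_std: float
    regressor: SVR
    best_params: dict
    metrics: dict
    seed: int
    n_train: int
    n_valid: int

    def predict_descriptors(self, X: Union[np.ndarray, pd.DataFrame]) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        scaled = self.scaler.transform(X)
        return self.regressor.predict(scaled) * self.y_std + self.y_mean

    def predict(self, structure: str, adduct: Optional[str] = None) -> float:
        """Predicted CCS (A^2) for one structure; deterministic given the model."""
        if adduct is not None and self.adduct is not None and adduct != self.adduct:
            warnings.warn(
                f"predicting a {adduct} ion with a model trained for "
                f"{self.adduct}",
                stacklevel=2,
            )
        vec = featurize(structure, self.descriptor_names)
        return float(self.predict_descriptors(vec.to_numpy())[0])


def train_from_descriptors(
    X: Union[np.ndarray, pd.DataFrame],
    y: Sequence[float],
    *,
    adduct: Optional[str] = None,
    descriptor_names: Optional[Sequence[str]] = None,
    train_fraction: float = 0.70,
    seed: int = 0,
    param_grid: Optional[Mapping[str, Sequence]] = None,
    cv: int = 3,
    min_records: int = 20,
) -> PredictorModel:
    """Fit an SVR CCS model on a precomputed descriptor matrix.

    The split is ceil(train_fraction * n) training records (shuffled by
    ``seed``) and the remainder held out; validation metrics are computed on
    the held-out records only.
    """
    if isinstance(X, pd.DataFrame):
        if descriptor_names is None:
            descriptor_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if descriptor_names is None:
            descriptor_names = [f"d{i}" for i in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < min_records:
        raise ValueError(f"need at least {min_records} records, got {n}")
    if np.ptp(y) == 0:
        raise ValueError("CCS target is single-valued; nothing to learn")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = math.ceil(train_fraction * n)
    train_idx, valid_idx = perm[:n_train], perm[n_train:]

    scaler = StandardScaler().fit(X[train_idx])
    y_mean = float(y[train_idx].mean())
    y_std = float(y[train_idx].std())
    if y_std == 0:
        raise ValueError("training fold has single-valued CCS")
    Xt = scaler.transform(X[train_idx])
    yt = (y[train_idx] - y_mean) / y_std

    search = GridSearchCV(
        SVR(kernel="rbf"),
        dict(param_grid or _DEFAULT_GRID),
        cv=min(cv, n_train),
        n_jobs=1,
    )
    search.fit(Xt, yt)
    svr = search.best_estimator_

    model = PredictorModel(
        adduct=adduct,
        descriptor_names=list(descriptor_names),
        scaler=scaler,
        y_mean=y_mean,
        y_std=y_std,
        regressor=svr,
        best_params=dict(search.best_params_),
        metrics={},
        seed=seed,
        n_train=int(n_train),
        n_valid=int(n - n_train),
    )
    if valid_idx.size:
        pred = model.predict_descriptors(X[valid_idx])
        rel = np.abs(pred - y[valid_idx]) / y[valid_idx] * 100.0
        model.metrics = {
            "median_rel_error_pct": float(np.median(rel)),
            "mean_rel_error_pct": float(np.mean(rel)),
            "rmse": float(np.sqrt(np.mean((pred - y[valid_idx]) ** 2))),
        }
    return model


def train(
    records: pd.DataFrame,
    adduct: str,
    *,
    train_fraction: float = 0.70,
    seed: int = 0,
    descriptor_names: Sequence[str] = DEFAULT_DESCRIPTORS,
    param_grid: Optional[Mapping[str, Sequence]] = None,
    min_records: int = 20,
) -> PredictorModel:
    """Train a CCS model for one adduct from (structure, adduct, ccs) records.

    ``records`` needs columns ``structure`` (SMILES or InChI), ``adduct``
    and ``ccs``; rows for other adducts are ignored.
    """
    for col in ("structure", "adduct", "ccs"):
        if col not in records.columns:
            raise ValueError(f"training records are missing column {col!r}")
    subset = records[records["adduct"] == adduct]
    if len(subset) < min_records:
        raise ValueError(
            f"need at least {min_records} records for adduct {adduct}, "
            f"got {len(subset)}"
        )
    X = np.vstack(
        [featurize(s, descriptor_names).to_numpy() for s in subset["structure"]]
    )
    model = train_from_descriptors(
        X,
        subset["ccs"].to_numpy(dtype=float),
        adduct=adduct,
        descriptor_names=descriptor_names,
        train_fraction=train_fraction,
        seed=seed,
        param_grid=param_grid,
        min_records=min_records,
    )
    return model


def percent_difference(
    predicted: float, experimental: float, *, signed: bool = True
) -> float:
    """Percent difference of a predicted CCS relative to the experimental one."""
    if experimental <= 0:
        raise ValueError("experimental CCS must be positive")
    diff = (predicted - experimental) / experimental * 100.0
    return diff if signed else abs(diff)


def predict_with_fallback(
    models: Mapping[str, PredictorModel],
    structure: str,
    adduct: str,
    *,
    fallback_adduct: str = "[M+H]+",
) -> tuple:
    """Predict with the adduct's own model, or fall back to the protonated
    model (flagged) when no model exists for the adduct.

    Returns ``(ccs, used_fallback)``.
    """
    if adduct in models:
        return models[adduct].predict(structure), False
    if fallback_adduct not in models:
        raise KeyError(
            f"no model for adduct {adduct} and no {fallback_adduct} fallback"
        )
    warnings.warn(
        f"no CCS model for {adduct}; falling back to the {fallback_adduct} model",
        stacklevel=2,
    )
    return models[fallback_adduct].predict(structure), True


def save_model(model: PredictorModel, path) -> None:
    """Serialise a trained model (joblib) with its metadata embedded."""
    joblib.dump({"format": "cimccs-predictor-v1", "model": model}, path)


def load_model(path) -> PredictorModel:
    payload = joblib.load(path)
    if not isinstance(payload, dict) or "model" not in payload:
        raise ValueError(f"{path} is not a cimccs predictor file")
    return payload["model"]
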