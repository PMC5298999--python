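"""Binding-affinity prediction by k-nearest-neighbor regression.

The dissociation free energy −ΔG = −RT·ln(Kd/c°) (c° = 1 M) of an Ig–Ag
complex is estimated by averaging the affinities of its k nearest
neighbours (default k = 10, explored over k ∈ 5..25) in the
two-dimensional descriptor space (IVW-IPL, NIS_charged), trained on
non-Ig–Ag protein complexes.  Reliability diagnostics follow: the mean
neighbour distance d_i, the neighbour-affinity standard deviation σ_i, and
their ratio d_i/σ_i, correlated with the absolute prediction error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import NearestNeighbors

#: gas constant, kcal·mol⁻¹·K⁻¹
R_GAS = 1.9872e-3

#: default temperature, K
T_DEFAULT = 298.0


def kd_to_dG(kd: float, T: float = T_DEFAULT) -> float:
    """Dissociation free energy −ΔG (kcal/mol) from Kd (mol/L).

    −ΔG = −RT·ln(Kd/c°) with the 1 M standard state; Kd = 1 M gives 0.
    """
    if kd <= 0:
        raise ValueError("Kd must be positive")
    if T <= 0:
        raise ValueError("temperature must be positive")
    return -R_GAS * T * math.log(kd)


def dG_to_kd(minus_dG: float, T: float = T_DEFAULT) -> float:
    """Inverse of :func:`kd_to_dG`."""
    return math.exp(-minus_dG / (R_GAS * T))


def dG_to_kd_ratio(err_kcal: float, T: float = T_DEFAULT) -> float:
    """Fold-change in Kd corresponding to a free-energy error (kcal/mol).

    0.878 kcal/mol at 298 K is a factor ≈ 4.4 on Kd; one order of
    magnitude in Kd is RT·ln 10 ≈ 1.36 kcal/mol.
    """
    return math.exp(abs(err_kcal) / (R_GAS * T))


def orders_of_magnitude_threshold(m: float, T: float = T_DEFAULT) -> float:
    """|error| threshold (kcal/mol) for "Kd within m orders of magnitude"."""
    return m * R_GAS * T * math.log(10.0)


@dataclass
class AffinityRecord:
    complex_id: str
    kd: float
    T: float = T_DEFAULT
    is_ig_ag: bool = False

    @property
    def minus_dG(self) -> float:
        return kd_to_dG(self.kd, self.T)


@dataclass
class KnnModel:
    X_train: np.ndarray            # scaled features
    y_train: np.ndarray            # minus_dG responses
    k: int
    scale_mean: np.ndarray
    scale_std: np.ndarray
    scaling: str
    nn: NearestNeighbors | None = None


@dataclass
class PredictionDiagnostics:
    predicted: np.ndarray
    d_i: np.ndarray                # mean distance to the k neighbours
    sigma_i: np.ndarray            # std of the k neighbours' responses
    truth: np.ndarray | None = None

    @property
    def abs_error(self) -> np.ndarray:
        if self.truth is None:
            raise ValueError("no ground truth attached")
        return np.abs(self.truth - self.predicted)

    @property
    def ratio(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.d_i / self.sigma_i


def fit_knn(features: np.ndarray, responses: np.ndarray, k: int = 10,
            scaling: str = "zscore") -> KnnModel:
    """Store the (scaled) training cloud for k-nearest-neighbour regression.

    Features are z-scored with training statistics by default (the two
    descriptors live on very different scales); ``scaling="none"`` keeps
    raw coordinates.  Requires k < n_training.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(responses, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not (0 < k < len(X)):
        raise ValueError(f"k={k} must satisfy 0 < k < n_training={len(X)}")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite training features")
    if scaling == "zscore":
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std[std == 0] = 1.0
    elif scaling == "none":
        mean = np.zeros(X.shape[1])
        std = np.ones(X.shape[1])
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    Xs = (X - mean) / std
    nn = NearestNeighbors(n_neighbors=k, algorithm="brute")
    nn.fit(Xs)
    return KnnModel(X_train=Xs, y_train=y, k=k, scale_mean=mean,
                    scale_std=std, scaling=scaling, nn=nn)


def predict(model: KnnModel, queries: np.ndarray,
            truth: np.ndarray | None = None) -> PredictionDiagnostics:
    """Unweighted k-NN mean prediction with reliability diagnostics.

    Euclidean distances in the scaled feature space; ties at the k-th
    distance resolve by stable training order.  σ_i is the population
    standard deviation of the k neighbour responses.
    """
    Q = np.asarray(queries, dtype=float)
    if Q.ndim == 1:
        Q = Q[:, None]
    Qs = (Q - model.scale_mean) / model.scale_std
    dist, idx = model.nn.kneighbors(Qs)
    resp = model.y_train[idx]
    return PredictionDiagnostics(
        predicted=resp.mean(axis=1),
        d_i=dist.mean(axis=1),
        sigma_i=resp.std(axis=1),
        truth=None if truth is None else np.asarray(truth, dtype=float),
    )


def error_metrics(diag: PredictionDiagnostics, T: float = T_DEFAULT) -> dict:
    """Median |e| and fractions of predictions within 1/2/3 orders of
    magnitude on Kd (thresholds m·RT·ln10, boundary inclusive)."""
    e = diag.abs_error
    out = {"median_abs_error": float(np.median(e)), "n": int(len(e))}
    for m in (1, 2, 3):
        thr = orders_of_magnitude_threshold(m, T)
        out[f"frac_within_{m}_orders"] = float(np.mean(e <= thr))
    if len(e) >= 3 and np.ptp(diag.truth) > 0 and np.ptp(diag.predicted) > 0:
        out["pearson_r"] = float(stats.pearsonr(diag.truth, diag.predicted)[0])
        out["spearman_r"] = float(stats.spearmanr(diag.truth, diag.predicted)[0])
    return out


def k_sweep(features_train, responses_train, features_test, responses_test,
            k_range=range(5, 26), scaling: str = "zscore",
            T: float = T_DEFAULT) -> pd.DataFrame:
    """Per-k metric table over the stability range k ∈ 5..25."""
    rows = []
    for k in k_range:
        model = fit_knn(features_train, responses_train, k=k, scaling=scaling)
        diag = predict(model, features_test, truth=responses_test)
        rows.append({"k": k, **error_metrics(diag, T)})
    return pd.DataFrame(rows)


def null_model(responses_train, features_test, responses_test,
               T: float = T_DEFAULT) -> tuple[PredictionDiagnostics, dict]:
    """Constant predictor: the training-set mean −ΔG for every query."""
    y = np.asarray(responses_train, dtype=float)
    n_test = len(np.atleast_1d(np.asarray(responses_test)))
    diag = PredictionDiagnostics(
        predicted=np.full(n_test, y.mean()),
        d_i=np.zeros(n_test),
        sigma_i=np.full(n_test, y.std()),
        truth=np.asarray(responses_test, dtype=float),
    )
    return diag, error_metrics(diag, T)


def reliability_analysis(diag: PredictionDiagnostics) -> dict:
    """Pearson correlations (with two-sided p-values) of |e_i| against the
    neighbour-distance and neighbour-spread diagnostics d_i, σ_i, d_i/σ_i."""
    e = diag.abs_error
    if len(e) < 3:
        raise ValueError("need at least 3 test points with known truth")
    out = {}
    for name, v in (("d_i", diag.d_i), ("sigma_i", diag.sigma_i),
                    ("d_over_sigma", diag.ratio)):
        if not np.all(np.isfinite(v)):
            raise ValueError(f"{name} contains non-finite values "
                             "(zero neighbour spread?)")
        if np.std(v) == 0 or np.std(e) == 0:
            raise ValueError(f"zero variance in {name} or |e|: "
                             "correlation undefined")
        r, p = stats.pearsonr(e, v)
        out[name] = {"r": float(r), "p": float(p)}
    return out
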