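"""Population gating: standardized MOBs -> PCA -> LDA planar gate.

A binary linear-discriminant plane in the 3-D principal-component space
separates a target population (e.g. HSC) from the pooled rest; the gate is
reported as per-population fractions on the target side, mirroring the
planar-gate readout of FLIM population plots.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .features import MOB_FEATURES

__all__ = [
    "FeatureMatrix",
    "GateModel",
    "build_feature_matrix",
    "pca_project",
    "fit_lda_gate",
    "apply_gate",
    "population_centroids",
]

SINGLE_CELL_FEATURES = ["orr", "alpha_bound", "tau_bound_ns"]  # 3-feature variant


@dataclass
class FeatureMatrix:
    """Standardized per-cell feature matrix with its inverse transform."""

    values: np.ndarray                 # (n_cells, n_features), z-scored
    feature_names: list[str]
    cell_ids: np.ndarray
    populations: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    impute_policy: str = "drop"

    def destandardize(self) -> np.ndarray:
        return self.values * self.sd + self.mean


@dataclass
class GateModel:
    """PCA loadings plus an LDA plane (normal w, offset b) in PC space.

    A record with PC scores z is on the target side when w.z + b >= 0
    (points exactly on the plane count as target by convention).
    """

    feature_names: list[str]
    standardize_mean: np.ndarray
    standardize_sd: np.ndarray
    pca_mean: np.ndarray
    pca_loadings: np.ndarray           # (k, n_features) rows = components
    explained_variance_ratio: np.ndarray
    w: np.ndarray                      # unit normal in PC space
    b: float
    target: str
    ridge: float = 0.0

    def scores(self, records: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in records.columns]
        if missing:
            raise ValueError(f"records missing feature columns: {missing}")
        x = records[self.feature_names].to_numpy(dtype=float)
        z = (x - self.standardize_mean) / self.standardize_sd
        return (z - self.pca_mean) @ self.pca_loadings.T

    def signed_distance(self, records: pd.DataFrame) -> np.ndarray:
        return self.scores(records) @ self.w + self.b

    def to_json(self, path) -> None:
        payload = {
            "feature_names": self.feature_names,
            "standardize_mean": self.standardize_mean.tolist(),
            "standardize_sd": self.standardize_sd.tolist(),
            "pca_mean": self.pca_mean.tolist(),
            "pca_loadings": self.pca_loadings.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "w": self.w.tolist(),
            "b": self.b,
            "target": self.target,
            "ridge": self.ridge,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GateModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            feature_names=d["feature_names"],
            standardize_mean=np.array(d["standardize_mean"]),
            standardize_sd=np.array(d["standardize_sd"]),
            pca_mean=np.array(d["pca_mean"]),
            pca_loadings=np.array(d["pca_loadings"]),
            explained_variance_ratio=np.array(d["explained_variance_ratio"]),
            w=np.array(d["w"]),
            b=float(d["b"]),
            target=d["target"],
            ridge=float(d["ridge"]),
        )


def build_feature_matrix(records: pd.DataFrame,
                         features: list[str] | None = None,
                         impute: str = "drop") -> FeatureMatrix:
    """Z-score-standardize the selected MOB columns.

    ``impute='drop'`` removes rows with any missing feature;
    ``impute='median'`` fills missing entries with the column median.
    """
    feats = list(features or MOB_FEATURES)
    unknown = [f for f in feats if f not in records.columns]
    if unknown:
        raise ValueError(f"unknown feature columns: {unknown}")
    df = records[feats].astype(float)
    keep = np.ones(len(df), dtype=bool)
    if impute == "drop":
        keep = ~df.isna().any(axis=1).to_numpy()
        df = df[keep]
    elif impute == "median":
        df = df.fillna(df.median())
    else:
        raise ValueError(f"unknown impute policy {impute!r}")
    if len(df) < 2:
        raise ValueError("need at least 2 cells after imputation")
    x = df.to_numpy(dtype=float)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    zero = sd <= 1e-12 * (np.abs(mean) + 1.0)
    if np.any(zero):
        bad = [f for f, z in zip(feats, zero) if z]
        raise ValueError(f"constant feature column(s): {bad}")
    ids = records["cell_id"].to_numpy()[keep] if "cell_id" in records else np.arange(len(records))[keep]
    pops = (records["population"].to_numpy()[keep] if "population" in records
            else np.array([None] * int(keep.sum())))
    return FeatureMatrix(values=(x - mean) / sd, feature_names=feats,
                         cell_ids=ids, populations=pops,
                         mean=mean, sd=sd, impute_policy=impute)


def pca_project(matrix: FeatureMatrix, k: int = 3):
    """Project onto the top-k principal components (deterministic sign).

    The sign of each component is fixed so its largest-magnitude loading
    entry is positive. Returns (scores, model_dict) where the dict carries
    pca_mean, loadings and explained-variance fractions.
    """
    x = matrix.values
    if k > x.shape[1]:
        raise ValueError(f"k={k} exceeds the number of features {x.shape[1]}")
    if x.shape[0] < k:
        raise ValueError("need at least k rows")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(x)
    loadings = pca.components_.copy()
    for i in range(k):
        j = np.argmax(np.abs(loadings[i]))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
            scores[:, i] = -scores[:, i]
    return scores, {
        "pca_mean": pca.mean_,
        "loadings": loadings,
        "explained_variance_ratio": pca.explained_variance_ratio_.copy(),
    }


def fit_lda_gate(scores: np.ndarray, is_target: np.ndarray,
                 ridge: float = 1e-6) -> tuple[np.ndarray, float, float]:
    """Fisher discriminant plane with equal priors.

    ``w`` is proportional to ``Sigma_pooled^{-1} (mu_target - mu_rest)``,
    normalized to unit length; the offset places the threshold at the
    midpoint ``w.(mu_t + mu_r)/2`` (the equal-prior, equal-covariance LDA
    decision boundary). A ridge is added only when the pooled covariance is
    singular; the ridge actually used is returned.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(is_target, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("each class needs at least 2 members")
    mu_t = scores[y].mean(axis=0)
    mu_r = scores[~y].mean(axis=0)
    xt = scores[y] - mu_t
    xr = scores[~y] - mu_r
    n = scores.shape[0]
    cov = (xt.T @ xt + xr.T @ xr) / (n - 2)
    used_ridge = 0.0
    try:
        w = np.linalg.solve(cov, mu_t - mu_r)
    except np.linalg.LinAlgError:
        used_ridge = ridge
        w = np.linalg.solve(cov + ridge * np.eye(cov.shape[0]), mu_t - mu_r)
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("degenerate discriminant (identical class means)")
    w = w / norm
    b = -float(w @ (mu_t + mu_r) / 2.0)
    return w, b, used_ridge


def fit_gate(records: pd.DataFrame, target: str,
             features: list[str] | None = None, k: int = 3,
             impute: str = "drop") -> GateModel:
    """Full gate fit: standardize -> PCA(k) -> binary LDA vs pooled rest."""
    matrix = build_feature_matrix(records, features=features, impute=impute)
    scores, pca = pca_project(matrix, k=k)
    is_target = matrix.populations == target
    if not is_target.any():
        raise ValueError(f"target population {target!r} absent from records")
    w, b, ridge = fit_lda_gate(scores, is_target)
    return GateModel(
        feature_names=matrix.feature_names,
        standardize_mean=matrix.mean, standardize_sd=matrix.sd,
        pca_mean=pca["pca_mean"], pca_loadings=pca["loadings"],
        explained_variance_ratio=pca["explained_variance_ratio"],
        w=w, b=b, target=target, ridge=ridge,
    )


def apply_gate(model: GateModel, records: pd.DataFrame):
    """Evaluate the gate: per-record side and per-population target-side fraction.

    Returns (per_record, fractions): per_record adds ``signed_distance``
    and ``on_target_side`` columns; fractions maps population ->
    fraction of its cells on the target side.
    """
    dist = model.signed_distance(records)
    per_record = records.copy()
    per_record["signed_distance"] = dist
    per_record["on_target_side"] = dist >= 0
    fractions: dict[str, float] = {}
    if "population" in records.columns:
        for pop, grp in per_record.groupby("population", dropna=False):
            fractions[pop] = float(grp["on_target_side"].mean())
    return per_record, fractions


def population_centroids(records: pd.DataFrame,
                         features: list[str] | None = None) -> pd.DataFrame:
    """Per-population mean vector in the given feature space."""
    feats = list(features or MOB_FEATURES)
    if "population" not in records.columns:
        raise ValueError("records need a 'population' column")
    if records["population"].isna().all() or len(records) == 0:
        raise ValueError("no populated records")
    out = records.groupby("population")[feats].mean()
    if (records.groupby("population").size() < 1).any():
        raise ValueError("empty population")
    return out
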