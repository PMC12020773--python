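"""Meal-timing pattern derivation: z-scoring, k-means, naming, assignment.

Stage 2 of the three-stage analysis.  Usual exposures are column-standardised,
partitioned by k-means (best of ``n_starts`` k-means++ initialisations), and
for k = 3 the clusters are named by their centroid signatures:

* highest morning-energy z  -> "early-often"
* of the remaining two, lowest eating-window z -> "late-infrequent-short"
* the other                 -> "late-long"

The standardisation parameters and centroids are frozen in the model
artifact so imputation draws are classified by the exact same function that
defined the patterns (no label switching across imputations).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .recall_processing import EXPOSURE_NAMES

__all__ = [
    "MTPModel",
    "standardize_exposures",
    "fit_kmeans",
    "name_patterns",
    "assign",
    "fit_mtp_model",
]


@dataclass
class MTPModel:
    """Frozen Stage-2 artifact: standardisation + centroids + names."""

    means: np.ndarray
    sds: np.ndarray
    centroids: np.ndarray            # (k, 5) in standardised space
    names: list[str]
    k: int
    n_starts: int
    seed: int
    inertia: float
    exposure_names: list[str]

    def to_json(self, path) -> None:
        payload = {
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "centroids": self.centroids.tolist(),
            "names": self.names,
            "k": self.k,
            "n_starts": self.n_starts,
            "seed": self.seed,
            "inertia": self.inertia,
            "exposure_names": self.exposure_names,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "MTPModel":
        d = json.loads(Path(path).read_text())
        return cls(
            means=np.asarray(d["means"], dtype=float),
            sds=np.asarray(d["sds"], dtype=float),
            centroids=np.asarray(d["centroids"], dtype=float),
            names=list(d["names"]),
            k=int(d["k"]),
            n_starts=int(d["n_starts"]),
            seed=int(d["seed"]),
            inertia=float(d["inertia"]),
            exposure_names=list(d["exposure_names"]),
        )


def standardize_exposures(usual: pd.DataFrame, exposure_names=None):
    """Column-wise z-scores of the usual exposures.

    Returns ``(Z, means, sds)`` with sample (ddof=1) SDs; a zero-SD column is
    an error because a constant exposure carries no pattern information.
    """
    exposure_names = list(exposure_names or EXPOSURE_NAMES)
    X = usual[exposure_names].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("NaN in usual exposures")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    if np.any(sds <= 0):
        bad = [n for n, s in zip(exposure_names, sds) if s <= 0]
        raise ValueError(f"zero-variance exposure column(s): {bad}")
    return (X - means) / sds, means, sds


def fit_kmeans(Z: np.ndarray, k: int = 3, n_starts: int = 25, seed: int = 0):
    """Best-of-``n_starts`` Lloyd's k-means with k-means++ seeding."""
    Z = np.asarray(Z, dtype=float)
    if k > len(Z):
        raise ValueError(f"k={k} exceeds number of rows {len(Z)}")
    km = KMeans(n_clusters=k, n_init=n_starts, random_state=seed)
    km.fit(Z)
    return km.cluster_centers_.copy(), float(km.inertia_), km.labels_.copy()


def name_patterns(centroids: np.ndarray, exposure_names=None) -> list[str]:
    """Name centroids by signature (k = 3 only; otherwise generic names).

    Ties on the morning-energy maximum are broken toward the lower evening z
    (the more "early" centroid); ties on the eating-window minimum toward the
    higher evening z.
    """
    centroids = np.asarray(centroids, dtype=float)
    k = len(centroids)
    if k != 3:
        return [f"pattern_{i + 1}" for i in range(k)]
    exposure_names = list(exposure_names or EXPOSURE_NAMES)
    i_morning = exposure_names.index("morning_pct")
    i_evening = exposure_names.index("evening_pct")
    i_window = exposure_names.index("eating_window_h")

    order = np.lexsort((centroids[:, i_evening], -centroids[:, i_morning]))
    early = int(order[0])
    rest = [i for i in range(3) if i != early]
    # of the remaining two: shortest window -> late-infrequent-short
    r = sorted(rest, key=lambda i: (centroids[i, i_window], -centroids[i, i_evening]))
    names = [""] * 3
    names[early] = "early-often"
    names[r[0]] = "late-infrequent-short"
    names[r[1]] = "late-long"
    return names


def assign(model: MTPModel, exposures) -> np.ndarray:
    """Classify natural-unit exposure vectors to their nearest centroid.

    Deterministic; Euclidean distance in the frozen standardised space; exact
    ties go to the lowest-index centroid.
    """
    if isinstance(exposures, pd.DataFrame):
        X = exposures[model.exposure_names].to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(exposures, dtype=float))
    if X.shape[1] != len(model.exposure_names):
        raise ValueError("exposure vector has wrong number of components")
    if np.isnan(X).any():
        raise ValueError("missing component in exposure vector")
    Z = (X - model.means) / model.sds
    d2 = ((Z[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    idx = np.argmin(d2, axis=1)
    return np.array([model.names[i] for i in idx], dtype=object)


def fit_mtp_model(
    usual: pd.DataFrame, k: int = 3, n_starts: int = 25, seed: int = 0
) -> tuple[MTPModel, np.ndarray]:
    """Standardise, cluster and name in one step.

    Returns the frozen model plus the training-row pattern names.
    """
    Z, means, sds = standardize_exposures(usual)
    centroids, inertia, labels = fit_kmeans(Z, k=k, n_starts=n_starts, seed=seed)
    names = name_patterns(centroids)
    model = MTPModel(
        means=means,
        sds=sds,
        centroids=centroids,
        names=names,
        k=k,
        n_starts=n_starts,
        seed=seed,
        inertia=inertia,
        exposure_names=list(EXPOSURE_NAMES),
    )
    train_names = np.array([names[i] for i in labels], dtype=object)
    return model, train_names
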