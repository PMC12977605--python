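"""Metagenomic subspecies (mgSs) derivation.

For each candidate species, samples are clustered on their binary vaginal
orthologous gene (VOG) profiles: Jaccard distances, Ward agglomeration
(Lance-Williams update applied directly to the distance matrix), hybrid
dynamic tree cut with a joint sweep of ``min_cluster_size`` (10..20) and
``deep_split`` (0..4) choosing the labeling with the best average
silhouette width. The chosen clustering is then validated against
randomized tables in which 10% of presence/absence cells are bit-flipped:
if the observed silhouette does not strictly exceed every randomized
silhouette, the dendrogram is re-cut at k-1 flat clusters, repeatedly,
until it does or k reaches 2 (a floor; a species still failing at k=2 is
flagged ``weak_structure`` rather than collapsed).

Randomness is controlled by a master seed; each species derives its own
stream by hashing the species name, so adding a species never perturbs the
others.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import silhouette_score

from .treecut import cut_tree_hybrid, flat_cut

DEFAULT_MIN_CLUSTER_SIZE_RANGE = (10, 20)
DEFAULT_DEEP_SPLIT_RANGE = (0, 4)
DEFAULT_N_RANDOM = 10
DEFAULT_RANDOM_FRACTION = 0.10


def jaccard_distances(profiles: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Pairwise Jaccard distances between rows of a binary sample x VOG
    matrix: 1 - |A and B| / |A or B| over present-VOG sets; two empty sets
    are at distance 0."""
    X = np.asarray(profiles, dtype=bool)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    # scipy's boolean jaccard defines d(empty, empty) = 0, as required
    return squareform(pdist(X, metric="jaccard"))


def ward_linkage(dist: np.ndarray) -> np.ndarray:
    """Ward agglomeration on a (possibly non-Euclidean) distance matrix."""
    dist = np.asarray(dist, dtype=float)
    if dist.ndim == 2:
        n = dist.shape[0]
        condensed = squareform(dist, checks=False)
    else:
        condensed = dist
        n = int((1 + np.sqrt(1 + 8 * len(dist))) / 2)
    if n < 2:
        raise ValueError("need at least 2 samples")
    return scipy_linkage(condensed, method="ward")


def dynamic_cut(
    linkage: np.ndarray,
    dist: np.ndarray,
    min_cluster_size: int = 10,
    deep_split: int = 2,
) -> np.ndarray:
    """Hybrid dynamic tree cut labels (1..k) for the leaves of ``linkage``."""
    return cut_tree_hybrid(linkage, dist, min_cluster_size, deep_split)


def average_silhouette(dist: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width on a precomputed distance matrix; singleton
    clusters contribute 0; defined only for 2 <= k <= n-1."""
    labels = np.asarray(labels)
    k = len(np.unique(labels))
    if k < 2 or k >= len(labels):
        raise ValueError("silhouette needs 2 <= k <= n-1")
    return float(silhouette_score(np.asarray(dist), labels, metric="precomputed"))


def sweep_parameters(
    linkage: np.ndarray,
    dist: np.ndarray,
    min_cluster_size_range: tuple[int, int] = DEFAULT_MIN_CLUSTER_SIZE_RANGE,
    deep_split_range: tuple[int, int] = DEFAULT_DEEP_SPLIT_RANGE,
) -> tuple[np.ndarray, tuple[int, int], float]:
    """Joint grid search over (min_cluster_size, deep_split).

    Returns the labeling maximizing average silhouette width on ``dist``;
    ties go to the lexicographically lowest grid point. Labelings with a
    single cluster score -inf; if every grid point collapses to one
    cluster, that k=1 labeling is returned with silhouette 0.0.
    """
    dist = np.asarray(dist, dtype=float)
    best = None  # (score, params, labels)
    fallback = None
    for mcs in range(min_cluster_size_range[0], min_cluster_size_range[1] + 1):
        for ds in range(deep_split_range[0], deep_split_range[1] + 1):
            labels = dynamic_cut(linkage, dist, mcs, ds)
            k = len(np.unique(labels))
            if k < 2 or k >= len(labels):
                if fallback is None:
                    fallback = (labels, (mcs, ds))
                continue
            score = average_silhouette(dist, labels)
            if best is None or score > best[0]:
                best = (score, (mcs, ds), labels)
    if best is None:
        labels, params = fallback
        return labels, params, 0.0
    score, params, labels = best
    return labels, params, score


def randomize_table(
    pa: pd.DataFrame, fraction: float = DEFAULT_RANDOM_FRACTION, seed=None
) -> pd.DataFrame:
    """Bit-flip exactly round(fraction * n_cells) distinct cells, chosen
    uniformly without replacement; reproducible given ``seed``."""
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    values = pa.to_numpy().copy()
    n_cells = values.size
    n_flip = int(round(fraction * n_cells))
    if n_flip:
        flat = rng.choice(n_cells, size=n_flip, replace=False)
        rows, cols = np.unravel_index(flat, values.shape)
        values[rows, cols] = 1 - values[rows, cols]
    return pd.DataFrame(values, index=pa.index, columns=pa.columns)


def species_seed(master_seed: int, species: str) -> int:
    """Stable per-species RNG seed below 2^31, derived from the master seed
    and a hash of the species name."""
    digest = hashlib.blake2b(
        f"{master_seed}:{species}".encode(), digest_size=4
    ).digest()
    return int.from_bytes(digest, "big") % (2**31)


class SubspeciesClusterer(ClusterMixin, BaseEstimator):
    """Cluster samples into metagenomic subspecies from binary VOG profiles.

    scikit-learn-style estimator: ``fit(X)`` takes a samples x VOGs binary
    matrix (array or DataFrame). The fitted attributes record the full
    derivation: chosen cut parameters, the Ward dendrogram, observed and
    randomized-table silhouettes, and the validated labels (1..k).

    Parameters
    ----------
    min_cluster_size_range, deep_split_range : (low, high) inclusive
        Grid swept by average silhouette width.
    n_random : int
        Number of randomized tables for the validation stage.
    random_fraction : float
        Fraction of cells bit-flipped per randomized table.
    random_state : int or None
        Seed for the randomization streams.
    validate : bool
        Skip the randomized-table stage when False.
    """

    def __init__(
        self,
        min_cluster_size_range=DEFAULT_MIN_CLUSTER_SIZE_RANGE,
        deep_split_range=DEFAULT_DEEP_SPLIT_RANGE,
        n_random=DEFAULT_N_RANDOM,
        random_fraction=DEFAULT_RANDOM_FRACTION,
        random_state=None,
        validate=True,
    ):
        self.min_cluster_size_range = min_cluster_size_range
        self.deep_split_range = deep_split_range
        self.n_random = n_random
        self.random_fraction = random_fraction
        self.random_state = random_state
        self.validate = validate

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 samples to derive subspecies")
        dist = jaccard_distances(X)
        Z = ward_linkage(dist)
        labels, params, score = sweep_parameters(
            Z, dist, tuple(self.min_cluster_size_range), tuple(self.deep_split_range)
        )
        self.linkage_ = Z
        self.distances_ = dist
        self.params_ = {"min_cluster_size": params[0], "deep_split": params[1]}
        self.randomized_silhouettes_ = []
        self.weak_structure_ = False
        self.reduced_ = False

        if self.validate and self.n_random >= 1:
            rng = np.random.default_rng(self.random_state)
            child_seeds = rng.integers(0, 2**31, size=self.n_random)
            for child in child_seeds:
                rand = randomize_table(X, self.random_fraction, int(child))
                rdist = jaccard_distances(rand)
                rZ = ward_linkage(rdist)
                _, _, rscore = sweep_parameters(
                    rZ,
                    rdist,
                    tuple(self.min_cluster_size_range),
                    tuple(self.deep_split_range),
                )
                self.randomized_silhouettes_.append(rscore)
            threshold = max(self.randomized_silhouettes_)
            k = len(np.unique(labels))
            while score <= threshold and k > 2:
                k -= 1
                labels = flat_cut(Z, k)
                if len(np.unique(labels)) < 2:
                    break
                score = average_silhouette(dist, labels)
                self.reduced_ = True
            if score <= threshold:
                self.weak_structure_ = True
                warnings.warn(
                    "observed silhouette does not exceed randomized tables at "
                    "the k=2 floor; subspecies structure is weak",
                    stacklevel=2,
                )
        self.labels_ = np.asarray(labels)
        self.k_ = int(len(np.unique(self.labels_)))
        self.silhouette_ = float(score)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


@dataclass
class MgssModel:
    """Per-species subspecies clustering result."""

    species: str
    k: int
    labels: pd.Series  # eligible sample -> mgSs index (1..k)
    params: dict
    observed_silhouette: float
    randomized_silhouettes: list[float]
    linkage: np.ndarray
    seed: int
    weak_structure: bool = False
    vog_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "kind": "mgss",
            "species": self.species,
            "k": self.k,
            "labels": pd.Series(self.labels, dtype=int),
            "params": self.params,
            "observed_silhouette": self.observed_silhouette,
            "randomized_silhouettes": list(map(float, self.randomized_silhouettes)),
            "linkage": np.asarray(self.linkage),
            "seed": self.seed,
            "weak_structure": self.weak_structure,
            "vog_ids": list(self.vog_ids),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "MgssModel":
        return cls(
            species=payload["species"],
            k=int(payload["k"]),
            labels=pd.Series(payload["labels"], dtype=int),
            params=dict(payload["params"]),
            observed_silhouette=float(payload["observed_silhouette"]),
            randomized_silhouettes=list(payload["randomized_silhouettes"]),
            linkage=np.asarray(payload["linkage"], dtype=float),
            seed=int(payload["seed"]),
            weak_structure=bool(payload["weak_structure"]),
            vog_ids=list(payload["vog_ids"]),
        )


def validate_and_finalize(
    pa: pd.DataFrame,
    species: str,
    n_random: int = DEFAULT_N_RANDOM,
    fraction: float = DEFAULT_RANDOM_FRACTION,
    seed: int = 0,
    min_cluster_size_range=DEFAULT_MIN_CLUSTER_SIZE_RANGE,
    deep_split_range=DEFAULT_DEEP_SPLIT_RANGE,
) -> MgssModel:
    """Run the full derivation for one species.

    ``pa`` is the species' VOG x eligible-sample presence/absence table
    (the on-disk orientation); samples are the clustering units.
    """
    if pa.shape[1] < 2:
        raise ValueError(f"{species}: fewer than 2 eligible samples")
    sp_seed = species_seed(seed, species)
    est = SubspeciesClusterer(
        min_cluster_size_range=min_cluster_size_range,
        deep_split_range=deep_split_range,
        n_random=n_random,
        random_fraction=fraction,
        random_state=sp_seed,
    ).fit(pa.T)
    return MgssModel(
        species=species,
        k=est.k_,
        labels=pd.Series(est.labels_, index=pa.columns, dtype=int),
        params=est.params_,
        observed_silhouette=est.silhouette_,
        randomized_silhouettes=est.randomized_silhouettes_,
        linkage=est.linkage_,
        seed=sp_seed,
        weak_structure=est.weak_structure_,
        vog_ids=list(pa.index),
    )
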