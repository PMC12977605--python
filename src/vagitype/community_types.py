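"""Metagenomic community state types (mgCSTs).

Samples are described by the relative abundance of taxonomic units: a
species that qualified for subspecies analysis contributes one
``species::mgSs_j`` unit per sample (or ``species::mgSs_0`` when detected
below the genome-coverage bar), other species contribute species-level
units. The abundance basis is mapped-read mass per species, renormalized
per sample. mgCSTs are Ward clusters of between-sample Bray-Curtis
dissimilarities, cut with the hybrid dynamic tree cut at deep_split=4 and
the silhouette-optimal min_cluster_size in 10..20; each mgCST is summarized
by a centroid of mean unit relative abundances.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .presence import ABSENT, ELIGIBLE, MGSS0, EligibilityMask
from .subspecies import MgssModel, sweep_parameters, ward_linkage


def unit_name(species: str, mgss: int | None = None) -> str:
    if mgss is None:
        return species
    return f"{species}::mgSs_{mgss}"


def build_composition(
    counts: pd.DataFrame,
    annotation: pd.DataFrame,
    mgss_models: dict[str, MgssModel],
    mask: EligibilityMask,
) -> pd.DataFrame:
    """Samples x unit relative-abundance table.

    Per sample, read counts are summed per species; mass of a candidate
    species is relabeled to its assigned mgSs unit where the sample is
    eligible, to ``species::mgSs_0`` where the species is detected below
    the genome-coverage bar, and dropped entirely where no ortholog of the
    species is present (state "absent" — such reads are excluded before
    normalization). Rows sum to 1.
    """
    ann = annotation.loc[annotation.index.intersection(counts.index)]
    species_mass = counts.groupby(ann["species"]).sum()  # species x samples
    samples = counts.columns
    rows: dict[str, dict[str, float]] = {s: {} for s in samples}
    for species in species_mass.index.astype(str):
        model = mgss_models.get(species)
        in_mask = species in mask.states.index
        for sample in samples:
            mass = float(species_mass.at[species, sample])
            if mass <= 0:
                continue
            state = mask.state(species, sample) if in_mask else MGSS0
            if state == ABSENT:
                continue  # reads map to genes below the presence threshold
            if model is not None and species in mask.candidates:
                if state == ELIGIBLE and sample in model.labels.index:
                    unit = unit_name(species, int(model.labels[sample]))
                else:
                    unit = unit_name(species, 0)
            else:
                unit = unit_name(species)
            rows[sample][unit] = rows[sample].get(unit, 0.0) + mass
    comp = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    comp = comp.reindex(index=samples)
    totals = comp.sum(axis=1)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"samples with zero attributable reads: {bad}")
    comp = comp.div(totals, axis=0)
    return comp.reindex(sorted(comp.columns), axis=1)


def shannon_diversity(comp_row: pd.Series, unit_subset=None) -> float:
    """Shannon diversity H = -sum p ln p over the selected units,
    renormalized to sum 1; zero-abundance units contribute 0."""
    if unit_subset is not None:
        if len(unit_subset) == 0:
            raise ValueError("empty unit subset")
        comp_row = comp_row.reindex(unit_subset, fill_value=0.0)
    p = np.asarray(comp_row, dtype=float)
    total = p.sum()
    if total <= 0:
        raise ValueError("subset has zero total abundance")
    p = p[p > 0] / total
    return float(-(p * np.log(p)).sum())


class CommunityTypeClusterer(ClusterMixin, BaseEstimator):
    """Derive mgCSTs from a samples x unit composition table.

    ``fit(X)`` clusters the samples (Ward on the chosen dissimilarity,
    hybrid dynamic tree cut) and records ``labels_`` (1..K), ``centroids_``
    (K x unit mean relative abundances, rows renormalized) and silhouette
    diagnostics. ``predict`` delegates to nearest-centroid assignment by
    Yue-Clayton theta (see :mod:`vagitype.classify`).
    """

    def __init__(
        self,
        metric: str = "braycurtis",
        deep_split: int = 4,
        min_cluster_size_range=(10, 20),
    ):
        self.metric = metric
        self.deep_split = deep_split
        self.min_cluster_size_range = min_cluster_size_range

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 samples")
        dist = squareform(pdist(X.to_numpy(dtype=float), metric=self.metric))
        Z = ward_linkage(dist)
        labels, params, score = sweep_parameters(
            Z,
            dist,
            tuple(self.min_cluster_size_range),
            (self.deep_split, self.deep_split),
        )
        self.linkage_ = Z
        self.labels_ = np.asarray(labels)
        self.k_ = int(len(np.unique(labels)))
        self.params_ = {"min_cluster_size": params[0], "deep_split": params[1]}
        self.silhouette_ = float(score)
        self.feature_names_in_ = np.asarray(X.columns)
        self.centroids_ = _centroids(X, self.labels_)
        return self

    def predict(self, X):
        from .classify import assign_mgcst_frame

        assignments = assign_mgcst_frame(pd.DataFrame(X), self.centroids_)
        return assignments["mgcst"].to_numpy()


def _centroids(comp: pd.DataFrame, labels: np.ndarray) -> pd.DataFrame:
    """Per-cluster mean unit relative abundances, rows renormalized to 1."""
    cent = comp.groupby(pd.Series(labels, index=comp.index)).mean()
    cent = cent.div(cent.sum(axis=1), axis=0)
    cent.index = cent.index.astype(int)
    return cent.sort_index()


class McgstModel:
    """Community-state-type model: labels, centroids and cut diagnostics."""

    def __init__(
        self,
        labels: pd.Series,
        centroids: pd.DataFrame,
        params: dict,
        silhouette: float,
    ):
        self.labels = pd.Series(labels, dtype=int)
        self.centroids = centroids
        self.params = dict(params)
        self.silhouette = float(silhouette)
        self.K = int(centroids.shape[0])

    def to_dict(self) -> dict:
        return {
            "kind": "mgcst",
            "labels": self.labels,
            "centroids": self.centroids,
            "params": self.params,
            "silhouette": self.silhouette,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "McgstModel":
        centroids = payload["centroids"]
        centroids.index = centroids.index.astype(int)
        return cls(
            labels=pd.Series(payload["labels"], dtype=int),
            centroids=centroids,
            params=dict(payload["params"]),
            silhouette=float(payload["silhouette"]),
        )

    def dominant_units(self) -> pd.Series:
        """Convenience: highest-mean unit per mgCST (reporting only)."""
        return self.centroids.idxmax(axis=1)


def derive_mgcst(
    comp: pd.DataFrame,
    metric: str = "braycurtis",
    deep_split: int = 4,
    min_cluster_size_range=(10, 20),
) -> McgstModel:
    """Cluster a composition table into mgCSTs and build centroids."""
    est = CommunityTypeClusterer(
        metric=metric,
        deep_split=deep_split,
        min_cluster_size_range=min_cluster_size_range,
    ).fit(comp)
    return McgstModel(
        labels=pd.Series(est.labels_, index=comp.index, dtype=int),
        centroids=est.centroids_,
        params=est.params_,
        silhouette=est.silhouette_,
    )
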