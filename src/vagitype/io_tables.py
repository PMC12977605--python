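"""Readers, validators and model (de)serialization.

Count tables follow the gene-catalog mapper dialect: plain TSV (optionally
gzip-compressed), first column the gene identifier, one column per sample,
integer mapped-read counts. Annotation inputs are three TSVs keyed by gene
identifier (gene length in bp, gene -> species taxon, gene -> vaginal
orthologous gene), plus a species -> expected protein-coding gene count
table used by the genome-coverage eligibility rule.

Derived models are stored as a JSON container (scalars, labels, parameters,
seeds) with TSV sidecars for matrices; the layout is versioned with a
schema string and round-trips exactly.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

SCHEMA_VERSION = "vagitype-model-1"

PathLike = Union[str, Path]


class ModelFormatError(ValueError):
    """Raised when a model file is corrupt or from an incompatible schema."""


def _open_text(path: PathLike):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_gene_table(path: PathLike) -> pd.DataFrame:
    """Read a genes x samples integer count table.

    Returns a DataFrame indexed by gene identifier with one integer column
    per sample. Duplicate gene rows, negative or non-integer counts are
    errors; a header-only file yields a valid 0-gene table.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"count table not found: {path}")
    with _open_text(path) as fh:
        table = pd.read_csv(fh, sep="\t", index_col=0, dtype=str)
    table.index = table.index.astype(str)
    table.index.name = None
    dup = table.index[table.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene identifiers: {sorted(set(dup))}")
    dup_s = table.columns[table.columns.duplicated()]
    if len(dup_s):
        raise ValueError(f"duplicate sample identifiers: {sorted(set(dup_s))}")
    if table.shape[0] == 0:
        return table.astype(np.int64)
    if table.isna().any().any():
        raise ValueError("ragged or missing cells in count table")
    try:
        numeric = table.astype(np.float64)
    except ValueError as exc:
        raise ValueError(f"non-numeric count cell: {exc}") from exc
    if (numeric < 0).any().any():
        raise ValueError("negative counts in table")
    if not np.array_equal(numeric.to_numpy(), np.floor(numeric.to_numpy())):
        raise ValueError("non-integer counts in table")
    return numeric.astype(np.int64)


def write_gene_table(table: pd.DataFrame, path: PathLike) -> None:
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "wt") as fh:
            table.to_csv(fh, sep="\t", index_label="Gene")
    else:
        table.to_csv(path, sep="\t", index_label="Gene")


def read_annotations(
    length_path: PathLike,
    taxa_path: PathLike,
    vog_path: PathLike,
    genome_size_path: PathLike,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join gene-level annotation files and build the species catalog.

    Parameters
    ----------
    length_path, taxa_path, vog_path
        Two-column TSVs (gene id, value) giving gene length in bp, species
        taxon and ortholog (VOG) identifier. Genes absent from the VOG file
        carry no ``vog_id`` and are excluded from ortholog rollups.
    genome_size_path
        Two-column TSV (species, expected protein-coding gene count).

    Returns
    -------
    annotation : DataFrame indexed by gene id with columns
        ``length_bp``, ``species``, ``vog_id`` (NaN when unclustered).
    catalog : DataFrame indexed by species with column
        ``expected_gene_count``; per-species VOG sets are derivable from the
        annotation and exposed via :func:`species_vogs`.
    """
    lengths = _read_two_col(length_path, "length_bp")
    taxa = _read_two_col(taxa_path, "species")
    vogs = _read_two_col(vog_path, "vog_id")
    sizes = _read_two_col(genome_size_path, "expected_gene_count")

    lengths["length_bp"] = lengths["length_bp"].astype(np.int64)
    if (lengths["length_bp"] < 1).any():
        bad = lengths.index[lengths["length_bp"] < 1].tolist()
        raise ValueError(f"non-positive gene length for: {bad}")

    annotation = lengths.join(taxa, how="outer").join(vogs, how="outer")
    missing_len = annotation.index[annotation["length_bp"].isna()].tolist()
    if missing_len:
        raise ValueError(f"genes missing from length file: {missing_len}")
    annotation["length_bp"] = annotation["length_bp"].astype(np.int64)

    catalog = sizes.copy()
    catalog["expected_gene_count"] = catalog["expected_gene_count"].astype(np.int64)
    if (catalog["expected_gene_count"] < 1).any():
        raise ValueError("expected_gene_count must be >= 1")
    return annotation, catalog


def validate_annotation(counts: pd.DataFrame, annotation: pd.DataFrame) -> None:
    """Every gene in the count table must carry a length annotation."""
    missing = counts.index.difference(annotation.index).tolist()
    if missing:
        raise ValueError(f"genes missing annotation: {missing}")


def species_vogs(annotation: pd.DataFrame) -> dict[str, list[str]]:
    """Ordered, de-duplicated VOG list per species (unclustered genes skipped)."""
    ann = annotation.dropna(subset=["vog_id", "species"])
    out: dict[str, list[str]] = {}
    for species, sub in ann.groupby("species", sort=True):
        out[str(species)] = sorted(sub["vog_id"].unique())
    return out


def _read_two_col(path: PathLike, value_name: str) -> pd.DataFrame:
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", header=0)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns")
    df = df.iloc[:, :2]
    df.columns = ["gene_id", value_name]
    df["gene_id"] = df["gene_id"].astype(str)
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate keys {sorted(set(dup))}")
    return df.set_index("gene_id").rename_axis(index=None)


# ---------------------------------------------------------------------------
# Model serialization: JSON container + TSV sidecars for matrices.
# ---------------------------------------------------------------------------

_MATRIX_KEYS = ("linkage", "centroids", "distance")


def save_model(model: dict, path: PathLike) -> None:
    """Serialize a model dict; DataFrame/ndarray values go to TSV sidecars."""
    path = Path(path)
    payload = {"schema": SCHEMA_VERSION}
    sidecars = {}
    for key, value in model.items():
        if isinstance(value, pd.DataFrame):
            sidecars[key] = value
            payload[key] = {"__sidecar__": f"{path.name}.{key}.tsv", "kind": "frame"}
        elif isinstance(value, np.ndarray):
            sidecars[key] = pd.DataFrame(value)
            payload[key] = {"__sidecar__": f"{path.name}.{key}.tsv", "kind": "array"}
        elif isinstance(value, pd.Series):
            payload[key] = {"__series__": {str(k): _scalar(v) for k, v in value.items()}}
        else:
            payload[key] = _scalar(value)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=_scalar)
    for key, frame in sidecars.items():
        # %.17g round-trips IEEE doubles exactly
        frame.to_csv(path.parent / f"{path.name}.{key}.tsv", sep="\t", float_format="%.17g")


def load_model(path: PathLike) -> dict:
    path = Path(path)
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"corrupt model file {path}: {exc}") from exc
    if payload.get("schema") != SCHEMA_VERSION:
        raise ModelFormatError(
            f"model schema {payload.get('schema')!r} incompatible with {SCHEMA_VERSION!r}"
        )
    model = {}
    for key, value in payload.items():
        if key == "schema":
            continue
        if isinstance(value, dict) and "__sidecar__" in value:
            sidecar = path.parent / value["__sidecar__"]
            if not sidecar.exists():
                raise ModelFormatError(f"missing sidecar {sidecar}")
            frame = pd.read_csv(
                sidecar, sep="\t", index_col=0, float_precision="round_trip"
            )
            model[key] = frame.to_numpy() if value["kind"] == "array" else frame
        elif isinstance(value, dict) and "__series__" in value:
            model[key] = pd.Series(value["__series__"])
        else:
            model[key] = value
    return model


def _scalar(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (set, tuple)):
        return list(value)
    return value
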