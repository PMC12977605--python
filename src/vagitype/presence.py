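"""Coverage, gene and ortholog presence/absence, and species eligibility.

The chain mirrors standard gene-catalog processing of shotgun vaginal
metagenomes: samples with too few mapped reads are dropped, per-gene fold
coverage is estimated as ``reads * read_length / gene_length``, a coverage
threshold converts counts to binary gene presence, genes roll up to vaginal
orthologous genes (VOGs, present when at least one member gene is present),
and a species becomes a subspecies (mgSs) candidate when enough samples
carry enough of its expected protein-coding genes.

All threshold comparisons are inclusive (``>=``) so boundary behavior is
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_tables import validate_annotation

DEFAULT_MIN_READS = 100_000
DEFAULT_READ_LENGTH = 150
DEFAULT_PRESENCE_THRESHOLD = 0.5
DEFAULT_GENOME_FRACTION = 0.80
DEFAULT_MIN_ELIGIBLE_SAMPLES = 10

#: eligibility states per (species, sample)
ELIGIBLE = "eligible"
MGSS0 = "mgss0"
ABSENT = "absent"


def filter_samples(counts: pd.DataFrame, min_reads: int = DEFAULT_MIN_READS) -> pd.DataFrame:
    """Drop samples whose total mapped reads fall below ``min_reads``."""
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    if counts.shape[1] == 0:
        return counts
    keep = counts.sum(axis=0) >= min_reads
    if not keep.any():
        raise ValueError(
            f"all {counts.shape[1]} samples fall below min_reads={min_reads}; "
            "review the threshold"
        )
    return counts.loc[:, keep]


def gene_coverage(
    counts: pd.DataFrame,
    annotation: pd.DataFrame,
    read_length: int = DEFAULT_READ_LENGTH,
) -> pd.DataFrame:
    """Estimated fold coverage: ``counts * read_length / length_bp``."""
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    validate_annotation(counts, annotation)
    lengths = annotation.loc[counts.index, "length_bp"].to_numpy(dtype=float)
    return counts.astype(float).mul(read_length).div(lengths, axis=0)


def presence_absence(
    coverage: pd.DataFrame, threshold: float = DEFAULT_PRESENCE_THRESHOLD
) -> pd.DataFrame:
    """Binary gene x sample matrix: present iff coverage >= threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    return (coverage >= threshold).astype(np.int8)


def vog_rollup(
    gene_pa: pd.DataFrame, annotation: pd.DataFrame, species: str
) -> pd.DataFrame:
    """Per-species VOG x sample presence: a VOG is present in a sample iff
    at least one member gene is present there. Genes without a VOG
    annotation are excluded."""
    ann = annotation.loc[annotation.index.intersection(gene_pa.index)]
    ann = ann[(ann["species"] == species) & ann["vog_id"].notna()]
    if ann.empty:
        return pd.DataFrame(
            np.empty((0, gene_pa.shape[1]), dtype=np.int8), columns=gene_pa.columns
        )
    sub = gene_pa.loc[ann.index]
    rolled = sub.groupby(ann["vog_id"]).max().sort_index()
    return rolled.astype(np.int8)


def vog_rollup_all(
    gene_pa: pd.DataFrame, annotation: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """VOG presence tables for every species in the annotation."""
    out = {}
    for species in sorted(annotation["species"].dropna().unique()):
        table = vog_rollup(gene_pa, annotation, species)
        if table.shape[0]:
            out[str(species)] = table
    return out


@dataclass
class EligibilityMask:
    """Per-(species, sample) eligibility states and the candidate list.

    ``states`` is a species x sample DataFrame of {"eligible", "mgss0",
    "absent"}; ``candidates`` lists species eligible in at least the
    required number of samples, the only species for which subspecies are
    derived.
    """

    states: pd.DataFrame
    candidates: list[str] = field(default_factory=list)

    def state(self, species: str, sample: str) -> str:
        return self.states.at[species, sample]

    def eligible_samples(self, species: str) -> list[str]:
        row = self.states.loc[species]
        return list(row.index[row == ELIGIBLE])


def eligibility(
    gene_pa: pd.DataFrame,
    annotation: pd.DataFrame,
    catalog: pd.DataFrame,
    coverage_fraction: float = DEFAULT_GENOME_FRACTION,
    min_samples: int = DEFAULT_MIN_ELIGIBLE_SAMPLES,
) -> EligibilityMask:
    """Classify every (species, sample) pair.

    eligible : present genes / expected protein-coding genes >= fraction
    mgss0    : at least one VOG present but below the fraction
    absent   : no VOG of the species present
    """
    if not (0 < coverage_fraction <= 1):
        raise ValueError("coverage_fraction must be in (0, 1]")
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    species_list = sorted(catalog.index.astype(str))
    samples = gene_pa.columns
    states = pd.DataFrame(ABSENT, index=species_list, columns=samples, dtype=object)
    ann = annotation.loc[annotation.index.intersection(gene_pa.index)]
    for species in species_list:
        genes = ann.index[ann["species"] == species]
        expected = int(catalog.at[species, "expected_gene_count"])
        if len(genes) == 0:
            continue
        present_genes = gene_pa.loc[genes].sum(axis=0)
        vog_table = vog_rollup(gene_pa, annotation, species)
        any_vog = (
            vog_table.sum(axis=0) > 0
            if vog_table.shape[0]
            else pd.Series(False, index=samples)
        )
        frac = present_genes / expected
        states.loc[species] = np.where(
            frac >= coverage_fraction, ELIGIBLE, np.where(any_vog, MGSS0, ABSENT)
        )
    candidates = [
        sp for sp in species_list if int((states.loc[sp] == ELIGIBLE).sum()) >= min_samples
    ]
    return EligibilityMask(states=states, candidates=candidates)


def vog_richness(
    vog_tables: dict[str, pd.DataFrame], sample: str | None = None
) -> pd.Series | int:
    """Number of distinct (species, VOG) units present per sample.

    VOG units are species-scoped: the same ortholog family observed in two
    species counts once per species, matching the per-species tables.
    """
    totals: pd.Series | None = None
    for table in vog_tables.values():
        col = table.sum(axis=0)
        totals = col if totals is None else totals.add(col, fill_value=0)
    if totals is None:
        if sample is not None:
            return 0
        return pd.Series(dtype=np.int64)
    totals = totals.astype(np.int64)
    if sample is not None:
        return int(totals.get(sample, 0))
    return totals
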