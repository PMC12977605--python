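"""Metatranscriptome companion computations.

TPM normalization of transcript counts mapped to the gene catalog,
species-level activity summaries, expression of target orthologs relative
to the single-copy recA housekeeping gene, and two presence-based
comparisons used when contrasting subspecies: differentially present
orthologs between two sample groups and per-group prevalence of named VOG
clusters.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_MIN_TOTAL_READS = 30
DEFAULT_SPECIES_ZERO_FRACTION = 0.90
DEFAULT_TOP_N = 70
DEFAULT_RECA_VOG = "VOG0190358"


def filter_low_abundance(
    counts: pd.DataFrame, min_total: int = DEFAULT_MIN_TOTAL_READS
) -> pd.DataFrame:
    """Drop genes with fewer than ``min_total`` reads summed over samples
    (row sum >= min_total is kept)."""
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    if counts.shape[0] == 0:
        return counts
    return counts.loc[counts.sum(axis=1) >= min_total]


def tpm(counts: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Transcripts-per-million normalization using catalog gene lengths.

    rate[g,s] = counts / length_kb; TPM[g,s] = 1e6 * rate / sum_g rate.
    Columns sum to 1e6. A sample with zero mapped expression is an error.
    """
    missing = counts.index.difference(annotation.index).tolist()
    if missing:
        raise ValueError(f"genes missing length annotation: {missing}")
    lengths_kb = annotation.loc[counts.index, "length_bp"].to_numpy(dtype=float) / 1e3
    rate = counts.astype(float).div(lengths_kb, axis=0)
    totals = rate.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"samples with zero expression: {bad}")
    return rate.div(totals, axis=1) * 1e6


def species_activity(
    tpm_table: pd.DataFrame,
    annotation: pd.DataFrame,
    metagenome_species: set[str] | None = None,
    zero_fraction: float = DEFAULT_SPECIES_ZERO_FRACTION,
    top_n: int | None = None,
    log2: bool = False,
) -> pd.DataFrame:
    """Species x sample transcriptional activity.

    Gene TPM is summed within each species; a species is dropped when it is
    zero in at least ``zero_fraction`` of samples or absent from the
    matched metagenome (when ``metagenome_species`` is given). Optionally
    restrict to the ``top_n`` species by total expression and/or return
    log2(x+1)-transformed values.
    """
    ann = annotation.loc[annotation.index.intersection(tpm_table.index)]
    act = tpm_table.groupby(ann["species"]).sum()
    act = act.loc[sorted(act.index.astype(str))]
    if metagenome_species is not None:
        act = act.loc[[sp for sp in act.index if sp in metagenome_species]]
    if act.shape[1]:
        zero_frac = (act == 0).sum(axis=1) / act.shape[1]
        act = act.loc[zero_frac < zero_fraction]
    if top_n is not None:
        keep = act.sum(axis=1).sort_values(ascending=False).index[:top_n]
        act = act.loc[[sp for sp in act.index if sp in set(keep)]]
    if log2:
        act = np.log2(act + 1.0)
    return act


def reca_relative(
    tpm_table: pd.DataFrame,
    annotation: pd.DataFrame,
    target_vogs: list[str],
    reca_vog: str = DEFAULT_RECA_VOG,
) -> pd.Series:
    """Per-sample ratio of target-ortholog TPM to recA TPM.

    recA (single-copy housekeeping gene) normalizes expression across
    samples; where recA itself is unexpressed the ratio is undefined and
    reported as missing (NaN), never as 0.
    """
    ann = annotation.loc[annotation.index.intersection(tpm_table.index)]
    target_genes = ann.index[ann["vog_id"].isin(target_vogs)]
    reca_genes = ann.index[ann["vog_id"] == reca_vog]
    if len(reca_genes) == 0:
        raise ValueError(f"no genes annotated to recA ortholog {reca_vog}")
    target = tpm_table.loc[target_genes].sum(axis=0)
    reca = tpm_table.loc[reca_genes].sum(axis=0)
    ratio = target / reca
    ratio[reca <= 0] = np.nan
    return ratio


def differential_vogs(
    pa_group1: pd.DataFrame,
    pa_group2: pd.DataFrame,
    present_frac: float = 0.50,
    absent_frac: float = 0.75,
) -> dict[str, list[str]]:
    """Orthologs differentially present between two subspecies groups.

    A VOG is reported for group 1 iff its prevalence in group 1 is
    >= ``present_frac`` and its absence fraction in group 2 is strictly
    > ``absent_frac`` (and symmetrically for group 2). Inputs are VOG x
    sample binary tables over a shared VOG axis; each group needs >= 1
    sample. The two directional lists are disjoint by construction.
    """
    if pa_group1.shape[1] < 1 or pa_group2.shape[1] < 1:
        raise ValueError("both groups need at least one sample")
    vogs = pa_group1.index.union(pa_group2.index)
    prev1 = pa_group1.reindex(vogs, fill_value=0).mean(axis=1)
    prev2 = pa_group2.reindex(vogs, fill_value=0).mean(axis=1)
    in1 = (prev1 >= present_frac) & ((1.0 - prev2) > absent_frac)
    in2 = (prev2 >= present_frac) & ((1.0 - prev1) > absent_frac)
    return {
        "group1": sorted(vogs[in1]),
        "group2": sorted(vogs[in2]),
    }


def vog_cluster_prevalence(
    pa: pd.DataFrame,
    vog_clusters: dict[str, list[str]],
    sample_groups: pd.Series,
) -> pd.DataFrame:
    """Fraction of samples per group in which at least half of a VOG
    cluster's orthologs are present (inclusive at one half).

    Returns a cluster x group proportion table.
    """
    groups = sorted(sample_groups.unique())
    out = pd.DataFrame(0.0, index=sorted(vog_clusters), columns=groups)
    for name, members in vog_clusters.items():
        if len(members) == 0:
            raise ValueError(f"empty VOG cluster {name!r}")
        member_pa = pa.reindex(members, fill_value=0)
        carried = member_pa.mean(axis=0) >= 0.5
        for group in groups:
            in_group = sample_groups.index[sample_groups == group]
            cols = [s for s in in_group if s in carried.index]
            out.at[name, group] = float(carried[cols].mean()) if cols else np.nan
    return out
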