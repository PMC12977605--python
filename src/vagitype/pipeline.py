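"""End-to-end orchestration of the typing workflow.

Chains the stages: sample read filter -> coverage -> gene presence ->
per-species ortholog presence -> eligibility -> subspecies derivation for
candidate species -> composition table -> community state types. Used by
the command-line interface and kept importable so scripted analyses can
reuse intermediate results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import presence as pres
from .community_types import McgstModel, build_composition, derive_mgcst
from .subspecies import MgssModel, validate_and_finalize


@dataclass
class PipelineParams:
    min_reads: int = pres.DEFAULT_MIN_READS
    read_length: int = pres.DEFAULT_READ_LENGTH
    presence_threshold: float = pres.DEFAULT_PRESENCE_THRESHOLD
    genome_fraction: float = pres.DEFAULT_GENOME_FRACTION
    min_eligible_samples: int = pres.DEFAULT_MIN_ELIGIBLE_SAMPLES
    min_cluster_size_range: tuple[int, int] = (10, 20)
    deep_split_range: tuple[int, int] = (0, 4)
    n_random: int = 10
    random_fraction: float = 0.10
    mgcst_deep_split: int = 4
    mgcst_distance: str = "braycurtis"


@dataclass
class PipelineResult:
    gene_pa: pd.DataFrame
    vog_tables: dict[str, pd.DataFrame]
    mask: pres.EligibilityMask
    mgss_models: dict[str, MgssModel] = field(default_factory=dict)
    composition: pd.DataFrame | None = None
    mgcst: McgstModel | None = None


def run_presence(counts, annotation, catalog, params: PipelineParams) -> PipelineResult:
    counts = pres.filter_samples(counts, params.min_reads)
    cov = pres.gene_coverage(counts, annotation, params.read_length)
    gene_pa = pres.presence_absence(cov, params.presence_threshold)
    vog_tables = pres.vog_rollup_all(gene_pa, annotation)
    mask = pres.eligibility(
        gene_pa,
        annotation,
        catalog,
        params.genome_fraction,
        params.min_eligible_samples,
    )
    return PipelineResult(gene_pa=gene_pa, vog_tables=vog_tables, mask=mask)


def run_full(
    counts, annotation, catalog, seed: int = 0, params: PipelineParams | None = None
) -> PipelineResult:
    params = params or PipelineParams()
    result = run_presence(counts, annotation, catalog, params)
    for species in result.mask.candidates:
        eligible = result.mask.eligible_samples(species)
        table = result.vog_tables[species][eligible]
        result.mgss_models[species] = validate_and_finalize(
            table,
            species,
            n_random=params.n_random,
            fraction=params.random_fraction,
            seed=seed,
            min_cluster_size_range=params.min_cluster_size_range,
            deep_split_range=params.deep_split_range,
        )
    counts_kept = counts[result.gene_pa.columns]
    result.composition = build_composition(
        counts_kept, annotation, result.mgss_models, result.mask
    )
    result.mgcst = derive_mgcst(
        result.composition,
        metric=params.mgcst_distance,
        deep_split=params.mgcst_deep_split,
    )
    return result
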