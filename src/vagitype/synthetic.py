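"""Synthetic pangenomes and communities with planted ground truth.

The generator emulates the statistical structure the typing pipeline
assumes: per-species pangenomes with core orthologs shared by all
subspecies plus subspecies-specific accessory blocks, multi-species
communities drawn from a small set of template compositions (the planted
community state types), and read counts consistent with the coverage model
(reads allocated multinomially, proportional to species abundance times
gene length, so a species' expected read share equals its composition).

Every stage of the pipeline has its truth label here: the per-sample
template (planted mgCST), and the per-(species, sample) subspecies
(planted mgSs).

Accessory structure: with divergence d and A accessory orthologs, a
fraction 1-d is shared by all subspecies and the rest is split into k
equal blocks private to one subspecies, so the Jaccard distance between
two subspecies profiles is 2b / (n_core + shared + 2b) with
b = floor(d*A/k) — closed form used by the tests. d=0 makes subspecies
identical; d=1 with k=2 makes accessory blocks disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class SpeciesSpec:
    name: str
    k_subspecies: int
    n_core_vogs: int = 80
    n_accessory_vogs: int = 60
    accessory_divergence: float = 0.8
    genes_per_vog: int = 2
    gene_length_range: tuple[int, int] = (500, 1500)  # bacterial CDS scale

    def __post_init__(self):
        if self.k_subspecies < 1:
            raise ValueError("k_subspecies must be >= 1")
        if not (0.0 <= self.accessory_divergence <= 1.0):
            raise ValueError("accessory_divergence must be in [0, 1]")
        if self.k_subspecies > max(1, self.n_accessory_vogs):
            raise ValueError("more subspecies than accessory VOGs")


@dataclass
class TemplateSpec:
    name: str
    proportions: dict[str, float]  # species -> expected proportion
    subspecies: dict[str, int]  # species -> planted subspecies (1..k)

    def __post_init__(self):
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"template {self.name}: proportions sum to {total}")


@dataclass
class SyntheticSpec:
    species: list[SpeciesSpec]
    templates: list[TemplateSpec]
    n_samples_per_template: int = 30
    reads_per_sample: int = 400_000
    dirichlet_concentration: float = 100.0
    noise: float = 0.01  # per-(sample, species, VOG) presence flip rate
    read_length: int = 150


@dataclass
class Pangenome:
    species: str
    annotation: pd.DataFrame  # gene_id-indexed: length_bp, species, vog_id
    subspecies_vogs: dict[int, list[str]]  # 1..k -> ortholog ids in genome
    expected_gene_count: int
    vog_genes: dict[str, list[str]] = field(default_factory=dict)


def expected_subspecies_jaccard(spec: SpeciesSpec) -> float:
    """Closed-form Jaccard distance between any two subspecies profiles."""
    if spec.k_subspecies < 2:
        return 0.0
    shared = round((1.0 - spec.accessory_divergence) * spec.n_accessory_vogs)
    block = (spec.n_accessory_vogs - shared) // spec.k_subspecies
    common = spec.n_core_vogs + shared
    return 2 * block / (common + 2 * block) if (common + 2 * block) else 0.0


def generate_pangenome(spec: SpeciesSpec, rng: np.random.Generator) -> Pangenome:
    """Build one species' gene catalog and subspecies ortholog profiles."""
    n_vogs = spec.n_core_vogs + spec.n_accessory_vogs
    vog_ids = [f"VOG_{spec.name}_{i:04d}" for i in range(n_vogs)]
    core = vog_ids[: spec.n_core_vogs]
    accessory = vog_ids[spec.n_core_vogs :]
    shared_n = round((1.0 - spec.accessory_divergence) * spec.n_accessory_vogs)
    shared = accessory[:shared_n]
    block = (spec.n_accessory_vogs - shared_n) // spec.k_subspecies
    profiles: dict[int, list[str]] = {}
    for j in range(spec.k_subspecies):
        start = shared_n + j * block
        private = accessory[start : start + block]
        profiles[j + 1] = core + shared + private

    records = []
    vog_genes: dict[str, list[str]] = {}
    gi = 0
    lo, hi = spec.gene_length_range
    for vog in vog_ids:
        members = []
        for _ in range(spec.genes_per_vog):
            gene_id = f"{spec.name}_g{gi:05d}"
            gi += 1
            records.append(
                {
                    "gene_id": gene_id,
                    "length_bp": int(rng.integers(lo, hi + 1)),
                    "species": spec.name,
                    "vog_id": vog,
                }
            )
            members.append(gene_id)
        vog_genes[vog] = members
    annotation = pd.DataFrame(records).set_index("gene_id").rename_axis(index=None)
    expected = len(profiles[1]) * spec.genes_per_vog
    return Pangenome(
        species=spec.name,
        annotation=annotation,
        subspecies_vogs=profiles,
        expected_gene_count=expected,
        vog_genes=vog_genes,
    )


@dataclass
class SyntheticDataset:
    counts: pd.DataFrame  # genes x samples
    annotation: pd.DataFrame
    catalog: pd.DataFrame  # species -> expected_gene_count
    template_truth: pd.Series  # sample -> template name
    subspecies_truth: pd.DataFrame  # species x sample planted subspecies
    compositions: pd.DataFrame  # samples x species drawn proportions
    pangenomes: dict[str, Pangenome]

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.counts.to_csv(outdir / "counts.tsv", sep="\t", index_label="Gene")
        ann = self.annotation
        ann[["length_bp"]].to_csv(
            outdir / "gene_lengths.tsv", sep="\t", index_label="Gene"
        )
        ann[["species"]].to_csv(outdir / "taxa.tsv", sep="\t", index_label="Gene")
        ann.loc[ann["vog_id"].notna(), ["vog_id"]].to_csv(
            outdir / "vogs.tsv", sep="\t", index_label="Gene"
        )
        self.catalog.to_csv(outdir / "genome_sizes.tsv", sep="\t", index_label="Species")
        self.template_truth.rename("template").to_csv(
            outdir / "truth_templates.tsv", sep="\t", index_label="Sample"
        )
        self.subspecies_truth.to_csv(
            outdir / "truth_subspecies.tsv", sep="\t", index_label="Species"
        )


def generate_samples(spec: SyntheticSpec, seed: int = 0) -> SyntheticDataset:
    """Draw the full community dataset with truth labels.

    Per sample: composition from the template's Dirichlet
    (concentration * expected proportions); each present species
    contributes its planted subspecies' genes, with each ortholog's
    membership flipped at the noise rate; reads_per_sample reads are
    multinomially allocated with weight proportional to
    (species proportion) * (gene length / total present gene length of the
    species), so each species' expected read share equals its composition.
    """
    rng = np.random.default_rng(seed)
    pangenomes = {s.name: generate_pangenome(s, rng) for s in spec.species}
    annotation = pd.concat([p.annotation for p in pangenomes.values()])
    catalog = pd.DataFrame(
        {
            "expected_gene_count": {
                p.species: p.expected_gene_count for p in pangenomes.values()
            }
        }
    ).rename_axis(index=None)
    gene_index = annotation.index
    gene_pos = {g: i for i, g in enumerate(gene_index)}
    lengths = annotation["length_bp"].to_numpy(dtype=float)

    species_names = [s.name for s in spec.species]
    sample_ids, template_truth = [], []
    comp_rows = []
    counts = np.zeros((len(gene_index), 0), dtype=np.int64)
    columns = []
    sub_truth = pd.DataFrame(
        0, index=species_names, columns=[], dtype=int
    )

    sub_truth_cols = {}
    for template in spec.templates:
        props = np.array([template.proportions.get(sp, 0.0) for sp in species_names])
        alpha = spec.dirichlet_concentration * np.clip(props, 1e-12, None)
        for rep in range(spec.n_samples_per_template):
            sample_id = f"{template.name}_{rep:02d}"
            sample_ids.append(sample_id)
            template_truth.append(template.name)
            comp = rng.dirichlet(alpha)
            comp_rows.append(comp)
            weights = np.zeros(len(gene_index))
            truth_col = {}
            for sp, p_sp in zip(species_names, comp):
                pan = pangenomes[sp]
                ss = template.subspecies.get(sp, 1)
                truth_col[sp] = ss
                in_genome = set(pan.subspecies_vogs[ss])
                present_genes: list[str] = []
                for vog, members in pan.vog_genes.items():
                    member = vog in in_genome
                    if spec.noise > 0 and rng.random() < spec.noise:
                        member = not member
                    if member:
                        present_genes.extend(members)
                if not present_genes or p_sp <= 0:
                    continue
                idx = np.array([gene_pos[g] for g in present_genes])
                w = lengths[idx]
                weights[idx] = p_sp * w / w.sum()
            total = weights.sum()
            if total <= 0:
                raise ValueError(f"sample {sample_id}: no present genes")
            column = rng.multinomial(spec.reads_per_sample, weights / total)
            columns.append(column)
            sub_truth_cols[sample_id] = truth_col

    counts = pd.DataFrame(
        np.column_stack(columns).astype(np.int64), index=gene_index, columns=sample_ids
    )
    subspecies_truth = pd.DataFrame(sub_truth_cols).reindex(species_names)
    compositions = pd.DataFrame(comp_rows, index=sample_ids, columns=species_names)
    return SyntheticDataset(
        counts=counts,
        annotation=annotation,
        catalog=catalog,
        template_truth=pd.Series(template_truth, index=sample_ids, name="template"),
        subspecies_truth=subspecies_truth,
        compositions=compositions,
        pangenomes=pangenomes,
    )


def default_scenario() -> SyntheticSpec:
    """The shipped study scenario: six species with 2-4 subspecies each and
    four community templates (one Lactobacillus-like dominated, two
    polymicrobial, one intermediate), 30 samples per template."""
    species = [
        SpeciesSpec("Lcrispatus_like", k_subspecies=2),
        SpeciesSpec("Gvaginalis_like", k_subspecies=3),
        SpeciesSpec("Prevotella_like", k_subspecies=4),
        SpeciesSpec("Liners_like", k_subspecies=2),
        SpeciesSpec("Fvaginae_like", k_subspecies=3),
        SpeciesSpec("Sneathia_like", k_subspecies=2),
    ]
    names = [s.name for s in species]

    def template(name, props, subs):
        return TemplateSpec(
            name=name,
            proportions=dict(zip(names, props)),
            subspecies=dict(zip(names, subs)),
        )

    templates = [
        template("lacto_dom", [0.70, 0.06, 0.06, 0.06, 0.06, 0.06], [1, 1, 1, 1, 1, 2]),
        template("poly_a", [0.05, 0.30, 0.20, 0.15, 0.15, 0.15], [2, 2, 2, 1, 2, 1]),
        template("poly_b", [0.05, 0.10, 0.30, 0.10, 0.25, 0.20], [2, 3, 3, 2, 2, 2]),
        template("intermediate", [0.40, 0.20, 0.10, 0.10, 0.10, 0.10], [1, 3, 4, 2, 3, 1]),
    ]
    return SyntheticSpec(species=species, templates=templates)
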