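"""End-to-end convenience driver over a (simulated or loaded) study.

Runs normalization, per-species differential expression, pre-ranked GSEA
over one gene-set collection, and cross-species pathway classification, and
scores planted-label recovery when a ground truth is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .concordance import (
    AlignedGeneTable,
    CrossSpeciesGeneTable,
    PathwayConcordance,
    classify_genes,
    classify_pathways,
    map_to_reference,
    overlap_counts,
)
from .diffexp import DEGTable, call_degs
from .gsea import GseaResult, gsea_prerank, rank_genes
from .io import normalize_log1p_cp10k
from .simulate import SimulatedStudy


@dataclass
class PipelineResult:
    degs: dict[str, DEGTable]
    gsea: dict[str, GseaResult]
    aligned: AlignedGeneTable
    genes: CrossSpeciesGeneTable
    overlaps: pd.DataFrame
    pathways: PathwayConcordance


def run_study(
    study: SimulatedStudy,
    n_perm: int = 200,
    min_size: int = 5,
    statistic: str = "log2fc",
    seed: int = 0,
) -> PipelineResult:
    """DEG + GSEA + concordance over every species of a study."""
    cfg = study.config
    degs: dict[str, DEGTable] = {}
    gsea: dict[str, GseaResult] = {}
    for sp in cfg.species:
        norm = normalize_log1p_cp10k(study.matrices[sp])
        degs[sp] = call_degs(norm, study.annotations[sp], species=sp)
        ranked = rank_genes(degs[sp], statistic=statistic)
        gsea[sp] = gsea_prerank(
            ranked, study.gene_sets, n_perm=n_perm, min_size=min_size,
            seed=seed, species=sp,
        )
    aligned = map_to_reference(degs, study.orthologs, cfg.reference)
    genes = classify_genes(aligned)
    overlaps = overlap_counts(aligned)
    pathways = classify_pathways(gsea, cfg.reference)
    return PipelineResult(degs, gsea, aligned, genes, overlaps, pathways)


def pathway_recovery(result: PipelineResult, study: SimulatedStudy) -> float:
    """Fraction of planted pathways whose SM/DE label was recovered."""
    truth = {p["name"]: p["label"] for p in study.truth.pathways}
    if not truth:
        raise ValueError("study has no planted pathways")
    hits = sum(
        1 for name, label in truth.items()
        if result.pathways.label_of(name) == label
    )
    return hits / len(truth)
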