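"""Synthetic three-species young/old single-cell studies with planted truth.

The generator emulates the study design every downstream stage consumes:
per-species gene x cell count matrices over labeled cell types and age
groups, with known structure planted so recovery can be scored exactly.

* Counts are negative binomial on a log link: gene baselines are log-normal
  and each planted effect multiplies the mean.
* Concordant ("SM") pathways shift the old-group log-mean by +-delta with
  the same sign in every species; discordant ("DE") pathways flip the sign
  in exactly one species (default: monkey).
* Each regulon couples target genes to a TF: the target log-mean gains
  beta * centered log1p(TF count) per cell, in both age groups.
* Planted ligand-receptor pairs have both genes' log-means raised in old
  cells, so the old - young communication differential is positive.
* The PPI edge list wires planted-pathway genes densely against a sparse
  background, and the ortholog map shares symbols across species at a
  configurable fraction (plus a few many-to-many decoys so one-to-one
  filtering is exercised).

All randomness flows from one seed through a named generator per artifact,
so the same seed reproduces every file byte-for-byte and adding one
artifact does not shift another's stream.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    CellAnnotation,
    ExpressionMatrix,
    GeneSetCollection,
    GraphEdgeList,
    LigandReceptor,
    LigandReceptorDB,
    OrthologMap,
    write_annotations,
    write_edges,
    write_expression_mtx,
    write_gmt,
    write_lr_database,
    write_orthologs,
)


def _rng(seed: int, name: str) -> np.random.Generator:
    """Named child generator: independent stream per artifact."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(zlib.crc32(name.encode()),))
    )


@dataclass
class SimulationConfig:
    """Study-design knobs for the synthetic generator.

    ``cells_per_group`` is per (species, cell type, age group); ``delta`` is
    the old-group shift of planted pathway genes on the natural-log mean
    scale; ``beta`` the regulon coupling; ``lr_effect`` the old-group
    log-mean raise of planted ligand/receptor genes.
    """

    species: tuple[str, ...] = ("human", "monkey", "rat")
    reference: str = "human"
    genes_per_species: int = 2400
    ortholog_fraction: float = 0.8
    cell_types: tuple[str, ...] = ("EC", "FB", "IMM", "SMC")
    cells_per_group: int = 50
    dispersion: float = 2.0
    baseline_meanlog: float = 0.0
    baseline_sdlog: float = 1.0
    n_sm_pathways: int = 10
    n_de_pathways: int = 10
    genes_per_pathway: int = 50
    delta: float = 0.5
    discordant_species: str = "monkey"
    n_regulons: int = 4
    targets_per_regulon: int = 10
    beta: float = 1.0
    tf_mean: float = 3.0
    n_lr_pairs: int = 5
    lr_effect: float = 1.0
    ppi_within_p: float = 0.25
    ppi_background_p: float = 0.002
    n_many_to_many: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "genes_per_species": self.genes_per_species,
            "cells_per_group": self.cells_per_group,
            "dispersion": self.dispersion,
            "genes_per_pathway": self.genes_per_pathway,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if not (0 < self.ortholog_fraction <= 1):
            raise ValueError("ortholog_fraction must be in (0, 1]")
        for name in ("delta", "beta", "lr_effect"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.discordant_species not in self.species:
            raise ValueError("discordant_species must be one of the simulated species")
        if self.reference not in self.species:
            raise ValueError("reference must be one of the simulated species")
        n_shared = int(round(self.ortholog_fraction * self.genes_per_species))
        n_planted = (
            (self.n_sm_pathways + self.n_de_pathways) * self.genes_per_pathway
            + self.n_regulons * (1 + self.targets_per_regulon)
            + 2 * self.n_lr_pairs
        )
        if n_planted > n_shared:
            raise ValueError(
                f"{n_planted} planted genes exceed {n_shared} shared genes; "
                "increase genes_per_species or ortholog_fraction"
            )

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("species", "cell_types"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class GroundTruth:
    """Planted structure emitted alongside the data for recovery scoring."""

    pathways: list[dict]  # name, genes, label, signs {species: +-1}
    regulons: list[dict]  # tf, targets, beta_sign
    lr_pairs: list[dict]  # name, ligand, receptor, effect_sign

    def __post_init__(self) -> None:
        for p in self.pathways:
            signs = list(p["signs"].values())
            expected = "SM" if len(set(signs)) == 1 else "DE"
            if p["label"] != expected:
                raise ValueError(
                    f"pathway {p['name']}: label {p['label']} inconsistent with signs"
                )

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        data = json.loads(Path(path).read_text())
        return cls(**data)


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    matrices: dict[str, ExpressionMatrix]  # raw counts per species
    annotations: dict[str, CellAnnotation]
    gene_sets: GeneSetCollection
    orthologs: OrthologMap
    lrdb: LigandReceptorDB
    ppi: GraphEdgeList
    truth: GroundTruth

    @property
    def combined_annotation(self) -> CellAnnotation:
        return CellAnnotation(
            pd.concat([a.table for a in self.annotations.values()], ignore_index=True)
        )


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    p = theta / (theta + mean)
    return rng.negative_binomial(theta, p).astype(float)


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate the full three-species study plus its ground truth."""
    cfg = config
    n_shared = int(round(cfg.ortholog_fraction * cfg.genes_per_species))
    n_private = cfg.genes_per_species - n_shared
    shared = [f"G{i:05d}" for i in range(n_shared)]

    # --- assign planted roles among shared genes (deterministic layout) ---
    cursor = 0
    pathways: list[dict] = []
    n_pw = cfg.n_sm_pathways + cfg.n_de_pathways
    for p in range(n_pw):
        genes = shared[cursor : cursor + cfg.genes_per_pathway]
        cursor += cfg.genes_per_pathway
        base_sign = 1 if p % 2 == 0 else -1
        if p < cfg.n_sm_pathways:
            name = f"SM{p + 1:02d}"
            signs = {sp: base_sign for sp in cfg.species}
            label = "SM"
        else:
            name = f"DE{p - cfg.n_sm_pathways + 1:02d}"
            signs = {
                sp: (-base_sign if sp == cfg.discordant_species else base_sign)
                for sp in cfg.species
            }
            label = "DE"
        pathways.append({"name": name, "genes": genes, "label": label, "signs": signs})

    regulons: list[dict] = []
    for r in range(cfg.n_regulons):
        tf = shared[cursor]
        targets = shared[cursor + 1 : cursor + 1 + cfg.targets_per_regulon]
        cursor += 1 + cfg.targets_per_regulon
        regulons.append({"tf": tf, "targets": targets, "beta_sign": int(np.sign(cfg.beta)) or 1})

    lr_pairs: list[dict] = []
    for k in range(cfg.n_lr_pairs):
        ligand, receptor = shared[cursor], shared[cursor + 1]
        cursor += 2
        lr_pairs.append(
            {"name": f"LR{k + 1:02d}", "ligand": ligand, "receptor": receptor,
             "effect_sign": 1}
        )
    truth = GroundTruth(pathways, regulons, lr_pairs)

    pathway_sign: dict[str, dict[str, int]] = {}
    for p in pathways:
        for g in p["genes"]:
            pathway_sign[g] = p["signs"]
    tf_of_target = {t: r["tf"] for r in regulons for t in r["targets"]}
    tf_genes = {r["tf"] for r in regulons}
    lr_genes = {x["ligand"] for x in lr_pairs} | {x["receptor"] for x in lr_pairs}

    # --- per-species expression ---
    matrices: dict[str, ExpressionMatrix] = {}
    annotations: dict[str, CellAnnotation] = {}
    for sp in cfg.species:
        genes = shared + [f"{sp.upper()}_P{i:04d}" for i in range(n_private)]
        rng = _rng(cfg.seed, f"expression/{sp}")
        base = rng.lognormal(cfg.baseline_meanlog, cfg.baseline_sdlog, size=len(genes))
        for i, g in enumerate(genes):
            if g in tf_genes:
                base[i] = cfg.tf_mean
        cells, ann_rows = [], []
        ages = []
        for ct in cfg.cell_types:
            for age in ("young", "old"):
                for i in range(cfg.cells_per_group):
                    cid = f"{sp}_{ct}_{age}_{i:03d}"
                    cells.append(cid)
                    ages.append(age)
                    ann_rows.append(
                        {"cell_id": cid, "species": sp, "cell_type": ct, "age_group": age}
                    )
        old_mask = np.array([a == "old" for a in ages])
        n_cells = len(cells)

        log_mean = np.log(base)[:, None] * np.ones((1, n_cells))
        gene_index = {g: i for i, g in enumerate(genes)}
        for g, signs in pathway_sign.items():
            log_mean[gene_index[g], old_mask] += signs[sp] * cfg.delta
        for g in lr_genes:
            log_mean[gene_index[g], old_mask] += cfg.lr_effect

        # TF counts first, then targets coupled to the realized TF values
        counts = np.zeros((len(genes), n_cells))
        tf_rows = sorted(gene_index[t] for t in tf_genes)
        other_rows = [i for i in range(len(genes)) if i not in set(tf_rows)]
        if tf_rows:
            counts[tf_rows] = _nb_counts(
                rng, np.exp(log_mean[tf_rows]), cfg.dispersion
            )
        for tgt, tf in tf_of_target.items():
            tf_vals = np.log1p(counts[gene_index[tf]])
            centered = tf_vals - tf_vals.mean()
            log_mean[gene_index[tgt]] += cfg.beta * centered
        counts[other_rows] = _nb_counts(
            rng, np.exp(log_mean[other_rows]), cfg.dispersion
        )
        matrices[sp] = ExpressionMatrix(genes, cells, counts, normalized=False)
        annotations[sp] = CellAnnotation(pd.DataFrame(ann_rows))

    # --- gene sets (GMT) over planted pathways ---
    gene_sets = GeneSetCollection(
        {p["name"]: list(p["genes"]) for p in pathways},
        {p["name"]: f"planted {p['label']} pathway" for p in pathways},
    )

    # --- ortholog map: shared symbols across all species pairs + decoys ---
    orth_rows = []
    sp_list = list(cfg.species)
    for a_i in range(len(sp_list)):
        for b_i in range(a_i + 1, len(sp_list)):
            for g in shared:
                orth_rows.append(
                    {"species_a": sp_list[a_i], "gene_a": g,
                     "species_b": sp_list[b_i], "gene_b": g}
                )
    # many-to-many decoys among private genes (dropped by 1:1 filtering)
    if n_private > 0 and len(sp_list) >= 2:
        a_sp, b_sp = sp_list[0], sp_list[1]
        for d in range(min(cfg.n_many_to_many, n_private - 1)):
            orth_rows.append(
                {"species_a": a_sp, "gene_a": f"{a_sp.upper()}_P{d:04d}",
                 "species_b": b_sp, "gene_b": f"{b_sp.upper()}_P{d:04d}"}
            )
            orth_rows.append(
                {"species_a": a_sp, "gene_a": f"{a_sp.upper()}_P{d:04d}",
                 "species_b": b_sp, "gene_b": f"{b_sp.upper()}_P{d + 1:04d}"}
            )
    orthologs = OrthologMap(
        pd.DataFrame(orth_rows, columns=["species_a", "gene_a", "species_b", "gene_b"])
    )

    # --- ligand-receptor database over planted pairs ---
    lrdb = LigandReceptorDB(
        [
            LigandReceptor(
                name=x["name"], pathway=f"LRPATH{i + 1:02d}",
                ligand=[x["ligand"]], receptor=[x["receptor"]],
            )
            for i, x in enumerate(lr_pairs)
        ]
    )

    # --- PPI: dense within planted pathways, sparse background ---
    g_rng = _rng(cfg.seed, "graph")
    edges: list[tuple[str, str, float]] = []
    for p in pathways:
        genes_p = p["genes"]
        for i in range(len(genes_p)):
            for j in range(i + 1, len(genes_p)):
                if g_rng.random() < cfg.ppi_within_p:
                    edges.append((genes_p[i], genes_p[j], 1.0))
    planted = [g for p in pathways for g in p["genes"]]
    n_bg = int(cfg.ppi_background_p * len(shared) * (len(shared) - 1) / 2)
    if n_bg > 0 and len(shared) > 1:
        ii = g_rng.integers(0, len(shared), size=n_bg)
        jj = g_rng.integers(0, len(shared), size=n_bg)
        for a, b in zip(ii, jj):
            if a != b:
                edges.append((shared[a], shared[b], 1.0))
    ppi = GraphEdgeList(edges)

    return SimulatedStudy(cfg, matrices, annotations, gene_sets, orthologs, lrdb, ppi, truth)


FIXTURE_PRESETS: dict[str, dict] = {
    "tiny": dict(
        genes_per_species=50, cells_per_group=10, n_sm_pathways=1, n_de_pathways=1,
        genes_per_pathway=8, n_regulons=1, targets_per_regulon=4, n_lr_pairs=1,
        ortholog_fraction=0.8, n_many_to_many=2, delta=1.5, lr_effect=1.5,
    ),
    "small": dict(
        genes_per_species=600, cells_per_group=25, n_sm_pathways=4, n_de_pathways=4,
        genes_per_pathway=20, n_regulons=2, targets_per_regulon=6, n_lr_pairs=2,
    ),
    "default": dict(),
}


def fixture_config(size: str = "tiny", seed: int = 0) -> SimulationConfig:
    if size not in FIXTURE_PRESETS:
        raise ValueError(f"size must be one of {sorted(FIXTURE_PRESETS)}")
    return SimulationConfig(seed=seed, **FIXTURE_PRESETS[size])


def write_study(study: SimulatedStudy, out_dir) -> None:
    """Write every artifact in its interchange format plus ground_truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sp, m in study.matrices.items():
        write_expression_mtx(
            m, out / f"{sp}_matrix.mtx", out / f"{sp}_genes.tsv", out / f"{sp}_cells.tsv"
        )
        write_annotations(study.annotations[sp], out / f"{sp}_annotations.tsv")
    write_gmt(study.gene_sets, out / "gene_sets.gmt")
    write_orthologs(study.orthologs, out / "orthologs.tsv")
    write_lr_database(study.lrdb, out / "lr_database.tsv")
    write_edges(study.ppi, out / "ppi_edges.tsv")
    study.truth.to_json(out / "ground_truth.json")


def emit_fixture(size: str = "tiny", out_dir=None, seed: int = 0) -> SimulatedStudy:
    """Generate a preset-size study; optionally write it to ``out_dir``."""
    study = simulate_study(fixture_config(size, seed=seed))
    if out_dir is not None:
        write_study(study, out_dir)
    return study
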