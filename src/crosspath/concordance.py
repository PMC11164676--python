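"""Cross-species concordance of differential expression and pathways.

The core of the pipeline: differential-expression results from several
species are aligned to a reference species (typically human) through a
one-to-one ortholog map, overlapping differentially expressed genes are
labeled SM (same trend in every species) or DE (trend flips somewhere), and
gene sets are labeled SM/DE by whether their GSEA NES signs agree across
species.  A species is recommended as an animal model for a target pathway
exactly when its NES sign matches the reference sign — SM pathways admit
every model species, DE pathways only the concordant ones.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .diffexp import DEGTable
from .gsea import GseaResult
from .io import OrthologMap

logger = logging.getLogger(__name__)

GENE_LABELS = ("SM", "DE", "not_shared")


@dataclass
class AlignedGeneTable:
    """Per-reference-gene log2fc sign and DEG flag for every species.

    Columns: ``gene`` (reference symbols) plus ``sign_<sp>`` / ``deg_<sp>``
    per species; genes absent from a species carry sign 0 and flag False.
    """

    table: pd.DataFrame
    species: list[str]
    reference: str
    dropped_multi: dict[str, int] = field(default_factory=dict)


def map_to_reference(
    degs_by_species: dict[str, DEGTable],
    orthologs: OrthologMap,
    reference: str,
) -> AlignedGeneTable:
    """Align per-species DEG tables on reference gene ids via orthologs.

    Only one-to-one ortholog pairs are kept; genes with multiple partners
    are dropped and the count logged.  The row universe is the reference
    species' tested genes.
    """
    if reference not in degs_by_species:
        raise ValueError(f"reference species {reference!r} has no DEG table")
    species = sorted(degs_by_species)
    ref_table = degs_by_species[reference].table
    out = pd.DataFrame({"gene": ref_table["gene"]})
    out[f"sign_{reference}"] = np.sign(ref_table["log2fc"].to_numpy())
    out[f"deg_{reference}"] = ref_table["is_deg"].to_numpy()
    dropped: dict[str, int] = {}
    for sp in species:
        if sp == reference:
            continue
        pairs = orthologs.one_to_one(reference, sp)
        all_pairs = orthologs.table
        n_records = len(
            all_pairs[
                ((all_pairs["species_a"] == reference) & (all_pairs["species_b"] == sp))
                | ((all_pairs["species_a"] == sp) & (all_pairs["species_b"] == reference))
            ]
        )
        dropped[sp] = n_records - len(pairs)
        if dropped[sp]:
            logger.info("dropped %d non-one-to-one ortholog records for %s", dropped[sp], sp)
        t = degs_by_species[sp].table.set_index("gene")
        partner = out["gene"].map(pairs)
        found = partner.isin(t.index)
        sign = np.zeros(len(out))
        flag = np.zeros(len(out), dtype=bool)
        sign[found] = np.sign(t.loc[partner[found], "log2fc"].to_numpy())
        flag[found] = t.loc[partner[found], "is_deg"].to_numpy()
        out[f"sign_{sp}"] = sign
        out[f"deg_{sp}"] = flag
    return AlignedGeneTable(out, species, reference, dropped)


def overlap_counts(aligned: AlignedGeneTable) -> pd.DataFrame:
    """Venn-style DEG overlap counts for every species subset.

    A reference gene counts toward a subset when it is a DEG in each of the
    subset's species; percentages are relative to the reference species'
    DEG count.
    """
    t = aligned.table
    ref_deg = int(t[f"deg_{aligned.reference}"].sum())
    rows = []
    for r in range(1, len(aligned.species) + 1):
        for combo in itertools.combinations(aligned.species, r):
            mask = np.ones(len(t), dtype=bool)
            for sp in combo:
                mask &= t[f"deg_{sp}"].to_numpy()
            count = int(mask.sum())
            pct = 100.0 * count / ref_deg if ref_deg else np.nan
            rows.append(
                {
                    "species_subset": "+".join(combo),
                    "n_species": r,
                    "count": count,
                    "pct_of_reference_degs": pct,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class CrossSpeciesGeneTable:
    """Aligned gene table plus the SM/DE/not_shared label per gene."""

    table: pd.DataFrame
    species: list[str]
    reference: str

    def genes_with_label(self, label: str) -> list[str]:
        return list(self.table.loc[self.table["label"] == label, "gene"])


def classify_genes(aligned: AlignedGeneTable) -> CrossSpeciesGeneTable:
    """Label each reference gene SM / DE / not_shared.

    SM: DEG in every compared species with identical fold-change signs.
    DE: DEG in every species but signs disagree.  Everything else is
    not_shared.
    """
    t = aligned.table.copy()
    deg_cols = [f"deg_{sp}" for sp in aligned.species]
    sign_cols = [f"sign_{sp}" for sp in aligned.species]
    all_deg = t[deg_cols].all(axis=1).to_numpy()
    signs = t[sign_cols].to_numpy()
    same_sign = np.all(signs == signs[:, [0]], axis=1) & np.all(signs != 0, axis=1)
    label = np.where(all_deg & same_sign, "SM", np.where(all_deg, "DE", "not_shared"))
    t["label"] = label
    return CrossSpeciesGeneTable(t, aligned.species, aligned.reference)


@dataclass
class PathwayConcordance:
    """Per-set NES and sign for every species plus the SM/DE label."""

    table: pd.DataFrame
    species: list[str]
    reference: str

    def label_of(self, gene_set: str) -> str:
        row = self.table[self.table["gene_set"] == gene_set]
        if row.empty:
            raise KeyError(gene_set)
        return str(row["label"].iloc[0])


def classify_pathways(
    gsea_by_species: dict[str, GseaResult], reference: str
) -> PathwayConcordance:
    """Label each gene set SM or DE from the per-species NES signs.

    SM: the set is scored (not skipped, NES nonzero and finite) in every
    species and all NES signs agree; DE: scored everywhere but signs
    disagree; not_shared: skipped or unscored in at least one species.
    All species must have been run over the same collection.
    """
    if reference not in gsea_by_species:
        raise ValueError(f"reference species {reference!r} has no GSEA table")
    species = sorted(gsea_by_species)
    universes = {sp: list(r.table["gene_set"]) for sp, r in gsea_by_species.items()}
    ref_universe = universes[reference]
    for sp, u in universes.items():
        if sorted(u) != sorted(ref_universe):
            raise ValueError(
                f"species {sp!r} was scored over a different gene-set collection"
            )
    rows = []
    for gene_set in ref_universe:
        rec: dict = {"gene_set": gene_set}
        signs = []
        valid = True
        for sp in species:
            nes = gsea_by_species[sp].nes_of(gene_set)
            rec[f"nes_{sp}"] = nes
            if not np.isfinite(nes) or nes == 0:
                valid = False
                rec[f"sign_{sp}"] = ""
            else:
                rec[f"sign_{sp}"] = "+" if nes > 0 else "-"
                signs.append(np.sign(nes))
        if not valid:
            rec["label"] = "not_shared"
        elif all(s == signs[0] for s in signs):
            rec["label"] = "SM"
        else:
            rec["label"] = "DE"
        rows.append(rec)
    return PathwayConcordance(pd.DataFrame(rows), species, reference)


def recommend_models(
    pc: PathwayConcordance, target_pathway: str
) -> tuple[list[str], list[str]]:
    """Model species suitable for a drug targeting ``target_pathway``.

    A species is recommended exactly when its NES sign equals the reference
    sign for that pathway: for an SM pathway every model species qualifies;
    for a DE pathway only the concordant ones do.  Returns (recommended
    species, rationale strings).
    """
    t = pc.table
    row = t[t["gene_set"] == target_pathway]
    if row.empty:
        near = [
            s for s in t["gene_set"]
            if target_pathway.lower() in str(s).lower() or str(s).lower() in target_pathway.lower()
        ]
        raise KeyError(
            f"pathway {target_pathway!r} not in concordance table; "
            f"near matches: {near[:5]}"
        )
    row = row.iloc[0]
    ref_sign = row[f"sign_{pc.reference}"]
    rationale = []
    recommended = []
    for sp in pc.species:
        if sp == pc.reference:
            continue
        sign = row[f"sign_{sp}"]
        if ref_sign and sign == ref_sign:
            recommended.append(sp)
            rationale.append(
                f"{sp}: NES sign {sign!r} matches {pc.reference} ({ref_sign!r}) "
                f"for {target_pathway!r} -> suitable model"
            )
        else:
            rationale.append(
                f"{sp}: NES sign {sign!r} differs from {pc.reference} "
                f"({ref_sign!r}) for {target_pathway!r} -> use with caution"
            )
    if not recommended:
        rationale.append(
            f"warning: no model species matches the {pc.reference} NES sign for "
            f"{target_pathway!r}"
        )
    return recommended, rationale


def concordance_report(
    overlaps: pd.DataFrame,
    genes: CrossSpeciesGeneTable,
    pathways: PathwayConcordance | None = None,
    recommendations: dict[str, list[str]] | None = None,
) -> tuple[dict, str]:
    """Machine-readable (JSON-serializable dict) and Markdown report twins.

    Both carry exactly the same numbers: DEG overlap counts, SM/DE gene
    counts, the SM/DE pathway table, and any model recommendations.
    """
    label_counts = genes.table["label"].value_counts().to_dict()
    payload = {
        "reference": genes.reference,
        "species": genes.species,
        "overlap_counts": overlaps.to_dict(orient="records"),
        "gene_labels": {lab: int(label_counts.get(lab, 0)) for lab in GENE_LABELS},
        "pathways": (
            pathways.table.replace({np.nan: None}).to_dict(orient="records")
            if pathways is not None
            else []
        ),
        "recommendations": recommendations or {},
    }
    lines = [
        "# Cross-species concordance report",
        "",
        f"Reference species: {payload['reference']}",
        f"Species compared: {', '.join(payload['species'])}",
        "",
        "## DEG overlaps",
    ]
    if payload["overlap_counts"]:
        for rec in payload["overlap_counts"]:
            lines.append(
                f"- {rec['species_subset']}: {rec['count']} "
                f"({rec['pct_of_reference_degs']:.2f}% of reference DEGs)"
            )
    else:
        lines.append("- none")
    lines += ["", "## Gene labels"]
    for lab in GENE_LABELS:
        lines.append(f"- {lab}: {payload['gene_labels'][lab]}")
    lines += ["", "## Pathways"]
    if payload["pathways"]:
        for rec in payload["pathways"]:
            signs = ", ".join(
                f"{sp}={rec[f'sign_{sp}'] or '?'}" for sp in payload["species"]
            )
            lines.append(f"- {rec['gene_set']}: {rec['label']} ({signs})")
    else:
        lines.append("- none")
    lines += ["", "## Recommendations"]
    if payload["recommendations"]:
        for pw, specs in payload["recommendations"].items():
            lines.append(f"- {pw}: {', '.join(specs) if specs else 'no suitable model'}")
    else:
        lines.append("- none")
    return payload, "\n".join(lines) + "\n"


def write_report(payload: dict, markdown: str, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(json.dumps(payload, indent=2))
    (out_dir / "report.md").write_text(markdown)
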