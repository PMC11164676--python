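import json

import numpy as np
import pandas as pd
import pytest

from crosspath.concordance import (
    classify_genes,
    classify_pathways,
    concordance_report,
    map_to_reference,
    overlap_counts,
    recommend_models,
)
from crosspath.diffexp import DEGTable
from crosspath.gsea import GseaResult
from crosspath.io import OrthologMap


def deg_table(rows, species):
    genes = list(rows)
    return DEGTable(
        pd.DataFrame(
            {
                "gene": genes,
                "log2fc": [rows[g][0] for g in genes],
                "p_raw": 0.001,
                "p_adj": 0.01,
                "n_old": 10,
                "n_young": 10,
                "mean_old": 1.0,
                "mean_young": 1.0,
                "is_deg": [rows[g][1] for g in genes],
            }
        ),
        species=species,
    )


def identity_orthologs(genes, species):
    rows = []
    for i, a in enumerate(species):
        for b in species[i + 1:]:
            for g in genes:
                rows.append({"species_a": a, "gene_a": g, "species_b": b, "gene_b": g})
    return OrthologMap(pd.DataFrame(rows))


def gsea_table(nes: dict, species):
    names = list(nes)
    return GseaResult(
        pd.DataFrame(
            {
                "gene_set": names,
                "es": [np.sign(nes[s]) * 0.5 for s in names],
                "nes": [nes[s] for s in names],
                "p_nominal": 0.01,
                "sign": ["+" if nes[s] > 0 else "-" for s in names],
                "n_hits": 10,
                "leading_edge": "",
                "skipped": False,
                "skip_reason": "",
            }
        ),
        species=species,
    )


@pytest.fixture
def three_species_degs():
    # human: A up-DEG, B down-DEG, C up-DEG, D up (not DEG)
    h = deg_table({"A": (1.0, True), "B": (-1.0, True), "C": (0.5, True), "D": (0.4, False)}, "human")
    r = deg_table({"A": (0.8, True), "B": (-0.2, True), "C": (-0.5, True), "D": (0.4, True)}, "rat")
    m = deg_table({"A": (0.3, True), "B": (-0.9, True), "C": (0.2, False), "D": (0.4, True)}, "monkey")
    return {"human": h, "rat": r, "monkey": m}


class TestMapToReference:
    def test_identity_map_preserves_reference_rows(self, three_species_degs):
        orth = identity_orthologs(["A", "B", "C", "D"], ["human", "monkey", "rat"])
        aligned = map_to_reference(three_species_degs, orth, "human")
        assert list(aligned.table["gene"]) == ["A", "B", "C", "D"]
        assert aligned.reference == "human"

    def test_multi_partner_genes_dropped(self, three_species_degs):
        orth = identity_orthologs(["A", "B", "C", "D"], ["human", "monkey", "rat"])
        extra = pd.DataFrame(
            [{"species_a": "human", "gene_a": "A", "species_b": "rat", "gene_b": "A2"}]
        )
        orth = OrthologMap(pd.concat([orth.table, extra], ignore_index=True))
        aligned = map_to_reference(three_species_degs, orth, "human")
        # A now maps to two rat genes -> no rat signal for A
        row = aligned.table[aligned.table["gene"] == "A"].iloc[0]
        assert row["sign_rat"] == 0 and not row["deg_rat"]
        assert aligned.dropped_multi["rat"] == 2

    def test_missing_reference_rejected(self, three_species_degs):
        orth = identity_orthologs(["A"], ["human", "monkey", "rat"])
        with pytest.raises(ValueError, match="pig"):
            map_to_reference(three_species_degs, orth, "pig")


class TestOverlapCounts:
    def test_counts_and_reference_percentages(self, three_species_degs):
        orth = identity_orthologs(["A", "B", "C", "D"], ["human", "monkey", "rat"])
        aligned = map_to_reference(three_species_degs, orth, "human")
        counts = overlap_counts(aligned).set_index("species_subset")
        assert counts.loc["human", "count"] == 3
        assert counts.loc["human+rat", "count"] == 3  # A, B, C
        assert counts.loc["human+monkey", "count"] == 2  # A, B
        assert counts.loc["human+monkey+rat", "count"] == 2
        assert counts.loc["human+rat", "pct_of_reference_degs"] == pytest.approx(100.0)

    def test_subset_relation(self):
        h = deg_table({"A": (1.0, True), "B": (1.0, True)}, "human")
        r = deg_table({"A": (1.0, True), "B": (1.0, False)}, "rat")
        orth = identity_orthologs(["A", "B"], ["human", "rat"])
        aligned = map_to_reference({"human": h, "rat": r}, orth, "human")
        counts = overlap_counts(aligned).set_index("species_subset")
        assert counts.loc["human+rat", "count"] == counts.loc["rat", "count"] == 1

    def test_disjoint_degs_have_zero_overlap(self):
        h = deg_table({"A": (1.0, True), "B": (1.0, False)}, "human")
        r = deg_table({"A": (1.0, False), "B": (1.0, True)}, "rat")
        orth = identity_orthologs(["A", "B"], ["human", "rat"])
        aligned = map_to_reference({"human": h, "rat": r}, orth, "human")
        counts = overlap_counts(aligned).set_index("species_subset")
        assert counts.loc["human+rat", "count"] == 0


class TestClassifyGenes:
    def test_sign_patterns(self, three_species_degs):
        orth = identity_orthologs(["A", "B", "C", "D"], ["human", "monkey", "rat"])
        labeled = classify_genes(map_to_reference(three_species_degs, orth, "human"))
        by_gene = labeled.table.set_index("gene")["label"]
        assert by_gene["A"] == "SM"  # (+,+,+) DEG everywhere
        assert by_gene["B"] == "SM"  # (-,-,-)
        assert by_gene["C"] == "not_shared"  # not DEG in monkey
        assert by_gene["D"] == "not_shared"  # not DEG in human

    def test_discordant_sign_labeled_de(self):
        h = deg_table({"A": (1.0, True)}, "human")
        r = deg_table({"A": (-1.0, True)}, "rat")
        orth = identity_orthologs(["A"], ["human", "rat"])
        labeled = classify_genes(map_to_reference({"human": h, "rat": r}, orth, "human"))
        assert labeled.table["label"].iloc[0] == "DE"


class TestClassifyPathways:
    def test_consistent_negative_nes_is_sm(self):
        tables = {
            sp: gsea_table({"ECM": -1.5, "LIPID": 1.2 if sp != "monkey" else -0.8}, sp)
            for sp in ("human", "monkey", "rat")
        }
        pc = classify_pathways(tables, "human")
        assert pc.label_of("ECM") == "SM"
        assert pc.label_of("LIPID") == "DE"

    def test_identical_results_all_sm(self, rng):
        base = gsea_table({"P1": 1.0, "P2": -2.0}, "human")
        tables = {sp: gsea_table({"P1": 1.0, "P2": -2.0}, sp) for sp in ("human", "rat")}
        pc = classify_pathways(tables, "human")
        assert set(pc.table["label"]) == {"SM"}

    def test_skipped_set_becomes_not_shared(self):
        a = gsea_table({"P1": 1.0}, "human")
        b = gsea_table({"P1": 1.0}, "rat")
        b.table.loc[0, "skipped"] = True
        pc = classify_pathways({"human": a, "rat": b}, "human")
        assert pc.label_of("P1") == "not_shared"

    def test_mismatched_collections_rejected(self):
        a = gsea_table({"P1": 1.0}, "human")
        b = gsea_table({"P2": 1.0}, "rat")
        with pytest.raises(ValueError, match="different gene-set collection"):
            classify_pathways({"human": a, "rat": b}, "human")

    def test_labels_invariant_under_species_relabeling(self):
        nes = {"human": {"P": 1.0}, "rat": {"P": 1.0}, "monkey": {"P": -1.0}}
        pc1 = classify_pathways({sp: gsea_table(v, sp) for sp, v in nes.items()}, "human")
        swapped = {"human": nes["human"], "rat": nes["monkey"], "monkey": nes["rat"]}
        pc2 = classify_pathways({sp: gsea_table(v, sp) for sp, v in swapped.items()}, "human")
        assert pc1.label_of("P") == pc2.label_of("P") == "DE"


class TestRecommendModels:
    def make_pc(self, nes_by_species):
        return classify_pathways(
            {sp: gsea_table(v, sp) for sp, v in nes_by_species.items()}, "human"
        )

    def test_sm_pathway_recommends_all_models(self):
        pc = self.make_pc({sp: {"ECM": -1.0} for sp in ("human", "monkey", "rat")})
        recommended, rationale = recommend_models(pc, "ECM")
        assert recommended == ["monkey", "rat"]
        assert any("suitable model" in r for r in rationale)

    def test_de_pattern_recommends_only_concordant_species(self):
        pc = self.make_pc(
            {"human": {"LIPID": 1.0}, "rat": {"LIPID": 1.1}, "monkey": {"LIPID": -0.9}}
        )
        recommended, rationale = recommend_models(pc, "LIPID")
        assert recommended == ["rat"]
        assert any("monkey" in r and "caution" in r for r in rationale)

    def test_no_matching_species_warns(self):
        pc = self.make_pc({"human": {"P": 1.0}, "rat": {"P": -1.0}})
        recommended, rationale = recommend_models(pc, "P")
        assert recommended == []
        assert any("warning" in r for r in rationale)

    def test_unknown_pathway_lists_near_matches(self):
        pc = self.make_pc({"human": {"Lipid and atherosclerosis": 1.0},
                           "rat": {"Lipid and atherosclerosis": 1.0}})
        with pytest.raises(KeyError, match="Lipid"):
            recommend_models(pc, "Lipid")


class TestReport:
    def test_json_and_markdown_carry_same_numbers(self, three_species_degs, tmp_path):
        orth = identity_orthologs(["A", "B", "C", "D"], ["human", "monkey", "rat"])
        aligned = map_to_reference(three_species_degs, orth, "human")
        genes = classify_genes(aligned)
        overlaps = overlap_counts(aligned)
        tables = {sp: gsea_table({"ECM": -1.0}, sp) for sp in ("human", "monkey", "rat")}
        pc = classify_pathways(tables, "human")
        payload, md = concordance_report(overlaps, genes, pc, {"ECM": ["monkey", "rat"]})
        assert json.dumps(payload)  # JSON-serializable
        for lab, n in payload["gene_labels"].items():
            assert f"{lab}: {n}" in md
        assert "ECM: SM" in md
        assert "ECM: monkey, rat" in md

    def test_empty_pathway_section_explicit(self, three_species_degs):
        orth = identity_orthologs(["A"], ["human", "monkey", "rat"])
        aligned = map_to_reference(three_species_degs, orth, "human")
        payload, md = concordance_report(overlap_counts(aligned), classify_genes(aligned))
        assert payload["pathways"] == []
        assert "## Pathways\n- none" in md
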