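import numpy as np
import pandas as pd
import pytest

from crosspath.cellcomm import (
    build_networks,
    communication_probability,
    group_expression,
    ligand_activity,
    permutation_test,
    receptor_activity,
    trimean,
)
from crosspath.io import (
    CellAnnotation,
    ExpressionMatrix,
    LigandReceptor,
    LigandReceptorDB,
    normalize_log1p_cp10k,
)


class TestTrimean:
    def test_constant_vector(self):
        assert trimean([3.0] * 7) == 3.0

    def test_skewed_example_against_independent_quantiles(self):
        values = [0.0, 0.0, 0.0, 4.0]
        q1, q2, q3 = np.percentile(values, [25, 50, 75])
        assert trimean(values) == pytest.approx(0.5 * q2 + 0.25 * (q1 + q3))
        assert trimean(values) == pytest.approx(0.25)

    def test_symmetric_sample_equals_median(self, rng):
        x = rng.normal(size=101)
        sym = np.concatenate([x, -x])
        assert trimean(sym) == pytest.approx(np.median(sym), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            trimean([])


def two_group_study(values_by_gene, groups=("A", "B"), age="young"):
    """Matrix with one cell group per key of each gene's value list."""
    genes = list(values_by_gene)
    n_per = len(next(iter(values_by_gene.values()))[0])
    cells, rows = [], []
    for gi, g in enumerate(groups):
        for i in range(n_per):
            cid = f"{g}{i}"
            if cid not in cells:
                cells.append(cid)
                rows.append({"cell_id": cid, "species": "h", "cell_type": g,
                             "age_group": age})
    values = np.zeros((len(genes), len(cells)))
    for r, g in enumerate(genes):
        values[r] = np.concatenate(values_by_gene[g])
    m = ExpressionMatrix(genes, cells, values, normalized=True)
    return m, CellAnnotation(pd.DataFrame(rows))


class TestActivities:
    def make_em(self):
        m, ann = two_group_study(
            {
                "L1": ([1.0] * 4, [0.0] * 4),
                "L2": ([4.0] * 4, [1.0] * 4),
                "RA1": ([1.0] * 4, [0.0] * 4),
            }
        )
        return group_expression(m, ann, ["L1", "L2", "RA1"], age_group="young")

    def test_single_subunit_equals_trimean(self):
        em = self.make_em()
        assert ligand_activity(em, ["L1"], "A") == 1.0

    def test_zero_subunit_zeroes_complex(self):
        em = self.make_em()
        assert ligand_activity(em, ["L1", "L2"], "B") == 0.0

    def test_geometric_mean_of_subunits(self):
        em = self.make_em()
        assert ligand_activity(em, ["L1", "L2"], "A") == pytest.approx(2.0)

    def test_costimulatory_mean_one_doubles_receptor(self):
        em = self.make_em()
        base = receptor_activity(em, ["L1"], [], [], "A")
        boosted = receptor_activity(em, ["L1"], ["RA1"], [], "A")
        assert boosted == pytest.approx(2.0 * base)

    def test_missing_gene_counts_as_zero(self):
        em = self.make_em()
        assert ligand_activity(em, ["ABSENT"], "A") == 0.0


class TestCommunicationProbability:
    def test_zero_ligand_gives_zero(self):
        assert communication_probability(0.0, 5.0, n_i=3, n_j=3, n=6) == 0.0

    def test_half_saturation_point(self):
        # L*R = Kh, no modulators, unit proportions
        assert communication_probability(1.0, 0.5, n_i=1, n_j=1, n=1, Kh=0.5) == pytest.approx(0.5)

    def test_monotone_in_lr_ag_an(self):
        grid = np.linspace(0.1, 5.0, 10)
        p_lr = [communication_probability(v, 1.0, n_i=1, n_j=1, n=1) for v in grid]
        assert np.all(np.diff(p_lr) > 0)
        p_ag = [communication_probability(1.0, 1.0, AG_i=v, n_i=1, n_j=1, n=1) for v in grid]
        assert np.all(np.diff(p_ag) > 0)
        p_an = [communication_probability(1.0, 1.0, AN_i=v, n_i=1, n_j=1, n=1) for v in grid]
        assert np.all(np.diff(p_an) < 0)

    def test_hill_saturation_limit(self):
        p_small = communication_probability(1.0, 1.0, n_i=1, n_j=1, n=1)
        p_large = communication_probability(1e6, 1e6, n_i=1, n_j=1, n=1)
        assert p_small < 1.0
        assert p_large == pytest.approx(1.0, abs=1e-9)

    def test_invalid_kh_rejected(self):
        with pytest.raises(ValueError):
            communication_probability(1.0, 1.0, Kh=0.0)


def lr_db():
    return LigandReceptorDB([LigandReceptor("I1", "P1", ["LIG"], ["REC"])])


class TestBuildNetworks:
    def make_aging_study(self, old_boost=2.0):
        """Two cell types, both ages; LIG/REC higher in old cells."""
        rng = np.random.default_rng(1)
        genes = ["LIG", "REC", "OTHER"]
        cells, rows = [], []
        values = []
        for age, boost in (("young", 1.0), ("old", old_boost)):
            for ct in ("A", "B"):
                for i in range(10):
                    cid = f"{ct}_{age}_{i}"
                    cells.append(cid)
                    rows.append({"cell_id": cid, "species": "h", "cell_type": ct,
                                 "age_group": age})
                    values.append([boost, boost, 1.0])
        m = ExpressionMatrix(genes, cells, np.array(values).T, normalized=True)
        return m, CellAnnotation(pd.DataFrame(rows))

    def test_planted_lr_differential_positive(self):
        m, ann = self.make_aging_study()
        net = build_networks(m, ann, lr_db())
        assert (net.diff_strength.to_numpy() > 0).all()

    def test_identical_ages_give_zero_differential(self):
        m, ann = self.make_aging_study(old_boost=1.0)
        net = build_networks(m, ann, lr_db())
        assert np.allclose(net.diff_strength.to_numpy(), 0.0)
        assert np.allclose(net.diff_count.to_numpy(), 0.0)

    def test_planted_pair_recovered_on_tiny_fixture(self, tiny_study, tiny_normalized):
        study = tiny_study
        sp = "human"
        net = build_networks(tiny_normalized[sp], study.annotations[sp], study.lrdb)
        assert (net.diff_strength.to_numpy() > 0).any()
        assert net.diff_strength.to_numpy().sum() > 0

    def test_shuffling_cells_within_group_changes_nothing(self):
        m, ann = self.make_aging_study()
        rng = np.random.default_rng(0)
        perm = rng.permutation(m.n_cells)
        shuffled = ExpressionMatrix(
            list(m.gene_ids), [m.cell_ids[i] for i in perm], m.values[:, perm],
            normalized=True,
        )
        a = build_networks(m, ann, lr_db())
        b = build_networks(shuffled, ann, lr_db())
        pd.testing.assert_frame_equal(a.strength["old"], b.strength["old"])

    def test_small_group_flagged_low_confidence(self):
        m, ann = self.make_aging_study()
        keep = [c for c in m.cell_ids if not c.startswith("B_old")] + ["B_old_0"]
        sub_ann = CellAnnotation(ann.table[ann.table["cell_id"].isin(keep)])
        sub_m = m.subset_cells(keep)
        net = build_networks(sub_m, sub_ann, lr_db())
        assert "B" in net.low_confidence["old"]


class TestPermutationTest:
    def exchangeable_study(self):
        rng = np.random.default_rng(2)
        genes = ["LIG", "REC"]
        cells, rows = [], []
        for ct in ("A", "B"):
            for i in range(15):
                cid = f"{ct}{i}"
                cells.append(cid)
                rows.append({"cell_id": cid, "species": "h", "cell_type": ct,
                             "age_group": "old"})
        values = rng.gamma(2.0, 1.0, size=(2, len(cells)))
        m = ExpressionMatrix(genes, cells, values, normalized=True)
        return m, CellAnnotation(pd.DataFrame(rows))

    def test_deterministic_under_seed(self):
        m, ann = self.exchangeable_study()
        a = permutation_test(m, ann, lr_db(), "old", n_perm=20, seed=4)
        b = permutation_test(m, ann, lr_db(), "old", n_perm=20, seed=4)
        np.testing.assert_array_equal(a, b)

    def test_exchangeable_labels_give_moderate_p(self):
        m, ann = self.exchangeable_study()
        p = permutation_test(m, ann, lr_db(), "old", n_perm=50, seed=0)
        assert p.min() > 0.02  # nothing spuriously significant
        assert 0.2 < p.mean() < 0.9

    def test_too_few_permutations_rejected(self):
        m, ann = self.exchangeable_study()
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test(m, ann, lr_db(), "old", n_perm=5)
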