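"""Ligand-receptor cell-cell communication probabilities.

For every ordered pair of cell groups (sender i, receiver j) and every
ligand-receptor interaction k, the communication probability is

    p_ij^k = LR / (Kh + LR)
             * (1 + AG_i/(Kh + AG_i)) * (1 + AG_j/(Kh + AG_j))
             * Kh/(Kh + AN_i) * Kh/(Kh + AN_j)
             * n_i * n_j / n^2

where L and R are geometric means of ligand/receptor subunit group
expression, AG/AN are mean expressions of soluble agonist/antagonist gene
lists (their factors collapse to 1 when the list is empty), Kh is the Hill
half-saturation constant, and n_i/n_j/n are group and total cell counts.

Group-level expression is the Tukey trimean EM = Q2/2 + (Q1+Q3)/4, a robust
"ensemble average" that damps dropout noise.  Receptor activity is further
modulated by co-stimulatory (RA) and co-inhibitory (RI) receptor lists via
the factor (1 + RA_j) / (1 + RI_j).

Networks are built per age group over cell-type groups; the old - young
entrywise difference of the strength matrices is the aging differential.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AGE_GROUPS, CellAnnotation, ExpressionMatrix, LigandReceptor, LigandReceptorDB

logger = logging.getLogger(__name__)

DEFAULT_KH = 0.5

#: groups smaller than this are computed but flagged low-confidence
MIN_GROUP_CELLS = 3


def trimean(values) -> float:
    """Tukey trimean: Q2/2 + (Q1+Q3)/4 with linear-interpolation quartiles."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("trimean of empty input")
    q1, q2, q3 = np.quantile(values, [0.25, 0.5, 0.75], method="linear")
    return float(0.5 * q2 + 0.25 * (q1 + q3))


@dataclass
class GroupExpression:
    """Trimean expression per gene per cell group, plus group sizes."""

    groups: list[str]
    n_cells: dict[str, int]
    em: dict[str, dict[str, float]]  # group -> gene -> trimean
    low_confidence: set[str] = field(default_factory=set)

    @property
    def n_total(self) -> int:
        return sum(self.n_cells.values())

    def gene_em(self, group: str, gene: str) -> float:
        return self.em[group].get(gene, 0.0)

    def mean_em(self, group: str, genes) -> float:
        """Mean trimean over a gene list; 0 for an empty list."""
        genes = list(genes)
        if not genes:
            return 0.0
        return float(np.mean([self.gene_em(group, g) for g in genes]))

    def geometric_mean_em(self, group: str, genes) -> float:
        vals = np.array([self.gene_em(group, g) for g in genes], dtype=float)
        if np.any(vals == 0):
            return 0.0
        return float(np.exp(np.mean(np.log(vals))))


def group_expression(
    m: ExpressionMatrix,
    ann: CellAnnotation,
    genes,
    age_group: str | None = None,
    species: str | None = None,
) -> GroupExpression:
    """Trimean expression of ``genes`` within each cell-type group."""
    if not m.normalized:
        raise ValueError("group_expression requires a normalized matrix")
    t = ann.table
    if species is not None:
        t = t[t["species"] == species]
    if age_group is not None:
        t = t[t["age_group"] == age_group]
    t = t[t["cell_id"].isin(set(m.cell_ids))]
    genes = [g for g in dict.fromkeys(genes)]
    groups = sorted(t["cell_type"].unique())
    em: dict[str, dict[str, float]] = {}
    n_cells: dict[str, int] = {}
    low_conf: set[str] = set()
    for ct in groups:
        ids = list(t.loc[t["cell_type"] == ct, "cell_id"])
        n_cells[ct] = len(ids)
        if len(ids) < MIN_GROUP_CELLS:
            low_conf.add(ct)
            logger.warning("cell group %r has only %d cells", ct, len(ids))
        idx = [m._cell_index[c] for c in ids]
        sub = m.values[:, idx]
        em[ct] = {}
        for g in genes:
            gi = m._gene_index.get(g)
            em[ct][g] = trimean(sub[gi]) if gi is not None else 0.0
    return GroupExpression(groups, n_cells, em, low_conf)


def ligand_activity(em: GroupExpression, subunits, group: str) -> float:
    """Ligand activity L_i: geometric mean of subunit trimeans.

    A zero subunit zeroes the whole complex; genes absent from the matrix
    count as zero expression.
    """
    if not list(subunits):
        raise ValueError("ligand subunit list must be non-empty")
    return em.geometric_mean_em(group, subunits)


def receptor_activity(
    em: GroupExpression, subunits, co_stim, co_inhib, group: str
) -> float:
    """Receptor activity R_j: subunit geometric mean times (1+RA_j)/(1+RI_j)."""
    if not list(subunits):
        raise ValueError("receptor subunit list must be non-empty")
    base = em.geometric_mean_em(group, subunits)
    ra = em.mean_em(group, co_stim)
    ri = em.mean_em(group, co_inhib)
    return base * (1.0 + ra) / (1.0 + ri)


def communication_probability(
    L_i: float,
    R_j: float,
    AG_i: float = 0.0,
    AG_j: float = 0.0,
    AN_i: float = 0.0,
    AN_j: float = 0.0,
    n_i: int = 1,
    n_j: int = 1,
    n: int = 1,
    Kh: float = DEFAULT_KH,
    agonists_present: bool = True,
    antagonists_present: bool = True,
) -> float:
    """Hill-saturated communication probability for one (i, j, k) triple.

    When the agonist/antagonist gene list is empty the corresponding factors
    are the identity (set ``*_present=False``); passing mean expression 0
    gives the same result, so the flags only document intent.
    """
    if Kh <= 0:
        raise ValueError("Kh must be positive")
    if min(L_i, R_j, AG_i, AG_j, AN_i, AN_j) < 0:
        raise ValueError("activities must be non-negative")
    if not (1 <= n_i <= n and 1 <= n_j <= n):
        raise ValueError("need 1 <= n_i, n_j <= n")
    lr = L_i * R_j
    p = lr / (Kh + lr)
    if agonists_present:
        p *= (1.0 + AG_i / (Kh + AG_i)) * (1.0 + AG_j / (Kh + AG_j))
    if antagonists_present:
        p *= (Kh / (Kh + AN_i)) * (Kh / (Kh + AN_j))
    p *= (n_i * n_j) / (n * n)
    return float(p)


@dataclass
class CommProbability:
    """Probabilities p[i, j, k] over sender group, receiver group, interaction."""

    groups: list[str]
    interactions: list[str]
    pathways: dict[str, str]  # interaction -> pathway
    p: np.ndarray  # (K, K, N)
    low_confidence: set[str] = field(default_factory=set)

    def pathway_aggregate(self, pathway: str) -> np.ndarray:
        idx = [k for k, name in enumerate(self.interactions) if self.pathways[name] == pathway]
        return self.p[:, :, idx].sum(axis=2)


def interaction_probabilities(
    m: ExpressionMatrix,
    ann: CellAnnotation,
    lrdb: LigandReceptorDB,
    age_group: str,
    species: str | None = None,
    Kh: float = DEFAULT_KH,
) -> CommProbability:
    """All p[i, j, k] for one age group, cell types as groups."""
    genes_needed: list[str] = []
    for x in lrdb:
        genes_needed += x.ligand + x.receptor + x.agonist + x.antagonist
        genes_needed += x.co_stim + x.co_inhib
    em = group_expression(m, ann, genes_needed, age_group=age_group, species=species)
    groups = em.groups
    K = len(groups)
    n = em.n_total
    p = np.zeros((K, K, len(lrdb)))
    for k, x in enumerate(lrdb):
        L = {g: ligand_activity(em, x.ligand, g) for g in groups}
        R = {g: receptor_activity(em, x.receptor, x.co_stim, x.co_inhib, g) for g in groups}
        AG = {g: em.mean_em(g, x.agonist) for g in groups}
        AN = {g: em.mean_em(g, x.antagonist) for g in groups}
        for a, gi in enumerate(groups):
            for b, gj in enumerate(groups):
                p[a, b, k] = communication_probability(
                    L[gi], R[gj], AG[gi], AG[gj], AN[gi], AN[gj],
                    n_i=em.n_cells[gi], n_j=em.n_cells[gj], n=n, Kh=Kh,
                    agonists_present=bool(x.agonist),
                    antagonists_present=bool(x.antagonist),
                )
    return CommProbability(
        groups, [x.name for x in lrdb], {x.name: x.pathway for x in lrdb},
        p, em.low_confidence,
    )


@dataclass
class CommNetwork:
    """Interaction count and strength matrices per age group + differential."""

    groups: list[str]
    count: dict[str, pd.DataFrame]  # age_group -> K x K
    strength: dict[str, pd.DataFrame]
    diff_count: pd.DataFrame  # old - young
    diff_strength: pd.DataFrame
    low_confidence: dict[str, set] = field(default_factory=dict)


def build_networks(
    m: ExpressionMatrix,
    ann: CellAnnotation,
    lrdb: LigandReceptorDB,
    species: str | None = None,
    Kh: float = DEFAULT_KH,
    n_perm: int = 0,
    p_threshold: float = 0.05,
    seed: int = 0,
) -> CommNetwork:
    """Old and young communication networks and their differential.

    A ligand-receptor pair contributes to a (sender, receiver) cell when its
    probability is positive (and, if ``n_perm`` > 0, its permutation p-value
    is at or below ``p_threshold``).
    """
    per_age: dict[str, CommProbability] = {}
    retained: dict[str, np.ndarray] = {}
    for age in AGE_GROUPS:
        cp = interaction_probabilities(m, ann, lrdb, age, species=species, Kh=Kh)
        keep = cp.p > 0
        if n_perm > 0:
            pvals = permutation_test(
                m, ann, lrdb, age, species=species, Kh=Kh, n_perm=n_perm, seed=seed
            )
            keep &= pvals <= p_threshold
        per_age[age] = cp
        retained[age] = keep
    groups = sorted(set(per_age["young"].groups) | set(per_age["old"].groups))

    def expand(cp: CommProbability, arr: np.ndarray) -> pd.DataFrame:
        df = pd.DataFrame(0.0, index=groups, columns=groups)
        df.loc[cp.groups, cp.groups] = arr
        return df

    count = {
        age: expand(per_age[age], (per_age[age].p * retained[age]).astype(bool).sum(axis=2))
        for age in AGE_GROUPS
    }
    strength = {
        age: expand(per_age[age], (per_age[age].p * retained[age]).sum(axis=2))
        for age in AGE_GROUPS
    }
    return CommNetwork(
        groups=groups,
        count=count,
        strength=strength,
        diff_count=count["old"] - count["young"],
        diff_strength=strength["old"] - strength["young"],
        low_confidence={age: per_age[age].low_confidence for age in AGE_GROUPS},
    )


def permutation_test(
    m: ExpressionMatrix,
    ann: CellAnnotation,
    lrdb: LigandReceptorDB,
    age_group: str,
    species: str | None = None,
    Kh: float = DEFAULT_KH,
    n_perm: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Permutation p-values for p[i, j, k] within one age group.

    The null recomputes all probabilities after shuffling cell-type labels
    within the age group; p is the add-one fraction of null values at least
    as large as the observed one.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be at least 10")
    observed = interaction_probabilities(m, ann, lrdb, age_group, species=species, Kh=Kh)
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(observed.p)
    base = ann.table.copy()
    sel = base["age_group"] == age_group
    if species is not None:
        sel &= base["species"] == species
    labels = base.loc[sel, "cell_type"].to_numpy()
    for _ in range(n_perm):
        perm = base.copy()
        perm.loc[sel, "cell_type"] = rng.permutation(labels)
        null = interaction_probabilities(
            m, CellAnnotation(perm), lrdb, age_group, species=species, Kh=Kh
        )
        exceed += null.p >= observed.p
    return (1.0 + exceed) / (1.0 + n_perm)
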