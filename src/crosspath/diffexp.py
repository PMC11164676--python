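"""Old-vs-young differential expression by Wilcoxon rank-sum.

Per gene, the two age groups are compared with the two-sided Wilcoxon
rank-sum (Mann-Whitney U) test; p-values are Bonferroni-corrected over the
genes actually tested, and genes are flagged as differentially expressed
when they clear both a log2 fold-change and a p-value threshold.

Defaults follow the common single-cell convention: |log2fc| >= 0.1 and
adjusted p <= 0.05.  Which p column the threshold applies to (raw or
Bonferroni-adjusted) and whether the comparison is strict are exposed as
switches because tool conventions differ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import AGE_GROUPS, CellAnnotation, ExpressionMatrix

#: number of pooled observations at or below which the exact null is used
EXACT_LIMIT = 16

DEG_COLUMNS = [
    "gene",
    "log2fc",
    "p_raw",
    "p_adj",
    "n_old",
    "n_young",
    "mean_old",
    "mean_young",
    "is_deg",
]


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (U statistic, p).

    The exact permutation null is used when the pooled sample has at most
    ``EXACT_LIMIT`` observations and no ties; otherwise the normal
    approximation with tie-corrected variance and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= EXACT_LIMIT and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def log2_fold_change(mean_old: float, mean_young: float, pseudocount: float = 1.0) -> float:
    """log2((mean_old + c) / (mean_young + c)) with pseudocount c > 0."""
    if mean_old < 0 or mean_young < 0:
        raise ValueError("group means must be non-negative")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return float(np.log2((mean_old + pseudocount) / (mean_young + pseudocount)))


@dataclass
class DEGTable:
    """Per-gene differential expression results for one comparison scope."""

    table: pd.DataFrame
    species: str | None = None
    scope: str = "all_cells"

    def __post_init__(self) -> None:
        missing = [c for c in DEG_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"DEG table missing columns: {missing}")
        self.table = self.table[DEG_COLUMNS].reset_index(drop=True)

    @property
    def degs(self) -> list[str]:
        return list(self.table.loc[self.table["is_deg"], "gene"])

    def sign_of(self, gene: str) -> int:
        row = self.table[self.table["gene"] == gene]
        if row.empty:
            return 0
        return int(np.sign(row["log2fc"].iloc[0]))

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, species=None, scope="all_cells") -> "DEGTable":
        t = pd.read_csv(path, sep="\t")
        t["is_deg"] = t["is_deg"].astype(bool)
        return cls(t, species=species, scope=scope)


def _test_genes(
    values_old: np.ndarray,
    values_young: np.ndarray,
    genes: list[str],
    fc_threshold: float,
    p_threshold: float,
    p_column: str,
    strict: bool,
    pseudocount: float,
) -> pd.DataFrame:
    # Drop genes expressed in neither group before testing (and before the
    # Bonferroni denominator is counted).
    expressed = (values_old.sum(axis=1) > 0) | (values_young.sum(axis=1) > 0)
    values_old = values_old[expressed]
    values_young = values_young[expressed]
    genes = [g for g, keep in zip(genes, expressed) if keep]
    m = len(genes)

    n_old = values_old.shape[1]
    n_young = values_young.shape[1]
    if m == 0:
        p_raw = np.array([])
    elif n_old + n_young <= EXACT_LIMIT:
        p_raw = np.array(
            [wilcoxon_rank_sum(values_old[i], values_young[i])[1] for i in range(m)]
        )
    else:
        res = stats.mannwhitneyu(
            values_old, values_young, alternative="two-sided",
            method="asymptotic", axis=1,
        )
        p_raw = np.asarray(res.pvalue, dtype=float)

    mean_old = values_old.mean(axis=1) if m else np.array([])
    mean_young = values_young.mean(axis=1) if m else np.array([])
    log2fc = np.log2((mean_old + pseudocount) / (mean_young + pseudocount)) if m else np.array([])
    p_adj = np.minimum(1.0, p_raw * m)

    p_used = p_adj if p_column == "adj" else p_raw
    pass_p = (p_used < p_threshold) if strict else (p_used <= p_threshold)
    is_deg = (np.abs(log2fc) >= fc_threshold) & pass_p if m else np.array([], dtype=bool)

    return pd.DataFrame(
        {
            "gene": genes,
            "log2fc": log2fc,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "n_old": n_old,
            "n_young": n_young,
            "mean_old": mean_old,
            "mean_young": mean_young,
            "is_deg": is_deg,
        }
    )


def call_degs(
    m: ExpressionMatrix,
    ann: CellAnnotation,
    species: str | None = None,
    fc_threshold: float = 0.1,
    p_threshold: float = 0.05,
    p_column: str = "adj",
    strict: bool = False,
    scope: str = "all_cells",
    pseudocount: float = 1.0,
) -> DEGTable | dict[str, DEGTable]:
    """Old-vs-young DEG calling over all cells or within each cell type.

    Requires a normalized matrix.  Returns one :class:`DEGTable` for
    ``scope="all_cells"`` or a dict keyed by cell type for
    ``scope="per_cell_type"``.
    """
    if not m.normalized:
        raise ValueError("call_degs requires a normalized expression matrix")
    if p_column not in ("raw", "adj"):
        raise ValueError("p_column must be 'raw' or 'adj'")
    if scope not in ("all_cells", "per_cell_type"):
        raise ValueError("scope must be 'all_cells' or 'per_cell_type'")

    ann_t = ann.table
    if species is not None:
        ann_t = ann_t[ann_t["species"] == species]
    covered = set(ann_t["cell_id"])
    missing = [c for c in m.cell_ids if c not in covered]
    if missing:
        raise ValueError(f"{len(missing)} matrix cells lack annotation (e.g. {missing[0]!r})")

    def run(scope_name: str, cells: pd.DataFrame) -> DEGTable:
        old_ids = list(cells.loc[cells["age_group"] == "old", "cell_id"])
        young_ids = list(cells.loc[cells["age_group"] == "young", "cell_id"])
        if not old_ids or not young_ids:
            raise ValueError(f"scope {scope_name!r} lacks one of the age groups")
        idx_old = [m._cell_index[c] for c in old_ids]
        idx_young = [m._cell_index[c] for c in young_ids]
        table = _test_genes(
            m.values[:, idx_old],
            m.values[:, idx_young],
            list(m.gene_ids),
            fc_threshold,
            p_threshold,
            p_column,
            strict,
            pseudocount,
        )
        return DEGTable(table, species=species, scope=scope_name)

    in_matrix = ann_t[ann_t["cell_id"].isin(set(m.cell_ids))]
    if scope == "all_cells":
        return run("all_cells", in_matrix)
    return {
        ct: run(ct, grp) for ct, grp in in_matrix.groupby("cell_type", sort=True)
    }
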