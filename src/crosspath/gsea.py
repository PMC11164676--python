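"""Pre-ranked gene set enrichment analysis (GSEA).

Given a list of genes ranked by a differential-expression statistic, the
enrichment score (ES) of a gene set is the signed maximal deviation of the
classic weighted Kolmogorov-Smirnov running sum: walking down the ranking,
member genes ("hits") increment the sum by |statistic|^p normalized over the
hits, non-members decrement by 1/(N - n_hits).  A positive ES means the set
concentrates at the top of the ranking (activated old vs young), a negative
ES at the bottom (inhibited).

The null distribution is obtained by drawing random member sets of the same
size from the ranked universe.  NES divides ES by the mean |ES| of the
same-sign null, and the nominal p is the add-one fraction of same-sign null
scores at least as extreme.  The sign of NES always equals the sign of ES;
downstream concordance logic reads that sign as pathway activation (+) or
inhibition (-).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexp import DEGTable
from .io import GeneSetCollection

logger = logging.getLogger(__name__)

GSEA_COLUMNS = [
    "gene_set",
    "es",
    "nes",
    "p_nominal",
    "sign",
    "n_hits",
    "leading_edge",
    "skipped",
    "skip_reason",
]


@dataclass
class RankedList:
    """Genes in descending order of a ranking statistic."""

    genes: list[str]
    stats: np.ndarray

    def __post_init__(self) -> None:
        self.stats = np.asarray(self.stats, dtype=float)
        if len(self.genes) != self.stats.size:
            raise ValueError("gene list and statistic vector differ in length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in ranking")
        if not np.all(np.isfinite(self.stats)):
            raise ValueError("ranking statistics must be finite")
        if np.any(np.diff(self.stats) > 0):
            raise ValueError("statistics must be in descending order")
        self._index = {g: i for i, g in enumerate(self.genes)}

    def __len__(self) -> int:
        return len(self.genes)


def rank_genes(degs: DEGTable, statistic: str = "log2fc") -> RankedList:
    """Build a ranked list from a DEG table (all tested genes, not only DEGs).

    ``statistic`` is ``log2fc`` or ``signed_logp`` (-sign(log2fc)*log10(p_raw)).
    Ties are broken by gene id so the ordering is deterministic.
    """
    t = degs.table
    if t.empty:
        raise ValueError("cannot rank an empty DEG table")
    if statistic == "log2fc":
        values = t["log2fc"].to_numpy(dtype=float)
    elif statistic == "signed_logp":
        # p floored at tiny to keep the statistic finite
        p = np.maximum(t["p_raw"].to_numpy(dtype=float), 1e-300)
        values = np.sign(t["log2fc"].to_numpy(dtype=float)) * (-np.log10(p))
    else:
        raise ValueError(f"unknown ranking statistic {statistic!r}")
    order = sorted(range(len(t)), key=lambda i: (-values[i], t["gene"].iloc[i]))
    return RankedList([t["gene"].iloc[i] for i in order], values[order])


def enrichment_score(
    ranked: RankedList, members, exponent: float = 1.0
) -> tuple[float, np.ndarray]:
    """Classic weighted KS enrichment score and the full running sum.

    Returns (ES, running_sum) where running_sum[i] is the value after
    processing position i.  The set must have at least one member in the
    ranking and may not cover it entirely.
    """
    members = set(members)
    hits = np.fromiter((g in members for g in ranked.genes), dtype=bool, count=len(ranked))
    n_hits = int(hits.sum())
    n = len(ranked)
    if n_hits == 0:
        raise ValueError("no gene set member present in the ranking")
    if n_hits == n:
        raise ValueError("gene set covers the entire ranking")
    weights = np.abs(ranked.stats) ** exponent
    hit_w = np.where(hits, weights, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        # all hit statistics are zero: fall back to unweighted increments
        hit_w = hits.astype(float)
        denom = float(n_hits)
    running = np.cumsum(hit_w / denom - (~hits) / (n - n_hits))
    es = float(running[np.argmax(np.abs(running))])
    return es, running


def _es_batch(weights: np.ndarray, positions: np.ndarray, n: int) -> np.ndarray:
    """ES for many hit-index sets at once.

    ``positions`` is (n_draws, n_hits) of ranking indices, sorted ascending
    per row; ``weights`` is the |stat|^p vector over the full ranking.  The
    running sum is piecewise linear between hits, so its extrema occur either
    right after a hit or right before the next one; only those candidates
    are evaluated.
    """
    n_hits = positions.shape[1]
    miss_step = 1.0 / (n - n_hits)
    w = weights[positions]
    denom = w.sum(axis=1, keepdims=True)
    # guard all-zero rows (degenerate flat statistic)
    unweighted = denom == 0
    if np.any(unweighted):
        w = np.where(unweighted, 1.0, w)
        denom = np.where(unweighted, float(n_hits), denom)
    cum = np.cumsum(w, axis=1) / denom
    j = np.arange(1, n_hits + 1)
    after_hit = cum - (positions + 1 - j) * miss_step
    before_hit = np.concatenate(
        [np.zeros((positions.shape[0], 1)), cum[:, :-1]], axis=1
    ) - (positions - (j - 1)) * miss_step
    cand = np.concatenate([after_hit, before_hit], axis=1)
    return np.take_along_axis(
        cand, np.argmax(np.abs(cand), axis=1)[:, None], axis=1
    )[:, 0]


@dataclass
class GseaResult:
    """Per-set enrichment results for one species/comparison."""

    table: pd.DataFrame
    species: str | None = None

    def __post_init__(self) -> None:
        missing = [c for c in GSEA_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"GSEA table missing columns: {missing}")
        self.table = self.table[GSEA_COLUMNS].reset_index(drop=True)

    def nes_of(self, gene_set: str) -> float:
        row = self.table[self.table["gene_set"] == gene_set]
        if row.empty or bool(row["skipped"].iloc[0]):
            return np.nan
        return float(row["nes"].iloc[0])

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, species=None) -> "GseaResult":
        t = pd.read_csv(path, sep="\t")
        t["skipped"] = t["skipped"].astype(bool)
        t["skip_reason"] = t["skip_reason"].fillna("")
        t["leading_edge"] = t["leading_edge"].fillna("")
        return cls(t, species=species)


def gsea_prerank(
    ranked: RankedList,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    min_size: int = 5,
    max_size: int = 500,
    exponent: float = 1.0,
    seed: int = 0,
    species: str | None = None,
) -> GseaResult:
    """Run pre-ranked GSEA over a gene-set collection.

    Sets whose intersection with the ranking falls outside
    [min_size, max_size] are reported as skipped with a reason.  The
    permutation null draws ``n_perm`` random same-size member sets from the
    ranked universe; identical seeds give identical tables.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be at least 10")
    n = len(ranked)
    weights = np.abs(ranked.stats) ** exponent
    rng = np.random.default_rng(seed)
    rows = []
    for name, members in sets:
        member_set = set(members)
        hit_idx = np.array(
            [i for i, g in enumerate(ranked.genes) if g in member_set], dtype=int
        )
        n_hits = hit_idx.size
        if n_hits < min_size or n_hits > max_size or n_hits == n:
            reason = (
                "covers entire ranking"
                if n_hits == n
                else f"{n_hits} members in ranking outside [{min_size}, {max_size}]"
            )
            logger.info("skipping gene set %s: %s", name, reason)
            rows.append(
                dict(
                    gene_set=name, es=np.nan, nes=np.nan, p_nominal=np.nan,
                    sign="", n_hits=n_hits, leading_edge="",
                    skipped=True, skip_reason=reason,
                )
            )
            continue
        es, running = enrichment_score(ranked, member_set, exponent)
        # independent permutation null per set: p-values of disjoint random
        # sets stay independent, keeping their joint distribution uniform
        draws = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n_hits]
        draws.sort(axis=1)
        null = _es_batch(weights, draws, n)
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        if same_sign.size:
            nes = es / np.mean(np.abs(same_sign))
            p_nom = (1 + np.sum(np.abs(same_sign) >= abs(es))) / (1 + same_sign.size)
        else:
            nes = np.nan
            p_nom = 1.0 / (1 + n_perm)
        peak = int(np.argmax(np.abs(running)))
        if es >= 0:
            le = [g for i, g in enumerate(ranked.genes) if i <= peak and g in member_set]
        else:
            le = [g for i, g in enumerate(ranked.genes) if i >= peak and g in member_set]
        rows.append(
            dict(
                gene_set=name, es=es, nes=float(nes), p_nominal=float(p_nom),
                sign="+" if es > 0 else ("-" if es < 0 else ""),
                n_hits=n_hits, leading_edge=",".join(le),
                skipped=False, skip_reason="",
            )
        )
    return GseaResult(pd.DataFrame(rows, columns=GSEA_COLUMNS), species=species)
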