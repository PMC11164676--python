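"""Transcription-factor regulon inference by gradient boosting.

For each candidate target gene, a gradient-boosting model F_m(x) =
F_{m-1}(x) + lr * h_m(x) is grown on the expression of a transcription
factor (TF) panel: each round fits a depth-1 regression stump h_m to the
current residual under squared loss, so every round reduces training loss.
The importance of a TF for a target is the total training-loss reduction of
the stumps that split on it.  Regulons are the top targets per TF by
importance, and a cross-species TF concordance step labels each TF as
shared-up / shared-down / discordant from two species' differential-
expression tables joined through an ortholog map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexp import DEGTable
from .io import ExpressionMatrix, OrthologMap

MIN_CELLS = 20
TF_CONCORDANCE_COLUMNS = [
    "tf",
    "log2fc_a",
    "log2fc_b",
    "is_deg_a",
    "is_deg_b",
    "label",
]


def _best_stump(x_sorted: np.ndarray, r_sorted: np.ndarray, prefix: np.ndarray,
                prefix_sq: np.ndarray) -> tuple[float, float, float, float]:
    """Best single split of one feature under squared loss.

    Inputs are the feature values sorted ascending, residuals in the same
    order, and residual prefix sums.  Returns (loss_reduction, threshold,
    left_value, right_value); loss_reduction is 0 when no split helps.
    """
    n = x_sorted.size
    total = prefix[-1]
    base_sse = prefix_sq[-1] - total * total / n
    # candidate split after position i (left = [0..i]) only where x changes
    change = np.nonzero(np.diff(x_sorted))[0]
    if change.size == 0:
        return 0.0, 0.0, 0.0, 0.0
    nl = change + 1
    nr = n - nl
    sl = prefix[change]
    sr = total - sl
    sse = (prefix_sq[-1]) - sl * sl / nl - sr * sr / nr
    best = int(np.argmin(sse))
    reduction = base_sse - sse[best]
    if reduction <= 0:
        return 0.0, 0.0, 0.0, 0.0
    i = change[best]
    threshold = 0.5 * (x_sorted[i] + x_sorted[i + 1])
    return float(reduction), float(threshold), float(sl[best] / nl[best]), float(
        sr[best] / nr[best]
    )


def gbm_importance(
    m: ExpressionMatrix,
    tf_list,
    target: str,
    n_rounds: int = 50,
    learning_rate: float = 0.1,
    seed: int = 0,
    subsample: float = 1.0,
    return_loss: bool = False,
):
    """Per-TF importance for one target gene.

    Boosts depth-1 stumps over TF expression against the target's expression
    under squared loss; importance(TF) sums the training-loss reduction of
    every split on that TF.  A constant target yields all-zero importances.
    ``subsample`` < 1 draws a seeded random cell subset each round.
    """
    tf_list = list(tf_list)
    if target in tf_list:
        raise ValueError("target gene must not be in the TF panel")
    if m.n_cells < MIN_CELLS:
        raise ValueError(f"need at least {MIN_CELLS} cells, got {m.n_cells}")
    X = np.stack([m.gene_row(tf) for tf in tf_list], axis=1)  # cells x TFs
    y = m.gene_row(target).astype(float)
    n, k = X.shape
    rng = np.random.default_rng(seed)
    order = np.argsort(X, axis=0)
    pred = np.full(n, y.mean())
    importance = np.zeros(k)
    losses = [float(np.mean((y - pred) ** 2))]
    for _ in range(n_rounds):
        residual = y - pred
        if subsample < 1.0:
            rows = rng.choice(n, size=max(2, int(round(subsample * n))), replace=False)
        else:
            rows = None
        best = (0.0, -1, 0.0, 0.0, 0.0)  # reduction, feature, threshold, left, right
        for f in range(k):
            if rows is None:
                xs = X[order[:, f], f]
                rs = residual[order[:, f]]
            else:
                sub_x = X[rows, f]
                o = np.argsort(sub_x, kind="stable")
                xs = sub_x[o]
                rs = residual[rows][o]
            prefix = np.cumsum(rs)
            prefix_sq = np.cumsum(rs * rs)
            red, thr, left, right = _best_stump(xs, rs, prefix, prefix_sq)
            if red > best[0]:
                best = (red, f, thr, left, right)
        red, f, thr, left, right = best
        if f < 0:
            losses.append(losses[-1])
            continue
        update = np.where(X[:, f] <= thr, left, right)
        pred = pred + learning_rate * update
        new_loss = float(np.mean((y - pred) ** 2))
        importance[f] += losses[-1] - new_loss
        losses.append(new_loss)
    result = dict(zip(tf_list, importance))
    if return_loss:
        return result, losses
    return result


@dataclass
class RegulonTable:
    """(TF, target) importances and the derived per-TF regulons."""

    importances: pd.DataFrame  # columns: tf, target, importance
    regulons: dict[str, list[str]]

    def write_tsv(self, path) -> None:
        self.importances.to_csv(path, sep="\t", index=False)


def all_importances(
    m: ExpressionMatrix,
    tf_list,
    targets,
    n_rounds: int = 50,
    learning_rate: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """gbm_importance over many targets, one seeded run per target."""
    rows = []
    for t_i, target in enumerate(targets):
        panel = [tf for tf in tf_list if tf != target]
        if not panel:
            continue
        imp = gbm_importance(
            m, panel, target, n_rounds=n_rounds, learning_rate=learning_rate,
            seed=seed + t_i,
        )
        for tf, value in imp.items():
            rows.append({"tf": tf, "target": target, "importance": value})
    return pd.DataFrame(rows, columns=["tf", "target", "importance"])


def build_regulons(
    importances: pd.DataFrame, top_k_per_tf: int | None = 10,
    importance_quantile: float | None = None,
) -> RegulonTable:
    """Assemble per-TF regulons from an importance table.

    Targets are ranked by descending importance (ties broken by gene id); a
    regulon keeps the top ``top_k_per_tf`` targets, or all targets above the
    global ``importance_quantile`` when that is given instead.  A TF never
    appears in its own regulon.
    """
    if importances.empty:
        return RegulonTable(importances, {})
    imp = importances[importances["tf"] != importances["target"]].copy()
    if importance_quantile is not None:
        cutoff = imp["importance"].quantile(importance_quantile)
        imp = imp[imp["importance"] >= cutoff]
    regulons: dict[str, list[str]] = {}
    for tf, grp in imp.groupby("tf", sort=True):
        ranked = grp.sort_values(
            by=["importance", "target"], ascending=[False, True]
        )
        if top_k_per_tf is not None:
            ranked = ranked.head(top_k_per_tf)
        regulons[tf] = list(ranked["target"])
    return RegulonTable(importances, regulons)


def tf_concordance(
    degs_a: DEGTable,
    degs_b: DEGTable,
    orthologs: OrthologMap,
    species_a: str,
    species_b: str,
    tf_list,
) -> pd.DataFrame:
    """Cross-species expression-trend labels for a TF panel.

    A TF (named in species-a symbols) is ``shared_up`` when it is a DEG with
    positive log2 fold change in both species, ``shared_down`` symmetrically,
    ``discordant`` when a DEG in both with opposite signs, and
    ``not_shared`` otherwise.  Species-b rows are joined through the
    one-to-one ortholog map.
    """
    tf_list = list(tf_list)
    if not tf_list:
        raise ValueError("TF list is empty")
    mapping = orthologs.one_to_one(species_a, species_b)
    ta = degs_a.table.set_index("gene")
    tb = degs_b.table.set_index("gene")
    rows = []
    for tf in tf_list:
        partner = mapping.get(tf)
        in_a = tf in ta.index
        in_b = partner is not None and partner in tb.index
        fc_a = float(ta.loc[tf, "log2fc"]) if in_a else np.nan
        fc_b = float(tb.loc[partner, "log2fc"]) if in_b else np.nan
        deg_a = bool(ta.loc[tf, "is_deg"]) if in_a else False
        deg_b = bool(tb.loc[partner, "is_deg"]) if in_b else False
        if deg_a and deg_b and fc_a > 0 and fc_b > 0:
            label = "shared_up"
        elif deg_a and deg_b and fc_a < 0 and fc_b < 0:
            label = "shared_down"
        elif deg_a and deg_b:
            label = "discordant"
        else:
            label = "not_shared"
        rows.append(
            {
                "tf": tf, "log2fc_a": fc_a, "log2fc_b": fc_b,
                "is_deg_a": deg_a, "is_deg_b": deg_b, "label": label,
            }
        )
    return pd.DataFrame(rows, columns=TF_CONCORDANCE_COLUMNS)
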