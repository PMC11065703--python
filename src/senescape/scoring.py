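"""Per-cell gene-set activity scores.

Two scorers are provided:

* ``auc`` — rank-based area-under-the-recovery-curve enrichment in the
  AUCell style: genes are ranked per cell by descending expression and
  the score measures how early the set's genes appear, truncated at
  ``max_rank_frac`` of the genes (default 5%).
* ``module`` — an expression-bin-matched control score in the
  AddModuleScore style: mean expression of the set genes minus the mean
  of randomly drawn control genes from matching mean-expression bins.

AUC scores are normalised by the top-packed maximum area and so lie in
[0, 1]; module scores are unbounded and require log-normalised input.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionDataset, GeneSetCollection


@dataclass
class Ranking:
    """Per-cell gene rankings: ``ranks[g, c]`` is the 1-based rank of gene
    g in cell c (rank 1 = highest expression)."""

    ranks: np.ndarray  # (n_genes, n_cells) int
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    seed: int | None = None
    tie_method: str = "random"


def rank_genes_per_cell(
    dataset: ExpressionDataset,
    seed: int = 0,
    tie_method: str = "random",
) -> Ranking:
    """Rank genes per cell by descending expression.

    Ties are broken by a seeded uniform shuffle within tie groups
    (``tie_method="random"``); ``tie_method="average"`` assigns midranks
    instead, a deterministic alternative useful for testing.
    """
    if dataset.n_cells == 0 or dataset.n_genes == 0:
        raise ValueError("dataset is empty")
    expr = dataset.dense()
    n_genes, n_cells = expr.shape
    ranks = np.empty((n_genes, n_cells), dtype=np.int32)
    if tie_method == "random":
        rng = np.random.default_rng(seed)
        # one random key per entry; lexsort = descending expr, then key
        tiebreak = rng.random(expr.shape)
        for c in range(n_cells):
            order = np.lexsort((tiebreak[:, c], -expr[:, c]))
            ranks[order, c] = np.arange(1, n_genes + 1)
    elif tie_method == "average":
        from scipy.stats import rankdata

        for c in range(n_cells):
            ranks[:, c] = np.round(rankdata(-expr[:, c], method="average")).astype(np.int32)
    else:
        raise ValueError(f"unknown tie_method '{tie_method}'")
    return Ranking(
        ranks=ranks,
        gene_ids=dataset.gene_ids,
        cell_ids=dataset.cell_ids,
        seed=seed,
        tie_method=tie_method,
    )


def max_rank_from_frac(n_genes: int, max_rank_frac: float) -> int:
    if not 0 < max_rank_frac <= 1:
        raise ValueError("max_rank_frac must be in (0, 1]")
    return max(1, math.ceil(max_rank_frac * n_genes))


def auc_score(ranking: Ranking, gene_set, max_rank_frac: float = 0.05) -> np.ndarray:
    """AUC enrichment of ``gene_set`` per cell.

    With maxRank = ceil(max_rank_frac * n_genes), the recovery curve is
    y(i) = #set genes at rank <= i for i = 1..maxRank; the raw area
    sum(y) is normalised by the top-packed maximum
    sum_i min(i, k_eff), where k_eff is the matched set size.  Cells with
    no matched genes score 0 (with a warning).
    """
    n_genes = len(ranking.gene_ids)
    max_rank = max_rank_from_frac(n_genes, max_rank_frac)
    lookup = {g: i for i, g in enumerate(ranking.gene_ids)}
    idx = [lookup[str(s).strip()] for s in gene_set if str(s).strip() in lookup]
    k_eff = len(idx)
    if k_eff == 0:
        warnings.warn("gene set has no genes in the matrix; scores are 0", stacklevel=2)
        return np.zeros(len(ranking.cell_ids))
    set_ranks = ranking.ranks[idx, :]  # (k_eff, n_cells)
    area = np.clip(max_rank - set_ranks + 1, 0, None).sum(axis=0).astype(float)
    i = np.arange(1, max_rank + 1)
    max_area = float(np.minimum(i, k_eff).sum())
    return area / max_area


def module_score(
    dataset: ExpressionDataset,
    gene_set,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Bin-matched control module score per cell.

    Genes are binned into ``n_bins`` groups of (near-)equal size by rank
    of dataset-wide mean expression.  For each matched set gene,
    ``n_ctrl`` control genes are drawn (seeded; with replacement when the
    bin's non-set pool is smaller than ``n_ctrl``) from the same bin,
    excluding set genes; the score is mean(set genes) − mean(pooled
    controls) per cell.  Requires log-normalised input.
    """
    if n_bins < 1 or n_ctrl < 1:
        raise ValueError("n_bins and n_ctrl must be >= 1")
    if not dataset.normalised:
        warnings.warn("module_score expects log-normalised data", stacklevel=2)
    expr = dataset.dense()
    set_idx = dataset.gene_indices(gene_set)
    if len(set_idx) == 0:
        raise ValueError("gene set has no genes in the matrix")
    means = expr.mean(axis=1)
    order = np.argsort(means, kind="stable")
    bins = np.empty(dataset.n_genes, dtype=int)
    for b, chunk in enumerate(np.array_split(order, min(n_bins, dataset.n_genes))):
        bins[chunk] = b
    set_mask = np.zeros(dataset.n_genes, dtype=bool)
    set_mask[set_idx] = True
    rng = np.random.default_rng(seed)
    ctrl_rows = []
    for g in set_idx:
        pool = np.flatnonzero((bins == bins[g]) & ~set_mask)
        if len(pool) == 0:
            pool = np.flatnonzero(~set_mask)
        if len(pool) == 0:  # pathological: every gene is in the set
            pool = np.arange(dataset.n_genes)
        replace = len(pool) < n_ctrl
        ctrl_rows.append(rng.choice(pool, size=n_ctrl, replace=replace))
    ctrl_idx = np.concatenate(ctrl_rows)
    return expr[set_idx, :].mean(axis=0) - expr[ctrl_idx, :].mean(axis=0)


def score_cells(
    dataset: ExpressionDataset,
    collection: GeneSetCollection,
    method: str = "auc",
    max_rank_frac: float = 0.05,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    tie_method: str = "random",
) -> pd.DataFrame:
    """Score every cell against every gene set in ``collection``.

    Returns a tidy CellScoreTable: one row per (cell, set) with columns
    (cell_id, set_name, score, method, params_digest).
    """
    if method not in {"auc", "module"}:
        raise ValueError(f"unknown scoring method '{method}'")
    params = {
        "method": method,
        "max_rank_frac": max_rank_frac,
        "n_bins": n_bins,
        "n_ctrl": n_ctrl,
        "seed": seed,
        "tie_method": tie_method,
    }
    digest = hashlib.sha256(json.dumps(params, sort_keys=True).encode()).hexdigest()[:12]
    frames = []
    ranking = rank_genes_per_cell(dataset, seed=seed, tie_method=tie_method) if method == "auc" else None
    for name, symbols in collection.items():
        if method == "auc":
            scores = auc_score(ranking, symbols, max_rank_frac=max_rank_frac)
        else:
            scores = module_score(dataset, symbols, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": dataset.cell_ids,
                    "set_name": name,
                    "score": scores,
                    "method": method,
                    "params_digest": digest,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def mean_score_per_group(
    scores: pd.DataFrame,
    cell_meta: pd.DataFrame,
    group_by,
    z_scale: bool = False,
) -> pd.DataFrame:
    """Arithmetic mean score per group (e.g. per sample, per cell type).

    ``group_by`` is a metadata column name or list of names.  Empty
    groups are dropped.  With ``z_scale`` the group means are centred
    and scaled to unit variance across groups (per set), and the output
    carries a ``scaled`` flag.
    """
    if isinstance(group_by, str):
        group_by = [group_by]
    missing = [g for g in group_by if g not in cell_meta.columns]
    if missing:
        raise KeyError(f"grouping column(s) not in cell_meta: {missing}")
    merged = scores.merge(
        cell_meta[group_by].rename_axis("cell_id").reset_index(), on="cell_id", how="left"
    )
    out = (
        merged.groupby(["set_name", *group_by], observed=True, dropna=True)["score"]
        .agg(mean_score="mean", n_cells="size")
        .reset_index()
    )
    out["scaled"] = False
    if z_scale:
        def _z(g):
            sd = g["mean_score"].std(ddof=0)
            g = g.copy()
            g["mean_score"] = (g["mean_score"] - g["mean_score"].mean()) / (sd if sd > 0 else 1.0)
            return g

        out = out.groupby("set_name", group_keys=False)[out.columns].apply(_z)
        out["scaled"] = True
    return out.reset_index(drop=True)
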