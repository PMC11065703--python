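"""Senescent-nucleus calling by a robust outlier threshold.

A nucleus is called senescent when its gene-set score strictly exceeds
median + k * MAD of its stratum (default k = 3, MAD scaled by 1.4826 for
consistency with the normal standard deviation).  With MAD = 0 the
threshold degenerates to the median and only strictly greater scores are
called, so constant strata yield zero calls.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

#: normal-consistency factor for the median absolute deviation
NORMAL_MAD_SCALE = 1.4826


def mad_threshold(scores: np.ndarray, k_mad: float = 3.0, mad_scale: float = NORMAL_MAD_SCALE) -> float:
    """median + k_mad * (mad_scale * median |x - median|)."""
    scores = np.asarray(scores, dtype=float)
    med = float(np.median(scores))
    mad = float(np.median(np.abs(scores - med))) * mad_scale
    return med + k_mad * mad


def call_senescent(
    scores: pd.DataFrame,
    cell_meta: pd.DataFrame,
    group_by="cell_type",
    k_mad: float = 3.0,
    mad_scale: float = NORMAL_MAD_SCALE,
) -> pd.DataFrame:
    """Call senescent cells per stratum of ``group_by``.

    ``scores`` is a CellScoreTable (cell_id, set_name, score).  The
    stratum defaults to cell type pooled across samples and diagnoses so
    AD and NDC calls share one yardstick.  Returns one row per (cell,
    set) with (senescent, threshold_used, grouping_key).  Strata with
    fewer than two cells get all-false calls with a warning.
    """
    if k_mad <= 0:
        raise ValueError("k_mad must be > 0")
    if isinstance(group_by, str):
        group_by = [group_by]
    missing = [g for g in group_by if g not in cell_meta.columns]
    if missing:
        raise KeyError(f"grouping column(s) not in cell_meta: {missing}")
    merged = scores.merge(
        cell_meta[group_by].rename_axis("cell_id").reset_index(), on="cell_id", how="left"
    )
    out = []
    for (set_name, *strat), grp in merged.groupby(["set_name", *group_by], observed=True):
        key = "|".join(str(s) for s in strat)
        if len(grp) < 2:
            warnings.warn(f"stratum '{key}' has < 2 cells; all calls false", stacklevel=2)
            thr = np.inf
            called = np.zeros(len(grp), dtype=bool)
        else:
            thr = mad_threshold(grp["score"].to_numpy(), k_mad=k_mad, mad_scale=mad_scale)
            called = grp["score"].to_numpy() > thr  # strictly greater
        out.append(
            pd.DataFrame(
                {
                    "cell_id": grp["cell_id"].to_numpy(),
                    "set_name": set_name,
                    "senescent": called,
                    "threshold_used": thr,
                    "grouping_key": key,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def sample_proportions(
    calls: pd.DataFrame,
    cell_meta: pd.DataFrame,
    stratify_by="cell_type",
    min_cells: int = 3,
) -> pd.DataFrame:
    """Per-(sample, stratum) senescent proportions.

    Strata with fewer than ``min_cells`` cells in a sample are flagged
    excluded (proportion NaN), mirroring the rule that samples with < 3
    cells per cluster are removed from analysis.
    """
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    if isinstance(stratify_by, str):
        stratify_by = [stratify_by]
    cols = ["sample_id", *stratify_by]
    merged = calls.merge(
        cell_meta[cols].rename_axis("cell_id").reset_index(), on="cell_id", how="left"
    )
    agg = (
        merged.groupby(["set_name", "sample_id", *stratify_by], observed=True)["senescent"]
        .agg(n_cells="size", n_senescent="sum")
        .reset_index()
    )
    agg["n_senescent"] = agg["n_senescent"].astype(int)
    agg["excluded"] = agg["n_cells"] < min_cells
    agg["reason"] = np.where(agg["excluded"], f"fewer than {min_cells} cells", "")
    agg["proportion"] = np.where(
        agg["excluded"], np.nan, agg["n_senescent"] / agg["n_cells"]
    )
    return agg
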