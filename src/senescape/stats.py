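"""Group contrasts: rank-sum tests with rank-biserial effect sizes,
Pearson regression against pathology load, and BH-FDR adjustment."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class EffectResult:
    """A two-group contrast: Mann-Whitney U, p, rank-biserial r with CI."""

    contrast: str
    n1: int
    n2: int
    U: float
    p_value: float
    rank_biserial: float
    ci_low: float
    ci_high: float
    method: str = ""

    def __post_init__(self) -> None:
        if not -1 - 1e-12 <= self.rank_biserial <= 1 + 1e-12:
            raise ValueError("rank-biserial must lie in [-1, 1]")


@dataclass
class CorrelationResult:
    """Pearson correlation with the OLS line."""

    r: float
    p_value: float
    n: int
    slope: float
    intercept: float


def _u1_midranks(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic for x: #{pairs x>y} + 0.5 * #{ties}, via midranks."""
    n1 = len(x)
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    r1 = ranks[:n1].sum()
    return r1 - n1 * (n1 + 1) / 2.0


def rank_biserial(x, y) -> float:
    """P(x > y) - P(x < y) over all cross-pairs (ties split)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return 2.0 * _u1_midranks(x, y) / (len(x) * len(y)) - 1.0


def wilcoxon_rank_biserial(
    x_group1,
    x_group2,
    alternative: str = "two-sided",
    ci_method: str = "bootstrap",
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
    contrast: str = "group1 vs group2",
) -> EffectResult:
    """Wilcoxon rank-sum (Mann-Whitney) test with rank-biserial effect size.

    The p-value is exact (full null distribution) when both groups have
    <= 10 observations and there are no ties, otherwise the normal
    approximation with continuity and tie correction is used.  The CI on
    the rank-biserial correlation is a seeded percentile bootstrap
    (resampling within each arm) by default, or a Fisher-z normal
    approximation with ``ci_method="normal"``.
    """
    x = np.asarray(x_group1, dtype=float)
    y = np.asarray(x_group2, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(x), len(y)
    u1 = _u1_midranks(x, y)
    has_ties = len(np.unique(np.concatenate([x, y]))) < n1 + n2
    exact = n1 <= 10 and n2 <= 10 and not has_ties
    res = sps.mannwhitneyu(
        x, y, alternative=alternative, method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    rb = 2.0 * u1 / (n1 * n2) - 1.0
    alpha = 1 - ci_level
    if ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            xb = x[rng.integers(0, n1, n1)]
            yb = y[rng.integers(0, n2, n2)]
            boots[b] = rank_biserial(xb, yb)
        ci_low, ci_high = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    elif ci_method == "normal":
        # normal approximation on U; se of rb = 2*se(U)/(n1*n2)
        se_u = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
        se_rb = 2.0 * se_u / (n1 * n2)
        z = sps.norm.ppf(1 - alpha / 2)
        ci_low, ci_high = rb - z * se_rb, rb + z * se_rb
    else:
        raise ValueError(f"unknown ci_method '{ci_method}'")
    ci_low = float(min(max(ci_low, -1.0), rb))
    ci_high = float(max(min(ci_high, 1.0), rb))
    return EffectResult(
        contrast=contrast,
        n1=n1,
        n2=n2,
        U=float(u1),
        p_value=float(res.pvalue),
        rank_biserial=float(rb),
        ci_low=ci_low,
        ci_high=ci_high,
        method=("exact" if exact else "normal-approx") + f"; CI {ci_method}",
    )


def pearson_regression(x, y) -> CorrelationResult:
    """Pearson r with two-sided t-test p (n-2 df) and the OLS line."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0:
        raise ValueError("x has zero variance")
    if np.std(y) == 0:
        raise ValueError("y has zero variance")
    fit = sps.linregress(x, y)
    return CorrelationResult(
        r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        n=len(x),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def contrast_proportions(
    props: pd.DataFrame,
    sample_meta: pd.DataFrame,
    contrast: str = "diagnosis",
    stratify_by="cell_type",
    group_order=("AD", "NDC"),
    ci_method: str = "bootstrap",
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """One rank-sum contrast of per-sample proportions per stratum.

    ``props`` is a sample_proportions table; ``sample_meta`` maps
    sample_id to the contrast column (e.g. diagnosis) and any
    stratification columns not already in ``props`` (e.g. region).
    Strata with fewer than two samples in either arm after exclusions
    are reported as skipped.  BH-FDR adjusted p-values are appended
    across the tested strata.
    """
    if isinstance(stratify_by, str):
        stratify_by = [stratify_by]
    meta_cols = [contrast] + [c for c in stratify_by if c not in props.columns]
    merged = props.merge(
        sample_meta[["sample_id", *meta_cols]].drop_duplicates("sample_id"),
        on="sample_id",
        how="left",
    )
    merged = merged[~merged["excluded"]]
    rows = []
    keys = ["set_name", *stratify_by] if "set_name" in merged.columns else list(stratify_by)
    for strat, grp in merged.groupby(keys, observed=True):
        strat = strat if isinstance(strat, tuple) else (strat,)
        label = "|".join(str(s) for s in strat)
        a = grp.loc[grp[contrast] == group_order[0], "proportion"].to_numpy()
        b = grp.loc[grp[contrast] == group_order[1], "proportion"].to_numpy()
        base = dict(zip(keys, strat))
        if len(a) < 2 or len(b) < 2:
            rows.append(
                {**base, "skipped": True,
                 "reason": f"need >= 2 samples per arm (got {len(a)}, {len(b)})",
                 "n1": len(a), "n2": len(b), "U": np.nan, "p_value": np.nan,
                 "rank_biserial": np.nan, "ci_low": np.nan, "ci_high": np.nan}
            )
            continue
        eff = wilcoxon_rank_biserial(
            a, b, ci_method=ci_method, n_boot=n_boot, seed=seed,
            contrast=f"{group_order[0]} vs {group_order[1]} | {label}",
        )
        rows.append(
            {**base, "skipped": False, "reason": "",
             "n1": eff.n1, "n2": eff.n2, "U": eff.U, "p_value": eff.p_value,
             "rank_biserial": eff.rank_biserial, "ci_low": eff.ci_low,
             "ci_high": eff.ci_high}
        )
    out = pd.DataFrame(rows)
    if len(out):
        tested = ~out["skipped"]
        out["p_adj"] = np.nan
        if tested.any():
            out.loc[tested, "p_adj"] = bh_fdr(out.loc[tested, "p_value"].to_numpy())
    return out
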