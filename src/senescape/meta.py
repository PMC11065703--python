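"""Random-effects meta-analysis of case-control score differences.

The unit of analysis is the sample (donor): gene-set scores are first
averaged over nuclei per sample, each dataset contributes a Hedges' g
standardized mean difference between arms, and datasets are pooled with
the DerSimonian-Laird estimator of between-dataset variance tau^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class DatasetEffect:
    dataset_id: str
    n_case: int
    n_control: int
    mean_case: float
    mean_control: float
    sd_case: float
    sd_control: float
    g: float
    se_g: float

    def __post_init__(self) -> None:
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need >= 2 samples per arm")
        if not np.isfinite(self.g) or self.se_g <= 0:
            raise ValueError(f"non-finite effect for dataset '{self.dataset_id}'")


@dataclass
class MetaResult:
    pooled: float
    se: float
    z: float
    p_value: float
    tau2: float
    i2: float
    k: int
    n_positive_direction: int


def hedges_j(n1: int, n2: int) -> float:
    """Small-sample correction J = 1 - 3/(4(n1+n2) - 9)."""
    return 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)


def dataset_effect(per_sample_means, arm_labels, case_label="AD", control_label="NDC",
                   dataset_id: str = "dataset") -> DatasetEffect:
    """Hedges' g for one dataset from per-sample mean scores.

    Cohen's d = (mean_case - mean_control) / pooled sd; g = d * J with
    J the small-sample correction; se_g from the standard large-sample
    variance J^2 * (1/n1 + 1/n2 + d^2 / (2(n1+n2-2))).
    """
    vals = np.asarray(per_sample_means, dtype=float)
    labels = np.asarray(arm_labels)
    case = vals[labels == case_label]
    ctrl = vals[labels == control_label]
    n1, n2 = len(case), len(ctrl)
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 samples per arm")
    s1, s2 = case.std(ddof=1), ctrl.std(ddof=1)
    sp = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    if sp == 0:
        raise ValueError("pooled standard deviation is zero")
    d = (case.mean() - ctrl.mean()) / sp
    j = hedges_j(n1, n2)
    g = d * j
    var_g = j**2 * (1.0 / n1 + 1.0 / n2 + d**2 / (2.0 * (n1 + n2 - 2)))
    return DatasetEffect(
        dataset_id=dataset_id, n_case=n1, n_control=n2,
        mean_case=float(case.mean()), mean_control=float(ctrl.mean()),
        sd_case=float(s1), sd_control=float(s2),
        g=float(g), se_g=float(np.sqrt(var_g)),
    )


def pool_random_effects(effects) -> MetaResult:
    """DerSimonian-Laird pooling of per-dataset Hedges' g values.

    tau^2 = max(0, (Q - (k-1)) / C) with Q the fixed-effect
    heterogeneity statistic and C = sum(w) - sum(w^2)/sum(w); pooled
    effect is the inverse-variance weighted mean with weights
    1/(se^2 + tau^2).  I^2 = max(0, (Q - (k-1))/Q) * 100.
    """
    effects = list(effects)
    k = len(effects)
    if k < 1:
        raise ValueError("need at least one dataset")
    g = np.array([e.g for e in effects], dtype=float)
    se = np.array([e.se_g for e in effects], dtype=float)
    if np.any(~np.isfinite(g)) or np.any(~np.isfinite(se)):
        bad = effects[int(np.flatnonzero(~np.isfinite(g) | ~np.isfinite(se))[0])]
        raise ValueError(f"non-finite effect for dataset '{bad.dataset_id}'")
    w = 1.0 / se**2
    g_fe = float(np.sum(w * g) / np.sum(w))
    q = float(np.sum(w * (g - g_fe) ** 2))
    if k == 1:
        tau2 = 0.0
        i2 = 0.0
    else:
        c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (q - (k - 1)) / c)
        i2 = max(0.0, (q - (k - 1)) / q) * 100.0 if q > 0 else 0.0
    w_star = 1.0 / (se**2 + tau2)
    pooled = float(np.sum(w_star * g) / np.sum(w_star))
    se_pooled = float(np.sqrt(1.0 / np.sum(w_star)))
    z = pooled / se_pooled
    p = float(2.0 * sps.norm.sf(abs(z)))
    return MetaResult(
        pooled=pooled, se=se_pooled, z=float(z), p_value=p,
        tau2=float(tau2), i2=float(i2), k=k,
        n_positive_direction=int(np.sum(g > 0)),
    )


def forest_table(effects, result: MetaResult):
    """Per-dataset effects with 95% CIs plus the pooled row, as records."""
    import pandas as pd

    z = sps.norm.ppf(0.975)
    rows = [
        {
            "dataset_id": e.dataset_id, "g": e.g,
            "ci_low": e.g - z * e.se_g, "ci_high": e.g + z * e.se_g,
            "n_case": e.n_case, "n_control": e.n_control, "pooled": False,
        }
        for e in effects
    ]
    rows.append(
        {
            "dataset_id": "POOLED", "g": result.pooled,
            "ci_low": result.pooled - z * result.se,
            "ci_high": result.pooled + z * result.se,
            "n_case": sum(e.n_case for e in effects),
            "n_control": sum(e.n_control for e in effects), "pooled": True,
        }
    )
    return pd.DataFrame(rows)
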