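"""Linear-plateau model of senescence score versus donor age.

The model is y = a + b * min(x, c): score rises linearly with age up to
a breakpoint c (years) and is flat beyond it — the pattern expected when
cells approach a replicative limit in late life.  The breakpoint is
profiled on a dense grid over the observed age range (the objective is
piecewise-quadratic in c, so grid profiling is robust and reproducible);
significance is an F-test of the 3-parameter fit against the
intercept-only null, i.e. a test for the presence of any age trend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class LinearPlateauFit:
    intercept: float
    slope: float
    breakpoint: float
    plateau: float
    rss: float
    p_value: float
    n: int

    def predict(self, age) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        return self.intercept + self.slope * np.minimum(age, self.breakpoint)


def fit_linear_plateau(age, score, n_grid: int = 200) -> LinearPlateauFit:
    """Fit y = a + b*min(x, c) by grid-profiling c, OLS in (a, b).

    Requires at least 5 distinct ages.  Constant scores return a flat
    fit with p = 1.  The p-value compares the fitted model with the
    intercept-only null via F with (2, n-3) degrees of freedom.
    """
    x = np.asarray(age, dtype=float)
    y = np.asarray(score, dtype=float)
    if len(x) != len(y):
        raise ValueError("age and score must have equal length")
    n = len(x)
    if len(np.unique(x)) < 5:
        raise ValueError("need at least 5 distinct ages")
    rss0 = float(np.sum((y - y.mean()) ** 2))
    if rss0 == 0:  # all scores identical
        return LinearPlateauFit(
            intercept=float(y[0]), slope=0.0, breakpoint=float(x.max()),
            plateau=float(y[0]), rss=0.0, p_value=1.0, n=n,
        )
    grid = np.linspace(x.min(), x.max(), n_grid)
    best = None
    for c in grid:
        z = np.minimum(x, c)
        if np.ptp(z) == 0:  # c at/below min age: model degenerates to intercept
            rss, a, b = rss0, float(y.mean()), 0.0
        else:
            X = np.column_stack([np.ones(n), z])
            coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ coef
            rss = float(resid @ resid)
            a, b = float(coef[0]), float(coef[1])
        if best is None or rss < best[0] - 1e-15:
            best = (rss, a, b, float(c))
    rss, a, b, c = best
    df2 = n - 3
    if df2 <= 0:
        raise ValueError("need n >= 4 for the F-test")
    if rss <= 0:
        p = 0.0
    else:
        f = ((rss0 - rss) / 2.0) / (rss / df2)
        p = float(sps.f.sf(f, 2, df2))
    return LinearPlateauFit(
        intercept=a, slope=b, breakpoint=c, plateau=a + b * c,
        rss=rss, p_value=p, n=n,
    )
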