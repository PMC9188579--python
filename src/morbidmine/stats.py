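"""Statistics for stratified prevalence comparison.

Implemented directly from the defining formulas:

* Clopper-Pearson exact binomial confidence interval — inversion of the
  binomial tails, evaluated through the equivalent Beta-quantile closed
  form; deliberately conservative (coverage >= nominal).
* g-test of independence — likelihood-ratio statistic
  G = 2 * sum O * ln(O/E) against a chi-square reference, optional
  Williams correction.
* Kruskal-Wallis rank test with mid-ranks and tie correction
  C = 1 - sum(t^3 - t) / (N^3 - N).

scipy supplies only quantile/tail functions and the mid-rank utility; the
statistics themselves are computed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta as _beta
from scipy.stats import chi2 as _chi2
from scipy.stats import rankdata as _rankdata

__all__ = [
    "PrevalenceCI",
    "TestResult",
    "DegenerateTableError",
    "clopper_pearson",
    "g_test",
    "kruskal_wallis",
    "median_bmi_summary",
    "benjamini_hochberg",
]


class DegenerateTableError(ValueError):
    """A contingency table with a zero margin (test undefined)."""


@dataclass(frozen=True)
class PrevalenceCI:
    """Exact binomial proportion confidence interval."""

    x: int
    n: int
    level: float
    point: float
    lower: float
    upper: float

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float
    method: str


def clopper_pearson(x: int, n: int, level: float = 0.95) -> PrevalenceCI:
    """Exact (Clopper-Pearson) confidence interval for a binomial proportion.

    The bounds invert the binomial tail probabilities; by the standard
    Beta-binomial identity they equal Beta quantiles:

        lower = BetaInv(alpha/2; x, n - x + 1)        (0 when x = 0)
        upper = BetaInv(1 - alpha/2; x + 1, n - x)    (1 when x = n)
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= x <= n:
        raise ValueError("x must satisfy 0 <= x <= n")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    alpha = 1.0 - level
    lower = 0.0 if x == 0 else float(_beta.ppf(alpha / 2.0, x, n - x + 1))
    upper = 1.0 if x == n else float(_beta.ppf(1.0 - alpha / 2.0, x + 1, n - x))
    return PrevalenceCI(x=x, n=n, level=level, point=x / n, lower=lower, upper=upper)


def g_test(
    observed: Sequence[Sequence[float]] | np.ndarray,
    *,
    williams: bool = False,
) -> TestResult:
    """Likelihood-ratio (g) test of independence on an r x c count table.

    G = 2 * sum_ij O_ij * ln(O_ij / E_ij) with the 0*ln(0) = 0 convention,
    E_ij the usual product-of-margins expectation, df = (r-1)(c-1) and the
    p-value from the chi-square upper tail.  The Williams small-sample
    correction divides G by q and is off by default.
    """
    O = np.asarray(observed, dtype=float)
    if O.ndim != 2 or O.shape[0] < 2 or O.shape[1] < 2:
        raise ValueError("observed must be a table with >= 2 rows and >= 2 columns")
    if (O < 0).any():
        raise ValueError("counts must be non-negative")
    row = O.sum(axis=1)
    col = O.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise DegenerateTableError("zero row or column margin")
    N = O.sum()
    E = np.outer(row, col) / N
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(O > 0, O * np.log(O / E), 0.0)
    G = 2.0 * float(terms.sum())
    G = max(G, 0.0)
    df = (O.shape[0] - 1) * (O.shape[1] - 1)
    method = "g-test"
    if williams:
        q = 1.0 + ((N / row).sum() - 1.0) * ((N / col).sum() - 1.0) / (6.0 * N * df)
        G /= q
        method = "g-test (Williams)"
    return TestResult(statistic=G, df=df, p_value=float(_chi2.sf(G, df)), method=method)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis rank test across k groups, with tie correction.

    Mid-ranks are assigned over the pooled sample; the statistic is
    H = 12 / (N (N+1)) * sum_i R_i^2 / n_i - 3 (N+1), divided by the tie
    correction C.  p-value from chi-square at k-1 degrees of freedom.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must be non-empty")
    pooled = np.concatenate(arrays)
    N = pooled.size
    ranks = _rankdata(pooled)  # mid-ranks for ties
    H = 0.0
    start = 0
    for a in arrays:
        r = ranks[start : start + a.size]
        H += r.sum() ** 2 / a.size
        start += a.size
    H = 12.0 / (N * (N + 1)) * H - 3.0 * (N + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    C = 1.0 - float((tie_counts**3 - tie_counts).sum()) / (N**3 - N)
    if C == 0.0:
        raise ValueError("all pooled values identical; H undefined")
    H /= C
    df = len(arrays) - 1
    return TestResult(
        statistic=float(H), df=df, p_value=float(_chi2.sf(H, df)), method="kruskal-wallis"
    )


def median_bmi_summary(
    cohort: pd.DataFrame, *, precision: int | None = 1
) -> pd.DataFrame:
    """Median of per-patient mean BMI for each (age band, obesity, race) stratum.

    Expects the cohort frame produced by :func:`morbidmine.cohort.build_cohort`;
    only included patients contribute.  Empty strata are simply absent.
    """
    inc = cohort[cohort["included"]]
    rows = []
    for (band, obesity, race), grp in inc.groupby(
        ["age_band", "obesity_class", "race"], sort=True
    ):
        med = float(grp["mean_bmi"].median())
        rows.append(
            {
                "age_band": band,
                "obesity_class": obesity,
                "race": race,
                "n_patients": len(grp),
                "median_bmi": round(med, precision) if precision is not None else med,
            }
        )
    return pd.DataFrame(rows)


def benjamini_hochberg(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; off by default upstream)."""
    p = np.asarray(list(p_values), dtype=float)
    m = p.size
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * m / (rank_idx + 1))
        adjusted[i] = running
    return adjusted
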