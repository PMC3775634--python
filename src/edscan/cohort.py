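"""Donor-level cohort statistics for editing-rate comparisons.

Paired (Wilcoxon signed-rank) and unpaired (Mann-Whitney U)
nonparametric tests, Pearson correlation of editing with cell-type
fraction, and linear extrapolation of the editing rate to a pure cell
population.

The signed-rank and rank-sum null distributions are computed exactly —
by dynamic programming over (doubled) midranks, equivalent to full
enumeration of sign assignments / group labelings and valid under ties
— for small samples (n <= 25 pairs; combined n <= 20), and by the
tie-corrected normal approximation with continuity correction above
those sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DonorMeasurement",
    "PairedComparison",
    "GroupComparison",
    "Extrapolation",
    "DegenerateTestError",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "pearson_correlation",
    "extrapolate_pure_population",
    "read_donor_table",
    "EXACT_SIGNED_RANK_MAX_N",
    "EXACT_RANK_SUM_MAX_N",
]

EXACT_SIGNED_RANK_MAX_N = 25
EXACT_RANK_SUM_MAX_N = 20

CONDITIONS = ("uncultured", "normoxia", "hypoxia")
COMPARTMENTS = ("total", "adherent", "supernatant", "cd14_pos", "cd14_neg")


class DegenerateTestError(ValueError):
    """All information cancelled (e.g. every paired difference is zero)."""


@dataclass(frozen=True)
class DonorMeasurement:
    """One donor x condition x day editing-rate observation."""

    donor_id: str
    condition: str
    day: int
    compartment: str
    editing_fraction: float
    cd14_fraction: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.editing_fraction <= 1:
            raise ValueError("editing_fraction must be in [0, 1]")
        if self.cd14_fraction is not None and not 0 <= self.cd14_fraction <= 1:
            raise ValueError("cd14_fraction must be in [0, 1]")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"compartment must be one of {COMPARTMENTS}")
        if self.day < 0:
            raise ValueError("day must be >= 0")


@dataclass(frozen=True)
class PairedComparison:
    n: int  # pairs used (zero differences dropped)
    statistic: float  # W+ (sum of ranks of positive differences)
    p_two_sided: float
    direction: int  # sign of the median difference
    exact: bool


@dataclass(frozen=True)
class GroupComparison:
    n_a: int
    n_b: int
    statistic: float  # U for group a
    p_value: float
    alternative: str
    exact: bool


@dataclass(frozen=True)
class Extrapolation:
    slope: float
    intercept: float
    prediction_at_one: float
    r: float
    extrapolated: bool  # 1.0 lies outside the observed fraction range


def _doubled_midranks(values: np.ndarray) -> np.ndarray:
    """Midranks scaled by 2 so that ties yield exact integers."""
    r2 = np.round(2.0 * stats.rankdata(values)).astype(np.int64)
    return r2


def _signed_rank_counts(r2: np.ndarray) -> np.ndarray:
    """counts[s] = number of sign assignments with doubled positive-rank
    sum s; sums to 2**n."""
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in r2:
        new = counts.copy()
        new[r:] += counts[: total + 1 - r]
        counts = new
    return counts


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]) -> PairedComparison:
    """Two-sided Wilcoxon matched-pairs signed-rank test.

    Zero differences are dropped; ties among |differences| are
    midranked. Exact null distribution (all 2**n sign assignments) for
    n <= 25 pairs, tie-corrected normal approximation with continuity
    correction above.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DegenerateTestError("all paired differences are zero")
    if n < 3:
        raise ValueError("need at least 3 non-zero paired differences")
    r2 = _doubled_midranks(np.abs(d))
    w_plus2 = int(r2[d > 0].sum())
    direction = int(np.sign(np.median(d)))
    if n <= EXACT_SIGNED_RANK_MAX_N:
        counts = _signed_rank_counts(r2)
        denom = 2.0**n
        cdf = counts[: w_plus2 + 1].sum() / denom
        sf = counts[w_plus2:].sum() / denom
        p = min(1.0, 2.0 * min(cdf, sf))
        exact = True
    else:
        mean = r2.sum() / 2.0
        var = (r2.astype(float) ** 2).sum() / 4.0  # midrank form; exact under ties
        if var == 0:
            raise DegenerateTestError("zero variance of the signed-rank statistic")
        z = (w_plus2 - mean - np.sign(w_plus2 - mean)) / np.sqrt(var)  # 0.5*2 continuity
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
        exact = False
    return PairedComparison(n=n, statistic=w_plus2 / 2.0, p_two_sided=float(p), direction=direction, exact=exact)


def _rank_sum_counts(r2: np.ndarray, k: int) -> np.ndarray:
    """counts[s] = number of k-subsets of the doubled ranks with sum s."""
    total = int(r2.sum())
    counts = np.zeros((k + 1, total + 1), dtype=np.float64)
    counts[0, 0] = 1.0
    for r in r2:
        new = counts.copy()
        new[1:, r:] += counts[:-1, : total + 1 - r]
        counts = new
    return counts[k]


def mann_whitney_u(
    a: Sequence[float],
    b: Sequence[float],
    one_sided: bool = False,
    alternative: str | None = None,
) -> GroupComparison:
    """Mann-Whitney U test on two independent groups.

    ``alternative`` is 'two-sided', 'less' (a tends lower than b) or
    'greater'. With ``one_sided=True`` and no explicit alternative the
    tail in the observed direction is used. Exact null distribution
    (all group labelings) when the combined size is <= 20, otherwise
    the tie-corrected normal approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 observations")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    r2 = _doubled_midranks(np.concatenate([a, b]))
    rank_sum_a2 = int(r2[:n_a].sum())
    u_a = rank_sum_a2 / 2.0 - n_a * (n_a + 1) / 2.0
    if alternative is None:
        if one_sided:
            alternative = "greater" if u_a > n_a * n_b / 2.0 else "less"
        else:
            alternative = "two-sided"
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError("alternative must be 'two-sided', 'less' or 'greater'")
    if n <= EXACT_RANK_SUM_MAX_N:
        counts = _rank_sum_counts(r2, n_a)
        denom = counts.sum()  # C(n, n_a)
        p_less = counts[: rank_sum_a2 + 1].sum() / denom
        p_greater = counts[rank_sum_a2:].sum() / denom
        exact = True
    else:
        mean = n_a * n_b / 2.0
        _, tie_counts = np.unique(r2, return_counts=True)
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
        var = n_a * n_b / 12.0 * (n + 1 - tie_term)
        if var == 0:
            raise DegenerateTestError("zero variance of the rank-sum statistic")
        sd = np.sqrt(var)
        p_less = float(stats.norm.cdf((u_a - mean + 0.5) / sd))
        p_greater = float(stats.norm.sf((u_a - mean - 0.5) / sd))
        exact = False
    if alternative == "less":
        p = p_less
    elif alternative == "greater":
        p = p_greater
    else:
        p = min(1.0, 2.0 * min(p_less, p_greater))
    return GroupComparison(
        n_a=n_a, n_b=n_b, statistic=float(u_a), p_value=float(p), alternative=alternative, exact=exact
    )


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateTestError("correlation undefined: zero variance")
    return float(stats.pearsonr(x, y).statistic)


def extrapolate_pure_population(
    editing: Sequence[float], cell_fraction: Sequence[float]
) -> Extrapolation:
    """Ordinary least squares of editing rate on cell-type fraction and
    the predicted rate in a pure (fraction = 1.0) population."""
    y = np.asarray(editing, dtype=float)
    x = np.asarray(cell_fraction, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 matched points")
    if np.std(x) == 0:
        raise DegenerateTestError("degenerate design: all cell fractions equal")
    fit = stats.linregress(x, y)
    return Extrapolation(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        prediction_at_one=float(fit.intercept + fit.slope),
        r=float(fit.rvalue),
        extrapolated=bool(1.0 > x.max() or 1.0 < x.min()),
    )


def read_donor_table(path: str | Path) -> list[DonorMeasurement]:
    """Read a donor table TSV (donor_id, condition, day, compartment,
    editing_fraction, optional cd14_fraction)."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        cd14 = getattr(row, "cd14_fraction", None)
        out.append(
            DonorMeasurement(
                donor_id=str(row.donor_id),
                condition=str(row.condition),
                day=int(row.day),
                compartment=str(row.compartment),
                editing_fraction=float(row.editing_fraction),
                cd14_fraction=None if cd14 is None or pd.isna(cd14) else float(cd14),
            )
        )
    return out
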