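"""Chronosequence statistics.

Distributional checks (Shapiro-Wilk, Levene), normalizing transformations
(log / Box-Cox power), quadratic trend fits with interior-peak location, and
one-way ANOVA followed by Duncan's multiple range test rendered as compact
letter groups (the lowercase a/b/c annotations of stage-comparison figures).
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "TrendFit",
    "GroupComparison",
    "check_normality",
    "check_homogeneity",
    "normalize_transform",
    "fit_trend",
    "anova_oneway",
    "duncan_letters",
]

logger = logging.getLogger(__name__)


def check_normality(values) -> tuple[float, float]:
    """Shapiro-Wilk test; returns (W, p).  Degenerate input gives (nan, nan)."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 observations")
    if np.ptp(x) == 0:
        logger.warning("constant sample: Shapiro-Wilk undefined")
        return float("nan"), float("nan")
    w, p = stats.shapiro(x)
    return float(w), float(p)


def check_homogeneity(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Levene's test (center = mean) for homogeneity of variances."""
    if len(groups) < 2:
        raise ValueError("Levene's test requires at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 observations")
    stat, p = stats.levene(*arrays, center="mean")
    return float(stat), float(p)


def normalize_transform(
    values, alpha: float = 0.05
) -> tuple[np.ndarray, str, dict]:
    """Search none -> log -> Box-Cox power for a transform that passes Shapiro-Wilk.

    Returns ``(transformed, method, info)``.  ``info`` holds the post-transform
    (W, p), any shift applied to make the data positive, the Box-Cox lambda,
    and ``info["passed"]`` — False when no candidate reaches ``alpha`` (the
    best-W transform is then returned).
    """
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    candidates: list[tuple[float, np.ndarray, str, dict]] = []

    w, p = check_normality(x)
    if np.isnan(w):
        return x, "none", {"W": w, "p": p, "passed": False, "degenerate": True}
    if p > alpha:
        return x, "none", {"W": w, "p": p, "passed": True}
    candidates.append((w, x, "none", {"W": w, "p": p}))

    shift = 0.0
    if x.min() <= 0:
        span = np.ptp(x)
        shift = -x.min() + (1e-3 * span if span > 0 else 1.0)
        logger.info("nonpositive values: shifting by +%g before log/power", shift)
    pos = x + shift

    logs = np.log(pos)
    w, p = check_normality(logs)
    if p > alpha:
        return logs, "log", {"W": w, "p": p, "shift": shift, "passed": True}
    candidates.append((w, logs, "log", {"W": w, "p": p, "shift": shift}))

    bc, lam = stats.boxcox(pos)
    w, p = check_normality(bc)
    info = {"W": w, "p": p, "shift": shift, "lambda": float(lam)}
    if p > alpha:
        return bc, "power", {**info, "passed": True}
    candidates.append((w, bc, "power", info))

    wbest, xbest, method, info = max(candidates, key=lambda c: c[0])
    logger.warning(
        "no transform reaches Shapiro-Wilk p > %g; returning best (%s, W=%.4f)",
        alpha, method, wbest,
    )
    return xbest, method, {**info, "passed": False}


@dataclass
class TrendFit:
    """A polynomial trend of a response against recovery time."""

    response: str
    degree: int
    coefficients: np.ndarray  # highest power first (numpy.polyval order)
    r2: float
    p_value: float
    peak_tvr: float | None
    x: np.ndarray = field(repr=False)
    fitted: np.ndarray = field(repr=False)
    ci_lower: np.ndarray = field(repr=False)
    ci_upper: np.ndarray = field(repr=False)

    def predict(self, x) -> np.ndarray:
        return np.polyval(self.coefficients, np.asarray(x, dtype=float))


def fit_trend(tvr, y, degree: int = 2, response: str = "y") -> TrendFit:
    """Least-squares polynomial trend of ``y`` on recovery time ``tvr``.

    Reports R², the overall regression F-test p-value, a pointwise 95%
    confidence band, and — when the fitted curve has an interior maximum on
    the observed range — its location ``peak_tvr`` (``None`` for monotone or
    convex fits).
    """
    x = np.asarray(tvr, dtype=float)
    yv = np.asarray(y, dtype=float)
    if x.size != yv.size:
        raise ValueError("tvr and y must have equal length")
    if x.size < degree + 2:
        raise ValueError(f"need at least {degree + 2} points for degree {degree}")
    X = np.vander(x, degree + 1)  # columns x^degree ... x^0
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient polynomial design (too few distinct x)")
    model = sm.OLS(yv, X).fit()
    coef = model.params
    pred = model.get_prediction(X).summary_frame(alpha=0.05)

    peak: float | None = None
    lo, hi = float(x.min()), float(x.max())
    if degree == 2 and coef[0] < 0:
        vertex = -coef[1] / (2.0 * coef[0])
        if lo < vertex < hi:
            peak = float(vertex)
    elif degree != 2:
        grid = np.linspace(lo, hi, 512)
        vals = np.polyval(coef, grid)
        j = int(np.argmax(vals))
        if 0 < j < grid.size - 1:
            peak = float(grid[j])

    return TrendFit(
        response=response,
        degree=degree,
        coefficients=np.asarray(coef, dtype=float),
        r2=float(model.rsquared),
        p_value=float(model.f_pvalue),
        peak_tvr=peak,
        x=x,
        fitted=pred["mean"].to_numpy(),
        ci_lower=pred["mean_ci_lower"].to_numpy(),
        ci_upper=pred["mean_ci_upper"].to_numpy(),
    )


def anova_oneway(groups: Mapping[object, Sequence[float]]):
    """Classical one-way ANOVA.

    Returns ``(F, p, MSE, (df_between, df_within))`` from the standard
    between/within sum-of-squares decomposition.
    """
    keys = list(groups)
    if len(keys) < 2:
        raise ValueError("one-way ANOVA requires at least 2 groups")
    arrays = [np.asarray(groups[k], dtype=float) for k in keys]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group in ANOVA input")
    n_total = sum(a.size for a in arrays)
    grand = np.concatenate(arrays).mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    dfb = len(arrays) - 1
    dfw = n_total - len(arrays)
    if dfw < 1:
        raise ValueError("no residual degrees of freedom")
    msb = ssb / dfb
    mse = ssw / dfw
    if mse == 0:
        f = float("inf") if msb > 0 else float("nan")
        p = 0.0 if msb > 0 else float("nan")
    else:
        f = msb / mse
        p = float(stats.f.sf(f, dfb, dfw))
    return float(f), p, float(mse), (dfb, dfw)


@dataclass
class GroupComparison:
    """One-way ANOVA with Duncan multiple-range letter groups."""

    means: dict
    n: dict
    F: float
    p_value: float
    mse: float
    df: tuple[int, int]
    letters: dict
    alpha: float


def _duncan_nonsig(means_sorted: np.ndarray, mse: float, dfw: int, n_h: float,
                   alpha: float) -> np.ndarray:
    """Upper-triangular boolean matrix: span [i, j] not significant.

    Duncan's protection level for a span of p means is (1 - alpha)**(p - 1);
    the critical range is the corresponding studentized-range quantile times
    sqrt(MSE / n_h).  Step-down rule: a span containing a wider
    non-significant span is itself declared non-significant.
    """
    g = means_sorted.size
    se = np.sqrt(mse / n_h)
    crit = {
        p: stats.studentized_range.ppf((1.0 - alpha) ** (p - 1), p, dfw) * se
        for p in range(2, g + 1)
    }
    ns = np.zeros((g, g), dtype=bool)
    # widest spans first so the step-down containment rule can propagate
    for span in range(g, 1, -1):
        for i in range(0, g - span + 1):
            j = i + span - 1
            diff = means_sorted[i] - means_sorted[j]
            if diff <= crit[span] or (span < g and (
                (i > 0 and ns[i - 1, j]) or (j < g - 1 and ns[i, j + 1])
            )):
                ns[i, j] = True
    # containment closure: sub-spans of a non-significant span are non-significant
    for span in range(g - 1, 1, -1):
        for i in range(0, g - span + 1):
            j = i + span - 1
            if (i > 0 and ns[i - 1, j]) or (j < g - 1 and ns[i, j + 1]):
                ns[i, j] = True
    np.fill_diagonal(ns, True)
    return ns


def duncan_letters(
    groups: Mapping[object, Sequence[float]], alpha: float = 0.05
) -> GroupComparison:
    """Duncan's multiple range test with a compact letter display.

    Groups sharing no letter differ at ``alpha``; the largest mean gets 'a'.
    Unbalanced designs use the harmonic mean group size.
    """
    f, p, mse, (dfb, dfw) = anova_oneway(groups)
    keys = list(groups)
    means = {k: float(np.mean(groups[k])) for k in keys}
    sizes = {k: len(groups[k]) for k in keys}
    order = sorted(keys, key=lambda k: means[k], reverse=True)
    m_sorted = np.array([means[k] for k in order])
    n_h = len(keys) / sum(1.0 / sizes[k] for k in keys)
    if dfw < 1:
        raise ValueError("Duncan test requires residual degrees of freedom")
    if mse == 0:
        # all-identical groups collapse to a single letter per mean ordering
        ns = np.eye(len(order), dtype=bool)
        for i in range(len(order)):
            for j in range(i + 1, len(order)):
                ns[i, j] = m_sorted[i] == m_sorted[j]
    else:
        ns = _duncan_nonsig(m_sorted, mse, dfw, n_h, alpha)

    # maximal non-significant intervals over the sorted means -> letters
    g = len(order)
    intervals: list[tuple[int, int]] = []
    for i in range(g):
        j = i
        while j + 1 < g and ns[i, j + 1]:
            j += 1
        if not intervals or j > intervals[-1][1]:  # skip contained intervals
            intervals.append((i, j))
    letters = {k: "" for k in order}
    for letter_idx, (i, j) in enumerate(intervals):
        ch = chr(ord("a") + letter_idx)
        for t in range(i, j + 1):
            letters[order[t]] += ch
    return GroupComparison(
        means=means, n=sizes, F=f, p_value=p, mse=mse, df=(dfb, dfw),
        letters={k: letters[k] for k in keys}, alpha=alpha,
    )
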