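"""Hypothesis tests and effect measures used throughout the analysis.

The tests are implemented self-contained — Welch's t, Fisher's exact test
(two-sided by the point-probability rule, computed in exact integer
arithmetic), Pearson's chi-square, and the point-biserial correlation —
with scipy used only for distribution tail probabilities.  Each returns a
:class:`~codsig.io.TestResult`.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np
from scipy import stats as spstats

from .errors import ValidationError
from .io import ExpressionMatrix, TestResult, warn

__all__ = [
    "ContingencyTable2x2",
    "welch_t_test",
    "welch_t_matrix",
    "fisher_exact_two_sided",
    "chi_square_test",
    "point_biserial",
    "log2_fold_difference",
    "TestResult",
]

_TINY_VARIANCE = 1e-300  # tie-guard for the zero-variance convention


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 count table; rows are groups, columns are outcomes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValidationError(f"cells must be nonnegative integers: {cells}")
        if sum(cells) == 0:
            raise ValidationError("all-zero 2x2 table")


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sample t test with unequal variances (Welch / Satterthwaite).

    Degenerate convention: when both groups have zero variance the statistic
    is computed against a vanishing variance guard, giving p = 1 for equal
    means and p ~ 0 for separated constants.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("welch_t_test needs at least 2 observations per group")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("welch_t_test requires finite values")
    nx, ny = x.size, y.size
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    if se2 > 0:
        t = (mx - my) / np.sqrt(se2)
        df = se2 ** 2 / (
            (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
        )
    else:
        t = (mx - my) / np.sqrt(_TINY_VARIANCE)
        df = float(nx + ny - 2)
    p = 2.0 * float(spstats.t.sf(abs(t), df))
    return TestResult(
        statistic=float(t), p_value=min(p, 1.0), df=float(df),
        method="Welch two-sample t test",
        effect=float(mx - my), effect_name="mean difference",
    )


def welch_t_matrix(a: np.ndarray, b: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise Welch t over two genes x samples blocks -> (t, df, p) arrays.

    Same formulas as :func:`welch_t_test`, vectorized for genome-wide screens.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValidationError("each group needs at least 2 samples")
    na, nb = a.shape[1], b.shape[1]
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    se2 = va / na + vb / nb
    diff = a.mean(axis=1) - b.mean(axis=1)
    safe = np.maximum(se2, _TINY_VARIANCE)
    t = diff / np.sqrt(safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    df = np.where(se2 > 0, df, na + nb - 2)
    p = np.minimum(2.0 * spstats.t.sf(np.abs(t), df), 1.0)
    return t, df, p


def fisher_exact_two_sided(table: ContingencyTable2x2) -> TestResult:
    """Fisher's exact test, two-sided by the point-probability rule.

    All hypergeometric tables with the observed margins whose probability does
    not exceed the observed table's are summed.  Probabilities are compared as
    exact integers (numerators over the common denominator C(n, a+c)), so the
    result is free of floating-point tie ambiguity.

    The reported effect is the sample odds ratio; when any cell is zero the
    Haldane 0.5 correction is substituted and flagged in ``extras``.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    num_obs = comb(r1, a) * comb(r2, c)
    total = comb(n, c1)
    acc = 0
    for k in range(lo, hi + 1):
        num = comb(r1, k) * comb(r2, c1 - k)
        if num <= num_obs:
            acc += num
    p = acc / total
    extras: dict[str, object] = {}
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        extras["haldane_correction"] = True
    else:
        odds = (a * d) / (b * c)
    return TestResult(
        statistic=float(num_obs / total), p_value=float(min(p, 1.0)),
        method="Fisher exact test (two-sided, point probability)",
        effect=float(odds), effect_name="odds ratio", extras=extras,
    )


def chi_square_test(table: np.ndarray, strict: bool = True) -> TestResult:
    """Pearson chi-square test of independence on an r x c count table.

    Expected counts come from the margins; df = (r-1)(c-1).  Rows or columns
    with a zero margin make expected counts zero: an error under ``strict``,
    silently dropped otherwise.  A low-expected-count condition (any expected
    < 5) is flagged in ``extras`` and warned about.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValidationError("chi_square_test needs an r x c table with r, c >= 2")
    if np.any(obs < 0) or not np.all(np.isfinite(obs)):
        raise ValidationError("counts must be finite and nonnegative")
    if obs.sum() == 0:
        raise ValidationError("zero grand total")
    row_ok = obs.sum(axis=1) > 0
    col_ok = obs.sum(axis=0) > 0
    if not (row_ok.all() and col_ok.all()):
        if strict:
            raise ValidationError(
                "margin with zero total (expected counts would be 0); "
                "pass strict=False to drop empty rows/columns"
            )
        obs = obs[row_ok][:, col_ok]
        if obs.shape[0] < 2 or obs.shape[1] < 2:
            raise ValidationError("fewer than 2 nonempty rows/columns remain")
    rows = obs.sum(axis=1, keepdims=True)
    cols = obs.sum(axis=0, keepdims=True)
    expected = rows @ cols / obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    extras: dict[str, object] = {}
    if (expected < 5).any():
        extras["low_expected_counts"] = True
        warn("chi-square expected count below 5; the asymptotic p may be unreliable")
    return TestResult(
        statistic=stat, p_value=float(spstats.chi2.sf(stat, df)), df=float(df),
        method="Pearson chi-square test", extras=extras,
    )


def point_biserial(binary: Sequence[int], x: Sequence[float],
                   latent_normal: bool = False) -> TestResult:
    """Correlation between a 0/1 dichotomy and a continuous variable.

    The default is the point-biserial coefficient, identical to the Pearson
    correlation of ``x`` with the 0/1 coding; ``latent_normal=True`` instead
    reports the classical biserial coefficient, which assumes the dichotomy
    cuts a latent normal variable.  The p-value always comes from the
    t-transform of the point-biserial r with n - 2 df.
    """
    g = np.asarray(binary, dtype=float)
    x = np.asarray(x, dtype=float)
    if g.shape != x.shape or g.ndim != 1:
        raise ValidationError("binary and x must be 1-d vectors of equal length")
    if not set(np.unique(g)) <= {0.0, 1.0}:
        raise ValidationError("binary vector must contain only 0 and 1")
    n = g.size
    n1 = int(g.sum())
    if n1 == 0 or n1 == n:
        raise ValidationError("both classes must be present")
    sx = x.std(ddof=1)
    if sx == 0:
        r = 0.0
    else:
        p1 = n1 / n
        # Pearson r of x with the 0/1 coding, written in group-mean form
        r = float((x[g == 1].mean() - x[g == 0].mean())
                  * np.sqrt(p1 * (1 - p1) * n / (n - 1)) / sx)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        t, p = np.inf * np.sign(r), 0.0
    else:
        t = r * np.sqrt((n - 2) / (1 - r * r))
        p = 2.0 * float(spstats.t.sf(abs(t), n - 2))
    effect = r
    method = "point-biserial correlation"
    if latent_normal:
        p1 = n1 / n
        density = float(spstats.norm.pdf(spstats.norm.ppf(p1)))
        effect = float(np.clip(r * np.sqrt(p1 * (1 - p1)) / density, -1.0, 1.0))
        method = "biserial correlation (latent normal)"
    return TestResult(
        statistic=float(t), p_value=min(p, 1.0), df=float(n - 2),
        method=method, effect=effect, effect_name="r",
    )


def log2_fold_difference(expr: ExpressionMatrix, gene: str,
                         group_a: Sequence[str], group_b: Sequence[str]) -> float:
    """Linear fold difference 2^(meanA - meanB) for one gene on log2 input."""
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValidationError("both groups must be nonempty")
    if set(group_a) & set(group_b):
        raise ValidationError("groups must be disjoint")
    gi = expr.gene_index([gene])[0]
    mean_a = expr.values[gi, expr.sample_index(group_a)].mean()
    mean_b = expr.values[gi, expr.sample_index(group_b)].mean()
    return float(2.0 ** (mean_a - mean_b))
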