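"""Inferential statistics for behavioural index tables.

Paired t-tests, the 2x2 within-subject ANOVA (computed through
per-subject contrasts, where each effect's F is the squared paired-t of
the corresponding contrast with df = (1, n-1) -- algebraically identical
to the classical partitioned-sums-of-squares formulation for a balanced
2x2 design), Pearson correlation, and a Dienes-style Bayes factor for
evidence of a null effect (half-normal alternative prior by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate
from scipy import stats as sps

__all__ = [
    "TTestResult",
    "AnovaEffect",
    "paired_t",
    "rm_anova_2x2",
    "pearson",
    "bayes_factor_null",
    "read_index_table",
    "write_index_table",
]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float


@dataclass(frozen=True)
class AnovaEffect:
    F: float
    df1: int
    df2: int
    p: float


def paired_t(x, y) -> TTestResult:
    """Two-sided paired t-test of per-subject values ``x`` vs ``y``.

    df = n - 1.  Raises on zero variance of the differences (a paired t
    is undefined there, and reporting infinity would be misleading).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return TTestResult(t=0.0, df=n - 1, p=1.0)
        raise ZeroDivisionError("zero variance of paired differences")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return TTestResult(t=float(t), df=n - 1, p=float(p))


def _cell_matrix(table: pd.DataFrame, index: str, subject: str,
                 factor_a: str, factor_b: str) -> np.ndarray:
    """(n_subjects, 2, 2) cell values; raises on an unbalanced design."""
    levels_a = sorted(table[factor_a].unique())
    levels_b = sorted(table[factor_b].unique())
    if len(levels_a) != 2 or len(levels_b) != 2:
        raise ValueError("both factors must have exactly 2 levels")
    subjects = sorted(table[subject].unique())
    cells = np.full((len(subjects), 2, 2), np.nan)
    for (s, a, b), grp in table.groupby([subject, factor_a, factor_b]):
        if len(grp) != 1:
            raise ValueError(f"duplicate cell for subject={s}, {a}, {b}")
        cells[subjects.index(s), levels_a.index(a), levels_b.index(b)] = \
            grp[index].iloc[0]
    if np.isnan(cells).any():
        raise ValueError("unbalanced design: every subject needs all 4 cells")
    return cells


def rm_anova_2x2(table: pd.DataFrame, index: str, subject: str = "id",
                 factor_a: str = "dbs", factor_b: str = "value") -> dict:
    """Two-way fully-within 2x2 repeated-measures ANOVA.

    Returns ``{factor_a: AnovaEffect, factor_b: ..., 'interaction': ...}``.
    Each effect is the squared paired-t of the per-subject contrast
    (main effects: difference of factor means; interaction: difference
    of differences), F(1, n-1).
    """
    cells = _cell_matrix(table, index, subject, factor_a, factor_b)
    n = cells.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    contrasts = {
        factor_a: cells[:, 1, :].mean(axis=1) - cells[:, 0, :].mean(axis=1),
        factor_b: cells[:, :, 1].mean(axis=1) - cells[:, :, 0].mean(axis=1),
        "interaction": (cells[:, 1, 1] - cells[:, 1, 0]
                        - cells[:, 0, 1] + cells[:, 0, 0]) / 2.0,
    }
    out = {}
    for name, c in contrasts.items():
        sd = c.std(ddof=1)
        if sd == 0:
            F = 0.0 if np.allclose(c, 0) else np.inf
        else:
            t = c.mean() / (sd / np.sqrt(n))
            F = t * t
        p = float(sps.f.sf(F, 1, n - 1)) if np.isfinite(F) else 0.0
        out[name] = AnovaEffect(F=float(F), df1=1, df2=n - 1, p=p)
    return out


def pearson(x, y) -> tuple:
    """Pearson correlation with t-based two-sided p; errors on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("need equal-length arrays with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ZeroDivisionError("zero variance input to pearson()")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def bayes_factor_null(obs_diff: float, se: float, h1_sd: float = 0.2,
                      tails: int = 1, direction: int = +1,
                      rel_tol: float = 1e-8) -> tuple:
    """Bayes factor comparing a point null against a directional H1.

    The alternative predicts effects drawn from a normal with mean 0 and
    standard deviation ``h1_sd``; ``tails=1`` folds it to a half-normal
    on the side given by ``direction`` (the Dienes-calculator
    convention), ``tails=2`` keeps both tails.  The data enter as a
    normal likelihood centred on ``obs_diff`` with standard error
    ``se``.  Returns ``(BF10, BF01)``; BF01 > 1 favours the null.

    The marginal likelihood under H1 is integrated numerically
    (adaptive quadrature over +-12 prior SDs, relative tolerance
    ``rel_tol``).
    """
    if not se > 0:
        raise ValueError("se must be > 0")
    if not h1_sd > 0:
        raise ValueError("h1_sd must be > 0")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    if direction not in (+1, -1):
        raise ValueError("direction must be +1 or -1")

    like_null = sps.norm.pdf(obs_diff, loc=0.0, scale=se)

    if tails == 1:
        lo, hi = (0.0, 12.0 * h1_sd) if direction > 0 else (-12.0 * h1_sd, 0.0)
        prior_scale = 2.0  # half-normal density doubles the folded normal
    else:
        lo, hi = -12.0 * h1_sd, 12.0 * h1_sd
        prior_scale = 1.0

    def integrand(delta):
        return (prior_scale * sps.norm.pdf(delta, 0.0, h1_sd)
                * sps.norm.pdf(obs_diff, delta, se))

    like_alt, _ = integrate.quad(integrand, lo, hi, epsrel=rel_tol,
                                 points=[0.0, obs_diff] if lo < obs_diff < hi else None,
                                 limit=200)
    if like_alt == 0 and like_null == 0:
        raise FloatingPointError("both likelihoods underflowed")
    bf10 = like_alt / like_null
    return float(bf10), float(1.0 / bf10) if bf10 > 0 else float("inf")


# -- index-table round-trip --------------------------------------------


def write_index_table(table: pd.DataFrame, path) -> None:
    """Write an index table (id, factor columns, index columns) as TSV."""
    table.to_csv(path, sep="\t", index=False)


def read_index_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
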