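"""Per-mouse aggregation and group comparisons.

The experimental unit is the mouse.  Two aggregation rules apply:

* densities — the mean over a mouse's image crops;
* percentage statistics — the ratio of summed counts across crops
  (sum of positives / sum of totals), never the mean of crop percentages.

Group comparisons follow the original analysis conventions: normally
distributed statistics (densities) are compared with a two-way ANOVA over
genotype × age; non-normal statistics (colocalization percentages) with
the Kruskal–Wallis rank test.  The normality gate is Shapiro–Wilk at
α = 0.05 and can be overridden so either branch can be forced.

Both tests are computed from their defining formulas.  For unbalanced
designs (group sizes here run 3–6 mice) the ANOVA uses Type-II sums of
squares: each main effect is the reduction in residual sum of squares it
buys over the model with the other main effect, and the interaction is the
further reduction over both mains; for balanced designs this coincides
with the classical decomposition SS_total = SS_A + SS_B + SS_AB + SS_err.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import ConfigError


@dataclass(frozen=True)
class TermResult:
    """One effect term of an omnibus test."""

    ss: float
    df: int
    statistic: float
    p_value: float


@dataclass
class GroupResult:
    """Outcome of one group comparison."""

    test: str
    statistic: float
    df: float
    p_value: float
    terms: dict[str, TermResult] = field(default_factory=dict)


# --------------------------------------------------------------------------
# per-mouse aggregation

def aggregate_mouse(
    crop_values: Sequence, statistic_kind: str
) -> float | None:
    """Aggregate crop-level values for one mouse.

    ``statistic_kind="mean"`` takes the mean of crop values (densities);
    ``statistic_kind="sum_ratio"`` takes 100 × Σnumerators / Σdenominators
    over (numerator, denominator) count pairs (percentages).  A mouse whose
    denominators sum to zero yields None (missing, not zero).
    """
    if len(crop_values) == 0:
        raise ConfigError("at least one crop per mouse is required")
    if statistic_kind == "mean":
        return float(np.mean([float(v) for v in crop_values]))
    if statistic_kind == "sum_ratio":
        num = sum(n for n, _ in crop_values)
        den = sum(d for _, d in crop_values)
        if den == 0:
            return None
        return 100.0 * num / den
    raise ConfigError(f"unknown statistic kind {statistic_kind!r}")


# --------------------------------------------------------------------------
# two-way ANOVA from formulas (Type-II SS)

def _dummies(labels: np.ndarray) -> np.ndarray:
    """Treatment-coded dummy columns (first level dropped)."""
    levels = sorted(set(labels.tolist()))
    return np.column_stack([(labels == lv).astype(float) for lv in levels[1:]]) \
        if len(levels) > 1 else np.empty((len(labels), 0))


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def two_way_anova(
    values: Sequence[float],
    factor_a: Sequence,
    factor_b: Sequence,
) -> GroupResult:
    """Two-way fixed-effects ANOVA with interaction (Type-II SS).

    ``factor_a`` and ``factor_b`` are the level labels (e.g. genotype and
    age group) of each observation.  Every cell of the design must contain
    at least one observation.  Returns per-term F statistics and p-values
    from the F distribution; the headline ``statistic`` is the factor-A F.
    """
    y = np.asarray(values, dtype=float)
    a = np.asarray(factor_a)
    b = np.asarray(factor_b)
    if not (len(y) == len(a) == len(b)):
        raise ConfigError("values and factor labels must have equal length")
    levels_a, levels_b = sorted(set(a.tolist())), sorted(set(b.tolist()))
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise ConfigError("each factor needs at least two levels")
    for la in levels_a:
        for lb in levels_b:
            if not np.any((a == la) & (b == lb)):
                raise ConfigError(f"empty design cell: ({la!r}, {lb!r})")

    n = len(y)
    ones = np.ones((n, 1))
    A = _dummies(a)
    B = _dummies(b)
    AB = np.column_stack(
        [A[:, i] * B[:, j] for i in range(A.shape[1]) for j in range(B.shape[1])]
    ) if A.shape[1] and B.shape[1] else np.empty((n, 0))

    rss_a = _rss(y, np.hstack([ones, A]))
    rss_b = _rss(y, np.hstack([ones, B]))
    rss_ab = _rss(y, np.hstack([ones, A, B]))
    rss_full = _rss(y, np.hstack([ones, A, B, AB]))

    df_a = len(levels_a) - 1
    df_b = len(levels_b) - 1
    df_int = df_a * df_b
    df_err = n - len(levels_a) * len(levels_b)
    if df_err <= 0:
        raise ConfigError("no residual degrees of freedom (one observation per cell)")

    ss = {
        "factor_a": rss_b - rss_ab,
        "factor_b": rss_a - rss_ab,
        "interaction": rss_ab - rss_full,
    }
    dfs = {"factor_a": df_a, "factor_b": df_b, "interaction": df_int}
    mse = rss_full / df_err

    terms: dict[str, TermResult] = {}
    for name in ss:
        ssq = max(ss[name], 0.0)  # guard tiny negative round-off
        if mse == 0.0:
            f_stat = 0.0 if ssq == 0.0 else np.inf
        else:
            f_stat = (ssq / dfs[name]) / mse
        p = float(sps.f.sf(f_stat, dfs[name], df_err)) if np.isfinite(f_stat) else 0.0
        terms[name] = TermResult(ss=ssq, df=dfs[name], statistic=f_stat, p_value=p)
    terms["residual"] = TermResult(ss=rss_full, df=df_err, statistic=np.nan, p_value=np.nan)

    head = terms["factor_a"]
    return GroupResult(
        test="two_way_anova",
        statistic=head.statistic,
        df=head.df,
        p_value=head.p_value,
        terms=terms,
    )


# --------------------------------------------------------------------------
# Kruskal–Wallis from formulas

def kruskal_wallis(groups: Sequence[Sequence[float]]) -> GroupResult:
    """Kruskal–Wallis H test with tie correction.

    H = 12/(N(N+1)) Σ R_i²/n_i − 3(N+1), divided by the tie-correction
    factor 1 − Σ(t³ − t)/(N³ − N); the p-value comes from the χ² limit
    with k − 1 degrees of freedom.  All observations identical → H = 0,
    p = 1 by convention.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ConfigError("need at least two non-empty groups")
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)

    h = 0.0
    start = 0
    for g in groups:
        r_sum = float(ranks[start : start + len(g)].sum())
        h += r_sum * r_sum / len(g)
        start += len(g)
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)

    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    denom = 1.0 - tie_term / (n_total**3 - n_total)
    if denom == 0.0:
        h = 0.0  # all observations identical
    else:
        h = h / denom

    df = len(groups) - 1
    p = 1.0 if h == 0.0 else float(sps.chi2.sf(h, df))
    return GroupResult(test="kruskal_wallis", statistic=h, df=df, p_value=p)


# --------------------------------------------------------------------------
# normality gate

def shapiro_normality(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro–Wilk W and p; used only to pick the parametric branch."""
    y = np.asarray(values, dtype=float)
    if len(y) < 3:
        raise ConfigError("Shapiro–Wilk needs at least three observations")
    if np.ptp(y) == 0:
        raise ConfigError("normality test undefined for constant values")
    w, p = sps.shapiro(y)
    return float(w), float(p)


def choose_branch(values: Sequence[float], alpha: float = 0.05,
                  override: str | None = None) -> str:
    """Pick "anova" or "kruskal_wallis" via Shapiro–Wilk, unless overridden."""
    if override in ("anova", "kruskal_wallis"):
        return override
    if override is not None:
        raise ConfigError(f"unknown branch override {override!r}")
    _, p = shapiro_normality(values)
    return "anova" if p > alpha else "kruskal_wallis"
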