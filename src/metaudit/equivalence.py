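"""Equivalence (TOST) and Welch tests for meta-analytic summaries.

Two one-sided tests (TOST) declare an effect statistically equivalent to
zero, given a smallest effect size of interest (SESOI) Delta, when both
H0: theta <= -Delta and H0: theta >= +Delta are rejected at level alpha
— equivalently, when the (1-2*alpha) confidence interval lies strictly
inside (-Delta, +Delta).

Meta-analytic summary estimates arrive as (smd, se) pairs with no
degrees of freedom, so the one-sample TOST here is z-based, consistent
with the Wald treatment used for power.  Subgroup contrasts from summary
statistics (n, mean, sd per group) use Welch's t-test with
Satterthwaite degrees of freedom, and a two-sample TOST whose Cohen's-d
bound is converted to the raw scale via sqrt((sd1^2 + sd2^2)/2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import norm

from .data_model import Corpus, EffectEstimate


@dataclass
class TostResult:
    bound: float                      # SESOI Delta on the SMD / d scale
    estimate: float                   # point estimate tested
    p_lower: float                    # H0: theta <= -Delta
    p_upper: float                    # H0: theta >= +Delta
    p_tost: float                     # max of the two one-sided p-values
    ci_tost: tuple[float, float]      # (1 - 2*alpha) CI
    nhst_ci: tuple[float, float]      # (1 - alpha) CI
    equivalent: bool
    alpha: float = 0.05
    df: Optional[float] = None        # Welch df for the two-sample form


@dataclass
class WelchResult:
    t: float
    df: float
    p: float
    group1: tuple[int, float, float]  # (n, mean, sd)
    group2: tuple[int, float, float]


def tost_meta(summary: EffectEstimate, bound: float,
              alpha: float = 0.05) -> TostResult:
    """One-sample z-based TOST of a summary SMD against bounds (-D, +D)."""
    if not bound > 0:
        raise ValueError(f"equivalence bound must be positive, got {bound}")
    est = summary if summary.se is not None else summary.resolve()
    smd, se = est.smd, est.se
    p_upper = norm.cdf((smd - bound) / se)
    p_lower = norm.sf((smd + bound) / se)
    p_tost = max(p_lower, p_upper)
    z1 = norm.ppf(1.0 - alpha)
    z2 = norm.ppf(1.0 - alpha / 2.0)
    return TostResult(
        bound=bound, estimate=smd,
        p_lower=float(p_lower), p_upper=float(p_upper), p_tost=float(p_tost),
        ci_tost=(smd - z1 * se, smd + z1 * se),
        nhst_ci=(smd - z2 * se, smd + z2 * se),
        equivalent=bool(p_tost <= alpha), alpha=alpha)


def nhst_significant(summary: EffectEstimate, alpha: float = 0.05) -> bool:
    """Two-sided Wald significance of a summary estimate."""
    est = summary if summary.se is not None else summary.resolve()
    return bool(abs(est.smd / est.se) > norm.ppf(1.0 - alpha / 2.0))


DEFAULT_BOUNDS: tuple[float, ...] = (0.1, 0.2, 0.3)


def equivalence_screen(corpus: Corpus,
                       bounds: Sequence[float] = DEFAULT_BOUNDS,
                       alpha: float = 0.05) -> pd.DataFrame:
    """TOST screen of every meta-analytic summary at each SESOI bound.

    Returns one row per meta-analysis: its NHST significance, then per
    bound the TOST p-value, (1-2*alpha) CI and equivalence flag.
    Equivalence counts are conventionally reported among the
    NHST-non-significant meta-analyses; use ``equivalence_counts``.
    """
    rows = []
    for meta in corpus.metas:
        row: dict = {"meta_id": meta.meta_id,
                     "smd": meta.summary.smd, "se": meta.summary.se,
                     "nhst_significant": nhst_significant(meta.summary, alpha)}
        for b in bounds:
            r = tost_meta(meta.summary, b, alpha)
            tag = f"{b:g}"
            row[f"p_tost_{tag}"] = r.p_tost
            row[f"ci_low_tost_{tag}"] = r.ci_tost[0]
            row[f"ci_high_tost_{tag}"] = r.ci_tost[1]
            row[f"equivalent_{tag}"] = r.equivalent
        rows.append(row)
    return pd.DataFrame(rows)


def equivalence_counts(screen: pd.DataFrame,
                       bounds: Sequence[float] = DEFAULT_BOUNDS) -> dict:
    """Counts of equivalent results among the non-significant metas."""
    nonsig = screen[~screen["nhst_significant"]]
    out = {"n_metas": int(len(screen)),
           "n_significant": int(screen["nhst_significant"].sum()),
           "n_nonsignificant": int(len(nonsig))}
    for b in bounds:
        out[f"n_equivalent_at_{b:g}"] = int(nonsig[f"equivalent_{b:g}"].sum())
    return out


def _welch_se_df(n1, sd1, n2, sd2) -> tuple[float, float]:
    v1, v2 = sd1 ** 2 / n1, sd2 ** 2 / n2
    se = np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    return float(se), float(df)


def _check_groups(n1, sd1, n2, sd2) -> None:
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("group standard deviations must be positive")


def welch_t(n1: int, mean1: float, sd1: float,
            n2: int, mean2: float, sd2: float) -> WelchResult:
    """Welch's two-sample t-test from group summary statistics."""
    _check_groups(n1, sd1, n2, sd2)
    se, df = _welch_se_df(n1, sd1, n2, sd2)
    t = (mean1 - mean2) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(t=float(t), df=df, p=float(p),
                       group1=(n1, mean1, sd1), group2=(n2, mean2, sd2))


def tost_two_sample(n1: int, mean1: float, sd1: float,
                    n2: int, mean2: float, sd2: float,
                    d_bound: float, alpha: float = 0.05) -> TostResult:
    """Welch-based two-sample TOST with a Cohen's-d equivalence bound.

    The d-scale bound is converted to the raw mean-difference scale with
    the root-mean-square of the two group SDs; both one-sided tests run
    on the Welch degrees of freedom.
    """
    if not d_bound > 0:
        raise ValueError(f"equivalence bound must be positive, got {d_bound}")
    _check_groups(n1, sd1, n2, sd2)
    se, df = _welch_se_df(n1, sd1, n2, sd2)
    diff = mean1 - mean2
    raw_bound = d_bound * np.sqrt((sd1 ** 2 + sd2 ** 2) / 2.0)
    p_upper = stats.t.cdf((diff - raw_bound) / se, df)
    p_lower = stats.t.sf((diff + raw_bound) / se, df)
    p_tost = max(p_lower, p_upper)
    tq1 = stats.t.ppf(1.0 - alpha, df)
    tq2 = stats.t.ppf(1.0 - alpha / 2.0, df)
    return TostResult(
        bound=d_bound, estimate=float(diff),
        p_lower=float(p_lower), p_upper=float(p_upper), p_tost=float(p_tost),
        ci_tost=(diff - tq1 * se, diff + tq1 * se),
        nhst_ci=(diff - tq2 * se, diff + tq2 * se),
        equivalent=bool(p_tost <= alpha), alpha=alpha, df=df)
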