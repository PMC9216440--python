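"""Temporal trends in study-level power: year-by-year profiles and a
one-way ANOVA for change over time.

The trend table gives, for every publication year and every assumed true
effect delta* in a grid, the median power of the unique studies published
that year.  The ANOVA groups per-study powers (at the parent
meta-analysis' observed summary estimate by default) by publication year
and tests for any between-year difference in mean power.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import Corpus
from .power import DEFAULT_GRID, study_power, unique_study_powers

logger = logging.getLogger(__name__)


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    degenerate: bool = False   # zero within-group variance


def trend_table(corpus: Corpus, grid: Sequence[float] = DEFAULT_GRID,
                alpha: float = 0.05) -> pd.DataFrame:
    """Median unique-study power per (year, delta*), years ascending.

    Undated studies are excluded with a logged count.  Columns: year,
    delta_star, median_power, n_studies.
    """
    dated = {sid: st for sid, st in corpus.studies.items()
             if st.year is not None}
    n_undated = corpus.n_unique_studies - len(dated)
    if n_undated:
        logger.info("trend_table: excluded %d undated studies", n_undated)
    rows = []
    years = sorted({st.year for st in dated.values()})
    for year in years:
        sts = [st for st in dated.values() if st.year == year]
        for g in sorted(float(x) for x in grid):
            powers = [study_power(st, g, alpha) for st in sts]
            rows.append({"year": year, "delta_star": g,
                         "median_power": float(np.median(powers)),
                         "n_studies": len(sts)})
    return pd.DataFrame(rows, columns=["year", "delta_star", "median_power",
                                       "n_studies"])


def study_year_powers(corpus: Corpus, alpha: float = 0.05,
                      delta_star: Optional[float] = None) -> pd.DataFrame:
    """Flat (study_id, year, power) rows for dated unique studies."""
    powers = unique_study_powers(corpus, alpha, delta_star)
    rows = [{"study_id": sid, "year": corpus.studies[sid].year,
             "power": p}
            for sid, p in powers.items()
            if corpus.studies[sid].year is not None]
    return pd.DataFrame(rows, columns=["study_id", "year", "power"])


def oneway_anova(values: Sequence[float],
                 groups: Sequence) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA.

    Decomposes total sum of squares into between- and within-group
    components; F = MS_between / MS_within on (k-1, N-k) degrees of
    freedom.  Degenerate inputs are handled explicitly: identical group
    means give F = 0, p = 1; zero within-group variance with unequal
    means gives an infinite F, p = 0, flagged degenerate.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must be the same length")
    labels, inverse = np.unique(groups, return_inverse=True)
    k, n = len(labels), len(values)
    if k < 2:
        raise ValueError("one-way ANOVA needs at least 2 groups")
    if n - k < 1:
        raise ValueError("one-way ANOVA needs at least one group with >= 2 "
                         "values (positive within-group df)")
    grand = values.mean()
    group_means = np.array([values[inverse == i].mean() for i in range(k)])
    counts = np.bincount(inverse, minlength=k)
    ss_between = float(np.sum(counts * (group_means - grand) ** 2))
    ss_within = float(sum(np.sum((values[inverse == i]
                                  - group_means[i]) ** 2)
                          for i in range(k)))
    df_b, df_w = k - 1, n - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            logger.warning("oneway_anova: all values identical; F = 0")
            return AnovaResult(F=0.0, df_between=df_b, df_within=df_w,
                               p=1.0, degenerate=True)
        logger.warning("oneway_anova: zero within-group variance with "
                       "unequal means; F is infinite")
        return AnovaResult(F=math.inf, df_between=df_b, df_within=df_w,
                           p=0.0, degenerate=True)
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(F=float(F), df_between=df_b, df_within=df_w, p=p)


def power_trend_anova(corpus: Corpus, alpha: float = 0.05,
                      delta_star: Optional[float] = None) -> AnovaResult:
    """ANOVA of per-study power on publication year (dated studies)."""
    df = study_year_powers(corpus, alpha, delta_star)
    if df["year"].nunique() < 2:
        raise ValueError("need studies from at least 2 years for the trend "
                         "ANOVA")
    return oneway_anova(df["power"].to_numpy(), df["year"].to_numpy())
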