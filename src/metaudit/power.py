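"""Wald-test power profiling for studies in a meta-analytic corpus.

Each study contributes an SMD estimate with a standard error; the power
of its two-sided Wald (z) test at level alpha, under an assumed true
effect delta*, is

    power = Phi(delta*/se - c) + Phi(-delta*/se - c),   c = z_{1-alpha/2}.

Power is profiled over a grid of assumed true effects and at the parent
meta-analysis' observed summary estimate.  A study reporting several
outcomes contributes the median of its per-outcome powers ("median power
rule"), and studies shared across meta-analyses are collapsed the same
way for corpus-level summaries of unique studies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data_model import Corpus, MetaAnalysisRecord, StudyRecord

DEFAULT_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.1, 1.01, 0.1), 10))


def wald_power(delta, se, alpha: float = 0.05):
    """Power of the two-sided Wald test given a true SMD and an SE.

    Vectorized over ``delta`` and ``se``.  Symmetric in the sign of
    ``delta``; equals ``alpha`` exactly at delta = 0 and tends to 1 as
    se -> 0 for fixed delta != 0.
    """
    delta = np.asarray(delta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard error must be positive")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    c = norm.ppf(1.0 - alpha / 2.0)
    z = delta / se
    out = norm.sf(c - z) + norm.cdf(-c - z)
    return out if out.ndim else float(out)


def dedup_power(powers: Sequence[float]) -> float:
    """Collapse per-outcome powers to one per-study value: the median."""
    arr = np.asarray(list(powers), dtype=float)
    if arr.size == 0:
        raise ValueError("no power values to aggregate")
    return float(np.median(arr))


@dataclass
class PowerProfile:
    study_id: str
    ses: list[float]
    grid: list[tuple[float, float]]          # (delta*, power), delta* ascending
    power_at_observed: Optional[float] = None


@dataclass
class PowerSummary:
    scope: str                                # per-meta | corpus | subgroup
    n: int
    median: float                             # percent, one decimal
    mean: float
    min: float
    max: float


def study_power(study: StudyRecord, delta: float, alpha: float = 0.05) -> float:
    """Median across the study's outcomes of the per-outcome Wald power."""
    return dedup_power([wald_power(delta, o.se, alpha) for o in study.outcomes])


def power_grid(study: StudyRecord, grid: Sequence[float],
               summary_delta: Optional[float] = None,
               alpha: float = 0.05) -> PowerProfile:
    """Power profile of one study over a grid of assumed true effects."""
    if len(grid) == 0:
        raise ValueError("empty delta* grid")
    grid = sorted(float(g) for g in grid)
    pairs = [(g, study_power(study, g, alpha)) for g in grid]
    at_obs = (None if summary_delta is None
              else study_power(study, summary_delta, alpha))
    return PowerProfile(study_id=study.study_id,
                        ses=[o.se for o in study.outcomes],
                        grid=pairs, power_at_observed=at_obs)


def power_table(corpus: Corpus, grid: Sequence[float] = DEFAULT_GRID,
                alpha: float = 0.05) -> pd.DataFrame:
    """Long-format per-study power table over the whole corpus.

    One row per (meta, study, delta*), plus a row with delta_star = NaN
    holding the power at the parent meta-analysis' observed summary
    estimate.
    """
    rows = []
    for meta in corpus.metas:
        for st in corpus.meta_studies(meta):
            prof = power_grid(st, grid, meta.summary.smd, alpha)
            for g, p in prof.grid:
                rows.append({"meta_id": meta.meta_id, "study_id": st.study_id,
                             "delta_star": g, "power": p})
            rows.append({"meta_id": meta.meta_id, "study_id": st.study_id,
                         "delta_star": np.nan,
                         "power": prof.power_at_observed})
    return pd.DataFrame(rows, columns=["meta_id", "study_id", "delta_star",
                                       "power"])


def observed_power_frame(corpus: Corpus, alpha: float = 0.05) -> pd.DataFrame:
    """Per-(meta, study) power at the meta's observed summary estimate."""
    rows = []
    for meta in corpus.metas:
        for st in corpus.meta_studies(meta):
            rows.append({
                "meta_id": meta.meta_id, "study_id": st.study_id,
                "year": st.year, "population": st.population,
                "dosing": st.dosing,
                "power": study_power(st, meta.summary.smd, alpha),
            })
    return pd.DataFrame(rows, columns=["meta_id", "study_id", "year",
                                       "population", "dosing", "power"])


def unique_study_powers(corpus: Corpus, alpha: float = 0.05,
                        delta_star: Optional[float] = None) -> pd.Series:
    """One power value per unique study.

    At the observed summary by default; a study shared across
    meta-analyses (hence with several observed-summary powers) is
    collapsed by the median, consistent with the per-outcome rule.  With
    ``delta_star`` given, power is evaluated at that fixed effect
    instead and sharing is moot.
    """
    if delta_star is not None:
        return pd.Series(
            {sid: study_power(st, delta_star, alpha)
             for sid, st in corpus.studies.items()},
            name="power").sort_index()
    df = observed_power_frame(corpus, alpha)
    return df.groupby("study_id")["power"].median().sort_index()


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the reporting convention for percents)."""
    factor = 10.0 ** decimals
    return float(np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor)


def summarize_power(powers: Iterable[float], scope: str = "corpus") -> PowerSummary:
    """Median/mean/min/max of study powers, reported in percent (1 dp)."""
    arr = np.asarray(list(powers), dtype=float)
    if arr.size == 0:
        raise ValueError(f"no studies in scope {scope!r}")
    pct = lambda v: round_half_up(100.0 * v, 1)
    return PowerSummary(scope=scope, n=int(arr.size),
                        median=pct(np.median(arr)), mean=pct(np.mean(arr)),
                        min=pct(np.min(arr)), max=pct(np.max(arr)))


def per_meta_power_summaries(corpus: Corpus, alpha: float = 0.05
                             ) -> pd.DataFrame:
    """Per-meta-analysis summary of member-study powers at the observed
    summary estimate (the per-meta rows behind the corpus medians)."""
    df = observed_power_frame(corpus, alpha)
    rows = []
    for mid, grp in df.groupby("meta_id", sort=False):
        s = summarize_power(grp["power"], scope="per-meta")
        rows.append({"meta_id": mid, "n_studies": s.n, "median_pct": s.median,
                     "mean_pct": s.mean, "min_pct": s.min, "max_pct": s.max})
    return pd.DataFrame(rows, columns=["meta_id", "n_studies", "median_pct",
                                       "mean_pct", "min_pct", "max_pct"])


def subgroup_power_summaries(corpus: Corpus, alpha: float = 0.05
                             ) -> dict[str, PowerSummary]:
    """Unique-study power summaries for the moderator subgroups.

    Population (clinical vs healthy) over all unique studies, and dosing
    (single vs multiple) within clinical studies; records labelled
    unknown are left out of the corresponding contrast only.
    """
    powers = unique_study_powers(corpus, alpha)
    meta_attrs = pd.DataFrame(
        {sid: {"population": st.population, "dosing": st.dosing}
         for sid, st in corpus.studies.items()}).T
    meta_attrs = meta_attrs.loc[powers.index]
    out: dict[str, PowerSummary] = {}
    for pop in ("clinical", "healthy"):
        sel = powers[meta_attrs["population"] == pop]
        if len(sel):
            out[pop] = summarize_power(sel, scope="subgroup")
    clin = meta_attrs["population"] == "clinical"
    for dos in ("single", "multiple"):
        sel = powers[clin & (meta_attrs["dosing"] == dos)]
        if len(sel):
            out[f"clinical_{dos}_dose"] = summarize_power(sel, scope="subgroup")
    return out
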