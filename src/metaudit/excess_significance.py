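"""Test of Excess Significance (TES) for univariate meta-analyses.

The TES asks whether a meta-analysis contains more statistically
significant constituent studies than their individual powers can
explain.  With O the observed count of significant studies among n, and
E = sum of per-study powers at a reference true effect (by default the
meta-analysis' own summary estimate), the chi-square form uses the
Ioannidis–Trikalinos statistic

    A = (O - E)^2 / E + (O - E)^2 / (n - E),

referred to chi-square(1) and halved into a one-sided p assigned to the
excess (O > E) direction.  The exact form evaluates the one-sided tail
P(X >= O) of the Poisson-binomial distribution with the per-study powers
as success probabilities; it is also the fallback when E is degenerate
(0 or n).  A meta-analysis is flagged when p falls below the threshold
with O > E.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import norm

from .data_model import Corpus, EffectEstimate, MetaAnalysisRecord, StudyRecord
from .power import dedup_power, wald_power

logger = logging.getLogger(__name__)


@dataclass
class TesConfig:
    reference: Union[str, float] = "meta_summary"  # or a fixed true SMD
    alpha: float = 0.05           # per-study significance level
    form: str = "chi_square"      # chi_square | exact
    threshold: float = 0.05       # one-sided flag threshold
    outcome_rule: str = "median"  # median | any

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0,1)")
        if self.form not in ("chi_square", "exact"):
            raise ValueError(f"unknown test form {self.form!r}")
        if self.outcome_rule not in ("median", "any"):
            raise ValueError(f"unknown outcome rule {self.outcome_rule!r}")


@dataclass
class TesResult:
    meta_id: str
    n: int
    observed: int       # O
    expected: float     # E
    statistic: Optional[float]  # A (chi-square form only)
    p: float            # one-sided, excess direction
    flagged: bool
    form: str


def study_significant(outcome: EffectEstimate, alpha: float = 0.05) -> bool:
    """Two-sided Wald significance of a single outcome."""
    est = outcome if outcome.se is not None else outcome.resolve()
    return bool(abs(est.smd / est.se) > norm.ppf(1.0 - alpha / 2.0))


def _study_is_significant(study: StudyRecord, alpha: float,
                          rule: str) -> bool:
    """Collapse outcome-level significance to the study level.

    ``median``: the study counts as significant when the median of its
    outcome |z| statistics exceeds the critical value — the counting
    analogue of the median-power rule.  ``any``: one significant outcome
    suffices.
    """
    zs = np.array([abs(o.smd / o.se) for o in study.outcomes])
    crit = norm.ppf(1.0 - alpha / 2.0)
    if rule == "any":
        return bool(np.any(zs > crit))
    return bool(np.median(zs) > crit)


def _study_tes_power(study: StudyRecord, theta: float, alpha: float) -> float:
    return dedup_power([wald_power(theta, o.se, alpha)
                        for o in study.outcomes])


def poisson_binomial_tail(powers: np.ndarray, observed: int) -> float:
    """P(X >= observed) for X Poisson-binomial with the given probabilities."""
    if observed <= 0:
        return 1.0
    return float(stats.poisson_binom(list(powers)).sf(observed - 0.5))


def tes(meta: MetaAnalysisRecord, corpus: Corpus,
        config: TesConfig = TesConfig()) -> TesResult:
    """Run the TES for one meta-analysis over its deduplicated studies."""
    studies = corpus.meta_studies(meta)
    n = len(studies)
    if n < 2:
        raise ValueError(
            f"meta-analysis {meta.meta_id}: TES needs at least 2 studies")
    if config.reference == "meta_summary":
        theta = meta.summary.smd
    else:
        theta = float(config.reference)

    powers = np.array([_study_tes_power(st, theta, config.alpha)
                       for st in studies])
    expected = float(powers.sum())
    observed = int(sum(_study_is_significant(st, config.alpha,
                                             config.outcome_rule)
                       for st in studies))

    form = config.form
    degenerate = expected <= 0.0 or expected >= n
    if degenerate and form == "chi_square":
        logger.warning(
            "meta-analysis %s: expected count E=%.3f is degenerate for the "
            "chi-square form; falling back to the exact test", meta.meta_id,
            expected)
        form = "exact"

    if form == "chi_square":
        dev = observed - expected
        statistic = dev ** 2 / expected + dev ** 2 / (n - expected)
        p_two = float(stats.chi2.sf(statistic, 1))
        p = p_two / 2.0 if observed > expected else 1.0 - p_two / 2.0
        stat_out: Optional[float] = float(statistic)
    else:
        p = poisson_binomial_tail(powers, observed)
        stat_out = None

    flagged = bool(p < config.threshold and observed > expected)
    return TesResult(meta_id=meta.meta_id, n=n, observed=observed,
                     expected=expected, statistic=stat_out, p=float(p),
                     flagged=flagged, form=form)


def tes_screen(corpus: Corpus, config: TesConfig = TesConfig()
               ) -> pd.DataFrame:
    """TES over every univariate meta-analysis in the corpus.

    Multivariate meta-analyses are excluded (their constituent tests are
    not independent draws of one outcome).  Meta-analyses with fewer
    than 2 studies are skipped with a warning.
    """
    rows = []
    univariate = [m for m in corpus.metas if m.design == "univariate"]
    if not univariate:
        logger.warning("tes_screen: corpus contains no univariate "
                       "meta-analyses; returning an empty table")
    for meta in univariate:
        if len(meta.study_ids) < 2:
            logger.warning("tes_screen: meta-analysis %s has < 2 studies; "
                           "skipped", meta.meta_id)
            continue
        r = tes(meta, corpus, config)
        rows.append({"meta_id": r.meta_id, "n": r.n, "observed": r.observed,
                     "expected": r.expected, "statistic": r.statistic,
                     "p": r.p, "flagged": r.flagged, "form": r.form})
    return pd.DataFrame(rows, columns=["meta_id", "n", "observed", "expected",
                                       "statistic", "p", "flagged", "form"])
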