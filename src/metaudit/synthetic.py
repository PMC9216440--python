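"""Synthetic meta-analysis corpora with the statistical structure the
audit assumes.

The generator draws a random-effects hierarchy of standardized mean
differences: each meta-analysis k has a true effect theta_k ~
Normal(mu, tau^2); each member study i has a true effect theta_ki ~
Normal(theta_k, within_tau^2); the observed SMD is the true effect plus
sampling noise whose variance follows the large-sample two-group SMD
form

    Var(d) = 2/n + d^2 / (4 n)          (n subjects per group).

Publication bias is emulated by censoring: a study whose observed SMD is
not statistically significant is dropped with probability
``censor_prob`` and redrawn from the remaining candidates; the summary
estimate is then the fixed-effect inverse-variance average of the
surviving studies (a DerSimonian–Laird random-effects option is
available).  Defaults emulate a small behavioural-neuroendocrinology
literature: 35 meta-analyses, roughly a hundred unique studies with
modest per-group samples, small true effects centered near 0.15, and a
mix of clinical/healthy populations and single/multiple dosing.

Everything is reproducible from the config seed; per-meta substreams are
spawned deterministically so regenerating one meta-analysis does not
perturb the others.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.stats import norm

from .data_model import (Corpus, EffectEstimate, MetaAnalysisRecord,
                         StudyRecord, corpus_to_frames)

logger = logging.getLogger(__name__)


@dataclass
class GeneratorConfig:
    n_metas: int = 35
    studies_per_meta: tuple[int, int] = (2, 6)      # inclusive range
    mu: float = 0.15              # grand mean true SMD
    tau: float = 0.15             # between-meta SD of true effects
    within_tau: float = 0.10      # between-study SD within a meta
    n_per_group: tuple[int, int] = (10, 40)         # inclusive, >= 5
    censor_prob: float = 0.0      # P(drop | non-significant)
    sig_alpha: float = 0.05       # significance level used for censoring
    multi_outcome_prob: float = 0.25
    outcomes_per_study: tuple[int, int] = (2, 3)
    year_range: tuple[int, int] = (2010, 2017)
    clinical_prob: float = 0.64
    multiple_dose_prob: float = 0.44
    univariate_prob: float = 0.5  # fraction of metas labelled univariate
    study_reuse_prob: float = 0.12  # P(slot filled by an earlier study)
    summary_model: str = "fixed"  # fixed | dl (DerSimonian-Laird)
    seed: int = 0
    max_retries: int = 100        # regeneration cap per meta under censoring

    def __post_init__(self) -> None:
        for name in ("censor_prob", "multi_outcome_prob", "clinical_prob",
                     "multiple_dose_prob", "univariate_prob",
                     "study_reuse_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.tau < 0 or self.within_tau < 0:
            raise ValueError("tau and within_tau must be >= 0")
        for name in ("studies_per_meta", "n_per_group", "outcomes_per_study",
                     "year_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range ({lo}, {hi}) is empty")
        if self.n_per_group[0] < 5:
            raise ValueError("n_per_group must be >= 5")
        if self.summary_model not in ("fixed", "dl"):
            raise ValueError(f"unknown summary model {self.summary_model!r}")


def smd_se(d: float, n_per_group: int) -> float:
    """Large-sample SE of an SMD from two equal groups of size n."""
    n = n_per_group
    return float(np.sqrt(2.0 / n + d ** 2 / (4.0 * n)))


def _draw_outcome(rng: np.random.Generator, theta: float,
                  n: int) -> EffectEstimate:
    # provisional SE at the true effect generates the estimate; the
    # emitted SE is re-evaluated at the observed SMD, as real
    # meta-analyses estimate the sampling variance from the observed d
    d = rng.normal(theta, smd_se(theta, n))
    return EffectEstimate(smd=float(d), se=smd_se(d, n), n_per_group=n)


def _summary(outs: list[EffectEstimate], model: str) -> EffectEstimate:
    d = np.array([o.smd for o in outs])
    v = np.array([o.se ** 2 for o in outs])
    w = 1.0 / v
    if model == "dl" and len(outs) > 1:
        mu_fe = np.sum(w * d) / np.sum(w)
        q = float(np.sum(w * (d - mu_fe) ** 2))
        c = np.sum(w) - np.sum(w ** 2) / np.sum(w)
        tau2 = max(0.0, (q - (len(outs) - 1)) / c) if c > 0 else 0.0
        w = 1.0 / (v + tau2)
    est = float(np.sum(w * d) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    z = norm.ppf(0.975)
    return EffectEstimate(smd=est, se=se, ci_low=est - z * se,
                          ci_high=est + z * se)


def _gen_study(rng: np.random.Generator, cfg: GeneratorConfig,
               theta_meta: float, study_id: str) -> StudyRecord:
    theta = rng.normal(theta_meta, cfg.within_tau)
    n = int(rng.integers(cfg.n_per_group[0], cfg.n_per_group[1] + 1))
    k = 1
    if rng.random() < cfg.multi_outcome_prob:
        k = int(rng.integers(cfg.outcomes_per_study[0],
                             cfg.outcomes_per_study[1] + 1))
    outcomes = [_draw_outcome(rng, theta, n) for _ in range(k)]
    population = "clinical" if rng.random() < cfg.clinical_prob else "healthy"
    dosing = ("multiple" if rng.random() < cfg.multiple_dose_prob
              else "single")
    year = int(rng.integers(cfg.year_range[0], cfg.year_range[1] + 1))
    return StudyRecord(study_id=study_id, outcomes=outcomes, year=year,
                       population=population, dosing=dosing)


def _study_survives(rng: np.random.Generator, cfg: GeneratorConfig,
                    study: StudyRecord) -> bool:
    if cfg.censor_prob == 0.0:
        return True
    crit = norm.ppf(1.0 - cfg.sig_alpha / 2.0)
    zs = np.array([abs(o.smd / o.se) for o in study.outcomes])
    significant = bool(np.median(zs) > crit)
    if significant:
        return True
    return rng.random() >= cfg.censor_prob


def generate_corpus(cfg: GeneratorConfig) -> Corpus:
    """Draw one full synthetic corpus; byte-stable for a given config."""
    root = np.random.SeedSequence(cfg.seed)
    meta_seeds = root.spawn(cfg.n_metas)
    studies: dict[str, StudyRecord] = {}
    study_order: list[str] = []   # candidates for cross-meta reuse
    metas: list[MetaAnalysisRecord] = []
    counter = 0

    for k, seq in enumerate(meta_seeds):
        rng = np.random.default_rng(seq)
        theta_k = rng.normal(cfg.mu, cfg.tau)
        n_studies = int(rng.integers(cfg.studies_per_meta[0],
                                     cfg.studies_per_meta[1] + 1))
        members: list[StudyRecord] = []
        member_ids: set[str] = set()
        for attempt in range(cfg.max_retries * n_studies):
            if len(members) == n_studies:
                break
            if (study_order and rng.random() < cfg.study_reuse_prob):
                sid = study_order[int(rng.integers(len(study_order)))]
                if sid not in member_ids:
                    members.append(studies[sid])
                    member_ids.add(sid)
                continue
            counter += 1
            st = _gen_study(rng, cfg, theta_k, f"study_{counter:04d}")
            if _study_survives(rng, cfg, st):
                members.append(st)
                member_ids.add(st.study_id)
        if len(members) < n_studies:
            raise RuntimeError(
                f"meta {k}: could not assemble {n_studies} surviving "
                f"studies within the retry cap (censor_prob="
                f"{cfg.censor_prob}); lower the censoring or raise "
                "max_retries")
        for st in members:
            if st.study_id not in studies:
                studies[st.study_id] = st
                study_order.append(st.study_id)
        all_outcomes = [o for st in members for o in st.outcomes]
        design = ("univariate" if rng.random() < cfg.univariate_prob
                  else "multivariate")
        metas.append(MetaAnalysisRecord(
            meta_id=f"meta_{k + 1:03d}",
            summary=_summary(all_outcomes, cfg.summary_model),
            study_ids=[st.study_id for st in members],
            label=f"synthetic meta-analysis {k + 1}",
            reverse_sign=False, sign_applied=False, design=design))

    corpus = Corpus(metas=metas, studies=studies,
                    load_report={"generator": asdict(cfg)})
    logger.info("generate_corpus: %d metas, %d unique studies",
                corpus.n_metas, corpus.n_unique_studies)
    return corpus


def write_fixture(cfg: GeneratorConfig, out_dir: str | Path
                  ) -> dict[str, Path]:
    """Emit a generated corpus in the tabular schema plus a manifest.

    Writes ``metas.csv``, ``studies.csv`` and ``manifest.json`` (the
    full config, so the fixture is regenerable) into ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    corpus = generate_corpus(cfg)
    mdf, sdf = corpus_to_frames(corpus)
    paths = {"metas": out / "metas.csv", "studies": out / "studies.csv",
             "manifest": out / "manifest.json"}
    mdf.to_csv(paths["metas"], index=False, float_format="%.17g")
    sdf.to_csv(paths["studies"], index=False, float_format="%.17g")
    manifest = {"config": asdict(cfg), "n_metas": corpus.n_metas,
                "n_unique_studies": corpus.n_unique_studies,
                "schema_version": 1}
    paths["manifest"].write_text(json.dumps(manifest, indent=2) + "\n")
    return paths
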