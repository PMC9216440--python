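"""Corpus data types and tabular I/O for meta-analysis audits.

The corpus is a collection of meta-analyses of standardized mean
differences (SMD; Cohen's d, Hedges' g and standardized mean change are
treated as one scale, with an optional free-text flavor preserved for
provenance).  Every effect estimate is resolved to (smd, se) form on
ingest: a missing standard error is reconstructed from the 95% confidence
interval, and meta-analyses whose source coded benefit as a negative
effect are sign-reversed so that positive SMDs always mean a beneficial
outcome.

Two delimited-text tables define the on-disk schema (comma for ``.csv``,
tab for ``.tsv``/``.txt``):

* study table: ``meta_id, study_id, year, smd, se, ci_low, ci_high,
  population, dosing``
* meta table: ``meta_id, label, smd, se, ci_low, ci_high, reverse_sign,
  design``

A study appearing in several meta-analyses (shared ``study_id``) is kept
once in a registry; per-study deduplication is the caller's handle on the
"unique studies" analyses.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

POPULATIONS = ("clinical", "healthy", "unknown")
DOSINGS = ("single", "multiple", "unknown")
DESIGNS = ("univariate", "multivariate")

STUDY_COLUMNS = [
    "meta_id", "study_id", "year", "smd", "se", "ci_low", "ci_high",
    "population", "dosing",
]
META_COLUMNS = [
    "meta_id", "label", "smd", "se", "ci_low", "ci_high", "reverse_sign",
    "design",
]

YEAR_RANGE = (1990, 2035)


class CorpusError(ValueError):
    """Raised for malformed corpus inputs; the message names the record."""


def se_from_ci(ci_low: float, ci_high: float, level: float = 0.95) -> float:
    """Standard error implied by a symmetric normal confidence interval.

    SE = (ci_high - ci_low) / (2 * z), with z the (1+level)/2 normal
    quantile (1.959964 at the default 95% level).
    """
    if not (0.0 < level < 1.0):
        raise CorpusError(f"confidence level must be in (0,1), got {level}")
    if not (np.isfinite(ci_low) and np.isfinite(ci_high)):
        raise CorpusError(
            f"non-finite confidence bounds ({ci_low}, {ci_high})")
    if not ci_low < ci_high:
        raise CorpusError(
            f"inverted or degenerate confidence interval ({ci_low}, {ci_high})")
    z = norm.ppf(0.5 + level / 2.0)
    return (ci_high - ci_low) / (2.0 * z)


@dataclass
class EffectEstimate:
    """One SMD with its uncertainty.

    ``se`` may be absent on construction if a CI is supplied; ``resolve``
    fills it in.  ``n_per_group`` is optional provenance (used by the
    synthetic generator; real extractions rarely have it).
    """

    smd: float
    se: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    flavor: Optional[str] = None
    n_per_group: Optional[int] = None

    def resolve(self, level: float = 0.95, context: str = "") -> "EffectEstimate":
        """Return a copy with ``se`` populated, from the CI if needed."""
        se = self.se
        if se is None or not np.isfinite(se):
            if self.ci_low is None or self.ci_high is None:
                raise CorpusError(
                    f"effect estimate {context or repr(self)} has neither "
                    "a standard error nor a confidence interval")
            se = se_from_ci(self.ci_low, self.ci_high, level)
        if not se > 0:
            raise CorpusError(
                f"effect estimate {context or repr(self)} has "
                f"non-positive standard error {se}")
        if self.ci_low is not None and self.ci_high is not None:
            if not self.ci_low < self.ci_high:
                raise CorpusError(
                    f"effect estimate {context or repr(self)} has an "
                    f"inverted CI ({self.ci_low}, {self.ci_high})")
        return replace(self, se=float(se))

    @property
    def z(self) -> float:
        if self.se is None:
            raise CorpusError("estimate not resolved; call resolve() first")
        return self.smd / self.se

    def negated(self) -> "EffectEstimate":
        """Flip the direction convention: negate smd, swap CI bounds."""
        lo = None if self.ci_high is None else -self.ci_high
        hi = None if self.ci_low is None else -self.ci_low
        return replace(self, smd=-self.smd, ci_low=lo, ci_high=hi)


@dataclass
class StudyRecord:
    study_id: str
    outcomes: list[EffectEstimate]
    year: Optional[int] = None
    population: str = "unknown"
    dosing: str = "unknown"

    def __post_init__(self) -> None:
        if len(self.outcomes) < 1:
            raise CorpusError(f"study {self.study_id} has no outcomes")
        if self.population not in POPULATIONS:
            raise CorpusError(
                f"study {self.study_id}: unknown population "
                f"{self.population!r}")
        if self.dosing not in DOSINGS:
            raise CorpusError(
                f"study {self.study_id}: unknown dosing {self.dosing!r}")
        if self.year is not None and not (
                YEAR_RANGE[0] <= self.year <= YEAR_RANGE[1]):
            logger.warning(
                "study %s: implausible publication year %s",
                self.study_id, self.year)


@dataclass
class MetaAnalysisRecord:
    meta_id: str
    summary: EffectEstimate
    study_ids: list[str]
    label: str = ""
    reverse_sign: bool = False
    sign_applied: bool = False
    design: str = "univariate"

    def __post_init__(self) -> None:
        if len(self.study_ids) < 1:
            raise CorpusError(f"meta-analysis {self.meta_id} has no studies")
        if self.design not in DESIGNS:
            raise CorpusError(
                f"meta-analysis {self.meta_id}: unknown design "
                f"{self.design!r}")


@dataclass
class Corpus:
    metas: list[MetaAnalysisRecord]
    studies: dict[str, StudyRecord]
    load_report: dict = field(default_factory=dict)

    @property
    def n_metas(self) -> int:
        return len(self.metas)

    @property
    def n_unique_studies(self) -> int:
        return len(self.studies)

    def meta_studies(self, meta: MetaAnalysisRecord) -> list[StudyRecord]:
        return [self.studies[sid] for sid in meta.study_ids]

    def get_meta(self, meta_id: str) -> MetaAnalysisRecord:
        for m in self.metas:
            if m.meta_id == meta_id:
                return m
        raise KeyError(meta_id)


def apply_sign_convention(meta: MetaAnalysisRecord,
                          studies: Optional[dict[str, StudyRecord]] = None,
                          reversed_ids: Optional[set[str]] = None
                          ) -> MetaAnalysisRecord:
    """Apply a meta-analysis' sign-reversal flag, once.

    If ``reverse_sign`` is set and not yet applied, the summary estimate
    and (when ``studies`` is given) every member outcome are negated —
    smd flips sign, CI bounds swap and flip, SE unchanged.  Re-applying
    to an already-normalized record is a no-op; the negation itself is an
    involution on the numeric fields.  Member studies are mutated in
    place in the registry; ``reversed_ids`` (shared across calls) keeps a
    study that belongs to several reversed meta-analyses from being
    negated twice.
    """
    if not meta.reverse_sign or meta.sign_applied:
        return meta
    if studies is not None:
        for sid in meta.study_ids:
            if reversed_ids is not None:
                if sid in reversed_ids:
                    continue
                reversed_ids.add(sid)
            st = studies[sid]
            st.outcomes = [o.negated() for o in st.outcomes]
    return replace(meta, summary=meta.summary.negated(), sign_applied=True)


# ---------------------------------------------------------------------------
# tabular I/O

def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".txt", ".tab"} else ","


def _opt_float(v) -> Optional[float]:
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return float(v)


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    if isinstance(v, (int, np.integer, float)):
        return bool(int(v))
    return str(v).strip().lower() in {"true", "1", "yes", "y"}


def read_corpus(meta_path: str | Path, study_path: str | Path,
                ci_level: float = 0.95) -> Corpus:
    """Read and normalize a corpus from the two-table schema.

    All estimates are resolved to SE form (CI fallback), the sign
    convention is applied, and studies shared between meta-analyses are
    merged into a single registry entry.  A load report (row counts,
    CI conversions, reversals) is attached to the returned corpus and
    logged.
    """
    meta_path, study_path = Path(meta_path), Path(study_path)
    mdf = pd.read_csv(meta_path, sep=_sep_for(meta_path),
                      float_precision="round_trip")
    sdf = pd.read_csv(study_path, sep=_sep_for(study_path),
                      float_precision="round_trip")
    for cols, df, name in ((META_COLUMNS, mdf, meta_path.name),
                           (STUDY_COLUMNS, sdf, study_path.name)):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise CorpusError(f"{name}: missing required columns {missing}")

    n_ci_conversions = 0
    studies: dict[str, StudyRecord] = {}
    meta_members: dict[str, list[str]] = {}

    for idx, row in sdf.iterrows():
        sid = str(row["study_id"])
        mid = str(row["meta_id"])
        se = _opt_float(row["se"])
        est = EffectEstimate(
            smd=float(row["smd"]), se=se,
            ci_low=_opt_float(row["ci_low"]),
            ci_high=_opt_float(row["ci_high"]),
            flavor=str(row["flavor"]) if "flavor" in sdf.columns
            and not pd.isna(row.get("flavor")) else None,
            n_per_group=int(row["n_per_group"]) if "n_per_group" in sdf.columns
            and not pd.isna(row.get("n_per_group")) else None,
        )
        if se is None or not np.isfinite(se):
            n_ci_conversions += 1
        est = est.resolve(ci_level,
                          context=f"{study_path.name} row {idx} "
                                  f"(study {sid}, meta {mid})")
        year = row["year"]
        year = None if pd.isna(year) else int(year)
        pop = str(row["population"]) if not pd.isna(row["population"]) else "unknown"
        dos = str(row["dosing"]) if not pd.isna(row["dosing"]) else "unknown"
        if sid in studies:
            st = studies[sid]
            # same study contributed by another meta or another outcome row
            if not any(np.isclose(o.smd, est.smd) and np.isclose(o.se, est.se)
                       for o in st.outcomes):
                st.outcomes.append(est)
        else:
            studies[sid] = StudyRecord(
                study_id=sid, outcomes=[est], year=year,
                population=pop, dosing=dos)
        meta_members.setdefault(mid, [])
        if sid not in meta_members[mid]:
            meta_members[mid].append(sid)

    metas: list[MetaAnalysisRecord] = []
    n_reversed = 0
    reversed_ids: set[str] = set()
    for idx, row in mdf.iterrows():
        mid = str(row["meta_id"])
        se = _opt_float(row["se"])
        summ = EffectEstimate(
            smd=float(row["smd"]), se=se,
            ci_low=_opt_float(row["ci_low"]),
            ci_high=_opt_float(row["ci_high"]))
        if se is None or not np.isfinite(se):
            n_ci_conversions += 1
        summ = summ.resolve(ci_level,
                            context=f"{meta_path.name} row {idx} (meta {mid})")
        members = meta_members.get(mid)
        if not members:
            raise CorpusError(
                f"{meta_path.name} row {idx}: meta-analysis {mid} has no "
                f"member studies in {study_path.name}")
        design = str(row["design"]) if not pd.isna(row["design"]) else "univariate"
        meta = MetaAnalysisRecord(
            meta_id=mid, summary=summ, study_ids=members,
            label=str(row["label"]) if not pd.isna(row["label"]) else "",
            reverse_sign=_parse_bool(row["reverse_sign"]), design=design)
        if meta.reverse_sign:
            n_reversed += 1
            meta = apply_sign_convention(meta, studies, reversed_ids)
        metas.append(meta)
    shared_mixed = reversed_ids & {
        sid for m in metas if not m.reverse_sign for sid in m.study_ids}
    if shared_mixed:
        logger.warning(
            "studies %s are shared between reversed and non-reversed "
            "meta-analyses; their outcomes follow the reversed convention",
            sorted(shared_mixed))

    report = {
        "n_metas": len(metas),
        "n_unique_studies": len(studies),
        "n_study_rows": int(len(sdf)),
        "n_ci_conversions": n_ci_conversions,
        "n_sign_reversed": n_reversed,
    }
    logger.info("read_corpus: %s", json.dumps(report))
    return Corpus(metas=metas, studies=studies, load_report=report)


def corpus_to_frames(corpus: Corpus) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalized meta and study tables for the corpus (schema order)."""
    mrows = []
    for m in corpus.metas:
        mrows.append({
            "meta_id": m.meta_id, "label": m.label,
            "smd": m.summary.smd, "se": m.summary.se,
            "ci_low": m.summary.ci_low, "ci_high": m.summary.ci_high,
            "reverse_sign": m.reverse_sign, "design": m.design,
        })
    srows = []
    for m in corpus.metas:
        for sid in m.study_ids:
            st = corpus.studies[sid]
            for o in st.outcomes:
                srows.append({
                    "meta_id": m.meta_id, "study_id": st.study_id,
                    "year": st.year, "smd": o.smd, "se": o.se,
                    "ci_low": o.ci_low, "ci_high": o.ci_high,
                    "population": st.population, "dosing": st.dosing,
                    "n_per_group": o.n_per_group,
                })
    return (pd.DataFrame(mrows, columns=META_COLUMNS),
            pd.DataFrame(srows, columns=STUDY_COLUMNS + ["n_per_group"]))


def write_corpus(corpus: Corpus, meta_path: str | Path,
                 study_path: str | Path) -> None:
    """Write the normalized corpus back in the input schema.

    Already-applied sign reversals are written with ``reverse_sign`` set
    to False so a re-read does not reverse twice (round-trip identity on
    the numeric fields).
    """
    meta_path, study_path = Path(meta_path), Path(study_path)
    mdf, sdf = corpus_to_frames(corpus)
    mdf = mdf.copy()
    mdf["reverse_sign"] = False
    mdf.to_csv(meta_path, sep=_sep_for(meta_path), index=False,
               float_format="%.17g")
    sdf.to_csv(study_path, sep=_sep_for(study_path), index=False,
               float_format="%.17g")
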