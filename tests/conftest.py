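import textwrap

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from metaudit.data_model import (Corpus, EffectEstimate, MetaAnalysisRecord,
                                 StudyRecord)
from metaudit.synthetic import GeneratorConfig, generate_corpus


@pytest.fixture
def tiny_tables(tmp_path):
    """Hand-written two-meta / three-study corpus in the tabular schema.

    study s2 is shared between the two meta-analyses; study s3 carries
    only a confidence interval (SE must be reconstructed) and two
    outcome rows.
    """
    metas = textwrap.dedent("""\
        meta_id,label,smd,se,ci_low,ci_high,reverse_sign,design
        m1,first synthetic meta,0.30,0.10,,,false,univariate
        m2,second synthetic meta,-0.20,,-0.55,0.15,true,multivariate
        """)
    studies = textwrap.dedent("""\
        meta_id,study_id,year,smd,se,ci_low,ci_high,population,dosing
        m1,s1,2012,0.50,0.25,,,clinical,single
        m1,s2,2014,0.10,0.20,,,healthy,multiple
        m2,s2,2014,0.10,0.20,,,healthy,multiple
        m2,s3,2016,0.40,,0.01,0.79,clinical,multiple
        m2,s3,2016,0.20,0.30,,,clinical,multiple
        """)
    mp, sp = tmp_path / "metas.csv", tmp_path / "studies.csv"
    mp.write_text(metas)
    sp.write_text(studies)
    return mp, sp


def make_meta(meta_id, summary_smd, summary_se, study_specs,
              design="univariate"):
    """Assemble a small in-memory corpus fragment.

    ``study_specs`` is a list of (study_id, [(smd, se), ...]) pairs.
    Returns (MetaAnalysisRecord, {study_id: StudyRecord}).
    """
    studies = {}
    for sid, outcomes in study_specs:
        studies[sid] = StudyRecord(
            study_id=sid,
            outcomes=[EffectEstimate(smd=d, se=s) for d, s in outcomes])
    meta = MetaAnalysisRecord(
        meta_id=meta_id,
        summary=EffectEstimate(smd=summary_smd, se=summary_se),
        study_ids=list(studies), design=design)
    return meta, studies


def corpus_of(*meta_study_pairs):
    metas, studies = [], {}
    for meta, sts in meta_study_pairs:
        metas.append(meta)
        studies.update(sts)
    return Corpus(metas=metas, studies=studies)


@pytest.fixture(scope="session")
def small_synthetic_corpus():
    """A default-condition synthetic corpus shared across tests."""
    return generate_corpus(GeneratorConfig(seed=20250927))
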