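import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metaudit.data_model import (CorpusError, EffectEstimate,
                                 MetaAnalysisRecord, StudyRecord,
                                 apply_sign_convention, corpus_to_frames,
                                 read_corpus, se_from_ci, write_corpus)

Z975 = 1.959963984540054


class TestSeFromCi:
    @pytest.mark.parametrize("lo, hi, expected", [
        (-1.959964, 1.959964, 1.0),
        (0.05, 0.45, 0.10204),
    ])
    def test_known_values(self, lo, hi, expected):
        assert se_from_ci(lo, hi) == pytest.approx(expected, abs=5e-6)

    @pytest.mark.parametrize("lo, hi", [
        (0.0, 0.0),           # degenerate
        (0.5, 0.1),           # inverted
        (float("nan"), 1.0),  # non-finite
        (0.0, float("inf")),
    ])
    def test_rejects_bad_intervals(self, lo, hi):
        with pytest.raises(CorpusError):
            se_from_ci(lo, hi)

    def test_rejects_bad_level(self):
        with pytest.raises(CorpusError):
            se_from_ci(0.0, 1.0, level=1.5)

    @settings(max_examples=200, deadline=None)
    @given(mid=st.floats(-2, 2), half=st.floats(0.01, 3),
           level=st.floats(0.5, 0.999))
    def test_ci_reconstruction_roundtrip(self, mid, half, level):
        """Rebuilding the CI from (midpoint, se) recovers the bounds."""
        from scipy.stats import norm
        se = se_from_ci(mid - half, mid + half, level)
        z = norm.ppf(0.5 + level / 2)
        assert mid - z * se == pytest.approx(mid - half, abs=1e-9)
        assert mid + z * se == pytest.approx(mid + half, abs=1e-9)


class TestEffectEstimate:
    def test_resolve_from_ci(self):
        est = EffectEstimate(smd=0.25, ci_low=0.05, ci_high=0.45).resolve()
        assert est.se == pytest.approx(0.4 / (2 * Z975))

    def test_resolve_keeps_explicit_se(self):
        est = EffectEstimate(smd=0.25, se=0.3, ci_low=0.0, ci_high=0.5)
        assert est.resolve().se == 0.3

    def test_resolve_without_any_uncertainty_names_record(self):
        with pytest.raises(CorpusError, match="row 7"):
            EffectEstimate(smd=0.1).resolve(context="row 7")

    def test_nonpositive_se_rejected(self):
        with pytest.raises(CorpusError):
            EffectEstimate(smd=0.1, se=0.0).resolve()


class TestSignConvention:
    def _meta(self, smd=-0.3, ci=(-0.5, -0.1), flag=True):
        summary = EffectEstimate(smd=smd, se=0.1, ci_low=ci[0], ci_high=ci[1])
        study = StudyRecord(study_id="s1",
                            outcomes=[EffectEstimate(smd=-0.2, se=0.15)])
        meta = MetaAnalysisRecord(meta_id="m1", summary=summary,
                                  study_ids=["s1"], reverse_sign=flag)
        return meta, {"s1": study}

    def test_reversal_negates_and_swaps_ci(self):
        meta, studies = self._meta()
        out = apply_sign_convention(meta, studies)
        assert out.summary.smd == 0.3
        assert out.summary.se == 0.1
        assert (out.summary.ci_low, out.summary.ci_high) == (0.1, 0.5)
        assert studies["s1"].outcomes[0].smd == 0.2
        assert out.sign_applied

    def test_flag_false_is_identity(self):
        meta, studies = self._meta(flag=False)
        out = apply_sign_convention(meta, studies)
        assert out is meta

    def test_applied_flag_makes_idempotent(self):
        meta, studies = self._meta()
        once = apply_sign_convention(meta, studies)
        twice = apply_sign_convention(once, studies)
        assert twice.summary.smd == once.summary.smd
        assert studies["s1"].outcomes[0].smd == 0.2

    @given(smd=st.floats(-3, 3), lo=st.floats(-3, 0), width=st.floats(0.1, 2))
    def test_negation_is_involution(self, smd, lo, width):
        est = EffectEstimate(smd=smd, se=0.1, ci_low=lo, ci_high=lo + width)
        back = est.negated().negated()
        assert back.smd == est.smd
        assert back.ci_low == est.ci_low and back.ci_high == est.ci_high


class TestReadCorpus:
    def test_counts_and_dedup(self, tiny_tables):
        corpus = read_corpus(*tiny_tables)
        assert corpus.n_metas == 2
        assert corpus.n_unique_studies == 3  # s2 shared between m1 and m2
        assert corpus.load_report["n_ci_conversions"] == 2  # m2 + s3 row

    def test_sign_reversal_applied_on_ingest(self, tiny_tables):
        corpus = read_corpus(*tiny_tables)
        m2 = corpus.get_meta("m2")
        assert m2.summary.smd == pytest.approx(0.20)
        assert (m2.summary.ci_low, m2.summary.ci_high) == (-0.15, 0.55)
        # member outcomes reversed too (s3 had two rows -> two outcomes)
        s3 = corpus.studies["s3"]
        assert sorted(o.smd for o in s3.outcomes) == [-0.4, -0.2]

    def test_ci_fallback_resolves_se(self, tiny_tables):
        corpus = read_corpus(*tiny_tables)
        s3 = corpus.studies["s3"]
        ses = sorted(o.se for o in s3.outcomes)
        assert ses[0] == pytest.approx(0.78 / (2 * Z975))
        assert ses[1] == 0.30

    def test_row_without_uncertainty_is_named(self, tiny_tables, tmp_path):
        mp, sp = tiny_tables
        bad = sp.read_text().replace("m1,s1,2012,0.50,0.25,,",
                                     "m1,s1,2012,0.50,,,")
        sp2 = tmp_path / "bad_studies.csv"
        sp2.write_text(bad)
        with pytest.raises(CorpusError, match="row 0"):
            read_corpus(mp, sp2)

    def test_missing_column_rejected(self, tiny_tables, tmp_path):
        mp, sp = tiny_tables
        df = pd.read_csv(sp).drop(columns=["population"])
        sp2 = tmp_path / "nocol.csv"
        df.to_csv(sp2, index=False)
        with pytest.raises(CorpusError, match="population"):
            read_corpus(mp, sp2)

    def test_roundtrip_identity(self, tiny_tables, tmp_path):
        corpus = read_corpus(*tiny_tables)
        mp2, sp2 = tmp_path / "m2.csv", tmp_path / "s2.csv"
        write_corpus(corpus, mp2, sp2)
        again = read_corpus(mp2, sp2)
        assert again.n_metas == corpus.n_metas
        assert again.n_unique_studies == corpus.n_unique_studies
        for m1, m2 in zip(corpus.metas, again.metas):
            assert m2.summary.smd == pytest.approx(m1.summary.smd)
            assert m2.summary.se == pytest.approx(m1.summary.se)
            assert m2.study_ids == m1.study_ids
        for sid, st1 in corpus.studies.items():
            st2 = again.studies[sid]
            assert [o.smd for o in st2.outcomes] == pytest.approx(
                [o.smd for o in st1.outcomes])
            assert [o.se for o in st2.outcomes] == pytest.approx(
                [o.se for o in st1.outcomes])

    def test_frames_cover_all_memberships(self, tiny_tables):
        corpus = read_corpus(*tiny_tables)
        _, sdf = corpus_to_frames(corpus)
        # s2 appears under both metas; s3 twice under m2
        assert len(sdf) == 5
        assert set(sdf["meta_id"]) == {"m1", "m2"}
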