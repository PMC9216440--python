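import itertools

import numpy as np
import pytest

from conftest import corpus_of, make_meta
from metaudit.data_model import EffectEstimate
from metaudit.excess_significance import (TesConfig, poisson_binomial_tail,
                                          study_significant, tes, tes_screen)
from metaudit.power import wald_power
from metaudit.synthetic import GeneratorConfig, generate_corpus


def brute_force_tail(powers, observed):
    """Tail P(X >= observed) by explicit enumeration of all outcomes."""
    total = 0.0
    for bits in itertools.product([0, 1], repeat=len(powers)):
        if sum(bits) >= observed:
            prob = 1.0
            for p, b in zip(powers, bits):
                prob *= p if b else (1.0 - p)
            total += prob
    return total


class TestStudySignificant:
    @pytest.mark.parametrize("smd, se, expected", [
        (0.4, 0.1, True),              # z = 4
        (0.1, 0.1, False),             # z = 1
        (1.959965 * 0.1, 0.1, True),   # just over the boundary
    ])
    def test_wald_criterion(self, smd, se, expected):
        assert study_significant(EffectEstimate(smd=smd, se=se)) is expected


class TestPoissonBinomialTail:
    def test_matches_enumeration(self):
        rng = np.random.default_rng(17)
        for n in range(2, 13):
            powers = rng.uniform(0.05, 0.95, size=n)
            for obs in (0, 1, n // 2, n - 1, n):
                assert poisson_binomial_tail(powers, obs) == pytest.approx(
                    brute_force_tail(powers, obs), abs=1e-10)

    def test_homogeneous_reduces_to_binomial(self):
        from scipy.stats import binom
        assert poisson_binomial_tail(np.full(10, 0.5), 9) == pytest.approx(
            binom.sf(8, 10, 0.5), abs=1e-12)


def _uniform_power_meta(n=10, n_sig=9, theta=0.4):
    """Meta whose studies all have Wald power 1/2 at the summary effect.

    se = theta / z_crit makes wald_power(theta, se) = 0.5 (+ a negligible
    lower-tail term); the first ``n_sig`` studies carry |z| > z_crit.
    """
    se = theta / 1.959963984540054
    specs = []
    for i in range(n):
        smd = (theta + 3 * se) if i < n_sig else 0.0
        specs.append((f"s{i}", [(smd, se)]))
    return make_meta("m", theta, 0.01, specs)


class TestTes:
    def test_chi_square_form_known_case(self):
        meta, studies = _uniform_power_meta()
        corpus = corpus_of((meta, studies))
        r = tes(meta, corpus, TesConfig(form="chi_square"))
        assert r.observed == 9
        assert r.expected == pytest.approx(5.0, abs=1e-3)
        assert r.statistic == pytest.approx(6.4, abs=0.01)
        assert r.p == pytest.approx(0.0057, abs=3e-4)
        assert r.flagged

    def test_exact_form_known_case(self):
        meta, studies = _uniform_power_meta()
        corpus = corpus_of((meta, studies))
        r = tes(meta, corpus, TesConfig(form="exact"))
        assert r.p == pytest.approx(0.0107, abs=2e-4)
        assert r.flagged

    def test_observed_equals_expected_not_flagged(self):
        meta, studies = _uniform_power_meta(n=10, n_sig=5)
        corpus = corpus_of((meta, studies))
        r = tes(meta, corpus)
        assert r.observed == 5
        assert r.statistic == pytest.approx(0.0, abs=1e-3)
        assert not r.flagged

    def test_saturated_meta_degenerates_to_exact(self):
        # every study overwhelmingly powered and significant: no excess
        specs = [(f"s{i}", [(2.0, 0.1)]) for i in range(5)]
        meta, studies = make_meta("m", 2.0, 0.05, specs)
        corpus = corpus_of((meta, studies))
        r = tes(meta, corpus)
        assert r.form == "exact"
        assert r.observed == r.n
        assert not r.flagged

    def test_multi_outcome_median_rule(self):
        # median |z| of (4, 1, 0.5) is 1 -> not significant under the
        # median rule, significant under the any rule
        specs = [("s0", [(0.4, 0.1), (0.1, 0.1), (0.05, 0.1)]),
                 ("s1", [(0.5, 0.1)])]
        meta, studies = make_meta("m", 0.2, 0.05, specs)
        corpus = corpus_of((meta, studies))
        assert tes(meta, corpus, TesConfig(outcome_rule="median")).observed == 1
        assert tes(meta, corpus, TesConfig(outcome_rule="any")).observed == 2

    def test_fixed_reference_effect(self):
        meta, studies = _uniform_power_meta()
        corpus = corpus_of((meta, studies))
        r = tes(meta, corpus, TesConfig(reference=0.0))
        assert r.expected == pytest.approx(0.05 * 10)

    def test_single_study_meta_rejected(self):
        meta, studies = make_meta("m", 0.1, 0.1, [("s0", [(0.1, 0.2)])])
        with pytest.raises(ValueError):
            tes(meta, corpus_of((meta, studies)))

    def test_forms_usually_agree_on_flags(self):
        """Chi-square and exact decisions coincide for moderate E/n."""
        rng = np.random.default_rng(23)
        agree = 0
        trials = 200
        for _ in range(trials):
            n = int(rng.integers(10, 20))
            powers = rng.uniform(0.2, 0.8, size=n)
            observed = int(rng.integers(0, n + 1))
            expected = powers.sum()
            # chi-square decision
            dev = observed - expected
            a = dev ** 2 / expected + dev ** 2 / (n - expected)
            from scipy.stats import chi2
            p_chi = (chi2.sf(a, 1) / 2 if observed > expected
                     else 1 - chi2.sf(a, 1) / 2)
            flag_chi = p_chi < 0.05 and observed > expected
            p_ex = poisson_binomial_tail(powers, observed)
            flag_ex = p_ex < 0.05 and observed > expected
            agree += flag_chi == flag_ex
        assert agree / trials >= 0.95


class TestTesScreen:
    def test_only_univariate_metas_screened(self):
        m1 = make_meta("u1", 0.2, 0.1,
                       [("a", [(0.2, 0.2)]), ("b", [(0.3, 0.2)])],
                       design="univariate")
        m2 = make_meta("mv", 0.2, 0.1,
                       [("c", [(0.2, 0.2)]), ("d", [(0.3, 0.2)])],
                       design="multivariate")
        tab = tes_screen(corpus_of(m1, m2))
        assert list(tab["meta_id"]) == ["u1"]

    def test_empty_when_no_univariate(self, caplog):
        m = make_meta("mv", 0.2, 0.1,
                      [("c", [(0.2, 0.2)]), ("d", [(0.3, 0.2)])],
                      design="multivariate")
        with caplog.at_level("WARNING"):
            tab = tes_screen(corpus_of(m))
        assert tab.empty
        assert "no univariate" in caplog.text

    def test_censoring_inflates_flag_rate(self):
        """Publication-bias censoring raises the excess-significance rate."""
        base = dict(n_metas=120, univariate_prob=1.0, study_reuse_prob=0.0,
                    studies_per_meta=(4, 8), seed=99)
        cfg0 = GeneratorConfig(censor_prob=0.0, **base)
        cfg9 = GeneratorConfig(censor_prob=0.9, **base)
        rate0 = tes_screen(generate_corpus(cfg0),
                           TesConfig(form="exact"))["flagged"].mean()
        rate9 = tes_screen(generate_corpus(cfg9),
                           TesConfig(form="exact"))["flagged"].mean()
        assert rate9 > rate0
        assert rate0 <= 0.08
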