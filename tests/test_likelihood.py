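import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mixsim as mx
from mixsim.likelihood import AlleleAbsentError, locus_likelihood
from mixsim.study import _batch_locus_ratio
from oracles import brute_force_locus_likelihood

PARAMS = mx.LRParams()  # d_het=0.01, d_hom=0.0001, c=0
NO_DROPOUT = mx.LRParams(d_het=0.0, d_hom=0.0)
HALF = {"A": 0.5, "B": 0.5}


class TestLocusLikelihood:
    def test_full_match_no_dropout_needed(self):
        lik = locus_likelihood({"A", "B"}, [("A", "B")], 0, HALF, PARAMS)
        assert lik == pytest.approx(0.9801, abs=1e-12)  # (1 - d_het)^2

    def test_one_allele_must_drop_out(self):
        lik = locus_likelihood({"A"}, [("A", "B")], 0, HALF, PARAMS)
        assert lik == pytest.approx(0.99 * 0.01, abs=1e-12)

    def test_single_unknown_must_be_heterozygote(self):
        lik = locus_likelihood({"A", "B"}, [], 1, HALF, NO_DROPOUT)
        assert lik == pytest.approx(0.5, abs=1e-12)  # only AB explains both

    def test_likelihoods_bounded(self, rng):
        for _ in range(50):
            m = rng.integers(2, 5)
            p = rng.dirichlet(np.ones(m))
            freqs = {str(i): float(x) for i, x in enumerate(p)}
            obs = {str(i) for i in rng.choice(m, size=rng.integers(1, m + 1), replace=False)}
            lik = locus_likelihood(obs, [], 1, freqs, PARAMS)
            assert 0.0 <= lik <= 1.0

    def test_empty_observed_rejected(self):
        with pytest.raises(ValueError):
            locus_likelihood(set(), [], 1, HALF, PARAMS)

    def test_floor_policy_error_names_locus_and_allele(self):
        params = mx.LRParams(floor_policy="error")
        with pytest.raises(AlleleAbsentError, match="C.*absent.*TPOX"):
            locus_likelihood({"A", "C"}, [], 1, HALF, params, locus="TPOX")

    def test_floor_policy_floor_renormalises(self):
        lik = locus_likelihood({"C"}, [], 1, HALF, mx.LRParams(d_het=0.0, d_hom=0.0))
        # unknown must be C/C with floored renormalised frequency
        f = 1e-4 / (1.0 + 1e-4)
        assert lik == pytest.approx(f * f, rel=1e-12)

    def test_dropin_explains_unexplained_allele(self):
        params = mx.LRParams(d_het=0.0, d_hom=0.0, drop_in=0.05)
        lik = locus_likelihood({"A", "B"}, [("A", "A")], 0, HALF, params)
        assert lik == pytest.approx(0.05 * 0.5, abs=1e-15)

    def test_no_dropin_factor(self):
        params = mx.LRParams(d_het=0.0, d_hom=0.0, drop_in=0.05)
        lik = locus_likelihood({"A"}, [("A", "A")], 0, HALF, params)
        assert lik == pytest.approx(0.95, abs=1e-15)

    def test_raising_d_het_increases_dropout_profiles(self):
        """A profile requiring dropout becomes likelier as d_het rises."""
        liks = [
            locus_likelihood({"A"}, [("A", "B")], 0, HALF, mx.LRParams(d_het=d))
            for d in (0.01, 0.05, 0.2)
        ]
        assert liks == sorted(liks)


class TestBruteForceOracle:
    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=80)
    def test_matches_dropout_event_enumeration(self, seed):
        """Random loci (<=4 alleles, <=3 contributors, <=1 unknown): the
        per-allele factorisation equals a sum over all dropout events."""
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 5))
        labels = [str(i) for i in range(m)]
        p = rng.dirichlet(np.ones(m))
        freqs = dict(zip(labels, map(float, p)))
        n_contrib = int(rng.integers(1, 4))
        n_unknown = int(rng.integers(0, 2))
        n_known = n_contrib - n_unknown
        if n_known < 0:
            n_known = 0
        knowns = [
            tuple(sorted(rng.choice(labels, size=2))) for _ in range(n_known)
        ]
        pool = sorted({a for g in knowns for a in g} | set(labels[:2]))
        obs = set(rng.choice(pool, size=int(rng.integers(1, len(pool) + 1)), replace=False))
        params = mx.LRParams(
            d_het=float(rng.uniform(0.0, 0.3)),
            d_hom=float(rng.uniform(0.0, 0.05)),
            drop_in=float(rng.choice([0.0, 0.05])),
        )
        ours = locus_likelihood(obs, knowns, n_unknown, freqs, params)
        oracle = brute_force_locus_likelihood(
            obs, knowns, n_unknown, freqs, params.d_het, params.d_hom,
            params.drop_in, params.freq_floor,
        )
        assert ours == pytest.approx(oracle, rel=1e-12, abs=1e-300)

    def test_two_unknowns_supported(self):
        ours = locus_likelihood({"A", "B"}, [], 2, HALF, PARAMS)
        oracle = brute_force_locus_likelihood(
            {"A", "B"}, [], 2, HALF, PARAMS.d_het, PARAMS.d_hom
        )
        assert ours == pytest.approx(oracle, rel=1e-12)


class TestComputeLR:
    def test_single_source_heterozygote_closed_form(self):
        table = mx.FrequencyTable("g", 10, {"L": HALF})
        poi = mx.Genotype({"L": ("A", "B")})
        res = mx.compute_lr(mx.build_mixture([poi]), poi, [], table, NO_DROPOUT)
        assert res.lr == pytest.approx(2.0, rel=1e-12)  # 1/(2 p q)

    def test_single_source_homozygote_closed_form(self):
        table = mx.FrequencyTable("g", 10, {"L": {"A": 0.25, "B": 0.75}})
        poi = mx.Genotype({"L": ("A", "A")})
        res = mx.compute_lr(mx.build_mixture([poi]), poi, [], table, NO_DROPOUT)
        assert res.lr == pytest.approx(16.0, rel=1e-12)  # 1/p^2

    def test_monomorphic_locus_uninformative(self):
        table = mx.FrequencyTable("g", 10, {"L": {"A": 1.0}})
        poi = mx.Genotype({"L": ("A", "A")})
        res = mx.compute_lr(mx.build_mixture([poi]), poi, [], table, PARAMS)
        assert res.lr == 1.0

    def test_lr_is_product_of_locus_ratios(self, codis_table):
        rng = np.random.default_rng(3)
        contributors = [mx.sample_genotype(codis_table, rng) for _ in range(3)]
        mixture = mx.build_mixture(contributors)
        res = mx.compute_lr(
            mixture, contributors[0], contributors[1:], codis_table, PARAMS
        )
        assert res.lr == pytest.approx(
            math.prod(res.per_locus_ratios.values()), rel=1e-9
        )
        assert res.log10_lr == pytest.approx(math.log10(res.lr), rel=1e-9)

    def test_single_source_inverse_hwe_multi_locus(self, codis_table):
        """With no dropout/drop-in, single-source LR is the inverse HWE
        genotype probability at every locus."""
        rng = np.random.default_rng(9)
        poi = mx.sample_genotype(codis_table, rng)
        res = mx.compute_lr(mx.build_mixture([poi]), poi, [], codis_table, NO_DROPOUT)
        for locus, (a, b) in poi.alleles_by_locus.items():
            freqs = codis_table.loci[locus]
            prob = freqs[a] ** 2 if a == b else 2 * freqs[a] * freqs[b]
            assert res.per_locus_ratios[locus] == pytest.approx(1 / prob, rel=1e-9)

    def test_degenerate_both_zero_flagged(self):
        table = mx.FrequencyTable("g", 10, {"L": {"A": 0.25, "B": 0.25, "C": 0.25, "D": 0.25}})
        mixture = mx.MixtureProfile({"L": frozenset({"A", "B", "C", "D"})}, 2)
        poi = mx.Genotype({"L": ("A", "B")})
        known = mx.Genotype({"L": ("C", "C")})  # D unexplained under both
        res = mx.compute_lr(mixture, poi, [known], table, NO_DROPOUT)
        assert res.degenerate
        assert math.isnan(res.lr)
        assert not mx.classify(res.lr)

    def test_missing_locus_rejected(self, codis_table):
        mixture = mx.MixtureProfile({"NOPE": frozenset({"1"})}, 1)
        poi = mx.Genotype({"NOPE": ("1", "1")})
        with pytest.raises(KeyError):
            mx.compute_lr(mixture, poi, [], codis_table, PARAMS)


class TestClassify:
    @pytest.mark.parametrize(
        "lr,threshold,expected",
        [
            (1.0, 1.0, False),  # strict inequality
            (2.0, 1.0, True),
            (10.0, 100.0, False),
            (math.inf, 1.0, True),
        ],
    )
    def test_decision_rule(self, lr, threshold, expected):
        assert mx.classify(lr, threshold) is expected

    def test_negative_lr_rejected(self):
        with pytest.raises(ValueError):
            mx.classify(-0.5)


class TestBatchEngineEquivalence:
    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=80)
    def test_batch_ratio_equals_scalar_engine(self, seed):
        """The study's vectorised per-locus LR equals the scalar engine on
        identical genotypes (correct reference, drop-in 0)."""
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 7))
        labels = [str(i) for i in range(m)]
        p = rng.dirichlet(np.ones(m))
        freqs = dict(zip(labels, map(float, p)))
        k = int(rng.integers(1, 5))
        contrib = rng.integers(0, m, size=(1, k, 2))
        poi = contrib[:, 0, :] if rng.random() < 0.5 else rng.integers(0, m, size=(1, 2))
        ratio_batch = _batch_locus_ratio(contrib, poi, p, PARAMS.d_het, PARAMS.d_hom)[0]
        obs = {str(a) for a in contrib.reshape(-1)}
        knowns = [
            (str(contrib[0, j, 0]), str(contrib[0, j, 1])) for j in range(1, k)
        ]
        num = locus_likelihood(
            obs, knowns + [(str(poi[0, 0]), str(poi[0, 1]))], 0, freqs, PARAMS
        )
        den = locus_likelihood(obs, knowns, 1, freqs, PARAMS)
        assert ratio_batch == pytest.approx(num / den, rel=1e-9)
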