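"""Fisher enrichment, BH adjustment and the annotation node score theta."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biorank import (AnnotationCatalog, bh_adjust, compute_theta,
                     fisher_one_sided, select_significant_terms)


def exact_tail(k, K, n, N):
    """Independent oracle: exact integer enumeration of the hypergeometric
    upper tail P(X >= k)."""
    num = sum(math.comb(n, x) * math.comb(N - n, K - x)
              for x in range(k, min(K, n) + 1) if K - x <= N - n)
    return num / math.comb(N, K)


class TestFisherOneSided:
    def test_zero_overlap_gives_one(self):
        assert fisher_one_sided(0, 5, 5, 20) == 1.0

    def test_forced_total_overlap_gives_one(self):
        assert fisher_one_sided(10, 10, 10, 10) == pytest.approx(1.0)

    def test_enumeration_example(self):
        """k=4, K=5, n=5, N=20 against the explicit tail sum."""
        expected = exact_tail(4, 5, 5, 20)
        assert fisher_one_sided(4, 5, 5, 20) == pytest.approx(expected, rel=1e-12)
        # frozen value from the enumeration oracle
        assert expected == pytest.approx(
            (math.comb(5, 4) * math.comb(15, 1) + math.comb(5, 5)) / math.comb(20, 5))

    def test_random_tables_match_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            N = int(rng.integers(2, 61))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            lo, hi = max(0, n + K - N), min(K, n)
            k = int(rng.integers(lo, hi + 1))
            expected = exact_tail(k, K, n, N)
            assert fisher_one_sided(k, K, n, N) == pytest.approx(expected, rel=1e-10)

    def test_inconsistent_counts_error(self):
        with pytest.raises(ValueError):
            fisher_one_sided(6, 5, 10, 20)   # k > K
        with pytest.raises(ValueError):
            fisher_one_sided(6, 10, 5, 20)   # k > n
        with pytest.raises(ValueError):
            fisher_one_sided(1, 30, 5, 20)   # K > N


def step_up_oracle(p):
    """Textbook BH step-up: sort, p_(i) * m / i, cumulative min from the
    largest rank, undo the sort."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = float("inf")
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = min(running, 1.0)
    return adj


class TestBHAdjust:
    def test_single_p_is_identity(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_all_equal_unchanged(self):
        assert bh_adjust([0.2] * 5) == pytest.approx([0.2] * 5)

    def test_three_value_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx(
            step_up_oracle([0.01, 0.02, 0.03]))

    def test_empty_input(self):
        assert bh_adjust([]).size == 0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    def test_matches_step_up_oracle(self, p):
        assert bh_adjust(p) == pytest.approx(step_up_oracle(p), abs=1e-12)

    def test_matches_statsmodels(self):
        """Independent library cross-check on random vectors."""
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(1)
        for _ in range(50):
            p = rng.random(rng.integers(1, 60))
            ours = bh_adjust(p)
            theirs = multipletests(p, method="fdr_bh")[1]
            assert ours == pytest.approx(theirs, abs=1e-12)


def _catalog(**sources):
    return AnnotationCatalog(
        {s: {t: frozenset(g) for t, g in terms.items()}
         for s, terms in sources.items()})


class TestSelectSignificantTerms:
    def test_term_equal_to_seed_set_retained(self):
        """A term exactly matching the seeds in a 10x larger universe is
        significant at 0.05 (p checked against the enumeration oracle)."""
        universe = {f"g{i}" for i in range(50)}
        seeds = {f"g{i}" for i in range(5)}
        cat = _catalog(src={"hit": seeds, "miss": {f"g{i}" for i in range(40, 45)}})
        raw_p = exact_tail(5, 5, 5, 50)
        assert raw_p * 2 < 0.05  # survives BH over the 2-term family
        sig = select_significant_terms(cat, seeds, universe, level=0.05)
        assert ("src", "hit") in sig.union

    def test_term_disjoint_from_seeds_never_retained(self):
        universe = {f"g{i}" for i in range(30)}
        cat = _catalog(src={"t": {f"g{i}" for i in range(10, 20)}})
        sig = select_significant_terms(cat, {"g0", "g1"}, universe, level=0.999)
        rec = sig.records[0]
        assert rec.p == 1.0 and not rec.retained

    def test_level_zero_empties_f(self):
        universe = {f"g{i}" for i in range(50)}
        seeds = {f"g{i}" for i in range(5)}
        cat = _catalog(src={"hit": seeds})
        sig = select_significant_terms(cat, seeds, universe, level=0.0)
        assert sig.union == frozenset()

    def test_seedless_term_never_changes_f(self):
        universe = {f"g{i}" for i in range(60)}
        seeds = {f"g{i}" for i in range(6)}
        base = {"hit": seeds}
        with_noise = dict(base, noise={f"g{i}" for i in range(30, 50)})
        f1 = select_significant_terms(_catalog(src=base), seeds, universe,
                                      level=0.05).union
        f2 = select_significant_terms(_catalog(src=with_noise), seeds, universe,
                                      level=0.05).union
        assert f1 == f2

    def test_no_seeds_in_universe_errors(self):
        cat = _catalog(src={"t": {"g1"}})
        with pytest.raises(ValueError, match="seed"):
            select_significant_terms(cat, {"absent"}, {"g1", "g2"}, level=0.05)


class TestComputeTheta:
    def _setup(self):
        universe = {f"g{i}" for i in range(20)}
        seeds = {"g0", "g1"}
        cat = _catalog(
            s1={"a": {"g0", "g1", "g5"}, "b": {"g5", "g6"},
                "c": {"g7"}, "d": {"g8"}},
            s2={"x": {"g5", "g9"}, "y": {"g10"}},
        )
        return universe, seeds, cat

    def test_seed_gets_ell_and_nonseed_formula(self):
        universe, seeds, cat = self._setup()
        sig = select_significant_terms(cat, seeds, universe, level=2.0)
        # level > 1 retains everything: F1 has 4 terms, F2 has 2
        theta = compute_theta(cat, sig, seeds, universe, ell=1000.0)
        assert theta.values["g0"] == 1000.0
        # g5: in a, b of source1 (|F1|=4) and x of source2 (|F2|=2)
        assert theta.values["g5"] == pytest.approx(2 / 4 + 1 / 2)
        assert theta.values["g19"] == 0.0

    def test_seed_priority_bound(self):
        """max over non-seeds <= number of sources < ell = min over seeds."""
        universe, seeds, cat = self._setup()
        sig = select_significant_terms(cat, seeds, universe, level=2.0)
        theta = compute_theta(cat, sig, seeds, universe, ell=1000.0)
        non_seed_max = max(v for g, v in theta.values.items() if g not in seeds)
        assert non_seed_max <= cat.n_sources < 1000.0

    def test_ell_not_above_source_count_errors(self):
        universe, seeds, cat = self._setup()
        sig = select_significant_terms(cat, seeds, universe, level=2.0)
        with pytest.raises(ValueError, match="ell"):
            compute_theta(cat, sig, seeds, universe, ell=2.0)

    def test_empty_source_contributes_zero(self):
        universe, seeds, cat = self._setup()
        sig = select_significant_terms(cat, seeds, universe, level=0.0)
        theta = compute_theta(cat, sig, seeds, universe, ell=1000.0)
        assert all(theta.values[g] == 0.0 for g in universe - seeds)
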