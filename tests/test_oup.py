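"""Unit and property tests for the pattern-statistics core."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gisniffer import oup
from gisniffer.oup import (
    DegenerateCompositionError,
    IncompatiblePatternError,
    NormalizationScheme,
    SequenceTooShortError,
    compute_pattern,
    count_words,
    d_max,
    expected_counts,
    pattern_distance,
    pattern_skew,
    pattern_variance,
    ps_d_min,
    rv_grv,
    sigma0,
)

from _oracle import (
    delta_vector,
    distance as oracle_distance,
    ranks_of,
    revcomp,
    rv_grv_ratio as oracle_rv_grv,
    skew as oracle_skew,
    variance as oracle_variance,
)
from conftest import random_dna

dna = st.text(alphabet="ACGT", min_size=8, max_size=200)
seeded = settings(deadline=None, derandomize=True)


# ---------------------------------------------------------------------------
# word counting

@pytest.mark.parametrize(
    "seq,n,expected,w",
    [
        ("ACGTACGT", 4, {"ACGT": 2, "CGTA": 1, "GTAC": 1, "TACG": 1}, 5),
        ("AAAAA", 4, {"AAAA": 2}, 2),
        ("ACNGT", 2, {"AC": 1, "GT": 1}, 2),
        ("acgt", 2, {"AC": 1, "CG": 1, "GT": 1}, 3),
    ],
)
def test_count_words_examples(seq, n, expected, w):
    wc = count_words(seq, n)
    assert wc.counts == expected
    assert wc.W == w
    assert wc.array.sum() == w


def test_count_words_too_short():
    with pytest.raises(SequenceTooShortError):
        count_words("ACG", 4)


# ---------------------------------------------------------------------------
# expected counts

def test_expected_counts_uniform():
    wc = count_words("ACGTACGT", 4)
    exp = expected_counts(wc, NormalizationScheme.none())
    assert np.allclose(exp, 5 / 256)


def test_expected_counts_gc_half_equals_uniform():
    wc = oup.WordCounts(4, np.zeros(256, dtype=int), 0)
    wc.array[:] = 0
    wc.array[0] = 1000
    wc.W = 1000
    for scheme in (NormalizationScheme.gc_local(),
                   NormalizationScheme.gc_generalized(0.5)):
        exp = expected_counts(wc, scheme, gc=0.5)
        assert np.allclose(exp, 1000 * 0.25**4)


def test_expected_counts_gc_skewed():
    wc = oup.WordCounts(4, np.full(256, 1000 / 256), 1000)
    exp = expected_counts(wc, NormalizationScheme.gc_generalized(0.6))
    words = oup.all_words(4)
    assert exp[words.index("GGGG")] == pytest.approx(1000 * 0.3**4)
    assert exp[words.index("AAAA")] == pytest.approx(1000 * 0.2**4)


def test_expected_counts_degenerate_gc():
    wc = count_words("GGGGGGGG", 4)
    with pytest.raises(DegenerateCompositionError):
        expected_counts(wc, NormalizationScheme.gc_local(), gc=1.0)


def test_markov_expectation_consistency():
    # on a long random sequence, the order-1 expectation reproduces the
    # observed dinucleotide structure: deltas shrink vs the uniform scheme
    seq = random_dna(20_000, 5, gc=0.35)
    p_none = compute_pattern(seq, 4, NormalizationScheme.none())
    p_m1 = compute_pattern(seq, 4, NormalizationScheme.markov(1))
    assert (p_m1.delta**2).sum() < (p_none.delta**2).sum()


# ---------------------------------------------------------------------------
# patterns

def test_homopolymer_delta():
    p = compute_pattern("A" * 1000, 4)
    words = oup.all_words(4)
    aaaa = words.index("AAAA")
    assert p.delta[aaaa] == pytest.approx(255.0)
    others = np.delete(p.delta, aaaa)
    assert np.allclose(others, -1.0)


def test_uniform_counts_all_zero_delta():
    # every word of length 1 equally often
    p = compute_pattern("ACGT" * 100, 1)
    assert np.allclose(p.delta, 0.0)


def test_delta_sums_to_zero_unnormalized():
    p = compute_pattern(random_dna(5000, 3), 4)
    assert p.delta.sum() == pytest.approx(0.0, abs=1e-9)


@seeded
@given(dna)
def test_ranks_are_permutation(seq):
    p = compute_pattern(seq, 2)
    assert sorted(p.ranks.tolist()) == list(range(1, 17))


def test_delta_matches_oracle_on_synthetic_window():
    seq = random_dna(50_000, 9, gc=0.42)
    p = compute_pattern(seq, 4)
    oracle = delta_vector(seq, 4)
    mine = dict(zip(oup.all_words(4), p.delta))
    for w in oracle:
        assert mine[w] == pytest.approx(oracle[w], abs=1e-12)


# ---------------------------------------------------------------------------
# distance and skew

def test_distance_constants():
    assert d_max(4) == 32640
    assert ps_d_min(4) == 240
    assert ps_d_min(3) == 64


def test_distance_identity_and_symmetry():
    a = compute_pattern(random_dna(2000, 1), 4)
    b = compute_pattern(random_dna(2000, 2), 4)
    assert pattern_distance(a, a) == 0.0
    assert pattern_distance(a, b) == pattern_distance(b, a)
    assert pattern_distance(a, b) >= 0.0


def test_distance_rank_reversal_exceeds_100():
    # N=1: ranks (1,2,3,4) vs (4,3,2,1) -> sum 8, D_max 6 -> 133.33
    a = compute_pattern("A" * 10 + "C" * 8 + "G" * 6 + "T" * 4, 1)
    b = compute_pattern("A" * 4 + "C" * 6 + "G" * 8 + "T" * 10, 1)
    assert pattern_distance(a, b) == pytest.approx(100 * 8 / 6)


def test_distance_incompatible_word_lengths():
    with pytest.raises(IncompatiblePatternError):
        pattern_distance(compute_pattern("ACGTACGT", 2),
                         compute_pattern("ACGTACGT", 4))


def test_skew_palindromic_construction():
    # s + revcomp(s) is its own reverse complement: rank sum is exactly 0
    s = random_dna(5000, 7)
    sym = s + revcomp(s)
    ps = pattern_skew(sym, 4)
    assert ps == pytest.approx(100 * (0 - 240) / (32640 - 240))
    assert ps == pytest.approx(-0.7407, abs=1e-4)


def test_skew_purine_rich_exceeds_cutoff():
    rng = np.random.default_rng(13)
    seq = "".join("ACGT"[i] for i in rng.choice(4, 20_000, p=[0.4, 0.1, 0.4, 0.1]))
    assert pattern_skew(seq, 4) >= 55.0


@seeded
@given(dna)
def test_skew_strand_swap_invariant(seq):
    assert pattern_skew(seq, 2) == pytest.approx(pattern_skew(revcomp(seq), 2))


# ---------------------------------------------------------------------------
# variance

def test_sigma0_closed_form_and_monotone():
    assert sigma0(4, 8000) == pytest.approx(math.sqrt(0.052))
    assert sigma0(4, 8000) == pytest.approx(0.22804, abs=1e-5)
    lengths = [1000, 5000, 8000, 50_000, 1_000_000]
    values = [sigma0(4, L) for L in lengths]
    assert values == sorted(values, reverse=True)


def test_variance_zero_for_zero_delta():
    p = compute_pattern("ACGT" * 100, 1)
    assert pattern_variance(p) == pytest.approx(0.0)


def test_variance_matches_oracle():
    seq = random_dna(8000, 17, gc=0.4)
    p = compute_pattern(seq, 4)
    assert pattern_variance(p) == pytest.approx(oracle_variance(seq, 4), abs=1e-12)


# ---------------------------------------------------------------------------
# RV / GRV

def test_rv_grv_equal_when_gc_matches():
    seq = random_dna(8000, 23, gc=0.45)
    gc = oup.gc_fraction(seq)
    v = rv_grv(seq, gc)
    assert v.rv == pytest.approx(v.grv)
    assert v.grv_over_rv == pytest.approx(1.0)


def test_rv_grv_gc_shift_raises_ratio():
    # internally GC-typical window vs a strongly different reference GC:
    # local normalization absorbs the shift, the generalized one cannot
    seq = random_dna(8000, 29, gc=0.30)
    v = rv_grv(seq, 0.50)
    assert v.grv_over_rv > 1.0


@pytest.mark.parametrize("seed,gc,ref", [(1, 0.35, 0.5), (2, 0.5, 0.5), (3, 0.6, 0.42)])
def test_rv_grv_matches_oracle(seed, gc, ref):
    seq = random_dna(4000, seed, gc=gc)
    v = rv_grv(seq, ref)
    orv, ogrv, oratio = oracle_rv_grv(seq, 4, ref)
    assert v.rv == pytest.approx(orv, abs=1e-10)
    assert v.grv == pytest.approx(ogrv, abs=1e-10)
    assert v.grv_over_rv == pytest.approx(oratio, abs=1e-10)


# ---------------------------------------------------------------------------
# full oracle equivalence at small N

@seeded
@given(st.integers(1, 2), st.integers(0, 2**31 - 1))
def test_all_statistics_match_bruteforce(n, seed):
    rng = np.random.default_rng(seed)
    length = int(rng.integers(n + 5, 200))
    seq = "".join("ACGT"[i] for i in rng.choice(4, length))
    p = compute_pattern(seq, n)
    oracle_d = delta_vector(seq, n)
    mine = dict(zip(oup.all_words(n), p.delta))
    for w, v in oracle_d.items():
        assert mine[w] == pytest.approx(v, abs=1e-12)
    oracle_ranks = ranks_of(oracle_d)
    mine_ranks = dict(zip(oup.all_words(n), p.ranks))
    assert {w: int(r) for w, r in mine_ranks.items()} == oracle_ranks
    other = "".join("ACGT"[i] for i in rng.choice(4, length))
    q = compute_pattern(other, n)
    assert pattern_distance(p, q) == pytest.approx(
        oracle_distance(oracle_d, delta_vector(other, n), n), abs=1e-12
    )
    assert pattern_skew(seq, n) == pytest.approx(oracle_skew(seq, n), abs=1e-12)
    assert pattern_variance(p) == pytest.approx(oracle_variance(seq, n), abs=1e-12)
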