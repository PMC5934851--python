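"""Oligonucleotide usage pattern (OUP) statistics.

The compositional signature of a DNA segment is summarised as the vector of
deviations (``delta``) of observed word counts (tetranucleotides by default)
from the counts expected under a null model.  Horizontally acquired segments
carry their donor's signature and stand out against the host background.

This module implements the signature itself and the scalar statistics
derived from it:

* :func:`pattern_distance` (D) -- rank-based distance between two patterns,
  expressed as a percentage of a formula-defined maximum;
* :func:`pattern_skew` (PS) -- D between the patterns of the direct and
  reverse-complement strands of the same segment; high values mark
  strand-asymmetric loci such as rRNA operons;
* :func:`pattern_variance` (V) -- size of the deviation vector relative to
  the sampling spread expected for the segment length;
* :func:`rv_grv` (RV, GRV) -- V computed after normalising expected counts
  by the segment's own GC content (relative variance, RV) or by the GC
  content of a reference sequence (generalised relative variance, GRV).
  The ratio of the two flags segments whose atypicality is not explained by
  their GC content alone.

Words are indexed lexicographically over the alphabet ``ACGT`` throughout
(``A=0, C=1, G=2, T=3``); a word's index is its base-4 encoding, so
lexicographic order and numeric order coincide.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, Optional, Tuple

import numpy as np

ALPHABET = "ACGT"

#: Largest supported word length.  4**6 = 4096 words is the practical limit
#: for rank statistics on windows of a few kilobases.
MAX_WORD_LENGTH = 6

DEFAULT_WORD_LENGTH = 4


class OupError(ValueError):
    """Base class for pattern-statistics errors."""


class SequenceTooShortError(OupError):
    """The sequence is shorter than the word length (or a window bound)."""


class DegenerateSequenceError(OupError):
    """The sequence contains no countable word (all positions ambiguous)."""


class DegenerateCompositionError(OupError):
    """A GC fraction of exactly 0 or 1 makes the GC null model degenerate."""


class IncompatiblePatternError(OupError):
    """Two patterns with different word lengths cannot be compared."""


class DegenerateWindowError(OupError):
    """A variance of zero makes the RV/GRV ratio undefined."""


# ---------------------------------------------------------------------------
# encoding helpers

_CODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET):
    _CODE_TABLE[ord(_b)] = _i
    _CODE_TABLE[ord(_b.lower())] = _i

_DECODE_TABLE = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)


def encode_sequence(sequence: str) -> np.ndarray:
    """Map a nucleotide string to codes ``A,C,G,T -> 0..3`` (case folded).

    Any other symbol (ambiguity codes, gaps) maps to 255 and is treated as
    uncountable downstream.
    """
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _CODE_TABLE[raw]


def decode_codes(codes: np.ndarray) -> str:
    """Inverse of :func:`encode_sequence` for valid codes 0..3."""
    return _DECODE_TABLE[codes].tobytes().decode("ascii")


def word_codes(codes: np.ndarray, N: int) -> np.ndarray:
    """Base-4 index of every length-``N`` window of ``codes``.

    Windows containing a non-ACGT position get the sentinel value ``4**N``
    so that a single ``bincount`` can drop them.
    """
    n_words = codes.size - N + 1
    if n_words < 1:
        raise SequenceTooShortError(
            f"sequence of length {codes.size} is shorter than word length {N}"
        )
    valid = codes < 4
    wc = np.zeros(n_words, dtype=np.int64)
    ok = np.ones(n_words, dtype=bool)
    for i in range(N):
        sl_codes = codes[i : i + n_words]
        sl_valid = valid[i : i + n_words]
        wc = wc * 4 + np.where(sl_valid, sl_codes, 0)
        ok &= sl_valid
    wc[~ok] = 4**N
    return wc


def gc_fraction(sequence: str) -> float:
    """GC fraction among unambiguous (ACGT) bases."""
    codes = encode_sequence(sequence)
    valid = int((codes < 4).sum())
    if valid == 0:
        raise DegenerateSequenceError("sequence contains no unambiguous base")
    gc = int(((codes == 1) | (codes == 2)).sum())
    return gc / valid


@lru_cache(maxsize=None)
def all_words(N: int) -> Tuple[str, ...]:
    """All 4**N words in lexicographic order."""
    return tuple("".join(p) for p in itertools.product(ALPHABET, repeat=N))


@lru_cache(maxsize=None)
def _word_digits(N: int) -> np.ndarray:
    """(4**N, N) matrix of base-4 digits of each word index."""
    idx = np.arange(4**N)
    digits = np.empty((4**N, N), dtype=np.int64)
    for i in range(N):
        digits[:, N - 1 - i] = (idx >> (2 * i)) & 3
    return digits


@lru_cache(maxsize=None)
def gc_letter_counts(N: int) -> np.ndarray:
    """Number of G/C letters in each word, lexicographic order."""
    digits = _word_digits(N)
    return ((digits == 1) | (digits == 2)).sum(axis=1)


@lru_cache(maxsize=None)
def rc_permutation(N: int) -> np.ndarray:
    """Index permutation mapping each word to its reverse complement.

    The permutation is an involution, so ``counts[perm]`` is the count
    vector of the reverse-complement strand.
    """
    digits = _word_digits(N)
    rc_digits = 3 - digits[:, ::-1]
    weights = 4 ** np.arange(N - 1, -1, -1, dtype=np.int64)
    return rc_digits @ weights


def d_max(N: int) -> int:
    """Maximum rank-distance denominator: ``4**N * (4**N - 1) / 2``."""
    m = 4**N
    return m * (m - 1) // 2


def ps_d_min(N: int) -> int:
    """Baseline rank distance used for pattern skew.

    ``4**N - 2**N`` for even N (reverse-complement palindromic words exist
    and necessarily tie), ``4**N`` for odd N.
    """
    if N % 2 == 0:
        return 4**N - 2**N
    return 4**N


# ---------------------------------------------------------------------------
# domain types

@dataclass
class WordCounts:
    """Observed counts of all ``4**N`` words of a sequence.

    ``array`` is the full count vector in lexicographic word order; ``W``
    is the number of counted word positions (windows containing ambiguous
    bases are skipped and do not contribute to ``W``).
    """

    N: int
    array: np.ndarray
    W: int

    @property
    def counts(self) -> Dict[str, int]:
        """Non-zero counts as a word -> count mapping."""
        ws = all_words(self.N)
        return {ws[i]: int(c) for i, c in enumerate(self.array) if c}

    def gc_estimate(self) -> float:
        """GC fraction estimated from the counted words themselves.

        The mean GC of all counted words; for clean sequences it differs
        from the base-level GC only by edge effects of order N / L.
        """
        if self.W == 0:
            raise DegenerateSequenceError("no countable words")
        return float((self.array * gc_letter_counts(self.N)).sum()) / (self.W * self.N)

    def reverse_complement(self) -> "WordCounts":
        """Word counts of the reverse-complement strand."""
        return WordCounts(self.N, self.array[rc_permutation(self.N)], self.W)


@dataclass(frozen=True)
class NormalizationScheme:
    """How expected word counts are derived from a sequence.

    * ``none`` -- uniform expectation ``C_0 = W * 4**-N``;
    * ``gc_local`` -- zero-order model from the sequence's own GC;
    * ``gc_generalized`` -- zero-order model from a reference GC
      (``gc_reference``);
    * ``markov_k`` -- Markov chain of order ``k`` fitted to the sequence's
      own shorter-word frequencies.
    """

    tag: str
    k: Optional[int] = None
    gc_reference: Optional[float] = None

    _TAGS = ("none", "gc_local", "gc_generalized", "markov_k")

    def __post_init__(self) -> None:
        if self.tag not in self._TAGS:
            raise ValueError(f"unknown normalization tag {self.tag!r}")
        if self.tag == "markov_k":
            if self.k not in (1, 2):
                raise ValueError("Markov normalization supports order k in {1, 2}")
        elif self.k is not None:
            raise ValueError("k is only meaningful for markov_k")
        if self.tag == "gc_generalized":
            if self.gc_reference is None or not 0.0 < self.gc_reference < 1.0:
                raise DegenerateCompositionError(
                    "gc_generalized needs a reference GC strictly inside (0, 1)"
                )
        elif self.gc_reference is not None:
            raise ValueError("gc_reference is only meaningful for gc_generalized")

    # convenience constructors ------------------------------------------------
    @classmethod
    def none(cls) -> "NormalizationScheme":
        return cls("none")

    @classmethod
    def gc_local(cls) -> "NormalizationScheme":
        return cls("gc_local")

    @classmethod
    def gc_generalized(cls, gc_reference: float) -> "NormalizationScheme":
        return cls("gc_generalized", gc_reference=gc_reference)

    @classmethod
    def markov(cls, k: int) -> "NormalizationScheme":
        return cls("markov_k", k=k)


@dataclass
class OUPattern:
    """A usage pattern: deviation vector, its ranks and provenance metadata.

    ``delta`` holds one deviation per word in lexicographic order; ``ranks``
    is the permutation of 1..4**N obtained by sorting words by ascending
    delta (ties broken by lexicographic word order).
    """

    N: int
    delta: np.ndarray
    ranks: np.ndarray
    scheme: NormalizationScheme
    L_seq: int
    W: int
    gc: float


@dataclass(frozen=True)
class RelativeVariances:
    """Locally (RV) and globally (GRV) GC-normalised pattern variances."""

    rv: float
    grv: float

    @property
    def rv_over_grv(self) -> float:
        if self.grv == 0.0:
            raise DegenerateWindowError("GRV is zero; RV/GRV undefined")
        return self.rv / self.grv

    @property
    def grv_over_rv(self) -> float:
        if self.rv == 0.0:
            raise DegenerateWindowError("RV is zero; GRV/RV undefined")
        return self.grv / self.rv


# ---------------------------------------------------------------------------
# operations

def count_words(sequence: str, N: int = DEFAULT_WORD_LENGTH) -> WordCounts:
    """Count every length-``N`` window made solely of A/C/G/T (case folded).

    Windows containing any other symbol are skipped and do not increment
    ``W``.  Raises :class:`SequenceTooShortError` if the sequence is
    shorter than ``N``.
    """
    _check_n(N)
    codes = encode_sequence(sequence)
    return counts_from_codes(codes, N)


def counts_from_codes(codes: np.ndarray, N: int) -> WordCounts:
    wc = word_codes(codes, N)
    counts = np.bincount(wc, minlength=4**N + 1)[: 4**N]
    return WordCounts(N, counts, int(counts.sum()))


def _check_n(N: int) -> None:
    if not 1 <= N <= MAX_WORD_LENGTH:
        raise ValueError(f"word length must be in 1..{MAX_WORD_LENGTH}, got {N}")


def expected_counts(
    wc: WordCounts,
    scheme: NormalizationScheme,
    gc: Optional[float] = None,
) -> np.ndarray:
    """Expected count of every word under ``scheme``.

    For ``gc_local`` the GC fraction is taken from ``gc`` when supplied
    (e.g. the base-level GC of the source window) and otherwise estimated
    from the word counts themselves.  For ``gc_generalized`` the scheme's
    ``gc_reference`` is used.  The Markov expectation is the standard chain
    estimate from the empirical k-mer / (k+1)-mer frequencies, obtained
    here by marginalising the N-word counts.
    """
    if wc.W <= 0:
        raise DegenerateSequenceError("no countable words")
    m = 4**wc.N
    if scheme.tag == "none":
        return np.full(m, wc.W / m)
    if scheme.tag in ("gc_local", "gc_generalized"):
        if scheme.tag == "gc_generalized":
            gc_used = scheme.gc_reference
        else:
            gc_used = gc if gc is not None else wc.gc_estimate()
        if not 0.0 < gc_used < 1.0:
            raise DegenerateCompositionError(
                f"GC fraction {gc_used} outside (0, 1): zero-order model degenerate"
            )
        ngc = gc_letter_counts(wc.N)
        probs = (gc_used / 2.0) ** ngc * ((1.0 - gc_used) / 2.0) ** (wc.N - ngc)
        return wc.W * probs
    # markov_k
    return _markov_expected(wc, scheme.k)


def _markov_expected(wc: WordCounts, k: int) -> np.ndarray:
    """Order-k Markov chain expectation for all N-words.

    p(w) = p(w[0:k+1]) * prod_i p(w[i:i+k+1]) / p(w[i:i+k]) with sub-word
    probabilities taken as position-specific marginals of the observed
    N-word counts.
    """
    N = wc.N
    if k >= N:
        raise ValueError(f"Markov order {k} must be smaller than word length {N}")
    tensor = (wc.array / wc.W).reshape((4,) * N)
    digits = _word_digits(N)

    def marginal(i: int, j: int) -> np.ndarray:
        axes = tuple(a for a in range(N) if not i <= a < j)
        return tensor.sum(axis=axes) if axes else tensor

    probs = marginal(0, k + 1)[tuple(digits[:, : k + 1].T)]
    for i in range(1, N - k):
        num = marginal(i, i + k + 1)[tuple(digits[:, i : i + k + 1].T)]
        den = marginal(i, i + k)[tuple(digits[:, i : i + k].T)]
        safe = den > 0
        probs = np.where(safe, probs * num / np.where(safe, den, 1.0), 0.0)
    return wc.W * probs


def _ranks(delta: np.ndarray) -> np.ndarray:
    """Ranks 1..4**N by ascending delta; ties broken lexicographically.

    A stable sort on the lexicographically ordered vector implements the
    tie-break for free.
    """
    order = np.argsort(delta, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(1, delta.size + 1)
    return ranks


def pattern_from_counts(
    wc: WordCounts,
    scheme: NormalizationScheme,
    L_seq: int,
    gc: Optional[float] = None,
) -> OUPattern:
    """Build a pattern from precomputed word counts.

    ``delta = (C_obs - C_e) / C_0`` with ``C_0 = W * 4**-N`` (the uniform
    expectation over counted positions, which keeps ``sum(delta) == 0``
    under the un-normalised scheme even when ambiguous bases were skipped).
    """
    if wc.W <= 0:
        raise DegenerateSequenceError("no countable words")
    exp = expected_counts(wc, scheme, gc=gc)
    c0 = wc.W / 4**wc.N
    delta = (wc.array - exp) / c0
    gc_val = gc if gc is not None else wc.gc_estimate()
    return OUPattern(wc.N, delta, _ranks(delta), scheme, L_seq, wc.W, gc_val)


def compute_pattern(
    sequence: str,
    N: int = DEFAULT_WORD_LENGTH,
    scheme: NormalizationScheme = NormalizationScheme("none"),
) -> OUPattern:
    """Usage pattern of a sequence under the given normalization scheme."""
    _check_n(N)
    wc = count_words(sequence, N)
    if wc.W == 0:
        raise DegenerateSequenceError("sequence contains no countable word")
    gc = gc_fraction(sequence) if scheme.tag != "markov_k" else None
    return pattern_from_counts(wc, scheme, L_seq=len(sequence), gc=gc)


def rank_sum_distance(ranks_i: np.ndarray, ranks_j: np.ndarray) -> int:
    return int(np.abs(ranks_i.astype(np.int64) - ranks_j.astype(np.int64)).sum())


def pattern_distance(p_i: OUPattern, p_j: OUPattern) -> float:
    """Rank distance D between two patterns, in percent.

    ``D(%) = 100 * (sum_w |rank_w,i - rank_w,j| - D_min) / (D_max - D_min)``
    with ``D_min = 0`` and ``D_max = 4**N (4**N - 1) / 2``.  The value is
    not clamped: the printed D_max is below the combinatorial maximum of
    the rank sum, so extreme rank reversals can exceed 100%.
    """
    if p_i.N != p_j.N:
        raise IncompatiblePatternError(
            f"patterns have different word lengths ({p_i.N} vs {p_j.N})"
        )
    return 100.0 * rank_sum_distance(p_i.ranks, p_j.ranks) / d_max(p_i.N)


def skew_from_counts(wc: WordCounts) -> float:
    """Pattern skew from precomputed (direct-strand) word counts."""
    fwd = _ranks((wc.array - wc.W / 4**wc.N) / (wc.W / 4**wc.N))
    rev_arr = wc.array[rc_permutation(wc.N)]
    rev = _ranks((rev_arr - wc.W / 4**wc.N) / (wc.W / 4**wc.N))
    s = rank_sum_distance(fwd, rev)
    dmin = ps_d_min(wc.N)
    return 100.0 * (s - dmin) / (d_max(wc.N) - dmin)


def pattern_skew(sequence: str, N: int = DEFAULT_WORD_LENGTH) -> float:
    """Pattern skew PS: D between direct and reverse-complement strands.

    Computed on un-normalised patterns with the skew-specific baseline
    ``D_min = 4**N - 2**N`` (even N) or ``4**N`` (odd N).  Not clamped;
    perfectly strand-symmetric sequences give a small negative value.
    """
    _check_n(N)
    wc = count_words(sequence, N)
    if wc.W == 0:
        raise DegenerateSequenceError("sequence contains no countable word")
    return skew_from_counts(wc)


def sigma0(N: int, L_seq: int) -> float:
    """Expected sampling standard deviation ``sqrt(0.02 + 4**N / L_seq)``."""
    if L_seq <= 0:
        raise ValueError("L_seq must be positive")
    return float(np.sqrt(0.02 + 4**N / L_seq))


def pattern_variance(p: OUPattern) -> float:
    """Pattern variance ``V = sum(delta**2) / ((4**N - 1) * sigma0)``."""
    return float((p.delta**2).sum()) / ((4**p.N - 1) * sigma0(p.N, p.L_seq))


def relative_variances_from_counts(
    wc: WordCounts,
    L_seq: int,
    window_gc: float,
    reference_gc: float,
) -> RelativeVariances:
    """RV and GRV from precomputed window counts.

    RV normalises expected counts by the window's own GC; GRV by the
    reference GC.  When the two GC values coincide, RV == GRV exactly.
    """
    p_local = pattern_from_counts(
        wc, NormalizationScheme.gc_local(), L_seq=L_seq, gc=window_gc
    )
    p_gen = pattern_from_counts(
        wc, NormalizationScheme.gc_generalized(reference_gc), L_seq=L_seq
    )
    return RelativeVariances(pattern_variance(p_local), pattern_variance(p_gen))


def rv_grv(
    window_sequence: str,
    reference_gc: float,
    N: int = DEFAULT_WORD_LENGTH,
) -> RelativeVariances:
    """RV and GRV of a window against a reference GC.

    Returns a :class:`RelativeVariances` carrying both values and both
    ratio orientations.  The island-calling ratio used by the detector is
    ``grv_over_rv`` (generalised over local): local normalisation absorbs a
    GC shift that the reference-GC model cannot explain, so the ratio rises
    above 1 exactly on windows whose composition deviates from the
    reference beyond what their own GC predicts.
    """
    _check_n(N)
    if not 0.0 < reference_gc < 1.0:
        raise DegenerateCompositionError("reference GC must lie strictly inside (0, 1)")
    wc = count_words(window_sequence, N)
    if wc.W == 0:
        raise DegenerateSequenceError("window contains no countable word")
    return relative_variances_from_counts(
        wc, L_seq=len(window_sequence), window_gc=gc_fraction(window_sequence),
        reference_gc=reference_gc,
    )
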