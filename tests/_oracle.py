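"""Independent brute-force reference implementation of the pattern
statistics, used only by the tests.

Deliberately naive: plain dicts, string slicing and ``sorted`` -- no numpy,
no shared code with the package -- so agreement between the two paths is
meaningful.
"""

import itertools
import math

BASES = "ACGT"
COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq):
    return "".join(COMP[b] for b in reversed(seq.upper()) if True)


def count_words(seq, n):
    seq = seq.upper()
    counts = {}
    total = 0
    for i in range(len(seq) - n + 1):
        w = seq[i : i + n]
        if any(b not in BASES for b in w):
            continue
        counts[w] = counts.get(w, 0) + 1
        total += 1
    return counts, total


def gc_of(seq):
    seq = seq.upper()
    valid = [b for b in seq if b in BASES]
    return sum(b in "GC" for b in valid) / len(valid)


def expected(word, scheme, gc, total, counts=None, n=None):
    if scheme == "none":
        return total / 4 ** len(word)
    if scheme == "gc":
        p = 1.0
        for b in word:
            p *= gc / 2 if b in "GC" else (1 - gc) / 2
        return total * p
    raise ValueError(scheme)


def delta_vector(seq, n, scheme="none", gc=None):
    counts, total = count_words(seq, n)
    if gc is None and scheme == "gc":
        gc = gc_of(seq)
    c0 = total / 4**n
    deltas = {}
    for word in ("".join(p) for p in itertools.product(BASES, repeat=n)):
        deltas[word] = (counts.get(word, 0) - expected(word, scheme, gc, total)) / c0
    return deltas


def ranks_of(deltas):
    ordered = sorted(deltas, key=lambda w: (deltas[w], w))
    return {w: i + 1 for i, w in enumerate(ordered)}


def distance(deltas_i, deltas_j, n):
    ri, rj = ranks_of(deltas_i), ranks_of(deltas_j)
    s = sum(abs(ri[w] - rj[w]) for w in ri)
    dmax = 4**n * (4**n - 1) // 2
    return 100.0 * s / dmax


def skew(seq, n):
    di = delta_vector(seq, n)
    dj = delta_vector(revcomp(seq), n)
    ri, rj = ranks_of(di), ranks_of(dj)
    s = sum(abs(ri[w] - rj[w]) for w in ri)
    dmin = 4**n - 2**n if n % 2 == 0 else 4**n
    dmax = 4**n * (4**n - 1) // 2
    return 100.0 * (s - dmin) / (dmax - dmin)


def variance(seq, n, scheme="none", gc=None):
    deltas = delta_vector(seq, n, scheme, gc)
    s0 = math.sqrt(0.02 + 4**n / len(seq))
    return sum(d * d for d in deltas.values()) / ((4**n - 1) * s0)


def rv_grv_ratio(seq, n, reference_gc):
    rv = variance(seq, n, "gc", gc_of(seq))
    grv = variance(seq, n, "gc", reference_gc)
    return rv, grv, grv / rv
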