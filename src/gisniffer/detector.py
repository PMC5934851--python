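"""Two-tier sliding-window genomic-island scan.

Large eukaryotic chromosomes are too heterogeneous for a single whole-
chromosome reference signature, so the scan uses two tiers:

* a *reference* tier: a 300-kbp window advanced in 100-kbp steps supplies
  the local "background" usage pattern and GC content;
* a *local* tier: an 8-kbp window advanced in 2-kbp steps is scored
  against the reference frame whose centre is nearest.

Per local window three statistics are evaluated against empirical
cut-offs: the rank distance D between the window's un-normalised pattern
and the reference pattern (D > 1.5), the window's strand pattern skew
(PS < 55, excluding rRNA-operon-like strand-asymmetric loci), and the
ratio of the globally to locally GC-normalised pattern variances
(GRV/RV > 1.5, requiring atypicality beyond what the window's own GC
explains).  Runs of flagged windows are merged into candidate islands.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import oup
from .oup import (
    NormalizationScheme,
    SequenceTooShortError,
    WordCounts,
)


@dataclass(frozen=True)
class DetectorParams:
    """Scan geometry and calling cut-offs.

    Defaults are the published operating point: 300-kbp reference window
    re-evaluated every 100 kbp, 8-kbp local window every 2 kbp,
    tetranucleotides, cut-offs D > 1.5 %, PS < 55 %, GRV/RV > 1.5, and a
    5-kbp minimum island length.
    """

    ref_window: int = 300_000
    ref_step: int = 100_000
    local_window: int = 8_000
    local_step: int = 2_000
    N: int = 4
    d_cutoff: float = 1.5
    ps_cutoff: float = 55.0
    grv_rv_cutoff: float = 1.5
    min_island: int = 5_000

    def __post_init__(self) -> None:
        if self.local_window > self.ref_window:
            raise ValueError("local_window must not exceed ref_window")
        if self.local_step > self.local_window:
            raise ValueError("local_step must not exceed local_window")
        if self.ref_step > self.ref_window:
            raise ValueError("ref_step must not exceed ref_window")
        for name in ("ref_window", "ref_step", "local_window", "local_step",
                     "min_island"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("d_cutoff", "ps_cutoff", "grv_rv_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 1 <= self.N <= oup.MAX_WORD_LENGTH:
            raise ValueError(f"N must be in 1..{oup.MAX_WORD_LENGTH}")


@dataclass
class WindowStats:
    """Per-window statistics track (0-based half-open coordinates)."""

    start: int
    end: int
    gc: float
    d: float
    ps: float
    rv: float
    grv: float
    grv_rv: float
    ref_start: int
    ref_end: int
    flagged: bool


@dataclass
class CandidateIsland:
    """A merged run of flagged windows, before annotation filters."""

    start: int
    end: int
    n_windows: int
    max_d: float
    min_ps: float
    max_grv_rv: float

    @property
    def length(self) -> int:
        return self.end - self.start


def reference_frames(seq_len: int, params: DetectorParams) -> List[Tuple[int, int]]:
    """Reference-tier frame coordinates for a chromosome of ``seq_len`` bp.

    Frames start at multiples of ``ref_step`` and span ``ref_window`` bp.
    If the chromosome is shorter than one frame, a single frame covers it
    entirely; otherwise a terminal frame anchored at ``seq_len -
    ref_window`` is appended when needed so the final frame reaches the
    chromosome end at full width.
    """
    if seq_len < params.local_window:
        raise SequenceTooShortError(
            f"sequence ({seq_len} bp) shorter than the local window"
        )
    if seq_len <= params.ref_window:
        return [(0, seq_len)]
    frames = [
        (s, s + params.ref_window)
        for s in range(0, seq_len - params.ref_window + 1, params.ref_step)
    ]
    if frames[-1][1] < seq_len:
        frames.append((seq_len - params.ref_window, seq_len))
    return frames


def assign_reference(
    window: Tuple[int, int], frames: Sequence[Tuple[int, int]]
) -> Tuple[int, int]:
    """The frame whose centre is nearest the window centre (ties: earlier).

    Computed on doubled coordinates so ties are exact in integers.
    """
    wc2 = window[0] + window[1]
    best = min(range(len(frames)), key=lambda i: abs(frames[i][0] + frames[i][1] - wc2))
    return frames[best]


class _EncodedChromosome:
    """One-pass encoding with prefix sums for O(1) per-range GC and counts."""

    def __init__(self, sequence: str, N: int):
        self.length = len(sequence)
        self.N = N
        codes = oup.encode_sequence(sequence)
        self._wcodes = oup.word_codes(codes, N)
        valid = codes < 4
        gc = (codes == 1) | (codes == 2)
        self._valid_cum = np.concatenate(([0], np.cumsum(valid)))
        self._gc_cum = np.concatenate(([0], np.cumsum(gc)))

    def word_counts(self, start: int, end: int) -> WordCounts:
        hi = max(start, end - self.N + 1)
        counts = np.bincount(self._wcodes[start:hi], minlength=4**self.N + 1)[: 4**self.N]
        return WordCounts(self.N, counts, int(counts.sum()))

    def gc(self, start: int, end: int) -> Optional[float]:
        valid = self._valid_cum[end] - self._valid_cum[start]
        if valid == 0:
            return None
        return (self._gc_cum[end] - self._gc_cum[start]) / valid


def _local_window_starts(seq_len: int, params: DetectorParams) -> List[int]:
    """Window start positions: full windows at every step, plus one
    truncated terminal window when it adds coverage and still spans at
    least half the nominal window length (shorter windows make the
    expected sampling spread unstable)."""
    w, step = params.local_window, params.local_step
    starts = list(range(0, seq_len - w + 1, step))
    tail_start = starts[-1] + step if starts else 0
    if (
        tail_start < seq_len
        and seq_len - tail_start >= (w + 1) // 2
        and (not starts or seq_len > starts[-1] + w)
    ):
        starts.append(tail_start)
    return starts


def scan_chromosome(
    sequence: str, params: DetectorParams = DetectorParams()
) -> List[WindowStats]:
    """Score every local window of a chromosome.

    Per window: D against the assigned reference frame's un-normalised
    pattern, strand pattern skew, and the GRV/RV variance ratio using the
    reference frame's GC.  Reference-frame patterns are computed once per
    frame and reused.  Windows without any countable word or with a
    degenerate (all-GC / all-AT) composition are skipped.
    """
    if len(sequence) < params.local_window:
        raise SequenceTooShortError(
            f"sequence ({len(sequence)} bp) shorter than local window "
            f"({params.local_window} bp)"
        )
    enc = _EncodedChromosome(sequence, params.N)
    frames = reference_frames(enc.length, params)

    frame_info = {}
    for fr in frames:
        wc = enc.word_counts(*fr)
        gc = enc.gc(*fr)
        if wc.W == 0 or gc is None or not 0.0 < gc < 1.0:
            frame_info[fr] = None
            continue
        pattern = oup.pattern_from_counts(
            wc, NormalizationScheme.none(), L_seq=fr[1] - fr[0], gc=gc
        )
        frame_info[fr] = (pattern, gc)

    stats: List[WindowStats] = []
    for start in _local_window_starts(enc.length, params):
        end = min(start + params.local_window, enc.length)
        fr = assign_reference((start, end), frames)
        if frame_info[fr] is None:
            continue
        ref_pattern, ref_gc = frame_info[fr]
        wc = enc.word_counts(start, end)
        gc = enc.gc(start, end)
        if wc.W == 0 or gc is None or not 0.0 < gc < 1.0:
            continue
        pattern = oup.pattern_from_counts(
            wc, NormalizationScheme.none(), L_seq=end - start, gc=gc
        )
        d = oup.pattern_distance(pattern, ref_pattern)
        ps = oup.skew_from_counts(wc)
        var = oup.relative_variances_from_counts(
            wc, L_seq=end - start, window_gc=gc, reference_gc=ref_gc
        )
        ratio = var.grv_over_rv
        flagged = (
            d > params.d_cutoff
            and ps < params.ps_cutoff
            and ratio > params.grv_rv_cutoff
        )
        stats.append(
            WindowStats(
                start=start, end=end, gc=gc, d=d, ps=ps,
                rv=var.rv, grv=var.grv, grv_rv=ratio,
                ref_start=fr[0], ref_end=fr[1], flagged=flagged,
            )
        )
    return stats


def merge_flagged(
    stats: Sequence[WindowStats], params: DetectorParams = DetectorParams()
) -> List[CandidateIsland]:
    """Merge maximal runs of overlapping or abutting flagged windows."""
    islands: List[CandidateIsland] = []
    current: Optional[CandidateIsland] = None
    for ws in stats:
        if not ws.flagged:
            continue
        if current is not None and ws.start <= current.end:
            current.end = max(current.end, ws.end)
            current.n_windows += 1
            current.max_d = max(current.max_d, ws.d)
            current.min_ps = min(current.min_ps, ws.ps)
            current.max_grv_rv = max(current.max_grv_rv, ws.grv_rv)
        else:
            current = CandidateIsland(
                start=ws.start, end=ws.end, n_windows=1,
                max_d=ws.d, min_ps=ws.ps, max_grv_rv=ws.grv_rv,
            )
            islands.append(current)
    return islands


def core_interval(
    island: CandidateIsland, params: DetectorParams
) -> Tuple[int, int]:
    """Shrink a merged run to the region its flagged windows actually
    support.

    A window flags only when atypical sequence contributes a substantial
    share of it, so the run's evidence localises near the window centres.
    The end windows of a run flag with the *least* foreign content, so the
    raw centres span still overestimates the segment by up to a step; the
    island interval is therefore the union trimmed by
    ``(local_window + local_step) / 2`` per side (never below one step of
    width), a conservative estimate of the supported extent.  This is what
    makes the minimum-length filter meaningful: under raw union semantics
    no call could ever be shorter than one full window.
    """
    trim = (params.local_window + params.local_step) // 2
    start, end = island.start + trim, island.end - trim
    if end - start < params.local_step:
        centre = (island.start + island.end) // 2
        start = centre - params.local_step // 2
        end = start + params.local_step
    return start, end


def predict_islands(
    sequence: str,
    params: DetectorParams = DetectorParams(),
    stats: Optional[Sequence[WindowStats]] = None,
    trim_to_core: bool = True,
) -> List[CandidateIsland]:
    """Scan, flag, merge and length-filter: the full compositional caller.

    Pass precomputed ``stats`` to avoid re-scanning.  Islands shorter than
    ``params.min_island`` (after trimming merged runs to their supported
    core) are dropped; the rRNA filters live in :mod:`gisniffer.annotate`.
    """
    if stats is None:
        stats = scan_chromosome(sequence, params)
    merged = merge_flagged(stats, params)
    out: List[CandidateIsland] = []
    for isl in merged:
        if trim_to_core:
            isl.start, isl.end = core_interval(isl, params)
        if isl.length >= params.min_island:
            out.append(isl)
    return out
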