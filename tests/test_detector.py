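"""Tests of the two-tier sliding-window scan and island assembly."""

import dataclasses

import numpy as np
import pytest

from gisniffer import CompositionModel, generate_background
from gisniffer.benchmark import is_detected
from gisniffer.detector import (
    CandidateIsland,
    DetectorParams,
    WindowStats,
    assign_reference,
    merge_flagged,
    predict_islands,
    reference_frames,
    scan_chromosome,
)
from gisniffer.oup import SequenceTooShortError


# ---------------------------------------------------------------------------
# reference frames

def test_reference_frames_defaults_1mbp():
    frames = reference_frames(1_000_000, DetectorParams())
    assert frames[0] == (0, 300_000)
    assert frames[1][0] == 100_000
    assert frames[-1][1] == 1_000_000
    assert all(e - s == 300_000 for s, e in frames)


def test_reference_frames_short_sequence_single_frame():
    assert reference_frames(250_000, DetectorParams()) == [(0, 250_000)]
    assert reference_frames(300_000, DetectorParams()) == [(0, 300_000)]


def test_reference_frames_tail_anchored_to_end():
    frames = reference_frames(1_040_000, DetectorParams())
    assert frames[-1] == (740_000, 1_040_000)


def test_reference_frames_too_short():
    with pytest.raises(SequenceTooShortError):
        reference_frames(4_000, DetectorParams())


def test_assign_reference_nearest_center_and_ties():
    frames = reference_frames(1_000_000, DetectorParams())
    assert assign_reference((0, 8000), frames) == (0, 300_000)
    # centre 154000 is nearest frame-centre 150000 (frame 0-300k)
    assert assign_reference((150_000, 158_000), frames) == (0, 300_000)
    # a window centred exactly between two frame centres takes the earlier
    mid = (150_000 + 250_000) // 2
    tie = assign_reference((mid - 4000, mid + 4000), frames)
    assert tie == (0, 300_000)


# ---------------------------------------------------------------------------
# merging

def _ws(start, end, flagged=True, d=10.0, ps=5.0, ratio=2.0):
    return WindowStats(start, end, 0.45, d, ps, 1.0, ratio, ratio,
                       0, 300_000, flagged)


def test_merge_overlapping_windows():
    islands = merge_flagged([_ws(0, 8000), _ws(2000, 10_000)])
    assert len(islands) == 1
    assert (islands[0].start, islands[0].end) == (0, 10_000)
    assert islands[0].n_windows == 2


def test_merge_disjoint_windows():
    islands = merge_flagged([_ws(0, 8000), _ws(20_000, 28_000)])
    assert [(i.start, i.end) for i in islands] == [(0, 8000), (20_000, 28_000)]


def test_merge_aggregates_extrema():
    islands = merge_flagged([_ws(0, 8000, d=5, ps=9, ratio=1.6),
                             _ws(2000, 10_000, d=7, ps=3, ratio=2.5)])
    isl = islands[0]
    assert (isl.max_d, isl.min_ps, isl.max_grv_rv) == (7, 3, 2.5)


def test_merge_no_flagged_windows():
    assert merge_flagged([_ws(0, 8000, flagged=False)]) == []


# ---------------------------------------------------------------------------
# scanning

def test_scan_too_short():
    with pytest.raises(SequenceTooShortError):
        scan_chromosome("ACGT" * 100, DetectorParams())


def test_scan_single_window_is_own_reference(small_params):
    seq = generate_background(5_000, CompositionModel(gc=0.45, seed=2))
    stats = scan_chromosome(seq, small_params)
    assert len(stats) == 1
    # the window is its own reference frame: identical patterns, D = 0
    assert stats[0].d == 0.0
    assert stats[0].grv_rv == pytest.approx(1.0)


def test_scan_homogeneous_background_unflagged(background_120k, small_params):
    stats = scan_chromosome(background_120k, small_params)
    assert stats, "scan produced no windows"
    assert not any(w.flagged for w in stats)
    ratios = np.array([w.grv_rv for w in stats])
    assert abs(ratios.mean() - 1.0) < 0.05


def test_scan_deterministic(background_120k, small_params):
    s1 = scan_chromosome(background_120k, small_params)
    s2 = scan_chromosome(background_120k, small_params)
    assert s1 == s2


def test_scan_flag_rule_consistency(background_120k, small_params):
    for w in scan_chromosome(background_120k, small_params):
        expected = (
            w.d > small_params.d_cutoff
            and w.ps < small_params.ps_cutoff
            and w.grv_rv > small_params.grv_rv_cutoff
        )
        assert w.flagged == expected


def test_flag_monotone_in_cutoffs(background_120k, small_params):
    """Raising d/ratio cut-offs or lowering the PS cut-off never flags more."""
    loose = dataclasses.replace(small_params, d_cutoff=0.5, ps_cutoff=80.0,
                                grv_rv_cutoff=0.9)
    strict = dataclasses.replace(small_params, d_cutoff=5.0, ps_cutoff=20.0,
                                 grv_rv_cutoff=1.2)
    flag_loose = {w.start for w in scan_chromosome(background_120k, loose)
                  if w.flagged}
    flag_strict = {w.start for w in scan_chromosome(background_120k, strict)
                   if w.flagged}
    assert flag_strict <= flag_loose


# ---------------------------------------------------------------------------
# island prediction on planted truth (default geometry, 1 Mbp)

def test_predict_islands_homogeneous_is_naive(planted_truth):
    bg_model = planted_truth.background_model
    naive = generate_background(400_000, bg_model, seed=909)
    assert predict_islands(naive) == []


def test_predict_islands_recovers_planted(planted_truth):
    islands = predict_islands(planted_truth.sequence)
    for start, end, tag in planted_truth.islands:
        assert is_detected(islands, (start, end), 0.5), f"missed {tag}"
    # no overlapping calls, all above the minimum length
    islands = sorted(islands, key=lambda i: i.start)
    for a, b in zip(islands, islands[1:]):
        assert a.end <= b.start
    assert all(i.length >= 5000 for i in islands)


def test_predict_islands_small_insert_dropped(planted_truth):
    """A 3-kbp foreign insert never yields a reportable island."""
    bg = generate_background(400_000, planted_truth.background_model, seed=77)
    frag = generate_background(3_000, CompositionModel(gc=0.30, seed=88))[:3000]
    pos = 200_000
    modified = bg[:pos] + frag + bg[pos:]
    islands = predict_islands(modified)
    assert islands == []


def test_islands_covered_by_flagged_windows(planted_truth):
    stats = scan_chromosome(planted_truth.sequence)
    islands = predict_islands(planted_truth.sequence, stats=stats)
    flagged = [w for w in stats if w.flagged]
    for isl in islands:
        assert any(w.start < isl.end and isl.start < w.end for w in flagged)
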