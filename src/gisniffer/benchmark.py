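"""Randomised false-negative / false-positive benchmark protocols.

Two simulation protocols estimate detector error rates without any ground
truth beyond the simulation itself:

* **False negatives** -- known island sequences (a donor set) are inserted
  one at a time at random positions of a test chromosome; the FN ratio is
  the percentage of inserts the detector misses.
* **False positives** -- fragments of fixed length (default 28,173 bp, the
  mean donor-island length) are copied from one chromosome of an organism
  and inserted at random positions of another; because the two chromosomes
  share their composition, any call covering the transferred fragment is a
  false positive.

Both protocols work against any detector callable returning intervals, so
stub detectors can exercise the bookkeeping and the real compositional
scanner can be benchmarked at any scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Sequence, Tuple

import numpy as np

Interval = Tuple[int, int]

#: Published benchmark sizes: donors in the FN protocol, trials in the FP
#: protocol, and the FP fragment length (mean donor-island length).
FN_DEFAULT_SIMS = 194
FP_DEFAULT_SIMS = 100
FP_FRAGMENT_LEN = 28_173


class BenchmarkError(ValueError):
    pass


class InfeasibleConfigurationError(BenchmarkError):
    """Rejection sampling could not satisfy the placement constraints."""


@dataclass
class InsertionEvent:
    """One simulated insertion, with truth in the modified coordinates."""

    position: int
    fragment_len: int
    fragment_source: str
    truth_interval: Interval

    def __post_init__(self) -> None:
        if self.position < 0:
            raise BenchmarkError("insertion position must be non-negative")


@dataclass(frozen=True)
class SimulationConfig:
    """Shared configuration of the FN and FP protocols."""

    n_sims: int = FP_DEFAULT_SIMS
    fragment_len: int = FP_FRAGMENT_LEN
    seed: int = 0
    overlap_frac: float = 0.5
    exclude_existing: bool = True

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise BenchmarkError("n_sims must be at least 1")
        if not 0.0 < self.overlap_frac <= 1.0:
            raise BenchmarkError("overlap_frac must lie in (0, 1]")


@dataclass
class SimulationResult:
    """Outcome of one benchmark run.

    ``ratio`` is a percentage: misses for FN runs, spurious detections for
    FP runs.
    """

    kind: str
    n_sims: int
    n_detected: int
    ratio: float
    per_trial: List[Tuple[InsertionEvent, bool]]
    seed: int


def insert_fragment(
    recipient: str, fragment: str, position: int
) -> Tuple[str, Interval]:
    """Insert ``fragment`` before index ``position`` of ``recipient``.

    Positions 0 and ``len(recipient)`` are legal (prepend / append).
    Returns the modified sequence and the truth interval of the insert.
    """
    if not 0 <= position <= len(recipient):
        raise BenchmarkError(
            f"position {position} outside [0, {len(recipient)}]"
        )
    modified = recipient[:position] + fragment + recipient[position:]
    return modified, (position, position + len(fragment))


def _intervals(islands: Sequence) -> List[Interval]:
    out = []
    for isl in islands:
        if hasattr(isl, "start"):
            out.append((int(isl.start), int(isl.end)))
        else:
            s, e = isl[0], isl[1]
            out.append((int(s), int(e)))
    return out


def _union_coverage(intervals: Sequence[Interval], truth: Interval) -> int:
    """Length of the truth interval covered by the union of intervals."""
    clipped = sorted(
        (max(s, truth[0]), min(e, truth[1]))
        for s, e in intervals
        if max(s, truth[0]) < min(e, truth[1])
    )
    covered = 0
    cursor = truth[0]
    for s, e in clipped:
        s = max(s, cursor)
        if e > s:
            covered += e - s
            cursor = e
    return covered


def is_detected(
    predicted_islands: Sequence,
    truth_interval: Interval,
    overlap_frac: float = 0.5,
) -> bool:
    """True when the union of predictions covers enough of the truth.

    The criterion is union coverage >= ``overlap_frac`` of the truth
    interval's length; as ``overlap_frac`` approaches 0 this reduces to
    "any overlap", at 1.0 to full coverage.
    """
    if truth_interval[1] <= truth_interval[0]:
        raise BenchmarkError("truth interval must be non-empty")
    covered = _union_coverage(_intervals(predicted_islands), truth_interval)
    return covered >= overlap_frac * (truth_interval[1] - truth_interval[0])


def simulate_fn(
    recipient: str,
    donor_islands: Sequence[str],
    detector: Callable[[str], Sequence],
    config: SimulationConfig,
) -> SimulationResult:
    """False-negative protocol: insert each donor island once, re-detect.

    Each trial uses a *different* donor island (cycling is forbidden, so
    ``n_sims`` must not exceed the donor count), drawn in order, inserted
    at a uniform random position of the recipient.  The FN ratio is
    ``100 * misses / n_sims``.
    """
    if not donor_islands:
        raise BenchmarkError("donor island set is empty")
    n = min(config.n_sims, len(donor_islands)) if config.n_sims else len(donor_islands)
    if config.n_sims > len(donor_islands):
        raise BenchmarkError(
            f"n_sims ({config.n_sims}) exceeds the number of donor islands "
            f"({len(donor_islands)}); each trial needs a different donor"
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xF0]))
    per_trial: List[Tuple[InsertionEvent, bool]] = []
    n_detected = 0
    for i in range(n):
        donor = donor_islands[i]
        position = int(rng.integers(0, len(recipient) + 1))
        modified, truth = insert_fragment(recipient, donor, position)
        event = InsertionEvent(
            position=position, fragment_len=len(donor),
            fragment_source="donor_island", truth_interval=truth,
        )
        detected = is_detected(detector(modified), truth, config.overlap_frac)
        n_detected += detected
        per_trial.append((event, detected))
    ratio = 100.0 * (n - n_detected) / n
    return SimulationResult("FN", n, n_detected, ratio, per_trial, config.seed)


def _overlaps_any(interval: Interval, intervals: Sequence[Interval]) -> bool:
    return any(interval[0] < e and s < interval[1] for s, e in intervals)


def simulate_fp(
    chrom_a: str,
    chrom_b: str,
    detector: Callable[[str], Sequence],
    config: SimulationConfig,
    known_islands_a: Sequence = (),
    known_islands_b: Sequence = (),
) -> SimulationResult:
    """False-positive protocol: transfer native fragments between
    chromosomes of the same organism.

    Per trial a source interval of ``fragment_len`` bp is sampled from
    ``chrom_b`` and inserted at a random position of ``chrom_a``.  With
    ``exclude_existing`` the source fragment must not overlap a known
    island of ``chrom_b`` and the insertion point must not fall inside a
    known island of ``chrom_a`` (rejection sampling, 1000 attempts).  The
    trial is a false positive iff the transferred interval itself is
    detected; calls elsewhere are ignored.
    """
    if len(chrom_b) <= config.fragment_len:
        raise BenchmarkError("source chromosome shorter than fragment_len")
    if len(chrom_a) < config.fragment_len:
        raise BenchmarkError("recipient chromosome shorter than fragment_len")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xF1]))
    iv_a = _intervals(known_islands_a)
    iv_b = _intervals(known_islands_b)
    per_trial: List[Tuple[InsertionEvent, bool]] = []
    n_detected = 0
    for _ in range(config.n_sims):
        src = _reject_sample(
            rng, lambda r: int(r.integers(0, len(chrom_b) - config.fragment_len + 1)),
            lambda s: not config.exclude_existing
            or not _overlaps_any((s, s + config.fragment_len), iv_b),
        )
        position = _reject_sample(
            rng, lambda r: int(r.integers(0, len(chrom_a) + 1)),
            lambda p: not config.exclude_existing
            or not any(s < p < e for s, e in iv_a),
        )
        fragment = chrom_b[src : src + config.fragment_len]
        modified, truth = insert_fragment(chrom_a, fragment, position)
        event = InsertionEvent(
            position=position, fragment_len=config.fragment_len,
            fragment_source="sister_chromosome", truth_interval=truth,
        )
        detected = is_detected(detector(modified), truth, config.overlap_frac)
        n_detected += detected
        per_trial.append((event, detected))
    ratio = 100.0 * n_detected / config.n_sims
    return SimulationResult(
        "FP", config.n_sims, n_detected, ratio, per_trial, config.seed
    )


def _reject_sample(rng, draw, accept, cap: int = 1000) -> int:
    for _ in range(cap):
        value = draw(rng)
        if accept(value):
            return value
    raise InfeasibleConfigurationError(
        f"rejection sampling exceeded {cap} attempts"
    )
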