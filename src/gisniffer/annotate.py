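"""Post-processing of candidate genomic islands.

Three filters and one classification are applied after the compositional
scan:

* a length filter dropping islands smaller than 5 kbp (such short calls are
  statistically unreliable at window resolution);
* a pattern-skew filter removing islands whose supporting windows all have
  a high PS -- rRNA operons are strongly strand-asymmetric and masquerade
  as compositional islands;
* an optional filter driven by externally produced alignment hits against
  an rRNA reference database (the aligner itself is not run here; a
  standard 12-column tabular hit file is consumed);
* a coding / non-coding classification: an island is *coding* when at
  least one protein-coding gene overlaps it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

FEATURE_KINDS = ("CDS", "rRNA", "tRNA", "other")

#: Filter reasons recorded on rejected islands.
REASON_TOO_SHORT = "too_short"
REASON_RRN_PS = "rrn_ps"
REASON_RRN_BLAST = "rrn_blast"


@dataclass
class GeneFeature:
    """A gene-level annotation feature in 0-based half-open coordinates."""

    kind: str
    start: int
    end: int
    strand: str = "+"
    product: str = ""
    locus_id: str = ""

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.end <= self.start:
            raise ValueError("feature end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomicIsland:
    """A called island with supporting statistics and annotation state."""

    start: int
    end: int
    n_windows: int = 1
    max_d: float = 0.0
    min_ps: float = 0.0
    max_grv_rv: float = 0.0
    island_id: str = ""
    coding: bool = False
    genes: List[GeneFeature] = field(default_factory=list)
    filtered_reason: Optional[str] = None

    @property
    def length(self) -> int:
        return self.end - self.start

    @classmethod
    def from_candidate(cls, candidate, island_id: str = "") -> "GenomicIsland":
        return cls(
            start=candidate.start,
            end=candidate.end,
            n_windows=candidate.n_windows,
            max_d=candidate.max_d,
            min_ps=candidate.min_ps,
            max_grv_rv=candidate.max_grv_rv,
            island_id=island_id,
        )


def filter_short(
    islands: Sequence[GenomicIsland], min_island: int
) -> List[GenomicIsland]:
    """Drop islands shorter than ``min_island`` bp.

    "Smaller than" is strict: an island of exactly ``min_island`` bp
    survives.  Removed islands are marked with reason ``too_short``.
    """
    if min_island <= 0:
        raise ValueError("min_island must be positive")
    kept = []
    for isl in islands:
        if isl.length < min_island:
            isl.filtered_reason = REASON_TOO_SHORT
        else:
            kept.append(isl)
    return kept


def filter_rrn_ps(
    islands: Sequence[GenomicIsland],
    window_stats: Sequence,
    ps_cutoff: float,
) -> List[GenomicIsland]:
    """Remove islands whose supporting windows all show high pattern skew.

    An island is removed when the minimum PS over windows overlapping it is
    at or above ``ps_cutoff``.  Under the main calling rule such windows
    cannot be flagged, so this acts as a safety net for islands assembled
    near rRNA loci and for externally supplied island lists.
    """
    kept = []
    for isl in islands:
        ps_values = [
            ws.ps for ws in window_stats if ws.start < isl.end and isl.start < ws.end
        ]
        if ps_values and min(ps_values) >= ps_cutoff:
            isl.filtered_reason = REASON_RRN_PS
        else:
            kept.append(isl)
    return kept


def filter_rrn_blast(
    islands: Sequence[GenomicIsland],
    rrn_hits: Iterable[Tuple[str, bool]],
) -> List[GenomicIsland]:
    """Remove islands matched by an external rRNA-database search.

    ``rrn_hits`` pairs island ids with a boolean match flag (see
    :func:`read_tabular_hits` for deriving these from a standard 12-column
    tabular alignment file).  Unknown island ids raise, to catch
    mismatched inputs early.
    """
    by_id = {isl.island_id: isl for isl in islands}
    matched = set()
    for island_id, hit in rrn_hits:
        if island_id not in by_id:
            raise KeyError(f"hit refers to unknown island id {island_id!r}")
        if hit:
            matched.add(island_id)
    kept = []
    for isl in islands:
        if isl.island_id in matched:
            isl.filtered_reason = REASON_RRN_BLAST
        else:
            kept.append(isl)
    return kept


def read_tabular_hits(path, evalue_cutoff: float = 1e-10) -> List[Tuple[str, bool]]:
    """Parse a standard 12-column tabular alignment file into hit flags.

    Column 1 is taken as the island id and column 11 as the e-value; an
    island counts as matched when any of its rows has
    ``e-value <= evalue_cutoff``.  Islands absent from the file yield no
    entry (i.e. are kept by :func:`filter_rrn_blast`).
    """
    best: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ValueError(f"expected 12 tab-separated columns, got {len(cols)}")
            qid, evalue = cols[0], float(cols[10])
            best[qid] = min(best.get(qid, float("inf")), evalue)
    return [(qid, ev <= evalue_cutoff) for qid, ev in best.items()]


def classify_coding(
    islands: Sequence[GenomicIsland],
    features: Sequence[GeneFeature],
) -> List[GenomicIsland]:
    """Attach overlapping features and set the coding flag on each island.

    A feature overlaps an island when their half-open intervals intersect
    by at least 1 bp; an island is coding when at least one overlapping
    feature is a CDS.  All overlapping features of any kind are attached.
    """
    ordered = sorted(features, key=lambda f: f.start)
    out = []
    for isl in islands:
        overlapping = [
            f for f in ordered if f.start < isl.end and isl.start < f.end
        ]
        isl.genes = overlapping
        isl.coding = any(f.kind == "CDS" for f in overlapping)
        out.append(isl)
    return out


def annotate_islands(
    candidates: Sequence,
    window_stats: Sequence,
    features: Sequence[GeneFeature] = (),
    min_island: int = 5000,
    ps_cutoff: float = 55.0,
    rrn_hits: Optional[Iterable[Tuple[str, bool]]] = None,
    chrom_id: str = "chr",
) -> Tuple[List[GenomicIsland], List[GenomicIsland]]:
    """Full post-processing pipeline: filters then coding classification.

    Returns ``(surviving, rejected)``; rejected islands carry their
    ``filtered_reason``.
    """
    islands = [
        GenomicIsland.from_candidate(c, island_id=f"{chrom_id}_GI_{i + 1}")
        for i, c in enumerate(candidates)
    ]
    surviving = filter_short(islands, min_island)
    surviving = filter_rrn_ps(surviving, window_stats, ps_cutoff)
    if rrn_hits is not None:
        surviving = filter_rrn_blast(surviving, rrn_hits)
    surviving = classify_coding(surviving, features)
    rejected = [isl for isl in islands if isl.filtered_reason is not None]
    return surviving, rejected
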