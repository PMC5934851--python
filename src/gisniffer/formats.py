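"""Reading and writing standard genomic formats.

Sequences come in as FASTA or annotated GenBank flat files (via Biopython);
results go out as GFF3 (primary interchange format), BED6, and TSV tracks.
All internal coordinates are 0-based half-open; GFF3 is converted to
1-based inclusive at emission, BED stays 0-based half-open.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .annotate import GeneFeature
from .benchmark import SimulationResult
from .detector import WindowStats
from .synthetic import SyntheticTruth

_FEATURE_KINDS = {"CDS": "CDS", "rRNA": "rRNA", "tRNA": "tRNA"}


class FormatError(ValueError):
    pass


@dataclass
class InputRecord:
    """One parsed sequence record with its gene-level features."""

    id: str
    sequence: str
    features: List[GeneFeature] = field(default_factory=list)


def _sniff_format(path: str) -> str:
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".fa", ".fasta", ".fna", ".mfa"):
        return "fasta"
    if ext in (".gb", ".gbk", ".gbff", ".genbank"):
        return "genbank"
    raise FormatError(
        f"cannot infer format from extension {ext!r}; pass format explicitly"
    )


def read_sequences(path, fmt: Optional[str] = None) -> List[InputRecord]:
    """Parse a FASTA or GenBank file into records with features.

    FASTA records carry empty feature lists; GenBank CDS/rRNA/tRNA
    features are converted to 0-based half-open coordinates.  Raises
    :class:`FormatError` on empty or unparsable input, naming the record
    where possible.
    """
    fmt = fmt or _sniff_format(path)
    if fmt not in ("fasta", "genbank"):
        raise FormatError(f"unsupported format {fmt!r}")
    records: List[InputRecord] = []
    try:
        for rec in SeqIO.parse(str(path), fmt):
            features = []
            for f in rec.features:
                kind = _FEATURE_KINDS.get(f.type)
                if kind is None or f.location is None:
                    continue
                quals = f.qualifiers
                features.append(
                    GeneFeature(
                        kind=kind,
                        start=int(f.location.start),
                        end=int(f.location.end),
                        strand="-" if f.location.strand == -1 else "+",
                        product=(quals.get("product", [""]) or [""])[0],
                        locus_id=(quals.get("locus_tag", [""]) or [""])[0],
                    )
                )
            records.append(InputRecord(rec.id, str(rec.seq).upper(), features))
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed record
        raise FormatError(f"failed to parse {path} as {fmt}: {exc}") from exc
    if not records:
        raise FormatError(f"no sequence records found in {path} (format {fmt})")
    return records


# ---------------------------------------------------------------------------
# island / track output

def _island_attrs(isl) -> str:
    island_id = getattr(isl, "island_id", "") or "GI"
    parts = [f"ID={island_id}"]
    if hasattr(isl, "coding"):
        parts.append(f"coding={'true' if isl.coding else 'false'}")
        genes = [g.locus_id or g.product or g.kind for g in isl.genes]
        parts.append(f"n_genes={len(genes)}")
        if genes:
            parts.append("genes=" + ",".join(genes))
    parts.append(f"max_d={isl.max_d:.4f}")
    parts.append(f"min_ps={isl.min_ps:.4f}")
    parts.append(f"max_grv_rv={isl.max_grv_rv:.4f}")
    reason = getattr(isl, "filtered_reason", None)
    if reason:
        parts.append(f"filtered_reason={reason}")
    return ";".join(parts)


def write_gff(
    islands: Sequence, chrom_id: str, path, seq_len: Optional[int] = None
) -> None:
    """GFF3 output: one ``genomic_island`` line per call, score = max D."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if seq_len is not None:
            fh.write(f"##sequence-region {chrom_id} 1 {seq_len}\n")
        for isl in islands:
            fh.write(
                "\t".join(
                    [
                        chrom_id,
                        "gisniffer",
                        "genomic_island",
                        str(isl.start + 1),
                        str(isl.end),
                        f"{isl.max_d:.4f}",
                        ".",
                        ".",
                        _island_attrs(isl),
                    ]
                )
                + "\n"
            )


def write_bed(islands: Sequence, chrom_id: str, path) -> None:
    """BED6 output (0-based half-open), score clipped to the 0-1000 range."""
    with open(path, "w") as fh:
        for isl in islands:
            name = getattr(isl, "island_id", "") or "GI"
            score = max(0, min(1000, int(round(10 * isl.max_d))))
            fh.write(
                f"{chrom_id}\t{isl.start}\t{isl.end}\t{name}\t{score}\t.\n"
            )


WINDOW_STATS_COLUMNS = (
    "start", "end", "gc", "d", "ps", "rv", "grv", "grv_rv",
    "ref_start", "ref_end", "flagged",
)


def write_window_stats(stats: Sequence[WindowStats], path) -> None:
    """Window-statistics track as TSV with a header row."""
    with open(path, "w") as fh:
        fh.write("\t".join(WINDOW_STATS_COLUMNS) + "\n")
        for w in stats:
            fh.write(
                f"{w.start}\t{w.end}\t{w.gc:.6f}\t{w.d:.6f}\t{w.ps:.6f}\t"
                f"{w.rv:.6g}\t{w.grv:.6g}\t{w.grv_rv:.6f}\t"
                f"{w.ref_start}\t{w.ref_end}\t{int(w.flagged)}\n"
            )


def write_trials(result: SimulationResult, path) -> None:
    """Per-trial benchmark records as TSV (byte-stable for fixed seeds)."""
    with open(path, "w") as fh:
        fh.write(
            "kind\ttrial\tposition\tfragment_len\tfragment_source\t"
            "truth_start\ttruth_end\tdetected\n"
        )
        for i, (event, detected) in enumerate(result.per_trial):
            fh.write(
                f"{result.kind}\t{i + 1}\t{event.position}\t{event.fragment_len}\t"
                f"{event.fragment_source}\t{event.truth_interval[0]}\t"
                f"{event.truth_interval[1]}\t{int(detected)}\n"
            )


def write_summary(results: Sequence[Tuple[str, SimulationResult]], path) -> None:
    """One summary row per (chromosome, run): the benchmark-table layout."""
    with open(path, "w") as fh:
        fh.write("chromosome\tkind\tn_sims\tn_detected\tratio_pct\tseed\n")
        for chrom, res in results:
            fh.write(
                f"{chrom}\t{res.kind}\t{res.n_sims}\t{res.n_detected}\t"
                f"{res.ratio:.2f}\t{res.seed}\n"
            )


def write_islands(
    islands: Sequence,
    chrom_id: str,
    out_dir,
    emit: Sequence[str] = ("gff", "bed", "tsv"),
    stats: Optional[Sequence[WindowStats]] = None,
    seq_len: Optional[int] = None,
) -> dict:
    """Write island calls in the requested formats; returns path mapping.

    ``emit`` may contain ``gff``, ``bed`` and ``tsv`` (the TSV window
    track requires ``stats``).  At least one format must be requested.
    """
    if not emit:
        raise ValueError("at least one output format must be requested")
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    if "gff" in emit:
        paths["gff"] = os.path.join(out_dir, f"{chrom_id}.islands.gff3")
        write_gff(islands, chrom_id, paths["gff"], seq_len=seq_len)
    if "bed" in emit:
        paths["bed"] = os.path.join(out_dir, f"{chrom_id}.islands.bed")
        write_bed(islands, chrom_id, paths["bed"])
    if "tsv" in emit:
        if stats is None:
            raise ValueError("the tsv track requires window stats")
        paths["tsv"] = os.path.join(out_dir, f"{chrom_id}.windows.tsv")
        write_window_stats(stats, paths["tsv"])
    return paths


# ---------------------------------------------------------------------------
# synthetic-fixture output

def truth_record(truth: SyntheticTruth, chrom_id: str) -> SeqRecord:
    """A Biopython record of a synthetic chromosome with its features."""
    rec = SeqRecord(Seq(truth.sequence), id=chrom_id, description="synthetic")
    rec.annotations["molecule_type"] = "DNA"
    for f in truth.features:
        rec.features.append(
            SeqFeature(
                FeatureLocation(f.start, f.end, strand=1 if f.strand == "+" else -1),
                type=f.kind,
                qualifiers={"product": [f.product], "locus_tag": [f.locus_id]},
            )
        )
    return rec


def write_truth(truth: SyntheticTruth, out_dir, chrom_id: str) -> dict:
    """Write a synthetic chromosome as FASTA + GenBank + truth BED.

    Returns the mapping of written paths.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "fasta": os.path.join(out_dir, f"{chrom_id}.fasta"),
        "genbank": os.path.join(out_dir, f"{chrom_id}.gbk"),
        "truth_bed": os.path.join(out_dir, f"{chrom_id}.truth.bed"),
    }
    rec = truth_record(truth, chrom_id)
    SeqIO.write([rec], paths["fasta"], "fasta")
    SeqIO.write([rec], paths["genbank"], "genbank")
    with open(paths["truth_bed"], "w") as fh:
        for start, end, tag in truth.islands:
            fh.write(f"{chrom_id}\t{start}\t{end}\t{tag}\t0\t.\n")
    return paths
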