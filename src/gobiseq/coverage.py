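"""Read preprocessing and per-base coverage / read-start profiles.

Implements the RNA-seq preprocessing used for a two-condition bacterial
UV-response experiment: end-trimming of low-quality bases (Q < 5), a strict
length filter (reads longer than 20 bp are kept), exclusion of alignments
touching rRNA regions, and construction of per-base depth tracks and
read-5'-end (start) profiles from which transcription start sites and
transcribed intergenic regions are later called.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam
from Bio import SeqIO

from .genome_io import Feature

#: feature types that define "genic" space for intergenic extraction
GENIC_TYPES = frozenset({"CDS", "rRNA", "tRNA"})


@dataclass(frozen=True)
class ReadRecord:
    id: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(f"read {self.id!r}: bases/quals length mismatch")
        if any(q < 0 for q in self.quals):
            raise ValueError(f"read {self.id!r}: negative quality")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class Alignment:
    """An aligned read span in 0-based half-open reference coordinates."""

    read_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"alignment {self.read_id!r}: invalid span [{self.start}, {self.end})"
            )


@dataclass
class CoverageTrack:
    replicon_id: str
    depth: np.ndarray  # one non-negative int per base
    strand_mode: str = "pooled"  # pooled | forward | reverse


@dataclass
class StartProfile:
    """Per-position counts of biological 5' ends of alignments."""

    replicon_id: str
    strand: str
    counts: np.ndarray
    sample_id: str = ""


def read_fastq(path: str | Path, phred_offset: int = 33) -> list[ReadRecord]:
    """Load a FASTQ file; qualities decoded as Phred+33 by default."""
    fmt = {33: "fastq", 64: "fastq-illumina"}[phred_offset]
    return [
        ReadRecord(
            id=rec.id,
            bases=str(rec.seq),
            quals=tuple(rec.letter_annotations["phred_quality"]),
        )
        for rec in SeqIO.parse(str(path), fmt)
    ]


def trim_read(read: ReadRecord, qmin: int = 5) -> ReadRecord:
    """Trim the maximal low-quality prefix and suffix of a read.

    Removes from each end the maximal run of bases with quality < ``qmin``;
    interior low-quality bases are untouched.  May return an empty read.
    """
    lo = 0
    hi = len(read)
    while lo < hi and read.quals[lo] < qmin:
        lo += 1
    while hi > lo and read.quals[hi - 1] < qmin:
        hi -= 1
    if lo == 0 and hi == len(read):
        return read
    return ReadRecord(id=read.id, bases=read.bases[lo:hi], quals=read.quals[lo:hi])


def filter_reads(reads: Iterable[ReadRecord], minlen: int = 20) -> list[ReadRecord]:
    """Keep reads strictly longer than ``minlen`` bases (default > 20 bp)."""
    return [r for r in reads if len(r) > minlen]


def read_sam(path: str | Path, sample_id: str = "") -> list[Alignment]:
    """Load alignments from a SAM file as aligned reference spans.

    The span is POS plus the CIGAR reference length; unmapped, secondary and
    supplementary records are skipped.  Paired-end mates count as
    independent alignments.
    """
    alignments: list[Alignment] = []
    with pysam.AlignmentFile(str(path), "r") as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            alignments.append(
                Alignment(
                    read_id=rec.query_name,
                    replicon_id=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    sample_id=sample_id,
                )
            )
    return alignments


def exclude_rrna(
    alignments: Sequence[Alignment], features: Sequence[Feature]
) -> tuple[list[Alignment], int]:
    """Drop alignments overlapping any rRNA feature by at least one base.

    Returns ``(survivors, n_excluded)``.
    """
    rrna_by_rep: dict[str, list[tuple[int, int]]] = {}
    for f in features:
        if f.ftype == "rRNA":
            rrna_by_rep.setdefault(f.replicon_id, []).append((f.start, f.end))
    survivors: list[Alignment] = []
    excluded = 0
    for a in alignments:
        hit = any(
            a.start < e and s < a.end for s, e in rrna_by_rep.get(a.replicon_id, ())
        )
        if hit:
            excluded += 1
        else:
            survivors.append(a)
    return survivors, excluded


def build_coverage(
    alignments: Sequence[Alignment],
    replicon_id: str,
    replicon_length: int,
    strand_mode: str = "pooled",
) -> CoverageTrack:
    """Per-base depth from aligned spans, via a difference array.

    ``strand_mode`` restricts to forward or reverse alignments, or pools
    both (the default; the underlying RNA-seq protocol is not
    strand-specific).
    """
    if strand_mode not in ("pooled", "forward", "reverse"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    diff = np.zeros(replicon_length + 1, dtype=np.int64)
    want = {"pooled": ("+", "-"), "forward": ("+",), "reverse": ("-",)}[strand_mode]
    for a in alignments:
        if a.replicon_id != replicon_id or a.strand not in want:
            continue
        if a.end > replicon_length:
            raise ValueError(
                f"alignment {a.read_id!r} extends beyond replicon length "
                f"{replicon_length}"
            )
        diff[a.start] += 1
        diff[a.end] -= 1
    return CoverageTrack(
        replicon_id=replicon_id,
        depth=np.cumsum(diff[:-1]),
        strand_mode=strand_mode,
    )


def read_start_profile(
    alignments: Sequence[Alignment],
    replicon_id: str,
    replicon_length: int,
    strand: str,
    sample_id: str = "",
) -> StartProfile:
    """Counts of alignment 5' ends for one strand.

    The biological 5' end is the leftmost base for ``+`` alignments and the
    rightmost base (``end - 1``) for ``-`` alignments.
    """
    counts = np.zeros(replicon_length, dtype=np.int64)
    for a in alignments:
        if a.replicon_id != replicon_id or a.strand != strand:
            continue
        if sample_id and a.sample_id and a.sample_id != sample_id:
            continue
        pos = a.start if strand == "+" else a.end - 1
        if pos >= replicon_length:
            raise ValueError(f"alignment {a.read_id!r} beyond replicon")
        counts[pos] += 1
    return StartProfile(
        replicon_id=replicon_id, strand=strand, counts=counts, sample_id=sample_id
    )


def intergenic_regions(
    features: Sequence[Feature], replicon_length: int, replicon_id: str | None = None
) -> list[tuple[int, int]]:
    """Complement of the union of annotated genic intervals (both strands).

    Genic space is defined by :data:`GENIC_TYPES`; the result is a sorted
    list of disjoint 0-based half-open intervals.
    """
    intervals = sorted(
        (f.start, min(f.end, replicon_length))
        for f in features
        if f.ftype in GENIC_TYPES
        and (replicon_id is None or f.replicon_id == replicon_id)
    )
    out: list[tuple[int, int]] = []
    cursor = 0
    for s, e in intervals:
        if s > cursor:
            out.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < replicon_length:
        out.append((cursor, replicon_length))
    return out


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write a depth track as bedGraph (0-based half-open, runs merged)."""
    depth = track.depth
    with open(path, "w") as fh:
        if len(depth) == 0:
            return
        boundaries = np.flatnonzero(np.diff(depth)) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [len(depth)]))
        for s, e in zip(starts, ends):
            v = depth[s]
            if v != 0:
                fh.write(f"{track.replicon_id}\t{s}\t{e}\t{v}\n")


def write_start_profile(profiles: Iterable[StartProfile], path: str | Path) -> None:
    """Write start profiles as 4-column TSV: replicon, pos, strand, count."""
    with open(path, "w") as fh:
        fh.write("replicon\tpos\tstrand\tcount\n")
        for p in profiles:
            for pos in np.flatnonzero(p.counts):
                fh.write(f"{p.replicon_id}\t{pos}\t{p.strand}\t{p.counts[pos]}\n")
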