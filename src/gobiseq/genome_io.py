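"""Genome sequence/annotation I/O and replicon-level summary statistics.

Reads FASTA genomes and GFF3 feature annotations, and computes the summary
table familiar from bacterial genome announcements: per-replicon size, GC
content, coding density, CDS count and mean CDS length, plus length-weighted
genome-wide totals.

Coordinate conventions: internal coordinates are 0-based half-open
throughout the package; GFF3 (1-based inclusive) is converted at the I/O
boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
from Bio import SeqIO

log = logging.getLogger(__name__)

#: GFF3 feature types the pipeline understands; anything else is skipped
#: with a warning.
KNOWN_FEATURE_TYPES = frozenset({"CDS", "rRNA", "tRNA", "ncRNA", "pseudogene"})

_IUPAC = frozenset("ACGTNRYSWKMBDHV")


class ParseError(ValueError):
    """Malformed input file (offending record named in the message)."""


@dataclass(frozen=True)
class Replicon:
    """A single chromosome or plasmid sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence.upper()) - _IUPAC
        if bad:
            raise ParseError(
                f"replicon {self.id!r}: non-IUPAC characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Feature:
    """An annotated feature in 0-based half-open coordinates.

    ``start``/``end`` satisfy ``0 <= start < end``; GFF3 I/O converts from
    the on-disk 1-based inclusive convention.
    """

    replicon_id: str
    start: int
    end: int
    strand: str
    ftype: str
    gene_id: str
    product: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.gene_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.gene_id!r}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RepliconStats:
    length: int
    gc_percent: float
    coding_density_percent: float
    n_cds: int
    mean_cds_length: float


@dataclass(frozen=True)
class GenomeStats:
    total_size: int
    total_cds: int
    weighted_gc_percent: float
    weighted_coding_density_percent: float
    feature_counts: Mapping[str, int] = field(default_factory=dict)


def read_fasta(path: str | Path) -> list[Replicon]:
    """Read a FASTA file into a list of :class:`Replicon`, order preserved.

    Raises :class:`ParseError` on an empty file, duplicate record ids, or
    non-IUPAC characters (the offending record is named).
    """
    replicons: list[Replicon] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"duplicate FASTA record id {rec.id!r}")
        seen.add(rec.id)
        replicons.append(Replicon(id=rec.id, sequence=str(rec.seq).upper()))
    if not replicons:
        raise ParseError(f"no FASTA records found in {path}")
    return replicons


def read_gff3(
    path: str | Path,
    replicon_lengths: Mapping[str, int] | None = None,
) -> list[Feature]:
    """Read GFF3 features, converting to 0-based half-open coordinates.

    Feature types outside :data:`KNOWN_FEATURE_TYPES` are ignored with a
    logged warning. If ``replicon_lengths`` is given, coordinates beyond the
    replicon end raise :class:`ParseError`.
    """
    features: list[Feature] = []
    seen_ids: set[str] = set()
    for rec in gffutils.DataIterator(str(path)):
        if rec.featuretype not in KNOWN_FEATURE_TYPES:
            log.warning("ignoring GFF3 feature of unknown type %r", rec.featuretype)
            continue
        if rec.end < rec.start:
            raise ParseError(
                f"GFF3 feature on {rec.seqid}: end {rec.end} < start {rec.start}"
            )
        if replicon_lengths is not None:
            rlen = replicon_lengths.get(rec.seqid)
            if rlen is not None and rec.end > rlen:
                raise ParseError(
                    f"GFF3 feature on {rec.seqid}: end {rec.end} beyond "
                    f"replicon length {rlen}"
                )
        gid = rec.attributes.get("ID", [None])[0] or rec.attributes.get(
            "locus_tag", [None]
        )[0]
        if gid is None:
            gid = f"{rec.seqid}:{rec.start}-{rec.end}"
        if gid in seen_ids:
            raise ParseError(f"duplicate gene_id {gid!r} in {path}")
        seen_ids.add(gid)
        product = rec.attributes.get("product", [""])[0]
        features.append(
            Feature(
                replicon_id=rec.seqid,
                start=rec.start - 1,  # GFF3 is 1-based inclusive
                end=rec.end,
                strand=rec.strand if rec.strand in ("+", "-") else "+",
                ftype=rec.featuretype,
                gene_id=gid,
                product=product,
            )
        )
    return features


def write_gff3(features: Iterable[Feature], path: str | Path) -> None:
    """Write features as GFF3 (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.gene_id}"
            if f.product:
                attrs += f";product={f.product}"
            fh.write(
                f"{f.replicon_id}\tgobiseq\t{f.ftype}\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\t{attrs}\n"
            )


def merged_cds_coverage(features: Sequence[Feature], length: int) -> int:
    """Number of bases covered by at least one CDS, overlaps merged.

    Both strands are pooled: the per-base union is the only aggregation of
    coding density that is reproducible from an annotation alone.
    """
    intervals = sorted(
        (f.start, f.end) for f in features if f.ftype == "CDS"
    )
    covered = 0
    cur_start, cur_end = None, None
    for s, e in intervals:
        e = min(e, length)
        if cur_end is None:
            cur_start, cur_end = s, e
        elif s <= cur_end:
            cur_end = max(cur_end, e)
        else:
            covered += cur_end - cur_start
            cur_start, cur_end = s, e
    if cur_end is not None:
        covered += cur_end - cur_start
    return covered


def replicon_summary(replicon: Replicon, features: Sequence[Feature]) -> RepliconStats:
    """Summary statistics for one replicon.

    GC% is computed over non-N bases only; coding density merges overlapping
    CDS on both strands; mean CDS length excludes pseudogenes (they are a
    separate annotation class).
    """
    if replicon.length == 0:
        raise ValueError(f"replicon {replicon.id!r} has empty sequence")
    own = [f for f in features if f.replicon_id == replicon.id]
    for f in own:
        if f.end > replicon.length:
            raise ValueError(
                f"feature {f.gene_id!r} extends beyond replicon {replicon.id!r}"
            )
    seq = replicon.sequence
    n_count = seq.count("N")
    gc = seq.count("G") + seq.count("C")
    denom = replicon.length - n_count
    gc_percent = 100.0 * gc / denom if denom else 0.0
    covered = merged_cds_coverage(own, replicon.length)
    cds = [f for f in own if f.ftype == "CDS"]
    mean_len = float(np.mean([f.length for f in cds])) if cds else 0.0
    return RepliconStats(
        length=replicon.length,
        gc_percent=gc_percent,
        coding_density_percent=100.0 * covered / replicon.length,
        n_cds=len(cds),
        mean_cds_length=mean_len,
    )


def genome_totals(
    stats: Sequence[RepliconStats],
    feature_counts: Mapping[str, int] | None = None,
) -> GenomeStats:
    """Aggregate per-replicon statistics into genome-wide totals.

    Sizes and CDS counts are summed; GC and coding density are
    length-weighted means rounded to two decimals.
    """
    if not stats:
        raise ValueError("genome_totals requires at least one replicon")
    total = sum(s.length for s in stats)
    wgc = sum(s.gc_percent * s.length for s in stats) / total
    wdens = sum(s.coding_density_percent * s.length for s in stats) / total
    return GenomeStats(
        total_size=total,
        total_cds=sum(s.n_cds for s in stats),
        weighted_gc_percent=round(wgc, 2),
        weighted_coding_density_percent=round(wdens, 2),
        feature_counts=dict(feature_counts or {}),
    )


def count_by_category(
    features: Sequence[Feature],
    category_map: Mapping[str, str],
    gene_types: frozenset[str] = frozenset({"CDS"}),
) -> dict[str, int]:
    """Tabulate genes by functional category (e.g. COG letters).

    Genes missing from ``category_map`` are counted under ``"unassigned"``;
    the counts always partition the gene set.
    """
    counts: dict[str, int] = {}
    for f in features:
        if f.ftype not in gene_types:
            continue
        cat = category_map.get(f.gene_id, "unassigned")
        counts[cat] = counts.get(cat, 0) + 1
    return counts


def summary_table(
    replicons: Sequence[Replicon],
    features: Sequence[Feature],
    path: str | Path | None = None,
):
    """Per-replicon summary rows plus an "All" totals row, as a DataFrame.

    Optionally written to ``path`` as TSV.
    """
    import pandas as pd

    rows = []
    per_rep = []
    for rep in replicons:
        st = replicon_summary(rep, features)
        per_rep.append(st)
        rows.append(
            {
                "replicon": rep.id,
                "size_bp": st.length,
                "gc_percent": round(st.gc_percent, 2),
                "coding_density_percent": round(st.coding_density_percent, 2),
                "n_cds": st.n_cds,
                "mean_cds_length_nt": round(st.mean_cds_length, 1),
            }
        )
    totals = genome_totals(per_rep)
    all_cds = [f for f in features if f.ftype == "CDS"]
    rows.append(
        {
            "replicon": "All",
            "size_bp": totals.total_size,
            "gc_percent": totals.weighted_gc_percent,
            "coding_density_percent": totals.weighted_coding_density_percent,
            "n_cds": totals.total_cds,
            "mean_cds_length_nt": round(
                float(np.mean([f.length for f in all_cds])) if all_cds else 0.0, 1
            ),
        }
    )
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
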