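"""TSS calling and intergenic ncRNA detection from coverage profiles.

A transcription start site (TSS) is a position whose read-5'-end support,
summed over the control and UV samples, reaches ``min_reads`` (default 5).
Each TSS is associated with the nearest downstream gene start on the same
strand within a configurable window.

An ncRNA candidate is a maximal run of transcribed positions (depth >= 1)
inside intergenic space that is at least ``minlen`` bases long (default 30)
with mean depth at least ``mindepth`` (default 15 reads/bp); candidates are
then classified with externally supplied homology flags (no similarity to
protein-coding genes, or similarity to known ncRNAs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .coverage import CoverageTrack, StartProfile
from .genome_io import Feature

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TSSCall:
    replicon_id: str
    position: int  # 0-based
    strand: str
    support_total: int  # reads summed over both samples
    gene_id: str | None = None


@dataclass(frozen=True)
class NcRNACandidate:
    replicon_id: str
    start: int
    end: int  # 0-based half-open
    mean_depth: float
    status: str = "candidate"  # candidate | rejected_protein_hit | confirmed_ncrna_hit

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def call_tss(
    start_ctrl: StartProfile,
    start_uv: StartProfile,
    features: Sequence[Feature],
    min_reads: int = 5,
    window: int = 250,
) -> list[TSSCall]:
    """Call TSS positions where ctrl+uv 5'-end support reaches ``min_reads``.

    Both profiles must come from the same replicon and strand.  Calls are
    associated with the nearest downstream gene start on the same strand
    within ``window`` bp, and returned sorted by position.
    """
    if (
        start_ctrl.replicon_id != start_uv.replicon_id
        or start_ctrl.strand != start_uv.strand
    ):
        raise ValueError("start profiles disagree on replicon or strand")
    strand = start_ctrl.strand
    total = start_ctrl.counts + start_uv.counts
    positions = np.flatnonzero(total >= min_reads)

    # gene 5' ends on this strand and replicon, sorted for bisection
    gene_5p = sorted(
        (f.start if strand == "+" else f.end - 1, f.gene_id)
        for f in features
        if f.ftype == "CDS"
        and f.strand == strand
        and f.replicon_id == start_ctrl.replicon_id
    )
    starts = np.array([p for p, _ in gene_5p], dtype=np.int64)

    calls = []
    for pos in positions:
        gene = None
        if len(starts):
            if strand == "+":
                # nearest gene start at or after pos
                i = int(np.searchsorted(starts, pos, side="left"))
                if i < len(starts) and starts[i] - pos <= window:
                    gene = gene_5p[i][1]
            else:
                # downstream on '-' means smaller coordinates
                i = int(np.searchsorted(starts, pos, side="right")) - 1
                if i >= 0 and pos - starts[i] <= window:
                    gene = gene_5p[i][1]
        calls.append(
            TSSCall(
                replicon_id=start_ctrl.replicon_id,
                position=int(pos),
                strand=strand,
                support_total=int(total[pos]),
                gene_id=gene,
            )
        )
    return calls


def detect_transcribed_intergenic(
    track: CoverageTrack,
    intergenic: Sequence[tuple[int, int]],
    minlen: int = 30,
    mindepth: float = 15.0,
) -> list[NcRNACandidate]:
    """Extract transcribed intergenic runs as ncRNA candidates.

    Within each intergenic interval, maximal runs of consecutive positions
    with depth >= 1 are formed; a run is emitted when its length is at least
    ``minlen`` AND its mean depth is at least ``mindepth``.  The track
    should be the pooled depth of both conditions.
    """
    depth = track.depth
    out: list[NcRNACandidate] = []
    for lo, hi in intergenic:
        seg = depth[lo:hi]
        nz = seg > 0
        if not nz.any():
            continue
        # run boundaries of the boolean mask
        edges = np.flatnonzero(np.diff(np.concatenate(([0], nz.view(np.int8), [0]))))
        for s, e in zip(edges[::2], edges[1::2]):
            run_len = e - s
            if run_len < minlen:
                continue
            mean = float(seg[s:e].mean())
            if mean >= mindepth:
                out.append(
                    NcRNACandidate(
                        replicon_id=track.replicon_id,
                        start=int(lo + s),
                        end=int(lo + e),
                        mean_depth=mean,
                    )
                )
    return out


def classify_ncrna(
    candidates: Sequence[NcRNACandidate],
    hit_flags: Mapping[tuple[int, int], Mapping[str, bool]],
) -> list[NcRNACandidate]:
    """Apply externally computed homology flags to ncRNA candidates.

    ``hit_flags`` maps candidate intervals to ``{"protein_hit": bool,
    "ncrna_hit": bool}``.  Similarity to a known ncRNA dominates: such a
    candidate is confirmed even if it also matches a protein.  A candidate
    with a protein hit only is rejected; with neither flag it stays a
    candidate.  Missing intervals are treated as (False, False) and logged.
    """
    out = []
    for c in candidates:
        flags = hit_flags.get(c.interval)
        if flags is None:
            log.warning("no homology flags for interval %s; assuming no hits", c.interval)
            flags = {}
        if flags.get("ncrna_hit", False):
            status = "confirmed_ncrna_hit"
        elif flags.get("protein_hit", False):
            status = "rejected_protein_hit"
        else:
            status = "candidate"
        out.append(
            NcRNACandidate(
                replicon_id=c.replicon_id,
                start=c.start,
                end=c.end,
                mean_depth=c.mean_depth,
                status=status,
            )
        )
    return out


def write_tss_tsv(calls: Sequence[TSSCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("replicon\tpos\tstrand\tsupport\tgene\n")
        for c in calls:
            fh.write(
                f"{c.replicon_id}\t{c.position}\t{c.strand}\t{c.support_total}\t"
                f"{c.gene_id or '.'}\n"
            )


def write_ncrna_bed(candidates: Sequence[NcRNACandidate], bed_path, tsv_path=None) -> None:
    """BED6 with mean depth in the score column (clamped to 1000 in BED;
    exact values in the companion TSV)."""
    with open(bed_path, "w") as fh:
        for i, c in enumerate(candidates):
            score = min(int(round(c.mean_depth)), 1000)
            fh.write(
                f"{c.replicon_id}\t{c.start}\t{c.end}\tncRNA_{i + 1}\t{score}\t.\n"
            )
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write("replicon\tstart\tend\tlength\tmean_depth\tstatus\n")
            for c in candidates:
                fh.write(
                    f"{c.replicon_id}\t{c.start}\t{c.end}\t{c.length}\t"
                    f"{c.mean_depth:.3f}\t{c.status}\n"
                )
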