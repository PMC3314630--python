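"""Synthetic data with planted ground truth for every pipeline stage.

Generates, deterministically from a seed, the whole input universe of the
pipeline at desk scale: a multi-replicon bacterial genome with non-
overlapping gene annotations (CDS plus rRNA/tRNA), two-condition Poisson
read counts with planted fold changes, coverage tracks with planted TSS
pileups and transcribed intergenic (ncRNA) segments, tabular homology-hit
tables with planted taxonomic affiliations, and support-annotated gene
trees perturbed from a known species tree.  The planted truth is returned
alongside the data, so recovery by the analysis modules can be scored
exactly.

All generators draw from a single numpy Generator created from
``SimConfig.seed``; the same config always yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from .coverage import CoverageTrack, StartProfile
from .diffexpr import GeneCountTable, GeneCounts
from .genome_io import Feature, Replicon
from .ortho_hgt import DEINO_PHYLUM
from .phylo_consensus import tree_bipartitions


@dataclass
class SimConfig:
    """All knobs of the synthetic universe; ``seed`` is mandatory."""

    seed: int
    # genome layout
    n_replicons: int = 2
    replicon_lengths: tuple[int, ...] = (60_000, 25_000)
    n_genes: int = 60
    gene_length_bounds: tuple[int, int] = (300, 1500)
    intergenic_gap_bounds: tuple[int, int] = (60, 400)
    gc_content: float = 0.69
    n_rrna: int = 2
    n_trna: int = 4
    # expression / differential expression
    expr_log_mean: float = 1.0
    expr_log_sd: float = 1.0
    induced_fraction: float = 0.05
    repressed_fraction: float = 0.05
    de_fold: float = 4.0
    genic_fraction: float = 0.9
    read_length: int = 101
    library_size_ctrl: int = 1_000_000
    library_size_uv: int = 1_000_000
    # planted TSS / ncRNA
    n_tss: int = 30
    tss_pileup_bounds: tuple[int, int] = (5, 50)
    n_ncrna: int = 10
    ncrna_length_bounds: tuple[int, int] = (30, 200)
    ncrna_depth_bounds: tuple[int, int] = (15, 60)
    background_noise_rate: float = 0.0
    # homology hits / affiliation
    n_queries: int = 500
    phylum_pool: tuple[str, ...] = (
        "Proteobacteria",
        "Actinobacteria",
        "Firmicutes",
        "Cyanobacteria",
        DEINO_PHYLUM,
    )
    affiliation_mix: tuple[float, float, float] = (0.6, 0.25, 0.15)
    # gene trees
    n_taxa: int = 8
    n_gene_trees: int = 20
    split_noise: float = 0.1
    support_true_bounds: tuple[int, int] = (70, 100)
    support_perturbed_bounds: tuple[int, int] = (30, 69)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class SyntheticTruth:
    """Planted ground truth, the recovery oracle for every stage."""

    gene_classes: dict[str, str] = field(default_factory=dict)
    gene_folds: dict[str, float] = field(default_factory=dict)
    tss: list[tuple[str, int, str, int]] = field(default_factory=list)
    ncrna: list[tuple[str, int, int, int]] = field(default_factory=list)
    affiliations: dict[str, dict] = field(default_factory=dict)
    species_tree_newick: str = ""

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=list)


def simulate_genome(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[Replicon], list[Feature], SyntheticTruth]:
    """Random genome with non-overlapping genes separated by sampled gaps.

    rRNA and tRNA features are interspersed among the CDS; placement walks
    each replicon left to right, drawing gap and gene lengths from the
    configured bounds.  Raises if the requested features cannot fit.
    """
    rng = config.rng() if rng is None else rng
    if len(config.replicon_lengths) != config.n_replicons:
        raise ValueError("replicon_lengths must match n_replicons")
    ftypes = (
        ["CDS"] * config.n_genes
        + ["rRNA"] * config.n_rrna
        + ["tRNA"] * config.n_trna
    )
    rng.shuffle(ftypes)
    features: list[Feature] = []
    queue = list(ftypes)
    counters = {"CDS": 0, "rRNA": 0, "tRNA": 0}
    prefix = {"CDS": "gene", "rRNA": "rrna", "tRNA": "trna"}
    for ridx, rlen in enumerate(config.replicon_lengths):
        rep_id = f"rep{ridx + 1}"
        cursor = 0
        while queue:
            gap = int(rng.integers(*config.intergenic_gap_bounds, endpoint=True))
            if queue[0] in ("rRNA", "tRNA"):
                flen = int(rng.integers(80, 1500 if queue[0] == "rRNA" else 90))
            else:
                flen = int(rng.integers(*config.gene_length_bounds, endpoint=True))
            if cursor + gap + flen + 1 > rlen:
                break
            ftype = queue.pop(0)
            counters[ftype] += 1
            start = cursor + gap
            features.append(
                Feature(
                    replicon_id=rep_id,
                    start=start,
                    end=start + flen,
                    strand="+" if rng.random() < 0.5 else "-",
                    ftype=ftype,
                    gene_id=f"{prefix[ftype]}_{counters[ftype]:04d}",
                    product=f"synthetic {ftype}",
                )
            )
            cursor = start + flen
    if queue:
        raise ValueError(
            f"{len(queue)} features could not be placed on "
            f"{sum(config.replicon_lengths)} bp of replicon space"
        )
    gc = config.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    replicons = [
        Replicon(
            id=f"rep{ridx + 1}",
            sequence="".join(
                rng.choice(np.array(list("ATGC")), size=rlen, p=p)
            ),
        )
        for ridx, rlen in enumerate(config.replicon_lengths)
    ]
    truth = SyntheticTruth()
    cds = [f for f in features if f.ftype == "CDS"]
    n_ind = int(round(config.induced_fraction * len(cds)))
    n_rep = int(round(config.repressed_fraction * len(cds)))
    de_idx = rng.choice(len(cds), size=min(n_ind + n_rep, len(cds)), replace=False)
    for rank, gidx in enumerate(de_idx):
        gid = cds[gidx].gene_id
        if rank < n_ind:
            truth.gene_classes[gid] = "induced"
            truth.gene_folds[gid] = config.de_fold
        else:
            truth.gene_classes[gid] = "repressed"
            truth.gene_folds[gid] = 1.0 / config.de_fold
    for f in cds:
        truth.gene_classes.setdefault(f.gene_id, "null")
        truth.gene_folds.setdefault(f.gene_id, 1.0)
    return replicons, features, truth


def simulate_counts(
    config: SimConfig,
    truth: SyntheticTruth,
    features: Sequence[Feature],
    rng: np.random.Generator | None = None,
) -> GeneCountTable:
    """Two-condition Poisson counts with planted fold changes.

    Per-gene rates are log-normal; a gene's expected count is the library
    size times the genic fraction times its rate-length share, and UV
    expectations are additionally multiplied by the planted fold.  Library
    totals are the configured mapped-read totals (genic reads are the
    configured fraction of them), so the expected FPKM ratio of a planted
    gene equals its fold exactly.
    """
    rng = config.rng() if rng is None else rng
    cds = [f for f in features if f.ftype == "CDS"]
    if not cds:
        raise ValueError("no CDS features to simulate counts for")
    rates = rng.lognormal(config.expr_log_mean, config.expr_log_sd, size=len(cds))
    weight = rates * np.array([f.length for f in cds])
    weight /= weight.sum()
    folds = np.array([truth.gene_folds.get(f.gene_id, 1.0) for f in cds])
    lam_ctrl = config.library_size_ctrl * config.genic_fraction * weight
    lam_uv = config.library_size_uv * config.genic_fraction * weight * folds
    a = rng.poisson(lam_ctrl)
    b = rng.poisson(lam_uv)
    genes = [
        GeneCounts(f.gene_id, f.length, int(a[i]), int(b[i]))
        for i, f in enumerate(cds)
    ]
    return GeneCountTable(
        genes=genes, n_ctrl=config.library_size_ctrl, n_uv=config.library_size_uv
    )


def simulate_coverage(
    config: SimConfig,
    truth: SyntheticTruth,
    replicons: Sequence[Replicon],
    features: Sequence[Feature],
    counts: GeneCountTable | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, CoverageTrack], dict[tuple[str, str, str], StartProfile]]:
    """Pooled coverage tracks plus per-sample, per-strand start profiles.

    Genic depth is spread uniformly over each gene from its (simulated)
    counts; TSS pileups of the configured size are planted at the 5' starts
    of a random gene subset and split binomially between the two samples;
    intergenic transcripts are planted one per chosen gap at uniform depth,
    flanked by at least one zero base.  With a zero background noise rate,
    intergenic depth is nonzero only inside planted ncRNAs.  Records the
    planted TSS and ncRNA truth in ``truth``.
    """
    rng = config.rng() if rng is None else rng
    from .coverage import intergenic_regions

    count_by_gene = (
        {g.gene_id: g.count_ctrl + g.count_uv for g in counts.genes}
        if counts is not None
        else {}
    )
    tracks: dict[str, CoverageTrack] = {}
    profiles: dict[tuple[str, str, str], StartProfile] = {}
    depth_arrays = {}
    for rep in replicons:
        depth_arrays[rep.id] = np.zeros(rep.length, dtype=np.int64)
        for sample in ("ctrl", "uv"):
            for strand in ("+", "-"):
                profiles[(rep.id, sample, strand)] = StartProfile(
                    replicon_id=rep.id,
                    strand=strand,
                    counts=np.zeros(rep.length, dtype=np.int64),
                    sample_id=sample,
                )
    # genic depth from counts (uniform across the gene)
    for f in features:
        if f.ftype != "CDS":
            continue
        total = count_by_gene.get(f.gene_id, 0)
        depth = int(round(total * config.read_length / f.length)) if total else 1
        depth_arrays[f.replicon_id][f.start : f.end] += depth

    # planted TSS pileups at gene 5' starts
    cds = [f for f in features if f.ftype == "CDS"]
    n_tss = min(config.n_tss, len(cds))
    chosen = rng.choice(len(cds), size=n_tss, replace=False)
    for gidx in sorted(chosen):
        f = cds[gidx]
        pos = f.start if f.strand == "+" else f.end - 1
        size = int(rng.integers(*config.tss_pileup_bounds, endpoint=True))
        in_ctrl = int(rng.binomial(size, 0.5))
        profiles[(f.replicon_id, "ctrl", f.strand)].counts[pos] += in_ctrl
        profiles[(f.replicon_id, "uv", f.strand)].counts[pos] += size - in_ctrl
        truth.tss.append((f.replicon_id, pos, f.strand, size))

    # planted intergenic transcripts, at most one per gap, 1-bp zero margin
    gaps = [
        (rep.id, lo, hi)
        for rep in replicons
        for lo, hi in intergenic_regions(features, rep.length, rep.id)
    ]
    rng.shuffle(gaps)
    planted = 0
    for rep_id, lo, hi in gaps:
        if planted >= config.n_ncrna:
            break
        length = int(rng.integers(*config.ncrna_length_bounds, endpoint=True))
        if hi - lo < length + 2:
            continue
        start = int(rng.integers(lo + 1, hi - length))
        depth = int(rng.integers(*config.ncrna_depth_bounds, endpoint=True))
        depth_arrays[rep_id][start : start + length] += depth
        truth.ncrna.append((rep_id, start, start + length, depth))
        planted += 1
    truth.ncrna.sort()

    # background singleton noise
    if config.background_noise_rate > 0:
        for rep in replicons:
            n_noise = rng.poisson(config.background_noise_rate * rep.length)
            for pos in rng.integers(0, rep.length, size=n_noise):
                depth_arrays[rep.id][pos] += 1
                sample = "ctrl" if rng.random() < 0.5 else "uv"
                strand = "+" if rng.random() < 0.5 else "-"
                profiles[(rep.id, sample, strand)].counts[pos] += 1

    for rep in replicons:
        tracks[rep.id] = CoverageTrack(
            replicon_id=rep.id, depth=depth_arrays[rep.id], strand_mode="pooled"
        )
    return tracks, profiles


def simulate_hits(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[dict], dict[str, tuple[str, str | None]], SyntheticTruth]:
    """Tabular hit rows with planted affiliation truth.

    Per query a true label is drawn from the affiliation mix; qualifying
    hits (E < 1e-4, bit score within 95% of the best) are emitted
    consistent with the label, plus decoy hits that fail either filter.
    Returns (hit rows, subject taxonomy map, truth).
    """
    rng = config.rng() if rng is None else rng
    truth = SyntheticTruth()
    orders = ("Deinococcales", "Thermales")
    rows: list[dict] = []
    taxonomy: dict[str, tuple[str, str | None]] = {}
    subj_counter = 0

    def new_subject(phylum: str, order: str | None) -> str:
        nonlocal subj_counter
        subj_counter += 1
        sid = f"subj_{subj_counter:05d}"
        taxonomy[sid] = (phylum, order)
        return sid

    def add_row(query: str, subject: str, bitscore: float, evalue: float) -> None:
        rows.append(
            {
                "qseqid": query,
                "sseqid": subject,
                "pident": round(float(rng.uniform(40, 99)), 1),
                "length": int(rng.integers(80, 400)),
                "mismatch": int(rng.integers(0, 50)),
                "gapopen": int(rng.integers(0, 5)),
                "qstart": 1,
                "qend": 100,
                "sstart": 1,
                "send": 100,
                "evalue": evalue,
                "bitscore": round(bitscore, 1),
            }
        )

    p_assigned, p_unresolved, _ = config.affiliation_mix
    for qidx in range(config.n_queries):
        query = f"q_{qidx + 1:04d}"
        u = rng.random()
        best = float(rng.uniform(150, 400))
        if u < p_assigned:
            phylum = str(rng.choice(list(config.phylum_pool)))
            order = str(rng.choice(list(orders))) if phylum == DEINO_PHYLUM else None
            n_hits = int(rng.integers(1, 6))
            # best hit carries the truth order; later hits strictly weaker
            scores = best * np.concatenate(
                ([1.0], rng.uniform(0.951, 0.999, size=n_hits - 1))
            )
            for k, score in enumerate(scores):
                o = order if phylum == DEINO_PHYLUM else None
                if k > 0 and phylum == DEINO_PHYLUM:
                    o = str(rng.choice(list(orders)))
                add_row(
                    query,
                    new_subject(phylum, o),
                    float(score),
                    float(10.0 ** rng.uniform(-30, -5)),
                )
            # decoys: wrong phylum but below the 95% band or above E cutoff
            for _ in range(int(rng.integers(0, 3))):
                other = str(rng.choice([p for p in config.phylum_pool if p != phylum]))
                if rng.random() < 0.5:
                    add_row(
                        query,
                        new_subject(other, None),
                        best * float(rng.uniform(0.5, 0.94)),
                        float(10.0 ** rng.uniform(-30, -5)),
                    )
                else:
                    add_row(
                        query,
                        new_subject(other, None),
                        best * float(rng.uniform(0.96, 0.999)),
                        float(10.0 ** rng.uniform(-3, 1)),
                    )
            truth.affiliations[query] = {
                "status": "assigned",
                "phylum": phylum,
                "order": order,
            }
        elif u < p_assigned + p_unresolved:
            two = rng.choice(len(config.phylum_pool), size=2, replace=False)
            phyla = [config.phylum_pool[i] for i in two]
            for k in range(2):
                add_row(
                    query,
                    new_subject(phyla[k], None),
                    best * (1.0 if k == 0 else float(rng.uniform(0.96, 0.999))),
                    float(10.0 ** rng.uniform(-30, -5)),
                )
            truth.affiliations[query] = {
                "status": "unresolved",
                "phylum": None,
                "order": None,
            }
        else:
            # no qualifying hit: either nothing, or hits above the E cutoff
            if rng.random() < 0.5:
                add_row(
                    query,
                    new_subject(str(rng.choice(list(config.phylum_pool))), None),
                    best,
                    float(10.0 ** rng.uniform(-3, 1)),
                )
            truth.affiliations[query] = {
                "status": "no_hit",
                "phylum": None,
                "order": None,
            }
    return rows, taxonomy, truth


def _random_binary_tree(
    taxa: Sequence[str], rng: np.random.Generator
) -> dendropy.Tree:
    """Random binary topology by successive joins; branch lengths U(0.1, 1)."""
    tns = dendropy.TaxonNamespace(list(taxa))
    nodes = [dendropy.Node(taxon=tns.get_taxon(t)) for t in taxa]
    for node in nodes:
        node.edge.length = float(rng.uniform(0.1, 1.0))
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = float(rng.uniform(0.1, 1.0))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = nodes[0]
    tree.seed_node.edge.length = None
    return tree


def _nni(tree: dendropy.Tree, rng: np.random.Generator) -> bool:
    """One nearest-neighbor interchange on a random internal edge."""
    candidates = [
        nd
        for nd in tree.preorder_internal_node_iter(exclude_seed_node=True)
        if nd.parent_node is not None and len(nd.child_nodes()) >= 2
    ]
    if not candidates:
        return False
    child = candidates[int(rng.integers(len(candidates)))]
    parent = child.parent_node
    siblings = [c for c in parent.child_nodes() if c is not child]
    if not siblings:
        return False
    sib = siblings[int(rng.integers(len(siblings)))]
    grandkids = child.child_nodes()
    moved = grandkids[int(rng.integers(len(grandkids)))]
    child.remove_child(moved)
    parent.remove_child(sib)
    child.add_child(sib)
    parent.add_child(moved)
    return True


def simulate_gene_trees(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[str], dendropy.Tree, SyntheticTruth]:
    """Gene trees perturbed from a random species tree, with supports.

    Each gene tree applies a nearest-neighbor interchange to each internal
    edge with probability ``split_noise``.  Splits also present in the
    species tree get supports from ``support_true_bounds`` (>= 70 by
    default); perturbed splits from ``support_perturbed_bounds``.
    Returns (newick strings, species tree, truth).
    """
    rng = config.rng() if rng is None else rng
    if config.n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    taxa = [f"T{i + 1:02d}" for i in range(config.n_taxa)]
    species = _random_binary_tree(taxa, rng)
    true_splits = set(tree_bipartitions(species))
    newicks: list[str] = []
    for _ in range(config.n_gene_trees):
        gt = dendropy.Tree.get(
            data=species.as_string(schema="newick"),
            schema="newick",
            preserve_underscores=True,
        )
        n_internal = sum(
            1 for _ in gt.preorder_internal_node_iter(exclude_seed_node=True)
        )
        n_moves = int(rng.binomial(n_internal, config.split_noise))
        for _ in range(n_moves):
            _nni(gt, rng)
        splits = tree_bipartitions(gt)
        support_of = {}
        for bp in splits:
            lo, hi = (
                config.support_true_bounds
                if bp in true_splits
                else config.support_perturbed_bounds
            )
            support_of[bp] = int(rng.integers(lo, hi, endpoint=True))
        leaf_set = frozenset(lf.taxon.label for lf in gt.leaf_node_iter())
        anchor = min(leaf_set)
        for node in gt.preorder_internal_node_iter(exclude_seed_node=True):
            below = frozenset(lf.taxon.label for lf in node.leaf_iter())
            side = leaf_set - below if anchor in below else below
            if len(side) < 2 or len(leaf_set - side) < 2:
                node.label = None
                continue
            from .phylo_consensus import Bipartition

            node.label = str(support_of[Bipartition(side=side, leaf_set=leaf_set)])
        newicks.append(
            gt.as_string(schema="newick", suppress_rooting=True).strip()
        )
    truth = SyntheticTruth(
        species_tree_newick=species.as_string(
            schema="newick", suppress_rooting=True
        ).strip()
    )
    return newicks, species, truth


def write_hit_table(rows: Sequence[dict], path) -> None:
    """12-column tabular hit format, no header."""
    cols = [
        "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    ]
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(r[c]) for c in cols) + "\n")


def write_taxonomy(taxonomy: dict[str, tuple[str, str | None]], path) -> None:
    with open(path, "w") as fh:
        fh.write("subject\tphylum\torder\n")
        for sid in sorted(taxonomy):
            phylum, order = taxonomy[sid]
            fh.write(f"{sid}\t{phylum}\t{order or ''}\n")


def write_fasta(replicons: Sequence[Replicon], path) -> None:
    with open(path, "w") as fh:
        for rep in replicons:
            fh.write(f">{rep.id}\n")
            for i in range(0, rep.length, 70):
                fh.write(rep.sequence[i : i + 70] + "\n")


def write_counts_tsv(table: GeneCountTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tlength\tcount_ctrl\tcount_uv\n")
        for g in table.genes:
            fh.write(f"{g.gene_id}\t{g.cds_length}\t{g.count_ctrl}\t{g.count_uv}\n")


def emit_sam(
    replicons: Sequence[Replicon],
    profiles_or_alignments,
    path,
    read_length: int = 50,
) -> None:
    """Emit synthetic perfectly-aligned reads as plain-text SAM.

    Accepts a list of :class:`~gobiseq.coverage.Alignment`; reads are
    unclipped full matches so the SAM round-trips through the SAM reader to
    the same spans.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for rep in replicons:
            fh.write(f"@SQ\tSN:{rep.id}\tLN:{rep.length}\n")
        seqs = {rep.id: rep.sequence for rep in replicons}
        for a in profiles_or_alignments:
            flag = 16 if a.strand == "-" else 0
            seq = seqs[a.replicon_id][a.start : a.end]
            fh.write(
                f"{a.read_id}\t{flag}\t{a.replicon_id}\t{a.start + 1}\t60\t"
                f"{a.end - a.start}M\t*\t0\t0\t{seq}\t*\n"
            )
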