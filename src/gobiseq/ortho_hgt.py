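"""Taxonomic-affiliation HGT screening and reciprocal-best-hit orthology.

A query protein's taxonomic affiliation is decided from its tabular BLAST
hits: among hits with E-value below 1e-4, keep those scoring at least 95%
of the best bit score; if every kept hit belongs to one phylum the query is
affiliated with that phylum, otherwise it is unresolved (queries whose
affiliation falls outside the self phylum are horizontal-transfer
candidates).  Queries affiliated with Deinococcus-Thermus are further
assigned an order from the best-scoring hit.

Orthologous groups across genomes are defined as mutual fully transitive
reciprocal best hits: connected components of the reciprocal-best-hit graph
that contain at most one gene per genome and are cliques across genomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

DEINO_PHYLUM = "Deinococcus-Thermus"


@dataclass(frozen=True)
class BlastHit:
    query: str
    subject: str
    bitscore: float
    evalue: float
    subject_phylum: str | None = None
    subject_order: str | None = None

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("negative E-value")
        if self.bitscore <= 0:
            raise ValueError("non-positive bit score")


@dataclass(frozen=True)
class Affiliation:
    query: str
    status: str  # assigned | unresolved | no_hit
    phylum: str | None = None
    order: str | None = None


@dataclass(frozen=True)
class OrthologCluster:
    """One ortholog per genome; members maps genome_id -> gene_id."""

    members: tuple[tuple[str, str], ...]

    @property
    def genomes(self) -> frozenset[str]:
        return frozenset(g for g, _ in self.members)

    @property
    def size(self) -> int:
        return len(self.members)


class MissingTaxonomyError(KeyError):
    pass


def read_hit_table(
    path, taxonomy: Mapping[str, tuple[str, str | None]] | None = None
) -> list[BlastHit]:
    """Read 12-column tabular hits (qseqid sseqid pident length mismatch
    gapopen qstart qend sstart send evalue bitscore), optionally attaching
    phylum/order from a taxonomy map."""
    cols = [
        "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    ]
    df = pd.read_csv(path, sep="\t", names=cols, comment="#")
    hits = []
    for r in df.itertuples():
        phylum = order = None
        if taxonomy is not None and r.sseqid in taxonomy:
            phylum, order = taxonomy[r.sseqid]
        hits.append(
            BlastHit(
                query=str(r.qseqid),
                subject=str(r.sseqid),
                bitscore=float(r.bitscore),
                evalue=float(r.evalue),
                subject_phylum=phylum,
                subject_order=order,
            )
        )
    return hits


def read_taxonomy(path) -> dict[str, tuple[str, str | None]]:
    """Read a subject->taxonomy TSV with columns subject, phylum[, order]."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, tuple[str, str | None]] = {}
    for r in df.itertuples():
        order = getattr(r, "order", None)
        out[str(r.subject)] = (str(r.phylum), None if pd.isna(order) else str(order))
    return out


def qualifying_hits(
    hits: Sequence[BlastHit],
    evalue_max: float = 1e-4,
    score_frac: float = 0.95,
) -> list[BlastHit]:
    """Hits passing the E-value cutoff and scoring >= score_frac of the
    best bit score among E-value-passing hits (filter order matters)."""
    queries = {h.query for h in hits}
    if len(queries) > 1:
        raise ValueError("qualifying_hits expects hits for a single query")
    passing = [h for h in hits if h.evalue < evalue_max]
    if not passing:
        return []
    best = max(h.bitscore for h in passing)
    return [h for h in passing if h.bitscore >= score_frac * best]


def taxonomic_affiliation(qhits: Sequence[BlastHit], query: str | None = None) -> Affiliation:
    """Affiliate one query from its qualifying hits by phylum unanimity.

    No hits -> no_hit.  All hit phyla identical -> assigned; otherwise
    unresolved.  For Deinococcus-Thermus assignments the order is taken
    from the best-bitscore hit (ties broken by smallest subject id).
    """
    if not qhits:
        return Affiliation(query=query or "", status="no_hit")
    q = query or qhits[0].query
    for h in qhits:
        if h.subject_phylum is None:
            raise MissingTaxonomyError(f"no taxonomy for subject {h.subject!r}")
    phyla = {h.subject_phylum for h in qhits}
    if len(phyla) > 1:
        return Affiliation(query=q, status="unresolved")
    phylum = next(iter(phyla))
    order = None
    if phylum == DEINO_PHYLUM:
        best = min(qhits, key=lambda h: (-h.bitscore, h.subject))
        order = best.subject_order
    return Affiliation(query=q, status="assigned", phylum=phylum, order=order)


def affiliate_all(
    hits: Iterable[BlastHit],
    queries: Iterable[str] | None = None,
    evalue_max: float = 1e-4,
    score_frac: float = 0.95,
) -> list[Affiliation]:
    """Group hits by query and affiliate each; ``queries`` may add
    hit-less queries that should be reported as no_hit."""
    by_query: dict[str, list[BlastHit]] = {}
    for h in hits:
        by_query.setdefault(h.query, []).append(h)
    all_queries = sorted(set(by_query) | set(queries or ()))
    return [
        taxonomic_affiliation(
            qualifying_hits(by_query.get(q, []), evalue_max, score_frac), query=q
        )
        for q in all_queries
    ]


def ortholog_clusters(
    reciprocal_pairs: Iterable[tuple[tuple[str, str], tuple[str, str]]],
) -> tuple[list[OrthologCluster], list[frozenset[tuple[str, str]]]]:
    """Cluster genes from reciprocal-best-hit pairs.

    Each pair links two ``(genome_id, gene_id)`` genes from different
    genomes.  Clusters are connected components that (a) contain at most
    one gene per genome and (b) are cliques — every cross-genome gene pair
    is itself a reciprocal best hit ("fully transitive").  Components
    failing either condition are returned separately as rejected.
    """
    graph: nx.Graph = nx.Graph()
    for u, v in reciprocal_pairs:
        if u[0] == v[0]:
            continue  # self-genome pairs are not orthology evidence
        graph.add_edge(u, v)
    clusters: list[OrthologCluster] = []
    rejected: list[frozenset[tuple[str, str]]] = []
    for comp in nx.connected_components(graph):
        genomes = [g for g, _ in comp]
        one_per_genome = len(genomes) == len(set(genomes))
        n = len(comp)
        is_clique = graph.subgraph(comp).number_of_edges() == n * (n - 1) // 2
        if one_per_genome and is_clique and n >= 2:
            clusters.append(OrthologCluster(members=tuple(sorted(comp))))
        else:
            rejected.append(frozenset(comp))
    clusters.sort(key=lambda c: c.members)
    return clusters, rejected


def presence_absence(
    clusters: Sequence[OrthologCluster],
    genome_genes: Mapping[str, Iterable[str]],
) -> tuple[int, dict[str, int]]:
    """Core-genome and species-specific gene counts.

    Core = clusters spanning every genome in ``genome_genes``; a genome's
    specific count is its genes that appear in no cluster at all.
    """
    genomes = set(genome_genes)
    core = sum(1 for c in clusters if c.genomes == genomes)
    clustered: dict[str, set[str]] = {g: set() for g in genomes}
    for c in clusters:
        for g, gene in c.members:
            if g in clustered:
                clustered[g].add(gene)
    specific = {
        g: sum(1 for gene in genes if gene not in clustered[g])
        for g, genes in genome_genes.items()
    }
    return core, specific


def presence_absence_matrix(
    clusters: Sequence[OrthologCluster], genomes: Sequence[str]
) -> pd.DataFrame:
    """0/1 cluster-by-genome membership matrix."""
    data = {
        g: [1 if g in c.genomes else 0 for c in clusters] for g in genomes
    }
    return pd.DataFrame(data, index=[f"cluster_{i + 1}" for i in range(len(clusters))])
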