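"""Hit filtering, taxonomic affiliation and ortholog clustering."""

import pytest

from gobiseq.ortho_hgt import (
    Affiliation,
    BlastHit,
    MissingTaxonomyError,
    affiliate_all,
    ortholog_clusters,
    presence_absence,
    qualifying_hits,
    taxonomic_affiliation,
)


def _hit(q="q1", s="s1", score=200.0, e=1e-20, phylum="Proteobacteria", order=None):
    return BlastHit(q, s, score, e, phylum, order)


class TestQualifyingHits:
    def test_score_boundary_at_95_percent(self):
        hits = [
            _hit(s="best", score=200.0),
            _hit(s="keep", score=190.0),
            _hit(s="drop", score=189.9),
        ]
        kept = {h.subject for h in qualifying_hits(hits)}
        assert kept == {"best", "keep"}

    def test_evalue_cutoff_strict(self):
        assert qualifying_hits([_hit(e=1e-3)]) == []
        assert len(qualifying_hits([_hit(e=9.9e-5)])) == 1

    def test_best_score_taken_among_evalue_passing(self):
        # a huge-score hit with bad E-value must not set the 95% bar
        hits = [_hit(s="bad", score=1000.0, e=1.0), _hit(s="ok", score=100.0)]
        assert [h.subject for h in qualifying_hits(hits)] == ["ok"]

    def test_order_invariance(self, rng):
        hits = [
            _hit(s=f"s{i}", score=float(rng.uniform(50, 300)), e=float(10.0 ** rng.uniform(-30, 0)))
            for i in range(30)
        ]
        ref = {h.subject for h in qualifying_hits(hits)}
        for _ in range(5):
            perm = [hits[i] for i in rng.permutation(30)]
            assert {h.subject for h in qualifying_hits(perm)} == ref

    def test_matches_two_pass_oracle(self, rng):
        hits = [
            _hit(s=f"s{i}", score=float(rng.uniform(50, 300)), e=float(10.0 ** rng.uniform(-30, 0)))
            for i in range(50)
        ]
        passing = [h for h in hits if h.evalue < 1e-4]
        best = max((h.bitscore for h in passing), default=0.0)
        oracle = {h.subject for h in passing if h.bitscore >= 0.95 * best}
        assert {h.subject for h in qualifying_hits(hits)} == oracle

    def test_raising_score_frac_never_adds_hits(self, rng):
        hits = [_hit(s=f"s{i}", score=float(rng.uniform(100, 300))) for i in range(20)]
        prev = {h.subject for h in qualifying_hits(hits, score_frac=0.90)}
        for frac in (0.95, 0.99, 1.0):
            cur = {h.subject for h in qualifying_hits(hits, score_frac=frac)}
            assert cur <= prev
            prev = cur

    def test_mixed_queries_rejected(self):
        with pytest.raises(ValueError):
            qualifying_hits([_hit(q="a"), _hit(q="b")])


class TestAffiliation:
    def test_unanimous_phylum_assigned(self):
        aff = taxonomic_affiliation([_hit(s=f"s{i}") for i in range(3)])
        assert aff.status == "assigned" and aff.phylum == "Proteobacteria"

    def test_mixed_phyla_unresolved(self):
        hits = [_hit(s="s1"), _hit(s="s2"), _hit(s="s3", phylum="Firmicutes")]
        assert taxonomic_affiliation(hits).status == "unresolved"

    def test_no_hits(self):
        assert taxonomic_affiliation([], query="q9").status == "no_hit"

    def test_deino_order_from_best_hit(self):
        hits = [
            _hit(s="s1", score=300.0, phylum="Deinococcus-Thermus", order="Deinococcales"),
            _hit(s="s2", score=290.0, phylum="Deinococcus-Thermus", order="Thermales"),
        ]
        aff = taxonomic_affiliation(hits)
        assert aff.order == "Deinococcales"

    def test_best_hit_tie_broken_by_subject_id(self):
        hits = [
            _hit(s="zz", score=300.0, phylum="Deinococcus-Thermus", order="Thermales"),
            _hit(s="aa", score=300.0, phylum="Deinococcus-Thermus", order="Deinococcales"),
        ]
        assert taxonomic_affiliation(hits).order == "Deinococcales"

    def test_missing_taxonomy_named(self):
        with pytest.raises(MissingTaxonomyError, match="s1"):
            taxonomic_affiliation([_hit(phylum=None)])

    def test_planted_labels_fully_recovered(self):
        from gobiseq.synthetic_data import SimConfig, simulate_hits

        cfg = SimConfig(seed=5, n_queries=500)
        rows, taxonomy, truth = simulate_hits(cfg)
        hits = [
            BlastHit(
                r["qseqid"], r["sseqid"], r["bitscore"], r["evalue"],
                *taxonomy[r["sseqid"]],
            )
            for r in rows
        ]
        affs = affiliate_all(hits, queries=truth.affiliations)
        assert len(affs) == 500
        for a in affs:
            t = truth.affiliations[a.query]
            assert a.status == t["status"]
            assert (a.phylum or None) == t["phylum"]
            assert (a.order or None) == t["order"]

    def test_monotone_degradation_as_filter_tightens(self):
        from gobiseq.synthetic_data import SimConfig, simulate_hits

        cfg = SimConfig(seed=6, n_queries=200)
        rows, taxonomy, _ = simulate_hits(cfg)
        hits = [
            BlastHit(r["qseqid"], r["sseqid"], r["bitscore"], r["evalue"],
                     *taxonomy[r["sseqid"]])
            for r in rows
        ]
        def by_query(frac):
            return {a.query: a for a in affiliate_all(hits, score_frac=frac)}

        prev = by_query(0.95)
        for frac in (0.99, 1.0):
            cur = by_query(frac)
            for q, before in prev.items():
                after = cur[q]
                if before.status == "assigned":
                    # an assigned query can only stay assigned (same phylum,
                    # a subset of unanimous hits stays unanimous) or lose
                    # all its hits
                    assert after.status in ("assigned", "no_hit")
                    if after.status == "assigned":
                        assert after.phylum == before.phylum
                if before.status == "no_hit":
                    assert after.status == "no_hit"
            prev = cur


class TestOrthologClusters:
    def test_three_way_clique_is_one_cluster(self):
        a, b, c = ("G1", "a"), ("G2", "b"), ("G3", "c")
        clusters, rejected = ortholog_clusters([(a, b), (b, c), (a, c)])
        assert rejected == []
        assert len(clusters) == 1 and clusters[0].size == 3

    def test_missing_transitive_edge_rejected(self):
        a, b, c = ("G1", "a"), ("G2", "b"), ("G3", "c")
        clusters, rejected = ortholog_clusters([(a, b), (b, c)])
        assert clusters == [] and len(rejected) == 1

    def test_two_genes_one_genome_rejected(self):
        a, a2, b = ("G1", "a"), ("G1", "a2"), ("G2", "b")
        clusters, rejected = ortholog_clusters([(a, b), (a2, b)])
        assert clusters == []

    def test_self_genome_pairs_ignored(self):
        clusters, rejected = ortholog_clusters([(("G1", "a"), ("G1", "b"))])
        assert clusters == [] and rejected == []

    def test_matches_brute_force_clique_check(self, rng):
        import itertools

        import networkx as nx

        genes = [(f"G{g}", f"g{g}_{i}") for g in range(4) for i in range(5)]
        pairs = []
        for u, v in itertools.combinations(genes, 2):
            if u[0] != v[0] and rng.random() < 0.12:
                pairs.append((u, v))
        clusters, rejected = ortholog_clusters(pairs)
        graph = nx.Graph(pairs)
        for comp in nx.connected_components(graph):
            comp = frozenset(comp)
            genomes = [g for g, _ in comp]
            ok = len(genomes) == len(set(genomes)) and all(
                graph.has_edge(u, v) for u, v in itertools.combinations(comp, 2)
            )
            if ok and len(comp) >= 2:
                assert any(frozenset(c.members) == comp for c in clusters)
            else:
                assert comp in rejected
        # every gene appears in at most one cluster
        seen = [m for c in clusters for m in c.members]
        assert len(seen) == len(set(seen))


class TestPresenceAbsence:
    def test_core_and_specific_counts(self):
        from gobiseq.ortho_hgt import OrthologCluster

        clusters = [OrthologCluster(members=(("G1", "a"), ("G2", "b")))]
        core, specific = presence_absence(
            clusters, {"G1": ["a", "x"], "G2": ["b", "y"]}
        )
        assert core == 1 and specific == {"G1": 1, "G2": 1}

    def test_no_clusters(self):
        core, specific = presence_absence([], {"G1": ["a"], "G2": ["b"]})
        assert core == 0 and specific == {"G1": 1, "G2": 1}

    def test_matches_set_algebra_oracle(self, rng):
        import itertools

        from gobiseq.ortho_hgt import OrthologCluster

        genomes = {f"G{g}": [f"g{g}_{i}" for i in range(10)] for g in range(3)}
        used = {g: set() for g in genomes}
        clusters = []
        for _ in range(6):
            members = []
            for g in genomes:
                if rng.random() < 0.7:
                    free = [x for x in genomes[g] if x not in used[g]]
                    if free:
                        pick = free[int(rng.integers(len(free)))]
                        used[g].add(pick)
                        members.append((g, pick))
            if len(members) >= 2:
                clusters.append(OrthologCluster(members=tuple(sorted(members))))
        core, specific = presence_absence(clusters, genomes)
        assert core == sum(1 for c in clusters if len(c.members) == 3)
        clustered = {m for c in clusters for m in c.members}
        for g, genes in genomes.items():
            assert specific[g] == sum(1 for x in genes if (g, x) not in clustered)
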