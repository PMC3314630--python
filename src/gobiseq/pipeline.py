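"""Run orchestration, configuration and the combined run report.

`run_pipeline` drives a simulate -> analyze round trip: generates a
synthetic genome, counts, coverage, hit tables and gene trees, runs every
analysis stage with the configured thresholds (the defaults reproduce the
study design: trim Q<5, keep reads >20 bp, TSS support >=5, ncRNA >=30 bp
at >=15x, chi-square alpha 0.05 with Bonferroni and 2-fold filter,
constitutive >=1%, affiliation E<1e-4 at 95% of best score, consensus
support >=70), writes all stage outputs under an output directory and
returns a machine-readable summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .coverage import write_bedgraph, write_start_profile
from .diffexpr import classify_de, constitutive_high, results_frame
from .feature_calling import (
    call_tss,
    detect_transcribed_intergenic,
    write_ncrna_bed,
    write_tss_tsv,
)
from .genome_io import summary_table, write_gff3
from .ortho_hgt import affiliate_all, read_hit_table
from .phylo_consensus import consensus_pipeline
from .synthetic_data import (
    SimConfig,
    simulate_counts,
    simulate_coverage,
    simulate_gene_trees,
    simulate_genome,
    simulate_hits,
    write_counts_tsv,
    write_fasta,
    write_hit_table,
    write_taxonomy,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline thresholds (defaults are the study's stated values)."""

    outdir: str = "gobiseq_out"
    seed: int = 0
    qmin: int = 5
    minlen: int = 20
    tss_min_reads: int = 5
    tss_window: int = 250
    ncrna_minlen: int = 30
    ncrna_mindepth: float = 15.0
    alpha: float = 0.05
    min_fold: float = 2.0
    constitutive_fraction: float = 0.01
    evalue_max: float = 1e-4
    score_frac: float = 0.95
    min_support: float = 70.0
    sim: SimConfig | None = None

    @classmethod
    def from_file(cls, path, **overrides):
        """Flat key=value config file; explicit keyword overrides win."""
        values: dict = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"bad config line: {line!r}")
                key, _, raw = line.partition("=")
                values[key.strip()] = raw.strip()
        cfg = cls()
        for key, raw in values.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            typ = type(current) if current is not None else str
            setattr(cfg, key, typ(raw) if typ is not bool else raw.lower() == "true")
        for key, val in overrides.items():
            if val is not None:
                setattr(cfg, key, val)
        return cfg


def round_half_up_percent(count: int, total: int) -> int:
    """Integer percentage, rounding halves up (reporting convention)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return int(math.floor(100.0 * count / total + 0.5))


def summarize(
    de_results,
    total_cds: int | None = None,
    tss_calls=None,
    ncrna_candidates=None,
) -> dict:
    """Combined run summary: DE class counts/percentages, per-replicon TSS
    counts, ncRNA status counts."""
    counts = {"induced": 0, "repressed": 0, "unchanged": 0}
    untestable = 0
    for r in de_results:
        counts[r.de_class] += 1
        if "untestable" in r.flags:
            untestable += 1
    total = total_cds if total_cds is not None else len(de_results)
    summary = {
        "n_genes": len(de_results),
        "n_untestable": untestable,
        "class_counts": counts,
        "class_percent": {
            k: round_half_up_percent(v, total) for k, v in counts.items()
        },
    }
    if tss_calls is not None:
        per_rep: dict[str, int] = {}
        for c in tss_calls:
            per_rep[c.replicon_id] = per_rep.get(c.replicon_id, 0) + 1
        summary["tss_total"] = len(tss_calls)
        summary["tss_per_replicon"] = per_rep
    if ncrna_candidates is not None:
        st: dict[str, int] = {}
        for c in ncrna_candidates:
            st[c.status] = st.get(c.status, 0) + 1
        summary["ncrna_total"] = len(ncrna_candidates)
        summary["ncrna_by_status"] = st
    return summary


def run_pipeline(config: RunConfig) -> dict:
    """Simulate -> analyze round trip; writes stage outputs and a summary.

    Returns the summary dict (also written as summary.json / summary.tsv).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    sim = config.sim or SimConfig(seed=config.seed)
    log.info("gobiseq %s, seed %d", __version__, sim.seed)

    replicons, features, truth = simulate_genome(sim)
    counts = simulate_counts(sim, truth, features)
    tracks, profiles = simulate_coverage(sim, truth, replicons, features, counts)
    hit_rows, taxonomy, hit_truth = simulate_hits(sim)
    newicks, species, tree_truth = simulate_gene_trees(sim)
    truth.affiliations = hit_truth.affiliations
    truth.species_tree_newick = tree_truth.species_tree_newick

    write_fasta(replicons, out / "genome.fasta")
    write_gff3(features, out / "genome.gff3")
    write_counts_tsv(counts, out / "counts.tsv")
    write_hit_table(hit_rows, out / "hits.tsv")
    write_taxonomy(taxonomy, out / "taxonomy.tsv")
    (out / "gene_trees.nwk").write_text("\n".join(newicks) + "\n")
    truth.to_json(out / "truth.json")

    summary_table(replicons, features, out / "genome_summary.tsv")

    # coverage and start profiles
    from .coverage import intergenic_regions

    tss_calls = []
    ncrna = []
    for rep in replicons:
        write_bedgraph(tracks[rep.id], out / f"coverage_{rep.id}.bedgraph")
        for strand in ("+", "-"):
            tss_calls.extend(
                call_tss(
                    profiles[(rep.id, "ctrl", strand)],
                    profiles[(rep.id, "uv", strand)],
                    features,
                    min_reads=config.tss_min_reads,
                    window=config.tss_window,
                )
            )
        intergenic = intergenic_regions(features, rep.length, rep.id)
        ncrna.extend(
            detect_transcribed_intergenic(
                tracks[rep.id],
                intergenic,
                minlen=config.ncrna_minlen,
                mindepth=config.ncrna_mindepth,
            )
        )
    write_start_profile(
        (profiles[k] for k in sorted(profiles)), out / "start_profiles.tsv"
    )
    write_tss_tsv(tss_calls, out / "tss.tsv")
    write_ncrna_bed(ncrna, out / "ncrna.bed", out / "ncrna.tsv")

    de = classify_de(counts, alpha=config.alpha, min_fold=config.min_fold)
    results_frame(de).to_csv(out / "diffexpr.tsv", sep="\t", index=False)
    high = constitutive_high(counts, fraction=config.constitutive_fraction)
    (out / "constitutive_high.txt").write_text("\n".join(high) + "\n")

    from .ortho_hgt import read_taxonomy

    hits = read_hit_table(out / "hits.tsv", read_taxonomy(out / "taxonomy.tsv"))
    affiliations = affiliate_all(
        hits,
        queries=truth.affiliations,
        evalue_max=config.evalue_max,
        score_frac=config.score_frac,
    )
    with open(out / "affiliations.tsv", "w") as fh:
        fh.write("query\tstatus\tphylum\torder\n")
        for a in affiliations:
            fh.write(f"{a.query}\t{a.status}\t{a.phylum or ''}\t{a.order or ''}\n")

    consensus = consensus_pipeline(newicks, min_support=config.min_support)
    (out / "consensus_tree.nwk").write_text(
        consensus.as_string(schema="newick", suppress_rooting=True)
    )

    summary = summarize(
        de,
        total_cds=len(counts.genes),
        tss_calls=tss_calls,
        ncrna_candidates=ncrna,
    )
    aff_tally: dict[str, int] = {}
    for a in affiliations:
        aff_tally[a.status] = aff_tally.get(a.status, 0) + 1
    summary["affiliation_counts"] = aff_tally
    summary["config"] = {
        k: v
        for k, v in dataclasses.asdict(config).items()
        if k not in ("sim", "outdir")
    }
    summary["seed"] = sim.seed
    summary["version"] = __version__
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    with open(out / "summary.tsv", "w") as fh:
        fh.write("key\tvalue\n")
        for key in ("n_genes", "tss_total", "ncrna_total"):
            if key in summary:
                fh.write(f"{key}\t{summary[key]}\n")
        for k, v in summary["class_counts"].items():
            fh.write(f"n_{k}\t{v}\n")
        for k, v in summary["class_percent"].items():
            fh.write(f"percent_{k}\t{v}\n")
    return summary
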