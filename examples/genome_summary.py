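"""Aggregate per-replicon summary rows into genome-wide totals.

Loads the published per-replicon table for the D. gobiensis I-0 genome
(chromosome + plasmids P1-P6) and computes the genome totals: summed size
and CDS count, and length-weighted GC and coding density.
"""

from gobiseq import published
from gobiseq.genome_io import genome_totals

stats = published.replicon_stats()
totals = genome_totals(stats)

print(published.replicon_table().to_string(index=False))
print()
print(f"total genome size : {totals.total_size:,} bp")
print(f"total CDS         : {totals.total_cds:,}")
print(f"weighted GC       : {totals.weighted_gc_percent}%")
print(f"weighted density  : {totals.weighted_coding_density_percent}%")
print()
print(
    "The totals are sums over the seven replicons; GC and coding density\n"
    "are weighted by replicon length, so the 3.1 Mb chromosome dominates."
)
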