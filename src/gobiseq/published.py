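"""Published summary values for the D. gobiensis I-0 genome.

The per-replicon summary table (chromosome plus plasmids P1-P6, GenBank
CP002191-CP002197) and the headline transcriptome/annotation counts, as
printed in the genome announcement.  These serve as worked-example inputs
for the aggregation and reporting arithmetic; the underlying sequence data
are not shipped.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .genome_io import GenomeStats, RepliconStats, genome_totals

#: headline counts out of the 4,340 annotated CDSs
TOTAL_CDS = 4340
N_INDUCED_UV = 390  # genes induced immediately after UV irradiation
N_REPRESSED_UV = 754  # genes repressed
N_COG_CLASSIFIED = 2376  # CDSs with a COG assignment
N_HYPOTHETICAL = 1534  # hypothetical proteins
N_ORPHAN = 834  # orphans without precedent


def replicon_table() -> pd.DataFrame:
    """The published per-replicon summary rows as a DataFrame."""
    ref = resources.files("gobiseq.data") / "dgobiensis_replicons.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def replicon_stats() -> list[RepliconStats]:
    """The published rows as :class:`~gobiseq.genome_io.RepliconStats`."""
    return [
        RepliconStats(
            length=int(r.size_bp),
            gc_percent=float(r.gc_percent),
            coding_density_percent=float(r.coding_density_percent),
            n_cds=int(r.n_cds),
            mean_cds_length=float(r.mean_cds_length_nt),
        )
        for r in replicon_table().itertuples()
    ]


def genome_stats() -> GenomeStats:
    """Genome-wide totals aggregated from the published replicon rows."""
    return genome_totals(replicon_stats())
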