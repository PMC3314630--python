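"""FPKM normalisation and chi-square differential expression.

Expression is normalised as FPKM (fragments per kilobase of CDS per million
mapped reads).  Differential expression between two conditions is tested
per gene with a Pearson chi-square on the 2x2 table

    [[count_ctrl, count_uv],
     [N_ctrl - count_ctrl, N_uv - count_uv]]

(1 df, no continuity correction), controlling the family-wise error rate by
Bonferroni over the testable genes, and requiring at least a 2-fold FPKM
change.  Genes at >= 1% of the library in both samples are reported as
constitutive high expressors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GeneCounts:
    gene_id: str
    cds_length: int  # nt
    count_ctrl: int
    count_uv: int

    def __post_init__(self) -> None:
        if self.cds_length <= 0:
            raise ValueError(f"gene {self.gene_id!r}: non-positive CDS length")


@dataclass
class GeneCountTable:
    """Per-gene counts plus library totals (non-rRNA mapped reads)."""

    genes: list[GeneCounts]
    n_ctrl: int
    n_uv: int

    def __post_init__(self) -> None:
        if self.n_ctrl <= 0 or self.n_uv <= 0:
            raise ValueError("library totals must be positive")
        for g in self.genes:
            if g.count_ctrl > self.n_ctrl or g.count_uv > self.n_uv:
                raise ValueError(f"gene {g.gene_id!r}: count exceeds library total")

    @classmethod
    def from_tsv(cls, path, n_ctrl: int | None = None, n_uv: int | None = None):
        """Read a counts TSV (gene_id, length, count_ctrl, count_uv).

        Library totals default to the column sums when not given.
        """
        df = pd.read_csv(path, sep="\t")
        genes = [
            GeneCounts(str(r.gene_id), int(r.length), int(r.count_ctrl), int(r.count_uv))
            for r in df.itertuples()
        ]
        return cls(
            genes=genes,
            n_ctrl=int(n_ctrl if n_ctrl is not None else df.count_ctrl.sum()),
            n_uv=int(n_uv if n_uv is not None else df.count_uv.sum()),
        )


@dataclass
class DEResult:
    gene_id: str
    fpkm_ctrl: float
    fpkm_uv: float
    fold_change: float  # uv / ctrl
    chi2_stat: float
    p_value: float
    significant: bool
    de_class: str  # induced | repressed | unchanged
    flags: tuple[str, ...] = ()


def fpkm(count: int | float, cds_length: int, total_mapped: int) -> float:
    """Fragments per kilobase of CDS per million mapped reads."""
    if cds_length <= 0 or total_mapped <= 0:
        raise ValueError("cds_length and total_mapped must be positive")
    return count * 1e9 / (cds_length * total_mapped)


def chi_square_gene(
    a: int, b: int, n_ctrl: int, n_uv: int
) -> tuple[float, float, bool]:
    """Pearson chi-square for one gene against the rest of each library.

    Returns ``(statistic, p, testable)``.  A gene with no reads in either
    sample is untestable and reported as (0, 1, False).
    """
    if a > n_ctrl or b > n_uv:
        raise ValueError("count exceeds library total")
    if a + b == 0:
        return 0.0, 1.0, False
    # Pearson statistic on [[a, b], [n_ctrl-a, n_uv-b]] in closed form:
    # N*(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)), 1 df, no continuity correction
    c = n_ctrl - a
    d = n_uv - b
    n = float(a + b + c + d)
    denom = float(a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0, 1.0, True
    stat = n * (float(a) * d - float(b) * c) ** 2 / denom
    return float(stat), float(stats.chi2.sf(stat, df=1)), True


def bonferroni_threshold(m: int, alpha: float = 0.05) -> float:
    """Per-test significance level alpha/m for a family of m tests."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def classify_de(
    table: GeneCountTable,
    alpha: float = 0.05,
    min_fold: float = 2.0,
) -> list[DEResult]:
    """Classify every gene as induced / repressed / unchanged.

    The Bonferroni family size m counts testable genes only (>= 1 read over
    both samples).  A gene is significant when p < alpha/m.  Fold change is
    fpkm_uv / fpkm_ctrl, with a one-read pseudocount substituted for any
    zero count (flagged).  Induced requires fold >= min_fold and
    significance; repressed requires fold <= 1/min_fold and significance.
    Expected counts below 5 are flagged, not excluded.
    """
    if not table.genes:
        raise ValueError("empty gene count table")
    m = sum(1 for g in table.genes if g.count_ctrl + g.count_uv >= 1)
    threshold = bonferroni_threshold(max(m, 1), alpha)
    n_c, n_u = table.n_ctrl, table.n_uv
    results: list[DEResult] = []
    for g in table.genes:
        stat, p, testable = chi_square_gene(g.count_ctrl, g.count_uv, n_c, n_u)
        flags: list[str] = []
        if not testable:
            flags.append("untestable")
        else:
            tot = g.count_ctrl + g.count_uv
            exp_min = min(
                tot * n_c / (n_c + n_u),
                tot * n_u / (n_c + n_u),
                (n_c + n_u - tot) * n_c / (n_c + n_u),
                (n_c + n_u - tot) * n_u / (n_c + n_u),
            )
            if exp_min < 5:
                flags.append("low-expected-count")
        c_ctrl, c_uv = g.count_ctrl, g.count_uv
        if c_ctrl == 0 or c_uv == 0:
            flags.append("zero-count-pseudocount")
            c_ctrl = max(c_ctrl, 1)
            c_uv = max(c_uv, 1)
        f_ctrl = fpkm(g.count_ctrl, g.cds_length, n_c)
        f_uv = fpkm(g.count_uv, g.cds_length, n_u)
        fold = fpkm(c_uv, g.cds_length, n_u) / fpkm(c_ctrl, g.cds_length, n_c)
        significant = testable and p < threshold
        if significant and fold >= min_fold:
            de_class = "induced"
        elif significant and fold <= 1.0 / min_fold:
            de_class = "repressed"
        else:
            de_class = "unchanged"
        results.append(
            DEResult(
                gene_id=g.gene_id,
                fpkm_ctrl=f_ctrl,
                fpkm_uv=f_uv,
                fold_change=fold,
                chi2_stat=stat,
                p_value=p,
                significant=significant,
                de_class=de_class,
                flags=tuple(flags),
            )
        )
    return results


def constitutive_high(table: GeneCountTable, fraction: float = 0.01) -> list[str]:
    """Genes holding at least ``fraction`` of the library in BOTH samples."""
    return [
        g.gene_id
        for g in table.genes
        if g.count_ctrl / table.n_ctrl >= fraction
        and g.count_uv / table.n_uv >= fraction
    ]


def results_frame(results: Sequence[DEResult]) -> pd.DataFrame:
    """DE results as a DataFrame ready for TSV export."""
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "fpkm_ctrl": [r.fpkm_ctrl for r in results],
            "fpkm_uv": [r.fpkm_uv for r in results],
            "fold_change": [r.fold_change for r in results],
            "chi2_stat": [r.chi2_stat for r in results],
            "p_value": [r.p_value for r in results],
            "significant": [r.significant for r in results],
            "class": [r.de_class for r in results],
            "flags": [",".join(r.flags) for r in results],
        }
    )
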