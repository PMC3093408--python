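"""Chromosome-level distribution statistics for proviral integrations.

Covers the genome fraction occupied by proviruses, fixed-width density
binning, distances to chromosome ends (telomeres), per-element genomic
region breakdown (CDS / UTR / intron / intergenic) and ordinary
least-squares correlation of per-chromosome integration counts against
covariates such as chromosome length or gene counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .model import GenomeIndex, ProviralChain, TranscriptRecord

DEFAULT_BIN = 1_000_000

REGION_LABELS = ("exonic", "UTR", "intronic", "intergenic")


@dataclass
class RegionBreakdown:
    """Nucleotide counts of one provirus in each genomic region class.

    Precedence when annotations overlap: coding exon > UTR > intron >
    intergenic; counts always sum to the provirus length.
    """

    erv_id: int
    exonic: int = 0
    utr: int = 0
    intronic: int = 0
    intergenic: int = 0

    @property
    def total(self) -> int:
        return self.exonic + self.utr + self.intronic + self.intergenic


@dataclass
class CorrelationResult:
    r_squared: float
    p_value: float
    n: int
    slope: float
    intercept: float
    excluded_outliers: list[str] = field(default_factory=list)


def genome_fraction(
    chains: Sequence[ProviralChain], genome_index: GenomeIndex
) -> float:
    """Percentage of the genome covered by the (deduplicated) chains."""
    total = genome_index.total_length
    if total <= 0:
        raise ValueError("genome has zero length")
    erv_bp = sum(c.length for c in chains)
    return 100.0 * erv_bp / total


def bin_density(
    features: Sequence[ProviralChain],
    genome_index: GenomeIndex,
    bin_size: int = DEFAULT_BIN,
) -> dict[str, np.ndarray]:
    """Per-chromosome counts of features in fixed half-open bins.

    A feature is assigned to the single bin containing its start
    coordinate; features spanning a bin boundary are not split.
    """
    if bin_size <= 0:
        raise ValueError("bin size must be positive")
    out = {
        chrom: np.zeros(-(-length // bin_size), dtype=np.int64)
        for chrom, length in genome_index.items()
    }
    for f in features:
        out[f.chromosome][f.start // bin_size] += 1
    return out


def telomere_distances(
    features: Sequence[ProviralChain], genome_index: GenomeIndex
) -> dict[str, tuple[int, int]]:
    """Minimum distance of any feature to each chromosome end.

    Returns ``{chrom: (start_side, end_side)}`` where ``start_side`` is the
    smallest feature start and ``end_side`` the smallest
    ``length - feature_end``; 0 signals a telomeric integration.
    Chromosomes without features are absent from the output.
    """
    out: dict[str, tuple[int, int]] = {}
    for f in features:
        length = genome_index[f.chromosome]
        start_d = f.start
        end_d = length - f.end
        prev = out.get(f.chromosome)
        if prev is None:
            out[f.chromosome] = (start_d, end_d)
        else:
            out[f.chromosome] = (min(prev[0], start_d), min(prev[1], end_d))
    return out


def region_breakdown(
    chain: ProviralChain, transcripts: Sequence[TranscriptRecord]
) -> RegionBreakdown:
    """Assign every provirus basepair to exonic-CDS / UTR / intron /
    intergenic with that precedence.

    ``transcripts`` must carry exon (and, where coding, CDS) sub-intervals;
    UTR is exon minus CDS.  Intronic means inside a transcript span but in
    no exon.
    """
    n = chain.length
    # per-base label masks over the chain span; precedence applied at the end
    in_cds = np.zeros(n, dtype=bool)
    in_exon = np.zeros(n, dtype=bool)
    in_tx = np.zeros(n, dtype=bool)

    def mark(mask: np.ndarray, s: int, e: int) -> None:
        a, b = max(s, chain.start), min(e, chain.end)
        if a < b:
            mask[a - chain.start : b - chain.start] = True

    for tx in transcripts:
        if tx.chromosome != chain.chromosome:
            continue
        mark(in_tx, tx.start, tx.end)
        for s, e in tx.exons:
            mark(in_exon, s, e)
        for s, e in tx.cds:
            mark(in_cds, s, e)
    exonic = int(in_cds.sum())
    utr = int((in_exon & ~in_cds).sum())
    intronic = int((in_tx & ~in_exon).sum())
    intergenic = n - exonic - utr - intronic
    return RegionBreakdown(
        erv_id=chain.id,
        exonic=exonic,
        utr=utr,
        intronic=intronic,
        intergenic=intergenic,
    )


def correlate_counts(
    counts: Mapping[str, float],
    covariate: Mapping[str, float],
    exclude: Sequence[str] = (),
) -> CorrelationResult:
    """OLS fit of per-chromosome feature counts against a covariate.

    ``exclude`` lists chromosomes to drop before fitting (the outlier call
    is the caller's judgment, not automated).  Returns r-squared and the
    two-sided p-value for slope != 0.
    """
    excluded = sorted(set(exclude))
    chroms = [
        c for c in counts if c in covariate and c not in set(excluded)
    ]
    if len(chroms) < 3:
        raise ValueError(
            f"need >= 3 chromosomes after exclusion, have {len(chroms)}"
        )
    x = np.array([covariate[c] for c in chroms], dtype=float)
    y = np.array([counts[c] for c in chroms], dtype=float)
    fit = stats.linregress(x, y)
    return CorrelationResult(
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=len(chroms),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        excluded_outliers=excluded,
    )
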