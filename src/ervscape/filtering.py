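"""Chain selection and sequence quality control.

Screening output contains spurious low-scoring chains and multiple
overlapping calls at a single integration locus.  The selection applied
here keeps chains scoring strictly above a threshold (default 300, the
margin that separates true from false retroviral chains on randomized
data) and then reduces each locus — a transitive-overlap cluster of chains
on one chromosome — to a single representative via a three-stage cascade:

1. most *distinct* proviral genes with an annotated putein (gag/pro/pol/env),
2. most annotated puteins in total,
3. highest score.

Residual ties are broken deterministically by smallest start coordinate,
then smallest chain id.  Lower-ranked chains in the same locus ("copies")
are excluded.

Sequence QC marks (never deletes) puteins with too many undetermined
residues and LTRs with too many ambiguous nucleotides, so that dating and
phylogenetics operate on trustworthy sequence only.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .model import ChainTable, ProviralChain

DEFAULT_SCORE_THRESHOLD = 300.0
DEFAULT_MAX_UNDETERMINED_AA = 5
DEFAULT_MAX_AMBIGUOUS_NT = 15


@dataclass
class ExclusionLog:
    """Per-chain / per-feature record of why something was excluded."""

    records: list[tuple[int, str, str]] = field(default_factory=list)
    # (chain id, feature, reason)

    def add(self, chain_id: int, feature: str, reason: str) -> None:
        self.records.append((chain_id, feature, reason))

    def write_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["chain_id", "feature", "reason"])
            w.writerows(self.records)


def filter_by_score(
    chains: Sequence[ProviralChain],
    threshold: float = DEFAULT_SCORE_THRESHOLD,
    log: ExclusionLog | None = None,
) -> list[ProviralChain]:
    """Keep chains whose score is strictly greater than ``threshold``.

    Input order is preserved.
    """
    if threshold <= 0 and threshold != 0:
        raise ValueError("threshold must be positive")
    kept = []
    for c in chains:
        if c.score > threshold:
            kept.append(c)
        elif log is not None:
            log.add(c.id, "chain", f"score {c.score} <= {threshold}")
    return kept


def cascade_key(chain: ProviralChain) -> tuple[int, int, float, int, int]:
    """Sort key implementing the locus tie-break cascade; larger wins.

    Stages: distinct putein genes, total puteins, score; then the
    deterministic residual tie-breaks (earlier start, smaller id win, hence
    negated).
    """
    return (
        chain.distinct_putein_genes,
        chain.n_puteins,
        chain.score,
        -chain.start,
        -chain.id,
    )


def locus_clusters(
    chains: Sequence[ProviralChain],
) -> list[list[ProviralChain]]:
    """Group chains into loci: transitive closure of >=1 bp span overlap on
    the same chromosome.  Found by a per-chromosome sweep over sorted
    starts."""
    by_chrom: dict[str, list[ProviralChain]] = {}
    for c in chains:
        by_chrom.setdefault(c.chromosome, []).append(c)
    clusters: list[list[ProviralChain]] = []
    for chrom in sorted(by_chrom):
        group = sorted(by_chrom[chrom], key=lambda c: (c.start, c.end, c.id))
        current: list[ProviralChain] = []
        reach = -1
        for c in group:
            if current and c.start < reach:
                current.append(c)
                reach = max(reach, c.end)
            else:
                if current:
                    clusters.append(current)
                current = [c]
                reach = c.end
        if current:
            clusters.append(current)
    return clusters


def dedup_loci(
    chains: Sequence[ProviralChain], log: ExclusionLog | None = None
) -> list[ProviralChain]:
    """Reduce every locus cluster to its cascade winner.

    Input order of the surviving chains is preserved.
    """
    winners: set[int] = set()
    for cluster in locus_clusters(chains):
        best = max(cluster, key=cascade_key)
        winners.add(best.id)
        if log is not None:
            for c in cluster:
                if c.id != best.id:
                    log.add(
                        c.id,
                        "chain",
                        f"copy in locus of chain {best.id} "
                        f"({c.chromosome}:{best.start}-{best.end})",
                    )
    return [c for c in chains if c.id in winners]


def qc_puteins(
    chains: Iterable[ProviralChain],
    max_undetermined: int = DEFAULT_MAX_UNDETERMINED_AA,
    log: ExclusionLog | None = None,
) -> list[ProviralChain]:
    """Mark puteins with ``max_undetermined`` or more undetermined (X)
    residues as excluded.  Chains themselves are retained; downstream
    phylogenetic operations see only passing puteins."""
    out = []
    for c in chains:
        for p in c.puteins:
            if p.n_undetermined >= max_undetermined:
                p.excluded = True
                if log is not None:
                    log.add(
                        c.id,
                        f"putein:{p.gene}",
                        f"{p.n_undetermined} undetermined residues "
                        f">= {max_undetermined}",
                    )
        out.append(c)
    return out


def qc_ltrs(
    chains: Iterable[ProviralChain],
    max_ambiguous_nt: int = DEFAULT_MAX_AMBIGUOUS_NT,
    log: ExclusionLog | None = None,
) -> list[ProviralChain]:
    """Mark LTRs with ``max_ambiguous_nt`` or more ambiguous (non-ACGT)
    positions as excluded; a chain whose LTR pair contains a flagged LTR is
    not datable from LTR divergence.

    The criterion is an ambiguity cap per LTR; both the threshold and this
    interpretation are configurable at the call site.
    """
    out = []
    for c in chains:
        for name, ltr in (("ltr5", c.ltr5), ("ltr3", c.ltr3)):
            if ltr is None or ltr.sequence is None:
                continue
            if ltr.n_ambiguous >= max_ambiguous_nt:
                ltr.excluded = True
                if log is not None:
                    log.add(
                        c.id,
                        name,
                        f"{ltr.n_ambiguous} ambiguous nt >= {max_ambiguous_nt}",
                    )
        out.append(c)
    return out


def run_filter_pipeline(
    table: ChainTable,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    max_undetermined: int = DEFAULT_MAX_UNDETERMINED_AA,
    max_ambiguous_nt: int = DEFAULT_MAX_AMBIGUOUS_NT,
) -> tuple[ChainTable, ExclusionLog]:
    """Score filter, locus dedup and both QC passes in canonical order."""
    log = ExclusionLog()
    chains = filter_by_score(table.rows, score_threshold, log)
    chains = dedup_loci(chains, log)
    chains = qc_puteins(chains, max_undetermined, log)
    chains = qc_ltrs(chains, max_ambiguous_nt, log)
    return ChainTable(rows=chains, genome_id=table.genome_id), log
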