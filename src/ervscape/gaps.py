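"""Classification of assembly gaps as possible ERV-containing sites.

Screening an assembly can only find proviruses in assembled sequence;
unassembled gaps may hide further elements.  A gap is a candidate for
containing a complete or partial provirus unless one of three exclusion
rules fires:

* the gap is a *clone* or *contig* gap — those arise from the assembly
  process, not from unassemblable repetitive insertions;
* the gap is confidently sized too small to hold an element (< 1 kb);
  gaps of unknown size (AGP ``U`` rows) cannot be excluded on size;
* the gap is clearly flanked by a fragment of a known non-ERV repeat
  (SINE, LINE or simple repeat) — the likely cause of the gap is then
  that repeat.  LTR-class repeats at the flank do NOT disqualify a gap:
  they are consistent with a truncated provirus continuing into it.

"Clearly flanked" is operationalized as an excluded-class repeat within
``flank_window`` bp (default 50) of either gap edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .model import AgpGap, GenomeIndex, RepeatInterval

DEFAULT_MIN_GAP_LENGTH = 1000
DEFAULT_FLANK_WINDOW = 50
EXCLUDED_GAP_TYPES = frozenset({"clone", "contig"})
EXCLUDED_FLANK_CLASSES = frozenset({"SINE", "LINE", "Simple_repeat"})


@dataclass
class GapRecord:
    """One assembly gap with its ERV-candidacy classification."""

    chromosome: str
    start: int
    end: int
    agp_gap_type: str
    sized: bool
    flank_repeat_classes: list[str] = field(default_factory=list)
    candidate: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


def classify_gaps(
    agp_gaps: Sequence[AgpGap],
    repeats: Sequence[RepeatInterval],
    genome_index: GenomeIndex | None = None,
    min_length: int = DEFAULT_MIN_GAP_LENGTH,
    flank_window: int = DEFAULT_FLANK_WINDOW,
    excluded_gap_types: frozenset[str] = EXCLUDED_GAP_TYPES,
    excluded_flank_classes: frozenset[str] = EXCLUDED_FLANK_CLASSES,
) -> list[GapRecord]:
    """Apply the three exclusion rules to every gap.

    candidate == (type not clone/contig) AND (unsized OR length >=
    min_length) AND (no excluded-class repeat within flank_window of
    either edge).
    """
    by_chrom: dict[str, list[RepeatInterval]] = {}
    for r in repeats:
        by_chrom.setdefault(r.chromosome, []).append(r)
    records: list[GapRecord] = []
    for gap in agp_gaps:
        if genome_index is not None:
            if gap.chromosome not in genome_index:
                raise ValueError(f"gap on unknown chromosome {gap.chromosome!r}")
            if gap.end > genome_index[gap.chromosome] or gap.start < 0:
                raise ValueError(
                    f"gap {gap.chromosome}:{gap.start}-{gap.end} outside "
                    "chromosome bounds"
                )
        flank_classes: list[str] = []
        left = (gap.start - flank_window, gap.start)
        right = (gap.end, gap.end + flank_window)
        for r in by_chrom.get(gap.chromosome, []):
            for a, b in (left, right):
                if r.start < b and a < r.end:
                    flank_classes.append(r.repeat_class)
                    break
        candidate = (
            gap.gap_type not in excluded_gap_types
            and (not gap.sized or gap.length >= min_length)
            and not any(c in excluded_flank_classes for c in flank_classes)
        )
        records.append(
            GapRecord(
                chromosome=gap.chromosome,
                start=gap.start,
                end=gap.end,
                agp_gap_type=gap.gap_type,
                sized=gap.sized,
                flank_repeat_classes=sorted(set(flank_classes)),
                candidate=candidate,
            )
        )
    return records


@dataclass
class ChromosomeGapSummary:
    chromosome: str
    n_candidates: int
    candidate_bp: int
    total_gap_bp: int
    density_per_mb: float


def gap_density_per_chromosome(
    records: Sequence[GapRecord], genome_index: GenomeIndex
) -> dict[str, ChromosomeGapSummary]:
    """Per-chromosome candidate-gap counts, total candidate Ns, and
    candidate density per Mb of chromosome length."""
    tally: Mapping[str, list[int]] = {
        chrom: [0, 0, 0] for chrom in genome_index
    }
    for rec in records:
        row = tally[rec.chromosome]
        row[2] += rec.length
        if rec.candidate:
            row[0] += 1
            row[1] += rec.length
    return {
        chrom: ChromosomeGapSummary(
            chromosome=chrom,
            n_candidates=n,
            candidate_bp=bp,
            total_gap_bp=total,
            density_per_mb=n / (genome_index[chrom] / 1e6),
        )
        for chrom, (n, bp, total) in tally.items()
    }
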