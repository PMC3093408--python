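"""Gene-neighborhood analysis of proviral integrations.

For every provirus, a window of +/- ``W`` bp (default 100 kb) centered on
the element is scanned for gene models, and every model nucleotide falling
in the window is tallied at its offset from the provirus — in the frame of
the provirus: positive offsets lie 3' (downstream) of the element, negative
offsets 5' (upstream), and any overlap with the element itself is collapsed
to position 0.  Tallies are kept separately for models transcribed in the
same orientation as the provirus ("sense") and the opposite one
("antisense").  Selection against integrations that interfere with host
transcription shows up as an excess of antisense gene coverage.

Gene models are composite "pseudo-transcripts": per gene, the longest
transcript extended by any alternative transcript that overlaps the
current model and reaches beyond it.

Two statistics summarize a profile:

* :func:`over_under` — per-position comparison of the antisense and sense
  curves, with a 1-df chi-square of the (over, under) counts against a
  50:50 split.  Window positions are highly autocorrelated (one gene covers
  thousands of consecutive positions), so this chi-square describes the
  magnitude of the imbalance rather than a calibrated significance level.
* :func:`orientation_bias_test` — the same comparison at the level of
  whole (provirus, model) pairs, whose orientations are independent
  sampling units; this one is calibrated and is what should be used for
  inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .dating import LTRPair
from .model import ProviralChain, TranscriptRecord

DEFAULT_WINDOW = 100_000
DEFAULT_FLANK = 5_000


@dataclass
class CompositeGeneModel:
    """Per-gene merged transcript interval; the unit of the analysis."""

    gene_id: str
    chromosome: str
    strand: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class NeighborhoodProfile:
    """Per-offset sense/antisense gene-coverage counts over [-W, +W].

    ``sense_counts[i]`` is the number of (provirus, model) pairs whose
    model covers offset ``i - W``; counts are of model nucleotides, not of
    proviruses or genes.  A position covered by two genes counts twice.
    """

    window_half_width: int = DEFAULT_WINDOW
    sense_counts: np.ndarray = field(default=None)  # type: ignore[assignment]
    antisense_counts: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_ervs: int = 0

    def __post_init__(self) -> None:
        n = 2 * self.window_half_width + 1
        if self.sense_counts is None:
            self.sense_counts = np.zeros(n, dtype=np.int64)
        if self.antisense_counts is None:
            self.antisense_counts = np.zeros(n, dtype=np.int64)
        if len(self.sense_counts) != n or len(self.antisense_counts) != n:
            raise ValueError("count arrays must have length 2W+1")

    @property
    def offsets(self) -> np.ndarray:
        w = self.window_half_width
        return np.arange(-w, w + 1)

    def total_coverage(self) -> int:
        return int(self.sense_counts.sum() + self.antisense_counts.sum())


@dataclass
class OverUnderResult:
    """Counts of positions (or pairs) where antisense coverage exceeds
    sense ("over"), is exceeded by it ("under"), or ties ("equal"), with a
    1-df chi-square of (over, under) against a uniform 50:50 expectation.
    Ties are tallied but excluded from the test."""

    over: int
    under: int
    equal: int
    chi2: float
    p_value: float
    unit: str = "position"

    @property
    def defined(self) -> bool:
        return self.over + self.under > 0


# ---------------------------------------------------------------------------
# composite gene models
# ---------------------------------------------------------------------------

def build_composite_models(
    transcripts: Iterable[TranscriptRecord],
) -> list[CompositeGeneModel]:
    """Merge each gene's transcripts into one composite model.

    Start from the gene's longest transcript and iteratively annex any
    alternative transcript that overlaps the current model and extends it
    beyond either end; transcripts that do not overlap the growing model
    are never annexed.  A gene with transcripts on both strands is split
    into one model per strand, with a warning.
    """
    groups: dict[tuple[str, str, str], list[TranscriptRecord]] = {}
    both_strands: set[str] = set()
    strands_seen: dict[str, set[str]] = {}
    for tx in transcripts:
        groups.setdefault((tx.gene_id, tx.chromosome, tx.strand), []).append(tx)
        strands_seen.setdefault(tx.gene_id, set()).add(tx.strand)
    for gene_id, strands in strands_seen.items():
        if len(strands) > 1:
            both_strands.add(gene_id)
    if both_strands:
        warnings.warn(
            f"genes with transcripts on both strands split into two models: "
            f"{sorted(both_strands)}"
        )
    models = []
    for (gene_id, chrom, strand), txs in groups.items():
        longest = max(txs, key=lambda t: (t.length, -t.start, t.transcript_id))
        start, end = longest.start, longest.end
        pool = [t for t in txs if t is not longest]
        changed = True
        while changed:
            changed = False
            for t in list(pool):
                overlaps = t.start < end and start < t.end
                extends = t.start < start or t.end > end
                if overlaps and extends:
                    start = min(start, t.start)
                    end = max(end, t.end)
                    pool.remove(t)
                    changed = True
        models.append(
            CompositeGeneModel(
                gene_id=gene_id,
                chromosome=chrom,
                strand=strand,
                start=start,
                end=end,
            )
        )
    models.sort(key=lambda m: (m.chromosome, m.start, m.gene_id, m.strand))
    return models


# ---------------------------------------------------------------------------
# offsets and profiles
# ---------------------------------------------------------------------------

def erv_relative_position(
    erv: ProviralChain, model: CompositeGeneModel
) -> int | None:
    """Signed offset of the model's nearest base in the provirus frame.

    0 when model and provirus overlap; otherwise the offset of the closest
    model nucleotide: +k for the k-th base 3' of the element (downstream of
    its 3' LTR), -k for the k-th base 5' of it.  A model immediately
    abutting the element is at +/-1.  ``None`` on different chromosomes.
    """
    if erv.chromosome != model.chromosome:
        return None
    if model.start < erv.end and erv.start < model.end:
        return 0
    if model.start >= erv.end:  # model is 3'-ward in genome coordinates
        genomic = model.start - erv.end + 1
    else:
        genomic = model.end - 1 - erv.start  # negative
    return genomic if erv.strand == "+" else -genomic


def _pair_offset_runs(
    erv: ProviralChain, model: CompositeGeneModel, window: int
) -> tuple[int, list[tuple[int, int]]]:
    """Offsets covered by a model around one provirus.

    Returns ``(overlap_len, runs)``: the number of model nucleotides
    overlapping the provirus span (they all collapse onto offset 0) and the
    half-open offset ranges, in the provirus frame and clipped to the
    window, covered by the model outside the element.
    """
    ms, me, es, ee = model.start, model.end, erv.start, erv.end
    overlap = max(0, min(me, ee) - max(ms, es))
    runs: list[tuple[int, int]] = []
    # genomic offsets of model bases left of the element: x - es for x < es
    lo, hi = ms - es, min(me, es) - es
    left = (lo, hi) if lo < hi else None
    # genomic offsets right of the element: x - ee + 1 for x >= ee
    lo, hi = max(ms, ee) - ee + 1, me - ee + 1
    right = (lo, hi) if lo < hi else None
    for rng in (left, right):
        if rng is None:
            continue
        a, b = rng
        if erv.strand == "-":
            a, b = -(b - 1), -a + 1  # reflect the half-open range
        a, b = max(a, -window), min(b, window + 1)
        if a < b:
            runs.append((a, b))
    return overlap, runs


def neighborhood_profile(
    ervs: Sequence[ProviralChain],
    models: Sequence[CompositeGeneModel],
    window: int = DEFAULT_WINDOW,
) -> NeighborhoodProfile:
    """Accumulate sense/antisense model-nucleotide counts around proviruses.

    For every (provirus, model) pair on the same chromosome, every model
    nucleotide within the provirus-centered window increments the sense
    array if the model's strand equals the provirus strand, else the
    antisense array, at its offset in the provirus frame.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    prof = NeighborhoodProfile(window_half_width=window, n_ervs=len(ervs))
    by_chrom: dict[str, list[CompositeGeneModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chromosome, []).append(m)
    w = window
    for erv in ervs:
        for model in by_chrom.get(erv.chromosome, []):
            if model.start >= erv.end + w or model.end <= erv.start - w:
                continue
            target = (
                prof.sense_counts
                if model.strand == erv.strand
                else prof.antisense_counts
            )
            overlap, runs = _pair_offset_runs(erv, model, w)
            target[w] += overlap
            for a, b in runs:
                target[a + w : b + w] += 1
    return prof


def over_under(profile: NeighborhoodProfile) -> OverUnderResult:
    """Per-position antisense-vs-sense comparison with a 1-df chi-square
    of (over, under) against 50:50; see the module docstring for the
    calibration caveat."""
    diff = profile.antisense_counts.astype(np.int64) - profile.sense_counts
    over = int((diff > 0).sum())
    under = int((diff < 0).sum())
    equal = int((diff == 0).sum())
    chi2, p = _chi2_over_under(over, under)
    return OverUnderResult(
        over=over, under=under, equal=equal, chi2=chi2, p_value=p
    )


def _chi2_over_under(over: int, under: int) -> tuple[float, float]:
    n = over + under
    if n == 0:
        return float("nan"), float("nan")
    chi2, p = stats.chisquare([over, under])
    return float(chi2), float(p)


def orientation_bias_test(
    ervs: Sequence[ProviralChain],
    models: Sequence[CompositeGeneModel],
    window: int = DEFAULT_WINDOW,
) -> OverUnderResult:
    """Orientation bias counted once per gene model.

    Each gene model with a provirus within the window is classified
    antisense ("over") or sense ("under") relative to the *nearest* such
    provirus (ties broken by smallest chain id).  Gene orientations are
    then independent sampling units, so the chi-square is calibrated
    under a random-orientation null — unlike the per-position statistic
    of :func:`over_under`.
    """
    over = under = 0
    for model in models:
        nearest: ProviralChain | None = None
        best = window + 1
        for erv in ervs:
            pos = erv_relative_position(erv, model)
            if pos is None or abs(pos) > window:
                continue
            if abs(pos) < best or (
                abs(pos) == best and nearest is not None and erv.id < nearest.id
            ):
                best = abs(pos)
                nearest = erv
        if nearest is None:
            continue
        if model.strand == nearest.strand:
            under += 1
        else:
            over += 1
    chi2, p = _chi2_over_under(over, under)
    return OverUnderResult(
        over=over, under=under, equal=0, chi2=chi2, p_value=p, unit="gene"
    )


def stratified_profiles(
    ervs: Sequence[ProviralChain],
    models: Sequence[CompositeGeneModel],
    dating: Iterable[LTRPair] | Mapping[int, str],
    window: int = DEFAULT_WINDOW,
) -> dict[str, NeighborhoodProfile]:
    """One profile per age class (young/middle/old); undatable proviruses
    are excluded.  An empty class yields an all-zero profile."""
    if isinstance(dating, Mapping):
        age_of = dict(dating)
    else:
        age_of = {p.chain_id: p.age_class for p in dating}
    out: dict[str, NeighborhoodProfile] = {}
    for cls in ("young", "middle", "old"):
        members = [e for e in ervs if age_of.get(e.id) == cls]
        out[cls] = neighborhood_profile(members, models, window)
    return out


# ---------------------------------------------------------------------------
# proximal genes
# ---------------------------------------------------------------------------

@dataclass
class ProximalGene:
    gene_id: str
    erv_id: int
    side: str  # "contained" (any overlap), "upstream", "downstream"
    orientation: str  # "sense" or "antisense"
    distance: int  # bp gap between nearest edges (0 for overlap)


def proximal_genes(
    ervs: Sequence[ProviralChain],
    models: Sequence[CompositeGeneModel],
    flank: int = DEFAULT_FLANK,
) -> list[ProximalGene]:
    """Genes overlapped by a provirus, plus proviruses within ``flank`` bp
    of a model's 5' or 3' end.  Sides are named in the *gene's* frame:
    "upstream" = beyond the model's 5' end (promoter side), "downstream" =
    beyond its 3' end."""
    rows: list[ProximalGene] = []
    for erv in ervs:
        for m in models:
            if erv.chromosome != m.chromosome:
                continue
            orientation = "sense" if erv.strand == m.strand else "antisense"
            if erv.start < m.end and m.start < erv.end:
                rows.append(
                    ProximalGene(m.gene_id, erv.id, "contained", orientation, 0)
                )
                continue
            if erv.end <= m.start:
                gap = m.start - erv.end
                genomic_side = "left"
            else:
                gap = erv.start - m.end
                genomic_side = "right"
            if gap > flank:
                continue
            five_prime_left = m.strand == "+"
            if (genomic_side == "left") == five_prime_left:
                side = "upstream"
            else:
                side = "downstream"
            rows.append(ProximalGene(m.gene_id, erv.id, side, orientation, gap))
    return rows
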