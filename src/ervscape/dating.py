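"""LTR-divergence molecular dating of proviral integrations.

At integration the two LTRs of a provirus are identical; under neutral
drift each LTR then accumulates substitutions independently, so the
pairwise divergence between the 5' and 3' LTR grows at twice the
per-lineage neutral rate.  With a neutral substitution rate ``r`` (fraction
per site per million years; default 0.002, i.e. 0.2%/mya):

    age [mya] = divergence / (2 * r)

so 5% divergence corresponds to ~12.5 mya and 10% to ~25 mya.  Divergence
is the gap- and ambiguity-excluded p-distance of a global pairwise
alignment of the two LTRs — an uncorrected linear clock, deliberately: the
anchor arithmetic above assumes no multiple-hit correction.

Age classes: "young" (< 5% divergence), "middle" (5-10%, both bounds
included), "old" (> 10%); chains without a QC-passing LTR pair are
"undatable" and carried through, never dropped.
"""

from __future__ import annotations

import csv
import math
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import Align

from .model import ChainTable, ProviralChain

AGE_CLASSES = ("young", "middle", "old", "undatable")

#: Sentinel divergence for pairs with no comparable alignment columns.
UNDATABLE = None


@dataclass(frozen=True)
class DatingConfig:
    """Clock and class-boundary parameters.

    substitution_rate
        Neutral substitution rate per site per million years, per lineage.
    young_max / old_min
        Divergence-fraction class bounds: young < young_max;
        young_max <= middle <= old_min; old > old_min.
    lineage_factor
        Number of independently mutating LTR copies (2: both LTRs drift).
    """

    substitution_rate: float = 0.002
    young_max: float = 0.05
    old_min: float = 0.10
    lineage_factor: float = 2.0

    def __post_init__(self) -> None:
        if not (0 < self.young_max <= self.old_min):
            raise ValueError("require 0 < young_max <= old_min")
        if self.substitution_rate <= 0:
            raise ValueError("substitution_rate must be positive")


@dataclass
class LTRPair:
    """An aligned 5'/3' LTR pair with its divergence-derived age."""

    chain_id: int
    seq5: str | None = None
    seq3: str | None = None
    divergence: float | None = None
    age: float | None = None
    age_class: str = "undatable"


def make_aligner(
    match: float = 2.0,
    mismatch: float = -1.0,
    gap_open: float = -10.0,
    gap_extend: float = -2.0,
) -> Align.PairwiseAligner:
    """Global (Needleman-Wunsch) aligner with affine gap costs.

    A gap of length k costs ``gap_open + (k - 1) * gap_extend``.
    Biopython's dynamic programming is exact, and its first reported
    alignment is deterministic (high road: diagonal preferred over
    vertical over horizontal), which fixes tie-breaking.

    The default gap costs are deliberately stiff relative to the mismatch
    cost: LTR pairs diverge mostly by substitution, and with weak gap
    penalties a global aligner starts absorbing runs of mismatches into
    spurious compensating indel pairs once divergence passes ~30%, which
    biases the gap-excluded p-distance (and hence the age estimate)
    downward.  At these settings a pure-substitution pair aligns gap-free
    across the whole usable divergence range.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def align_ltrs(
    seq5: str, seq3: str, aligner: Align.PairwiseAligner | None = None
) -> tuple[str, str, float]:
    """Globally align two LTR sequences.

    Returns the two gapped sequences of the optimal alignment plus its
    score.  Sequences must be non-empty over the ACGTN alphabet.
    """
    for name, seq in (("seq5", seq5), ("seq3", seq3)):
        if not seq:
            raise ValueError(f"{name} is empty")
        bad = set(seq.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"{name} contains non-ACGTN characters {sorted(bad)}")
    if aligner is None:
        aligner = make_aligner()
    aln = aligner.align(seq5.upper(), seq3.upper())[0]
    a, b = str(aln[0]), str(aln[1])
    return a, b, aln.score


def ltr_divergence(aligned5: str, aligned3: str) -> float | None:
    """Gap-excluded p-distance of an aligned LTR pair.

    Columns where either sequence has a gap or an ambiguous base are not
    comparable and are skipped.  Returns ``None`` (undatable) when no
    column is comparable.
    """
    if len(aligned5) != len(aligned3):
        raise ValueError("aligned sequences differ in length")
    comparable = 0
    mismatches = 0
    for a, b in zip(aligned5.upper(), aligned3.upper()):
        if a not in "ACGT" or b not in "ACGT":
            continue
        comparable += 1
        if a != b:
            mismatches += 1
    if comparable == 0:
        return UNDATABLE
    return mismatches / comparable


def age_from_divergence(
    divergence: float, config: DatingConfig | None = None
) -> float:
    """Convert an LTR-pair divergence fraction to an integration age in mya.

    Linear clock: ``age = d / (lineage_factor * substitution_rate)``.
    """
    if config is None:
        config = DatingConfig()
    if divergence < 0:
        raise ValueError("divergence must be non-negative")
    return divergence / (config.lineage_factor * config.substitution_rate)


def classify_age(
    divergence: float | None, config: DatingConfig | None = None
) -> str:
    """Assign the age class for a divergence fraction (None -> undatable)."""
    if config is None:
        config = DatingConfig()
    if divergence is None or math.isnan(divergence):
        return "undatable"
    if divergence < config.young_max:
        return "young"
    if divergence <= config.old_min:
        return "middle"
    return "old"


def date_chain(
    chain: ProviralChain,
    config: DatingConfig | None = None,
    aligner: Align.PairwiseAligner | None = None,
) -> LTRPair:
    """Date one chain from its LTR pair, honoring QC exclusion flags."""
    if config is None:
        config = DatingConfig()
    pair = LTRPair(chain_id=chain.id)
    l5, l3 = chain.ltr5, chain.ltr3
    usable = (
        l5 is not None
        and l3 is not None
        and not l5.excluded
        and not l3.excluded
        and l5.sequence
        and l3.sequence
    )
    if not usable:
        return pair
    pair.seq5, pair.seq3 = l5.sequence, l3.sequence
    a, b, _score = align_ltrs(l5.sequence, l3.sequence, aligner)
    d = ltr_divergence(a, b)
    pair.divergence = d
    if d is not None:
        pair.age = age_from_divergence(d, config)
    pair.age_class = classify_age(d, config)
    return pair


def date_chains(
    chains: ChainTable | Iterable[ProviralChain],
    config: DatingConfig | None = None,
) -> list[LTRPair]:
    aligner = make_aligner()
    return [date_chain(c, config, aligner) for c in chains]


def write_dating_tsv(pairs: Sequence[LTRPair], path: str | os.PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["chain_id", "divergence", "age_mya", "age_class"])
        for p in pairs:
            w.writerow(
                [
                    p.chain_id,
                    "NA" if p.divergence is None else f"{p.divergence:.6f}",
                    "NA" if p.age is None else f"{p.age:.4f}",
                    p.age_class,
                ]
            )
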