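"""Core domain types shared across the pipeline.

All coordinates held in memory are 0-based half-open ``[start, end)`` on the
forward strand of the assembly; format-specific conventions (GFF3, AGP,
RepeatMasker) are converted exactly once at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

PUTEIN_GENES: tuple[str, ...] = ("gag", "pro", "pol", "env")
GENUS_LABELS: frozenset[str] = frozenset(
    {"gamma", "beta", "spuma", "gypsy", "unclassified"}
)
STRANDS: frozenset[str] = frozenset({"+", "-"})

_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")


@dataclass
class Putein:
    """One putative ancestral protein reconstructed from a proviral reading
    frame.  ``X`` residues mark positions that could not be determined from
    the degraded genomic copy."""

    gene: str
    sequence: str
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.gene not in PUTEIN_GENES:
            raise ValueError(f"unknown putein gene {self.gene!r}")
        bad = set(self.sequence.upper()) - _AA_ALPHABET
        if bad:
            raise ValueError(f"non-amino-acid characters in putein: {sorted(bad)}")

    @property
    def n_undetermined(self) -> int:
        return self.sequence.upper().count("X")


@dataclass
class LTRFeature:
    """A long terminal repeat annotated within a provirus."""

    start: int
    end: int
    sequence: str | None = None
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty LTR span [{self.start}, {self.end})")

    @property
    def n_ambiguous(self) -> int:
        """Number of non-ACGT positions in the sequence (0 if no sequence)."""
        if self.sequence is None:
            return 0
        return sum(1 for c in self.sequence.upper() if c not in "ACGT")


@dataclass
class ProviralChain:
    """One detected candidate provirus ("chain"): an ordered run of
    retroviral motifs (LTR-gag-pro-pol-env-LTR) on a chromosome, with the
    detection score assigned by the screening program."""

    id: int
    chromosome: str
    start: int
    end: int
    strand: str
    score: float
    genus: str = "unclassified"
    puteins: list[Putein] = field(default_factory=list)
    ltr5: LTRFeature | None = None
    ltr3: LTRFeature | None = None
    pbs: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"chain {self.id}: end ({self.end}) <= start ({self.start})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"chain {self.id}: unknown strand {self.strand!r}")
        if self.score < 0:
            raise ValueError(f"chain {self.id}: negative score {self.score}")
        if self.genus not in GENUS_LABELS:
            raise ValueError(f"chain {self.id}: unknown genus {self.genus!r}")
        for ltr in (self.ltr5, self.ltr3):
            if ltr is not None and not (
                self.start <= ltr.start and ltr.end <= self.end
            ):
                raise ValueError(f"chain {self.id}: LTR span outside chain span")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def distinct_putein_genes(self) -> int:
        """Count of distinct proviral genes (gag/pro/pol/env) with at least
        one annotated putein."""
        return len({p.gene for p in self.puteins})

    @property
    def n_puteins(self) -> int:
        """Total count of annotated puteins, duplicates included."""
        return len(self.puteins)

    def putein(self, gene: str, *, passing_only: bool = False) -> Putein | None:
        """Return the first putein annotated for ``gene`` (or None)."""
        for p in self.puteins:
            if p.gene == gene and not (passing_only and p.excluded):
                return p
        return None

    def overlaps(self, other: "ProviralChain") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start < other.end
            and other.start < self.end
        )

    def copy(self) -> "ProviralChain":
        return replace(
            self,
            puteins=[replace(p) for p in self.puteins],
            ltr5=replace(self.ltr5) if self.ltr5 else None,
            ltr3=replace(self.ltr3) if self.ltr3 else None,
        )


@dataclass
class ChainTable:
    """A set of proviral chains detected in one genome assembly."""

    rows: list[ProviralChain]
    genome_id: str = ""
    coordinate_system: str = "0-based-half-open"

    def __post_init__(self) -> None:
        ids = [c.id for c in self.rows]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate chain ids in table")

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[ProviralChain]:
        return iter(self.rows)

    def __getitem__(self, chain_id: int) -> ProviralChain:
        for c in self.rows:
            if c.id == chain_id:
                return c
        raise KeyError(chain_id)


class GenomeIndex(Mapping[str, int]):
    """Chromosome name -> length (bp) lookup for one assembly."""

    def __init__(self, lengths: Mapping[str, int]):
        for name, length in lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
        self._lengths = dict(lengths)

    def __getitem__(self, name: str) -> int:
        return self._lengths[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._lengths)

    def __len__(self) -> int:
        return len(self._lengths)

    @property
    def total_length(self) -> int:
        return sum(self._lengths.values())

    def __repr__(self) -> str:
        return f"GenomeIndex({len(self)} chromosomes, {self.total_length} bp)"


@dataclass
class TranscriptRecord:
    """One transcript of a gene: its span plus optional exon/CDS structure.

    ``exons`` and ``cds`` are lists of 0-based half-open intervals within the
    span; untranslated regions are derived as exon minus CDS.
    """

    gene_id: str
    transcript_id: str
    chromosome: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"transcript {self.transcript_id}: end <= start"
            )
        if self.strand not in STRANDS:
            raise ValueError(
                f"transcript {self.transcript_id}: strandless features are "
                f"not allowed (got {self.strand!r}); the neighborhood "
                "analysis is orientation-critical"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RepeatInterval:
    """One interspersed-repeat annotation with a normalized class label."""

    chromosome: str
    start: int
    end: int
    repeat_class: str  # one of SINE, LINE, LTR, Simple_repeat, Other
    name: str = ""
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("empty repeat interval")


@dataclass
class AgpComponent:
    """A placed sequence component (W/F/D/... row) of an AGP object."""

    chromosome: str
    start: int
    end: int
    component_id: str
    orientation: str  # "+", "-", or "?" as given


@dataclass
class AgpGap:
    """A gap row (N/U) of an AGP object."""

    chromosome: str
    start: int
    end: int
    gap_type: str  # contig, clone, fragment, scaffold, ... lower-cased
    sized: bool  # True for "N" rows (known size), False for "U"

    @property
    def length(self) -> int:
        return self.end - self.start
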