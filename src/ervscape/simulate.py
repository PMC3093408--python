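"""Synthetic genome-annotation generator with known ground truth.

Produces every input the pipeline consumes — a chromosome-size index, a
provirus chain table, LTR sequences, gene/transcript annotation, a repeat
track and an assembly AGP — from one seeded configuration, together with
sidecar tables recording every planted value (true integration ages, locus
winners, gene orientations relative to their anchor provirus, gap
candidacy).  Each analysis module can therefore be scored against exact
truth.

Key modelling choices
---------------------
* LTR pairs: both LTRs descend from one ancestral sequence; the number of
  mismatching sites between the pair is drawn binomially at the *pairwise*
  expected divergence ``2 * rate * age`` (each mismatch assigned to one
  lineage at random), so realized divergence is exactly unbiased for the
  linear molecular clock the dating module assumes.  Substitutions only by
  default; no indels.
* Genes are anchored near proviruses with a configurable antisense
  probability and a distance drawn uniformly inside the neighborhood
  window, so orientation-bias statistics have known expectation.
* Gaps are planted as candidates or non-candidates by construction: a
  non-candidate violates exactly one exclusion rule (wrong AGP type, too
  small, or a disqualifying repeat planted at its flank).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from . import io as eio
from .model import (
    PUTEIN_GENES,
    AgpComponent,
    AgpGap,
    ChainTable,
    GenomeIndex,
    LTRFeature,
    ProviralChain,
    Putein,
    RepeatInterval,
    TranscriptRecord,
)

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_NT = "ACGT"

#: pairwise divergence is capped here; beyond it the linear clock is
#: meaningless anyway (expected identity at equilibrium is 25%)
MAX_DIVERGENCE = 0.75


class PlacementError(ValueError):
    """Requested features do not fit in the configured genome."""


@dataclass
class SimulationConfig:
    """All knobs of the generator; the seed fully determines the output.

    Defaults describe a desk-scale genome that keeps the structure of a
    mammalian assembly screened for proviruses: a handful of chromosomes
    of a few Mb, ~60 elements averaging ~9 kb with 400-nt LTRs, planted
    integration ages spanning recent (0-2 mya) through ancient (100 mya)
    under a 0.2%/mya neutral rate, genes with alternative transcripts on
    both strands, interspersed repeats, and assembly gaps of mixed type.
    ``antisense_bias`` is the probability that a gene anchored to a
    provirus is placed on the opposite strand; the neutral default 0.5
    makes orientation statistics calibrated out of the box.
    """

    seed: int = 0
    n_chromosomes: int = 6
    chromosome_lengths: tuple[int, ...] | None = None  # default: 10..3 Mb
    n_ervs: int = 60
    erv_length_range: tuple[int, int] = (5_000, 12_000)
    ltr_length: int = 400
    target_ages: tuple[float, ...] = (0.0, 2.0, 12.0, 25.0, 100.0)
    substitution_rate: float = 0.002  # per site per mya, per lineage
    dual_ltr_fraction: float = 0.8
    score_range: tuple[float, float] = (150.0, 1500.0)
    genus_weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "gamma": 0.77,
            "beta": 0.07,
            "spuma": 0.01,
            "gypsy": 0.01,
            "unclassified": 0.14,
        }
    )
    putein_presence: float = 0.6
    putein_length_range: tuple[int, int] = (100, 300)
    putein_x_range: tuple[int, int] = (0, 7)
    n_genes: int = 120
    gene_length_range: tuple[int, int] = (2_000, 30_000)
    transcripts_per_gene_range: tuple[int, int] = (1, 3)
    antisense_bias: float = 0.5
    neighborhood_window: int = 100_000
    n_gaps: int = 40
    gap_type_mix: Mapping[str, float] = field(
        default_factory=lambda: {"fragment": 0.6, "clone": 0.2, "contig": 0.2}
    )
    repeat_density: float = 5.0  # interspersed repeats per Mb
    genome_id: str = "synthetic"

    def __post_init__(self) -> None:
        if not 0 <= self.antisense_bias <= 1:
            raise ValueError("antisense_bias must be in [0, 1]")
        for name in ("n_chromosomes", "n_ervs", "n_genes", "n_gaps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.chromosome_lengths is None:
            base = [10, 8, 6, 5, 4, 3, 3, 2, 2, 2]
            lengths = [
                base[i % len(base)] * 1_000_000
                for i in range(self.n_chromosomes)
            ]
            object.__setattr__(self, "chromosome_lengths", tuple(lengths))
        if len(self.chromosome_lengths) != self.n_chromosomes:
            raise ValueError("chromosome_lengths length != n_chromosomes")


@dataclass
class ErvTruth:
    chain_id: int
    age_mya: float
    target_divergence: float
    realized_divergence: float | None  # None when LTR pair absent
    has_ltr_pair: bool


@dataclass
class GeneTruth:
    gene_id: str
    anchor_erv: int | None
    orientation: str  # sense/antisense relative to the anchor; "none" unanchored
    composite_start: int
    composite_end: int
    strand: str


@dataclass
class GapTruth:
    chromosome: str
    start: int
    end: int
    candidate: bool
    violated_rule: str  # "", "type", "size", "flank"


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome_index: GenomeIndex
    chain_table: ChainTable
    ltr_sequences: dict[str, str]
    transcripts: list[TranscriptRecord]
    repeats: list[RepeatInterval]
    agp_rows: list[AgpComponent | AgpGap]
    erv_truth: list[ErvTruth]
    gene_truth: list[GeneTruth]
    gap_truth: list[GapTruth]

    def write(self, out_dir: str | os.PathLike) -> None:
        """Write the five pipeline inputs plus ground-truth sidecars."""
        os.makedirs(out_dir, exist_ok=True)
        p = lambda name: os.path.join(out_dir, name)
        eio.write_genome_index(self.genome_index, p("genome.sizes"))
        eio.write_chain_table(self.chain_table, p("chains.tsv"))
        eio.write_fasta(self.ltr_sequences, p("ltrs.fasta"))
        eio.write_gff_genes(self.transcripts, p("genes.gff3"))
        eio.write_repeat_bed(self.repeats, p("repeats.bed"))
        eio.write_agp(self.agp_rows, p("assembly.agp"))
        _write_truth_tsv(p("truth_ervs.tsv"), self.erv_truth)
        _write_truth_tsv(p("truth_genes.tsv"), self.gene_truth)
        _write_truth_tsv(p("truth_gaps.tsv"), self.gap_truth)


def _write_truth_tsv(path: str, rows: Sequence) -> None:
    with open(path, "w") as fh:
        if not rows:
            fh.write("\n")
            return
        cols = list(asdict(rows[0]))
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            d = asdict(r)
            fh.write("\t".join(str(d[c]) for c in cols) + "\n")


# ---------------------------------------------------------------------------
# primitive generators
# ---------------------------------------------------------------------------

def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_NT), size=length))


def simulate_ltr_pair(
    rng: np.random.Generator,
    length: int,
    age_mya: float,
    substitution_rate: float = 0.002,
) -> tuple[str, str, float]:
    """Generate a 5'/3' LTR pair diverged to an expected ``2*rate*age``.

    The mismatch count is Binomial(length, target); mismatch sites are
    distinct and each is mutated in exactly one of the two copies, so the
    realized pairwise p-distance (returned third) is exactly the mismatch
    fraction and its expectation equals the target divergence.
    """
    ancestral = rng.integers(0, 4, size=length)
    target = min(2.0 * substitution_rate * age_mya, MAX_DIVERGENCE)
    n_mut = rng.binomial(length, target)
    sites = rng.choice(length, size=n_mut, replace=False)
    seqs = [ancestral.copy(), ancestral.copy()]
    which = rng.integers(0, 2, size=n_mut)
    shifts = rng.integers(1, 4, size=n_mut)  # guarantees a different base
    for site, w, shift in zip(sites, which, shifts):
        seqs[w][site] = (seqs[w][site] + shift) % 4
    to_str = lambda arr: "".join(_NT[b] for b in arr)
    return to_str(seqs[0]), to_str(seqs[1]), n_mut / length


def _random_putein(
    rng: np.random.Generator, gene: str, cfg: SimulationConfig
) -> Putein:
    length = int(rng.integers(*cfg.putein_length_range))
    n_x = int(rng.integers(cfg.putein_x_range[0], cfg.putein_x_range[1] + 1))
    n_x = min(n_x, length)
    seq = list(rng.choice(list(_AA20), size=length))
    for pos in rng.choice(length, size=n_x, replace=False):
        seq[pos] = "X"
    return Putein(gene=gene, sequence="".join(seq))


def _place_nonoverlapping(
    rng: np.random.Generator,
    occupied: dict[str, list[tuple[int, int]]],
    genome: GenomeIndex,
    length: int,
    margin: int = 0,
    max_tries: int = 2000,
) -> tuple[str, int]:
    """Pick a (chromosome, start) for a feature of ``length`` bp that does
    not overlap anything already placed (with ``margin`` slack)."""
    chroms = list(genome)
    weights = np.array([genome[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    for _ in range(max_tries):
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        limit = genome[chrom] - length
        if limit <= 0:
            continue
        start = int(rng.integers(0, limit))
        ok = all(
            not (start - margin < e and s < start + length + margin)
            for s, e in occupied.get(chrom, [])
        )
        if ok:
            occupied.setdefault(chrom, []).append((start, start + length))
            return chrom, start
    raise PlacementError(
        f"could not place a {length} bp feature after {max_tries} tries; "
        "requested features exceed genome space"
    )


# ---------------------------------------------------------------------------
# full-genome simulation
# ---------------------------------------------------------------------------

def simulate_genome(config: SimulationConfig) -> SimulatedDataset:
    """Generate one complete synthetic dataset from a seeded config."""
    rng = np.random.default_rng(config.seed)
    genome = GenomeIndex(
        {
            f"chr{i + 1}": length
            for i, length in enumerate(config.chromosome_lengths)
        }
    )
    chains, ltr_seqs, erv_truth = _simulate_ervs(rng, config, genome)
    transcripts, gene_truth = _simulate_genes(rng, config, genome, chains)
    repeats = _simulate_repeats(rng, config, genome)
    agp_rows, gap_truth = _simulate_gaps(rng, config, genome, repeats)
    return SimulatedDataset(
        config=config,
        genome_index=genome,
        chain_table=ChainTable(rows=chains, genome_id=config.genome_id),
        ltr_sequences=ltr_seqs,
        transcripts=transcripts,
        repeats=repeats,
        agp_rows=agp_rows,
        erv_truth=erv_truth,
        gene_truth=gene_truth,
        gap_truth=gap_truth,
    )


def _simulate_ervs(
    rng: np.random.Generator, cfg: SimulationConfig, genome: GenomeIndex
) -> tuple[list[ProviralChain], dict[str, str], list[ErvTruth]]:
    occupied: dict[str, list[tuple[int, int]]] = {}
    genera = list(cfg.genus_weights)
    gweights = np.array([cfg.genus_weights[g] for g in genera], dtype=float)
    gweights /= gweights.sum()
    chains: list[ProviralChain] = []
    ltr_seqs: dict[str, str] = {}
    truth: list[ErvTruth] = []
    for i in range(cfg.n_ervs):
        length = int(rng.integers(*cfg.erv_length_range))
        chrom, start = _place_nonoverlapping(rng, occupied, genome, length)
        strand = "+" if rng.random() < 0.5 else "-"
        age = float(cfg.target_ages[i % len(cfg.target_ages)])
        has_pair = bool(rng.random() < cfg.dual_ltr_fraction)
        chain_id = i + 1
        ltr5 = ltr3 = None
        realized = None
        if has_pair:
            s5, s3, realized = simulate_ltr_pair(
                rng, cfg.ltr_length, age, cfg.substitution_rate
            )
            # 5' LTR is at the chain's transcriptional start
            left, right = (s5, s3) if strand == "+" else (s3, s5)
            ltr_left = LTRFeature(start, start + cfg.ltr_length, sequence=left)
            ltr_right = LTRFeature(
                start + length - cfg.ltr_length, start + length, sequence=right
            )
            ltr5, ltr3 = (
                (ltr_left, ltr_right) if strand == "+" else (ltr_right, ltr_left)
            )
            ltr_seqs[eio.ltr_fasta_key(chain_id, "5")] = s5
            ltr_seqs[eio.ltr_fasta_key(chain_id, "3")] = s3
        puteins = [
            _random_putein(rng, gene, cfg)
            for gene in PUTEIN_GENES
            if rng.random() < cfg.putein_presence
        ]
        chains.append(
            ProviralChain(
                id=chain_id,
                chromosome=chrom,
                start=start,
                end=start + length,
                strand=strand,
                score=float(rng.uniform(*cfg.score_range)),
                genus=genera[rng.choice(len(genera), p=gweights)],
                puteins=puteins,
                ltr5=ltr5,
                ltr3=ltr3,
                pbs=str(rng.choice(["Pro", "Lys"])) if rng.random() < 0.7 else None,
            )
        )
        truth.append(
            ErvTruth(
                chain_id=chain_id,
                age_mya=age,
                target_divergence=min(
                    2 * cfg.substitution_rate * age, MAX_DIVERGENCE
                ),
                realized_divergence=realized,
                has_ltr_pair=has_pair,
            )
        )
    return chains, ltr_seqs, truth


def _simulate_genes(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    genome: GenomeIndex,
    chains: Sequence[ProviralChain],
) -> tuple[list[TranscriptRecord], list[GeneTruth]]:
    transcripts: list[TranscriptRecord] = []
    truth: list[GeneTruth] = []
    chroms = list(genome)
    for g in range(cfg.n_genes):
        gene_len = int(rng.integers(*cfg.gene_length_range))
        anchor: ProviralChain | None = None
        if chains:
            anchor = chains[g % len(chains)]
        if anchor is not None:
            antisense = bool(rng.random() < cfg.antisense_bias)
            strand = _flip(anchor.strand) if antisense else anchor.strand
            gap = int(rng.integers(0, cfg.neighborhood_window))
            side = 1 if rng.random() < 0.5 else -1
            if side > 0:
                start = anchor.end + gap
            else:
                start = anchor.start - gap - gene_len
            chrom = anchor.chromosome
            start = max(0, min(start, genome[chrom] - gene_len))
            orientation = "antisense" if antisense else "sense"
            anchor_id: int | None = anchor.id
        else:
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            start = int(rng.integers(0, max(1, genome[chrom] - gene_len)))
            strand = "+" if rng.random() < 0.5 else "-"
            orientation = "none"
            anchor_id = None
        end = start + gene_len
        gene_id = f"gene{g + 1}"
        n_tx = int(
            rng.integers(
                cfg.transcripts_per_gene_range[0],
                cfg.transcripts_per_gene_range[1] + 1,
            )
        )
        for t in range(n_tx):
            if t == 0:
                ts, te = start, end  # the longest transcript spans the gene
            else:
                # alternatives are contained in the longest, so the
                # composite model provably equals the gene span
                ts = start + int(rng.integers(0, gene_len // 3 + 1))
                te = end - int(rng.integers(0, gene_len // 3 + 1))
                if te <= ts:
                    te = ts + 1
            exons, cds = _transcript_structure(rng, ts, te)
            transcripts.append(
                TranscriptRecord(
                    gene_id=gene_id,
                    transcript_id=f"{gene_id}.t{t + 1}",
                    chromosome=chrom,
                    strand=strand,
                    start=ts,
                    end=te,
                    exons=exons,
                    cds=cds,
                )
            )
        truth.append(
            GeneTruth(
                gene_id=gene_id,
                anchor_erv=anchor_id,
                orientation=orientation,
                composite_start=start,
                composite_end=end,
                strand=strand,
            )
        )
    return transcripts, truth


def _transcript_structure(
    rng: np.random.Generator, start: int, end: int
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """2-3 exons with introns between them; CDS = central half of the span
    intersected with the exons (flanks become UTR)."""
    length = end - start
    if length < 9:
        return [(start, end)], []
    n_ex = int(rng.integers(2, 4))
    cuts = sorted(
        int(x) for x in rng.integers(1, length, size=2 * (n_ex - 1))
    )
    bounds = [start] + [start + c for c in cuts] + [end]
    exons = [
        (bounds[2 * k], bounds[2 * k + 1])
        for k in range(n_ex)
        if bounds[2 * k] < bounds[2 * k + 1]
    ]
    if not exons:
        exons = [(start, end)]
    cds_s, cds_e = start + length // 4, end - length // 4
    cds = [
        (max(s, cds_s), min(e, cds_e))
        for s, e in exons
        if max(s, cds_s) < min(e, cds_e)
    ]
    return exons, cds


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def _simulate_repeats(
    rng: np.random.Generator, cfg: SimulationConfig, genome: GenomeIndex
) -> list[RepeatInterval]:
    classes = ["SINE", "LINE", "LTR", "Simple_repeat"]
    weights = np.array([0.5, 0.3, 0.1, 0.1])
    repeats: list[RepeatInterval] = []
    i = 0
    for chrom, length in genome.items():
        n = int(round(cfg.repeat_density * length / 1e6))
        for _ in range(n):
            rep_len = int(rng.integers(150, 6000))
            if length <= rep_len:
                continue
            start = int(rng.integers(0, length - rep_len))
            i += 1
            repeats.append(
                RepeatInterval(
                    chromosome=chrom,
                    start=start,
                    end=start + rep_len,
                    repeat_class=classes[rng.choice(4, p=weights)],
                    name=f"rep{i}",
                    strand="+" if rng.random() < 0.5 else "-",
                )
            )
    return repeats


def _simulate_gaps(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    genome: GenomeIndex,
    repeats: list[RepeatInterval],
    flank_window: int = 50,
) -> tuple[list[AgpComponent | AgpGap], list[GapTruth]]:
    """Plant gaps with candidacy fixed by construction.

    A candidate gap is a sized fragment gap >= 1 kb (or an unsized U gap)
    with no repeat near either flank.  A non-candidate violates exactly
    one rule: clone/contig type, sub-kb size, or a planted SINE/LINE/
    simple repeat at a flank.
    """
    occupied: dict[str, list[tuple[int, int]]] = {}
    for r in repeats:
        occupied.setdefault(r.chromosome, []).append((r.start, r.end))
    gaps: list[AgpGap] = []
    truth: list[GapTruth] = []
    margin = flank_window + 10
    n_rep = 0
    for _ in range(cfg.n_gaps):
        candidate = bool(rng.random() < 0.5)
        violated = ""
        unsized = rng.random() < 0.2
        gap_len = int(rng.integers(1000, 5000))
        gap_type = "fragment"
        if not candidate:
            violated = str(rng.choice(["type", "size", "flank"]))
            if violated == "type":
                gap_type = str(rng.choice(["clone", "contig"]))
                unsized = False
            elif violated == "size":
                gap_len = int(rng.integers(100, 1000))
                unsized = False  # a U gap cannot be confidently sized small
        chrom, start = _place_nonoverlapping(
            rng, occupied, genome, gap_len, margin=margin
        )
        if not candidate and violated == "flank":
            flank_cls = str(rng.choice(["SINE", "LINE", "Simple_repeat"]))
            rep_len = int(rng.integers(150, 400))
            side = 1 if rng.random() < 0.5 else -1
            if side > 0:
                rs = start + gap_len + int(rng.integers(0, flank_window))
            else:
                rs = start - int(rng.integers(0, flank_window)) - rep_len
            rs = max(0, rs)
            n_rep += 1
            repeats.append(
                RepeatInterval(
                    chromosome=chrom,
                    start=rs,
                    end=rs + rep_len,
                    repeat_class=flank_cls,
                    name=f"flankrep{n_rep}",
                )
            )
        gaps.append(
            AgpGap(
                chromosome=chrom,
                start=start,
                end=start + gap_len,
                gap_type=gap_type,
                sized=not unsized,
            )
        )
        truth.append(
            GapTruth(
                chromosome=chrom,
                start=start,
                end=start + gap_len,
                candidate=candidate,
                violated_rule=violated,
            )
        )
    agp_rows = _gaps_to_agp(gaps, genome)
    truth.sort(key=lambda t: (t.chromosome, t.start))
    return agp_rows, truth


def _gaps_to_agp(
    gaps: list[AgpGap], genome: GenomeIndex
) -> list[AgpComponent | AgpGap]:
    rows: list[AgpComponent | AgpGap] = []
    by_chrom: dict[str, list[AgpGap]] = {}
    for g in gaps:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for chrom, length in genome.items():
        chrom_gaps = sorted(by_chrom.get(chrom, []), key=lambda g: g.start)
        pos = 0
        for k, gap in enumerate(chrom_gaps):
            if gap.start > pos:
                rows.append(
                    AgpComponent(
                        chromosome=chrom,
                        start=pos,
                        end=gap.start,
                        component_id=f"{chrom}_cmp{k + 1}",
                        orientation="+",
                    )
                )
            rows.append(gap)
            pos = gap.end
        if pos < length:
            rows.append(
                AgpComponent(
                    chromosome=chrom,
                    start=pos,
                    end=length,
                    component_id=f"{chrom}_cmp{len(chrom_gaps) + 1}",
                    orientation="+",
                )
            )
    return rows


# ---------------------------------------------------------------------------
# locus-cluster fixtures
# ---------------------------------------------------------------------------

def simulate_locus_cluster(
    rng: np.random.Generator,
    stage: int,
    size: int = 3,
    chromosome: str = "chr1",
    start: int = 1_000_000,
    id_offset: int = 0,
) -> tuple[list[ProviralChain], int]:
    """Overlapping chains whose dedup winner is decided at a chosen
    cascade ``stage`` (1 = distinct putein genes, 2 = total puteins,
    3 = score).  Returns the shuffled chains and the planted winner's id.

    Chains tied on every stage *before* the deciding one; the winner
    strictly dominates at the deciding stage; later stages are randomized
    (losers may beat the winner there, proving stage precedence).
    """
    if size < 2:
        raise ValueError("cluster size must be >= 2")
    if stage not in (1, 2, 3):
        raise ValueError("stage must be 1, 2 or 3")
    span = 9000
    chains: list[ProviralChain] = []
    winner_idx = int(rng.integers(0, size))
    for k in range(size):
        is_winner = k == winner_idx
        if stage == 1:
            distinct = 3 if is_winner else int(rng.integers(1, 3))
            extra = int(rng.integers(0, 3))  # duplicate puteins, any chain
        elif stage == 2:
            distinct = 2
            extra = 2 + int(rng.integers(0, 2)) if is_winner else 0
        else:
            distinct = 2
            extra = 1
        genes = list(PUTEIN_GENES[:distinct])
        genes += [PUTEIN_GENES[0]] * extra
        if stage == 3:
            score = 900.0 if is_winner else float(rng.uniform(310, 800))
        else:
            # losers may out-score the winner: earlier stages must win
            score = float(rng.uniform(310, 1200))
        offset = int(rng.integers(0, span // 2))
        chains.append(
            ProviralChain(
                id=id_offset + k + 1,
                chromosome=chromosome,
                start=start + offset,
                end=start + offset + span,
                strand="+",
                score=score,
                puteins=[
                    Putein(gene=g, sequence="M" * 50) for g in genes
                ],
            )
        )
    winner_id = chains[winner_idx].id
    perm = rng.permutation(size)
    return [chains[int(p)] for p in perm], winner_id


def random_locus_cluster(
    rng: np.random.Generator,
    size: int | None = None,
    chromosome: str = "chr1",
    start: int = 1_000_000,
    id_offset: int = 0,
) -> list[ProviralChain]:
    """Fully random overlapping cluster (no planted winner) for oracle
    comparisons against a brute-force cascade."""
    if size is None:
        size = int(rng.integers(2, 6))
    span = 8000
    chains = []
    for k in range(size):
        n_put = int(rng.integers(0, 6))
        genes = [
            PUTEIN_GENES[int(rng.integers(0, 4))] for _ in range(n_put)
        ]
        offset = int(rng.integers(0, span - 1000))
        chains.append(
            ProviralChain(
                id=id_offset + k + 1,
                chromosome=chromosome,
                start=start + offset,
                end=start + offset + span,
                strand="+",
                score=float(rng.integers(301, 1000)),
                puteins=[Putein(gene=g, sequence="M" * 30) for g in genes],
            )
        )
    return chains
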