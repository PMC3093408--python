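# Methods

This note documents the models, parameter choices and numerical decisions
behind `ervscape`, and what the synthetic-data validation does and does
not demonstrate.

## Provirus filtering

A detection screen of a genome assembly reports candidate proviral chains
with a score; randomized-sequence experiments place the true/false
boundary at a score of 300, read strictly (a chain scoring exactly 300 is
discarded). Overlapping chains on one chromosome are alternative calls of
one integration locus. A *locus* is defined here as the transitive
closure of ≥ 1 bp span overlap — the simplest reading of "lower scoring
elements in the same locus" — found by a per-chromosome sweep. One chain
survives per locus, chosen by a three-stage cascade: most distinct
proviral genes with an annotated putein (0–4), most annotated puteins in
total, highest score. The cascade can still tie (identical annotation and
score); the survivor is then the chain with the smallest start
coordinate, then the smallest id, purely for determinism. Both
`filter_by_score` and `dedup_loci` are idempotent, and deduplicated
output contains no overlapping pair.

Sequence QC *flags* rather than deletes: puteins with ≥ 5 undetermined
(X) residues and LTRs with ≥ 15 ambiguous (non-ACGT) nucleotides are
marked excluded and skipped by dating and phylogenetics, but the chains
remain in every coordinate-based analysis. The 15-nt LTR criterion is an
interpretation — the rule is stated in the source material without a
definition — implemented as an ambiguity cap with a configurable
threshold.

## LTR dating

Model: both LTRs of a provirus are identical at integration and
accumulate neutral substitutions independently, so their pairwise
divergence grows at twice the per-lineage rate *r* (default 0.002 per
site per million years; 0.2 %/mya). Age = d / (2r), a deliberately
*uncorrected* linear clock: the anchor arithmetic (5 % → 12.5 mya,
10 % → 25 mya) assumes no multiple-hit correction, and applying one would
break those anchors. Both the rate and the lineage factor are fields of
`DatingConfig`. Age classes partition [0, 1]: young d < 0.05, middle
0.05 ≤ d ≤ 0.10 (both bounds included), old d > 0.10; chains without a
QC-passing LTR pair are "undatable" and carried through with that
sentinel class, never dropped.

Divergence is the p-distance of a global Needleman–Wunsch alignment over
columns where both sequences have an unambiguous base. Alignment
defaults: match +2, mismatch −1, affine gaps at open −10 / extend −2 (a
length-k gap costs open + (k−1)·extend). The gap costs are deliberately
stiff relative to the mismatch cost: LTR pairs diverge predominantly by
substitution, and with weak gap penalties (e.g. open −5 / extend −1) a
global aligner starts absorbing runs of mismatches into spurious
compensating indel pairs once divergence passes roughly 30 %. Because
gap columns are excluded from the p-distance, those spurious gaps bias
divergence — and therefore age — downward; at a planted age of 100 mya
the mean bias is about −1.8 mya with the weak costs and −0.02 mya with
the defaults. Alignment is exact (Biopython's `PairwiseAligner`), with
deterministic tie-breaking, and is cross-checked in the test suite
against an independent three-state Gotoh dynamic program.

## Gene neighborhood

Gene models are composite "pseudo-transcripts": per gene, start from the
longest transcript and iteratively annex any alternative transcript that
overlaps the current model and extends it past either end; disjoint
alternatives are never annexed. Genes with transcripts on both strands
are split into one model per strand with a warning; strandless input is
rejected outright because the whole analysis is orientation-critical.

Offsets are measured in the provirus frame: the k-th base beyond the
element's 3′ end is at +k, the k-th base beyond its 5′ end at −k, and any
model base overlapping the element collapses to position 0 (an abutting
base is therefore at ±1, and the magnitude of a non-overlapping offset is
edge gap + 1). Counts are model *nucleotides*, not gene tallies, and are
accumulated once per (provirus, model) pair — a position covered by two
genes counts twice. The window is ±100 kb by default.

Two symmetries are tested: the profile is invariant under reflecting all
coordinates (x → L−1−x) together with flipping every strand; and flipping
only the provirus strands reverses the arrays and swaps sense with
antisense. (Flipping all strands *without* reflecting coordinates
reverses the arrays — the provirus frame flips — so "unchanged" holds
only for reflection-symmetric data.)

Two over/under statistics are provided because they answer different
questions. `over_under` compares the antisense and sense curves at each
of the 2W+1 window positions and computes a 1-df χ² of (over, under)
against 50:50, with ties tallied separately and excluded. This is the
scale on which such analyses are traditionally reported, but neighboring
positions are covered by the same genes and are strongly autocorrelated,
so the statistic is *descriptive*: its null distribution is far from
χ²₁, which is also why published values of this kind reach 10⁵.
`orientation_bias_test` classifies each gene model once — antisense or
sense relative to the *nearest* provirus within the window (ties by
smallest chain id) — making gene orientations the sampling units. Under
a random-orientation null these are independent, the χ² is calibrated
(measured null rejection ≈ 4.5 % at α = 0.05 over 200 simulations), and
this is the test to use for inference.

Proximal-gene reporting: any overlap is "contained"; otherwise an
element within 5 kb (inclusive) of a model's 5′ or 3′ end is reported
with the side named in the gene's frame (upstream = promoter side).

## Chromosomal landscape

Genome fraction is total chain bp over total assembly bp, as a
percentage. Bin densities assign each feature to the single bin holding
its start (features are ~kb, bins 1 Mb; splitting would complicate the
count for negligible gain). Telomere distances are the per-chromosome
minimum feature start and minimum (length − end); 0 means a telomeric
integration. Region breakdown labels every element basepair with
precedence coding exon > UTR > intron > intergenic (UTR = exon minus
CDS); the precedence is a determinism choice, and counts always sum to
the element length. Correlations are ordinary least squares with r² and
the two-sided slope p-value; outlier chromosomes are excluded by explicit
caller request, never auto-detected, mirroring the judgment call such
analyses involve.

## Assembly gaps

A gap may hide an unassembled element unless one of three exclusion rules
fires: (1) clone or contig gaps arise from the assembly process, not
from unassemblable inserts; (2) gaps confidently sized below 1 kb cannot
hold a meaningful element fragment — gaps of unknown size (AGP `U` rows)
cannot be excluded on size, so the length rule applies to sized (`N`)
rows only; (3) a SINE, LINE or simple repeat within 50 bp of either edge
marks the gap as caused by that repeat, whereas an LTR-class flank is
consistent with a truncated provirus continuing into the gap and does
not disqualify. The 50-bp flank window is this package's
operationalization of "clearly flanked" (no distance is defined in the
source); both it and the length threshold are configurable, and candidate
counts are monotone non-increasing under tightening either.

## Phylogenetics

Multiple alignments are inputs; everything downstream is implemented
here. Identities and distances use pairwise deletion (per pair, only
columns where both sequences carry a determined residue). The Kimura
amino-acid correction d = −ln(1 − p − 0.2p²) is strictly increasing and
saturates near p ≈ 0.795; `kimura_aa_distance` returns infinity there,
and the matrix builder substitutes a cap of 10.0 (the pragmatic device
distance-matrix phylogeny programs use) so tree building remains
possible.

Neighbor joining follows Saitou–Nei: Q-matrix selection with strict
lowest-index tie-breaking (fully deterministic topology), standard
branch-length estimates with negative estimates clamped to zero and the
deficit moved to the sister branch (preserving the joined pair's path
length), and a trifurcating root for the unrooted result, held as a
scikit-bio `TreeNode`. Correctness is checked three ways: exact recovery
(topology and path lengths) on additive matrices, agreement with
scikit-bio's independent NJ on noisy tree-derived matrices, and agreement
with an exhaustive least-squares topology search on 5-taxon matrices.
The least-squares comparison uses tree-derived matrices with small
(±2 %) noise: on arbitrary non-treelike matrices NJ and best-OLS
genuinely differ, so agreement there is not a meaningful property.

Bootstrap supports resample alignment columns with replacement (default
1000 replicates, seeded), rebuild the tree per replicate, and score each
internal edge of the full-alignment tree by the fraction of replicates
containing the same bipartition. Dot-matrix screening marks window pairs
agreeing at ≥ a minimum identity; it is a visual screen for segmental
duplication/recombination, not a statistical test.

## Synthetic data generator

`simulate_genome` emulates the structure of a mammalian assembly
screened for proviruses, at desk scale: by default 6 chromosomes of
3–10 Mb, 60 non-overlapping elements of 5–12 kb (mean ≈ 9 kb, matching
the reported mean element length) with 400-nt LTRs, planted integration
ages cycling through {0, 2, 12, 25, 100} mya (the span from the youngest
dated elements to the oldest groups) under the 0.2 %/mya rate, genes of
2–30 kb with 1–3 transcripts anchored near elements, interspersed
repeats at 5/Mb, and 40 assembly gaps of mixed type. Every planted value
is recorded in sidecar tables. The same seed and configuration produce
byte-identical files.

LTR pairs are generated so that the realized pairwise divergence is
*exactly* unbiased for the linear clock: the mismatch count is drawn
Binomial(L, 2·r·age), mismatch sites are distinct, and each is mutated in
one of the two copies. (Mutating each lineage independently at rate·age
per site would be the more literal evolutionary mechanism, but multiple
hits make its expected p-distance fall below 2·r·age — about 13 % low at
100 mya — i.e. it simulates the very homoplasy the uncorrected clock
ignores; since the clock is the model under test, the generator plants
the clock's own expectation.) Substitutions only by default; divergence
is capped at 0.75, the equilibrium identity floor.

Gene orientation is the generator's key dial: each gene anchored to an
element lies on the opposite strand with probability `antisense_bias`
(default 0.5, the neutral null, so orientation statistics are calibrated
out of the box) at a uniform distance within the ±100 kb window.
Alternative transcripts are contained in the longest one, so the true
composite model equals the gene span by construction. Non-candidate gaps
violate exactly one exclusion rule (type, size, or a planted flank
repeat), candidates none, so the classifier can be scored exactly.
Puteins are random amino-acid strings with a configured count of X
residues — sequence-realistic internal regions are out of scope. The
dual-LTR fraction defaults to 0.8 so that dating and age stratification
have enough material; in real screens the fraction of elements retaining
both LTRs is far lower.

What passing on synthetic data shows: the implementations compute their
definitions exactly (oracle agreement), recover planted parameters
without bias, and keep nominal error rates. What it cannot show:
behavior under real annotation pathologies (fragmented assemblies,
mis-annotated transcripts, nested or recombined elements, indel-rich LTR
evolution, non-uniform substitution rates), or any of the published
genome-specific numbers, which depend on the original assembly and
screen.

## Problem sizes and runtime

Validation runs are sized for interactive use: age recovery uses 200
replicate LTR pairs per stratum (so the Monte-Carlo 3-SE band at the
oldest stratum is ≈ 1.3 mya); dedup agreement 1000 random clusters;
the per-basepair profile oracle a 10-element / 20-gene fixture at the
full ±100 kb window; calibration and power 200 simulations each at
antisense bias 0.5 and 0.8 (15 elements, 60 genes per simulation); NJ
recovery 20 additive 6-taxon and 50 noisy 5-taxon matrices; gap recovery
100 simulated assemblies (1500 gaps). The whole suite and the acceptance
script each complete in well under a minute on one core.
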