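"""Comparative analysis of Pol puteins: identities, corrected distances,
neighbor-joining trees with bootstrap support, and dot-matrix screening.

Multiple alignments are inputs (any aligner may produce them); everything
downstream of the alignment is implemented here.  Distances use pairwise
deletion: for each sequence pair, only columns where both sequences carry
a determined residue are compared.  Protein distances apply the Kimura
correction for multiple substitutions,

    d = -ln(1 - p - 0.2 p**2),

where ``p`` is the proportion of differing residues.  Trees are built with
the Saitou-Nei neighbor-joining algorithm, with negative branch lengths
clamped to zero (the deficit moved to the sister branch) and deterministic
lowest-index tie-breaking on the Q matrix; bootstrap supports come from
column resampling with replacement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import skbio

GAP_CHARS = frozenset("-.")
#: characters never compared: gaps plus undetermined residues/bases
_SKIP_AA = GAP_CHARS | {"X", "*"}
_SKIP_NT = GAP_CHARS | {"N"}

#: distance assigned when the Kimura correction saturates (p too large)
SATURATED = math.inf


@dataclass
class DistanceMatrix:
    """Symmetric labelled distance (or identity) matrix."""

    labels: list[str]
    matrix: np.ndarray
    metric: str = "p_distance"  # p_distance | kimura_aa | identity_nt | identity_aa

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(np.diag(self.matrix), 0.0):
            raise ValueError("diagonal must be zero")
        finite = np.isfinite(self.matrix)
        if not np.array_equal(finite, finite.T) or not np.allclose(
            self.matrix[finite & finite.T], self.matrix.T[finite & finite.T]
        ):
            raise ValueError("matrix must be symmetric")

    def to_skbio(self) -> skbio.DistanceMatrix:
        return skbio.DistanceMatrix(self.matrix, ids=self.labels)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.matrix[i, j])


# ---------------------------------------------------------------------------
# identities and distances
# ---------------------------------------------------------------------------

def pairwise_identity(a: str, b: str, level: str = "aa") -> float:
    """Fraction of identical columns among columns where both sequences
    are non-gap (and determined).  ``nan`` when no column is comparable."""
    if len(a) != len(b):
        raise ValueError("aligned sequences differ in padded length")
    skip = _SKIP_NT if level == "nt" else _SKIP_AA
    comparable = identical = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in skip or y in skip:
            continue
        comparable += 1
        if x == y:
            identical += 1
    if comparable == 0:
        return float("nan")
    return identical / comparable


def p_distance(a: str, b: str, level: str = "aa") -> float:
    """Proportion of differing columns under pairwise deletion."""
    ident = pairwise_identity(a, b, level)
    return float("nan") if math.isnan(ident) else 1.0 - ident


def kimura_aa_distance(p: float) -> float:
    """Kimura-corrected amino-acid distance ``-ln(1 - p - 0.2 p^2)``.

    Returns :data:`SATURATED` (inf) when the correction's argument is
    non-positive, i.e. the sequences are too diverged to correct.
    """
    if p < 0:
        raise ValueError("p must be non-negative")
    arg = 1.0 - p - 0.2 * p * p
    if arg <= 0:
        return SATURATED
    return -math.log(arg)


def identity_matrix(
    msa: Mapping[str, str], level: str = "aa"
) -> DistanceMatrix:
    labels = list(msa)
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident = pairwise_identity(msa[labels[i]], msa[labels[j]], level)
            m[i, j] = m[j, i] = ident
    return DistanceMatrix(labels, m, metric=f"identity_{level}")


def identity_table(
    nt_msa: Mapping[str, str], aa_msa: Mapping[str, str]
) -> "pd.DataFrame":
    """Combined identity table: nucleotide identity in the upper triangle,
    amino-acid identity in the lower, 1.0 on the diagonal."""
    import pandas as pd

    labels = [k for k in nt_msa if k in aa_msa]
    nt = identity_matrix({k: nt_msa[k] for k in labels}, "nt").matrix
    aa = identity_matrix({k: aa_msa[k] for k in labels}, "aa").matrix
    n = len(labels)
    combined = np.eye(n)
    iu = np.triu_indices(n, 1)
    il = np.tril_indices(n, -1)
    combined[iu] = nt[iu]
    combined[il] = aa[il]
    return pd.DataFrame(combined, index=labels, columns=labels)


def kimura_distance_matrix(
    msa: Mapping[str, str], saturation_distance: float = 10.0
) -> DistanceMatrix:
    """Kimura-corrected pairwise-deletion distance matrix of a protein MSA.

    Pairs too diverged for the correction (or with no comparable columns)
    are set to ``saturation_distance`` so tree building stays possible —
    the same pragmatic cap distance-matrix phylogeny programs use; pass
    ``math.inf`` to make :func:`nj_tree` refuse such matrices instead.
    """
    labels = list(msa)
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = p_distance(msa[labels[i]], msa[labels[j]], "aa")
            d = SATURATED if math.isnan(p) else kimura_aa_distance(p)
            if math.isinf(d):
                d = saturation_distance
            m[i, j] = m[j, i] = d
    return DistanceMatrix(labels, m, metric="kimura_aa")


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> skbio.TreeNode:
    """Saitou-Nei neighbor joining.

    Returns an unrooted tree (trifurcating root) as a scikit-bio
    ``TreeNode``.  Negative branch-length estimates are clamped to zero
    with the deficit moved to the sister branch, preserving the joined
    pair's path length.  Q-matrix ties resolve to the lowest index pair,
    so the topology is fully deterministic.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    if not np.all(np.isfinite(dm.matrix)):
        raise ValueError("distance matrix contains saturated/undefined entries")
    d = dm.matrix.astype(float).copy()
    nodes: list[skbio.TreeNode] = [
        skbio.TreeNode(name=label) for label in dm.labels
    ]
    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best: tuple[int, int] | None = None
        best_q = math.inf
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if q < best_q:  # strict: first (lowest-index) minimum wins
                    best_q = q
                    best = (i, j)
        i, j = best  # type: ignore[misc]
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = _clamp_pair(li, lj)
        parent = skbio.TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.extend([nodes[i], nodes[j]])
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.zeros((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        d = d2
        nodes = [nodes[k] for k in keep] + [parent]
    # resolve the final three nodes around an unrooted center
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    root = skbio.TreeNode()
    for node, length in zip(nodes, (la, lb, lc)):
        node.length = max(0.0, length)
        root.append(node)
    return root


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += -li  # keep li + lj equal to the joined pair's distance
        li = 0.0
    if lj < 0:
        li += -lj
        lj = 0.0
    return li, lj


def tip_names(tree: skbio.TreeNode) -> frozenset[str]:
    return frozenset(t.name for t in tree.tips())


def bipartitions(tree: skbio.TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, each canonicalized as
    the tip set on the side *not* containing the lexicographically first
    taxon."""
    all_tips = tip_names(tree)
    ref = min(all_tips)
    splits: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        clade = tip_names(node)
        if ref in clade:
            clade = all_tips - clade
        if 1 < len(clade) < len(all_tips) - 1:
            splits.add(frozenset(clade))
    return splits


def bootstrap_support(
    msa: Mapping[str, str],
    n_reps: int = 1000,
    seed: int | np.random.Generator = 0,
) -> skbio.TreeNode:
    """NJ tree of a protein MSA with bootstrap supports on internal nodes.

    Alignment columns are resampled with replacement ``n_reps`` times; the
    support of each internal edge of the full-alignment tree is the
    fraction of replicate trees containing the same bipartition.  Supports
    are stored on internal nodes as ``node.support`` (fraction in [0, 1]).
    """
    labels = list(msa)
    seqs = [msa[k] for k in labels]
    n_cols = len(seqs[0])
    if any(len(s) != n_cols for s in seqs):
        raise ValueError("alignment rows differ in length")
    if n_cols < 2:
        raise ValueError("alignment must have >= 2 columns")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    tree = nj_tree(kimura_distance_matrix(msa))
    counts: dict[frozenset[str], int] = {}
    cols = [np.array(list(s)) for s in seqs]
    stacked = np.vstack(cols)  # taxa x columns
    for _ in range(n_reps):
        idx = rng.integers(0, n_cols, size=n_cols)
        res = stacked[:, idx]
        rep_msa = {
            label: "".join(res[i]) for i, label in enumerate(labels)
        }
        try:
            rep_tree = nj_tree(kimura_distance_matrix(rep_msa))
        except ValueError:
            continue  # saturated replicate contributes to no split
        for split in bipartitions(rep_tree):
            counts[split] = counts.get(split, 0) + 1
    all_tips = tip_names(tree)
    ref = min(all_tips)
    for node in tree.non_tips(include_self=False):
        clade = tip_names(node)
        if ref in clade:
            clade = all_tips - clade
        if 1 < len(clade) < len(all_tips) - 1:
            node.support = counts.get(frozenset(clade), 0) / n_reps
    return tree


def tree_to_newick(tree: skbio.TreeNode, supports: bool = True) -> str:
    """Serialize to Newick; internal-node labels carry bootstrap supports
    when present and requested."""
    clone = tree.copy()
    for node in clone.non_tips(include_self=False):
        sup = getattr(node, "support", None)
        node.name = f"{sup:.3f}" if (supports and sup is not None) else None
    return str(clone).strip()


def root_on_outgroup(tree: skbio.TreeNode, outgroup: str) -> skbio.TreeNode:
    """Display rooting on a designated outgroup taxon (topology unchanged)."""
    return tree.root_at(tree.find(outgroup).parent)


# ---------------------------------------------------------------------------
# dot matrix
# ---------------------------------------------------------------------------

def dot_matrix(
    seq_a: str,
    seq_b: str,
    window: int = 10,
    min_identity: float = 0.8,
) -> np.ndarray:
    """Sliding-window dot-matrix comparison.

    Cell ``(i, j)`` is True when the length-``window`` words starting at
    ``i`` in A and ``j`` in B agree at >= ``min_identity`` of positions.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(seq_a) or window > len(seq_b):
        raise ValueError("window longer than a sequence")
    a = np.frombuffer(seq_a.upper().encode(), dtype=np.uint8)
    b = np.frombuffer(seq_b.upper().encode(), dtype=np.uint8)
    wb = np.lib.stride_tricks.sliding_window_view(b, window)
    na = len(a) - window + 1
    out = np.zeros((na, len(wb)), dtype=bool)
    threshold = min_identity * window
    for i in range(na):
        matches = (wb == a[i : i + window]).sum(axis=1)
        out[i] = matches >= threshold
    return out
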