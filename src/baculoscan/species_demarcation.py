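"""Kimura 2-parameter distances and alphabaculovirus species demarcation.

Baculovirus taxonomy uses a distance criterion on partial marker genes
(*lef-8*, *lef-9*, *polh*): a pairwise K2P distance above 0.05
substitutions/site between two isolates indicates distinct species, below
0.015 the same species, and the band in between is indeterminate.  The K2P
model corrects separately for transitions (proportion P) and transversions
(proportion Q):

    d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q)

Sites where either sequence carries a gap or an ambiguous base are excluded
pair-by-pair (pairwise deletion).  When a log argument is non-positive the
distance is saturated: it is reported as undefined with an infinite
sentinel, and the demarcation call is "different species" with a caveat —
saturation itself evidences deep divergence.

A small canonical neighbor-joining implementation turns distance matrices
into Newick trees as a distance-based companion to likelihood phylogenies.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

T_LOW = 0.015
T_HIGH = 0.050

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


@dataclass
class AlignedPair:
    """Two equal-length gapped DNA strings with their substitution counts."""

    seq_a: str
    seq_b: str
    n_sites: int = field(init=False)
    n_transitions: int = field(init=False)
    n_transversions: int = field(init=False)

    def __post_init__(self) -> None:
        a, b = self.seq_a.upper(), self.seq_b.upper()
        if len(a) != len(b):
            raise ValueError("aligned sequences must have equal length")
        n = ts = tv = 0
        for x, y in zip(a, b):
            if x not in "ACGT" or y not in "ACGT":
                continue  # pairwise deletion of gaps/ambiguity
            n += 1
            if x == y:
                continue
            if (x in _PURINES) == (y in _PURINES):
                ts += 1
            else:
                tv += 1
        self.seq_a, self.seq_b = a, b
        self.n_sites, self.n_transitions, self.n_transversions = n, ts, tv

    @property
    def P(self) -> float:
        return self.n_transitions / self.n_sites

    @property
    def Q(self) -> float:
        return self.n_transversions / self.n_sites


@dataclass
class DistanceEstimate:
    d: float
    defined: bool = True
    P: float = 0.0
    Q: float = 0.0


@dataclass
class SpeciesCall:
    decision: str  # same_species | different_species | indeterminate
    d: float
    marker: str = ""
    saturated: bool = False


def k2p_from_proportions(P: float, Q: float) -> DistanceEstimate:
    """K2P distance from transition/transversion proportions."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return DistanceEstimate(math.inf, defined=False, P=P, Q=Q)
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return DistanceEstimate(d, defined=True, P=P, Q=Q)


def k2p_distance(pair: AlignedPair) -> DistanceEstimate:
    """K2P distance of an aligned pair under pairwise deletion."""
    if pair.n_sites == 0:
        raise ValueError("no comparable sites after pairwise deletion")
    return k2p_from_proportions(pair.P, pair.Q)


@dataclass
class DistanceMatrix:
    names: list[str]
    matrix: np.ndarray  # (n, n) float; inf where undefined
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.names.index(a), self.names.index(b)])


def distance_matrix(alignment: dict[str, str]) -> DistanceMatrix:
    """Pairwise K2P matrix of a multiple alignment (pairwise deletion)."""
    names = list(alignment)
    if len(names) < 2:
        raise ValueError("need at least 2 aligned sequences")
    n = len(names)
    mat = np.zeros((n, n))
    undefined = []
    for i, j in itertools.combinations(range(n), 2):
        est = k2p_distance(AlignedPair(alignment[names[i]], alignment[names[j]]))
        mat[i, j] = mat[j, i] = est.d
        if not est.defined:
            undefined.append((names[i], names[j]))
    return DistanceMatrix(names, mat, undefined)


def classify_species(d: float, t_low: float = T_LOW, t_high: float = T_HIGH,
                     marker: str = "") -> SpeciesCall:
    """Apply the marker-gene demarcation criterion to one distance.

    Boundary values (``d == t_low`` or ``d == t_high``) are indeterminate.
    A saturated (infinite/undefined) distance is called different_species
    with ``saturated=True``.
    """
    if math.isinf(d) or math.isnan(d):
        return SpeciesCall("different_species", d, marker, saturated=True)
    if d > t_high:
        return SpeciesCall("different_species", d, marker)
    if d < t_low:
        return SpeciesCall("same_species", d, marker)
    return SpeciesCall("indeterminate", d, marker)


def concatenate_alignments(per_gene: dict[str, dict[str, str]],
                           pad_missing: bool = False
                           ) -> tuple[dict[str, str], dict[str, tuple[int, int]]]:
    """Column-wise concatenation of per-gene alignments.

    Returns the combined alignment and the half-open column partition of
    each gene.  Taxa missing from a gene are gap-padded when ``pad_missing``
    is set, otherwise an error is raised.
    """
    taxa: list[str] = []
    for gene, aln in per_gene.items():
        for taxon in aln:
            if taxon not in taxa:
                taxa.append(taxon)
        if len(set(aln)) != len(aln):
            raise ValueError(f"gene {gene}: duplicated taxon names")
    combined = {t: [] for t in taxa}
    partitions: dict[str, tuple[int, int]] = {}
    offset = 0
    for gene, aln in per_gene.items():
        lengths = {len(s) for s in aln.values()}
        if len(lengths) != 1:
            raise ValueError(f"gene {gene}: ragged alignment")
        width = lengths.pop()
        for t in taxa:
            if t in aln:
                combined[t].append(aln[t])
            elif pad_missing:
                combined[t].append("-" * width)
            else:
                raise ValueError(f"taxon {t} missing from gene {gene}")
        partitions[gene] = (offset, offset + width)
        offset += width
    return {t: "".join(parts) for t, parts in combined.items()}, partitions


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


class _Node:
    __slots__ = ("newick", "min_leaf")

    def __init__(self, newick: str, min_leaf: str):
        self.newick = newick
        self.min_leaf = min_leaf


def _fmt(x: float) -> str:
    return f"{x:.6f}".rstrip("0").rstrip(".") or "0"


def neighbor_joining(dm: DistanceMatrix) -> str:
    """Canonical neighbor joining; returns an unrooted Newick string.

    Negative branch lengths are clamped to zero with the deficit moved to
    the sister branch.  Ties in the Q criterion break by the
    lexicographically smallest (min-leaf, min-leaf) pair, so output is
    deterministic.  ``n = 2`` gives a single edge split symmetrically.
    """
    names = list(dm.names)
    n = len(names)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    D = np.array(dm.matrix, dtype=float)
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix is not symmetric")
    nodes = [_Node(name, name) for name in names]

    if n == 2:
        h = D[0, 1] / 2.0
        a, b = sorted(nodes, key=lambda x: x.min_leaf)
        return f"({a.newick}:{_fmt(h)},{b.newick}:{_fmt(h)});"

    active = list(range(n))
    dist = {(i, j): D[i, j] for i in range(n) for j in range(n) if i < j}

    def d(i: int, j: int) -> float:
        return 0.0 if i == j else dist[(min(i, j), max(i, j))]

    next_id = n
    store: dict[int, _Node] = {i: nodes[i] for i in range(n)}

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d(i, k) for k in active) for i in active}
        best, best_q = None, math.inf
        for ii in range(m):
            for jj in range(ii + 1, m):
                i, j = active[ii], active[jj]
                q = (m - 2) * d(i, j) - r[i] - r[j]
                pair_key = tuple(sorted((store[i].min_leaf, store[j].min_leaf)))
                if (q < best_q - 1e-12 or
                        (abs(q - best_q) <= 1e-12 and best is not None
                         and pair_key < best[2])):
                    best, best_q = (i, j, pair_key), q
        i, j, _ = best
        li = 0.5 * d(i, j) + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d(i, j) - li
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        child_a, child_b = sorted((store[i], store[j]), key=lambda x: x.min_leaf)
        la, lb = (li, lj) if child_a is store[i] else (lj, li)
        new = _Node(
            f"({child_a.newick}:{_fmt(la)},{child_b.newick}:{_fmt(lb)})",
            min(store[i].min_leaf, store[j].min_leaf),
        )
        u = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            dist[(min(u, k), max(u, k))] = 0.5 * (d(i, k) + d(j, k) - d(i, j))
        active = [k for k in active if k not in (i, j)] + [u]
        store[u] = new

    # resolve the final 3-star with the three-point formulas
    i, j, k = active
    li = 0.5 * (d(i, j) + d(i, k) - d(j, k))
    lj = 0.5 * (d(i, j) + d(j, k) - d(i, k))
    lk = 0.5 * (d(i, k) + d(j, k) - d(i, j))
    tips = sorted(
        [(store[i], max(li, 0.0)), (store[j], max(lj, 0.0)), (store[k], max(lk, 0.0))],
        key=lambda t: t[0].min_leaf,
    )
    inner = ",".join(f"{node.newick}:{_fmt(bl)}" for node, bl in tips)
    return f"({inner});"
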