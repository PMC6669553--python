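"""Reciprocal-best-hit orthology, gene-content Venn partitioning, and
anchored locus context.

Multi-genome gene-content comparisons in baculovirus genomics ask three
questions: which genes have orthologs in which relatives (here answered by
strict reciprocal best hits over Smith–Waterman protein alignments), how
the pan-genome partitions across genome subsets (a Venn diagram over
ortholog groups), and what sits between two anchor orthologs in each genome
(locus context, used to spot gene gain/loss such as an *iap-3* deletion).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from Bio.Align import PairwiseAligner, substitution_matrices

from .genome_io import Feature


@dataclass(frozen=True)
class ProteinRecord:
    genome_id: str
    gene_label: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.genome_id}/{self.gene_label}: empty protein")


@dataclass
class AlignmentResult:
    score: float
    identity: float  # percent over aligned columns
    coverage: float  # aligned length / length of the shorter protein


@dataclass
class OrthologGroup:
    group_id: str
    members: frozenset  # of (genome_id, gene_label)


@dataclass
class RbhPair:
    a: tuple[str, str]  # (genome_id, gene_label)
    b: tuple[str, str]
    score: float


def _aligner(gap_open: float, gap_extend: float,
             matrix: str = "BLOSUM62") -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def align_proteins(a: str, b: str, gap_open: float = 11, gap_extend: float = 1,
                   matrix: str = "BLOSUM62") -> AlignmentResult:
    """Local (Smith–Waterman) protein alignment.

    Returns the raw score, percent identity over aligned columns, and the
    aligned-length coverage of the shorter protein.
    """
    if not a or not b:
        raise ValueError("protein sequences must be non-empty")
    aligner = _aligner(gap_open, gap_extend, matrix)
    alignments = aligner.align(a, b)
    if len(alignments) == 0 or alignments.score <= 0:
        return AlignmentResult(0.0, 0.0, 0.0)
    aln = alignments[0]
    counts = aln.counts()
    cols = aln.length
    identity = 100.0 * counts.identities / cols if cols else 0.0
    shorter = min(len(a), len(b))
    # aligned residues of the shorter sequence
    a_res = sum(e - s for s, e in aln.aligned[0])
    b_res = sum(e - s for s, e in aln.aligned[1])
    covered = a_res if len(a) <= len(b) else b_res
    return AlignmentResult(float(aln.score), round(identity, 1),
                           round(covered / shorter, 3))


def reciprocal_best_hits(proteome_a: list[ProteinRecord],
                         proteome_b: list[ProteinRecord],
                         min_score: float = 100.0,
                         min_coverage: float = 0.5,
                         gap_open: float = 11, gap_extend: float = 1
                         ) -> list[RbhPair]:
    """Strict RBH pairs between two proteomes.

    ``(x, y)`` is reported iff ``y`` is ``x``'s unique best hit in B and
    ``x`` is ``y``'s unique best hit in A, both passing the score and
    coverage thresholds.  Ties for best hit yield no pair (conservative).
    """
    if not proteome_a or not proteome_b:
        raise ValueError("both proteomes must be non-empty")
    scores: dict[tuple[int, int], float] = {}
    for i, x in enumerate(proteome_a):
        for j, y in enumerate(proteome_b):
            res = align_proteins(x.sequence, y.sequence, gap_open, gap_extend)
            ok = res.score >= min_score and res.coverage >= min_coverage
            scores[(i, j)] = res.score if ok else float("-inf")

    def unique_best(axis_scores: list[float]) -> int | None:
        best = max(axis_scores)
        if best == float("-inf"):
            return None
        idx = [k for k, s in enumerate(axis_scores) if s == best]
        return idx[0] if len(idx) == 1 else None

    best_in_b = {
        i: unique_best([scores[(i, j)] for j in range(len(proteome_b))])
        for i in range(len(proteome_a))
    }
    best_in_a = {
        j: unique_best([scores[(i, j)] for i in range(len(proteome_a))])
        for j in range(len(proteome_b))
    }
    pairs = []
    for i, j in best_in_b.items():
        if j is not None and best_in_a.get(j) == i:
            x, y = proteome_a[i], proteome_b[j]
            pairs.append(RbhPair((x.genome_id, x.gene_label),
                                 (y.genome_id, y.gene_label), scores[(i, j)]))
    return pairs


def all_pairwise_rbh(proteomes: dict[str, list[ProteinRecord]],
                     min_score: float = 100.0, min_coverage: float = 0.5
                     ) -> list[RbhPair]:
    """RBH over every unordered pair of proteomes."""
    pairs = []
    for ga, gb in itertools.combinations(sorted(proteomes), 2):
        pairs.extend(
            reciprocal_best_hits(proteomes[ga], proteomes[gb],
                                 min_score, min_coverage)
        )
    return pairs


def build_ortholog_groups(rbh_pairs: list[RbhPair],
                          all_genes: list[tuple[str, str]] | None = None
                          ) -> list[OrthologGroup]:
    """Single-linkage union of RBH pairs into disjoint ortholog groups.

    A group that would acquire two members from one genome is split by
    dropping the lowest-scoring conflicting edge and re-linking.  Genes in
    ``all_genes`` that pair with nothing become singleton groups.
    """
    edges = sorted(rbh_pairs, key=lambda p: -p.score)
    active = list(edges)
    while True:
        parent: dict = {}

        def find(x):
            while parent.get(x, x) != x:
                parent[x] = parent.get(parent[x], parent[x])
                x = parent[x]
            return x

        def union(x, y):
            rx, ry = find(x), find(y)
            if rx != ry:
                parent.setdefault(rx, rx)
                parent[ry] = rx

        for e in active:
            parent.setdefault(e.a, e.a)
            parent.setdefault(e.b, e.b)
            union(e.a, e.b)
        comp: dict = {}
        for node in list(parent):
            comp.setdefault(find(node), []).append(node)
        conflicted = set()
        for root, members in comp.items():
            genomes = [g for g, _ in members]
            if len(genomes) != len(set(genomes)):
                conflicted.add(root)
        if not conflicted:
            break
        # drop the weakest edge inside each conflicted component
        for root in conflicted:
            in_comp = [e for e in active if find(e.a) == root]
            weakest = min(in_comp, key=lambda e: e.score)
            active.remove(weakest)

    parent = {}

    def find2(x):
        while parent.get(x, x) != x:
            parent[x] = parent.get(parent[x], parent[x])
            x = parent[x]
        return x

    for e in active:
        parent.setdefault(e.a, e.a)
        parent.setdefault(e.b, e.b)
        ra, rb = find2(e.a), find2(e.b)
        if ra != rb:
            parent[rb] = ra
    comp = {}
    for node in list(parent):
        comp.setdefault(find2(node), set()).add(node)
    groups = [frozenset(m) for m in comp.values()]
    grouped = set().union(*groups) if groups else set()
    for gene in all_genes or []:
        if gene not in grouped:
            groups.append(frozenset([gene]))
    groups.sort(key=lambda g: sorted(g)[0])
    return [OrthologGroup(f"og{i + 1:04d}", g) for i, g in enumerate(groups)]


@dataclass
class VennPartition:
    """Counts of ortholog groups per exact genome subset."""

    counts: dict[frozenset, int]
    genome_ids: list[str]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def count(self, *genomes: str) -> int:
        return self.counts.get(frozenset(genomes), 0)


def venn_partition(groups: list[OrthologGroup],
                   genome_ids: list[str]) -> VennPartition:
    """Assign each group to the exact subset of genomes it touches.

    Every non-empty subset of ``genome_ids`` is enumerated, with zero counts
    for subsets no group occupies; counts sum to the number of groups.
    """
    counts: dict[frozenset, int] = {}
    for r in range(1, len(genome_ids) + 1):
        for sub in itertools.combinations(sorted(genome_ids), r):
            counts[frozenset(sub)] = 0
    for g in groups:
        subset = frozenset(genome for genome, _ in g.members)
        if subset not in counts:
            raise ValueError(f"group {g.group_id} touches unknown genomes {subset}")
        counts[subset] += 1
    return VennPartition(counts, sorted(genome_ids))


def locus_context(annotations: list[Feature], anchor_label_1: str,
                  anchor_label_2: str, genome_length: int,
                  circular: bool = True) -> list[Feature]:
    """Genes strictly between two anchor genes, oriented anchor-1 first.

    On circular genomes the shorter arc between the anchors is taken.  The
    anchors must each occur exactly once among the annotations.
    """
    def pick(label: str) -> Feature:
        hits = [f for f in annotations if f.label == label]
        if len(hits) != 1:
            raise ValueError(
                f"anchor {label!r} occurs {len(hits)} times (need exactly 1)"
            )
        return hits[0]

    a1, a2 = pick(anchor_label_1), pick(anchor_label_2)
    L = genome_length
    if not circular:
        lo, hi = sorted([a1, a2], key=lambda f: f.start)
        between = [f for f in annotations
                   if lo.end <= f.start and f.end <= hi.start]
        between.sort(key=lambda f: f.start)
        if lo is a2:
            between.reverse()
        return between

    def arc_genes(frm: Feature, to: Feature) -> tuple[int, list[Feature]]:
        """Genes in the clockwise arc from ``frm`` end to ``to`` start."""
        arc_len = (to.start - frm.end) % L
        out = []
        for f in annotations:
            if f is frm or f is to:
                continue
            off = (f.start - frm.end) % L
            if off + f.span <= arc_len:
                out.append((off, f))
        out.sort()
        return arc_len, [f for _, f in out]

    len12, genes12 = arc_genes(a1, a2)
    len21, genes21 = arc_genes(a2, a1)
    if len12 <= len21:
        return genes12
    return list(reversed(genes21))
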