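"""Direct-repeat and homologous-region (hr) discovery.

Baculovirus genomes carry two kinds of repetitive loci: tandem direct
repeats (dr), often inside coding sequences, and homologous regions (hrs) —
clusters of imperfect short core motifs (~11–13 nt) recurring at several
loci with high inter-copy identity.  hrs act as origins of replication and
transcriptional enhancers, so locating them and counting their core motifs
is a standard part of a genome report.

Tandem repeats are found by k-mer seeding: exact k-mer recurrences at a
spacing within the requested period range nominate a candidate period,
which is extended unit-by-unit while per-unit identity to the anchor stays
above threshold.  Overlapping reports are resolved in favour of the higher
number of matching bases, with the smallest period winning among harmonics.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

from Bio.Align import PairwiseAligner

from .genome_io import CircularGenome, Feature, reverse_complement

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass
class TandemRepeat:
    """A tandem array of a repeated unit.

    ``copies`` may be fractional when a partial unit terminates the array;
    ``internal_identity`` is the mean percent identity of each full copy to
    the majority-rule consensus unit.
    """

    span: Feature
    unit_length: int
    copies: float
    consensus_unit: str
    internal_identity: float

    @property
    def score(self) -> float:
        """Matches minus mismatches over the array (match +1, mismatch -1).

        This penalizes phase-shifted reports that gain span by absorbing
        flanking background, so the in-phase array wins overlap resolution.
        """
        total = self.unit_length * self.copies
        matches = self.internal_identity / 100.0 * total
        return 2.0 * matches - total


@dataclass
class RepeatRegion:
    """A dr or hr locus on the genome."""

    span: Feature
    kind: str  # "dr" or "hr"
    name: str = ""
    member_repeats: list[TandemRepeat] = field(default_factory=list)
    core_motifs: list[tuple[str, int]] = field(default_factory=list)
    n_hits: int = 0


# ---------------------------------------------------------------------------
# Motif counting
# ---------------------------------------------------------------------------


def _match_at(seq: str, pos: int, motif: str, max_mismatch: int) -> bool:
    mm = 0
    for j, m in enumerate(motif):
        if seq[pos + j] not in _IUPAC[m]:
            mm += 1
            if mm > max_mismatch:
                return False
    return True


def _find_occurrences(seq: str, motif: str, max_mismatch: int,
                      overlapping: bool, circular: bool, L: int) -> list[int]:
    """Start positions (mod L) of motif occurrences on the forward text."""
    m = len(motif)
    text = seq + seq[: m - 1] if circular else seq
    hits = []
    i = 0
    limit = L if circular else L - m + 1
    while i < limit:
        if _match_at(text, i, motif, max_mismatch):
            hits.append(i)
            i += m if not overlapping else 1
        else:
            i += 1
    return hits


def find_motif_positions(genome: CircularGenome, motif: str, strands: str = "both",
                         max_mismatch: int = 0, overlapping: bool = True
                         ) -> list[tuple[int, str]]:
    """Occurrence start positions with strand, wrap-aware on circular genomes.

    Minus-strand hits are reported at the forward-coordinate start of the
    motif's reverse complement.
    """
    motif = motif.upper()
    bad = set(motif) - set(_IUPAC)
    if bad:
        raise ValueError(f"motif contains non-IUPAC characters: {sorted(bad)!r}")
    if not 1 <= len(motif) <= len(genome):
        raise ValueError("motif length must be in [1, genome length]")
    seq, L = genome.sequence, len(genome)
    out: list[tuple[int, str]] = []
    if strands in ("both", "forward", "+"):
        out += [(p, "+") for p in _find_occurrences(seq, motif, max_mismatch,
                                                    overlapping, genome.circular, L)]
    if strands in ("both", "reverse", "-"):
        rc = reverse_complement(motif)
        out += [(p, "-") for p in _find_occurrences(seq, rc, max_mismatch,
                                                    overlapping, genome.circular, L)]
    return sorted(out)


def count_motif(genome: CircularGenome, motif: str, strands: str = "both",
                max_mismatch: int = 0, overlapping: bool = True) -> int:
    """Number of motif occurrences on the selected strands.

    Defaults: exact match, both strands, overlapping occurrences counted,
    origin wrap included on circular genomes.  A site matching on both
    strands of a palindromic motif counts once per strand selected.
    """
    return len(find_motif_positions(genome, motif, strands, max_mismatch,
                                    overlapping))


# ---------------------------------------------------------------------------
# Tandem repeats
# ---------------------------------------------------------------------------


def _unit_identity(a: str, b: str) -> float:
    """Percent identity of two equal-length strings (Hamming)."""
    return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)


def _extend_tandem(text: str, p: int, d: int, min_identity: float,
                   hard_end: int) -> tuple[int, int] | None:
    """Extend a candidate array of period ``d`` anchored at ``p``.

    Returns ``(lo, hi_full)`` covering all accepted full units, or None.
    """
    anchor = text[p : p + d]
    if len(anchor) < d:
        return None
    # extend right
    hi = p + d
    while hi + d <= hard_end and _unit_identity(text[hi : hi + d], anchor) >= min_identity:
        hi += d
    # extend left
    lo = p
    while lo - d >= 0 and _unit_identity(text[lo - d : lo], anchor) >= min_identity:
        lo -= d
    if hi - lo < 2 * d:
        return None
    return lo, hi


def _consensus(copies: list[str]) -> str:
    cols = []
    for j in range(len(copies[0])):
        counts: dict[str, int] = defaultdict(int)
        for c in copies:
            counts[c[j]] += 1
        cols.append(max(sorted(counts), key=lambda b: counts[b]))
    return "".join(cols)


def find_tandem_repeats(genome: CircularGenome, min_unit: int = 8,
                        max_unit: int = 200, min_copies: float = 3,
                        min_identity: float = 85.0,
                        seed_k: int | None = None) -> list[TandemRepeat]:
    """Locate tandem arrays of a repeated unit by k-mer seeding.

    Candidate periods come from exact k-mer recurrences at a spacing ``d``
    with ``min_unit <= d <= max_unit``; each candidate is extended while
    per-unit identity to the anchor unit stays at or above ``min_identity``.
    Overlapping reports are merged keeping the higher-scoring period, with
    the smallest period preferred among harmonics.  Wrap-aware on circular
    genomes.
    """
    if not 1 <= min_unit <= max_unit <= 2000:
        raise ValueError("require 1 <= min_unit <= max_unit <= 2000")
    L = len(genome)
    text = genome.sequence + genome.sequence if genome.circular else genome.sequence
    hard_end = len(text)
    k = seed_k if seed_k is not None else max(4, min(10, min_unit))

    kmer_pos: dict[str, list[int]] = defaultdict(list)
    for i in range(len(text) - k + 1):
        kmer_pos[text[i : i + k]].append(i)

    candidate_pd: set[tuple[int, int]] = set()
    for positions in kmer_pos.values():
        if len(positions) < 2:
            continue
        for a, b in zip(positions, positions[1:]):
            d = b - a
            if min_unit <= d <= max_unit:
                candidate_pd.add((a, d))

    raw: list[TandemRepeat] = []
    seen_arrays: set[tuple[int, int, int]] = set()
    for p, d in sorted(candidate_pd, key=lambda t: (t[1], t[0])):
        ext = _extend_tandem(text, p, d, min_identity, hard_end)
        if ext is None:
            continue
        lo, hi = ext
        if genome.circular and lo >= L:
            continue  # duplicate of a first-copy array
        key = (lo % L if genome.circular else lo, (hi - lo), d)
        if key in seen_arrays:
            continue
        seen_arrays.add(key)
        full = [text[i : i + d] for i in range(lo, hi, d)]
        cons = _consensus(full)
        ident = sum(_unit_identity(c, cons) for c in full) / len(full)
        # fractional tail: a partial unit matching the consensus prefix
        tail = 0
        j = hi
        while j < hard_end and tail < d - 1 and text[j] == cons[tail]:
            tail += 1
            j += 1
        copies = len(full) + tail / d
        if copies < min_copies or ident < min_identity:
            continue
        start = lo % L if genome.circular else lo
        span = Feature(genome.id, start, start + (hi - lo) + tail, "+",
                       kind="tandem_repeat")
        raw.append(TandemRepeat(span, d, round(copies, 2), cons, round(ident, 1)))

    # resolve overlaps: higher score first; smaller period wins among
    # near-equal harmonics
    raw.sort(key=lambda r: (-r.score, r.unit_length, r.span.start))
    accepted: list[TandemRepeat] = []
    for r in raw:
        keep = True
        for a in accepted:
            ov = _overlap_len(r.span, a.span, L if genome.circular else None)
            if ov > 0.5 * min(r.span.span, a.span.span):
                if (r.unit_length < a.unit_length
                        and a.unit_length % r.unit_length == 0
                        and r.score >= a.score - a.unit_length):
                    accepted.remove(a)
                else:
                    keep = False
                break
        if keep:
            accepted.append(r)
    accepted.sort(key=lambda r: r.span.start)
    return accepted


def _overlap_len(a: Feature, b: Feature, L: int | None) -> int:
    def segs(f: Feature):
        if L is None or f.end <= L:
            return [(f.start, f.end)]
        return [(f.start, L), (0, f.end - L)]

    return sum(
        max(0, min(ea, eb) - max(sa, sb))
        for sa, ea in segs(a)
        for sb, eb in segs(b)
    )


# ---------------------------------------------------------------------------
# hr clustering
# ---------------------------------------------------------------------------


def cluster_hrs(genome: CircularGenome, core_motifs: list[str], window: int = 2000,
                min_hits: int = 2, max_mismatch: int = 1,
                group_window: int = 10000) -> list[RepeatRegion]:
    """Cluster core-motif hits into hr regions by single linkage.

    Hits of every motif (default: allowing one mismatch, both strands) are
    projected to genome positions; hits whose gap is at most ``window`` join
    one cluster, and clusters with at least ``min_hits`` hits become hr
    regions spanning first-to-last hit.  Regions are named sequentially from
    the genome origin (``hr1a``, ``hr1b``, ``hr2a`` ...), with regions closer
    than ``group_window`` sharing a number.
    """
    if not core_motifs:
        raise ValueError("core_motifs must be non-empty")
    if window <= 0:
        raise ValueError("window must be > 0")
    L = len(genome)
    per_hit: list[tuple[int, str]] = []  # (position, motif)
    motif_len = {m: len(m) for m in core_motifs}
    for m in core_motifs:
        for p, _ in find_motif_positions(genome, m, "both", max_mismatch, True):
            per_hit.append((p, m))
    if not per_hit:
        return []
    per_hit.sort()
    clusters: list[list[tuple[int, str]]] = [[per_hit[0]]]
    for hit in per_hit[1:]:
        if hit[0] - clusters[-1][-1][0] <= window:
            clusters[-1].append(hit)
        else:
            clusters.append([hit])
    # circular wrap: join the first cluster onto the last across the origin,
    # shifting its positions by +L so the merged span is unwrapped
    if genome.circular and len(clusters) > 1:
        gap = clusters[0][0][0] + L - clusters[-1][-1][0]
        if gap <= window:
            first = clusters.pop(0)
            clusters[-1].extend((p + L, m) for p, m in first)

    regions: list[RepeatRegion] = []
    for cl in clusters:
        if len(cl) < min_hits:
            continue
        positions = [p for p, _ in cl]
        start = min(positions)
        end = max(p + motif_len[m] for p, m in cl)
        counts: dict[str, int] = defaultdict(int)
        for _, m in cl:
            counts[m] += 1
        regions.append(
            RepeatRegion(
                Feature(genome.id, start, end, "+", kind="repeat_region"),
                kind="hr",
                member_repeats=[],
                core_motifs=[(m, counts[m]) for m in core_motifs if counts[m]],
                n_hits=len(cl),
            )
        )
    regions.sort(key=lambda r: r.span.start)
    # positional naming grouped by inter-region distance
    group, letter = 0, 0
    prev_end = None
    for r in regions:
        if prev_end is None or r.span.start - prev_end > group_window:
            group += 1
            letter = 0
        r.name = f"hr{group}{chr(ord('a') + letter)}"
        letter += 1
        prev_end = r.span.end
    # single-member groups drop the letter suffix
    sizes = Counter(n[:-1] for n in [r.name for r in regions])
    for r in regions:
        if sizes[r.name[:-1]] == 1:
            r.name = r.name[:-1]
    return regions


# ---------------------------------------------------------------------------
# Pairwise identity
# ---------------------------------------------------------------------------


def pairwise_identity(seq_a: str, seq_b: str, match: float = 1,
                      mismatch: float = -1, gap_open: float = -2,
                      gap_extend: float = -1) -> float:
    """Global-alignment percent identity: 100 x matches / alignment columns."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    counts = aln.counts()
    columns = aln.length
    return round(100.0 * counts.identities / columns, 1)
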