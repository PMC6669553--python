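"""Six-frame ORF discovery on circular genomes under a liberal overlap rule.

Baculovirus genome reports conventionally annotate every ATG-initiated open
reading frame of at least 50 codons, then thin the candidate set with an
overlap criterion.  The liberal variant implemented here discards a candidate
only when it overlaps an already-retained (longer) ORF by at least half of
its *own* length, which keeps short genes nested against the flanks of long
ones — the convention under which unique short genes are discoverable at all.

Circular genomes are scanned on a doubled sequence so origin-spanning ORFs
are found exactly once; candidates are deduplicated by start position modulo
the genome length and strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

from .genome_io import CircularGenome, Feature, reverse_complement

_TABLE = unambiguous_dna_by_id[1]
_STOPS = frozenset(_TABLE.stop_codons)  # TAA, TAG, TGA


class TranslationError(ValueError):
    pass


def translate(cds_sequence: str) -> str:
    """Translate a CDS with the standard code; trailing stop dropped.

    Raises :class:`TranslationError` on non-triplet length or an internal
    stop codon.  ``N``-containing codons are not accepted.
    """
    seq = cds_sequence.upper()
    if len(seq) % 3 != 0:
        raise TranslationError(f"CDS length {len(seq)} is not a multiple of 3")
    if "N" in seq:
        raise TranslationError("CDS contains N")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons and codons[-1] in _STOPS:
        codons = codons[:-1]
    protein = []
    for i, codon in enumerate(codons):
        if codon in _STOPS:
            raise TranslationError(f"internal stop codon at codon {i + 1}")
        protein.append(_TABLE.forward_table[codon])
    return "".join(protein)


def translate_codon(codon: str) -> str:
    """Single-codon translation; stops give ``*``."""
    codon = codon.upper()
    if codon in _STOPS:
        return "*"
    return _TABLE.forward_table[codon]


@dataclass
class OrfCandidate:
    """An ATG-initiated reading frame on the genome.

    Coordinates follow :class:`~baculoscan.genome_io.Feature` conventions:
    0-based half-open, unwrapped (``end`` may exceed L for origin-spanning
    ORFs), and the span *includes* the stop codon, so
    ``length_codons = span/3 - 1``.
    """

    genome_id: str
    start: int
    end: int
    strand: str
    frame: int
    length_codons: int
    protein: str

    @property
    def span(self) -> int:
        return self.end - self.start

    def to_feature(self, label: str = "") -> Feature:
        return Feature(self.genome_id, self.start, self.end, self.strand,
                       kind="CDS", label=label)


@dataclass
class AnnotatedOrf:
    """An :class:`OrfCandidate` with a homology verdict."""

    orf: OrfCandidate
    label: str = "unique"
    best_score: float = 0.0
    core_gene: bool = False


def _scan_strand(seq: str, L: int, circular: bool, strand: str, min_aa: int,
                 genome_id: str) -> list[OrfCandidate]:
    """Scan the three frames of one strand given its 5'->3' sequence."""
    work = seq + seq if circular else seq
    n = len(work)
    out = []
    for frame in range(3):
        atg: int | None = None
        # On a circular genome the scan start is not a real segment boundary:
        # the segment may extend back across the origin, so ATGs seen before
        # the first stop could be internal, not 5'-most.  Such segments are
        # re-encountered with their true upstream stop in the doubled copy.
        stop_seen = not circular
        i = frame
        while i + 3 <= n:
            codon = work[i : i + 3]
            if codon in _STOPS:
                if atg is not None:
                    ncod = (i - atg) // 3
                    if ncod >= min_aa:
                        s, e = atg, i + 3
                        if e - s <= L:
                            cds = work[s:e]
                            if "N" not in cds:
                                out.append((s, e, frame, ncod, cds))
                    atg = None
                stop_seen = True
            elif atg is None and stop_seen and codon == "ATG":
                atg = i
            i += 3
    # map to genome-forward coordinates
    cands = []
    for s, e, frame, ncod, cds in out:
        if strand == "+":
            start, end = s, e
        else:
            # position p on the reverse strand maps to L-1-p forward (mod L)
            start = (2 * L - e) % L if circular else L - e
            end = start + (e - s)
        cands.append(
            OrfCandidate(genome_id, start % L if circular else start, 0, strand,
                         frame, ncod, translate(cds))
        )
        cands[-1].end = cands[-1].start + (e - s)
    return cands


def scan_orfs(genome: CircularGenome, min_aa: int = 50) -> list[OrfCandidate]:
    """All maximal ATG->stop ORFs of at least ``min_aa`` codons, six frames.

    Within a stop-to-stop frame segment only the 5'-most ATG defines the
    ORF; the stop codon is included in the span but not in ``length_codons``.
    ORFs with an ``N`` anywhere in the coding span are dropped.  On circular
    genomes origin-spanning ORFs are found via a doubled-sequence scan and
    reported once, with ``end > L``.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    L = len(genome)
    if L < 3 * (min_aa + 1):
        return []
    fwd = _scan_strand(genome.sequence, L, genome.circular, "+", min_aa, genome.id)
    rev = _scan_strand(reverse_complement(genome.sequence), L, genome.circular,
                       "-", min_aa, genome.id)
    seen: set[tuple[int, str]] = set()
    result = []
    for c in fwd + rev:
        key = (c.start % L, c.strand)
        if key in seen:
            continue
        seen.add(key)
        result.append(c)
    result.sort(key=lambda c: (c.start, c.end, c.strand))
    return result


def _circle_overlap(a: OrfCandidate | Feature, b: OrfCandidate | Feature,
                    L: int) -> int:
    """Overlap in nt of two (possibly wrapped) spans on a circle of size L."""

    def segs(x):
        if x.end <= L:
            return [(x.start, x.end)]
        return [(x.start, L), (0, x.end - L)]

    total = 0
    for sa, ea in segs(a):
        for sb, eb in segs(b):
            total += max(0, min(ea, eb) - max(sa, sb))
    return total


def filter_overlaps(candidates: list[OrfCandidate], max_fraction: float = 0.5,
                    genome_length: int | None = None) -> list[OrfCandidate]:
    """Greedy longest-first retention under the liberal overlap criterion.

    A candidate is discarded iff, for some already-retained ORF, the wrapped
    overlap divided by the candidate's *own* length reaches ``max_fraction``.
    Ties in length break by smaller start, then ``+`` strand first.  Overlap
    is computed on genome coordinates irrespective of strand.
    """
    if not candidates:
        return []
    L = genome_length
    if L is None:
        L = max(c.end for c in candidates)  # linear fallback: no wrapping
    order = sorted(candidates, key=lambda c: (-c.span, c.start, c.strand))
    retained: list[OrfCandidate] = []
    for c in order:
        ok = True
        for r in retained:
            if _circle_overlap(c, r, L) / c.span >= max_fraction:
                ok = False
                break
        if ok:
            retained.append(c)
    retained.sort(key=lambda c: (c.start, c.end, c.strand))
    return retained


def _protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def label_homologs(orfs: list[OrfCandidate], reference_proteomes: dict[str, str],
                   min_score: float = 100.0,
                   core_gene_names: set[str] | None = None) -> list[AnnotatedOrf]:
    """Label each ORF with its best-scoring reference protein, or ``unique``.

    ``reference_proteomes`` maps reference names to protein sequences.
    ``core_gene`` is set when the winning reference name is in
    ``core_gene_names``.
    """
    core_gene_names = core_gene_names or set()
    if not reference_proteomes:
        warnings.warn("empty reference set: all ORFs labeled 'unique'")
        return [AnnotatedOrf(o) for o in orfs]
    aligner = _protein_aligner()
    annotated = []
    for orf in orfs:
        best_name, best_score = None, float("-inf")
        for name, ref in reference_proteomes.items():
            score = aligner.score(orf.protein, ref)
            if score > best_score:
                best_name, best_score = name, score
        if best_score >= min_score:
            annotated.append(
                AnnotatedOrf(orf, best_name, float(best_score),
                             best_name in core_gene_names)
            )
        else:
            annotated.append(AnnotatedOrf(orf, "unique", float(best_score), False))
    return annotated
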