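"""Seeded generators of synthetic circular genomes with known ground truth.

The raw material of a baculovirus genome report — the assembled genome and
the read-level variant calls — is not something a test suite can download.
These generators produce inputs with the same statistical structure instead:
a circular ~120 kb genome at ~51% G+C carrying planted ATG-initiated ORFs
(including origin-spanning ones), hr loci built from short core motifs
repeated with small divergence, tandem direct repeats, SNVs with known
synonymous/non-synonymous truth at intermediate population frequencies, and
marker-gene pairs diverged under the K2P substitution process at a known
distance.  Every generator is driven by a single integer seed through one
`numpy` Generator, so identical seeds give byte-identical output.

The default design (:func:`dijunpv_like_design`) mirrors the architecture
of a sequenced nymphalid-host alphabaculovirus genome: 122,075 bp, G+C
0.509, 153 ORFs, five hr loci sharing a 12-nt core motif, one 10-nt-unit
and one 68-nt-unit direct repeat.  The default variant set mirrors the
published population structure: 203 SNVs of which 180 are coding (92
synonymous, 88 non-synonymous) at frequency 0.38 +/- 0.046.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genome_io import CircularGenome, Feature, reverse_complement
from .orf_annotation import OrfCandidate, scan_orfs, translate, translate_codon
from .species_demarcation import AlignedPair
from .variant_analysis import VariantRecord

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")
_SENSE_NO_ATG = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS and a + b + c != "ATG"
]
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


# ---------------------------------------------------------------------------
# Designs
# ---------------------------------------------------------------------------


@dataclass
class OrfDesign:
    length_codons: int
    strand: str = "+"
    placement: int | str = "auto"  # genome start, "auto", or "origin"


@dataclass
class HrDesign:
    core_motif: str
    copies: int = 8
    divergence: float = 0.05  # per-base substitution probability per copy
    window: int = 1000
    placement: int | str = "auto"


@dataclass
class DrDesign:
    unit_length: int = 68
    copies: int = 4
    divergence: float = 0.0  # substituted fraction of the whole array
    placement: int | str = "auto"


@dataclass
class GenomeDesign:
    length: int = 122075
    gc: float = 0.509
    orfs: list[OrfDesign] = field(default_factory=list)
    hr_designs: list[HrDesign] = field(default_factory=list)
    dr_designs: list[DrDesign] = field(default_factory=list)
    seed: int = 0
    genome_id: str = "synthetic_genome"
    min_gap: int = 20
    max_gap: int = 150
    sterilize_min_aa: int | None = 50  # break chance background ORFs >= this


def dijunpv_like_design(seed: int = 0, n_orfs: int = 153,
                        length: int = 122075) -> GenomeDesign:
    """A design mirroring the architecture of a ~122 kb alphabaculovirus.

    153 ORFs (one origin-spanning), five hr loci sharing one 12-nt core
    motif, a 10-nt-unit direct repeat of 12 copies and a 68-nt-unit direct
    repeat of 4 copies carrying one substitution.
    """
    rng = np.random.default_rng(seed)
    lengths = np.clip(50 + rng.exponential(scale=150, size=n_orfs), 50, 1100)
    lengths = lengths.astype(int)
    # budget the coding fraction so ORFs + repeat loci + inter-block gaps
    # always fit, with a 4% slack of trailing background
    n_repeats = 7  # 5 hrs + 2 drs below
    repeat_nt = 5 * 1000 + (10 * 12 + 68 * 4)
    gap_nt = (n_orfs + n_repeats) * 150
    budget = (length - repeat_nt - gap_nt - int(0.04 * length)) // 3 - 2 * n_orfs
    if budget < 50 * n_orfs:
        raise DesignError(
            f"genome of {length} nt cannot hold {n_orfs} ORFs of >= 50 codons "
            "alongside the default repeat loci"
        )
    while lengths.sum() > budget:
        lengths[np.argmax(lengths)] = max(50, int(lengths.max() * 0.7))
    strands = rng.choice(["+", "-"], size=n_orfs)
    orfs = [OrfDesign(int(l), s) for l, s in zip(lengths, strands)]
    if orfs:
        orfs[0] = OrfDesign(orfs[0].length_codons, orfs[0].strand, "origin")
    motif = "TTTTTAGCGATG"
    hrs = [HrDesign(motif, copies=8, divergence=0.05, window=1000)
           for _ in range(5)]
    drs = [
        DrDesign(unit_length=10, copies=12, divergence=0.0),
        DrDesign(unit_length=68, copies=4, divergence=1.0 / (68 * 4)),
    ]
    return GenomeDesign(length=length, gc=0.509, orfs=orfs, hr_designs=hrs,
                        dr_designs=drs, seed=seed)


# ---------------------------------------------------------------------------
# Truth bookkeeping
# ---------------------------------------------------------------------------


@dataclass
class PlantedOrf:
    start: int
    end: int  # unwrapped; may exceed L
    strand: str
    length_codons: int
    protein: str


@dataclass
class PlantedRepeat:
    start: int
    end: int
    kind: str  # "hr" or "dr"
    motif_or_unit: str
    copies: float
    unit_length: int = 0


@dataclass
class PlantedVariant:
    record: VariantRecord
    effect: str  # synonymous | non_synonymous | intergenic


@dataclass
class TruthSet:
    orfs: list[PlantedOrf] = field(default_factory=list)
    hrs: list[PlantedRepeat] = field(default_factory=list)
    drs: list[PlantedRepeat] = field(default_factory=list)
    variants: list[PlantedVariant] = field(default_factory=list)
    # chance ORFs that could not be disrupted without touching a planted
    # feature, as (start, strand, unwrapped end)
    residual_background_orfs: list[tuple[int, str, int]] = field(
        default_factory=list)


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------


def _random_orf_nt(rng: np.random.Generator, length_codons: int) -> str:
    body = rng.choice(_SENSE_NO_ATG, size=length_codons - 1)
    stop = _STOPS[rng.integers(0, 3)]
    return "ATG" + "".join(body) + stop


def _mutate(rng: np.random.Generator, seq: str, per_base_p: float) -> str:
    out = list(seq)
    for i, b in enumerate(out):
        if rng.random() < per_base_p:
            out[i] = rng.choice([x for x in "ACGT" if x != b])
    return "".join(out)


def _hr_block(rng: np.random.Generator, hr: HrDesign) -> tuple[str, int]:
    """Build one hr locus; returns (block sequence, n planted motif copies)."""
    m = len(hr.core_motif)
    spacer_budget = max(hr.window - hr.copies * m, hr.copies * 10)
    max_spacer = max(11, spacer_budget // max(1, hr.copies - 1))
    parts = []
    for i in range(hr.copies):
        parts.append(_mutate(rng, hr.core_motif, hr.divergence))
        if i < hr.copies - 1:
            parts.append(_background(rng, int(rng.integers(10, max_spacer)), 0.5))
    return "".join(parts), hr.copies


def _dr_block(rng: np.random.Generator, dr: DrDesign) -> tuple[str, str]:
    unit = _background(rng, dr.unit_length, 0.5)
    array = list(unit * dr.copies)
    n_subs = int(round(dr.divergence * dr.unit_length * dr.copies))
    if n_subs:
        for pos in rng.choice(len(array), size=n_subs, replace=False):
            array[pos] = rng.choice([x for x in "ACGT" if x != array[pos]])
    return "".join(array), unit


def _background(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(_BASES, size=n, p=p))


def _segments(start: int, end: int, L: int) -> list[tuple[int, int]]:
    if end <= L:
        return [(start, end)]
    return [(start, L), (0, end - L)]


def _overlaps(a: tuple[int, int], b: tuple[int, int], L: int) -> bool:
    return any(
        min(ea, eb) > max(sa, sb)
        for sa, ea in _segments(*a, L)
        for sb, eb in _segments(*b, L)
    )


class DesignError(ValueError):
    pass


def simulate_genome(design: GenomeDesign) -> tuple[CircularGenome, TruthSet]:
    """Build a circular genome from a design, with an exact truth set.

    Background bases are i.i.d. at the target G+C.  Planted ORFs are ATG +
    random non-stop, non-ATG codons + stop; hr loci are diverged copies of
    the core motif with random spacers inside the window; drs are tandem
    unit arrays with the requested substituted fraction.  Chance background
    ORFs of at least ``sterilize_min_aa`` codons are disrupted by writing a
    stop codon where this does not touch any planted feature; the few that
    cannot be disrupted are listed in the truth set.
    """
    rng = np.random.default_rng(design.seed)
    L = design.length
    seq = list(_background(rng, L, design.gc))
    truth = TruthSet()
    occupied: list[tuple[int, int]] = []
    cursor = 0  # linear packing frontier for "auto" placements

    def place(block: str, placement: int | str) -> int:
        nonlocal cursor
        span = len(block)
        if span >= L:
            raise DesignError(f"block of {span} nt does not fit genome of {L} nt")
        if placement == "origin":
            start = L - span // 2
        elif placement == "auto":
            start = cursor + int(rng.integers(design.min_gap, design.max_gap))
            if start + span > L:
                raise DesignError(
                    f"design does not fit: block of {span} nt would start at "
                    f"{start} on a genome of {L} nt"
                )
        else:
            start = int(placement)
        cand = (start, start + span)
        for occ in occupied:
            if _overlaps(cand, occ, L):
                raise DesignError(
                    f"planted block at [{cand[0]}, {cand[1]}) collides with "
                    f"an existing block at [{occ[0]}, {occ[1]})"
                )
        for i, b in enumerate(block):
            seq[(start + i) % L] = b
        occupied.append(cand)
        if placement == "origin":
            cursor = max(cursor, (start + span) % L)
        elif placement == "auto":
            cursor = start + span
        else:
            cursor = max(cursor, min(start + span, L))
        return start

    # Plan the placement order: origin-spanning blocks first (so "auto"
    # packing starts after the origin), then ORFs with the repeat loci
    # interleaved at even intervals so hrs end up spread along the genome,
    # as they are in real genomes, rather than packed side by side.
    orf_plan = sorted(
        [("orf", od) for od in design.orfs],
        key=lambda t: 0 if t[1].placement == "origin" else 1,
    )
    repeat_plan = ([("hr", h) for h in design.hr_designs]
                   + [("dr", d) for d in design.dr_designs])
    plan: list[tuple[str, object]] = []
    if repeat_plan:
        step = max(1, len(orf_plan) // (len(repeat_plan) + 1))
    else:
        step = len(orf_plan) + 1
    r = 0
    for i, item in enumerate(orf_plan):
        plan.append(item)
        if r < len(repeat_plan) and (i + 1) % step == 0:
            plan.append(repeat_plan[r])
            r += 1
    plan.extend(repeat_plan[r:])

    for kind, d in plan:
        if kind == "orf":
            od = d
            nt = _random_orf_nt(rng, od.length_codons)
            # an in-frame stop immediately upstream of the ATG guarantees
            # the planted ATG is the 5'-most of its stop-to-stop segment
            if od.strand == "+":
                ins = "TAA" + nt
                offset = 3
            else:
                ins = reverse_complement("TAA" + nt)
                offset = 0
            start = place(ins, od.placement)
            orf_start = (start + offset) % L
            truth.orfs.append(
                PlantedOrf(orf_start, orf_start + len(nt), od.strand,
                           od.length_codons, translate(nt))
            )
        elif kind == "hr":
            block, copies = _hr_block(rng, d)
            start = place(block, d.placement)
            truth.hrs.append(
                PlantedRepeat(start, start + len(block), "hr", d.core_motif,
                              copies, len(d.core_motif))
            )
        else:
            block, unit = _dr_block(rng, d)
            start = place(block, d.placement)
            truth.drs.append(
                PlantedRepeat(start, start + len(block), "dr", unit, d.copies,
                              d.unit_length)
            )

    genome = CircularGenome(design.genome_id, "".join(seq), "circular")
    if design.sterilize_min_aa is not None:
        genome = _sterilize(genome, truth, occupied, design.sterilize_min_aa, rng)
    truth.orfs.sort(key=lambda o: o.start)
    return genome, truth


def _sterilize(genome: CircularGenome, truth: TruthSet,
               occupied: list[tuple[int, int]], min_aa: int,
               rng: np.random.Generator) -> CircularGenome:
    """Disrupt chance background ORFs by writing stop codons outside blocks."""
    L = len(genome)
    planted_keys = {(o.start % L, o.strand) for o in truth.orfs}

    occ_mask = np.zeros(L, dtype=bool)
    for a, b in occupied:
        for s, e in _segments(a, b, L):
            occ_mask[s:e] = True

    def free(pos: int) -> bool:
        return not occ_mask[pos % L]

    seq = list(genome.sequence)
    for _ in range(20):
        current = CircularGenome(genome.id, "".join(seq), "circular")
        extras = [
            o for o in scan_orfs(current, min_aa)
            if (o.start % L, o.strand) not in planted_keys
        ]
        if not extras:
            break
        changed = False
        for orf in extras:
            # write a stop as early as possible so the truncated 5' part
            # falls below min_aa; try successive codons until one is free
            for ci in range(1, orf.length_codons):
                if orf.strand == "+":
                    p0 = (orf.start + 3 * ci) % L
                    ps = [(p0 + k) % L for k in range(3)]
                    stop = "TAA"
                else:
                    p_end = (orf.end - 3 * ci) % L
                    ps = [(p_end - 3 + k) % L for k in range(3)]
                    stop = reverse_complement("TAA")
                if all(free(p) for p in ps):
                    for p, b in zip(ps, stop):
                        seq[p] = b
                    changed = True
                    break
        if not changed:
            break
    final = CircularGenome(genome.id, "".join(seq), "circular")
    residual = [
        (o.start % L, o.strand, o.start % L + o.span)
        for o in scan_orfs(final, min_aa)
        if (o.start % L, o.strand) not in planted_keys
    ]
    truth.residual_background_orfs = residual
    return final


# ---------------------------------------------------------------------------
# Marker-gene divergence under K2P
# ---------------------------------------------------------------------------


def simulate_divergence(sequence: str, true_d: float, kappa: float = 2.0,
                        seed: int = 0) -> AlignedPair:
    """Diverge a sequence from itself under the K2P process at distance d.

    Per-site substitution probabilities are the exact K2P transition
    functions at branch length ``true_d`` with transition:transversion rate
    ratio ``kappa``; no indels are introduced, so the pair is returned
    already aligned.
    """
    if true_d < 0:
        raise ValueError("true_d must be >= 0")
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    rng = np.random.default_rng(seed)
    bt = true_d / (kappa + 2.0)  # beta * t
    at = kappa * bt  # alpha * t
    p_ts = 0.25 + 0.25 * math.exp(-4.0 * bt) - 0.5 * math.exp(-2.0 * (at + bt))
    p_tv = 0.5 - 0.5 * math.exp(-4.0 * bt)  # both transversions together
    seq = sequence.upper()
    transition = {"A": "G", "G": "A", "C": "T", "T": "C"}
    transversions = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
    out = []
    u = rng.random(len(seq))
    pick = rng.integers(0, 2, size=len(seq))
    for i, b in enumerate(seq):
        if b not in "ACGT":
            out.append(b)
        elif u[i] < p_ts:
            out.append(transition[b])
        elif u[i] < p_ts + p_tv:
            out.append(transversions[b][pick[i]])
        else:
            out.append(b)
    return AlignedPair(seq, "".join(out))


# ---------------------------------------------------------------------------
# Variant simulation
# ---------------------------------------------------------------------------


def _codon_of(genome: CircularGenome, orf: PlantedOrf, codon_index: int) -> str:
    cds = genome.subsequence(orf.start, orf.end)
    if orf.strand == "-":
        cds = reverse_complement(cds)
    return cds[3 * (codon_index - 1) : 3 * codon_index]


def _genome_position(orf: PlantedOrf, codon_index: int, codon_pos: int,
                     L: int) -> int:
    idx = 3 * (codon_index - 1) + (codon_pos - 1)
    if orf.strand == "+":
        return (orf.start + idx) % L
    return (orf.end - 1 - idx) % L


def simulate_variants(genome: CircularGenome, truth_orfs: list[PlantedOrf],
                      n: int = 203, frac_coding: float = 180 / 203,
                      frac_syn: float = 92 / 180, freq_mean: float = 0.38,
                      freq_sd: float = 0.046, seed: int = 0,
                      freq_dist: str = "normal", max_retries: int = 2000,
                      exclude_spans: list[tuple[int, int]] | None = None
                      ) -> tuple[list[VariantRecord], list[PlantedVariant]]:
    """Plant SNVs with a known coding/synonymous composition.

    Synonymity is enforced by codon-aware alternative-base choice; positions
    covered by more than one planted ORF are avoided so each truth effect is
    unambiguous, and positions inside ``exclude_spans`` (e.g. residual
    chance ORFs an annotation run would also report) are never used.
    Frequencies are drawn from a normal clipped to (0.01, 0.99) (or a
    moment-matched beta with ``freq_dist="beta"``).
    """
    rng = np.random.default_rng(seed)
    L = len(genome)
    n_coding = int(round(n * frac_coding))
    n_syn = int(round(n_coding * frac_syn))
    n_nonsyn = n_coding - n_syn
    n_inter = n - n_coding

    cover = np.zeros(L, dtype=np.int16)
    for o in truth_orfs:
        for s, e in _segments(o.start, o.end, L):
            cover[s:e] += 1
    excluded = np.zeros(L, dtype=bool)
    for a, b in exclude_spans or []:
        for s, e in _segments(a, b, L):
            excluded[s:e] = True
    intergenic_pool = np.flatnonzero((cover == 0) & ~excluded)
    if n_inter > len(intergenic_pool):
        raise ValueError("not enough intergenic positions for the request")

    used: set[int] = set()
    records: list[VariantRecord] = []
    planted: list[PlantedVariant] = []

    def draw_freq() -> float:
        if freq_dist == "beta":
            m, v = freq_mean, freq_sd**2
            common = m * (1 - m) / v - 1
            return float(np.clip(rng.beta(m * common, (1 - m) * common),
                                 0.01, 0.99))
        return float(np.clip(rng.normal(freq_mean, freq_sd), 0.01, 0.99))

    weights = np.array([o.length_codons for o in truth_orfs], dtype=float)
    weights /= weights.sum()

    def plant_coding(effect: str) -> None:
        for _ in range(max_retries):
            orf = truth_orfs[rng.choice(len(truth_orfs), p=weights)]
            ci = int(rng.integers(1, orf.length_codons + 1))  # skip stop codon
            codon = _codon_of(genome, orf, ci)
            options = []
            for cp in (1, 2, 3):
                for alt in "ACGT":
                    if alt == codon[cp - 1]:
                        continue
                    alt_codon = codon[: cp - 1] + alt + codon[cp:]
                    if translate_codon(alt_codon) == "*":
                        is_syn = False
                    else:
                        is_syn = translate_codon(alt_codon) == translate_codon(codon)
                    if (effect == "synonymous") == is_syn:
                        options.append((cp, alt))
            if not options:
                continue
            cp, alt = options[rng.integers(0, len(options))]
            pos = _genome_position(orf, ci, cp, L)
            if pos in used or cover[pos] != 1 or excluded[pos]:
                continue
            used.add(pos)
            ref_fwd = genome.base(pos)
            alt_fwd = alt if orf.strand == "+" else _COMP[alt]
            rec = VariantRecord(pos, ref_fwd, alt_fwd, draw_freq(),
                                depth=int(rng.integers(50, 300)))
            records.append(rec)
            planted.append(PlantedVariant(rec, effect))
            return
        raise RuntimeError(f"could not place a {effect} variant "
                           f"after {max_retries} retries")

    for _ in range(n_syn):
        plant_coding("synonymous")
    for _ in range(n_nonsyn):
        plant_coding("non_synonymous")
    for _ in range(n_inter):
        for _ in range(max_retries):
            pos = int(intergenic_pool[rng.integers(0, len(intergenic_pool))])
            if pos in used:
                continue
            used.add(pos)
            ref = genome.base(pos)
            alt = rng.choice([b for b in "ACGT" if b != ref])
            rec = VariantRecord(pos, ref, str(alt), draw_freq(),
                                depth=int(rng.integers(50, 300)))
            records.append(rec)
            planted.append(PlantedVariant(rec, "intergenic"))
            break
        else:
            raise RuntimeError("could not place an intergenic variant")

    order = np.argsort([r.position for r in records])
    return ([records[i] for i in order], [planted[i] for i in order])


def write_variants_vcf(records: list[VariantRecord], genome_id: str,
                       genome_length: int, path) -> None:
    """Write SNVs as a minimal VCF 4.2 with INFO AF/DP."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={genome_id},length={genome_length}>\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description='
                 '"Allele Frequency">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description='
                 '"Total Depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in records:
            fh.write(
                f"{genome_id}\t{r.position + 1}\t.\t{r.ref}\t{r.alt}\t.\t.\t"
                f"AF={r.frequency:.4f};DP={r.depth}\n"
            )


# ---------------------------------------------------------------------------
# Synthetic proteome families for ortholog tests
# ---------------------------------------------------------------------------

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def _random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_AA, size=n))


def _perturb_protein(rng: np.random.Generator, seq: str, divergence: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < divergence:
            out[i] = str(rng.choice(_AA))
    return "".join(out)


def simulate_proteome_family(genome_ids: list[str],
                             design: dict[frozenset, int],
                             divergence: float = 0.1,
                             mean_length: int = 250,
                             seed: int = 0):
    """Proteomes with a planted gene-content design.

    ``design`` maps each genome subset to the number of ortholog families
    present in exactly that subset.  Family members are ``divergence``-
    perturbed copies of a random ancestor protein, so reciprocal best hits
    recover the design.  Returns ``(proteomes, expected_counts)`` where
    proteomes maps genome id to a list of
    :class:`~baculoscan.ortholog_comparison.ProteinRecord`.
    """
    from .ortholog_comparison import ProteinRecord

    rng = np.random.default_rng(seed)
    proteomes: dict[str, list[ProteinRecord]] = {g: [] for g in genome_ids}
    fam = 0
    for subset, count in design.items():
        for _ in range(count):
            fam += 1
            n = int(rng.integers(int(0.6 * mean_length), int(1.4 * mean_length)))
            ancestor = _random_protein(rng, n)
            for g in sorted(subset):
                proteomes[g].append(
                    ProteinRecord(g, f"fam{fam:03d}",
                                  _perturb_protein(rng, ancestor, divergence))
                )
    return proteomes, dict(design)
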