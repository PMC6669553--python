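"""SNV effect classification and frequency summaries.

Field isolates of baculoviruses are virus *populations*: deep sequencing of
one occlusion-body preparation typically reveals hundreds of intrapopulation
single-nucleotide variants segregating at intermediate frequencies.  This
module joins each SNV to its codon context in the retained ORF annotation
and classifies it as synonymous, non-synonymous, or intergenic, then
summarizes counts and read frequencies.

Variants that fall inside two retained ORFs (possible under the liberal
overlap criterion) are classified against every covering ORF; the primary
effect is taken from the longest one.  Stop-gain/stop-loss changes are
folded into the non-synonymous class.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .genome_io import CircularGenome, GenomeIOError, reverse_complement
from .orf_annotation import OrfCandidate, translate_codon

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class VariantRecord:
    """One SNV: 0-based genome position, alleles, population frequency."""

    position: int
    ref: str
    alt: str
    frequency: float
    depth: int = 0

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"position {self.position}: ref == alt ({self.ref})")
        for b in (self.ref, self.alt):
            if b not in "ACGT" or len(b) != 1:
                raise ValueError(f"position {self.position}: bad allele {b!r}")
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError(f"position {self.position}: frequency outside [0,1]")


@dataclass
class VariantEffect:
    """An SNV joined to codon context and its coding verdict."""

    variant: VariantRecord
    gene_label: str = "intergenic"
    codon_index: int | None = None  # 1-based
    codon_position: int | None = None  # 1..3
    ref_codon: str | None = None
    alt_codon: str | None = None
    effect: str = "intergenic"  # synonymous | non_synonymous | intergenic
    secondary: list["VariantEffect"] = field(default_factory=list)


@dataclass
class VariantSummary:
    n_total: int = 0
    n_coding: int = 0
    n_synonymous: int = 0
    n_non_synonymous: int = 0
    n_intergenic: int = 0
    mean_frequency: float | None = None  # percent, over coding variants
    sd_frequency: float | None = None
    mean_frequency_all: float | None = None  # percent, over all variants
    sd_frequency_all: float | None = None


def _covering_orfs(position: int, orfs: list[OrfCandidate], L: int
                   ) -> list[OrfCandidate]:
    out = []
    for o in orfs:
        if (position - o.start) % L < o.span:
            out.append(o)
    return out


def _effect_in_orf(variant: VariantRecord, orf: OrfCandidate,
                   genome: CircularGenome) -> VariantEffect:
    L = len(genome)
    off_fwd = (variant.position - orf.start) % L
    if orf.strand == "+":
        idx = off_fwd
        ref_base, alt_base = variant.ref, variant.alt
    else:
        idx = orf.span - 1 - off_fwd
        ref_base, alt_base = _COMP[variant.ref], _COMP[variant.alt]
    codon_index = idx // 3 + 1
    codon_position = idx % 3 + 1
    cds = genome.subsequence(orf.start, orf.end)
    if orf.strand == "-":
        cds = reverse_complement(cds)
    ref_codon = cds[3 * (codon_index - 1) : 3 * codon_index]
    if ref_codon[codon_position - 1] != ref_base:
        raise GenomeIOError(
            f"position {variant.position}: ref allele {variant.ref} does not "
            f"match the genome base"
        )
    alt_codon = (ref_codon[: codon_position - 1] + alt_base
                 + ref_codon[codon_position:])
    effect = ("synonymous"
              if translate_codon(ref_codon) == translate_codon(alt_codon)
              else "non_synonymous")
    return VariantEffect(variant, _orf_label(orf), codon_index, codon_position,
                         ref_codon, alt_codon, effect)


def _orf_label(orf: OrfCandidate) -> str:
    return f"{orf.genome_id}:{orf.start}{orf.strand}"


def classify_variant(variant: VariantRecord, orfs: list[OrfCandidate],
                     genome: CircularGenome) -> VariantEffect:
    """Classify one SNV against the retained ORF annotation.

    The reference allele must match the genome base at the variant position
    (forward strand); minus-strand ORFs complement both alleles before the
    codon substitution.  When several retained ORFs cover the position the
    primary effect comes from the longest, with the rest in ``secondary``.
    A variant in a stop codon is coding (nonsense counts as non-synonymous).
    """
    L = len(genome)
    if genome.base(variant.position) != variant.ref:
        raise GenomeIOError(
            f"position {variant.position}: ref allele {variant.ref!r} does not "
            f"match genome base {genome.base(variant.position)!r}"
        )
    covering = _covering_orfs(variant.position % L, orfs, L)
    if not covering:
        return VariantEffect(variant)
    covering.sort(key=lambda o: (-o.span, o.start))
    effects = [_effect_in_orf(variant, o, genome) for o in covering]
    primary = effects[0]
    primary.secondary = effects[1:]
    return primary


def _mean_sd(values: list[float]) -> tuple[float | None, float | None]:
    if not values:
        return None, None
    mean = sum(values) / len(values)
    if len(values) < 2:
        return round(mean, 1), None
    var = sum((v - mean) ** 2 for v in values) / (len(values) - 1)
    return round(mean, 1), round(math.sqrt(var), 1)


def summarize_variants(effects: list[VariantEffect]) -> VariantSummary:
    """Counts plus mean and sample (n-1) SD of frequency, in percent.

    The headline mean/SD is over coding variants; ``*_all`` fields give the
    same over every variant, since reporting conventions differ.
    """
    s = VariantSummary(n_total=len(effects))
    coding_freqs, all_freqs = [], []
    for e in effects:
        all_freqs.append(100.0 * e.variant.frequency)
        if e.effect == "intergenic":
            s.n_intergenic += 1
        else:
            s.n_coding += 1
            coding_freqs.append(100.0 * e.variant.frequency)
            if e.effect == "synonymous":
                s.n_synonymous += 1
            else:
                s.n_non_synonymous += 1
    s.mean_frequency, s.sd_frequency = _mean_sd(coding_freqs)
    s.mean_frequency_all, s.sd_frequency_all = _mean_sd(all_freqs)
    return s


# ---------------------------------------------------------------------------
# Input
# ---------------------------------------------------------------------------


@dataclass
class VariantTable:
    """Parsed variant input plus a count of rejected indel rows."""

    records: list[VariantRecord]
    n_indels_skipped: int = 0

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


def read_variants(path, format: str = "auto", af_field: str = "AF") -> VariantTable:
    """Read SNVs from VCF or delimited text.

    VCF: coordinates become 0-based; multi-allelic rows are split; the
    allele frequency is taken from INFO ``af_field`` (one value per alt).
    Delimited text needs columns ``position`` (1-based), ``ref``, ``alt``,
    ``frequency`` and optionally ``depth``.  Indel rows are rejected with a
    counted warning — these genomes are reported SNV-only.
    """
    path = Path(path)
    if format == "auto":
        format = "vcf" if path.suffix.lower() == ".vcf" else "table"
    if format == "vcf":
        return _read_vcf(path, af_field)
    return _read_table(path)


def _read_vcf(path, af_field: str) -> VariantTable:
    import pysam

    records, skipped = [], 0
    with pysam.VariantFile(str(path)) as vf:
        for row in vf:
            if af_field not in row.info:
                raise GenomeIOError(
                    f"{path}: VCF row at POS {row.pos} lacks INFO/{af_field}"
                )
            afs = row.info[af_field]
            if not isinstance(afs, tuple):
                afs = (afs,)
            depth = int(row.info.get("DP", 0) or 0)
            for alt, af in zip(row.alts or (), afs):
                if len(row.ref) != 1 or len(alt) != 1 or alt == "*":
                    skipped += 1
                    continue
                records.append(
                    VariantRecord(row.pos - 1, row.ref.upper(), alt.upper(),
                                  float(af), depth)
                )
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} indel/non-SNV allele(s)")
    return VariantTable(records, skipped)


def _read_table(path) -> VariantTable:
    import pandas as pd

    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower(): c for c in df.columns}
    for need in ("position", "ref", "alt", "frequency"):
        if need not in cols:
            raise GenomeIOError(f"{path}: missing column {need!r}")
    records, skipped = [], 0
    for _, row in df.iterrows():
        ref, alt = str(row[cols["ref"]]).upper(), str(row[cols["alt"]]).upper()
        if len(ref) != 1 or len(alt) != 1:
            skipped += 1
            continue
        depth = int(row[cols["depth"]]) if "depth" in cols else 0
        records.append(
            VariantRecord(int(row[cols["position"]]) - 1, ref, alt,
                          float(row[cols["frequency"]]), depth)
        )
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} indel row(s)")
    return VariantTable(records, skipped)
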