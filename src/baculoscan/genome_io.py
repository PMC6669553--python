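"""Sequence and annotation data model plus readers/writers.

Baculovirus genomes are circular double-stranded DNA molecules of roughly
80–180 kb.  Everything downstream (ORF scanning, repeat discovery, variant
classification) needs coordinate arithmetic that is aware of the circular
topology, so the central type here, :class:`CircularGenome`, owns that
arithmetic.  Coordinates are 0-based half-open internally; the 1-based
inclusive convention of GenBank/GFF3 appears only at format boundaries.

Origin-spanning features are stored *unwrapped*: ``end`` may exceed the
genome length ``L`` (up to ``2L``), so that ``end - start`` is always the
true feature length.  They are wrapped into two-part locations only when
written out.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq

_VALID_BASES = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeIOError(ValueError):
    """Raised on malformed sequence or annotation input."""


@dataclass(frozen=True)
class CircularGenome:
    """A topology-aware nucleotide sequence.

    Parameters
    ----------
    id:
        Record identifier (e.g. a GenBank accession).
    sequence:
        DNA over ``{A, C, G, T, N}``; lowercase is folded to uppercase.
    topology:
        ``"circular"`` (default) or ``"linear"``.
    """

    id: str
    sequence: str
    topology: str = "circular"

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise GenomeIOError(f"record {self.id!r}: empty sequence")
        bad = set(seq) - _VALID_BASES
        if bad:
            raise GenomeIOError(
                f"record {self.id!r}: invalid characters {sorted(bad)!r} "
                "(alphabet is A/C/G/T/N)"
            )
        if self.topology not in ("circular", "linear"):
            raise GenomeIOError(f"record {self.id!r}: bad topology {self.topology!r}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def circular(self) -> bool:
        return self.topology == "circular"

    def base(self, position: int) -> str:
        """Base at ``position``; wraps modulo length on circular genomes."""
        L = len(self.sequence)
        if self.circular:
            return self.sequence[position % L]
        if not 0 <= position < L:
            raise IndexError(f"position {position} outside linear genome of {L} nt")
        return self.sequence[position]

    def subsequence(self, start: int, end: int) -> str:
        """Slice ``[start, end)``; ``end`` may exceed L on circular genomes.

        ``subsequence(p, p + L)`` is a rotation of the full genome.
        """
        L = len(self.sequence)
        if end < start:
            raise GenomeIOError(f"end {end} < start {start}")
        if not self.circular:
            if start < 0 or end > L:
                raise GenomeIOError(
                    f"span [{start}, {end}) outside linear genome of {L} nt"
                )
            return self.sequence[start:end]
        span = end - start
        if span > 2 * L:
            raise GenomeIOError(f"span of {span} nt exceeds twice the genome length")
        start %= L
        doubled = self.sequence + self.sequence
        return (doubled + self.sequence)[start : start + span]

    def rotate(self, offset: int) -> "CircularGenome":
        """Return the genome with its origin moved to ``offset`` (circular only)."""
        if not self.circular:
            raise GenomeIOError("cannot rotate a linear genome")
        L = len(self.sequence)
        offset %= L
        return CircularGenome(
            self.id, self.sequence[offset:] + self.sequence[:offset], self.topology
        )

    def reverse_complemented(self) -> "CircularGenome":
        return CircularGenome(self.id, reverse_complement(self.sequence), self.topology)


@dataclass
class Feature:
    """A located annotation on a genome.

    ``start`` is 0-based inclusive, ``end`` exclusive.  For origin-spanning
    features on a circular genome ``end`` may exceed the genome length (it
    is then interpreted modulo L), so ``end - start`` is always the span.
    """

    genome_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    kind: str = "CDS"
    label: str = ""
    qualifiers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GenomeIOError(f"bad strand {self.strand!r}")
        if self.end <= self.start:
            raise GenomeIOError(f"empty/inverted span [{self.start}, {self.end})")

    @property
    def span(self) -> int:
        return self.end - self.start

    def wraps(self, genome_length: int) -> bool:
        return self.end > genome_length

    def segments(self, genome_length: int) -> list[tuple[int, int]]:
        """The feature's coverage as 1 or 2 in-bounds half-open intervals."""
        if self.end <= genome_length:
            return [(self.start, self.end)]
        return [(self.start, genome_length), (0, self.end - genome_length)]

    def extract(self, genome: CircularGenome) -> str:
        """The feature's sequence, reverse-complemented for minus-strand."""
        s = genome.subsequence(self.start, self.end)
        return reverse_complement(s) if self.strand == "-" else s


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_fasta(path, topology: str = "circular") -> list[CircularGenome]:
    """Read a (multi-)FASTA file into :class:`CircularGenome` records."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise GenomeIOError(f"{path}: no FASTA records found")
    return [CircularGenome(r.id, str(r.seq), topology) for r in records]


def write_fasta(genomes: Iterable[CircularGenome], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.id}\n")
            for i in range(0, len(g.sequence), width):
                fh.write(g.sequence[i : i + width] + "\n")


def read_genbank(path, topology: str | None = None) -> tuple[CircularGenome, list[Feature]]:
    """Read a GenBank flat file: sequence plus CDS/repeat features.

    GenBank 1-based inclusive ``a..b`` becomes ``start=a-1, end=b``;
    ``complement(...)`` sets strand ``-``.  A ``join`` crossing the origin of
    a circular record is preserved as one unwrapped feature with ``end > L``.
    """
    record = SeqIO.read(str(path), "genbank")
    if len(record.seq) == 0:
        raise GenomeIOError(f"{path}: GenBank record has no ORIGIN sequence")
    if topology is None:
        topology = record.annotations.get("topology", "circular")
        if topology not in ("circular", "linear"):
            topology = "circular"
    genome = CircularGenome(record.id, str(record.seq), topology)
    L = len(genome)
    features: list[Feature] = []
    for feat in record.features:
        if feat.type in ("source",):
            continue
        loc = feat.location
        strand = "-" if loc.strand == -1 else "+"
        parts = sorted(
            [(int(p.start), int(p.end)) for p in loc.parts], key=lambda t: t[0]
        )
        if len(parts) == 1:
            start, end = parts[0]
        elif (
            len(parts) == 2
            and parts[1][1] == L
            and parts[0][0] == 0
            and genome.circular
        ):
            # origin-spanning join: (hi..L, 1..lo_end) -> unwrapped
            start, end = parts[1][0], L + parts[0][1]
        else:
            # multi-exon joins are rare in these genomes; take the hull
            start, end = parts[0][0], parts[-1][1]
        label = ""
        for key in ("gene", "locus_tag", "product", "note"):
            if key in feat.qualifiers:
                label = feat.qualifiers[key][0]
                break
        quals = {k: v[0] for k, v in feat.qualifiers.items() if v}
        features.append(
            Feature(genome.id, start, end, strand, kind=feat.type, label=label,
                    qualifiers=quals)
        )
    return genome, features


def gc_content(genome: CircularGenome) -> float:
    """G+C percentage to one decimal; N sites are excluded from the denominator."""
    seq = genome.sequence
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise GenomeIOError(f"record {genome.id!r}: all-N sequence, G+C undefined")
    return round(100.0 * (counts["G"] + counts["C"]) / denom, 1)


# -- GFF3 -------------------------------------------------------------------


def write_gff3(features: Iterable[Feature], path, genome_length: int | None = None) -> None:
    """Write features as GFF3.

    Wrapped (origin-spanning) features are emitted as two lines sharing one
    ``ID`` attribute, tiling the wrapped span.  Requires ``genome_length``
    when any feature wraps.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, f in enumerate(features):
            attrs = [f"ID=feat{i}"]
            if f.label:
                attrs.append(f"Name={f.label}")
            for k, v in f.qualifiers.items():
                if k == "Name":
                    continue
                attrs.append(f"{k}={v}")
            attr_s = ";".join(attrs)
            if genome_length is not None and f.end > genome_length:
                if f.start >= genome_length:
                    raise GenomeIOError(f"feature start {f.start} beyond genome end")
                segs = f.segments(genome_length)
            else:
                if genome_length is not None and f.end > genome_length:
                    raise GenomeIOError("feature outside genome length")
                segs = [(f.start, f.end)]
            for s, e in segs:
                fh.write(
                    "\t".join(
                        [
                            f.genome_id,
                            "baculoscan",
                            f.kind,
                            str(s + 1),
                            str(e),
                            ".",
                            f.strand,
                            ".",
                            attr_s,
                        ]
                    )
                    + "\n"
                )


def read_gff3(path, genome_length: int | None = None) -> list[Feature]:
    """Read GFF3 written by :func:`write_gff3`; re-joins two-part wrapped features."""
    by_id: dict[str, Feature] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise GenomeIOError(f"{path}: malformed GFF3 line: {line!r}")
            seqid, _, kind, start1, end1, _, strand, _, attr_s = cols
            attrs = dict(
                kv.split("=", 1) for kv in attr_s.split(";") if "=" in kv
            )
            fid = attrs.get("ID", f"anon{len(order)}")
            start, end = int(start1) - 1, int(end1)
            label = attrs.get("Name", "")
            quals = {k: v for k, v in attrs.items() if k not in ("ID", "Name")}
            if fid in by_id:
                prev = by_id[fid]
                if genome_length is None:
                    raise GenomeIOError(
                        f"{path}: two-part feature {fid} needs genome_length to re-join"
                    )
                # parts are (hi..L) and (0..lo); re-join unwrapped
                if start == 0:
                    joined = Feature(seqid, prev.start, genome_length + end, strand,
                                     kind, prev.label or label,
                                     prev.qualifiers or quals)
                else:
                    joined = Feature(seqid, start, genome_length + prev.end, strand,
                                     kind, label or prev.label,
                                     quals or prev.qualifiers)
                by_id[fid] = joined
            else:
                by_id[fid] = Feature(seqid, start, end, strand, kind, label, quals)
                order.append(fid)
    return [by_id[fid] for fid in order]


def write_table(rows: Iterable[dict], path) -> None:
    """Write a list of dict rows as CSV with a header."""
    rows = list(rows)
    if not rows:
        with open(path, "w") as fh:
            fh.write("")
        return
    fieldnames = list(rows[0].keys())
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        writer.writeheader()
        writer.writerows(rows)
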