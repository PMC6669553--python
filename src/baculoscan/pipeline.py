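"""End-to-end genome report: orchestrates every stage over plain-file I/O.

A single :func:`run_report` call turns a genome (FASTA or GenBank) into the
standard desk-scale report a genome announcement is built from: genome
stats (length, G+C), the retained ORF table with core/unique counts,
repeat regions and core-motif counts, and — when the corresponding inputs
are supplied — the variant summary, marker-gene species calls, and
multi-genome Venn counts.  All outputs are diffable text files (GFF3, CSV,
Newick, JSON) plus a resolved-config snapshot, so a rerun from the snapshot
reproduces the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import genome_io, orf_annotation, ortholog_comparison, repeat_discovery
from . import species_demarcation, variant_analysis

logger = logging.getLogger("baculoscan")

DEFAULT_CORE_MOTIFS = [
    "TTACGAGAACATT",
    "GTACTCGAAAA",
    "AAAATAGAACA",
    "TTTTTAGCGATG",
]


@dataclass
class PipelineConfig:
    genome: str = ""
    genome_format: str = "auto"  # fasta | genbank | auto
    topology: str = "circular"
    min_aa: int = 50
    max_overlap: float = 0.5
    refs: str | None = None  # reference proteome FASTA
    core_list: str | None = None  # file of core-gene reference names
    min_homology_score: float = 100.0
    core_motifs: list[str] = field(default_factory=lambda: list(DEFAULT_CORE_MOTIFS))
    hr_window: int = 2000
    hr_min_hits: int = 2
    dr_min_unit: int = 8
    dr_max_unit: int = 200
    dr_min_copies: float = 3
    dr_min_identity: float = 85.0
    variants: str | None = None  # VCF or table
    markers: str | None = None  # aligned marker-gene FASTA
    t_low: float = species_demarcation.T_LOW
    t_high: float = species_demarcation.T_HIGH
    compare: list[str] = field(default_factory=list)  # proteome FASTAs
    rbh_min_score: float = 100.0
    rbh_min_coverage: float = 0.5
    seed: int = 0
    out_dir: str = "baculoscan_out"


def _read_protein_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {r.id: str(r.seq).rstrip("*") for r in SeqIO.parse(str(path), "fasta")}


def _load_genome(config: PipelineConfig):
    fmt = config.genome_format
    if fmt == "auto":
        fmt = ("genbank"
               if Path(config.genome).suffix.lower() in (".gb", ".gbk", ".gbff")
               else "fasta")
    if fmt == "genbank":
        genome, _ = genome_io.read_genbank(config.genome, topology=config.topology)
        return genome
    return genome_io.read_fasta(config.genome, topology=config.topology)[0]


def run_report(config: PipelineConfig) -> dict:
    """Run every configured stage; returns the report dict (also written out).

    A stage failure is recorded in the report (``stages[name] = "failed:
    ..."``) and the remaining stages still run; the caller decides the exit
    status from ``report["ok"]``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "ok": True}

    def stage(name):
        def deco(fn):
            try:
                fn()
                report["stages"][name] = "ok"
            except Exception as exc:  # noqa: BLE001 - partial failure is reported
                logger.error("stage %s failed: %s", name, exc)
                report["stages"][name] = f"failed: {exc}"
                report["ok"] = False
        return deco

    genome = _load_genome(config)
    L = len(genome)
    report["genome"] = {
        "id": genome.id,
        "length": L,
        "gc_percent": genome_io.gc_content(genome),
        "topology": genome.topology,
    }

    retained: list = []

    @stage("orfs")
    def _orfs():
        nonlocal retained
        candidates = orf_annotation.scan_orfs(genome, config.min_aa)
        retained = orf_annotation.filter_overlaps(candidates, config.max_overlap, L)
        labels = {}
        n_core = n_unique = None
        if config.refs:
            refs = _read_protein_fasta(config.refs)
            core_names: set[str] = set()
            if config.core_list:
                core_names = {
                    line.strip() for line in open(config.core_list)
                    if line.strip()
                }
            annotated = orf_annotation.label_homologs(
                retained, refs, config.min_homology_score, core_names)
            labels = {id(a.orf): a for a in annotated}
            n_core = sum(a.core_gene for a in annotated)
            n_unique = sum(a.label == "unique" for a in annotated)
        feats = []
        rows = []
        for o in retained:
            a = labels.get(id(o))
            label = a.label if a else ""
            feats.append(o.to_feature(label))
            rows.append({
                "start": o.start, "end": o.end, "strand": o.strand,
                "length_codons": o.length_codons, "label": label,
                "core_gene": bool(a.core_gene) if a else "",
            })
        genome_io.write_gff3(feats, out / "orfs.gff3", L)
        genome_io.write_table(rows, out / "orfs.csv")
        with open(out / "proteins.faa", "w") as fh:
            for o in retained:
                fh.write(f">{genome.id}_{o.start}{o.strand}\n{o.protein}\n")
        report["orfs"] = {
            "n_candidates": len(candidates),
            "n_retained": len(retained),
            "n_core": n_core,
            "n_unique": n_unique,
        }

    @stage("repeats")
    def _repeats():
        drs = repeat_discovery.find_tandem_repeats(
            genome, config.dr_min_unit, config.dr_max_unit,
            config.dr_min_copies, config.dr_min_identity)
        hrs = repeat_discovery.cluster_hrs(
            genome, config.core_motifs, config.hr_window, config.hr_min_hits)
        motif_counts = {
            m: repeat_discovery.count_motif(genome, m)
            for m in config.core_motifs
        }
        feats = [r.span for r in drs] + [r.span for r in hrs]
        genome_io.write_gff3(feats, out / "repeats.gff3", L)
        genome_io.write_table(
            [{"motif": m, "count": c} for m, c in motif_counts.items()],
            out / "motif_counts.csv",
        )
        report["repeats"] = {
            "n_tandem": len(drs),
            "tandem": [
                {"start": r.span.start % L, "unit_length": r.unit_length,
                 "copies": r.copies, "identity": r.internal_identity}
                for r in drs
            ],
            "n_hr": len(hrs),
            "hr": [{"name": r.name, "start": r.span.start % L,
                    "end": r.span.end, "hits": r.n_hits} for r in hrs],
            "motif_counts": motif_counts,
        }

    if config.variants:
        @stage("variants")
        def _variants():
            table = variant_analysis.read_variants(config.variants)
            effects = [
                variant_analysis.classify_variant(v, retained, genome)
                for v in table
            ]
            summary = variant_analysis.summarize_variants(effects)
            genome_io.write_table(
                [{
                    "position": e.variant.position + 1, "ref": e.variant.ref,
                    "alt": e.variant.alt, "frequency": e.variant.frequency,
                    "gene": e.gene_label, "effect": e.effect,
                    "codon_index": e.codon_index or "",
                    "ref_codon": e.ref_codon or "", "alt_codon": e.alt_codon or "",
                } for e in effects],
                out / "variant_effects.csv",
            )
            report["variants"] = dataclasses.asdict(summary)
            report["variants"]["n_indels_skipped"] = table.n_indels_skipped

    if config.markers:
        @stage("demarcation")
        def _demarcation():
            # aligned FASTA may contain gaps, which CircularGenome rejects,
            # so read it directly
            from Bio import SeqIO

            aln = {r.id: str(r.seq).upper()
                   for r in SeqIO.parse(config.markers, "fasta")}
            dm = species_demarcation.distance_matrix(aln)
            calls = []
            for i, a in enumerate(dm.names):
                for b in dm.names[i + 1:]:
                    call = species_demarcation.classify_species(
                        dm.get(a, b), config.t_low, config.t_high,
                        marker=f"{a}|{b}")
                    calls.append({
                        "pair": f"{a}|{b}", "d": call.d,
                        "decision": call.decision, "saturated": call.saturated,
                    })
            genome_io.write_table(calls, out / "species_calls.csv")
            with open(out / "markers.nwk", "w") as fh:
                fh.write(species_demarcation.neighbor_joining(dm) + "\n")
            report["demarcation"] = {"n_pairs": len(calls), "calls": calls}

    if config.compare:
        @stage("compare")
        def _compare():
            proteomes = {}
            for path in config.compare:
                gid = Path(path).stem
                proteomes[gid] = [
                    ortholog_comparison.ProteinRecord(gid, name, seq)
                    for name, seq in _read_protein_fasta(path).items()
                ]
            pairs = ortholog_comparison.all_pairwise_rbh(
                proteomes, config.rbh_min_score, config.rbh_min_coverage)
            all_genes = [
                (g, p.gene_label) for g, ps in proteomes.items() for p in ps
            ]
            groups = ortholog_comparison.build_ortholog_groups(pairs, all_genes)
            venn = ortholog_comparison.venn_partition(groups, list(proteomes))
            genome_io.write_table(
                [{"subset": "+".join(sorted(s)), "count": c}
                 for s, c in sorted(venn.counts.items(),
                                    key=lambda kv: (len(kv[0]), sorted(kv[0])))],
                out / "venn.csv",
            )
            genome_io.write_table(
                [{"group": g.group_id,
                  "members": ";".join(f"{a}:{b}" for a, b in sorted(g.members))}
                 for g in groups],
                out / "groups.csv",
            )
            report["compare"] = {
                "n_groups": len(groups),
                "n_shared_all": venn.counts.get(frozenset(proteomes), 0),
            }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)
    return report


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig(**data)
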