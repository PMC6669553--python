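import numpy as np
import pytest

from baculoscan import genome_io as gio
from baculoscan import orf_annotation as oa
from baculoscan import synthetic_data as sd

STOPS = {"TAA", "TAG", "TGA"}

# independent single-letter codon table, typed from the standard code
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def oracle_orfs(genome, min_aa):
    """Brute-force six-frame enumeration, independent of the scanner.

    For every ATG on either strand, walk codon-by-codon (with modular
    wrapping on circular genomes) to the next stop, then walk upstream to
    check no in-frame ATG precedes it within its stop-to-stop segment.
    """
    L = len(genome)
    found = set()
    for strand in "+-":
        s = genome.sequence if strand == "+" else gio.reverse_complement(
            genome.sequence)

        def codon_at(i):
            if genome.circular:
                return "".join(s[(i + t) % L] for t in range(3))
            if i + 3 > L:
                return None
            return s[i : i + 3]

        max_steps = L // 3
        for p in range(L):
            if codon_at(p) != "ATG":
                continue
            # upstream: a stop must come before any ATG
            ok = False
            k, steps = p - 3, 0
            while steps < max_steps:
                if not genome.circular and k < 0:
                    ok = True  # the sequence start is a real segment boundary
                    break
                c = codon_at(k % L if genome.circular else k)
                if c in STOPS:
                    ok = True
                    break
                if c == "ATG":
                    break
                k -= 3
                steps += 1
            if not ok:
                continue
            # downstream: find the stop
            j, steps = p + 3, 0
            length = None
            while steps <= max_steps:
                c = codon_at(j % L if genome.circular else j)
                if c is None:
                    break
                if c in STOPS:
                    length = (j - p) // 3
                    break
                j += 3
                steps += 1
            if length is None or length < min_aa:
                continue
            span = 3 * (length + 1)
            if span > L:
                continue
            cds = "".join(codon_at((p + 3 * t) % L) for t in range(length + 1))
            if "N" in cds:
                continue
            if strand == "+":
                start = p
            else:
                start = (L - p - span) % L if genome.circular else L - p - span
            found.add((start % L, strand, length))
    return found


def random_genome(rng, n, circular=True):
    return gio.CircularGenome(
        "r", "".join(rng.choice(list("ACGT"), size=n)),
        "circular" if circular else "linear")


class TestScanOrfs:
    def test_no_atg_gives_empty(self):
        g = gio.CircularGenome("x", "CCCCCCGGGGGGTTTTTT" * 20)
        assert oa.scan_orfs(g, 1) == []

    @pytest.mark.parametrize("seed,n", [(0, 900), (1, 1500), (2, 3000),
                                        (3, 4800), (4, 2222)])
    def test_equals_bruteforce_oracle_circular(self, seed, n):
        g = random_genome(np.random.default_rng(seed), n)
        got = {(o.start % n, o.strand, o.length_codons)
               for o in oa.scan_orfs(g, 10)}
        assert got == oracle_orfs(g, 10)

    @pytest.mark.parametrize("seed", [5, 6])
    def test_equals_bruteforce_oracle_linear(self, seed):
        g = random_genome(np.random.default_rng(seed), 2000, circular=False)
        got = {(o.start, o.strand, o.length_codons)
               for o in oa.scan_orfs(g, 10)}
        assert got == oracle_orfs(g, 10)

    def test_rotation_invariance(self):
        g = random_genome(np.random.default_rng(7), 3000)
        L = len(g)
        base = {((o.start) % L, o.strand, o.protein)
                for o in oa.scan_orfs(g, 10)}
        for r in (1, 137, 1500):
            rot = g.rotate(r)
            shifted = {((o.start + r) % L, o.strand, o.protein)
                       for o in oa.scan_orfs(rot, 10)}
            assert shifted == base

    def test_revcomp_swaps_strands_keeps_proteins(self):
        g = random_genome(np.random.default_rng(8), 2500)
        a = sorted(o.protein for o in oa.scan_orfs(g, 10))
        b = sorted(o.protein for o in oa.scan_orfs(g.reverse_complemented(), 10))
        assert a == b
        strands_a = sorted((o.protein, o.strand) for o in oa.scan_orfs(g, 10))
        strands_b = sorted(
            (o.protein, "+-"[o.strand == "+"])
            for o in oa.scan_orfs(g.reverse_complemented(), 10))
        assert strands_a == strands_b

    def test_origin_spanning_minus_strand_orf(self):
        """A 122-codon ORF planted across the origin on the minus strand."""
        design = sd.GenomeDesign(
            length=4000, gc=0.5,
            orfs=[sd.OrfDesign(122, "-", "origin")],
            seed=42, sterilize_min_aa=50)
        genome, truth = sd.simulate_genome(design)
        (planted,) = truth.orfs
        assert planted.end > len(genome)  # really wraps
        hits = [o for o in oa.scan_orfs(genome, 50)
                if (o.start % 4000, o.strand) == (planted.start, "-")]
        assert len(hits) == 1
        assert hits[0].protein == planted.protein
        assert hits[0].length_codons == 122

    def test_planted_recovery(self, mid_genome):
        genome, truth = mid_genome
        L = len(genome)
        found = {(o.start % L, o.strand): o for o in oa.scan_orfs(genome, 50)}
        for p in truth.orfs:
            o = found[(p.start % L, p.strand)]
            assert o.protein == p.protein
            assert o.length_codons == p.length_codons
        extras = set(found) - {(p.start % L, p.strand) for p in truth.orfs}
        assert extras == {(s, st) for s, st, _ in truth.residual_background_orfs}


class TestFilterOverlaps:
    def _orf(self, start, end, strand="+"):
        ncod = (end - start) // 3 - 1
        return oa.OrfCandidate("g", start, end, strand, 0, ncod, "M" * ncod)

    def test_disjoint_both_retained(self):
        a, b = self._orf(0, 300), self._orf(400, 550)
        assert len(oa.filter_overlaps([a, b], 0.5, 1000)) == 2

    def test_smaller_orf_discarded_at_two_thirds_overlap(self):
        a = self._orf(0, 300)
        b = self._orf(200, 350)  # 150 nt, overlap 100 -> 66.7% of its length
        kept = oa.filter_overlaps([a, b], 0.5, 1000)
        assert [(o.start, o.end) for o in kept] == [(0, 300)]

    def test_just_under_half_overlap_both_retained(self):
        a = self._orf(0, 300)
        b = self._orf(151, 451)  # overlap 149/300 < 50%
        assert len(oa.filter_overlaps([a, b], 0.5, 1000)) == 2

    def test_exactly_half_overlap_discards(self):
        a = self._orf(0, 300)
        b = self._orf(150, 450)  # overlap 150/300 = 50% exactly
        kept = oa.filter_overlaps([a, b], 0.5, 1000)
        assert len(kept) == 1

    def test_wrapped_overlap_counted(self):
        a = self._orf(900, 1200)  # wraps L=1000, covers [900,1000)+[0,200)
        b = self._orf(0, 150)  # fully inside a's wrapped part
        kept = oa.filter_overlaps([a, b], 0.5, 1000)
        assert [(o.start % 1000, o.strand) for o in kept] == [(900, "+")]

    def test_idempotent_and_pairwise_bound(self):
        rng = np.random.default_rng(9)
        g = random_genome(rng, 5000)
        kept = oa.filter_overlaps(oa.scan_orfs(g, 10), 0.5, 5000)
        again = oa.filter_overlaps(kept, 0.5, 5000)
        assert [(o.start, o.end) for o in again] == \
            [(o.start, o.end) for o in kept]
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                ov = oa._circle_overlap(a, b, 5000)
                assert ov / a.span < 0.5 or ov / b.span < 0.5


class TestTranslate:
    def test_single_codon(self):
        assert oa.translate("ATGTAA") == "M"

    def test_alanine_run(self):
        assert oa.translate("ATGGCTGCC") == "MAA"

    def test_internal_stop_errors(self):
        with pytest.raises(oa.TranslationError):
            oa.translate("ATGTAAATG")

    def test_non_triplet_errors(self):
        with pytest.raises(oa.TranslationError):
            oa.translate("ATGTA")

    def test_matches_independent_codon_table(self):
        rng = np.random.default_rng(10)
        sense = [c for c in CODON_TABLE if CODON_TABLE[c] != "*"]
        codons = ["ATG"] + list(rng.choice(sense, size=299)) + ["TAA"]
        cds = "".join(codons)
        try:
            got = oa.translate(cds)
        except oa.TranslationError:
            pytest.skip("random draw produced an internal stop")
        assert got == "".join(CODON_TABLE[c] for c in codons[:-1])


class TestLabelHomologs:
    def test_identical_protein_gets_reference_label(self):
        orf = oa.OrfCandidate("g", 0, 306, "+", 0, 101, "MKV" * 33 + "LI")
        refs = {"polh": orf.protein, "lef8": "MW" * 60}
        (ann,) = oa.label_homologs([orf], refs, min_score=100,
                                   core_gene_names={"polh"})
        assert ann.label == "polh"
        assert ann.core_gene

    def test_random_protein_is_unique(self):
        rng = np.random.default_rng(12)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        orf = oa.OrfCandidate("g", 0, 306, "+", 0, 101,
                              "".join(rng.choice(aas, size=101)))
        refs = {f"ref{i}": "".join(rng.choice(aas, size=150)) for i in range(5)}
        (ann,) = oa.label_homologs([orf], refs, min_score=100)
        assert ann.label == "unique"

    def test_empty_reference_warns(self):
        orf = oa.OrfCandidate("g", 0, 306, "+", 0, 101, "M" * 101)
        with pytest.warns(UserWarning):
            (ann,) = oa.label_homologs([orf], {})
        assert ann.label == "unique"
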