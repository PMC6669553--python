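import numpy as np
import pytest
from Bio.Align import substitution_matrices

from baculoscan import genome_io as gio
from baculoscan import ortholog_comparison as oc
from baculoscan import synthetic_data as sd

BLOSUM62 = substitution_matrices.load("BLOSUM62")
AAS = list("ACDEFGHIKLMNPQRSTVWY")


def gotoh_local_score(a, b, gap_open=11, gap_extend=1):
    """Independent affine-gap Smith-Waterman (Gotoh), first gap position
    costs ``gap_open``, each further position ``gap_extend``."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = np.zeros((n + 1, m + 1))
    X = np.full((n + 1, m + 1), NEG)  # gap in b (consume a)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (consume b)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = BLOSUM62[a[i - 1], b[j - 1]]
            M[i, j] = max(0.0, s + max(M[i - 1, j - 1], X[i - 1, j - 1],
                                       Y[i - 1, j - 1]))
            X[i, j] = max(M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend)
            Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend)
            best = max(best, M[i, j])
    return best


def _random_protein(rng, n):
    return "".join(rng.choice(AAS, size=n))


class TestAlignProteins:
    def test_identical_full_coverage(self):
        p = "MKVLITGASGFIGSHL"
        r = oc.align_proteins(p, p)
        assert r.identity == 100.0
        assert r.coverage == 1.0
        assert r.score == sum(BLOSUM62[c, c] for c in p)

    @pytest.mark.parametrize("seed", range(8))
    def test_score_matches_independent_gotoh(self, seed):
        rng = np.random.default_rng(seed)
        a = _random_protein(rng, int(rng.integers(5, 13)))
        b = _random_protein(rng, int(rng.integers(5, 13)))
        got = oc.align_proteins(a, b).score
        assert got == pytest.approx(gotoh_local_score(a, b), abs=1e-9)

    def test_gotoh_on_longer_pairs(self):
        rng = np.random.default_rng(99)
        for _ in range(3):
            a = _random_protein(rng, 40)
            b = _random_protein(rng, 35)
            assert oc.align_proteins(a, b).score == \
                pytest.approx(gotoh_local_score(a, b), abs=1e-9)

    def test_unrelated_random_pairs_fail_homology_threshold(self):
        """Random length-300 proteins stay below score 100 at coverage 0.5."""
        rng = np.random.default_rng(13)
        passing = 0
        trials = 30
        for _ in range(trials):
            a = _random_protein(rng, 300)
            b = _random_protein(rng, 300)
            r = oc.align_proteins(a, b)
            if r.score >= 100 and r.coverage >= 0.5:
                passing += 1
        assert passing / trials <= 0.01


class TestReciprocalBestHits:
    def _proteome(self, gid, seqs):
        return [oc.ProteinRecord(gid, f"p{i}", s) for i, s in enumerate(seqs)]

    def test_identical_proteomes_perfect_matching(self):
        rng = np.random.default_rng(14)
        seqs = [_random_protein(rng, 120) for _ in range(6)]
        pa = self._proteome("A", seqs)
        pb = self._proteome("B", seqs)
        pairs = oc.reciprocal_best_hits(pa, pb)
        assert len(pairs) == 6
        assert all(p.a[1] == p.b[1] for p in pairs)

    def test_duplicated_gene_tie_yields_no_pair(self):
        rng = np.random.default_rng(15)
        s = _random_protein(rng, 120)
        other = _random_protein(rng, 120)
        pa = self._proteome("A", [s, other])
        pb = [oc.ProteinRecord("B", "dup1", s),
              oc.ProteinRecord("B", "dup2", s),
              oc.ProteinRecord("B", "o", other)]
        pairs = oc.reciprocal_best_hits(pa, pb)
        assert [(p.a[1], p.b[1]) for p in pairs] == [("p1", "o")]

    def test_symmetry(self):
        rng = np.random.default_rng(16)
        base = [_random_protein(rng, 100) for _ in range(4)]
        pa = self._proteome("A", base)
        pb = self._proteome("B", [sd._perturb_protein(rng, s, 0.1)
                                  for s in base])
        fwd = {(p.a, p.b) for p in oc.reciprocal_best_hits(pa, pb)}
        rev = {(p.b, p.a) for p in oc.reciprocal_best_hits(pb, pa)}
        assert fwd == rev


class TestOrthologGroups:
    def test_no_pairs_gives_singletons(self):
        genes = [("A", "x"), ("A", "y"), ("B", "z")]
        groups = oc.build_ortholog_groups([], genes)
        assert sorted(len(g.members) for g in groups) == [1, 1, 1]

    def test_clean_clique_one_group(self):
        members = [(g, "gene") for g in "ABCDE"]
        pairs = [oc.RbhPair(members[i], members[j], 500.0)
                 for i in range(5) for j in range(i + 1, 5)]
        groups = oc.build_ortholog_groups(pairs)
        assert len(groups) == 1
        assert groups[0].members == frozenset(members)

    def test_single_linkage_chain(self):
        a, b, c = ("A", "g"), ("B", "g"), ("C", "g")
        groups = oc.build_ortholog_groups(
            [oc.RbhPair(a, b, 300.0), oc.RbhPair(b, c, 280.0)])
        assert len(groups) == 1
        assert groups[0].members == frozenset([a, b, c])

    def test_conflict_split_drops_weakest_edge(self):
        # two A-genes chained through one B-gene: dropping the weaker edge
        # leaves one pair plus one singleton
        a1, a2, b = ("A", "g1"), ("A", "g2"), ("B", "g")
        groups = oc.build_ortholog_groups(
            [oc.RbhPair(a1, b, 300.0), oc.RbhPair(a2, b, 100.0)],
            all_genes=[a1, a2, b])
        by_size = sorted(groups, key=lambda g: -len(g.members))
        assert by_size[0].members == frozenset([a1, b])
        assert by_size[1].members == frozenset([a2])


class TestVennPartition:
    def _group(self, i, *genomes):
        return oc.OrthologGroup(f"og{i}", frozenset((g, f"x{i}")
                                                    for g in genomes))

    def test_single_genome(self):
        groups = [self._group(i, "A") for i in range(4)]
        venn = oc.venn_partition(groups, ["A"])
        assert venn.count("A") == 4

    def test_toy_enumeration(self):
        groups = [self._group(0, "A", "B"), self._group(1, "A", "B", "C"),
                  self._group(2, "C"), self._group(3, "C")]
        venn = oc.venn_partition(groups, ["A", "B", "C"])
        assert venn.count("A", "B") == 1
        assert venn.count("A", "B", "C") == 1
        assert venn.count("C") == 2
        assert venn.count("A") == 0
        assert venn.total == 4

    def test_counts_conserved_random(self):
        rng = np.random.default_rng(17)
        gids = ["A", "B", "C", "D"]
        groups = []
        for i in range(50):
            k = int(rng.integers(1, 5))
            sub = list(rng.choice(gids, size=k, replace=False))
            groups.append(self._group(i, *sub))
        venn = oc.venn_partition(groups, gids)
        assert venn.total == 50


class TestPlantedFiveProteomeDesign:
    def test_venn_counts_equal_design(self):
        gids = ["g1", "g2", "g3", "g4", "g5"]
        design = {
            frozenset(gids): 8,
            frozenset(["g1"]): 3,
            frozenset(["g2"]): 1,
            frozenset(["g1", "g2"]): 1,
            frozenset(["g2", "g3", "g4"]): 2,
            frozenset(["g4", "g5"]): 2,
        }
        proteomes, _ = sd.simulate_proteome_family(
            gids, design, divergence=0.1, mean_length=150, seed=3)
        pairs = oc.all_pairwise_rbh(proteomes)
        all_genes = [(g, p.gene_label)
                     for g, ps in proteomes.items() for p in ps]
        groups = oc.build_ortholog_groups(pairs, all_genes)
        venn = oc.venn_partition(groups, gids)
        for subset, count in design.items():
            assert venn.counts[subset] == count
        assert venn.total == sum(design.values())


class TestLocusContext:
    def _feat(self, start, end, strand, label):
        return gio.Feature("g", start, end, strand, "CDS", label)

    def test_adjacent_anchors_empty(self):
        anns = [self._feat(0, 300, "+", "ac30"),
                self._feat(310, 600, "+", "fgf")]
        assert oc.locus_context(anns, "ac30", "fgf", 10000) == []

    def test_planted_locus_in_order_with_strands(self):
        anns = [
            self._feat(0, 300, "+", "ac30"),
            self._feat(350, 500, "+", "iap"),
            self._feat(520, 700, "-", "rr1"),
            self._feat(720, 900, "+", "rr2"),
            self._feat(950, 1100, "-", "tmk"),
            self._feat(1150, 1400, "+", "fgf"),
            self._feat(5000, 6000, "+", "far"),
        ]
        got = oc.locus_context(anns, "ac30", "fgf", 10000)
        assert [(f.label, f.strand) for f in got] == \
            [("iap", "+"), ("rr1", "-"), ("rr2", "+"), ("tmk", "-")]

    def test_shorter_arc_chosen_and_oriented(self):
        # anchors placed so the short arc crosses the origin
        anns = [
            self._feat(9000, 9300, "+", "ac30"),
            self._feat(9400, 9600, "+", "mid"),
            self._feat(200, 500, "+", "fgf"),
            self._feat(2000, 7000, "+", "huge"),
        ]
        got = oc.locus_context(anns, "ac30", "fgf", 10000)
        assert [f.label for f in got] == ["mid"]
        got_rev = oc.locus_context(anns, "fgf", "ac30", 10000)
        assert [f.label for f in got_rev] == ["mid"]

    def test_rotation_invariance(self):
        anns = [
            self._feat(0, 300, "+", "ac30"),
            self._feat(350, 500, "+", "a"),
            self._feat(520, 700, "-", "b"),
            self._feat(800, 1000, "+", "fgf"),
            self._feat(4000, 9000, "+", "far"),
        ]
        base = [f.label for f in oc.locus_context(anns, "ac30", "fgf", 10000)]
        r = 7777
        rotated = [gio.Feature("g", (f.start - r) % 10000,
                               (f.start - r) % 10000 + f.span, f.strand,
                               "CDS", f.label) for f in anns]
        got = [f.label
               for f in oc.locus_context(rotated, "ac30", "fgf", 10000)]
        assert got == base

    def test_missing_or_duplicated_anchor_errors(self):
        anns = [self._feat(0, 300, "+", "ac30"),
                self._feat(400, 600, "+", "ac30")]
        with pytest.raises(ValueError):
            oc.locus_context(anns, "ac30", "fgf", 10000)
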