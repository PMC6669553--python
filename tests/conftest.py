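import numpy as np
import pytest

from baculoscan import synthetic_data as sd


@pytest.fixture(scope="session")
def mid_genome():
    """A 40 kb circular genome with 40 planted ORFs, 2 hrs, 1 dr."""
    rng = np.random.default_rng(11)
    lengths = np.clip(50 + rng.exponential(scale=120, size=40), 50, 600).astype(int)
    strands = rng.choice(["+", "-"], size=40)
    orfs = [sd.OrfDesign(int(l), s) for l, s in zip(lengths, strands)]
    orfs[0] = sd.OrfDesign(orfs[0].length_codons, orfs[0].strand, "origin")
    design = sd.GenomeDesign(
        length=40000,
        gc=0.509,
        orfs=orfs,
        hr_designs=[sd.HrDesign("TTTTTAGCGATG", copies=8, divergence=0.05,
                                window=800) for _ in range(2)],
        dr_designs=[sd.DrDesign(unit_length=68, copies=4,
                                divergence=1.0 / (68 * 4))],
        seed=11,
    )
    return sd.simulate_genome(design)


@pytest.fixture(scope="session")
def mid_variants(mid_genome):
    genome, truth = mid_genome
    # keep planted variants out of residual chance ORFs so their truth
    # effects are unambiguous under any annotation of this genome
    exclude = [(s, e) for s, _, e in truth.residual_background_orfs]
    return sd.simulate_variants(genome, truth.orfs, n=60, seed=5,
                                exclude_spans=exclude)
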