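
import pandas as pd
import pytest

from rilmap._rng import substream
from rilmap.mapping import GeneticMap, build_scan_grid, genotype_probabilities
from rilmap.simulate import lt_ril_template, simulate_ril_genotypes


@pytest.fixture(scope="session")
def template_map():
    return lt_ril_template()


@pytest.fixture(scope="session")
def small_map():
    """Two chromosomes, markers every 10 cM — hand-checkable geometry."""
    rows = []
    for chrom, n in ((1, 5), (2, 4)):
        for i in range(n):
            rows.append((f"m{chrom}_{i}", chrom, 10.0 * i))
    return GeneticMap(pd.DataFrame(rows, columns=["marker", "chromosome", "position_cm"]))


@pytest.fixture(scope="session")
def small_genotypes(small_map):
    return simulate_ril_genotypes(small_map, 50, substream(42, "small_geno"))


@pytest.fixture(scope="session")
def template_probs(template_map):
    """Shared (genotypes, grid, probability matrix) for 250 template lines."""
    geno = simulate_ril_genotypes(template_map, 250, substream(42, "tpl_geno"))
    grid = build_scan_grid(template_map, 2.0)
    probs = genotype_probabilities(template_map, geno, grid)
    return geno, grid, probs
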