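import math

import numpy as np
import pytest

from driftkit.io_formats import (
    GenotypeTable,
    IndividualRecord,
    SnpRecord,
)
from driftkit.synthdata import (
    PANEL_OUTGROUPS,
    PANEL_SOURCES,
    IndividualSim,
    default_snps,
    simulate_frequencies,
    simulate_individuals,
    three_source_panel,
)


def make_snps(n, chrom="1", spacing_morgans=0.001):
    return [
        SnpRecord(
            snp_id=f"s{i}",
            chrom=chrom,
            genetic_pos=i * spacing_morgans,
            physical_pos=i * 1000 + 1,
            allele1="A",
            allele2="C",
        )
        for i in range(n)
    ]


def make_inds(n, ploidy="diploid", group=None):
    return [
        IndividualRecord(ind_id=f"i{j}", group=group or f"i{j}", ploidy_mode=ploidy)
        for j in range(n)
    ]


def random_table(n_snps=1000, n_pops=4, n_per_pop=5, seed=0, missing_frac=0.0):
    """Complete (or masked) diploid table: each population's frequencies drawn
    independently per SNP."""
    rng = np.random.default_rng(seed)
    snps = default_snps(n_snps)
    inds, cols = [], []
    for p in range(n_pops):
        freq = rng.uniform(0.05, 0.95, n_snps)
        for j in range(n_per_pop):
            inds.append(
                IndividualRecord(ind_id=f"P{p}_{j}", group=f"P{p}", ploidy_mode="diploid")
            )
            cols.append(rng.binomial(2, freq))
    G = np.column_stack(cols).astype(np.int8)
    if missing_frac > 0:
        mask = rng.random(G.shape) < missing_frac
        G[mask] = -1
    return GenotypeTable(snps=snps, individuals=inds, G=G)


def panel_dataset(
    alpha=(0.62, 0.19, 0.19),
    n_snps=50_000,
    seed=0,
    target_coverage=0.5,
    target_ploidy="pseudohaploid",
    n_per_pop=8,
):
    """Three-source admixture panel with an admixed target individual."""
    graph = three_source_panel(alpha)
    rng = np.random.default_rng(seed)
    freqs = simulate_frequencies(graph, n_snps, seed=int(rng.integers(2**31)))
    sims = [
        IndividualSim(f"{p}_{i}", p, math.inf, "diploid", group=p)
        for p in PANEL_OUTGROUPS + PANEL_SOURCES
        for i in range(n_per_pop)
    ]
    sims.append(IndividualSim("T1", "T", target_coverage, target_ploidy, group="Tpop"))
    table, reads, _ = simulate_individuals(
        freqs, sims, seed=int(rng.integers(2**31)), snps=default_snps(n_snps)
    )
    return table, reads


@pytest.fixture(scope="session")
def small_panel():
    return panel_dataset(n_snps=20_000, seed=11)
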