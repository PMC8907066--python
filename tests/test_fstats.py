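import math

import numpy as np
import pytest

from driftkit.fstats import (
    FBasis,
    NoOverlapError,
    StatEngine,
    build_blocks,
    compute_fstat,
    derive_stat,
    qpfstats_solve,
)
from driftkit.io_formats import MISSING, GenotypeTable, IndividualRecord, SnpRecord
from driftkit.jackknife import jackknife_se
from driftkit.synthdata import IndividualSim, default_snps, simulate_individuals
from tests.conftest import make_inds, make_snps, random_table


class TestBuildBlocks:
    def test_uniform_chromosome_four_blocks(self):
        # 0.2-Morgan chromosome (positions in [0, 0.2)), block 0.05 -> 4 blocks
        snps = make_snps(100, spacing_morgans=0.002)
        part = build_blocks(snps, 0.05)
        assert part.n_blocks == 4
        assert part.snp_counts.sum() == 100

    def test_blocks_never_span_chromosomes(self):
        snps = make_snps(30, chrom="1", spacing_morgans=0.001) + make_snps(
            30, chrom="2", spacing_morgans=0.001
        )
        part = build_blocks(snps, 0.05)
        assert part.n_blocks == 2
        assert part.chroms == ["1", "2"]

    def test_empty_input(self):
        part = build_blocks([], 0.05)
        assert part.n_blocks == 0

    def test_every_snp_in_exactly_one_block(self):
        snps = make_snps(157, spacing_morgans=0.0013)
        part = build_blocks(snps, 0.05)
        covered = np.concatenate(
            [np.arange(s, e) for s, e in zip(part.starts, part.ends)]
        )
        assert (covered == np.arange(157)).all()


class TestComputeFstat:
    def test_f2_identical_frequency_columns_zero(self):
        # identical per-SNP frequencies with no estimable sampling correction
        # (single-allele samples): f2 = 0 exactly
        rng = np.random.default_rng(0)
        col = (2 * rng.binomial(1, 0.5, size=500)).astype(np.int8)
        G = np.column_stack([col, col]).astype(np.int8)
        inds = [
            IndividualRecord("x", group="X", ploidy_mode="pseudohaploid"),
            IndividualRecord("y", group="Y", ploidy_mode="pseudohaploid"),
        ]
        t = GenotypeTable(make_snps(500), inds, G)
        s = compute_fstat(t, ("f2", ("X", "Y")))
        assert s.estimate == pytest.approx(0.0, abs=1e-12)

    def test_f4_brute_force_oracle(self):
        t = random_table(n_snps=100, seed=5)
        s = compute_fstat(t, ("f4", ("P0", "P1", "P2", "P3")))
        eng = StatEngine(t, ["P0", "P1", "P2", "P3"])
        oracle = np.mean(
            (eng.freq["P0"] - eng.freq["P1"]) * (eng.freq["P2"] - eng.freq["P3"])
        )
        assert s.estimate == pytest.approx(oracle, abs=1e-15)

    def test_f2_unbiased_two_samples_one_population(self):
        # two independent 10-individual samples from one population:
        # |f2| < 2 se in >= 90/100 simulations
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            freq = rng.uniform(0.05, 0.95, 2000)
            cols = [rng.binomial(2, freq) for _ in range(20)]
            inds = [
                IndividualRecord(f"i{j}", group="A" if j < 10 else "B")
                for j in range(20)
            ]
            t = GenotypeTable(
                default_snps(2000), inds, np.column_stack(cols).astype(np.int8)
            )
            s = compute_fstat(t, ("f2", ("A", "B")))
            if abs(s.estimate) < 2 * s.jackknife_se:
                hits += 1
        assert hits >= 90

    def test_no_overlap_error(self):
        G = np.array([[0, MISSING], [2, MISSING]], dtype=np.int8)
        inds = [IndividualRecord("a", group="A"), IndividualRecord("b", group="B")]
        t = GenotypeTable(make_snps(2), inds, G)
        with pytest.raises(NoOverlapError):
            compute_fstat(t, ("f2", ("A", "B")))

    def test_pseudohaploid_contributes_one_allele(self):
        # one pseudohaploid individual: frequency is g/2 in {0,1}, n = 1
        G = np.array([[2], [0], [2]], dtype=np.int8)
        t = GenotypeTable(
            make_snps(3), make_inds(1, ploidy="pseudohaploid", group="X"), G
        )
        eng = StatEngine(t, ["i0"])
        assert eng.freq["i0"].tolist() == [1.0, 0.0, 1.0]
        assert (eng.corr["i0"] == 0).all()


class TestJackknife:
    def test_constant_loo_gives_zero_se(self):
        loo = np.full(10, 0.5)
        assert jackknife_se(0.5, loo, np.ones(10)) == pytest.approx(0.0)

    def test_equal_weight_reduces_to_standard_formula(self):
        rng = np.random.default_rng(2)
        loo = rng.normal(size=12)
        est = loo.mean()
        se = jackknife_se(est, loo, np.ones(12))
        expected = math.sqrt((11 / 12) * ((loo - loo.mean()) ** 2).sum())
        assert se == pytest.approx(expected, rel=1e-12)

    def test_calibration_over_simulations(self):
        # empirical sd of f4 across 60 sims within 25% of mean jackknife se
        ests, ses = [], []
        for rep in range(60):
            t = random_table(n_snps=3000, n_per_pop=5, seed=2000 + rep)
            s = compute_fstat(t, ("f4", ("P0", "P1", "P2", "P3")))
            ests.append(s.estimate)
            ses.append(s.jackknife_se)
        assert np.std(ests) == pytest.approx(np.mean(ses), rel=0.25)


def masked_panel(missing_frac, seed=7, n_snps=4000):
    return random_table(n_snps=n_snps, n_per_pop=6, seed=seed, missing_frac=missing_frac)


class TestQpfstats:
    def test_complete_data_equals_direct(self):
        t = masked_panel(0.0)
        basis = qpfstats_solve(t, ["P0", "P1", "P2", "P3"])
        for x, y in [("P0", "P1"), ("P1", "P3"), ("P0", "P3")]:
            direct = compute_fstat(t, ("f2", (x, y)))
            derived = derive_stat(basis, ("f2", (x, y)))
            assert derived.estimate == pytest.approx(direct.estimate, abs=1e-10)

    def test_f4_under_missingness_close_to_complete_truth(self):
        complete = masked_panel(0.0, seed=8)
        s_complete = compute_fstat(complete, ("f4", ("P0", "P1", "P2", "P3")))
        rng = np.random.default_rng(9)
        G = complete.G.copy()
        G[rng.random(G.shape) < 0.5] = MISSING
        masked = GenotypeTable(complete.snps, complete.individuals, G)
        basis = qpfstats_solve(masked, ["P0", "P1", "P2", "P3"])
        s_masked = derive_stat(basis, ("f4", ("P0", "P1", "P2", "P3")))
        combined = math.hypot(s_complete.jackknife_se, s_masked.jackknife_se)
        assert abs(s_masked.estimate - s_complete.estimate) < 3 * combined

    def test_all_missing_population_raises(self):
        t = masked_panel(0.0)
        G = t.G.copy()
        G[:, [j for j, i in enumerate(t.individuals) if i.group == "P2"]] = MISSING
        bad = GenotypeTable(t.snps, t.individuals, G)
        with pytest.raises(NoOverlapError, match="P2"):
            qpfstats_solve(bad, ["P0", "P1", "P2", "P3"])

    def test_covariance_symmetric_psd(self):
        t = masked_panel(0.3)
        basis = qpfstats_solve(t, ["P0", "P1", "P2", "P3"])
        assert np.allclose(basis.cov, basis.cov.T)
        ev = np.linalg.eigvalsh(basis.cov)
        assert ev.min() > -1e-12 * max(ev.max(), 1e-30)

    def test_f2_entries_nonnegative_within_noise(self):
        t = masked_panel(0.2, seed=10)
        basis = qpfstats_solve(t, ["P0", "P1", "P2", "P3"])
        se = np.sqrt(np.maximum(np.diag(basis.cov), 0.0))
        assert (basis.basis > -3 * se).all()


class TestDeriveStat:
    @pytest.fixture(scope="class")
    def basis(self):
        return qpfstats_solve(masked_panel(0.3, seed=12), ["P0", "P1", "P2", "P3"])

    def test_f3_self_equals_f2(self, basis):
        f3 = derive_stat(basis, ("f3", ("P0", "P1", "P1")))
        f2 = derive_stat(basis, ("f2", ("P0", "P1")))
        assert f3.estimate == pytest.approx(f2.estimate, abs=1e-12)

    def test_f4_antisymmetry(self, basis):
        a = derive_stat(basis, ("f4", ("P0", "P1", "P2", "P3"))).estimate
        b = derive_stat(basis, ("f4", ("P1", "P0", "P2", "P3"))).estimate
        c = derive_stat(basis, ("f4", ("P0", "P1", "P3", "P2"))).estimate
        assert a == pytest.approx(-b, abs=1e-12)
        assert a == pytest.approx(-c, abs=1e-12)

    def test_f4_additivity_exact(self, basis):
        f_ac = derive_stat(basis, ("f4", ("P0", "P1", "P2", "P3"))).estimate
        # f4(A,B;C,D) + f4(A,B;D,E): with 4 pops use D->P2 chain identity
        f_cd = derive_stat(basis, ("f4", ("P0", "P1", "P2", "P2")))
        assert f_cd.estimate == pytest.approx(0.0, abs=1e-12)

    def test_unknown_population(self, basis):
        with pytest.raises(KeyError):
            derive_stat(basis, ("f2", ("P0", "ZZZ")))


def test_f4_additivity_three_terms():
    t = random_table(n_snps=2000, n_pops=5, seed=13)
    basis = qpfstats_solve(t, [f"P{i}" for i in range(5)])
    f_cd = derive_stat(basis, ("f4", ("P0", "P1", "P2", "P3"))).estimate
    f_de = derive_stat(basis, ("f4", ("P0", "P1", "P3", "P4"))).estimate
    f_ce = derive_stat(basis, ("f4", ("P0", "P1", "P2", "P4"))).estimate
    assert f_cd + f_de == pytest.approx(f_ce, abs=1e-12)
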