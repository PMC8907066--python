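import math

import numpy as np
import pytest

from driftkit.io_formats import IndividualRecord, ReadCountTable
from driftkit.structure import (
    IllConditionedError,
    InsufficientDataError,
    UnderdeterminedError,
    excess_relatedness_residuals,
    fit_mixture,
    fit_source_f3_matrix,
    outgroup_f3_pairs,
    pairwise_mismatch,
    rank_test,
)
from driftkit.synthdata import (
    PANEL_OUTGROUPS,
    PANEL_SOURCES,
    ClineIndividual,
    ClineScenario,
    ClusterSpec,
    GraphSpec,
    IndividualSim,
    SiteSpec,
    default_snps,
    simulate_cline_dataset,
    simulate_frequencies,
    simulate_individuals,
    three_source_panel,
)
from tests.conftest import panel_dataset


def clone_table(n_snps=8000, seed=0, n_clones=3):
    """Targets all drawn from one node; five diverged outgroups."""
    nodes = ["ROOT", "SRC", "O1", "O2", "O3", "O4", "O5"]
    edges = [("ROOT", "SRC", 0.05)] + [
        ("ROOT", f"O{i}", 0.05 + 0.03 * i) for i in range(1, 6)
    ]
    g = GraphSpec(nodes=nodes, edges=edges)
    rng = np.random.default_rng(seed)
    fr = simulate_frequencies(g, n_snps, seed=int(rng.integers(2**31)))
    sims = [
        IndividualSim(f"T{k}_{i}", "SRC", math.inf, "diploid", group=f"T{k}")
        for k in range(n_clones)
        for i in range(4)
    ]
    sims += [
        IndividualSim(f"O{k}_{i}", f"O{k}", math.inf, "diploid", group=f"O{k}")
        for k in range(1, 6)
        for i in range(4)
    ]
    t, _, _ = simulate_individuals(fr, sims, seed=int(rng.integers(2**31)), snps=default_snps(n_snps))
    return t


class TestRankTest:
    def test_dof_arithmetic(self):
        # L=12, R=10, k=2 -> dof = 9*7 = 63
        assert (12 - 1 - 2) * (10 - 1 - 2) == 63

    def test_saturated_rank_zero_chisq(self):
        t = clone_table(seed=1)
        res = rank_test(t, ["T0", "T1", "T2"], ["O1", "O2", "O3", "O4", "O5"])
        top = res.ranks[-1]
        assert top.dof == 0
        assert top.chisq == pytest.approx(0.0, abs=1e-8)
        assert top.tail_p == 1.0

    def test_clones_accept_rank_zero(self):
        res = rank_test(
            clone_table(seed=2), ["T0", "T1", "T2"], ["O1", "O2", "O3", "O4", "O5"]
        )
        assert res.ranks[0].tail_p > 0.05

    def test_three_sources_reject_rank_one(self, small_panel):
        table, _ = small_panel
        res = rank_test(table, PANEL_SOURCES, PANEL_OUTGROUPS)
        assert res.ranks[0].tail_p < 1e-6
        assert res.ranks[1].tail_p < 1e-4

    def test_dof_reported(self):
        t = clone_table(seed=3)
        res = rank_test(t, ["T0", "T1", "T2"], ["O1", "O2", "O3", "O4", "O5"])
        assert [r.dof for r in res.ranks] == [8, 3, 0]
        assert set(res.taildiff_p) == {0, 1}

    def test_input_validation(self):
        t = clone_table(seed=4)
        with pytest.raises(ValueError, match="test populations"):
            rank_test(t, ["T0"], ["O1", "O2"])
        with pytest.raises(ValueError, match="outgroups"):
            rank_test(t, ["T0", "T1", "T2"], ["O1", "O2"])


class TestFitMixture:
    def test_target_is_source_one(self, small_panel):
        table, _ = small_panel
        fit = fit_mixture(table, "S1_0", PANEL_SOURCES, PANEL_OUTGROUPS)
        assert abs(fit.alpha[0] - 1.0) < 2 * max(fit.se[0], 0.02)
        assert fit.alpha.sum() == pytest.approx(1.0, abs=1e-12)

    def test_recovers_admixture_proportions(self, small_panel):
        table, _ = small_panel
        fit = fit_mixture(table, "T1", PANEL_SOURCES, PANEL_OUTGROUPS)
        truth = np.array([0.62, 0.19, 0.19])
        assert (np.abs(fit.alpha - truth) < 3 * fit.se).all()

    def test_clade_sources_ill_conditioned(self):
        # sources forming a clade relative to all outgroups
        nodes = ["ROOT", "ANC", "S1", "S2", "O1", "O2", "O3", "O4"]
        edges = [
            ("ROOT", "ANC", 0.05),
            ("ANC", "S1", 0.02),
            ("ANC", "S2", 0.02),
            ("ROOT", "O1", 0.1),
            ("ROOT", "O2", 0.15),
            ("ROOT", "O3", 0.2),
            ("ROOT", "O4", 0.12),
        ]
        g = GraphSpec(nodes=nodes, edges=edges)
        fr = simulate_frequencies(g, 5000, seed=5)
        sims = [
            IndividualSim(f"{n}_{i}", n, math.inf, "diploid", group=n)
            for n in ["S1", "S2", "O1", "O2", "O3", "O4"]
            for i in range(5)
        ]
        t, _, _ = simulate_individuals(fr, sims, seed=6, snps=default_snps(5000))
        with pytest.raises(IllConditionedError):
            fit_mixture(t, "S1_0", ["S1", "S2"], ["O1", "O2", "O3", "O4"])

    def test_source_permutation_consistency(self, small_panel):
        table, _ = small_panel
        fit1 = fit_mixture(table, "T1", ["S1", "S2", "S3"], PANEL_OUTGROUPS)
        fit2 = fit_mixture(table, "T1", ["S3", "S1", "S2"], PANEL_OUTGROUPS)
        assert fit2.alpha[[1, 2, 0]] == pytest.approx(fit1.alpha, abs=1e-8)


def residual_fixture(delta=0.0, n_snps=30_000, seed=0, spike_pair=("I0", "I1")):
    clusters = [
        ClusterSpec("c1", (0.62, 0.19, 0.19)),
        ClusterSpec("c2", (0.5, 0.2, 0.3)),
        ClusterSpec("c3", (0.3, 0.1, 0.6)),
        ClusterSpec("c4", (0.25, 0.05, 0.7)),
        ClusterSpec("c5", (0.45, 0.35, 0.2)),
        ClusterSpec("c6", (0.7, 0.1, 0.2)),
    ]
    sites, inds, k = [], [], 0
    for ci, c in enumerate(clusters):
        for s in range(3):
            sid = f"{c.cluster_id}s{s}"
            d = delta if (ci == 0 and s == 0) else 0.0
            sites.append(SiteSpec(sid, c.cluster_id, -5 + 2 * ci, 30 + s, delta_site=d))
            for _ in range(2):
                inds.append(ClineIndividual(f"I{k}", sid))
                k += 1
    sc = ClineScenario(clusters=clusters, sites=sites, individuals=inds)
    table, reads, coords, truth = simulate_cline_dataset(sc, n_snps, seed=seed)
    ids = [i.ind_id for i in inds]
    f3o, f3v, f3_loo, weights = outgroup_f3_pairs(
        table, "Outgroup", ids, return_loo=True
    )
    alphas = {i: np.array(truth.params["alphas"][i]) for i in ids}
    return ResidualFixture(ids, alphas, f3o, f3v, f3_loo, weights, truth)


class ResidualFixture:
    def __init__(self, ids, alphas, f3o, f3v, f3_loo, weights, truth):
        self.ids = ids
        self.alphas = alphas
        self.f3o = f3o
        self.f3v = f3v
        self.f3_loo = f3_loo
        self.weights = weights
        self.truth = truth

    def fit(self, locked=None):
        return fit_source_f3_matrix(
            self.ids,
            self.alphas,
            self.f3o,
            self.f3v,
            locked=locked,
            f3_loo=self.f3_loo,
            block_weights=self.weights,
        )


class TestSourceF3Model:
    def test_null_scores_within_noise(self):
        fx = residual_fixture(delta=0.0, seed=21)
        model = fx.fit()
        z = model.score / model.score_se
        frac_ok = np.mean(np.abs(z) < 2)
        assert frac_ok >= 0.90

    def test_null_standardized_scores_near_unit_variance(self):
        fx = residual_fixture(delta=0.0, seed=28)
        model = fx.fit()
        z = model.score / model.score_se
        assert 0.8 <= np.std(z) <= 1.25

    def test_spike_in_recovery(self):
        fx = residual_fixture(delta=0.005, seed=22)
        model = fx.fit()
        i = model.pair_record("I0", "I1")
        assert abs(model.score[i] - 0.005) < 2 * model.score_se[i]

    def test_degenerate_single_source(self):
        # K=1: every pair's fitted value is the single matrix entry
        ids = ["A", "B", "C"]
        alphas = {i: np.array([1.0]) for i in ids}
        f3o = {frozenset(p): 0.12 for p in [("A", "B"), ("A", "C"), ("B", "C")]}
        f3v = {k: 1e-6 for k in f3o}
        model = fit_source_f3_matrix(ids, alphas, f3o, f3v)
        assert model.M[0, 0] == pytest.approx(0.12, abs=1e-12)
        assert np.allclose(model.score, 0.0, atol=1e-12)

    def test_underdetermined_error(self):
        ids = ["A", "B"]
        alphas = {i: np.array([0.5, 0.3, 0.2]) for i in ids}
        f3o = {frozenset(("A", "B")): 0.1}
        f3v = {frozenset(("A", "B")): 1e-6}
        with pytest.raises(UnderdeterminedError):
            fit_source_f3_matrix(ids, alphas, f3o, f3v)

    def test_score_is_negative_residual(self):
        fx = residual_fixture(delta=0.0, seed=23, n_snps=5000)
        model = fx.fit()
        assert np.allclose(model.score, -model.residual)

    def test_spike_monotonicity(self):
        scores = []
        for delta in (0.002, 0.005, 0.01):
            fx = residual_fixture(delta=delta, seed=24)
            model = fx.fit()
            scores.append(model.score[model.pair_record("I0", "I1")])
        assert scores[0] < scores[1] < scores[2]


class TestExcessResiduals:
    def test_kin_pair_excluded(self):
        fx = residual_fixture(seed=25, n_snps=5000)
        model = fx.fit()
        with pytest.warns(UserWarning, match="excluded"):
            records, excluded = excess_relatedness_residuals(model, [("I0", "I1")])
        assert ("I0", "I1") in excluded or ("I1", "I0") in excluded
        assert len(records) == len(model.pairs) - 1
        assert not any({r[0], r[1]} == {"I0", "I1"} for r in records)

    def test_null_mean_zero_t_test(self):
        from scipy import stats

        fx = residual_fixture(delta=0.0, seed=26)
        model = fx.fit()
        records, _ = excess_relatedness_residuals(model)
        scores = np.array([r[2] for r in records])
        t = scores.mean() / (scores.std(ddof=1) / math.sqrt(len(scores)))
        assert abs(t) < stats.t.ppf(1 - 0.005, len(scores) - 1)

    def test_zero_lock_is_noop(self):
        fx = residual_fixture(seed=27, n_snps=5000)
        m1 = fx.fit()
        m2 = fx.fit(locked={k: 0.0 for k in fx.f3o})
        assert np.allclose(m1.score, m2.score)


def kin_read_counts(seed=0, n=30_000, lam=5.0):
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.9, n)
    gA = rng.binomial(2, p)
    gB = rng.binomial(2, p)
    child = rng.binomial(1, gA / 2.0) + rng.binomial(1, p)

    def reads(g):
        d = rng.poisson(lam, n)
        r1 = rng.binomial(d, g / 2.0)
        return r1, d - r1

    cols = [reads(g) for g in (gA, gA, gB, child)]
    return ReadCountTable(
        np.column_stack([c[0] for c in cols]),
        np.column_stack([c[1] for c in cols]),
        individuals=[IndividualRecord(i) for i in ("A", "Adup", "B", "C")],
    )


class TestPairwiseMismatch:
    @pytest.fixture(scope="class")
    def rc(self):
        return kin_read_counts(seed=31)

    def test_duplicate_ratio_one(self, rc):
        k = pairwise_mismatch(rc, ("A", "Adup"), seed=1)
        assert k.ratio == pytest.approx(1.0, abs=0.03)
        assert k.band == "duplicate"

    def test_unrelated_ratio_two(self, rc):
        k = pairwise_mismatch(rc, ("A", "B"), seed=2)
        assert k.ratio == pytest.approx(2.0, abs=0.1)
        assert k.band == "unrelated"

    def test_parent_child_intermediate(self, rc):
        k = pairwise_mismatch(rc, ("A", "C"), seed=3)
        assert 1.25 < k.ratio < 1.75
        assert k.band == "related"

    def test_insufficient_overlap(self):
        rc = kin_read_counts(seed=32, n=500)
        with pytest.raises(InsufficientDataError, match="overlapping"):
            pairwise_mismatch(rc, ("A", "B"), seed=4)

    def test_rates_in_unit_interval(self, rc):
        k = pairwise_mismatch(rc, ("A", "B"), seed=5)
        assert 0.0 <= k.pairwise_rate <= 1.0
        assert all(0.0 <= r <= 1.0 for r in k.within_rates)
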