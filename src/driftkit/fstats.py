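"""Block-jackknifed f-statistics and consistent f2-basis estimation under
missing data.

Statistics are computed from population allele frequencies with the standard
finite-sample bias corrections: f2 subtracts the sampling-variance term
h/n of both populations, f3 that of its target, and f4 needs none.  Each
statistic can be evaluated on its own maximal SNP set (``allsnps`` mode),
and a consistent basis of f2 parameters can be solved from all raw f2/f3/f4
statistics jointly by weighted least squares on the identities

    f3(X; Y, Z)   = (f2(X,Y) + f2(X,Z) - f2(Y,Z)) / 2
    f4(A, B; C, D) = (f2(A,D) + f2(B,C) - f2(A,C) - f2(B,D)) / 2
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .io_formats import MISSING, GenotypeTable, SnpRecord
from .jackknife import jackknife_cov, jackknife_se

DEFAULT_BLOCK_MORGANS = 0.05


class NoOverlapError(ValueError):
    """No SNP has data in every population of the requested statistic."""


@dataclass
class BlockPartition:
    """Contiguous SNP index blocks, never spanning chromosomes."""

    starts: np.ndarray  # (B,) first SNP index of each block
    ends: np.ndarray  # (B,) one-past-last SNP index
    chroms: list[str]
    block_size: float = DEFAULT_BLOCK_MORGANS

    @property
    def n_blocks(self) -> int:
        return len(self.starts)

    @property
    def snp_counts(self) -> np.ndarray:
        return self.ends - self.starts


def build_blocks(snps: list[SnpRecord], block_size_morgans: float = DEFAULT_BLOCK_MORGANS) -> BlockPartition:
    """Greedy partition of SNPs into blocks of >= ``block_size_morgans``
    genetic length; the last block of each chromosome may be short."""
    starts, ends, chroms = [], [], []
    i = 0
    n = len(snps)
    while i < n:
        chrom = snps[i].chrom
        g0 = snps[i].genetic_pos
        j = i
        while j < n and snps[j].chrom == chrom and snps[j].genetic_pos < g0 + block_size_morgans:
            j += 1
        starts.append(i)
        ends.append(j)
        chroms.append(chrom)
        i = j
    return BlockPartition(
        starts=np.array(starts, dtype=int),
        ends=np.array(ends, dtype=int),
        chroms=chroms,
        block_size=block_size_morgans,
    )


@dataclass
class BlockedStat:
    kind: str  # f2 | f3 | f4
    pops: tuple[str, ...]
    estimate: float
    jackknife_se: float
    n_snps_used: int
    loo: np.ndarray  # (B,) delete-one-block estimates
    block_weights: np.ndarray  # (B,)

    @property
    def z(self) -> float:
        if self.jackknife_se > 0:
            return self.estimate / self.jackknife_se
        return np.nan


class StatEngine:
    """Per-population allele frequencies plus block machinery, reused across
    many statistics on one genotype table."""

    def __init__(self, table: GenotypeTable, populations, blocks: BlockPartition | None = None):
        self.table = table
        self.blocks = blocks if blocks is not None else build_blocks(table.snps)
        self.pops = list(dict.fromkeys(populations))
        self.freq: dict[str, np.ndarray] = {}
        self.corr: dict[str, np.ndarray] = {}
        self.has_data: dict[str, np.ndarray] = {}
        for pop in self.pops:
            p, c, m = self._pop_freq(pop)
            self.freq[pop] = p
            self.corr[pop] = c
            self.has_data[pop] = m

    def _pop_freq(self, pop: str):
        cols = self.table.pop_columns(pop)
        G = self.table.G[:, cols].astype(float)
        G[G == MISSING] = np.nan
        a = np.zeros(self.table.n_snps)
        n = np.zeros(self.table.n_snps)
        for k, j in enumerate(cols):
            g = G[:, k]
            ok = ~np.isnan(g)
            if self.table.individuals[j].ploidy_mode == "pseudohaploid":
                a[ok] += g[ok] / 2.0
                n[ok] += 1.0
            else:
                a[ok] += g[ok]
                n[ok] += 2.0
        mask = n > 0
        p = np.full(self.table.n_snps, np.nan)
        p[mask] = a[mask] / n[mask]
        # h/n with h = a(n-a)/(n(n-1)), the unbiased estimate of p(1-p);
        # zero when n < 2 (correction not estimable from one allele)
        corr = np.zeros(self.table.n_snps)
        est = n >= 2
        corr[est] = a[est] * (n[est] - a[est]) / (n[est] * (n[est] - 1.0)) / n[est]
        return p, corr, mask

    def persnp(self, kind: str, pops: tuple[str, ...]):
        """Per-SNP statistic values and validity mask."""
        f, c = self.freq, self.corr
        mask = np.ones(self.table.n_snps, dtype=bool)
        for pop in pops:
            mask &= self.has_data[pop]
        if kind == "f2":
            X, Y = pops
            vals = (f[X] - f[Y]) ** 2 - c[X] - c[Y]
        elif kind == "f3":
            X, Y, Z = pops
            vals = (f[X] - f[Y]) * (f[X] - f[Z]) - c[X]
        elif kind == "f4":
            A, B, C, D = pops
            vals = (f[A] - f[B]) * (f[C] - f[D])
        else:
            raise ValueError(f"unknown statistic kind {kind!r}")
        vals = np.where(mask, vals, 0.0)
        return vals, mask

    def block_sums(self, kind: str, pops: tuple[str, ...], extra_mask=None):
        vals, mask = self.persnp(kind, pops)
        if extra_mask is not None:
            mask = mask & extra_mask
            vals = np.where(mask, vals, 0.0)
        starts = self.blocks.starts
        S = np.add.reduceat(vals, starts) if len(starts) else np.array([])
        C = np.add.reduceat(mask.astype(float), starts) if len(starts) else np.array([])
        return S, C

    def blocked_stat(self, kind: str, pops: tuple[str, ...], extra_mask=None) -> BlockedStat:
        S, C = self.block_sums(kind, pops, extra_mask)
        tot_c = C.sum()
        if tot_c == 0:
            raise NoOverlapError(f"no overlapping SNPs for {kind}{pops}")
        est = S.sum() / tot_c
        with np.errstate(invalid="ignore", divide="ignore"):
            loo = (S.sum() - S) / (tot_c - C)
        loo = np.where(np.isfinite(loo), loo, est)
        se = jackknife_se(est, loo, C)
        return BlockedStat(
            kind=kind,
            pops=tuple(pops),
            estimate=float(est),
            jackknife_se=float(se),
            n_snps_used=int(tot_c),
            loo=loo,
            block_weights=C,
        )


def compute_fstat(
    table: GenotypeTable,
    spec: tuple[str, tuple[str, ...]],
    blocks: BlockPartition | None = None,
    snp_mode: str = "allsnps",
) -> BlockedStat:
    """Compute one block-jackknifed f-statistic.

    ``spec`` is ``(kind, populations)`` with kind in {f2, f3, f4}.  In
    ``allsnps`` mode each statistic uses every SNP where all of its own
    populations have data; ``intersection`` restricts to SNPs with data in
    all populations passed to the call (identical for a single statistic).
    """
    kind, pops = spec
    if snp_mode not in ("allsnps", "intersection"):
        raise ValueError("snp_mode must be 'allsnps' or 'intersection'")
    engine = StatEngine(table, pops, blocks)
    return engine.blocked_stat(kind, tuple(pops))


@dataclass
class FBasis:
    """Consistent f2 basis: all pairwise f2 parameters with jackknife
    covariance and per-block solutions."""

    populations: list[str]
    basis: np.ndarray  # (P,) free f2 entries, P = n(n-1)/2
    cov: np.ndarray  # (P, P)
    loo_basis: np.ndarray  # (B, P) delete-one-block solutions
    block_weights: np.ndarray  # (B,)
    n_snps: int

    def pair_index(self, x: str, y: str) -> tuple[int, float]:
        i, j = self.populations.index(x), self.populations.index(y)
        if i == j:
            raise ValueError("f2 of a population with itself is zero by definition")
        if i > j:
            i, j = j, i
        n = len(self.populations)
        # position of (i, j), i<j, in row-major upper-triangle order
        idx = i * n - i * (i + 1) // 2 + (j - i - 1)
        return idx, 1.0

    @property
    def f2_matrix(self) -> np.ndarray:
        n = len(self.populations)
        M = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            idx, _ = self.pair_index(self.populations[i], self.populations[j])
            M[i, j] = M[j, i] = self.basis[idx]
        return M

    def coeffs(self, kind: str, pops: tuple[str, ...]) -> np.ndarray:
        """Linear coefficients expressing a statistic in the f2 basis."""
        c = np.zeros(len(self.basis))

        def add(x, y, w):
            if x == y:
                return
            idx, _ = self.pair_index(x, y)
            c[idx] += w

        if kind == "f2":
            X, Y = pops
            add(X, Y, 1.0)
        elif kind == "f3":
            X, Y, Z = pops
            add(X, Y, 0.5)
            add(X, Z, 0.5)
            add(Y, Z, -0.5)
        elif kind == "f4":
            A, B, C, D = pops
            add(A, D, 0.5)
            add(B, C, 0.5)
            add(A, C, -0.5)
            add(B, D, -0.5)
        else:
            raise ValueError(f"unknown statistic kind {kind!r}")
        return c


def _enumerate_stats(pops: list[str]):
    """All raw f2/f3/f4 statistics among a population list (f4 up to its
    symmetry f4(A,B;C,D) = f4(C,D;A,B))."""
    stats = []
    for x, y in itertools.combinations(pops, 2):
        stats.append(("f2", (x, y)))
    for x in pops:
        rest = [p for p in pops if p != x]
        for y, z in itertools.combinations(rest, 2):
            stats.append(("f3", (x, y, z)))
    pairs = list(itertools.combinations(range(len(pops)), 2))
    for ia, pair1 in enumerate(pairs):
        for pair2 in pairs[ia + 1 :]:
            if set(pair1) & set(pair2):
                continue
            a, b = pair1
            c, d = pair2
            stats.append(("f4", (pops[a], pops[b], pops[c], pops[d])))
    return stats


def qpfstats_solve(
    table: GenotypeTable,
    populations,
    blocks: BlockPartition | None = None,
    snp_mode: str = "allsnps",
) -> FBasis:
    """Solve a consistent f2 basis from all raw f2/f3/f4 statistics.

    Every raw statistic is computed on its own maximal SNP set with a block
    jackknife; the overdetermined linear system mapping the f2 basis to the
    raw statistics is solved by weighted least squares (weights = inverse
    jackknife variances), and the whole solve is repeated deleting each
    block to obtain the basis covariance.
    """
    pops = list(populations)
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    engine = StatEngine(table, pops, blocks)
    B = engine.blocks.n_blocks

    # a population sharing zero SNPs with every other one is unusable
    for p in pops:
        shared = 0
        for q in pops:
            if q != p:
                shared = max(shared, int((engine.has_data[p] & engine.has_data[q]).sum()))
        if shared == 0:
            raise NoOverlapError(f"population {p!r} shares no SNPs with any other population")

    extra_mask = None
    if snp_mode == "intersection":
        extra_mask = np.ones(table.n_snps, dtype=bool)
        for p in pops:
            extra_mask &= engine.has_data[p]

    ref = FBasis(
        populations=pops,
        basis=np.zeros(len(pops) * (len(pops) - 1) // 2),
        cov=np.zeros(0),
        loo_basis=np.zeros(0),
        block_weights=np.zeros(0),
        n_snps=0,
    )
    rows, ests, loos, variances = [], [], [], []
    union_mask = np.zeros(table.n_snps, dtype=bool)
    for kind, spops in _enumerate_stats(pops):
        try:
            stat = engine.blocked_stat(kind, spops, extra_mask)
        except NoOverlapError:
            continue
        rows.append(ref.coeffs(kind, spops))
        ests.append(stat.estimate)
        loos.append(stat.loo)
        variances.append(stat.jackknife_se**2)
        _, mask = engine.persnp(kind, spops)
        union_mask |= mask

    X = np.array(rows)  # (R, P)
    y = np.array(ests)
    var = np.maximum(np.array(variances), 1e-30)
    w = 1.0 / var
    XtW = X.T * w
    A = XtW @ X
    A_pinv = np.linalg.pinv(A, rcond=1e-10)
    solver = A_pinv @ XtW  # (P, R)
    beta = solver @ y

    Y_loo = np.array(loos)  # (R, B)
    beta_loo = (solver @ Y_loo).T  # (B, P)

    weights = engine.blocks.snp_counts.astype(float)
    cov = jackknife_cov(beta, beta_loo, weights)
    return FBasis(
        populations=pops,
        basis=beta,
        cov=cov,
        loo_basis=beta_loo,
        block_weights=weights,
        n_snps=int(union_mask.sum()),
    )


def derive_stat(basis: FBasis, spec: tuple[str, tuple[str, ...]]) -> BlockedStat:
    """Derive any f2/f3/f4 statistic (with propagated se) from an f2 basis."""
    kind, pops = spec
    for p in pops:
        if p not in basis.populations:
            raise KeyError(f"population {p!r} not in basis")
    c = basis.coeffs(kind, tuple(pops))
    est = float(c @ basis.basis)
    se = float(np.sqrt(max(c @ basis.cov @ c, 0.0)))
    loo = basis.loo_basis @ c
    return BlockedStat(
        kind=kind,
        pops=tuple(pops),
        estimate=est,
        jackknife_se=se,
        n_snps_used=basis.n_snps,
        loo=loo,
        block_weights=basis.block_weights,
    )


def fstat_vector_loo(source, specs, blocks=None):
    """Estimates and delete-one-block estimates for a list of statistics.

    ``source`` may be a GenotypeTable (direct allsnps computation) or an
    FBasis (statistics derived from the basis).  Returns
    (estimates (D,), loo (B, D), block_weights (B,)).
    """
    if isinstance(source, FBasis):
        stats = [derive_stat(source, s) for s in specs]
    else:
        pops = list(dict.fromkeys(p for _, ps in specs for p in ps))
        engine = StatEngine(source, pops, blocks)
        stats = [engine.blocked_stat(kind, tuple(ps)) for kind, ps in specs]
    est = np.array([s.estimate for s in stats])
    loo = np.column_stack([s.loo for s in stats])
    weights = stats[0].block_weights
    if not isinstance(source, FBasis):
        # common weighting across statistics: total SNPs per block
        weights = engine.blocks.snp_counts.astype(float)
    return est, loo, weights
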