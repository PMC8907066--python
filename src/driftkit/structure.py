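"""Ancestry structure analyses: rank tests for the number of ancestry
streams, mixture-proportion fitting, the independent-mixture outgroup-f3
residual model ("excess relatedness"), and allele-mismatch kin detection.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

from .fstats import FBasis, fstat_vector_loo
from .io_formats import ReadCountTable
from .jackknife import jackknife_cov


class IllConditionedError(ValueError):
    pass


class UnderdeterminedError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# rank test


@dataclass
class RankResult:
    k: int
    chisq: float
    dof: int
    tail_p: float


@dataclass
class RankTestResult:
    left: list[str]
    right: list[str]
    ranks: list[RankResult]
    taildiff_p: dict[int, float]  # k -> P comparing ranks k and k+1

    def rank(self, k: int) -> RankResult:
        return self.ranks[k]


def _regularized_inverse(Q: np.ndarray) -> np.ndarray:
    ev = np.linalg.eigvalsh(Q)
    if ev[0] <= 0 or ev[-1] / max(ev[0], 1e-300) > 1e12:
        warnings.warn("near-singular f4 covariance; using regularized inverse")
        ridge = max(ev[-1], 1e-300) * 1e-9
        Q = Q + ridge * np.eye(len(Q))
    return linalg.pinvh(Q)


def _rank_k_chisq(x: np.ndarray, Qinv: np.ndarray, Lm: int, Rm: int, k: int) -> float:
    """Minimize (x - vec(A B^T))' Qinv (x - vec(A B^T)) over rank-k matrices
    by alternating generalized least squares.  ``x`` is the row-major vec of
    the (Lm x Rm) f4 matrix."""
    if k == 0:
        return float(x @ Qinv @ x)
    if k >= min(Lm, Rm):
        return 0.0
    X = x.reshape(Lm, Rm)
    _, _, Vt = np.linalg.svd(X)
    Bmat = Vt[:k].T  # (Rm, k)

    def gls(D):
        A = D.T @ Qinv @ D
        return np.linalg.pinv(A, rcond=1e-12) @ (D.T @ Qinv @ x)

    chisq_prev = np.inf
    for _ in range(500):
        # solve for A given B: vec_row(A B^T) = kron(I_Lm, B) vec_row(A)
        DA = np.kron(np.eye(Lm), Bmat)  # (Lm*Rm, Lm*k)
        a = gls(DA)
        Amat = a.reshape(Lm, k)
        # solve for B given A
        DB = np.zeros((Lm * Rm, Rm * k))
        for i in range(Lm):
            for j in range(Rm):
                DB[i * Rm + j, j * k : (j + 1) * k] = Amat[i]
        b = gls(DB)
        Bmat = b.reshape(Rm, k)
        r = x - (Amat @ Bmat.T).reshape(-1)
        chisq = float(r @ Qinv @ r)
        if abs(chisq_prev - chisq) < 1e-12 * (1.0 + abs(chisq)):
            break
        chisq_prev = chisq
    return max(chisq, 0.0)


def rank_test(source, left, right, max_rank: int | None = None, blocks=None) -> RankTestResult:
    """Test how many ancestry streams relate ``left`` test populations to
    ``right`` outgroups, via the rank of the f4 matrix
    X_ij = f4(l_i, l_0; r_j, r_0).  Rank k implies k+1 ancestry sources.

    ``source`` is a GenotypeTable or an FBasis.
    """
    left, right = list(left), list(right)
    L, R = len(left), len(right)
    if L < 2:
        raise ValueError("need at least 2 test populations")
    if R < L:
        raise ValueError("need at least as many outgroups as test populations")
    Lm, Rm = L - 1, R - 1
    specs = [
        ("f4", (li, left[0], rj, right[0]))
        for li in left[1:]
        for rj in right[1:]
    ]
    est, loo, weights = fstat_vector_loo(source, specs, blocks)
    Q = jackknife_cov(est, loo, weights)
    Qinv = _regularized_inverse(Q)
    if max_rank is None:
        max_rank = min(Lm, Rm)
    ranks = []
    for k in range(max_rank + 1):
        dof = (Lm - k) * (Rm - k)
        chisq = _rank_k_chisq(est, Qinv, Lm, Rm, k)
        tail_p = float(stats.chi2.sf(chisq, dof)) if dof > 0 else 1.0
        ranks.append(RankResult(k=k, chisq=chisq, dof=dof, tail_p=tail_p))
    taildiff = {}
    for k in range(len(ranks) - 1):
        dchisq = max(ranks[k].chisq - ranks[k + 1].chisq, 0.0)
        ddof = ranks[k].dof - ranks[k + 1].dof
        taildiff[k] = float(stats.chi2.sf(dchisq, ddof)) if ddof > 0 else 1.0
    return RankTestResult(left=left, right=right, ranks=ranks, taildiff_p=taildiff)


# ---------------------------------------------------------------------------
# mixture fitting


@dataclass
class MixtureFit:
    target: str
    sources: list[str]
    alpha: np.ndarray  # (K,), sums to 1 exactly
    se: np.ndarray  # (K,)
    chisq: float
    dof: int
    p_value: float


def _solve_alpha(y, A, Om_inv, K):
    """Constrained GLS for mixture weights: y_j = sum_k alpha_k A_kj with
    sum(alpha) = 1, eliminating the last component."""
    At = A.T  # (M-1, K)
    y_adj = y - At[:, K - 1]
    D = At[:, : K - 1] - At[:, [K - 1]]
    M = D.T @ Om_inv @ D
    z = np.linalg.solve(M, D.T @ Om_inv @ y_adj)
    alpha = np.empty(K)
    alpha[: K - 1] = z
    alpha[K - 1] = 1.0 - z.sum()
    return alpha, D


def fit_mixture(source, target, sources, outgroups, blocks=None) -> MixtureFit:
    """Fit ancestry proportions of ``target`` as a mixture of ``sources``
    using f4 statistics against a panel of outgroups.

    Solves y_j = sum_k alpha_k A_kj with sum(alpha) = 1 by generalized least
    squares, where y_j = f4(T, R_1; R_j, R_1) and A_kj = f4(S_k, R_1; R_j, R_1),
    weighting by the block-jackknife covariance of y.  Standard errors come
    from re-solving on delete-one-block estimates.
    """
    sources = list(sources)
    outgroups = list(outgroups)
    K, M = len(sources), len(outgroups)
    if K < 2:
        raise ValueError("need at least 2 sources")
    if M < K + 1:
        raise ValueError("need at least K+1 outgroups")
    R1 = outgroups[0]
    y_specs = [("f4", (target, R1, rj, R1)) for rj in outgroups[1:]]
    a_specs = [("f4", (sk, R1, rj, R1)) for sk in sources for rj in outgroups[1:]]
    est, loo, weights = fstat_vector_loo(source, y_specs + a_specs, blocks)
    m = M - 1
    y = est[:m]
    A = est[m:].reshape(K, m)
    y_loo = loo[:, :m]
    A_loo = loo[:, m:].reshape(loo.shape[0], K, m)
    Om = jackknife_cov(y, y_loo, weights)
    Om_inv = linalg.pinvh(Om)
    D_check = A.T[:, : K - 1] - A.T[:, [K - 1]]
    if np.linalg.cond(D_check) > 1e8:
        raise IllConditionedError(f"sources {sources} are collinear against the outgroups")
    # a source contrast statistically indistinguishable from zero (e.g. two
    # sources forming a clade relative to all outgroups) is unusable
    for i in range(K):
        for j in range(i + 1, K):
            d = A.T[:, i] - A.T[:, j]
            if d @ Om_inv @ d < 3.0 * (M - 1):
                raise IllConditionedError(
                    f"sources {sources[i]!r} and {sources[j]!r} are not "
                    "distinguishable against the outgroups"
                )
    alpha, D = _solve_alpha(y, A, Om_inv, K)
    loo_alpha = np.array(
        [_solve_alpha(y_loo[b], A_loo[b], Om_inv, K)[0] for b in range(loo.shape[0])]
    )
    cov_alpha = jackknife_cov(alpha, loo_alpha, weights)
    se = np.sqrt(np.maximum(np.diag(cov_alpha), 0.0))
    resid = y - A.T @ alpha
    chisq = float(resid @ Om_inv @ resid)
    dof = (M - 1) - (K - 1)
    p = float(stats.chi2.sf(chisq, dof)) if dof > 0 else 1.0
    if (alpha < 0).any():
        warnings.warn(f"negative mixture proportion estimated for {target}: {alpha}")
    return MixtureFit(
        target=target, sources=sources, alpha=alpha, se=se, chisq=chisq, dof=dof, p_value=p
    )


# ---------------------------------------------------------------------------
# independent-mixture outgroup-f3 residual model


def outgroup_f3_pairs(table, outgroup, targets, blocks=None, return_loo=False):
    """Block-jackknifed f3(outgroup; X, Y) for all unordered target pairs.

    Returns (f3_obs, f3_var) dicts keyed by frozenset({X, Y}), as consumed by
    :func:`fit_source_f3_matrix`.  With ``return_loo`` also returns a dict of
    delete-one-block estimates plus the block weights, enabling a jackknife
    of the downstream residual fit.
    """
    from .fstats import StatEngine

    targets = list(targets)
    engine = StatEngine(table, [outgroup] + targets, blocks)
    f3_obs, f3_var, f3_loo = {}, {}, {}
    for x, y in itertools.combinations(targets, 2):
        stat = engine.blocked_stat("f3", (outgroup, x, y))
        key = frozenset((x, y))
        f3_obs[key] = stat.estimate
        f3_var[key] = stat.jackknife_se**2
        f3_loo[key] = stat.loo
    if return_loo:
        return f3_obs, f3_var, f3_loo, engine.blocks.snp_counts.astype(float)
    return f3_obs, f3_var


@dataclass
class SourceF3Model:
    """Fitted source-pair outgroup-f3 model.  For targets X, Y with mixture
    rows alpha_X, alpha_Y, the fitted statistic is alpha_X' M alpha_Y; the
    excess score is observed - fitted (positive = excess sharing) and the
    residual is its negation (fitted - observed)."""

    outgroup: str
    sources: list[str]
    M: np.ndarray  # (K, K) symmetric
    pairs: list[tuple[str, str]]
    observed: np.ndarray
    fitted: np.ndarray
    se: np.ndarray  # jackknife se of the observed f3 alone
    score_se: np.ndarray | None = None  # jackknife se of score incl. fit noise

    @property
    def score(self) -> np.ndarray:
        """Excess sharing: observed - fitted."""
        return self.observed - self.fitted

    @property
    def residual(self) -> np.ndarray:
        """fitted - observed (equal to -score)."""
        return self.fitted - self.observed

    def pair_record(self, x: str, y: str):
        for i, (a, b) in enumerate(self.pairs):
            if {a, b} == {x, y}:
                return i
        raise KeyError((x, y))


def fit_source_f3_matrix(
    targets,
    alphas,
    f3_obs,
    f3_var,
    outgroup: str = "Outgroup",
    sources=None,
    locked=None,
    f3_loo=None,
    block_weights=None,
) -> SourceF3Model:
    """Fit the symmetric source-pair matrix M of outgroup-f3 values under the
    independent-mixture model f3(O; X, Y) ~ alpha_X' M alpha_Y.

    Parameters
    ----------
    targets : labels X
    alphas : dict label -> (K,) mixture proportions (fitted or truth)
    f3_obs, f3_var : dicts keyed by frozenset({X, Y}) for X != Y
    locked : optional dict keyed like f3_obs with a fixed contribution
        (e.g. from extra admixture components locked upstream) subtracted
        from the observed value before fitting.
    f3_loo, block_weights : optional delete-one-block f3 estimates (from
        :func:`outgroup_f3_pairs` with ``return_loo=True``); when supplied,
        the whole fit is repeated per block and the excess score gets a
        jackknife se that includes the fit's own noise (``score_se``) —
        observed and fitted values share drift-realization noise, so the
        observed-f3 se alone misstates the score's uncertainty.
    """
    targets = list(targets)
    K = len(next(iter(alphas.values())))
    if sources is None:
        sources = [f"S{k + 1}" for k in range(K)]
    pairs = [
        (x, y) for x, y in itertools.combinations(targets, 2) if frozenset((x, y)) in f3_obs
    ]
    n_free = K * (K + 1) // 2
    if len(pairs) < n_free:
        raise UnderdeterminedError(
            f"{len(pairs)} usable pairs < {n_free} free matrix entries"
        )
    obs = np.array(
        [
            f3_obs[frozenset(p)] - (locked.get(frozenset(p), 0.0) if locked else 0.0)
            for p in pairs
        ]
    )
    var = np.array([f3_var[frozenset(p)] for p in pairs])
    w = 1.0 / np.maximum(var, 1e-30)
    # design over vech(M), diagonal first-class: entry (k,l), k<=l
    idx = [(k, l) for k in range(K) for l in range(k, K)]
    X = np.zeros((len(pairs), len(idx)))
    for r, (a, b) in enumerate(pairs):
        ax, ay = np.asarray(alphas[a], float), np.asarray(alphas[b], float)
        for cidx, (k, l) in enumerate(idx):
            if k == l:
                X[r, cidx] = ax[k] * ay[k]
            else:
                X[r, cidx] = ax[k] * ay[l] + ax[l] * ay[k]
    XtW = X.T * w
    G = XtW @ X
    if np.linalg.matrix_rank(G, tol=1e-12 * max(np.trace(G), 1e-30)) < len(idx):
        raise UnderdeterminedError("source-pair design matrix is rank-deficient")
    P_op = np.linalg.pinv(G, rcond=1e-10) @ XtW  # (n_free, n_pairs)
    m = P_op @ obs
    M = np.zeros((K, K))
    for cidx, (k, l) in enumerate(idx):
        M[k, l] = M[l, k] = m[cidx]
    fitted = X @ m
    score_se = None
    if f3_loo is not None:
        loo = np.column_stack([f3_loo[frozenset(p)] for p in pairs])  # (B, n_pairs)
        if locked:
            loo = loo - np.array([locked.get(frozenset(p), 0.0) for p in pairs])
        score_loo = loo - loo @ (X @ P_op).T  # per-block refit of M
        score = obs - fitted
        cov = jackknife_cov(score, score_loo, np.asarray(block_weights, float))
        score_se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return SourceF3Model(
        outgroup=outgroup,
        sources=list(sources),
        M=M,
        pairs=pairs,
        observed=obs,
        fitted=fitted,
        se=np.sqrt(var),
        score_se=score_se,
    )


def excess_relatedness_residuals(model: SourceF3Model, exclude_pairs=()):
    """Emit (id1, id2, excess score, variance) records for the spatial decay
    fit, dropping pairs flagged as close kin.

    Returns (records, excluded) where excluded lists the dropped pairs.
    """
    excl = {frozenset(p) for p in exclude_pairs}
    ses = model.score_se if model.score_se is not None else model.se
    records, excluded = [], []
    for i, (x, y) in enumerate(model.pairs):
        if frozenset((x, y)) in excl:
            excluded.append((x, y))
            continue
        records.append((x, y, float(model.score[i]), float(ses[i] ** 2)))
    if excluded:
        warnings.warn(f"excluded kin-flagged pairs: {excluded}")
    return records, excluded


# ---------------------------------------------------------------------------
# kin detection


@dataclass
class KinResult:
    pair: tuple[str, str]
    pairwise_rate: float
    within_rates: tuple[float, float]
    ratio: float
    band: str  # duplicate | related | unrelated
    n_sites: int


DUPLICATE_MAX_RATIO = 1.25
UNRELATED_MIN_RATIO = 1.75


def pairwise_mismatch(
    counts: ReadCountTable, pair, seed: int, min_sites: int = 1000
) -> KinResult:
    """Allele-mismatch kin test: the rate of mismatching alleles when one
    read is sampled per individual per site, compared against two-read draws
    within each individual.  Unrelated pairs mismatch about twice as often
    as within-individual draws; duplicates match them; relatives fall in
    between.
    """
    if counts.individuals is None:
        raise ValueError("read-count table lacks individual metadata")
    ids = [ind.ind_id for ind in counts.individuals]
    j1, j2 = ids.index(pair[0]), ids.index(pair[1])
    rng = np.random.default_rng(seed)
    n1 = counts.n_allele1
    tot = counts.total
    both = (tot[:, j1] > 0) & (tot[:, j2] > 0)
    n_sites = int(both.sum())
    if n_sites < min_sites:
        raise InsufficientDataError(
            f"only {n_sites} overlapping sites (< {min_sites}) for pair {pair}"
        )
    p1 = n1[both, j1] / tot[both, j1]
    p2 = n1[both, j2] / tot[both, j2]
    a1 = rng.random(n_sites) < p1
    a2 = rng.random(n_sites) < p2
    pairwise_rate = float(np.mean(a1 != a2))

    within = []
    for j in (j1, j2):
        sites = tot[:, j] >= 2
        t = tot[sites, j].astype(float)
        x = n1[sites, j].astype(float)
        # two reads drawn without replacement
        p_mismatch = 2.0 * x * (t - x) / (t * (t - 1.0))
        draws = rng.random(len(t)) < p_mismatch
        within.append(float(np.mean(draws)))
    baseline = float(np.mean(within))
    ratio = pairwise_rate / baseline if baseline > 0 else np.inf
    if ratio < DUPLICATE_MAX_RATIO:
        band = "duplicate"
    elif ratio > UNRELATED_MIN_RATIO:
        band = "unrelated"
    else:
        band = "related"
    return KinResult(
        pair=tuple(pair),
        pairwise_rate=pairwise_rate,
        within_rates=(within[0], within[1]),
        ratio=float(ratio),
        band=band,
        n_sites=n_sites,
    )
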