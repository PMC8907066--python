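"""Runs-of-homozygosity calling from genotype likelihoods and recent
effective-population-size inference from ROH length spectra.

The caller is a two-state HMM (non-ROH / ROH) decoded by Viterbi, in the
style of likelihood-based ROH callers for unphased low-coverage data: the
non-ROH state emits genotypes under Hardy-Weinberg priors at a single
default allele frequency, the ROH state allows heterozygotes only at a
small error rate, and switch probabilities scale with the physical gap
between sites.

Ne inference models post-filter block lengths l (Morgans) as an
inhomogeneous Poisson process with intensity

    lambda(l; N) = sum_g pi_g(N) * sum_i [ (2g)^2 max(G_i - l, 0) + 4g ] e^{-2gl}
    pi_g(N)      = (1/2N) (1 - 1/2N)^{g-1}

over chromosomes of genetic length G_i, maximized over N with a
profile-likelihood 95% CI whose upper limit may be unbounded.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .io_formats import LikelihoodTable


@dataclass
class RohBlock:
    chrom: str
    start_bp: int
    end_bp: int
    start_cm: float
    end_cm: float
    n_het_inside: int = 0

    def __post_init__(self):
        if self.end_bp <= self.start_bp:
            raise ValueError("block end must exceed start")

    @property
    def length_cm(self) -> float:
        return self.end_cm - self.start_cm


@dataclass
class RohCallerConfig:
    default_af: float = 0.4  # frequency of allele2 (the 'alt' allele)
    het_error: float = 1e-3  # P(apparent het) inside ROH
    rate_hw_to_az: float = 6.7e-8  # per bp
    rate_az_to_hw: float = 5e-9  # per bp
    cm_per_mb: float = 1.0  # constant-rate physical->genetic conversion

    def __post_init__(self):
        for name in ("default_af", "het_error"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0,1)")


#: human-autosome-like genetic lengths in Morgans (22 chromosomes, ~35 M)
_DEFAULT_CHROM_MORGANS = (
    2.87, 2.69, 2.23, 2.14, 2.04, 1.92, 1.87, 1.70, 1.68, 1.81,
    1.58, 1.75, 1.26, 1.19, 1.41, 1.34, 1.29, 1.17, 1.08, 1.08,
    0.62, 0.74,
)


@dataclass
class GenomeSpec:
    chrom_lengths_morgans: tuple[float, ...] = _DEFAULT_CHROM_MORGANS

    def __post_init__(self):
        if any(g <= 0 for g in self.chrom_lengths_morgans):
            raise ValueError("chromosome genetic lengths must be positive")

    @property
    def n_chrom(self) -> int:
        return len(self.chrom_lengths_morgans)

    @property
    def total_morgans(self) -> float:
        return float(sum(self.chrom_lengths_morgans))


@dataclass
class NeEstimate:
    ne: float
    ci_low: float
    ci_high: float  # may be math.inf (unbounded)
    window_cm: tuple[float, float]
    n_blocks: int

    def __post_init__(self):
        if not self.ci_low <= self.ne <= self.ci_high:
            raise ValueError("CI must bracket the MLE")


# ---------------------------------------------------------------------------
# HMM caller


def call_roh(pl: LikelihoodTable, config: RohCallerConfig | None = None, individual=None):
    """Call ROH blocks for one individual from Phred-scaled likelihoods.

    Sites must be sorted by position within each chromosome.  Returns a list
    of :class:`RohBlock` (unfiltered; see :func:`postprocess_blocks`).
    """
    if config is None:
        config = RohCallerConfig()
    if pl.snps is None:
        raise ValueError("likelihood table lacks SNP metadata")
    if individual is None:
        if pl.PL.shape[1] != 1:
            raise ValueError("specify the individual for a multi-sample table")
        col = 0
    else:
        ids = [ind.ind_id for ind in pl.individuals]
        col = ids.index(individual)

    lik = 10.0 ** (-pl.PL[:, col, :] / 10.0)  # (S, 3)
    af = config.default_af
    hw_prior = np.array([(1 - af) ** 2, 2 * af * (1 - af), af**2])
    az_prior = np.array(
        [(1 - config.het_error) * (1 - af), config.het_error, (1 - config.het_error) * af]
    )
    with np.errstate(divide="ignore"):
        e_hw = np.log(lik @ hw_prior)
        e_az = np.log(lik @ az_prior)
    het_call = (np.argmin(pl.PL[:, col, :], axis=1) == 1) & (
        np.ptp(pl.PL[:, col, :], axis=1) > 0
    )

    blocks: list[RohBlock] = []
    chroms = [s.chrom for s in pl.snps]
    pos = np.array([s.physical_pos for s in pl.snps], dtype=float)
    start = 0
    for end in range(1, len(chroms) + 1):
        if end == len(chroms) or chroms[end] != chroms[start]:
            idx = np.arange(start, end)
            if (np.diff(pos[idx]) < 0).any():
                raise ValueError(f"sites unsorted on chromosome {chroms[start]}")
            states = _viterbi(e_hw[idx], e_az[idx], pos[idx], config)
            blocks.extend(
                _states_to_blocks(states, pos[idx], het_call[idx], chroms[start], config)
            )
            start = end
    return blocks


def _viterbi(e_hw, e_az, pos, config):
    n = len(pos)
    gaps = np.diff(pos)
    p_to_az = -np.expm1(-config.rate_hw_to_az * gaps)
    p_to_hw = -np.expm1(-config.rate_az_to_hw * gaps)
    tiny = 1e-300
    lt = np.log(
        np.stack(
            [1.0 - p_to_az + tiny, p_to_az + tiny, p_to_hw + tiny, 1.0 - p_to_hw + tiny],
            axis=1,
        )
    )  # columns: hw->hw, hw->az, az->hw, az->az
    v_hw = math.log(0.5) + e_hw[0]
    v_az = math.log(0.5) + e_az[0]
    back = np.zeros((n, 2), dtype=np.int8)
    for t in range(1, n):
        hh, ha, ah, aa = lt[t - 1]
        from_hw = v_hw + hh
        from_az = v_az + ah
        if from_hw >= from_az:
            new_hw, back[t, 0] = from_hw + e_hw[t], 0
        else:
            new_hw, back[t, 0] = from_az + e_hw[t], 1
        from_hw2 = v_hw + ha
        from_az2 = v_az + aa
        if from_az2 >= from_hw2:
            new_az, back[t, 1] = from_az2 + e_az[t], 1
        else:
            new_az, back[t, 1] = from_hw2 + e_az[t], 0
        v_hw, v_az = new_hw, new_az
    states = np.zeros(n, dtype=np.int8)
    states[-1] = 1 if v_az > v_hw else 0
    for t in range(n - 1, 0, -1):
        states[t - 1] = back[t, states[t]]
    return states


def _states_to_blocks(states, pos, het_call, chrom, config):
    blocks = []
    in_block = False
    for t in range(len(states)):
        if states[t] == 1 and not in_block:
            in_block, first = True, t
        if in_block and (states[t] == 0 or t == len(states) - 1):
            last = t if states[t] == 1 else t - 1
            if last > first:
                sb, eb = int(pos[first]), int(pos[last])
                blocks.append(
                    RohBlock(
                        chrom=chrom,
                        start_bp=sb,
                        end_bp=eb,
                        start_cm=sb * config.cm_per_mb / 1e6,
                        end_cm=eb * config.cm_per_mb / 1e6,
                        n_het_inside=int(het_call[first : last + 1].sum()),
                    )
                )
            in_block = False
    return blocks


def postprocess_blocks(
    blocks,
    het_sites=None,
    min_length_cm: float = 4.0,
    max_gap_cm: float = 0.5,
    max_gap_hets: int = 2,
):
    """Merge adjacent blocks separated by a gap < 0.5 cM containing at most
    two apparent heterozygous sites, then retain only blocks > 4 cM.

    ``het_sites`` optionally lists (chrom, cm) of apparent het calls used to
    count hets within gaps; blocks' own ``n_het_inside`` is preserved and
    summed on merge.  Idempotent.
    """
    by_chrom: dict[str, list[RohBlock]] = {}
    for b in sorted(blocks, key=lambda b: (b.chrom, b.start_cm)):
        by_chrom.setdefault(b.chrom, []).append(b)
    hets = sorted(het_sites) if het_sites else []
    out = []
    for chrom, blist in by_chrom.items():
        merged = [blist[0]]
        for b in blist[1:]:
            prev = merged[-1]
            gap = b.start_cm - prev.end_cm
            gap_hets = sum(
                1 for (c, cm) in hets if c == chrom and prev.end_cm < cm < b.start_cm
            )
            if 0 <= gap < max_gap_cm and gap_hets <= max_gap_hets:
                merged[-1] = RohBlock(
                    chrom=chrom,
                    start_bp=prev.start_bp,
                    end_bp=b.end_bp,
                    start_cm=prev.start_cm,
                    end_cm=b.end_cm,
                    n_het_inside=prev.n_het_inside + b.n_het_inside + gap_hets,
                )
            else:
                merged.append(b)
        out.extend(merged)
    return [b for b in out if b.length_cm > min_length_cm]


def flag_long_roh(blocks, long_cm: float = 12.0, total_threshold_cm: float = 100.0) -> bool:
    """Flag an individual whose very long ROH (> ``long_cm``) total more than
    ``total_threshold_cm`` — a signature of close parental relatedness;
    flagged individuals are analyzed on the 4-8 cM window."""
    total = sum(b.length_cm for b in blocks if b.length_cm > long_cm)
    return total > total_threshold_cm


# ---------------------------------------------------------------------------
# Poisson intensity of the ROH length spectrum


G_MAX = 500


def roh_intensity(lengths_morgans, ne: float, genome: GenomeSpec, g_max: int = G_MAX):
    """lambda(l; Ne) evaluated at the given lengths (Morgans)."""
    K = _length_kernel(np.asarray(lengths_morgans, dtype=float), genome, g_max)
    return _pi_g(ne, g_max) @ K


def _pi_g(ne: float, g_max: int) -> np.ndarray:
    if ne < 2:
        raise ValueError("Ne must be >= 2")
    g = np.arange(1, g_max + 1, dtype=float)
    return (1.0 / (2.0 * ne)) * (1.0 - 1.0 / (2.0 * ne)) ** (g - 1.0)


def _length_kernel(lengths: np.ndarray, genome: GenomeSpec, g_max: int) -> np.ndarray:
    """Ne-independent kernel K[g-1, k] = sum_i [(2g)^2 max(G_i - l_k, 0) + 4g] e^{-2g l_k}."""
    G = np.asarray(genome.chrom_lengths_morgans)
    l = lengths[None, :]
    g = np.arange(1, g_max + 1, dtype=float)[:, None]
    span = np.clip(G[:, None] - lengths[None, :], 0.0, None).sum(axis=0)  # (n,)
    nc = genome.n_chrom
    return ((2 * g) ** 2 * span[None, :] + 2 * (2 * g) * nc) * np.exp(-2.0 * g * l)


class RohLikelihood:
    """Poisson-process likelihood of ROH lengths within a window, with the
    Ne-independent pieces precomputed for fast repeated evaluation."""

    def __init__(self, genome: GenomeSpec, window_cm=(4.0, math.inf), g_max: int = G_MAX, n_grid: int = 2048):
        self.genome = genome
        u_cm, v_cm = window_cm
        if not u_cm < v_cm:
            raise ValueError("window must satisfy u < v")
        self.window_cm = (float(u_cm), float(v_cm))
        u = u_cm / 100.0
        v_eff = min(v_cm / 100.0, max(genome.chrom_lengths_morgans))
        self.u_m, self.v_m = u, v_eff
        self.grid = np.linspace(u, v_eff, n_grid)
        self.K_grid = _length_kernel(self.grid, genome, g_max)  # (g_max, n_grid)
        self.K_int = np.trapezoid(self.K_grid, self.grid, axis=1)  # (g_max,)
        self.g_max = g_max

    def in_window(self, lengths_cm) -> np.ndarray:
        l = np.asarray(lengths_cm, dtype=float)
        u, v = self.window_cm
        return l[(l >= u) & (l <= v)]

    def expected_count(self, ne: float) -> float:
        return float(_pi_g(ne, self.g_max) @ self.K_int)

    def loglik(self, ne: float, lengths_cm: np.ndarray) -> float:
        pi = _pi_g(ne, self.g_max)
        ll = -float(pi @ self.K_int)
        if len(lengths_cm):
            K_obs = _length_kernel(np.asarray(lengths_cm) / 100.0, self.genome, self.g_max)
            lam = pi @ K_obs
            if (lam <= 0).any():
                return -math.inf
            ll += float(np.log(lam).sum())
        return ll


NE_SEARCH_RANGE = (2.0, 1e8)
CI_DROP = 1.92  # chi2(1)/2 at 95%


def estimate_ne(
    blocks,
    genome: GenomeSpec | None = None,
    window_cm=(4.0, math.inf),
    g_max: int = G_MAX,
) -> NeEstimate:
    """Maximum-likelihood recent Ne from ROH block lengths in a window.

    ``blocks`` is a list of RohBlock or an array of lengths in cM.  The 95%
    CI comes from the profile likelihood (1.92 log-unit drop); with no finite
    upper crossing the upper limit is reported as unbounded (inf).
    """
    if window_cm[0] < 4.0:
        raise ValueError("window must start at >= 4 cM")
    if genome is None:
        genome = GenomeSpec()
    if len(blocks) and isinstance(blocks[0], RohBlock):
        lengths = np.array([b.length_cm for b in blocks])
    else:
        lengths = np.asarray(blocks, dtype=float)
    model = RohLikelihood(genome, window_cm, g_max)
    lengths = model.in_window(lengths)

    lo, hi = NE_SEARCH_RANGE
    xs = np.linspace(math.log10(lo), math.log10(hi), 240)
    lls = np.array([model.loglik(10.0**x, lengths) for x in xs])
    i_best = int(np.argmax(lls))
    if i_best in (0, len(xs) - 1):
        x_mle = xs[i_best]
    else:
        res = optimize.minimize_scalar(
            lambda x: -model.loglik(10.0**x, lengths),
            bounds=(xs[i_best - 1], xs[i_best + 1]),
            method="bounded",
            options={"xatol": 1e-8},
        )
        x_mle = float(res.x)
    ll_max = model.loglik(10.0**x_mle, lengths)
    thr = ll_max - CI_DROP

    def f(x):
        return model.loglik(10.0**x, lengths) - thr

    x_lo = math.log10(lo)
    ci_low = lo if f(x_lo) >= 0 else 10.0 ** optimize.brentq(f, x_lo, x_mle, xtol=1e-8)
    x_hi = math.log10(hi)
    if f(x_hi) >= 0 or x_mle >= x_hi:
        ci_high = math.inf
    else:
        ci_high = 10.0 ** optimize.brentq(f, x_mle, x_hi, xtol=1e-8)
    return NeEstimate(
        ne=float(10.0**x_mle),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        window_cm=(float(window_cm[0]), float(window_cm[1])),
        n_blocks=int(len(lengths)),
    )
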