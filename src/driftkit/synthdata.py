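"""Synthetic genotype panels with known admixture-graph structure.

Drift along graph edges follows a Balding-Nichols parameterization: a child
frequency is Beta-distributed with mean p and variance F*p*(1-p).  Excess
shared drift between individuals from the same site or cluster is injected
as extra hierarchy levels below the admixture nodes, with the drift
parameter calibrated so that the expected excess outgroup-f3 covariance
equals the requested delta in raw frequency-squared units (the scale on
which f-statistics are computed).
"""
from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    MISSING,
    GenotypeTable,
    IndividualRecord,
    ReadCountTable,
    SnpRecord,
    reads_to_pseudohaploid,
)
from .roh_ne import GenomeSpec, RohLikelihood

DEFAULT_N_SNPS = 100_000
DEFAULT_N_CHROM = 22
CHROM_MORGANS = 1.5  # per synthetic chromosome
CM_PER_MB = 1.0


# ---------------------------------------------------------------------------
# admixture-graph frequency simulation


@dataclass
class GraphSpec:
    """Admixture graph: drift edges (parent, child, F) plus admixture nodes
    mixing their sources with proportions alpha."""

    nodes: list[str]
    edges: list[tuple[str, str, float]] = field(default_factory=list)
    admixtures: list[tuple[str, list[str], list[float]]] = field(default_factory=list)
    root_freq_range: tuple[float, float] = (0.05, 0.95)

    def __post_init__(self):
        for parent, child, F in self.edges:
            if not 0.0 <= F < 1.0:
                raise ValueError(f"edge {parent}->{child}: drift F must be in [0,1)")
        for node, sources, alpha in self.admixtures:
            a = np.asarray(alpha, dtype=float)
            if (a < 0).any() or not math.isclose(a.sum(), 1.0, abs_tol=1e-9):
                raise ValueError(f"admixture node {node}: proportions must be >=0 and sum to 1")
            if len(sources) != len(a):
                raise ValueError(f"admixture node {node}: sources/proportions length mismatch")
        self._check_dag()

    def _check_dag(self):
        parents: dict[str, list[str]] = {n: [] for n in self.nodes}
        for parent, child, _ in self.edges:
            parents[child].append(parent)
        for node, sources, _ in self.admixtures:
            parents[node].extend(sources)
        roots = [n for n in self.nodes if not parents[n]]
        if len(roots) != 1:
            raise ValueError(f"graph must have exactly one root, found {roots}")
        self.root = roots[0]
        # Kahn topological sort
        order, seen = [], set()
        pending = list(self.nodes)
        while pending:
            progressed = False
            for n in list(pending):
                if all(p in seen for p in parents[n]):
                    order.append(n)
                    seen.add(n)
                    pending.remove(n)
                    progressed = True
            if not progressed:
                raise ValueError("admixture graph contains a cycle")
        self.topo_order = order
        self._parents = parents


def _beta_drift(rng: np.random.Generator, p: np.ndarray, F: float) -> np.ndarray:
    """Child frequencies: Beta with mean p, variance F*p*(1-p)."""
    if F == 0.0:
        return p.copy()
    out = p.copy()
    interior = (p > 0.0) & (p < 1.0)
    pi = p[interior]
    scale = (1.0 - F) / F
    out[interior] = rng.beta(pi * scale, (1.0 - pi) * scale)
    return out


def simulate_frequencies(graph: GraphSpec, n_snps: int, seed: int) -> dict[str, np.ndarray]:
    """Allele-1 frequencies per graph node (pure function of (graph, seed))."""
    rng = np.random.default_rng(seed)
    lo, hi = graph.root_freq_range
    freqs: dict[str, np.ndarray] = {}
    edge_by_child = {child: (parent, F) for parent, child, F in graph.edges}
    admix_by_node = {node: (sources, alpha) for node, sources, alpha in graph.admixtures}
    for node in graph.topo_order:
        if node == graph.root:
            freqs[node] = rng.uniform(lo, hi, size=n_snps)
        elif node in admix_by_node:
            sources, alpha = admix_by_node[node]
            p = np.zeros(n_snps)
            for s, a in zip(sources, alpha):
                p += a * freqs[s]
            freqs[node] = p
        elif node in edge_by_child:
            parent, F = edge_by_child[node]
            freqs[node] = _beta_drift(rng, freqs[parent], F)
        else:  # pragma: no cover - unreachable given DAG check
            raise ValueError(f"node {node} has no parent")
    return freqs


def calibrated_drift(rng: np.random.Generator, p: np.ndarray, delta: float) -> np.ndarray:
    """Drift whose expected added covariance is ``delta`` in absolute
    frequency-squared units: F_eff = delta / mean(p(1-p))."""
    if delta == 0.0:
        return p.copy()
    s = float(np.mean(p * (1.0 - p)))
    if s <= 0:
        return p.copy()
    return _beta_drift(rng, p, min(delta / s, 0.95))


# ---------------------------------------------------------------------------
# individuals: genotypes and reads


@dataclass
class IndividualSim:
    ind_id: str
    node: str
    coverage: float  # mean reads per site; math.inf = fully observed diploid
    ploidy_mode: str = "pseudohaploid"
    group: str = ""

    def __post_init__(self):
        if not (self.coverage >= 0):
            raise ValueError(f"{self.ind_id}: coverage must be >= 0")


@dataclass
class Contamination:
    proportion: float
    node: str

    def __post_init__(self):
        if not 0.0 <= self.proportion <= 1.0:
            raise ValueError("contamination proportion must be in [0,1]")


import functools


@functools.lru_cache(maxsize=8)
def default_snps(n_snps: int, n_chrom: int = DEFAULT_N_CHROM) -> list[SnpRecord]:
    """Uniformly spaced synthetic marker panel over ``n_chrom`` chromosomes
    of 1.5 Morgans each (1 cM/Mb).  Cached; records are frozen, so sharing
    the list across tables is safe."""
    snps = []
    per = n_snps // n_chrom
    extra = n_snps - per * n_chrom
    k = 0
    for c in range(n_chrom):
        n_c = per + (1 if c < extra else 0)
        span_bp = CHROM_MORGANS * 100.0 / CM_PER_MB * 1e6
        for i in range(n_c):
            bp = int(i * span_bp / n_c) + 1
            snps.append(
                SnpRecord(
                    snp_id=f"snp{k}",
                    chrom=str(c + 1),
                    genetic_pos=bp * CM_PER_MB / 1e6 / 100.0,
                    physical_pos=bp,
                    allele1="A",
                    allele2="C",
                )
            )
            k += 1
    return snps


def simulate_individuals(
    freqs: dict[str, np.ndarray],
    individuals: list[IndividualSim],
    seed: int,
    contamination: Contamination | None = None,
    snps: list[SnpRecord] | None = None,
):
    """Sample diploid genotypes (Binomial(2, p)), Poisson read depths and
    derived pseudohaploid calls for each individual.

    Returns (GenotypeTable, ReadCountTable, TruthRecord).  With contamination
    (c, node), each read independently originates from the contaminant node's
    frequencies with probability c.
    """
    rng = np.random.default_rng(seed)
    n_snps = len(next(iter(freqs.values())))
    if snps is None:
        snps = default_snps(n_snps)
    n_inds = len(individuals)
    G = np.full((n_snps, n_inds), MISSING, dtype=np.int8)
    n1 = np.zeros((n_snps, n_inds), dtype=np.int64)
    n2 = np.zeros_like(n1)
    records = []
    for j, spec in enumerate(individuals):
        p = freqs[spec.node]
        g = rng.binomial(2, p)
        if math.isinf(spec.coverage):
            depth = np.full(n_snps, 2)
            r1 = g.copy()
        else:
            depth = rng.poisson(spec.coverage, size=n_snps)
            if contamination is not None and contamination.proportion > 0:
                n_cont = rng.binomial(depth, contamination.proportion)
                n_endo = depth - n_cont
                r1 = rng.binomial(n_endo, g / 2.0) + rng.binomial(
                    n_cont, freqs[contamination.node]
                )
            else:
                r1 = rng.binomial(depth, g / 2.0)
        n1[:, j] = r1
        n2[:, j] = depth - r1
        if spec.ploidy_mode == "diploid":
            G[:, j] = np.where(depth > 0, g, MISSING)
        records.append(
            IndividualRecord(
                ind_id=spec.ind_id, group=spec.group or spec.node, ploidy_mode=spec.ploidy_mode
            )
        )
    reads = ReadCountTable(n_allele1=n1, n_allele2=n2, snps=snps, individuals=records)
    ph_seed = int(rng.integers(0, 2**31 - 1))
    ph_cols = [j for j, s in enumerate(individuals) if s.ploidy_mode == "pseudohaploid"]
    if ph_cols:
        sub = ReadCountTable(
            n_allele1=n1[:, ph_cols],
            n_allele2=n2[:, ph_cols],
            snps=snps,
            individuals=[records[j] for j in ph_cols],
        )
        ph = reads_to_pseudohaploid(sub, seed=ph_seed)
        for k, j in enumerate(ph_cols):
            G[:, j] = ph.G[:, k]
    table = GenotypeTable(snps=snps, individuals=records, G=G)
    truth = TruthRecord(
        kind="individuals",
        seed=seed,
        n_snps=n_snps,
        params={
            "individuals": [asdict(s) for s in individuals],
            "contamination": asdict(contamination) if contamination else None,
            "pseudohaploid_seed": ph_seed,
        },
    )
    return table, reads, truth


def three_source_panel(alpha=(0.62, 0.19, 0.19), target: str = "T") -> GraphSpec:
    """Canonical identifiable three-source admixture graph: each source has a
    cousin outgroup sharing part of its lineage, so sources are
    differentially related to the outgroup panel (OUT, R2..R5) and mixture
    proportions of the admixed target are identifiable from f4 statistics."""
    nodes = [
        "ROOT", "OUT", "R5", "ANC", "L1", "S1", "R2",
        "L2", "L3", "S2", "R3", "L4", "S3", "R4", target,
    ]
    edges = [
        ("ROOT", "OUT", 0.20),
        ("ROOT", "R5", 0.12),
        ("ROOT", "ANC", 0.03),
        ("ANC", "L1", 0.05),
        ("L1", "S1", 0.05),
        ("L1", "R2", 0.08),
        ("ANC", "L2", 0.04),
        ("L2", "L3", 0.04),
        ("L3", "S2", 0.06),
        ("L3", "R3", 0.08),
        ("L2", "L4", 0.03),
        ("L4", "S3", 0.07),
        ("L4", "R4", 0.09),
    ]
    admixtures = [(target, ["S1", "S2", "S3"], list(alpha))]
    return GraphSpec(nodes=nodes, edges=edges, admixtures=admixtures)


PANEL_SOURCES = ["S1", "S2", "S3"]
PANEL_OUTGROUPS = ["OUT", "R2", "R3", "R4", "R5"]


# ---------------------------------------------------------------------------
# geographic cline scenario


@dataclass
class ClusterSpec:
    cluster_id: str
    alpha: tuple[float, ...]  # mixture over the K sources, sums to 1
    delta_cluster: float = 0.0

    def __post_init__(self):
        a = np.asarray(self.alpha, dtype=float)
        if (a < 0).any() or not math.isclose(a.sum(), 1.0, abs_tol=1e-9):
            raise ValueError(f"cluster {self.cluster_id}: alpha must sum to 1")
        if self.delta_cluster < 0:
            raise ValueError("delta_cluster must be >= 0")


@dataclass
class SiteSpec:
    site_id: str
    cluster_id: str
    latitude: float
    longitude: float
    delta_site: float = 0.0

    def __post_init__(self):
        if self.delta_site < 0:
            raise ValueError("delta_site must be >= 0")


@dataclass
class ClineIndividual:
    ind_id: str
    site_id: str
    coverage: float = math.inf
    ploidy_mode: str = "diploid"


@dataclass
class ClineScenario:
    clusters: list[ClusterSpec]
    sites: list[SiteSpec]
    individuals: list[ClineIndividual]
    source_drifts: tuple[float, ...] = (0.08, 0.10, 0.12)
    outgroup_drift: float = 0.2
    pre_source_drift: float = 0.03
    n_outgroup_inds: int = 10
    n_source_inds: int = 10
    contamination: Contamination | None = None
    root_freq_range: tuple[float, float] = (0.05, 0.95)

    @property
    def n_sources(self) -> int:
        return len(self.source_drifts)

    def site(self, site_id: str) -> SiteSpec:
        for s in self.sites:
            if s.site_id == site_id:
                return s
        raise KeyError(site_id)

    def cluster(self, cluster_id: str) -> ClusterSpec:
        for c in self.clusters:
            if c.cluster_id == cluster_id:
                return c
        raise KeyError(cluster_id)


@dataclass
class TruthRecord:
    """All generating parameters; sufficient to regenerate a dataset
    bit-identically via the same generator call."""

    kind: str
    seed: int
    n_snps: int
    params: dict

    def to_json(self) -> str:
        return json.dumps(
            {"kind": self.kind, "seed": self.seed, "n_snps": self.n_snps, "params": self.params},
            indent=2,
            default=_jsonable,
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        d = json.loads(text)
        return cls(kind=d["kind"], seed=d["seed"], n_snps=d["n_snps"], params=d["params"])


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if math.isinf(x):
        return "inf"
    raise TypeError(type(x))


def expected_excess(scenario: ClineScenario, ind1: str, ind2: str) -> float:
    """Expected excess shared drift for a pair under the hierarchy: same-site
    pairs share delta_site + delta_cluster, same-cluster pairs delta_cluster."""
    s1 = scenario.site(next(i.site_id for i in scenario.individuals if i.ind_id == ind1))
    s2 = scenario.site(next(i.site_id for i in scenario.individuals if i.ind_id == ind2))
    if s1.site_id == s2.site_id:
        return s1.delta_site + scenario.cluster(s1.cluster_id).delta_cluster
    if s1.cluster_id == s2.cluster_id:
        return scenario.cluster(s1.cluster_id).delta_cluster
    return 0.0


def simulate_cline_dataset(scenario: ClineScenario, n_snps: int, seed: int):
    """Generate a genotype panel for a geographic-cline scenario.

    Graph: ROOT -> Outgroup; ROOT -> ANC -> sources S1..SK; per cluster an
    admixture node with the cluster's alpha followed by a calibrated excess
    drift branch (delta_cluster); per site a further calibrated branch
    (delta_site).  Sites within a cluster must share the cluster's alpha —
    this keeps the per-pair expected excess sharing analytically exact.

    Returns (GenotypeTable, ReadCountTable, coords DataFrame, TruthRecord).
    """
    rng = np.random.default_rng(seed)
    K = scenario.n_sources
    for c in scenario.clusters:
        if len(c.alpha) != K:
            raise ValueError(f"cluster {c.cluster_id}: alpha has wrong length")

    sources = [f"S{k + 1}" for k in range(K)]
    nodes = ["ROOT", "OUT", "ANC"] + sources
    edges = [("ROOT", "OUT", scenario.outgroup_drift), ("ROOT", "ANC", scenario.pre_source_drift)]
    for k, F in enumerate(scenario.source_drifts):
        edges.append(("ANC", sources[k], F))
    admixtures = []
    for c in scenario.clusters:
        nodes.append(f"MIX_{c.cluster_id}")
        admixtures.append((f"MIX_{c.cluster_id}", list(sources), list(c.alpha)))
    graph = GraphSpec(
        nodes=nodes, edges=edges, admixtures=admixtures, root_freq_range=scenario.root_freq_range
    )
    freqs = simulate_frequencies(graph, n_snps, seed=int(rng.integers(0, 2**31 - 1)))

    # excess-drift hierarchy below the admixture nodes (variance-calibrated)
    for c in scenario.clusters:
        freqs[f"CL_{c.cluster_id}"] = calibrated_drift(
            rng, freqs[f"MIX_{c.cluster_id}"], c.delta_cluster
        )
    for s in scenario.sites:
        freqs[f"SITE_{s.site_id}"] = calibrated_drift(
            rng, freqs[f"CL_{s.cluster_id}"], s.delta_site
        )

    sims = []
    for i in range(scenario.n_outgroup_inds):
        sims.append(
            IndividualSim(
                ind_id=f"OUT{i}", node="OUT", coverage=math.inf, ploidy_mode="diploid",
                group="Outgroup",
            )
        )
    for k, src in enumerate(sources):
        for i in range(scenario.n_source_inds):
            sims.append(
                IndividualSim(
                    ind_id=f"{src}_{i}", node=src, coverage=math.inf, ploidy_mode="diploid",
                    group=src,
                )
            )
    for ind in scenario.individuals:
        sims.append(
            IndividualSim(
                ind_id=ind.ind_id,
                node=f"SITE_{ind.site_id}",
                coverage=ind.coverage,
                ploidy_mode=ind.ploidy_mode,
                group=ind.site_id,
            )
        )
    table, reads, _ = simulate_individuals(
        freqs,
        sims,
        seed=int(rng.integers(0, 2**31 - 1)),
        contamination=scenario.contamination,
    )
    coords = pd.DataFrame(
        [(s.site_id, s.latitude, s.longitude) for s in scenario.sites],
        columns=["id", "latitude", "longitude"],
    )
    test_ids = [i.ind_id for i in scenario.individuals]
    pair_excess = {}
    for a in range(len(test_ids)):
        for b in range(a + 1, len(test_ids)):
            pair_excess[f"{test_ids[a]}|{test_ids[b]}"] = expected_excess(
                scenario, test_ids[a], test_ids[b]
            )
    alphas = {
        i.ind_id: list(scenario.cluster(scenario.site(i.site_id).cluster_id).alpha)
        for i in scenario.individuals
    }
    truth = TruthRecord(
        kind="cline",
        seed=seed,
        n_snps=n_snps,
        params={
            "scenario": {
                "clusters": [asdict(c) for c in scenario.clusters],
                "sites": [asdict(s) for s in scenario.sites],
                "individuals": [asdict(i) for i in scenario.individuals],
                "source_drifts": list(scenario.source_drifts),
                "outgroup_drift": scenario.outgroup_drift,
                "pre_source_drift": scenario.pre_source_drift,
            },
            "alphas": alphas,
            "pair_excess": pair_excess,
            "sources": sources,
            "outgroup": "Outgroup",
        },
    )
    return table, reads, coords, truth


# ---------------------------------------------------------------------------
# ROH length and decay-point generators


def simulate_roh_blocks(
    ne: float,
    genome: GenomeSpec | None = None,
    window_cm=(4.0, math.inf),
    seed: int = 0,
) -> np.ndarray:
    """Draw ROH block lengths (cM) from the inhomogeneous Poisson process
    with intensity lambda(l; Ne); the count in the window is Poisson with
    mean equal to the closed-form integral of the intensity."""
    if ne < 2:
        raise ValueError("Ne must be >= 2")
    if genome is None:
        genome = GenomeSpec()
    rng = np.random.default_rng(seed)
    model = RohLikelihood(genome, window_cm)
    lam_grid = np.maximum(_intensity_on_grid(model, ne), 0.0)
    total = np.trapezoid(lam_grid, model.grid)
    n = rng.poisson(total)
    if n == 0:
        return np.array([])
    cdf = np.concatenate([[0.0], np.cumsum((lam_grid[1:] + lam_grid[:-1]) / 2.0 * np.diff(model.grid))])
    cdf /= cdf[-1]
    u = rng.random(n)
    lengths_m = np.interp(u, cdf, model.grid)
    return np.sort(lengths_m * 100.0)


def _intensity_on_grid(model: RohLikelihood, ne: float) -> np.ndarray:
    from .roh_ne import _pi_g

    return _pi_g(ne, model.g_max) @ model.K_grid


def simulate_decay_points(m, a, b, distances, noise_vars, seed: int = 0):
    """Points on y = 1/(m*x + a) + b with seeded Gaussian noise of the stated
    per-point variances."""
    from .spatial_decay import DecayPoint

    distances = np.asarray(distances, dtype=float)
    noise_vars = np.asarray(noise_vars, dtype=float)
    if ((m * distances + a) <= 0).any():
        raise ValueError("m*x + a must be positive over the supplied distances")
    rng = np.random.default_rng(seed)
    y = 1.0 / (m * distances + a) + b + rng.normal(0.0, np.sqrt(noise_vars))
    return [
        DecayPoint(
            id1=f"p{i}a", id2=f"p{i}b", x=float(max(x, 0.001)), y=float(yy),
            var_y=float(max(v, 1e-18)),
        )
        for i, (x, yy, v) in enumerate(zip(distances, y, noise_vars))
    ]
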