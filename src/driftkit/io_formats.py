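"""EIGENSTRAT-style genotype I/O, genetic-map interpolation and read-count
derived genotypes/likelihoods.

Genotype encoding
-----------------
The genotype matrix ``G`` counts copies of ``allele1`` (column 5 of the .snp
file): 0, 1 or 2, with :data:`MISSING` (internally ``-1``, written as ``9``)
for no data.  Pseudohaploid individuals carry only {0, 2, MISSING}.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1

_GENO_CHARS = {"0": 0, "1": 1, "2": 2, "9": MISSING}
_GENO_OUT = {0: "0", 1: "1", 2: "2", MISSING: "9"}


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class SnpRecord:
    snp_id: str
    chrom: str
    genetic_pos: float  # Morgans
    physical_pos: int  # 1-based bp
    allele1: str
    allele2: str

    def __post_init__(self):
        if self.allele1 == self.allele2:
            raise ValueError(f"{self.snp_id}: allele1 == allele2 ({self.allele1})")
        if self.physical_pos < 1:
            raise ValueError(f"{self.snp_id}: physical_pos must be >= 1")
        if self.genetic_pos < 0:
            raise ValueError(f"{self.snp_id}: genetic_pos must be >= 0")


@dataclass(frozen=True)
class IndividualRecord:
    ind_id: str
    sex: str = "U"
    group: str = ""
    ploidy_mode: str = "diploid"  # or "pseudohaploid"

    def __post_init__(self):
        if self.sex not in ("M", "F", "U"):
            raise ValueError(f"{self.ind_id}: sex must be M/F/U")
        if self.ploidy_mode not in ("diploid", "pseudohaploid"):
            raise ValueError(f"{self.ind_id}: bad ploidy_mode {self.ploidy_mode!r}")


@dataclass
class GenotypeTable:
    """SNP x individual genotype matrix with metadata."""

    snps: list[SnpRecord]
    individuals: list[IndividualRecord]
    G: np.ndarray  # (n_snps, n_inds) int8, values {0,1,2,MISSING}

    def __post_init__(self):
        self.G = np.asarray(self.G, dtype=np.int8)
        if self.G.shape != (len(self.snps), len(self.individuals)):
            raise ValueError(
                f"genotype matrix shape {self.G.shape} does not match "
                f"{len(self.snps)} SNPs x {len(self.individuals)} individuals"
            )
        bad = ~np.isin(self.G, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("genotype values must be in {0,1,2,MISSING}")
        ids = [ind.ind_id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate individual ids")
        for j, ind in enumerate(self.individuals):
            if ind.ploidy_mode == "pseudohaploid" and (self.G[:, j] == 1).any():
                raise ValueError(f"pseudohaploid individual {ind.ind_id} has het calls")

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def ind_index(self, ind_id: str) -> int:
        for j, ind in enumerate(self.individuals):
            if ind.ind_id == ind_id:
                return j
        raise KeyError(ind_id)

    def pop_columns(self, label: str) -> list[int]:
        """Column indices for a population label (group match, else ind_id)."""
        cols = [j for j, ind in enumerate(self.individuals) if ind.group == label]
        if not cols:
            cols = [j for j, ind in enumerate(self.individuals) if ind.ind_id == label]
        if not cols:
            raise KeyError(f"no individuals for population {label!r}")
        return cols


@dataclass
class ReadCountTable:
    """Per-SNP, per-individual read counts for each of the two alleles."""

    n_allele1: np.ndarray  # (n_snps, n_inds) int
    n_allele2: np.ndarray
    snps: list[SnpRecord] | None = None
    individuals: list[IndividualRecord] | None = None

    def __post_init__(self):
        self.n_allele1 = np.asarray(self.n_allele1)
        self.n_allele2 = np.asarray(self.n_allele2)
        if self.n_allele1.shape != self.n_allele2.shape:
            raise ValueError("count matrices must have equal shapes")
        if (self.n_allele1 < 0).any() or (self.n_allele2 < 0).any():
            raise ValueError("read counts must be non-negative")

    @property
    def total(self) -> np.ndarray:
        return self.n_allele1 + self.n_allele2


@dataclass
class LikelihoodTable:
    """Normalized Phred-scaled genotype likelihoods (hom1, het, hom2)."""

    PL: np.ndarray  # (n_snps, n_inds, 3) float
    snps: list[SnpRecord] | None = None
    individuals: list[IndividualRecord] | None = None

    def __post_init__(self):
        self.PL = np.asarray(self.PL, dtype=float)
        if self.PL.ndim != 3 or self.PL.shape[2] != 3:
            raise ValueError("PL must have shape (n_snps, n_inds, 3)")
        if (self.PL < -1e-9).any():
            raise ValueError("PL entries must be >= 0")
        if not np.allclose(self.PL.min(axis=2), 0.0, atol=1e-9):
            raise ValueError("each PL triple must be normalized to min 0")


def read_eigenstrat(geno_path, snp_path, ind_path, ploidy="auto") -> GenotypeTable:
    """Read an EIGENSTRAT geno/snp/ind trio.

    Parameters
    ----------
    ploidy
        ``"auto"`` marks a column pseudohaploid when it has data but no
        heterozygous calls; ``"diploid"`` forces diploid; or a sequence of
        ploidy modes, one per individual.
    """
    snps = _read_snp(snp_path)
    inds = _read_ind(ind_path)
    lines = Path(geno_path).read_text().splitlines()
    if len(lines) != len(snps):
        raise FormatError(
            f"{geno_path}: {len(lines)} genotype lines but {len(snps)} SNPs declared"
        )
    G = np.empty((len(snps), len(inds)), dtype=np.int8)
    for i, line in enumerate(lines):
        if len(line) != len(inds):
            raise FormatError(
                f"{geno_path} line {i + 1}: {len(line)} characters but "
                f"{len(inds)} individuals declared"
            )
        try:
            G[i] = [_GENO_CHARS[c] for c in line]
        except KeyError as e:
            raise FormatError(f"{geno_path} line {i + 1}: invalid character {e}") from None
    inds = _resolve_ploidy(inds, G, ploidy)
    return GenotypeTable(snps=snps, individuals=inds, G=G)


def _resolve_ploidy(inds, G, ploidy):
    if ploidy == "diploid":
        return inds
    if ploidy == "auto":
        out = []
        for j, ind in enumerate(inds):
            col = G[:, j]
            has_data = (col != MISSING).any()
            if has_data and not (col == 1).any():
                out.append(replace(ind, ploidy_mode="pseudohaploid"))
            else:
                out.append(ind)
        return out
    modes = list(ploidy)
    if len(modes) != len(inds):
        raise ValueError("ploidy list length mismatch")
    return [replace(ind, ploidy_mode=m) for ind, m in zip(inds, modes)]


def _read_snp(path) -> list[SnpRecord]:
    snps = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        parts = line.split()
        if not parts:
            continue
        if len(parts) != 6:
            raise FormatError(f"{path} line {i + 1}: expected 6 fields, got {len(parts)}")
        snps.append(
            SnpRecord(
                snp_id=parts[0],
                chrom=parts[1],
                genetic_pos=float(parts[2]),
                physical_pos=int(parts[3]),
                allele1=parts[4],
                allele2=parts[5],
            )
        )
    return snps


def _read_ind(path) -> list[IndividualRecord]:
    inds = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        parts = line.split()
        if not parts:
            continue
        if len(parts) != 3:
            raise FormatError(f"{path} line {i + 1}: expected 3 fields, got {len(parts)}")
        inds.append(IndividualRecord(ind_id=parts[0], sex=parts[1], group=parts[2]))
    return inds


def write_eigenstrat(table: GenotypeTable, out_prefix) -> tuple[Path, Path, Path]:
    """Write geno/snp/ind files readable by :func:`read_eigenstrat`.

    MISSING is written as ``'9'``; genetic positions are kept to 6 decimals.
    """
    prefix = Path(out_prefix)
    geno_path = prefix.with_suffix(".geno")
    snp_path = prefix.with_suffix(".snp")
    ind_path = prefix.with_suffix(".ind")
    with open(geno_path, "w") as fh:
        for row in table.G:
            fh.write("".join(_GENO_OUT[int(g)] for g in row) + "\n")
    with open(snp_path, "w") as fh:
        for s in table.snps:
            fh.write(
                f"{s.snp_id}\t{s.chrom}\t{s.genetic_pos:.6f}\t{s.physical_pos}"
                f"\t{s.allele1}\t{s.allele2}\n"
            )
    with open(ind_path, "w") as fh:
        for ind in table.individuals:
            fh.write(f"{ind.ind_id}\t{ind.sex}\t{ind.group or 'Ignore'}\n")
    return geno_path, snp_path, ind_path


@dataclass
class GeneticMap:
    """Piecewise-linear genetic map: per-chromosome (bp, cM) anchors."""

    anchors: dict[str, tuple[np.ndarray, np.ndarray]]  # chrom -> (bp, cM), sorted

    def interpolate_cm(self, chrom: str, bp: np.ndarray) -> np.ndarray:
        if chrom not in self.anchors:
            raise KeyError(f"chromosome {chrom!r} absent from genetic map")
        xs, ys = self.anchors[chrom]
        bp = np.asarray(bp, dtype=float)
        out = np.interp(bp, xs, ys)
        if len(xs) >= 2:
            # extrapolate at the terminal intervals' recombination rates
            lo_rate = (ys[1] - ys[0]) / (xs[1] - xs[0])
            hi_rate = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
            below = bp < xs[0]
            above = bp > xs[-1]
            out[below] = ys[0] + (bp[below] - xs[0]) * lo_rate
            out[above] = ys[-1] + (bp[above] - xs[-1]) * hi_rate
        return np.maximum(out, 0.0)


def read_genetic_map(path) -> GeneticMap:
    """Read a PLINK .map (chrom, id, cM, bp; headerless) or a HapMap-style map
    (header, then chrom, bp, rate, cumulative cM). Dialect is auto-detected.
    """
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty map file")
    first = lines[0].split()
    # PLINK rows carry >= 2 numeric fields (cM, bp); a HapMap header carries none
    hapmap = sum(_is_number(tok) for tok in first) <= 1
    anchors: dict[str, list[tuple[float, float]]] = {}
    body = lines[1:] if hapmap else lines
    for i, ln in enumerate(body):
        parts = ln.split()
        if len(parts) < 4:
            raise FormatError(f"{path} line {i + 1}: expected 4 columns")
        if hapmap:
            chrom, bp, _rate, cm = parts[0], float(parts[1]), parts[2], float(parts[3])
        else:
            chrom, _snp_id, cm, bp = parts[0], parts[1], float(parts[2]), float(parts[3])
        anchors.setdefault(chrom, []).append((bp, cm))
    out = {}
    for chrom, pts in anchors.items():
        pts.sort()
        xs = np.array([p[0] for p in pts])
        ys = np.array([p[1] for p in pts])
        out[chrom] = (xs, ys)
    return GeneticMap(anchors=out)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


DEFAULT_RATE_CM_PER_MB = 1.0


def assign_genetic_positions(
    snps: Sequence[SnpRecord], map_source: GeneticMap | str | None = None
) -> list[SnpRecord]:
    """Fill ``genetic_pos`` (Morgans) from a genetic map, or at a constant
    1 cM/Mb when no map is supplied."""
    if isinstance(map_source, (str, Path)):
        map_source = read_genetic_map(map_source)
    out = []
    for s in snps:
        if map_source is None:
            cm = s.physical_pos * DEFAULT_RATE_CM_PER_MB / 1e6
        else:
            cm = float(map_source.interpolate_cm(s.chrom, np.array([s.physical_pos]))[0])
        out.append(replace(s, genetic_pos=cm / 100.0))
    for i in range(1, len(out)):
        if out[i].chrom == out[i - 1].chrom and out[i].physical_pos >= out[i - 1].physical_pos:
            if out[i].genetic_pos < out[i - 1].genetic_pos:
                raise ValueError(
                    f"genetic positions not monotone at {out[i].snp_id}"
                )
    return out


def reads_to_pseudohaploid(counts: ReadCountTable, seed: int) -> GenotypeTable:
    """Call pseudohaploid genotypes by sampling one read per site.

    A cell with zero reads is MISSING; otherwise the call is 2 with
    probability ``n_allele1 / total`` and 0 otherwise.
    """
    rng = np.random.default_rng(seed)
    n1 = counts.n_allele1
    tot = counts.total
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(tot > 0, n1 / np.maximum(tot, 1), 0.0)
    draw = rng.random(n1.shape)
    G = np.where(tot == 0, MISSING, np.where(draw < p1, 2, 0)).astype(np.int8)
    snps = counts.snps if counts.snps is not None else _dummy_snps(n1.shape[0])
    inds = counts.individuals if counts.individuals is not None else _dummy_inds(n1.shape[1])
    inds = [replace(ind, ploidy_mode="pseudohaploid") for ind in inds]
    return GenotypeTable(snps=snps, individuals=inds, G=G)


def reads_to_likelihoods(counts: ReadCountTable, base_error: float = 0.01) -> LikelihoodTable:
    """Convert allele read counts to normalized Phred-scaled genotype
    likelihoods under a symmetric base-error model.

    L(hom1) = (1-e)^n1 e^n2, L(het) = 0.5^(n1+n2), L(hom2) = e^n1 (1-e)^n2.
    """
    eps = float(base_error)
    if not 0.0 < eps < 0.5:
        raise ValueError("base_error must be in (0, 0.5)")
    n1 = counts.n_allele1.astype(float)
    n2 = counts.n_allele2.astype(float)
    ll_hom1 = n1 * math.log10(1 - eps) + n2 * math.log10(eps)
    ll_het = (n1 + n2) * math.log10(0.5)
    ll_hom2 = n1 * math.log10(eps) + n2 * math.log10(1 - eps)
    PL = -10.0 * np.stack([ll_hom1, ll_het, ll_hom2], axis=-1)
    PL -= PL.min(axis=-1, keepdims=True)
    return LikelihoodTable(PL=PL, snps=counts.snps, individuals=counts.individuals)


def read_counts_tsv(path, snps=None, individuals=None) -> ReadCountTable:
    """Read a long-format TSV with header: snp_id ind_id n_allele1 n_allele2."""
    df = pd.read_csv(path, sep="\t")
    need = {"snp_id", "ind_id", "n_allele1", "n_allele2"}
    if not need.issubset(df.columns):
        raise FormatError(f"{path}: header must contain {sorted(need)}")
    snp_ids = list(dict.fromkeys(df["snp_id"])) if snps is None else [s.snp_id for s in snps]
    ind_ids = (
        list(dict.fromkeys(df["ind_id"]))
        if individuals is None
        else [i.ind_id for i in individuals]
    )
    si = {s: i for i, s in enumerate(snp_ids)}
    ii = {s: i for i, s in enumerate(ind_ids)}
    n1 = np.zeros((len(snp_ids), len(ind_ids)), dtype=int)
    n2 = np.zeros_like(n1)
    for row in df.itertuples(index=False):
        n1[si[row.snp_id], ii[row.ind_id]] = row.n_allele1
        n2[si[row.snp_id], ii[row.ind_id]] = row.n_allele2
    if snps is None:
        snps = _dummy_snps(len(snp_ids), snp_ids)
    if individuals is None:
        individuals = _dummy_inds(len(ind_ids), ind_ids)
    return ReadCountTable(n_allele1=n1, n_allele2=n2, snps=snps, individuals=individuals)


def _dummy_snps(n, ids=None) -> list[SnpRecord]:
    return [
        SnpRecord(
            snp_id=ids[i] if ids else f"snp{i}",
            chrom="1",
            genetic_pos=i * 1e-6,
            physical_pos=i + 1,
            allele1="A",
            allele2="C",
        )
        for i in range(n)
    ]


def _dummy_inds(n, ids=None) -> list[IndividualRecord]:
    return [IndividualRecord(ind_id=ids[i] if ids else f"ind{i}") for i in range(n)]
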