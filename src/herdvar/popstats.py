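"""Per-population diversity and between-population differentiation.

Implements the Weir & Cockerham (1984) ratio-of-components estimators for
theta (F_ST) and f (F_IS) in the unequal-sample-size formulation, Nei's
(1972) standard genetic distance, per-population diversity summaries, a
locus-bootstrap significance test for pairwise theta, and a marker-wise
theta scan with a mean + k*sd outlier threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .genotype_io import MISSING, GenotypeMatrix, PopulationPartition

__all__ = [
    "AlleleFreqTable",
    "DiversityRow",
    "DiversityTable",
    "DistanceSet",
    "allele_freq_table",
    "diversity_metrics",
    "wc_components",
    "wc_fstatistics",
    "pairwise_fst",
    "nei_distance",
    "fst_scan",
]


@dataclass
class AlleleFreqTable:
    """Genotype counts and allele_b frequencies per population x marker."""

    populations: list[str]
    marker_ids: list[str]
    n_hom_a: np.ndarray  # pops x markers, count of dosage-0 genotypes
    n_het: np.ndarray
    n_hom_b: np.ndarray

    @property
    def n_called(self) -> np.ndarray:
        return self.n_hom_a + self.n_het + self.n_hom_b

    @property
    def freq_b(self) -> np.ndarray:
        """allele_b frequency; NaN where a population has no calls."""
        n = self.n_called
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, (self.n_het + 2 * self.n_hom_b) / (2 * n), np.nan)

    @property
    def het_obs(self) -> np.ndarray:
        n = self.n_called
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, self.n_het / np.maximum(n, 1), np.nan)


def allele_freq_table(gm: GenotypeMatrix, partition: PopulationPartition) -> AlleleFreqTable:
    partition.validate_against(gm)
    by_pop = partition.indices_by_population(gm)
    pops = list(by_pop)
    shape = (len(pops), gm.n_markers)
    n0 = np.zeros(shape, dtype=np.int64)
    n1 = np.zeros(shape, dtype=np.int64)
    n2 = np.zeros(shape, dtype=np.int64)
    for k, pop in enumerate(pops):
        d = gm.dosages[by_pop[pop]]
        n0[k] = (d == 0).sum(axis=0)
        n1[k] = (d == 1).sum(axis=0)
        n2[k] = (d == 2).sum(axis=0)
    return AlleleFreqTable(pops, gm.marker_ids, n0, n1, n2)


@dataclass
class DiversityRow:
    population: str
    n_samples: int
    maf_mean: float
    maf_sd: float
    het_obs_mean: float
    het_obs_sd: float
    het_exp_mean: float
    n_fixed: int
    f_is: float
    t_statistic: float
    t_pvalue: float


@dataclass
class DiversityTable:
    rows: list[DiversityRow]

    def __iter__(self):
        return iter(self.rows)

    def row(self, population: str) -> DiversityRow:
        for r in self.rows:
            if r.population == population:
                return r
        raise KeyError(population)

    def to_tsv(self, path: str | Path) -> None:
        cols = [
            "population", "n_samples", "maf_mean", "maf_sd", "het_obs_mean",
            "het_obs_sd", "het_exp_mean", "n_fixed", "f_is", "t_statistic", "t_pvalue",
        ]
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for r in self.rows:
                fh.write("\t".join(str(getattr(r, c)) for c in cols) + "\n")


def diversity_metrics(
    gm: GenotypeMatrix,
    partition: PopulationPartition,
    unbiased_het_exp: bool = False,
) -> DiversityTable:
    """Per-population MAF, heterozygosities, fixed-marker count and F_IS.

    ``het_exp`` is the across-marker mean of 2p(1-p) (multiplied by
    2n/(2n-1) per locus when ``unbiased_het_exp``).  Includes a paired
    two-sided t-test across markers of per-locus H_obs - H_exp.  F_IS is
    the single-population Weir-Cockerham f.
    """
    table = allele_freq_table(gm, partition)
    rows: list[DiversityRow] = []
    for k, pop in enumerate(table.populations):
        n = table.n_called[k]
        if (n == 0).all():
            raise ValueError(f"population {pop!r} has no called genotypes")
        defined = n > 0
        p = table.freq_b[k, defined]
        maf = np.minimum(p, 1 - p)
        h_obs = table.het_obs[k, defined]
        h_exp = 2 * p * (1 - p)
        if unbiased_het_exp:
            two_n = 2 * n[defined]
            h_exp = h_exp * two_n / np.maximum(two_n - 1, 1)
        n_fixed = int(((p == 0) | (p == 1)).sum())
        diffs = h_obs - h_exp
        if diffs.size >= 2 and diffs.std(ddof=1) > 0:
            t_stat, t_p = stats.ttest_rel(h_obs, h_exp)
        else:
            t_stat, t_p = 0.0, 1.0
        try:
            _, f_is, _ = wc_fstatistics(gm, partition, pops_subset=[pop])
        except ValueError:  # fully monomorphic population: inbreeding undefined
            f_is = float("nan")
        rows.append(
            DiversityRow(
                population=pop,
                n_samples=int(n.max()),
                maf_mean=float(maf.mean()),
                maf_sd=float(maf.std(ddof=1)) if maf.size > 1 else 0.0,
                het_obs_mean=float(h_obs.mean()),
                het_obs_sd=float(h_obs.std(ddof=1)) if h_obs.size > 1 else 0.0,
                het_exp_mean=float(h_exp.mean()),
                n_fixed=n_fixed,
                f_is=float(f_is),
                t_statistic=float(t_stat),
                t_pvalue=float(t_p),
            )
        )
    return DiversityTable(rows)


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) variance components


def wc_components(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus W&C variance components (a, b, c) for r populations.

    Parameters are pops x loci arrays: sample sizes ``n`` (individuals with
    calls), allele frequencies ``p``, observed heterozygote fractions ``h``.
    Loci where fewer than 2 populations have data, or where n_c = 0, give
    NaN components.

    Returns (a, b, c): among-population, among-individual-within-population
    and within-individual components per locus.
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    h = np.asarray(h, dtype=float)
    has_data = n > 0
    r = has_data.sum(axis=0).astype(float)  # populations with data per locus

    n_safe = np.where(has_data, n, 0.0)
    p_safe = np.where(has_data, p, 0.0)
    h_safe = np.where(has_data, h, 0.0)

    n_total = n_safe.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_bar = n_total / r
        # n_c = (r*n_bar - sum(n_i^2)/(r*n_bar)) / (r - 1)
        n_c = (n_total - (n_safe**2).sum(axis=0) / n_total) / (r - 1)
        p_bar = (n_safe * p_safe).sum(axis=0) / n_total
        s2 = (n_safe * (p_safe - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n_safe * h_safe).sum(axis=0) / n_total

        a = (n_bar / n_c) * (
            s2 - (1.0 / (n_bar - 1)) * (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
        )
        c = h_bar / 2

    bad = (r < 2) | ~np.isfinite(a) | ~np.isfinite(b) | ~np.isfinite(c)
    a = np.where(bad, np.nan, a)
    b = np.where(bad, np.nan, b)
    c = np.where(bad, np.nan, c)
    return a, b, c


def _pop_arrays(
    gm: GenotypeMatrix, partition: PopulationPartition, pops: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n, p, h) pops x loci arrays for the requested populations."""
    by_pop = partition.indices_by_population(gm)
    n = np.zeros((len(pops), gm.n_markers))
    p = np.zeros_like(n)
    h = np.zeros_like(n)
    for k, pop in enumerate(pops):
        d = gm.dosages[by_pop[pop]]
        called = d != MISSING
        nk = called.sum(axis=0)
        n[k] = nk
        with np.errstate(invalid="ignore", divide="ignore"):
            p[k] = np.where(nk > 0, np.where(called, d, 0).sum(axis=0) / (2 * np.maximum(nk, 1)), np.nan)
            h[k] = np.where(nk > 0, ((d == 1) & called).sum(axis=0) / np.maximum(nk, 1), np.nan)
    return n, p, h


def wc_fstatistics(
    gm: GenotypeMatrix,
    partition: PopulationPartition,
    pops_subset: Sequence[str] | None = None,
) -> tuple[float, float, np.ndarray]:
    """Multi-locus Weir-Cockerham theta (F_ST) and f (F_IS).

    theta = sum(a) / sum(a+b+c) over loci with defined components;
    f = 1 - sum(c)/sum(b+c).  Negative per-locus components are retained.
    With a single population, theta is NaN and f is the within-population
    inbreeding estimate.  Returns (theta, f, per_locus_theta).
    """
    partition.validate_against(gm)
    pops = list(pops_subset) if pops_subset is not None else partition.populations
    if not pops:
        raise ValueError("no populations selected")

    if len(pops) == 1:
        # f only: per-locus b and c from the single population (r=1 case:
        # use the one-population reduction, equivalent to W&C f with r=1).
        n, p, h = _pop_arrays(gm, partition, pops)
        n1, p1, h1 = n[0], p[0], h[0]
        with np.errstate(invalid="ignore", divide="ignore"):
            b = (n1 / (n1 - 1)) * (p1 * (1 - p1) - ((2 * n1 - 1) / (4 * n1)) * h1)
            c = h1 / 2
        ok = np.isfinite(b) & np.isfinite(c) & ((b + c) > 0)
        if not ok.any():
            raise ValueError("all loci monomorphic or undefined")
        f = 1.0 - c[ok].sum() / (b[ok] + c[ok]).sum()
        return float("nan"), float(f), np.full(gm.n_markers, np.nan)

    n, p, h = _pop_arrays(gm, partition, pops)
    a, b, c = wc_components(n, p, h)
    denom = a + b + c
    ok = np.isfinite(denom) & (denom != 0)
    if not ok.any():
        raise ValueError("all loci monomorphic across the selected populations")
    theta = a[ok].sum() / denom[ok].sum()
    bc = b + c
    ok_f = np.isfinite(bc) & (bc != 0)
    f = 1.0 - c[ok_f].sum() / bc[ok_f].sum() if ok_f.any() else float("nan")
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus = np.where(ok, a / denom, np.nan)
    return float(theta), float(f), per_locus


@dataclass
class DistanceSet:
    """Pairwise F_ST and Nei's D with bootstrap significance."""

    populations: list[str]
    fst: np.ndarray  # symmetric, zero diagonal
    nei_d: np.ndarray
    p_values: np.ndarray  # NaN diagonal
    n_boot: int

    def to_tsv(self, path: str | Path) -> None:
        """Square matrix, F_ST above the diagonal and Nei's D below."""
        k = len(self.populations)
        with open(path, "w") as fh:
            fh.write("population\t" + "\t".join(self.populations) + "\n")
            for i in range(k):
                cells = []
                for j in range(k):
                    if i == j:
                        cells.append("0")
                    elif i < j:
                        cells.append(f"{self.fst[i, j]:.6g}")
                    else:
                        cells.append(f"{self.nei_d[i, j]:.6g}")
                fh.write(self.populations[i] + "\t" + "\t".join(cells) + "\n")


def nei_distance(freqs_x: np.ndarray, freqs_y: np.ndarray) -> float:
    """Nei's (1972) standard genetic distance from biallelic frequency vectors.

    J_X = mean over loci of (x^2 + (1-x)^2), likewise J_Y; J_XY the mean
    cross-product; D = -ln(J_XY / sqrt(J_X * J_Y)).  Returns +inf when the
    identity is 0.
    """
    x = np.asarray(freqs_x, dtype=float)
    y = np.asarray(freqs_y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if not ok.any():
        raise ValueError("no loci with defined frequencies in both populations")
    x, y = x[ok], y[ok]
    jx = np.mean(x**2 + (1 - x) ** 2)
    jy = np.mean(y**2 + (1 - y) ** 2)
    jxy = np.mean(x * y + (1 - x) * (1 - y))
    if jxy == 0:
        return float("inf")
    d = -np.log(jxy / np.sqrt(jx * jy))
    return float(max(d, 0.0)) if abs(d) < 1e-12 else float(d)


def pairwise_fst(
    gm: GenotypeMatrix,
    partition: PopulationPartition,
    n_boot: int = 100,
    seed: int | None = None,
) -> DistanceSet:
    """All population-pair theta and Nei's D with locus-bootstrap p-values.

    The bootstrap resamples loci with replacement and recomputes theta from
    the resampled per-locus components; p = (1 + #{theta* <= 0}) / (n_boot
    + 1), a one-sided test of theta > 0.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    partition.validate_against(gm)
    pops = partition.populations
    k = len(pops)
    fst = np.zeros((k, k))
    nei = np.zeros((k, k))
    pvals = np.full((k, k), np.nan)
    table = allele_freq_table(gm, partition)
    freq = table.freq_b
    pop_index = {p: i for i, p in enumerate(table.populations)}
    for i in range(k):
        for j in range(i + 1, k):
            n, p, h = _pop_arrays(gm, partition, [pops[i], pops[j]])
            a, b, c = wc_components(n, p, h)
            denom = a + b + c
            ok = np.isfinite(denom) & (denom != 0)
            if not ok.any():
                raise ValueError(f"no polymorphic loci for pair ({pops[i]}, {pops[j]})")
            a_ok, denom_ok = a[ok], denom[ok]
            theta = a_ok.sum() / denom_ok.sum()
            L = a_ok.size
            idx = rng.integers(0, L, size=(n_boot, L))
            boot_theta = a_ok[idx].sum(axis=1) / denom_ok[idx].sum(axis=1)
            pv = (1 + int((boot_theta <= 0).sum())) / (n_boot + 1)
            fst[i, j] = fst[j, i] = theta
            pvals[i, j] = pvals[j, i] = pv
            nei[i, j] = nei[j, i] = nei_distance(
                freq[pop_index[pops[i]]], freq[pop_index[pops[j]]]
            )
    return DistanceSet(pops, fst, nei, pvals, n_boot)


@dataclass
class FstScan:
    marker_ids: list[str]
    chromosomes: list[str]
    positions: list[int]
    theta: np.ndarray
    threshold: float
    outliers: list[str]

    def to_bed_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#chrom\tstart\tend\ttheta\toutlier\n")
            for mid, ch, pos, th in zip(self.marker_ids, self.chromosomes, self.positions, self.theta):
                flag = "1" if mid in set(self.outliers) else "0"
                fh.write(f"{ch}\t{pos}\t{pos}\t{th:.6g}\t{flag}\n")


def fst_scan(
    gm: GenotypeMatrix,
    partition: PopulationPartition,
    pop_a: str,
    pop_b: str,
    sd_window: float = 3.0,
) -> FstScan:
    """Marker-wise theta between two populations with a mean + k*sd threshold.

    Outliers are markers with theta strictly greater than the threshold,
    reported with chromosome/position for reading off contiguous regions.
    """
    n, p, h = _pop_arrays(gm, partition, [pop_a, pop_b])
    a, b, c = wc_components(n, p, h)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(np.isfinite(denom) & (denom != 0), a / denom, np.nan)
    defined = np.isfinite(theta)
    if defined.sum() < 2:
        raise ValueError("fewer than 2 markers with defined theta")
    mean = theta[defined].mean()
    sd = theta[defined].std(ddof=0)
    threshold = mean + sd_window * sd
    outliers = [
        m.id for m, t in zip(gm.markers, theta) if np.isfinite(t) and t > threshold
    ]
    return FstScan(
        marker_ids=gm.marker_ids,
        chromosomes=[m.chromosome for m in gm.markers],
        positions=[m.position for m in gm.markers],
        theta=theta,
        threshold=float(threshold),
        outliers=outliers,
    )
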