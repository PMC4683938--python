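"""LD-based effective population size and heterozygosity decay projection.

r-squared between marker pairs is the Burrows composite measure computed
from unphased dosages: Delta-hat is half the sample covariance (n-1
denominator) of the two dosage vectors over samples called at both loci,
and r2 = Delta-hat^2 / (p(1-p) q(1-q)).  Ne follows from the mean
within-chromosome r2 after subtracting the sample-size expectation, using
the random-mating bias-corrected estimator with separate branches for
harmonic sample size S >= 30 and S < 30.  Per-chromosome estimates are
averaged (arithmetic mean +/- sd) into the genome value.

Heterozygosity is projected forward as H_t = H_0 (1 - 1/(2 Ne))^t.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix, PopulationPartition, subset

__all__ = [
    "NeEstimate",
    "DecayForecast",
    "composite_r2",
    "mean_r2_chromosome",
    "ne_from_r2",
    "ne_genome",
    "project_heterozygosity",
]


@dataclass
class NeEstimate:
    population: str
    chromosomes: list[str]
    ne_per_chromosome: list[float]  # may contain inf
    mean_r2_per_chromosome: list[float]
    s_harmonic_per_chromosome: list[float]
    ne_mean: float
    ne_sd: float
    n_infinite: int
    mating_model: str = "random"

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chromosome\tne\tmean_r2\ts_harmonic\n")
            for ch, ne, r2, s in zip(
                self.chromosomes,
                self.ne_per_chromosome,
                self.mean_r2_per_chromosome,
                self.s_harmonic_per_chromosome,
            ):
                fh.write(f"{ch}\t{ne:.6g}\t{r2:.6g}\t{s:.6g}\n")
            fh.write(f"#genome\t{self.ne_mean:.6g} ± {self.ne_sd:.6g}"
                     f"\tn_infinite={self.n_infinite}\tmating={self.mating_model}\n")


@dataclass
class DecayForecast:
    h0: float
    ne: float
    t_max: int
    trajectory: np.ndarray  # H_t for t = 0..t_max
    halving_time: float  # smallest integer t with H_t <= H_0/2; inf if never

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("generation\theterozygosity\n")
            for t, h in enumerate(self.trajectory):
                fh.write(f"{t}\t{h:.10g}\n")


def _locus_denominator(x: np.ndarray, hw_adjust: bool) -> float:
    """Per-locus scaling term: p(1-p), or p(1-p) + D_A with the
    Hardy-Weinberg disequilibrium D_A = P_BB - p^2 when ``hw_adjust``."""
    p = x.mean() / 2.0
    base = p * (1 - p)
    if hw_adjust:
        base += float((x == 2).mean()) - p**2
    return base


def composite_r2(
    gm_pop: GenotypeMatrix, locus_i: int, locus_j: int, hw_adjust: bool = False
) -> float:
    """Burrows composite r2 for one locus pair; NaN if undefined.

    Delta-hat is half the sample covariance (n-1 denominator) of the two
    dosage vectors over samples called at both loci; the basic form divides
    by p(1-p) q(1-q).  ``hw_adjust`` uses the Hardy-Weinberg-adjusted
    denominators (p(1-p) + D_A)(q(1-q) + D_B) of the LD-Ne literature --
    the form whose null expectation the :func:`ne_from_r2` corrections were
    calibrated against, and the default throughout the Ne path.

    Undefined (pair excluded upstream, never counted as zero) when fewer
    than 2 shared non-missing samples or either locus is monomorphic on the
    shared samples.  Values > 1 are possible and retained.
    """
    x = gm_pop.dosages[:, locus_i].astype(float)
    y = gm_pop.dosages[:, locus_j].astype(float)
    shared = (gm_pop.dosages[:, locus_i] != MISSING) & (gm_pop.dosages[:, locus_j] != MISSING)
    x, y = x[shared], y[shared]
    n = x.size
    if n < 2:
        return float("nan")
    p = x.mean() / 2.0
    q = y.mean() / 2.0
    if p in (0.0, 1.0) or q in (0.0, 1.0):
        return float("nan")
    delta = 0.5 * float(np.cov(x, y, ddof=1)[0, 1])
    denom = _locus_denominator(x, hw_adjust) * _locus_denominator(y, hw_adjust)
    if denom <= 0:
        return float("nan")
    return delta**2 / denom


def _pair_stats_complete(d: np.ndarray, hw_adjust: bool) -> tuple[float, int, float]:
    """Vectorized (mean_r2, n_pairs, S_harmonic) for complete dosage block."""
    n, L = d.shape
    c = np.cov(d.T, ddof=1)  # L x L
    p = d.mean(axis=0) / 2.0
    var_term = p * (1 - p)
    if hw_adjust:
        var_term = var_term + (d == 2).mean(axis=0) - p**2
    denom = np.outer(var_term, var_term)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(denom > 0, (0.5 * c) ** 2 / denom, np.nan)
    iu = np.triu_indices(L, k=1)
    vals = r2[iu]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan"), 0, float("nan")
    return float(vals.mean()), int(vals.size), float(n)


def mean_r2_chromosome(
    gm_pop: GenotypeMatrix,
    chromosome: str,
    maf_min: float = 0.05,
    hw_adjust: bool = True,
) -> tuple[float, int, float]:
    """Unweighted mean composite r2 over all within-chromosome locus pairs.

    Loci are eligible when their within-population MAF (non-missing
    samples) is >= maf_min.  Returns (mean_r2, n_pairs, S_harmonic) where
    S_harmonic is the harmonic mean of per-pair shared sample counts;
    (NaN, 0, NaN) when no eligible pairs exist.
    """
    cols = [j for j, m in enumerate(gm_pop.markers) if m.chromosome == chromosome]
    if len(cols) < 2:
        return float("nan"), 0, float("nan")
    d = gm_pop.dosages[:, cols]
    called = d != MISSING
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, d, 0).sum(axis=0) / (2.0 * np.maximum(n_called, 1))
    maf = np.minimum(p, 1 - p)
    elig = (n_called >= 2) & (maf >= maf_min)
    cols = np.asarray(cols)[elig]
    if cols.size < 2:
        return float("nan"), 0, float("nan")
    d = gm_pop.dosages[:, cols]
    if not (d == MISSING).any():
        return _pair_stats_complete(d.astype(float), hw_adjust)
    return _pair_stats_masked(d, hw_adjust)


def _pair_stats_masked(d: np.ndarray, hw_adjust: bool) -> tuple[float, int, float]:
    """Per-pair shared-sample statistics via masked matrix products.

    Equivalent to looping :func:`composite_r2` over all pairs: every
    per-pair moment (shared n, sums, cross-products, dosage-2 counts) is a
    matmul of the masked dosage matrix, so sporadic missingness costs no
    more than the complete-data path.
    """
    called = (d != MISSING).astype(float)
    x = np.where(d == MISSING, 0.0, d).astype(float)
    x2 = x * x
    hom = (d == 2).astype(float)

    n_ab = called.T @ called  # shared sample counts, L x L
    sx = x.T @ called  # sx[a, b] = sum of dosages at a over samples shared with b
    sxx = x2.T @ called
    sxy = x.T @ x
    h2 = hom.T @ called  # dosage-2 counts at a over shared samples

    with np.errstate(invalid="ignore", divide="ignore"):
        mean_a = sx / n_ab  # row locus mean on shared samples
        mean_b = sx.T / n_ab
        cov = (sxy - n_ab * mean_a * mean_b) / (n_ab - 1)
        p_a = mean_a / 2.0
        p_b = mean_b / 2.0
        den_a = p_a * (1 - p_a)
        den_b = p_b * (1 - p_b)
        if hw_adjust:
            den_a = den_a + h2 / n_ab - p_a**2
            den_b = den_b + h2.T / n_ab - p_b**2
        denom = den_a * den_b
        r2 = np.where(denom > 0, (0.5 * cov) ** 2 / denom, np.nan)

    poly = (p_a > 0) & (p_a < 1) & (p_b > 0) & (p_b < 1)
    valid = (n_ab >= 2) & poly & np.isfinite(r2)
    iu = np.triu_indices(d.shape[1], k=1)
    ok = valid[iu]
    if not ok.any():
        return float("nan"), 0, float("nan")
    vals = r2[iu][ok]
    ns = n_ab[iu][ok]
    s_harm = len(ns) / float((1.0 / ns).sum())
    return float(vals.mean()), int(ok.sum()), float(s_harm)


def ne_from_r2(mean_r2: float, S: float) -> float:
    """Bias-corrected Ne from mean composite r2 at harmonic sample size S.

    Subtracts the finite-sample expectation and inverts the drift
    relationship (random mating).  For S >= 30:
        r2_drift = mean_r2 - (1/S + 3.19/S^2)
        Ne = (1/3 + sqrt(1/9 - 2.76 r2_drift)) / (2 r2_drift)
    For S < 30:
        r2_drift = mean_r2 - (0.0018 + 0.907/S + 4.44/S^2)
        Ne = (0.308 + sqrt(0.308^2 - 2.08 r2_drift)) / (2 r2_drift)
    Returns +inf when r2_drift <= 0 or the discriminant is negative (no
    drift signal resolvable).
    """
    if not (math.isfinite(mean_r2) and math.isfinite(S)):
        raise ValueError("non-finite inputs to ne_from_r2")
    if mean_r2 <= 0:
        raise ValueError("mean_r2 must be positive")
    if S < 2:
        raise ValueError("S must be >= 2")
    if S >= 30:
        r2_drift = mean_r2 - (1.0 / S + 3.19 / S**2)
        lin, quad = 1.0 / 3.0, 2.76
    else:
        r2_drift = mean_r2 - (0.0018 + 0.907 / S + 4.44 / S**2)
        lin, quad = 0.308, 2.08
    if r2_drift <= 0:
        return float("inf")
    disc = lin**2 - quad * r2_drift
    if disc < 0:
        return float("inf")
    return (lin + math.sqrt(disc)) / (2.0 * r2_drift)


def ne_genome(
    gm: GenotypeMatrix,
    partition: PopulationPartition,
    population: str,
    maf_min: float = 0.05,
    chromosome_mean: str = "arithmetic",
    hw_adjust: bool = True,
) -> NeEstimate:
    """Per-chromosome Ne averaged into a genome estimate for one population.

    Chromosomes with no eligible pairs are dropped; infinite per-chromosome
    estimates are counted separately and excluded from the mean/sd.
    ``chromosome_mean`` may be "arithmetic" (default) or "harmonic".
    """
    ids = partition.samples_in(population)
    if not ids:
        raise ValueError(f"no samples in population {population!r}")
    gm_pop = subset(gm, sample_ids=ids)
    chroms: list[str] = []
    for m in gm_pop.markers:
        if m.chromosome not in chroms:
            chroms.append(m.chromosome)
    kept_ch: list[str] = []
    nes: list[float] = []
    r2s: list[float] = []
    ss: list[float] = []
    for ch in chroms:
        r2, n_pairs, s = mean_r2_chromosome(gm_pop, ch, maf_min, hw_adjust=hw_adjust)
        if n_pairs == 0 or not math.isfinite(r2) or r2 <= 0:
            continue
        kept_ch.append(ch)
        nes.append(ne_from_r2(r2, s))
        r2s.append(r2)
        ss.append(s)
    finite = [x for x in nes if math.isfinite(x)]
    n_inf = len(nes) - len(finite)
    if len(finite) < 1:
        raise ValueError(f"no finite per-chromosome Ne estimates for {population!r}")
    if chromosome_mean == "harmonic":
        mean = len(finite) / sum(1.0 / x for x in finite)
    else:
        mean = float(np.mean(finite))
    sd = float(np.std(finite, ddof=1)) if len(finite) > 1 else 0.0
    return NeEstimate(
        population=population,
        chromosomes=kept_ch,
        ne_per_chromosome=nes,
        mean_r2_per_chromosome=r2s,
        s_harmonic_per_chromosome=ss,
        ne_mean=mean,
        ne_sd=sd,
        n_infinite=n_inf,
    )


def project_heterozygosity(h0: float, ne: float, t_max: int) -> DecayForecast:
    """Geometric decay H_t = H_0 (1 - 1/(2 Ne))^t for t = 0..t_max.

    ``halving_time`` is the smallest integer t with (1 - 1/(2 Ne))^t <=
    0.5, +inf for infinite Ne.  Ne <= 0.5 is degenerate and rejected.
    """
    if not (0.0 <= h0 <= 1.0):
        raise ValueError("H0 must be in [0, 1]")
    if ne <= 0.5:
        raise ValueError("Ne must exceed 0.5 for the decay formula")
    if t_max < 0:
        raise ValueError("t_max must be >= 0")
    if math.isinf(ne):
        traj = np.full(t_max + 1, h0)
        return DecayForecast(h0, ne, t_max, traj, float("inf"))
    factor = 1.0 - 1.0 / (2.0 * ne)
    traj = h0 * factor ** np.arange(t_max + 1)
    if factor <= 0.5:
        halving = 1.0
    else:
        halving = float(math.ceil(math.log(0.5) / math.log(factor)))
        # guard against floating point at the boundary
        while factor ** (halving - 1) <= 0.5:
            halving -= 1
        while factor**halving > 0.5:
            halving += 1
    return DecayForecast(h0, float(ne), t_max, traj, halving)
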