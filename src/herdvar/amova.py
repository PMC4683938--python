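"""One-level analysis of molecular variance with permutation significance.

Distances are squared Euclidean between mean-imputed dosage vectors
(equivalent up to scaling to allele-mismatch AMOVA for biallelic SNPs).
Sums of squares follow the pairwise-distance identities:

    SS_total  = (1/N)   sum_{i<j} d2_ij
    SS_within = sum_g (1/n_g) sum_{i<j in g} d2_ij
    SS_among  = SS_total - SS_within

with sigma2_w = MS_within and sigma2_a = (MS_among - sigma2_w)/n0,
n0 = (N - sum n_g^2 / N)/(k-1).  The permutation test shuffles sample
labels and compares sigma2_a.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .genotype_io import MISSING, GenotypeMatrix, PopulationPartition

__all__ = ["AmovaResult", "amova_one_level"]


@dataclass
class AmovaResult:
    ss_among: float
    ss_within: float
    ss_total: float
    df_among: int
    df_within: int
    df_total: int
    ms_among: float
    ms_within: float
    sigma2_among_raw: float
    sigma2_among: float  # truncated at 0
    sigma2_within: float
    pct_among: float
    pct_within: float
    f_value: float  # MS_among / MS_within
    p_value: float
    n_permutations: int

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("source\tSS\tMS\tdf\tF_value\tvariance_pct\tp_value\n")
            fh.write(
                f"between_populations\t{self.ss_among:.6g}\t{self.ms_among:.6g}\t"
                f"{self.df_among}\t{self.f_value:.6g}\t{self.pct_among:.4g}\t{self.p_value:.6g}\n"
            )
            fh.write(
                f"within_populations\t{self.ss_within:.6g}\t{self.ms_within:.6g}\t"
                f"{self.df_within}\t\t{self.pct_within:.4g}\t\n"
            )
            fh.write(f"total\t{self.ss_total:.6g}\t\t{self.df_total}\t\t100\t\n")


def _imputed_dosages(gm: GenotypeMatrix) -> np.ndarray:
    d = gm.dosages.astype(float)
    miss = gm.dosages == MISSING
    if miss.any():
        n_called = (~miss).sum(axis=0)
        col_mean = np.where(n_called > 0, np.where(miss, 0, d).sum(axis=0) / np.maximum(n_called, 1), 0.0)
        d = np.where(miss, col_mean, d)
    return d


def _components(d2: np.ndarray, labels: np.ndarray, sizes: np.ndarray) -> tuple[float, float, float, float]:
    """(ss_among, ss_within, sigma2_a_raw, sigma2_w) from a squared-distance matrix."""
    n = len(labels)
    k = len(sizes)
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in range(k):
        ix = np.nonzero(labels == g)[0]
        if len(ix) > 1:
            sub = d2[np.ix_(ix, ix)]
            su = np.triu_indices(len(ix), k=1)
            ss_within += sub[su].sum() / len(ix)
    ss_among = ss_total - ss_within
    df_among = k - 1
    df_within = n - k
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    n0 = (n - (sizes**2).sum() / n) / df_among
    sigma2_w = ms_within
    sigma2_a = (ms_among - sigma2_w) / n0
    return ss_among, ss_within, sigma2_a, sigma2_w


def amova_one_level(
    gm: GenotypeMatrix,
    partition: PopulationPartition,
    n_perm: int = 1000,
    seed: int | None = None,
) -> AmovaResult:
    """One-level AMOVA over the partition's populations.

    Requires >= 2 populations each with >= 2 samples.  Permutation p-value
    is (1 + #{sigma2_a* >= sigma2_a}) / (n_perm + 1); ``n_perm = 0`` skips
    the test (p reported as NaN).
    """
    partition.validate_against(gm)
    by_pop = partition.indices_by_population(gm)
    pops = list(by_pop)
    if len(pops) < 2:
        raise ValueError("AMOVA needs >= 2 populations")
    sizes = np.array([len(by_pop[p]) for p in pops])
    if (sizes < 2).any():
        raise ValueError("every population needs >= 2 samples")
    order = np.concatenate([by_pop[p] for p in pops])
    labels = np.concatenate([[g] * len(by_pop[p]) for g, p in enumerate(pops)])
    d = _imputed_dosages(gm)[order]
    d2 = squareform(pdist(d, metric="sqeuclidean"))

    n = len(labels)
    k = len(pops)
    ss_among, ss_within, sig_a_raw, sig_w = _components(d2, labels, sizes)
    ss_total = ss_among + ss_within
    df_among, df_within, df_total = k - 1, n - k, n - 1
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    sig_a = max(sig_a_raw, 0.0)
    total_var = sig_a + sig_w
    pct_among = 100.0 * sig_a / total_var if total_var > 0 else 0.0

    if n_perm >= 1:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(labels)
            _, _, sig_a_perm, _ = _components(d2, perm, sizes)
            if sig_a_perm >= sig_a_raw:
                count += 1
        p_value = (1 + count) / (n_perm + 1)
    else:
        p_value = float("nan")

    return AmovaResult(
        ss_among=float(ss_among),
        ss_within=float(ss_within),
        ss_total=float(ss_total),
        df_among=df_among,
        df_within=df_within,
        df_total=df_total,
        ms_among=float(ms_among),
        ms_within=float(ms_within),
        sigma2_among_raw=float(sig_a_raw),
        sigma2_among=float(sig_a),
        sigma2_within=float(sig_w),
        pct_among=float(pct_among),
        pct_within=float(100.0 - pct_among),
        f_value=float(ms_among / ms_within) if ms_within > 0 else float("inf"),
        p_value=float(p_value),
        n_permutations=n_perm,
    )
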