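"""Rarefaction allelic richness and private allelic richness.

For a locus with per-allele gene-copy counts N_a summing to N, the
expected number of distinct alleles in a subsample of g copies is

    A_R = sum_a [ 1 - C(N - N_a, g) / C(N, g) ]

with C(x, g) = 0 when x < g.  Private richness multiplies the focal
population's inclusion probability by the probability the allele is absent
from every other population's g-copy subsample.  Combinatorics are exact
integer arithmetic up to N = 500, log-gamma above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix, PopulationPartition
from .popstats import allele_freq_table

__all__ = [
    "RarefactionResult",
    "rarefied_allele_richness",
    "rarefied_private_richness",
    "richness_table",
]

_EXACT_LIMIT = 500


def _hyper_miss(N: int, N_a: int, g: int) -> float:
    """P(allele with N_a of N copies absent from a g-copy subsample)."""
    if N - N_a < g:
        return 0.0
    if N <= _EXACT_LIMIT:
        return math.comb(N - N_a, g) / math.comb(N, g)
    # log-space fallback: C(N-Na, g)/C(N, g)
    lg = (
        math.lgamma(N - N_a + 1)
        - math.lgamma(N - N_a - g + 1)
        - math.lgamma(N + 1)
        + math.lgamma(N - g + 1)
    )
    return math.exp(lg)


def rarefied_allele_richness(allele_counts: Sequence[int], g: int) -> float:
    """Expected allele count in a g-copy subsample of one locus.

    ``allele_counts`` are gene-copy counts per allele (zeros allowed).
    """
    counts = [int(c) for c in allele_counts]
    if any(c < 0 for c in counts):
        raise ValueError("negative allele count")
    N = sum(counts)
    if g < 1:
        raise ValueError("g must be >= 1")
    if g > N:
        raise ValueError(f"g={g} exceeds total gene copies N={N}")
    return float(sum(1.0 - _hyper_miss(N, c, g) for c in counts if c > 0))


def rarefied_private_richness(
    counts_by_population: Mapping[str, Sequence[int]],
    focal_pop: str,
    g: int,
) -> float:
    """Expected number of alleles private to ``focal_pop`` in g-copy subsamples.

    All populations must have at least g gene copies at the locus.  With
    Q(k, a) the probability allele a appears in a g-copy subsample from
    population k:  pA_R = sum_a Q(focal, a) * prod_{k != focal} (1 - Q(k, a)).
    """
    if focal_pop not in counts_by_population:
        raise KeyError(focal_pop)
    n_alleles = {len(c) for c in counts_by_population.values()}
    if len(n_alleles) != 1:
        raise ValueError("allele count tables must align across populations")
    totals = {k: sum(int(x) for x in c) for k, c in counts_by_population.items()}
    low = [k for k, N in totals.items() if N < g]
    if low:
        raise ValueError(f"populations below g={g} gene copies: {low}")
    (n_a,) = n_alleles
    out = 0.0
    for a in range(n_a):
        q_focal = 1.0 - _hyper_miss(totals[focal_pop], int(counts_by_population[focal_pop][a]), g)
        prod = 1.0
        for k, counts in counts_by_population.items():
            if k == focal_pop:
                continue
            prod *= _hyper_miss(totals[k], int(counts[a]), g)
        out += q_focal * prod
    return out


@dataclass
class RarefactionResult:
    populations: list[str]
    g: int
    ar_mean: dict[str, float]
    ar_sd: dict[str, float]
    par_mean: dict[str, float]  # empty when a single population
    par_sd: dict[str, float]
    loci_used: int
    loci_skipped: int

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("population\tg\tA_R\tA_R_sd\tpA_R\tpA_R_sd\tloci_used\n")
            for pop in self.populations:
                par = self.par_mean.get(pop)
                par_s = self.par_sd.get(pop)
                fh.write(
                    f"{pop}\t{self.g}\t{self.ar_mean[pop]:.6g}\t{self.ar_sd[pop]:.6g}\t"
                    f"{'NA' if par is None else format(par, '.6g')}\t"
                    f"{'NA' if par_s is None else format(par_s, '.6g')}\t{self.loci_used}\n"
                )


def richness_table(
    gm: GenotypeMatrix,
    partition: PopulationPartition,
    g: int | None = None,
) -> RarefactionResult:
    """Per-population A_R (and pA_R when >= 2 populations) averaged over loci.

    ``g`` defaults to the largest even value not exceeding the minimum
    non-missing gene-copy count over populations and loci.  Loci where any
    population falls below g copies are skipped for all populations.
    """
    table = allele_freq_table(gm, partition)
    pops = table.populations
    copies = 2 * table.n_called  # pops x loci gene copies
    if g is None:
        m = int(copies.min())
        g = m if m % 2 == 0 else m - 1
    if g < 2:
        raise ValueError(f"standardized gene-copy count g={g} < 2")
    usable = (copies >= g).all(axis=0)
    n_b = 2 * table.n_hom_b + table.n_het  # allele_b copies
    n_a = copies - n_b
    ar_per_locus = {p: [] for p in pops}
    par_per_locus = {p: [] for p in pops} if len(pops) >= 2 else {}
    for j in np.nonzero(usable)[0]:
        counts = {p: (int(n_a[k, j]), int(n_b[k, j])) for k, p in enumerate(pops)}
        for p in pops:
            ar_per_locus[p].append(rarefied_allele_richness(counts[p], g))
        if len(pops) >= 2:
            for p in pops:
                par_per_locus[p].append(rarefied_private_richness(counts, p, g))
    loci_used = int(usable.sum())
    if loci_used == 0:
        raise ValueError("no loci usable at the chosen g")

    def _stats(d: dict[str, list[float]]) -> tuple[dict[str, float], dict[str, float]]:
        means = {p: float(np.mean(v)) for p, v in d.items()}
        sds = {p: (float(np.std(v, ddof=1)) if len(v) > 1 else 0.0) for p, v in d.items()}
        return means, sds

    ar_mean, ar_sd = _stats(ar_per_locus)
    par_mean, par_sd = _stats(par_per_locus) if par_per_locus else ({}, {})
    return RarefactionResult(
        populations=pops,
        g=g,
        ar_mean=ar_mean,
        ar_sd=ar_sd,
        par_mean=par_mean,
        par_sd=par_sd,
        loci_used=loci_used,
        loci_skipped=int(gm.n_markers - loci_used),
    )
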