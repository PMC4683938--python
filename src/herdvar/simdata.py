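"""Synthetic genotype data with known truth.

Two generators cover the statistical structure the pipeline assumes:

* :func:`balding_nichols` — population allele frequencies drawn
  Beta(p(1-F)/F, (1-p)(1-F)/F) around a shared ancestral frequency,
  genotypes Binomial(2, p_k).  Ideal for differentiation statistics
  (theta, distances, AMOVA, rarefaction): expected pairwise F_ST between
  populations with divergences F_i and F_j is about (F_i + F_j)/2.
  Markers are independent, so there is no LD signal.

* :func:`wright_fisher_forward` — a forward diploid random-mating
  simulation that produces genuine drift LD for Ne estimation and
  heterozygosity-decay checks.

:func:`korean_like_scenario` packages a mainland-plus-two-islands design
(one large, two small drifting populations sampled 40/20/20) built on the
forward simulator so that both differentiation orderings and the
small-island LD signature hold at once.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix, MarkerInfo, PopulationPartition

__all__ = [
    "IslandScenario",
    "TruthManifest",
    "balding_nichols",
    "wright_fisher_forward",
    "korean_like_scenario",
]


@dataclass(frozen=True)
class IslandScenario:
    """Parameters for a Balding-Nichols island design."""

    n_markers: int = 1000
    n_chromosomes: int = 29
    population_f: tuple[float, ...] = (0.01, 0.05)
    sample_sizes: tuple[int, ...] = (20, 20)
    population_names: tuple[str, ...] | None = None
    ancestral_low: float = 0.05
    ancestral_high: float = 0.95
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.population_f) != len(self.sample_sizes):
            raise ValueError("population_f and sample_sizes must align")
        if any(not (0.0 <= f < 1.0) for f in self.population_f):
            raise ValueError("F values must be in [0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.population_names is not None and len(self.population_names) != len(self.population_f):
            raise ValueError("population_names must align with population_f")

    @property
    def names(self) -> tuple[str, ...]:
        if self.population_names is not None:
            return self.population_names
        return tuple(f"pop{k + 1}" for k in range(len(self.population_f)))


@dataclass
class TruthManifest:
    """Ground truth serialized beside every generated dataset."""

    model: str
    seed: int
    population_f: dict[str, float]
    census_sizes: dict[str, int]
    sample_sizes: dict[str, int]
    expected_pairwise_fst: dict[str, float]
    expected_het: dict[str, float]
    extras: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        return cls(**json.loads(Path(path).read_text()))


def _marker_list(n_markers: int, n_chromosomes: int) -> list[MarkerInfo]:
    """Evenly spread markers over autosomes, 1-based Mb-ish positions."""
    per = [n_markers // n_chromosomes] * n_chromosomes
    for i in range(n_markers % n_chromosomes):
        per[i] += 1
    markers = []
    idx = 1
    for c, cnt in enumerate(per, start=1):
        for j in range(cnt):
            markers.append(MarkerInfo(id=f"snp{idx}", chromosome=str(c), position=(j + 1) * 100_000))
            idx += 1
    return markers


def _sprinkle_missing(dosages: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    if rate > 0:
        mask = rng.random(dosages.shape) < rate
        dosages[mask] = MISSING


def balding_nichols(
    scenario: IslandScenario,
) -> tuple[GenotypeMatrix, PopulationPartition, TruthManifest]:
    """Generate genotypes under the Balding-Nichols divergence model.

    F = 0 reproduces the ancestral frequency exactly in that population.
    Deterministic for a given scenario (seed included in the scenario).
    """
    rng = np.random.default_rng(scenario.seed)
    L = scenario.n_markers
    anc = rng.uniform(scenario.ancestral_low, scenario.ancestral_high, size=L)
    names = scenario.names
    blocks: list[np.ndarray] = []
    sample_ids: list[str] = []
    mapping: dict[str, str] = {}
    het: dict[str, float] = {}
    for k, (f, s, name) in enumerate(zip(scenario.population_f, scenario.sample_sizes, names)):
        if f == 0.0:
            p_k = anc
        else:
            a = anc * (1 - f) / f
            b = (1 - anc) * (1 - f) / f
            p_k = rng.beta(a, b)
        g = rng.binomial(2, p_k, size=(s, L)).astype(np.int8)
        blocks.append(g)
        ids = [f"{name}_{i + 1}" for i in range(s)]
        sample_ids += ids
        mapping.update({i: name for i in ids})
        het[name] = float(np.mean(2 * anc * (1 - anc)) * (1 - f))
    dosages = np.vstack(blocks)
    _sprinkle_missing(dosages, scenario.missing_rate, rng)
    gm = GenotypeMatrix(dosages, _marker_list(L, scenario.n_chromosomes), sample_ids)
    fst = {
        f"{names[i]}|{names[j]}": (scenario.population_f[i] + scenario.population_f[j]) / 2.0
        for i in range(len(names))
        for j in range(i + 1, len(names))
    }
    manifest = TruthManifest(
        model="balding_nichols",
        seed=scenario.seed,
        population_f=dict(zip(names, scenario.population_f)),
        census_sizes={n: 0 for n in names},
        sample_sizes=dict(zip(names, scenario.sample_sizes)),
        expected_pairwise_fst=fst,
        expected_het=het,
    )
    return gm, PopulationPartition(mapping), manifest


def _wf_drift(
    haplotypes: np.ndarray,
    n_chrom_of: np.ndarray,
    generations: int,
    rng: np.random.Generator,
    recomb: float,
) -> np.ndarray:
    """Drift a haplotype pool (2N x L, 0/1) for ``generations`` generations.

    Random mating with distinct parents per offspring; ``recomb`` is the
    recombination fraction between adjacent markers within a chromosome
    (0.5 = free recombination); chromosomes always assort independently.
    """
    two_n, L = haplotypes.shape
    N = two_n // 2
    for _ in range(generations):
        # each offspring draws two distinct parents
        pa = rng.integers(0, N, size=N)
        pb = (pa + 1 + rng.integers(0, N - 1, size=N)) % N
        if recomb >= 0.5:
            # free recombination: per-locus coin flips, fully vectorized
            children = np.empty_like(haplotypes)
            for slot, parent in ((0, pa), (1, pb)):
                pick = rng.random((N, L)) < 0.5
                h1 = haplotypes[2 * parent]
                h2 = haplotypes[2 * parent + 1]
                children[slot::2] = np.where(pick, h1, h2)
            haplotypes = children
        else:
            # crossover walk along each chromosome: switch with prob. recomb
            # between adjacent markers, independent phase per chromosome
            new_chrom = np.empty(L, dtype=bool)
            new_chrom[0] = True
            new_chrom[1:] = n_chrom_of[1:] != n_chrom_of[:-1]
            children = np.empty_like(haplotypes)
            for slot, parent in ((0, pa), (1, pb)):
                switch = rng.random((N, L)) < recomb
                switch[:, new_chrom] = rng.random((N, int(new_chrom.sum()))) < 0.5
                # cumulative XOR of switches gives the current-haplotype phase
                pick = np.logical_xor.accumulate(switch, axis=1)
                h1 = haplotypes[2 * parent]
                h2 = haplotypes[2 * parent + 1]
                children[slot::2] = np.where(pick, h1, h2)
            haplotypes = children
    return haplotypes


def wright_fisher_forward(
    N: int,
    S: int,
    L: int,
    n_chrom: int,
    generations: int,
    seed: int,
    recomb: float = 0.5,
    init_freq: np.ndarray | None = None,
) -> GenotypeMatrix:
    """Forward Wright-Fisher simulation of one diploid population.

    Initial frequencies are Uniform(0.1, 0.9) unless ``init_freq`` is
    given; after ``generations`` of drift, ``S`` individuals are sampled
    without replacement.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    if S > N:
        raise ValueError(f"cannot sample S={S} from N={N}")
    if generations < 0:
        raise ValueError("generations must be >= 0")
    rng = np.random.default_rng(seed)
    if init_freq is None:
        init_freq = rng.uniform(0.1, 0.9, size=L)
    markers = _marker_list(L, n_chrom)
    chrom_of = np.array([int(m.chromosome) for m in markers])
    haps = (rng.random((2 * N, L)) < init_freq).astype(np.int8)
    haps = _wf_drift(haps, chrom_of, generations, rng, recomb)
    take = rng.choice(N, size=S, replace=False)
    dosages = (haps[2 * take] + haps[2 * take + 1]).astype(np.int8)
    ids = [f"ind_{i + 1}" for i in range(S)]
    return GenotypeMatrix(dosages, markers, ids)


def korean_like_scenario(
    seed: int,
    n_markers: int = 29_000,
    n_chromosomes: int = 29,
    census: tuple[int, int, int] = (500, 90, 60),
    samples: tuple[int, int, int] = (40, 20, 20),
    generations: int = 4,
    missing_rate: float = 0.002,
) -> tuple[GenotypeMatrix, PopulationPartition, TruthManifest]:
    """Mainland + two drifting islands sampled 40/20/20.

    All three populations are founded from one ancestral frequency pool
    and drift independently for ``generations`` generations at their
    census sizes (founding counts as one further generation of drift), so
    divergence from the ancestor is roughly F_k = (generations + 1) /
    (2 N_k) while small islands also accumulate the LD that the Ne
    estimator reads.  Defaults give expected pairwise theta of about 0.015
    (mainland-island) and 0.035 (island-island).
    """
    names = ("mainland", "island1", "island2")
    rng = np.random.default_rng(seed)
    anc = rng.uniform(0.05, 0.95, size=n_markers)
    markers = _marker_list(n_markers, n_chromosomes)
    chrom_of = np.array([int(m.chromosome) for m in markers])
    blocks: list[np.ndarray] = []
    sample_ids: list[str] = []
    mapping: dict[str, str] = {}
    f_truth: dict[str, float] = {}
    for name, N, S in zip(names, census, samples):
        sub_rng = np.random.default_rng(rng.integers(0, 2**63))
        haps = (sub_rng.random((2 * N, n_markers)) < anc).astype(np.int8)
        haps = _wf_drift(haps, chrom_of, generations, sub_rng, recomb=0.5)
        take = sub_rng.choice(N, size=S, replace=False)
        blocks.append((haps[2 * take] + haps[2 * take + 1]).astype(np.int8))
        ids = [f"{name}_{i + 1}" for i in range(S)]
        sample_ids += ids
        mapping.update({i: name for i in ids})
        f_truth[name] = 1.0 - (1.0 - 1.0 / (2 * N)) ** (generations + 1)
    dosages = np.vstack(blocks)
    _sprinkle_missing(dosages, missing_rate, rng)
    gm = GenotypeMatrix(dosages, markers, sample_ids)
    fst = {
        f"{a}|{b}": (f_truth[a] + f_truth[b]) / 2.0
        for i, a in enumerate(names)
        for b in names[i + 1 :]
    }
    manifest = TruthManifest(
        model="wright_fisher_islands",
        seed=seed,
        population_f=f_truth,
        census_sizes=dict(zip(names, census)),
        sample_sizes=dict(zip(names, samples)),
        expected_pairwise_fst=fst,
        expected_het={n: float(np.mean(2 * anc * (1 - anc)) * (1 - f)) for n, f in f_truth.items()},
        extras={"generations": generations, "missing_rate": missing_rate},
    )
    return gm, PopulationPartition(mapping), manifest
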