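import math
from decimal import Decimal, getcontext

import numpy as np
import pytest

from herdvar.genotype_io import MISSING, GenotypeMatrix, MarkerInfo, PopulationPartition
from herdvar.ne_ld import (
    composite_r2,
    mean_r2_chromosome,
    ne_from_r2,
    ne_genome,
    project_heterozygosity,
)
from herdvar.simdata import wright_fisher_forward

from conftest import random_gm


def gm_from_columns(cols):
    d = np.array(cols, dtype=np.int8).T
    markers = [MarkerInfo(f"m{j}", "1", j + 1) for j in range(len(cols))]
    return GenotypeMatrix(d, markers, [f"s{i}" for i in range(d.shape[0])])


class TestCompositeR2:
    def test_hand_covariance_arithmetic(self):
        # dosages (0,0,2,2) at both loci: cov = 4/3, delta = 2/3, p = q = 0.5
        gm = gm_from_columns([(0, 0, 2, 2), (0, 0, 2, 2)])
        r2 = composite_r2(gm, 0, 1)
        assert r2 == pytest.approx((2 / 3) ** 2 / (0.25 * 0.25), abs=1e-12)
        assert r2 > 1  # exceeds 1, retained by convention

    def test_locus_with_itself(self):
        gm = gm_from_columns([(0, 1, 1, 2), (0, 1, 1, 2)])
        x = np.array([0, 1, 1, 2], dtype=float)
        var = np.cov(x, ddof=1)
        p = x.mean() / 2
        expected = (0.5 * var) ** 2 / (p * (1 - p)) ** 2
        assert composite_r2(gm, 0, 1) == pytest.approx(float(expected), abs=1e-12)

    def test_independent_loci_small(self):
        rng = np.random.default_rng(0)
        n = 400
        vals = []
        for _ in range(40):
            gm = gm_from_columns([rng.binomial(2, 0.5, n), rng.binomial(2, 0.5, n)])
            vals.append(composite_r2(gm, 0, 1))
        # mean r2 on the 1/n scale for independent loci
        assert np.mean(vals) < 5 / n

    def test_monomorphic_undefined(self):
        gm = gm_from_columns([(0, 0, 0, 0), (0, 1, 2, 1)])
        assert math.isnan(composite_r2(gm, 0, 1))

    def test_symmetry_and_relabel_invariance(self):
        rng = np.random.default_rng(3)
        gm = gm_from_columns([rng.binomial(2, 0.3, 30), rng.binomial(2, 0.6, 30)])
        assert composite_r2(gm, 0, 1) == pytest.approx(composite_r2(gm, 1, 0), abs=1e-15)
        flipped = GenotypeMatrix(2 - gm.dosages, gm.markers, gm.sample_ids)
        assert composite_r2(flipped, 0, 1) == pytest.approx(composite_r2(gm, 0, 1), abs=1e-12)
        # hw-adjusted form shares both properties
        assert composite_r2(flipped, 0, 1, hw_adjust=True) == pytest.approx(
            composite_r2(gm, 0, 1, hw_adjust=True), abs=1e-12
        )

    def test_too_few_shared_samples(self):
        gm = gm_from_columns([(1, MISSING, MISSING, 2), (MISSING, 1, 2, MISSING)])
        assert math.isnan(composite_r2(gm, 0, 1))


class TestMeanR2Chromosome:
    def test_two_loci_single_pair(self):
        gm = gm_from_columns([(0, 1, 1, 2), (2, 1, 1, 0)])
        mean, n_pairs, s = mean_r2_chromosome(gm, "1", maf_min=0.0, hw_adjust=False)
        assert n_pairs == 1
        assert mean == pytest.approx(composite_r2(gm, 0, 1), abs=1e-12)
        assert s == 4.0

    def test_all_below_maf_undefined(self):
        gm = gm_from_columns([(0, 0, 0, 1), (0, 0, 1, 0)])
        mean, n_pairs, _ = mean_r2_chromosome(gm, "1", maf_min=0.2)
        assert n_pairs == 0 and math.isnan(mean)

    @pytest.mark.parametrize("hw_adjust", [False, True])
    @pytest.mark.parametrize("missing_rate", [0.0, 0.1])
    def test_brute_force_oracle_ten_loci(self, hw_adjust, missing_rate):
        rng = np.random.default_rng(17)
        gm = random_gm(rng, 25, 10, missing_rate=missing_rate, n_chrom=1)
        mean, n_pairs, s_harm = mean_r2_chromosome(gm, "1", maf_min=0.0, hw_adjust=hw_adjust)
        vals, ns = [], []
        for a in range(10):
            for b in range(a + 1, 10):
                r2 = composite_r2(gm, a, b, hw_adjust=hw_adjust)
                if math.isfinite(r2):
                    vals.append(r2)
                    shared = (gm.dosages[:, a] != MISSING) & (gm.dosages[:, b] != MISSING)
                    ns.append(int(shared.sum()))
        assert n_pairs == len(vals)
        assert mean == pytest.approx(np.mean(vals), abs=1e-10)
        assert s_harm == pytest.approx(len(ns) / sum(1 / n for n in ns), abs=1e-10)


class TestNeFromR2:
    def test_large_s_branch_quadratic(self):
        # r2_drift = 1/300 exactly; solve with Decimal arithmetic
        getcontext().prec = 50
        drift = Decimal(1) / Decimal(300)
        expected = (Decimal(1) / 3 + (Decimal(1) / 9 - Decimal("2.76") * drift).sqrt()) / (2 * drift)
        S = 100.0
        mean_r2 = float(drift) + 1 / S + 3.19 / S**2
        assert ne_from_r2(mean_r2, S) == pytest.approx(float(expected), rel=1e-10)

    def test_zero_drift_infinite(self):
        S = 50.0
        assert ne_from_r2(1 / S + 3.19 / S**2, S) == math.inf
        S = 20.0
        assert ne_from_r2(0.0018 + 0.907 / S + 4.44 / S**2, S) == math.inf

    def test_round_trip_inversion(self):
        # the S>=30 quadratic (minus 2.76 under the root, as published)
        # algebraically inverts E_drift(Ne) = 1/(3 Ne) - 0.69/Ne^2;
        # feeding that expectation back re-estimates Ne to 6 sig digits
        for ne in (50.0, 200.0, 1000.0):
            drift = 1 / (3 * ne) - 0.69 / ne**2
            S = 1000.0
            est = ne_from_r2(drift + 1 / S + 3.19 / S**2, S)
            assert est == pytest.approx(ne, rel=1e-6)

    def test_monotone_decreasing_in_r2(self):
        # monotone on the domain where the estimate is finite; above the
        # discriminant boundary the sentinel +inf is returned
        S = 40.0
        r2s = np.linspace(0.028, 0.065, 25)
        nes = [ne_from_r2(r, S) for r in r2s]
        finite = [x for x in nes if math.isfinite(x)]
        assert len(finite) >= 10
        assert all(a > b for a, b in zip(finite, finite[1:]))
        assert all(math.isfinite(x) or x == math.inf for x in nes)

    def test_small_s_branch_used(self):
        # identical mean_r2 maps differently through the two branches
        assert ne_from_r2(0.08, 29.0) != ne_from_r2(0.08, 30.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ne_from_r2(float("nan"), 50)
        with pytest.raises(ValueError):
            ne_from_r2(0.05, 1.0)
        with pytest.raises(ValueError):
            ne_from_r2(-0.1, 50)


class TestNeGenome:
    def _single_pop(self, gm):
        return PopulationPartition({s: "p" for s in gm.sample_ids})

    def test_wright_fisher_recovery(self):
        gm = wright_fisher_forward(N=50, S=50, L=1160, n_chrom=29, generations=20, seed=4)
        est = ne_genome(gm, self._single_pop(gm), "p")
        assert 25 <= est.ne_mean <= 100
        assert est.mating_model == "random"

    def test_identical_chromosomes_zero_sd(self):
        rng = np.random.default_rng(12)
        block = rng.binomial(2, rng.uniform(0.2, 0.8, 20), size=(30, 20)).astype(np.int8)
        d = np.hstack([block, block])
        markers = [MarkerInfo(f"a{j}", "1", j + 1) for j in range(20)] + [
            MarkerInfo(f"b{j}", "2", j + 1) for j in range(20)
        ]
        gm = GenotypeMatrix(d, markers, [f"s{i}" for i in range(30)])
        est = ne_genome(gm, self._single_pop(gm), "p")
        if len(est.chromosomes) == 2 and est.n_infinite == 0:
            assert est.ne_sd == pytest.approx(0.0, abs=1e-9)

    def test_island_smaller_than_mainland(self):
        big = wright_fisher_forward(N=200, S=30, L=580, n_chrom=29, generations=8, seed=2)
        small = wright_fisher_forward(N=20, S=20, L=580, n_chrom=29, generations=8, seed=2)
        ne_big = ne_genome(big, self._single_pop(big), "p").ne_mean
        ne_small = ne_genome(small, self._single_pop(small), "p").ne_mean
        assert ne_small < ne_big

    def test_tsv_output(self, tmp_path):
        gm = wright_fisher_forward(N=30, S=30, L=290, n_chrom=29, generations=10, seed=7)
        est = ne_genome(gm, self._single_pop(gm), "p")
        est.to_tsv(tmp_path / "ne.tsv")
        lines = (tmp_path / "ne.tsv").read_text().splitlines()
        assert lines[0] == "chromosome\tne\tmean_r2\ts_harmonic"


class TestProjectHeterozygosity:
    def test_t_zero_unchanged(self):
        fc = project_heterozygosity(0.31, 40.0, 10)
        assert fc.trajectory[0] == 0.31

    def test_reported_island_halving_times(self):
        assert project_heterozygosity(0.306, 7.0, 50).halving_time == 10
        assert project_heterozygosity(0.303, 11.0, 50).halving_time == 15

    def test_one_step_arithmetic(self):
        fc = project_heterozygosity(0.306, 7.0, 1)
        assert fc.trajectory[1] == pytest.approx(0.306 * 13 / 14, abs=1e-12)
        assert fc.trajectory[1] == pytest.approx(0.28414, abs=5e-6)

    def test_strictly_decreasing(self):
        fc = project_heterozygosity(0.5, 25.0, 30)
        assert all(a > b for a, b in zip(fc.trajectory, fc.trajectory[1:]))

    def test_infinite_ne_flat(self):
        fc = project_heterozygosity(0.4, math.inf, 5)
        assert np.all(fc.trajectory == 0.4)
        assert fc.halving_time == math.inf

    def test_degenerate_ne_rejected(self):
        with pytest.raises(ValueError):
            project_heterozygosity(0.3, 0.5, 10)

    def test_halving_definition_exact(self):
        # halving_time is the smallest integer t with factor^t <= 0.5
        for ne in (0.9, 1.0, 2.5, 7, 11, 33.3, 500):
            fc = project_heterozygosity(1.0, float(ne), 0)
            t = fc.halving_time
            factor = 1 - 1 / (2 * ne)
            assert factor**t <= 0.5
            if t > 0:
                assert factor ** (t - 1) > 0.5
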