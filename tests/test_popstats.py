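import math

import numpy as np
import pytest

from herdvar.genotype_io import MISSING, GenotypeMatrix, MarkerInfo, PopulationPartition
from herdvar.popstats import (
    allele_freq_table,
    diversity_metrics,
    fst_scan,
    nei_distance,
    pairwise_fst,
    wc_fstatistics,
)
from herdvar.simdata import IslandScenario, balding_nichols

from conftest import random_gm


def wc_oracle_locus(pop_counts):
    """Independent scalar transcription of the 1984 variance components.

    ``pop_counts``: list of (n_AA, n_Aa, n_aa) per population, counting
    genotypes for the allele whose frequency is p.  Returns (a, b, c).
    """
    r = len(pop_counts)
    n = [sum(t) for t in pop_counts]
    p = [(2 * t[0] + t[1]) / (2 * ni) for t, ni in zip(pop_counts, n)]
    h = [t[1] / ni for t, ni in zip(pop_counts, n)]
    nbar = sum(n) / r
    nc = (r * nbar - sum(ni**2 for ni in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, b, c


def gm_from_counts(pop_counts_per_locus):
    """Build a matrix + partition realizing genotype counts per pop per locus.

    ``pop_counts_per_locus``: list over loci of lists over populations of
    (n_AA, n_Aa, n_aa) where AA means dosage 2.  All loci must give the same
    per-population sample sizes.
    """
    n_loci = len(pop_counts_per_locus)
    sizes = [sum(t) for t in pop_counts_per_locus[0]]
    cols = {k: [] for k in range(len(sizes))}
    for locus in pop_counts_per_locus:
        for k, (n2, n1, n0) in enumerate(locus):
            cols[k].append([2] * n2 + [1] * n1 + [0] * n0)
    blocks = [np.array(cols[k], dtype=np.int8).T for k in range(len(sizes))]
    d = np.vstack(blocks)
    markers = [MarkerInfo(f"m{j}", "1", j + 1) for j in range(n_loci)]
    ids, mapping = [], {}
    for k, s in enumerate(sizes):
        for i in range(s):
            sid = f"p{k}_s{i}"
            ids.append(sid)
            mapping[sid] = f"pop{k}"
    return GenotypeMatrix(d, markers, ids), PopulationPartition(mapping)


class TestDiversity:
    def test_fixed_population(self):
        gm, part = gm_from_counts([[(3, 0, 0), (0, 0, 3)]])
        table = diversity_metrics(gm, part)
        for pop in ("pop0", "pop1"):
            row = table.row(pop)
            assert row.maf_mean == 0.0
            assert row.het_obs_mean == 0.0
            assert row.het_exp_mean == 0.0
            assert row.n_fixed == 1  # fixed at the single locus

    def test_single_marker_hand_arithmetic(self):
        # genotypes {AA, Aa, aa}: p = 0.5, H_obs = 1/3, H_exp = 0.5
        gm, part = gm_from_counts([[(1, 1, 1)]])
        row = diversity_metrics(gm, part).row("pop0")
        assert row.het_obs_mean == pytest.approx(1 / 3)
        assert row.het_exp_mean == pytest.approx(0.5)
        assert row.maf_mean == pytest.approx(0.5)

    def test_hobs_equals_hexp_gives_null_ttest(self):
        # dosage column (0,1,1,2): p=0.5, H_obs=0.5=H_exp at every marker
        gm, part = gm_from_counts([[(1, 2, 1)]] * 5)
        row = diversity_metrics(gm, part).row("pop0")
        assert row.t_statistic == 0.0
        assert row.t_pvalue == 1.0

    def test_unbiased_switch(self):
        gm, part = gm_from_counts([[(1, 2, 1)]])
        plain = diversity_metrics(gm, part).row("pop0").het_exp_mean
        unbiased = diversity_metrics(gm, part, unbiased_het_exp=True).row("pop0").het_exp_mean
        assert unbiased == pytest.approx(plain * 8 / 7)  # 2n/(2n-1) with n=4

    def test_allele_relabel_invariance(self):
        rng = np.random.default_rng(11)
        gm = random_gm(rng, 12, 100)
        part = PopulationPartition({s: "p" for s in gm.sample_ids})
        flipped = GenotypeMatrix(
            np.where(gm.dosages == MISSING, MISSING, 2 - gm.dosages),
            gm.markers,
            gm.sample_ids,
        )
        a = diversity_metrics(gm, part).row("p")
        b = diversity_metrics(flipped, part).row("p")
        assert a.maf_mean == pytest.approx(b.maf_mean)
        assert a.het_obs_mean == pytest.approx(b.het_obs_mean)
        assert a.n_fixed == b.n_fixed


class TestWcFstatistics:
    def test_opposite_fixation_theta_one(self):
        gm, part = gm_from_counts([[(5, 0, 0), (0, 0, 5)]] * 3)
        theta, _, _ = wc_fstatistics(gm, part)
        assert theta == pytest.approx(1.0)

    def test_duplicated_population_theta_near_zero(self):
        # theta-hat carries an O(1/n) negative bias at zero differentiation,
        # so a large-ish n keeps the duplicated-data estimate near zero
        rng = np.random.default_rng(0)
        gm_half = random_gm(rng, 120, 1200)
        d = np.vstack([gm_half.dosages, gm_half.dosages])
        ids = gm_half.sample_ids + [f"dup_{s}" for s in gm_half.sample_ids]
        gm = GenotypeMatrix(d, gm_half.markers, ids)
        mapping = {s: ("a" if not s.startswith("dup") else "b") for s in ids}
        theta, _, _ = wc_fstatistics(gm, PopulationPartition(mapping))
        assert abs(theta) <= 0.01

    def test_per_locus_matches_independent_oracle(self):
        counts = [(12, 5, 3), (2, 8, 10)]
        gm, part = gm_from_counts([counts])
        theta, f, per_locus = wc_fstatistics(gm, part)
        a, b, c = wc_oracle_locus(counts)
        assert theta == pytest.approx(a / (a + b + c), abs=1e-12)
        assert per_locus[0] == pytest.approx(a / (a + b + c), abs=1e-12)
        assert f == pytest.approx(1 - c / (b + c), abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_multilocus_matches_oracle_sums(self, seed):
        rng = np.random.default_rng(seed)
        loci = []
        for _ in range(20):
            loci.append([tuple(rng.multinomial(10, [1 / 3] * 3)) for _ in range(3)])
        gm, part = gm_from_counts(loci)
        theta, f, _ = wc_fstatistics(gm, part)
        sums = np.zeros(3)
        for locus in loci:
            a, b, c = wc_oracle_locus(locus)
            if math.isfinite(a + b + c) and (a + b + c) != 0:
                sums += (a, b, c)
        assert theta == pytest.approx(sums[0] / sums.sum(), abs=1e-12)
        assert f == pytest.approx(1 - sums[2] / (sums[1] + sums[2]), abs=1e-12)

    def test_monomorphic_everywhere_raises(self):
        gm, part = gm_from_counts([[(4, 0, 0), (4, 0, 0)]])
        with pytest.raises(ValueError):
            wc_fstatistics(gm, part)

    def test_theta_recovers_balding_nichols_f(self):
        scenario = IslandScenario(
            n_markers=5000, population_f=(0.15, 0.15), sample_sizes=(20, 20), seed=5
        )
        gm, part, _ = balding_nichols(scenario)
        theta, _, _ = wc_fstatistics(gm, part)
        assert 0.10 <= theta <= 0.20


class TestPairwiseFst:
    def test_identical_populations_not_significant(self):
        rng = np.random.default_rng(2)
        gm_half = random_gm(rng, 10, 400)
        d = np.vstack([gm_half.dosages, gm_half.dosages])
        ids = gm_half.sample_ids + [f"d_{s}" for s in gm_half.sample_ids]
        gm = GenotypeMatrix(d, gm_half.markers, ids)
        part = PopulationPartition({s: ("a" if not s.startswith("d_") else "b") for s in ids})
        ds = pairwise_fst(gm, part, n_boot=200, seed=1)
        assert ds.p_values[0, 1] > 0.2

    def test_balding_nichols_pair_significant(self):
        scenario = IslandScenario(
            n_markers=5000, population_f=(0.15, 0.15), sample_sizes=(20, 20), seed=8
        )
        gm, part, _ = balding_nichols(scenario)
        ds = pairwise_fst(gm, part, n_boot=100, seed=3)
        assert 0.10 <= ds.fst[0, 1] <= 0.20
        assert ds.p_values[0, 1] < 0.01

    def test_nboot_one_degenerate(self, three_pop):
        gm, part, _ = three_pop
        ds = pairwise_fst(gm, part, n_boot=1, seed=0)
        assert set(np.round(ds.p_values[np.isfinite(ds.p_values)], 6)) <= {0.5, 1.0}

    def test_seed_reproducible(self, three_pop):
        gm, part, _ = three_pop
        a = pairwise_fst(gm, part, n_boot=50, seed=9)
        b = pairwise_fst(gm, part, n_boot=50, seed=9)
        assert np.array_equal(a.p_values, b.p_values, equal_nan=True)

    def test_matrix_shape_and_symmetry(self, three_pop, tmp_path):
        gm, part, _ = three_pop
        ds = pairwise_fst(gm, part, n_boot=20, seed=0)
        assert np.allclose(ds.fst, ds.fst.T)
        assert np.allclose(np.diag(ds.fst), 0)
        assert np.allclose(ds.nei_d, ds.nei_d.T)
        ds.to_tsv(tmp_path / "d.tsv")
        lines = (tmp_path / "d.tsv").read_text().splitlines()
        assert len(lines) == 4


class TestNeiDistance:
    def test_identical_is_zero(self):
        f = np.array([0.2, 0.5, 0.9])
        assert nei_distance(f, f) == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic(self):
        # x: p=0.8 -> J_X = .64+.04 = .68; y: p=0.3 -> J_Y = .09+.49 = .58
        # J_XY = .24+.14 = .38; D = -ln(.38/sqrt(.3944))
        d = nei_distance(np.array([0.8]), np.array([0.3]))
        expected = -math.log(0.38 / math.sqrt(0.68 * 0.58))
        assert d == pytest.approx(expected, abs=1e-12)
        assert d == pytest.approx(0.5024, abs=5e-4)

    def test_opposite_fixation_infinite(self):
        assert nei_distance(np.array([1.0]), np.array([0.0])) == math.inf

    def test_no_loci_errors(self):
        with pytest.raises(ValueError):
            nei_distance(np.array([np.nan]), np.array([0.5]))

    def test_nonnegative_random(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            x, y = rng.uniform(0, 1, (2, 30))
            assert nei_distance(x, y) >= 0


class TestFstScan:
    def test_constant_theta_no_outliers(self):
        gm, part = gm_from_counts([[(2, 4, 2), (2, 4, 2)]] * 10)
        scan = fst_scan(gm, part, "pop0", "pop1")
        assert scan.outliers == []

    def test_engineered_outlier_flagged(self):
        rng = np.random.default_rng(6)
        loci = []
        for _ in range(999):
            g = tuple(rng.multinomial(10, [0.25, 0.5, 0.25]))
            loci.append([g, g])
        loci.append([(10, 0, 0), (0, 0, 10)])  # fixed difference
        gm, part = gm_from_counts(loci)
        scan = fst_scan(gm, part, "pop0", "pop1")
        assert scan.outliers == ["m999"]

    def test_symmetric_in_populations(self, three_pop):
        gm, part, _ = three_pop
        a, b = part.populations[:2]
        s1 = fst_scan(gm, part, a, b)
        s2 = fst_scan(gm, part, b, a)
        np.testing.assert_allclose(s1.theta, s2.theta, equal_nan=True)
        assert s1.threshold == pytest.approx(s2.threshold)

    def test_bed_output(self, tmp_path, three_pop):
        gm, part, _ = three_pop
        a, b = part.populations[:2]
        scan = fst_scan(gm, part, a, b)
        scan.to_bed_tsv(tmp_path / "scan.tsv")
        lines = (tmp_path / "scan.tsv").read_text().splitlines()
        assert len(lines) == gm.n_markers + 1


class TestAlleleFreqTable:
    def test_counts_consistent(self, three_pop_missing):
        gm, part, _ = three_pop_missing
        table = allele_freq_table(gm, part)
        called = table.n_called
        p = table.freq_b
        ok = called > 0
        manual = (table.n_het + 2 * table.n_hom_b)[ok] / (2 * called[ok])
        np.testing.assert_allclose(p[ok], manual)
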