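import itertools

import numpy as np
import pytest

from camelroutes.diversity_stats import (
    allelic_richness,
    amova,
    amova_fst,
    diversity_summary,
    groups_from_metadata,
    inbreeding_coefficient,
    pairwise_fst,
    per_locus_heterozygosity,
    weir_cockerham_fst,
    welch_t,
)
from camelroutes.genotype_io import MISSING, GenotypeMatrix
from camelroutes.synthetic_data import IslandModelSpec, simulate_island_genotypes


def matrix_from(rows, prefix="i"):
    rows = np.asarray(rows, dtype=np.int8)
    return GenotypeMatrix(
        [f"{prefix}{k}" for k in range(rows.shape[0])],
        [f"s{j}" for j in range(rows.shape[1])],
        rows,
    )


class TestHeterozygosity:
    def test_hand_arithmetic(self):
        G = matrix_from(np.array([[0], [1], [1], [2]]))
        he, ho = per_locus_heterozygosity(G)
        assert ho[0] == pytest.approx(0.5)
        assert he[0] == pytest.approx(8 / 7 * 0.5)  # unbiased (2n/(2n-1)) factor

    def test_monomorphic_is_zero(self):
        G = matrix_from(np.zeros((5, 1)))
        he, ho = per_locus_heterozygosity(G)
        assert he[0] == 0 and ho[0] == 0

    def test_fis_values(self):
        fis = inbreeding_coefficient(
            np.array([0.5, 0.5, 0.5714285714, 0.0]),
            np.array([0.5, 0.0, 0.5, 0.3]),
        )
        assert fis[0] == pytest.approx(0.0)
        assert fis[1] == pytest.approx(1.0)
        assert fis[2] == pytest.approx(0.125, abs=1e-6)
        assert np.isnan(fis[3])  # He = 0 -> undefined


class TestAllelicRichness:
    def test_combinatorial_oracle(self):
        # N=4 alleles with counts (2,2), g=2: AR = 2 - 2*C(2,2)/C(4,2)
        G = matrix_from(np.array([[1], [1]]))
        ar = allelic_richness(G, {"g": ["i0", "i1"]}, g=2)
        assert ar.loc[0, "AR"] == pytest.approx(2 - 2 / 6)
        assert ar.loc[0, "AR_minus_1"] == pytest.approx(1 - 2 / 6)

    def test_fixed_snp_gives_one(self):
        G = matrix_from(np.zeros((4, 1)))
        ar = allelic_richness(G, {"g": G.samples}, g=2)
        assert ar.loc[0, "AR"] == pytest.approx(1.0)

    def test_approaches_two_with_abundant_alleles(self):
        # counts (200, 200) at rarefaction size 10: both alleles near-certain
        G = matrix_from(np.ones((200, 1)))
        ar = allelic_richness(G, {"g": G.samples}, g=10)
        assert ar.loc[0, "AR"] > 1.99


class TestWelch:
    def test_hand_values(self):
        t, df, p = welch_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674234614)
        assert df == pytest.approx(4.0)
        assert 0 < p < 0.05

    def test_identical_groups(self):
        t, df, p = welch_t([1.0, 2, 3, 2], [2, 3, 1, 2.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_swap_negates_t_preserves_p(self):
        t1, _, p1 = welch_t([1, 2, 3, 7], [4, 5, 6])
        t2, _, p2 = welch_t([4, 5, 6], [1, 2, 3, 7])
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)


class TestWeirCockerham:
    def test_fixed_difference_gives_one(self):
        G = matrix_from([[0] * 5, [0] * 5, [0] * 5, [2] * 5, [2] * 5, [2] * 5])
        theta = weir_cockerham_fst(
            G, {"A": ["i0", "i1", "i2"], "B": ["i3", "i4", "i5"]}
        )
        assert theta == pytest.approx(1.0)

    def test_null_split_is_near_zero(self, island_unstructured):
        G, meta, _ = island_unstructured
        groups = groups_from_metadata(meta, G.samples, "population")
        theta = weir_cockerham_fst(G, groups)
        assert abs(theta) < 0.02

    @pytest.mark.parametrize("target", [0.05, 0.1])
    def test_recovers_simulated_fst(self, target):
        spec = IslandModelSpec(
            n_pops=2, n_per_pop=100, n_snps=2000, fst=target, seed=int(target * 100)
        )
        G, meta, _ = simulate_island_genotypes(spec)
        groups = groups_from_metadata(meta, G.samples, "population")
        assert weir_cockerham_fst(G, groups) == pytest.approx(target, abs=0.02)

    def test_invariant_to_allele_flip_and_order(self, island_3pop):
        G, meta, _ = island_3pop
        groups = groups_from_metadata(meta, G.samples, "population")
        theta = weir_cockerham_fst(G, groups)
        flipped = GenotypeMatrix(
            G.samples, G.snp_ids,
            np.where(G.calls == MISSING, MISSING, 2 - G.calls).astype(np.int8),
        )
        assert weir_cockerham_fst(flipped, groups) == pytest.approx(theta, abs=1e-12)
        perm = np.random.default_rng(0).permutation(G.n_samples)
        shuffled = GenotypeMatrix(
            [G.samples[i] for i in perm], G.snp_ids, G.calls[perm]
        )
        assert weir_cockerham_fst(shuffled, groups) == pytest.approx(theta, abs=1e-12)


def brute_force_amova(calls, pops):
    """Independent AMOVA oracle via pairwise squared haplotype distances.

    Computes sums of squares from pairwise distances (SSD identity:
    sum of squared deviations = sum of pairwise squared differences / n)
    instead of deviations from means, per SNP, then converts with the
    moment equations.
    """
    sig = np.zeros(3)
    for j in range(calls.shape[1]):
        haps, ind_of, pop_of = [], [], []
        for i, g in enumerate(calls[:, j]):
            if g == MISSING:
                continue
            a = [1, 0] if g == 1 else [g // 2] * 2
            for x in a:
                haps.append(x)
                ind_of.append(i)
                pop_of.append(pops[i])
        haps = np.array(haps, dtype=float)
        ind_of = np.array(ind_of)
        pop_of = np.array(pop_of)
        N = len(haps) // 2
        P = len(set(pop_of.tolist()))
        if P < 2 or N <= P:
            continue
        d2 = (haps[:, None] - haps[None, :]) ** 2

        def ssd(mask_groups):
            total = 0.0
            for g in mask_groups:
                idx = np.flatnonzero(g)
                total += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
            return total

        ssd_total = ssd([np.ones(len(haps), bool)])
        ssd_within_ind = ssd([ind_of == i for i in set(ind_of.tolist())])
        ssd_within_pop = ssd([pop_of == p for p in set(pop_of.tolist())])
        ss_wi = ssd_within_ind
        ss_ai = ssd_within_pop - ssd_within_ind
        ss_ap = ssd_total - ssd_within_pop
        ms_wi = ss_wi / N
        ms_ai = ss_ai / (N - P)
        ms_ap = ss_ap / (P - 1)
        n_hap = np.array([np.sum(pop_of == p) for p in set(pop_of.tolist())], float)
        nc = (n_hap.sum() - (n_hap**2).sum() / n_hap.sum()) / (P - 1)
        sig += [ (ms_ap - ms_ai) / nc, (ms_ai - ms_wi) / 2.0, ms_wi ]
    return sig


class TestAmova:
    def test_fixed_opposite_homozygotes(self):
        G = matrix_from([[0], [0], [2], [2]])
        res = amova(G, {"A": ["i0", "i1"], "B": ["i2", "i3"]}, n_perm=20, seed=1)
        assert res.percentages["within_individuals"] == pytest.approx(0.0)
        assert res.percentages["among_populations"] == pytest.approx(100.0)

    def test_matches_pairwise_distance_oracle_on_small_instances(self):
        """Moment components from deviations equal an independent oracle
        built from pairwise squared haplotype distances, to 1e-10."""
        rng = np.random.default_rng(5)
        for trial in range(8):
            n = int(rng.integers(4, 7))
            m = int(rng.integers(1, 4))
            calls = rng.integers(0, 3, size=(n, m)).astype(np.int8)
            if trial % 2:
                calls[rng.integers(n), rng.integers(m)] = MISSING
            pops = ["A"] * (n // 2) + ["B"] * (n - n // 2)
            G = matrix_from(calls)
            groups = {
                "A": [s for s, p in zip(G.samples, pops) if p == "A"],
                "B": [s for s, p in zip(G.samples, pops) if p == "B"],
            }
            try:
                res = amova(G, groups, n_perm=5, seed=1)
            except ValueError:
                continue  # degenerate draw without variation
            oracle = brute_force_amova(calls, pops)
            got = [
                res.components["among_populations"],
                res.components["among_individuals"],
                res.components["within_individuals"],
            ]
            assert np.allclose(got, oracle, atol=1e-10)

    def test_percentages_sum_to_100(self, island_3pop):
        G, meta, _ = island_3pop
        groups = groups_from_metadata(meta, G.samples, "population")
        res = amova(G, groups, n_perm=20, seed=2)
        assert sum(res.percentages.values()) == pytest.approx(100.0, abs=1e-6)
        assert res.p_values["among_populations"] <= 0.1

    def test_single_panmictic_population_split(self, island_unstructured):
        G, meta, _ = island_unstructured
        groups = groups_from_metadata(meta, G.samples, "population")
        res = amova(G, groups, n_perm=20, seed=3)
        assert abs(res.percentages["among_populations"]) < 2.0

    def test_clones_only_errors(self):
        G = matrix_from([[0], [0], [0], [0]])
        with pytest.raises(ValueError):
            amova(G, {"A": ["i0", "i1"], "B": ["i2", "i3"]}, n_perm=5, seed=1)


class TestPairwiseFst:
    def test_permutation_p_small_under_structure(self, island_3pop):
        G, meta, _ = island_3pop
        groups = groups_from_metadata(meta, G.samples, "population")
        two = {k: groups[k] for k in list(groups)[:2]}
        res = pairwise_fst(G, two, n_perm=49, seed=1)[0]
        assert res.estimate > 0.1
        assert res.p_value == pytest.approx(1 / 50)

    def test_small_group_skipped(self, island_3pop):
        G, meta, _ = island_3pop
        groups = groups_from_metadata(meta, G.samples, "population")
        small = {list(groups)[0]: groups[list(groups)[0]][:2],
                 list(groups)[1]: groups[list(groups)[1]]}
        with pytest.warns(UserWarning, match="skipped"):
            res = pairwise_fst(G, small, n_perm=9, seed=1)[0]
        assert np.isnan(res.estimate)

    def test_amova_estimator_also_recovers_target(self):
        spec = IslandModelSpec(n_pops=2, n_per_pop=100, n_snps=2000, fst=0.1, seed=77)
        G, meta, _ = simulate_island_genotypes(spec)
        groups = groups_from_metadata(meta, G.samples, "population")
        assert amova_fst(G, groups) == pytest.approx(0.1, abs=0.02)


class TestSummary:
    def test_diversity_summary_columns_and_ranges(self, island_3pop):
        G, meta, _ = island_3pop
        groups = groups_from_metadata(meta, G.samples, "continent")
        summary = diversity_summary(G, groups)
        assert set(summary["group"]) == {"Africa", "Asia"}
        assert ((summary["Ho_mean"] >= 0) & (summary["Ho_mean"] <= 1)).all()
        assert (summary["He_sd"] >= 0).all()
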