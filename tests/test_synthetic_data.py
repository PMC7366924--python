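import numpy as np
import pytest
from scipy import stats
from shapely.geometry import Polygon

from camelroutes.genotype_io import MISSING
from camelroutes.synthetic_data import (
    GridModelSpec,
    HybridSimSpec,
    IslandModelSpec,
    inject_relatives,
    simulate_grid_genotypes,
    simulate_island_genotypes,
    simulate_rad_loci,
    simulate_read_assignments,
)
from camelroutes.demographic_prep import locus_divergence
from camelroutes.qc_filter import ibs_distance_matrix


class TestIslandModel:
    def test_reproducible_under_seed(self):
        spec = IslandModelSpec(n_pops=2, n_per_pop=10, n_snps=50, seed=7)
        G1, m1, s1 = simulate_island_genotypes(spec)
        G2, m2, s2 = simulate_island_genotypes(spec)
        assert G1.equals(G2)
        assert m1.equals(m2) and s1.equals(s2)

    def test_no_differentiation_at_fst_zero(self):
        spec = IslandModelSpec(n_pops=2, n_per_pop=300, n_snps=400, fst=0.0, seed=1)
        G, meta, _ = simulate_island_genotypes(spec)
        a = G.calls[:300].mean(axis=0) / 2
        b = G.calls[300:].mean(axis=0) / 2
        assert np.abs(a - b).mean() < 0.03

    def test_missingness_rate_realized(self):
        spec = IslandModelSpec(
            n_pops=2, n_per_pop=50, n_snps=500, geno_missing_rate=0.3, seed=2
        )
        G, _, _ = simulate_island_genotypes(spec)
        assert (G.calls == MISSING).mean() == pytest.approx(0.3, abs=0.02)

    def test_metadata_spans_continents(self):
        spec = IslandModelSpec(n_pops=2, n_per_pop=5, n_snps=10, seed=3)
        _, meta, _ = simulate_island_genotypes(spec)
        assert set(meta["continent"]) == {"Africa", "Asia"}

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            IslandModelSpec(fst=1.0)
        with pytest.raises(ValueError):
            IslandModelSpec(n_pops=0)
        with pytest.raises(ValueError):
            IslandModelSpec(geno_missing_rate=1.0)


class TestInjectRelatives:
    def test_zero_error_gives_zero_ibs_distance(self):
        spec = IslandModelSpec(n_pops=1, n_per_pop=6, n_snps=200, seed=4)
        G, _, _ = simulate_island_genotypes(spec)
        G2 = inject_relatives(G, [(G.samples[0], G.samples[1])], copy_error=0.0)
        D = ibs_distance_matrix(G2)
        assert D[0, 1] == 0.0

    def test_full_error_gives_positive_distance(self):
        spec = IslandModelSpec(n_pops=1, n_per_pop=6, n_snps=200, seed=4)
        G, _, _ = simulate_island_genotypes(spec)
        G2 = inject_relatives(G, [(G.samples[0], G.samples[1])], copy_error=1.0, seed=1)
        assert ibs_distance_matrix(G2)[0, 1] > 0

    def test_small_error_matches_direct_count(self):
        spec = IslandModelSpec(n_pops=1, n_per_pop=6, n_snps=1000, seed=5)
        G, _, _ = simulate_island_genotypes(spec)
        G2 = inject_relatives(G, [(G.samples[0], G.samples[1])], copy_error=0.02,
                              seed=2)
        # direct oracle: distance = mean |g_a - g_b| / 2 over the pair
        diff = np.abs(G2.calls[0].astype(int) - G2.calls[1].astype(int)) / 2
        assert ibs_distance_matrix(G2)[0, 1] == pytest.approx(diff.mean())
        assert 0 < diff.mean() < 0.04

    def test_overlapping_pairs_rejected(self):
        spec = IslandModelSpec(n_pops=1, n_per_pop=6, n_snps=20, seed=6)
        G, _, _ = simulate_island_genotypes(spec)
        s = G.samples
        with pytest.raises(ValueError, match="overlapping"):
            inject_relatives(G, [(s[0], s[1]), (s[1], s[2])])


class TestReadAssignments:
    def test_fractions_within_binomial_interval(self):
        spec = HybridSimSpec(n_ind=50, mean_reads=50_000, baseline_frac=0.01, seed=8)
        t = simulate_read_assignments(spec)
        total = t["reads_primary"] + t["reads_alt"]
        for alt, n in zip(t["reads_alt"], total):
            lo, hi = stats.binom.interval(0.999, n, 0.01)
            assert lo <= alt <= hi

    def test_zero_mean_reads_rejected(self):
        with pytest.raises(ValueError, match="mean_reads"):
            HybridSimSpec(mean_reads=0)

    def test_hybrid_frac_must_exceed_baseline(self):
        with pytest.raises(ValueError, match="exceed"):
            HybridSimSpec(hybrid_ids=("ind000",), hybrid_frac=0.005,
                          baseline_frac=0.01)


class TestGridModel:
    def test_one_deme_shares_frequency_vector(self, rectangle_polygon):
        spec = GridModelSpec(
            polygon=rectangle_polygon, n_demes=1, n_per_deme=30, n_snps=200, seed=9
        )
        G, meta, grid = simulate_grid_genotypes(spec)
        assert grid.n_demes == 1
        # all individuals drawn from one frequency vector: no structure
        from camelroutes.diversity_stats import weir_cockerham_fst

        half = G.n_samples // 2
        theta = weir_cockerham_fst(
            G, {"a": G.samples[:half], "b": G.samples[half:]}
        )
        assert abs(theta) < 0.02

    def test_high_migration_flattens_distance_decay(self, rectangle_polygon):
        """Dissimilarity grows with graph distance much more slowly under
        uniform high migration than under low migration."""
        import networkx as nx

        def decay_slope(m, seed):
            spec = GridModelSpec(
                polygon=rectangle_polygon, n_demes=16, migration_field=m,
                within_deme_diversity=10.0, n_per_deme=3, n_snps=300, seed=seed,
            )
            G, _, grid = simulate_grid_genotypes(spec)
            from camelroutes.migration_surface import (
                deme_mean_dissimilarity,
                observed_dissimilarity,
            )

            D = observed_dissimilarity(G)
            pairs, vals = deme_mean_dissimilarity(D, G.samples, grid)
            sp = dict(nx.all_pairs_shortest_path_length(grid.graph()))
            x = np.array([sp[a][b] for a, b in pairs])
            keep = x > 0
            return np.polyfit(x[keep], vals[keep], 1)[0]

        assert decay_slope(50.0, 10) < 0.5 * decay_slope(0.2, 10) + 1e-9

    def test_barrier_elevates_cross_band_dissimilarity(self, rectangle_polygon):
        import networkx as nx

        barrier = lambda lon, lat: 0.02 if 4.0 <= lon <= 6.0 else 2.0
        spec = GridModelSpec(
            polygon=rectangle_polygon, n_demes=24, migration_field=barrier,
            within_deme_diversity=10.0, n_per_deme=4, n_snps=400, seed=11,
        )
        G, _, grid = simulate_grid_genotypes(spec)
        from camelroutes.migration_surface import (
            deme_mean_dissimilarity,
            observed_dissimilarity,
        )

        D = observed_dissimilarity(G)
        pairs, vals = deme_mean_dissimilarity(D, G.samples, grid)
        side = np.array([c[0] < 5.0 for c in grid.centres])
        band = np.array([4.0 <= c[0] <= 6.0 for c in grid.centres])
        sp = dict(nx.all_pairs_shortest_path_length(grid.graph()))
        same, cross = [], []
        for (a, b), v in zip(pairs, vals):
            if a == b or band[a] or band[b] or sp[a][b] != 2:
                continue
            (same if side[a] == side[b] else cross).append(v)
        assert np.mean(cross) > np.mean(same)

    def test_reproducible(self, rectangle_polygon):
        spec = GridModelSpec(polygon=rectangle_polygon, n_demes=9, n_snps=50, seed=12)
        G1, _, _ = simulate_grid_genotypes(spec)
        G2, _, _ = simulate_grid_genotypes(spec)
        assert G1.equals(G2)


class TestRadLoci:
    def test_fixed_snp_count_honoured(self):
        loci = simulate_rad_loci(n_loci=20, snps_per_locus=5, n_ind=12, seed=13)
        assert all(locus.n_segregating == 5 for locus in loci)

    def test_divergence_measured_close_to_target(self):
        target = 0.0159231
        loci = simulate_rad_loci(
            n_loci=150, locus_len=110, outgroup_divergence=target, n_ind=20, seed=14
        )
        measured = np.mean([locus_divergence(l) for l in loci])
        assert measured == pytest.approx(target, rel=0.1)

    def test_zero_divergence_plants_no_fixed_differences(self):
        with pytest.warns(UserWarning, match="clamped"):
            loci = simulate_rad_loci(
                n_loci=10, outgroup_divergence=0.0, n_ind=10, seed=15
            )
        for locus in loci:
            # at every ingroup-monomorphic site the outgroup carries the
            # same base: the only ingroup-outgroup differences left come
            # from segregating sites
            for j, base in enumerate(locus.outgroup):
                bases = {seq[j] for seq in locus.sequences.values()}
                if bases <= {"A", "C", "G", "T"} and len(bases) == 1:
                    assert bases == {base}

    def test_divergence_above_one_rejected(self):
        with pytest.raises(ValueError):
            simulate_rad_loci(outgroup_divergence=1.5)

    def test_reproducible(self):
        a = simulate_rad_loci(n_loci=5, n_ind=8, seed=16)
        b = simulate_rad_loci(n_loci=5, n_ind=8, seed=16)
        assert all(
            la.sequences == lb.sequences and la.outgroup == lb.outgroup
            for la, lb in zip(a, b)
        )
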