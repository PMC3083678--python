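import numpy as np
import pytest

from landbound import (BarrierSpec, SimulationParams, draw_parent_cell,
                       init_lattice, step_generation)
from landbound.lattice import (phase_rng, run_burn_in,
                               run_post_barrier, run_replicate,
                               sample_individuals)
from landbound.sumstats import (diversity, ewens_expected_alleles,
                                expected_heterozygosity)

from conftest import small_params


class TestInitLattice:
    def test_monomorphic_homozygous_start(self):
        p = small_params(grid_width=10, grid_height=10, n_loci=5)
        lat = init_lattice(p)
        assert lat.alleles.shape == (10, 10, 5, 2)
        assert (lat.alleles == 0).all()
        assert (lat.next_allele_id == 1).all()
        assert lat.generation == 0


class TestDrawParentCell:
    def test_degenerate_kernel_returns_focal_cell(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            assert draw_parent_cell(5, 7, 1e-9, None, rng, 16, 16) == (5, 7)

    def test_impermeable_barrier_confines_draws(self):
        rng = np.random.default_rng(1)
        bar = BarrierSpec(split_x=8, split_y=8, b=0.0)
        for x, y, quad in [(0, 0, 0), (15, 0, 1), (0, 15, 2), (15, 15, 3)]:
            for _ in range(300):
                px, py = draw_parent_cell(x, y, 6.0, bar, rng, 16, 16)
                assert bar.quadrant(px, py) == quad

    def test_fully_permeable_barrier_allows_crossings(self):
        rng = np.random.default_rng(2)
        bar = BarrierSpec(split_x=8, split_y=8, b=1.0)
        quads = {int(bar.quadrant(*draw_parent_cell(7, 7, 6.0, bar, rng,
                                                    16, 16)))
                 for _ in range(300)}
        assert quads == {0, 1, 2, 3}

    def test_draws_stay_inside_grid(self):
        rng = np.random.default_rng(3)
        for _ in range(500):
            px, py = draw_parent_cell(0, 0, 10.0, None, rng, 12, 12)
            assert 0 <= px < 12 and 0 <= py < 12

    def test_mean_dispersal_distance_matches_delta(self):
        # delta = sigma * sqrt(pi/2) is the Rayleigh mean of the Euclidean
        # parent-offspring distance under a bivariate normal kernel (its SD
        # is sigma * sqrt(2 - pi/2)); Monte-Carlo check far from any edge
        delta = 11.0
        sigma = delta / np.sqrt(np.pi / 2.0)
        rng = np.random.default_rng(4)
        n = 200_000
        r = np.empty(n)
        cx = cy = 2000
        for i in range(n):
            px, py = draw_parent_cell(cx, cy, sigma, None, rng, 4000, 4000)
            r[i] = np.hypot(px - cx, py - cy)
        sd = sigma * np.sqrt(2.0 - np.pi / 2.0)
        assert abs(np.mean(r) - delta) < 4 * sd / np.sqrt(n) + 0.05
        assert abs(np.std(r) - sd) < 0.1

    def test_focal_outside_grid_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError):
            draw_parent_cell(20, 0, 1.0, None, rng, 16, 16)


class TestStepGeneration:
    def test_no_mutation_keeps_monomorphic_lattice(self):
        p = small_params(mu=0.0)
        lat = init_lattice(p)
        rng = np.random.default_rng(0)
        for _ in range(10):
            lat = step_generation(lat, p, None, rng)
        assert (lat.alleles == 0).all()
        assert (lat.next_allele_id == 1).all()
        assert lat.generation == 10

    def test_forced_mutation_makes_every_allele_unique(self):
        p = small_params(mu=1.0, n_loci=3)
        lat = init_lattice(p)
        lat = step_generation(lat, p, None, np.random.default_rng(0))
        n = p.n_individuals
        for l in range(3):
            vals = lat.alleles[:, :, l, :]
            assert len(np.unique(vals)) == 2 * n
            # every individual heterozygous
            assert (vals[:, :, 0] != vals[:, :, 1]).all()
        assert (lat.next_allele_id == 1 + 2 * n).all()

    def test_population_size_and_shape_conserved(self):
        p = small_params()
        lat = init_lattice(p)
        new = step_generation(lat, p, None, np.random.default_rng(1))
        assert new.alleles.shape == lat.alleles.shape

    def test_allele_id_freshness(self):
        # infinite-alleles guarantee: every allele ID stays below the
        # per-locus counter, which never decreases
        p = small_params(mu=0.05)
        lat = init_lattice(p)
        rng = np.random.default_rng(2)
        prev = lat.next_allele_id.copy()
        for _ in range(20):
            lat = step_generation(lat, p, None, rng)
            assert (lat.next_allele_id >= prev).all()
            assert (lat.alleles.max(axis=(0, 1, 3))
                    < lat.next_allele_id).all()
            prev = lat.next_allele_id.copy()

    def test_neutrality_allele_frequency_unbiased(self):
        # over many one-generation replicates the expected frequency change
        # of a common allele is zero
        p = small_params(grid_width=8, grid_height=8, n_loci=1, mu=0.0)
        lat = init_lattice(p)
        # seed a 50/50 polymorphism in a spatially mixed pattern
        rng0 = np.random.default_rng(3)
        mask = rng0.random((8, 8, 1, 2)) < 0.5
        lat.alleles[mask] = 1
        lat.next_allele_id[:] = 2
        p0 = float(mask.mean())
        freqs = []
        for rep in range(400):
            new = step_generation(lat, p, None, np.random.default_rng(rep))
            freqs.append((new.alleles == 1).mean())
        n_genes = 2 * p.n_individuals
        se = np.sqrt(p0 * (1 - p0) / n_genes / 400)
        assert abs(np.mean(freqs) - p0) < 4 * se


class TestBurnInEquilibrium:
    def test_ewens_nei_equilibrium_small_lattice(self):
        # 10x10 lattice, mu=1e-3 -> theta = 0.4; near-panmixia via a large
        # dispersal distance.  Sampled gene diversity and allele count over
        # 10 replicates must match the closed-form neutral expectations.
        p = SimulationParams(grid_width=10, grid_height=10, n_loci=20,
                             mu=1e-3, delta=30.0, burn_in_generations=5000,
                             export_generations=(0,), sample_size=100,
                             seed=11)
        theta = p.theta
        hs, ks = [], []
        for rep in range(10):
            res = run_replicate(p, rep)
            d = diversity(res.samples[0])
            hs.append(d.h_per_locus)
            ks.append(d.na_per_locus)
        hs = np.concatenate(hs)
        ks = np.concatenate(ks)
        exp_h = expected_heterozygosity(theta)
        exp_k = ewens_expected_alleles(theta, 200)
        sem_h = hs.std() / np.sqrt(len(hs))
        sem_k = ks.std() / np.sqrt(len(ks))
        assert abs(hs.mean() - exp_h) < 3 * sem_h + 0.01
        assert abs(ks.mean() - exp_k) < 3 * sem_k + 0.05

    def test_zero_burn_in_is_identity(self):
        p = small_params(burn_in_generations=0)
        lat, diag = run_burn_in(p, np.random.default_rng(0))
        assert (lat.alleles == 0).all()
        assert diag == []


class TestPostBarrier:
    def test_generation_zero_snapshot_is_prebarrier_state(self):
        p = small_params(export_generations=(0,))
        lat, _ = run_burn_in(p, np.random.default_rng(0))
        bar = BarrierSpec.from_params(p)
        snaps = run_post_barrier(lat, p, bar, np.random.default_rng(1))
        assert len(snaps) == 1
        assert snaps[0].generation == 0
        np.testing.assert_array_equal(snaps[0].alleles, lat.alleles)

    def test_impermeable_barrier_confines_new_alleles(self):
        # with b = 0, any allele born after barrier imposition can never
        # appear outside its quadrant of origin
        p = small_params(grid_width=12, grid_height=12, mu=0.01,
                         burn_in_generations=30,
                         export_generations=(0, 20, 60))
        lat, _ = run_burn_in(p, np.random.default_rng(0))
        bar = BarrierSpec.from_params(p, b=0.0)
        born_at = lat.next_allele_id.copy()
        snaps = run_post_barrier(lat, p, bar, np.random.default_rng(1))
        ys, xs = np.mgrid[0:12, 0:12]
        quad = bar.quadrant(xs, ys)
        for l in range(p.n_loci):
            seen: dict[int, set] = {}
            for snap in snaps[1:]:
                vals = snap.alleles[:, :, l, :]
                for q in range(4):
                    sel = vals[quad == q]
                    for a in np.unique(sel):
                        if a >= born_at[l]:
                            seen.setdefault(int(a), set()).add(q)
            assert all(len(qs) == 1 for qs in seen.values())

    def test_export_schedule_and_clock_reset(self):
        p = small_params(export_generations=(0, 10, 30))
        lat, _ = run_burn_in(p, np.random.default_rng(0))
        bar = BarrierSpec.from_params(p)
        snaps = run_post_barrier(lat, p, bar, np.random.default_rng(1))
        assert [s.generation for s in snaps] == [0, 10, 30]


class TestSampling:
    def test_coordinates_unique_and_reused_across_snapshots(self):
        p = small_params()
        res = run_replicate(p, 0)
        coords0 = res.samples[0].coords
        assert len(np.unique(coords0, axis=0)) == len(coords0)
        for s in res.samples[1:]:
            np.testing.assert_array_equal(s.coords, coords0)

    def test_whole_lattice_sample(self):
        p = small_params(sample_size=16 * 16)
        res = run_replicate(p, 0)
        assert res.samples[0].n_individuals == 256

    def test_different_replicates_get_different_coordinates(self):
        p = small_params()
        r0 = run_replicate(p, 0)
        r1 = run_replicate(p, 1)
        assert not np.array_equal(r0.samples[0].coords, r1.samples[0].coords)

    def test_oversampling_rejected(self):
        p = small_params()
        lat, _ = run_burn_in(p, np.random.default_rng(0))
        bar = BarrierSpec.from_params(p)
        with pytest.raises(ValueError):
            sample_individuals([lat], 10_000, np.random.default_rng(1), bar)

    def test_quadrant_labels_match_geometry(self):
        p = small_params()
        res = run_replicate(p, 0)
        bar = BarrierSpec.from_params(p)
        s = res.samples[0]
        np.testing.assert_array_equal(
            s.quadrant, bar.quadrant(s.coords[:, 0], s.coords[:, 1]))


class TestDeterminism:
    def test_identical_seeds_reproduce_lattice_and_samples(self):
        p = small_params()
        a = run_replicate(p, 0)
        b = run_replicate(p, 0)
        for sa, sb in zip(a.samples, b.samples):
            np.testing.assert_array_equal(sa.genotypes, sb.genotypes)
            np.testing.assert_array_equal(sa.coords, sb.coords)

    def test_phase_streams_are_independent_of_call_order(self):
        a = phase_rng(3, 0, "burn_in").random(4)
        _ = phase_rng(3, 0, "sampling").random(4)
        b = phase_rng(3, 0, "burn_in").random(4)
        np.testing.assert_array_equal(a, b)
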