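"""Shared fixtures.

The ``study`` fixture runs the full-scale benchmark conditions once per
session (100x100 lattice, 20 loci, 20k/80k-generation burn-ins) and is
shared by all tests that check reproduction of the published summary
statistics and detection behaviour.  Replicate counts are scaled down from
the original 25 (see docs/methods.md); everything else uses the study
conditions unchanged.
"""

from __future__ import annotations

import numpy as np
import pytest

from landbound import PRESETS, BarrierSpec, SimulationParams
from landbound.lattice import (phase_rng, run_burn_in, run_post_barrier,
                               sample_individuals)

STUDY_SEED = 101


def small_params(**kw) -> SimulationParams:
    """A fast, small-lattice parameter set for unit tests."""
    defaults = dict(grid_width=16, grid_height=16, n_loci=5, mu=1e-3,
                    delta=2.0, burn_in_generations=200,
                    export_generations=(0, 50), sample_size=40, seed=7)
    defaults.update(kw)
    return SimulationParams(**defaults)


def run_with_b_variants(params: SimulationParams, replicate: int,
                        b_values: tuple[float, ...]):
    """One burn-in, then matched-seed post-barrier phases per permeability."""
    rng_burn = phase_rng(params.seed, replicate, "burn_in")
    lattice, _ = run_burn_in(params, rng_burn)
    out = {}
    for b in b_values:
        barrier = BarrierSpec.from_params(params, b=b)
        rng_post = phase_rng(params.seed, replicate, "post_barrier")
        snaps = run_post_barrier(lattice, params, barrier, rng_post)
        rng_s = phase_rng(params.seed, replicate, "sampling")
        out[b] = sample_individuals(snaps, params.sample_size, rng_s,
                                    barrier, replicate)
    return out


@pytest.fixture(scope="session")
def study():
    """Full-scale runs of the mu = 1e-4 presets (plus the low-mutation
    delta = 1 condition needed for the IBD ordering), 3-5 replicates."""
    d11 = PRESETS["d11-mu1e4"].with_(seed=STUDY_SEED)
    d1 = PRESETS["d1-mu1e4"].with_(seed=STUDY_SEED)
    d1lo = PRESETS["d1-mu2.5e5"].with_(seed=STUDY_SEED)

    out = {"d11": [], "d11_b03": [], "d1": [], "d1lo": []}
    # three fully exported replicates per mu=1e-4 preset; the delta=11 runs
    # also branch into a b=0.03 post-barrier phase from the same burn-in
    for rep in range(3):
        res = run_with_b_variants(d11, rep, (0.0, 0.03))
        out["d11"].append(res[0.0])
        out["d11_b03"].append(res[0.03])
        out["d1"].append(run_with_b_variants(d1, rep, (0.0,))[0.0])
        out["d1lo"].append(
            run_with_b_variants(d1lo.with_(export_generations=(0,)),
                                rep, (0.0,))[0.0])
    # two extra replicates where only the endpoints are needed (edge-method
    # correctness at generations 0 and 5000)
    for rep in range(3, 5):
        out["d11"].append(run_with_b_variants(
            d11.with_(export_generations=(0, 5000)), rep, (0.0,))[0.0])
        out["d1"].append(run_with_b_variants(
            d1.with_(export_generations=(0,)), rep, (0.0,))[0.0])
    return out


# ---------------------------------------------------------------------------
# independent oracles shared between unit and acceptance tests
# ---------------------------------------------------------------------------

def wc_fst_anova_oracle(genotypes: np.ndarray, groups: np.ndarray):
    """Weir-Cockerham theta via the three-level ANOVA mean squares -- an
    algebraically independent route from the moment formulas used in the
    implementation."""
    groups = np.asarray(groups)
    labels = np.unique(groups)
    r = len(labels)
    n_i = np.array([(groups == lab).sum() for lab in labels], dtype=float)
    n_tot = n_i.sum()
    nbar = n_i.mean()
    nc = (n_tot - np.sum(n_i ** 2) / n_tot) / (r - 1)
    n_loci = genotypes.shape[1]
    theta_per_locus = np.empty(n_loci)
    tot_a = tot_bc = 0.0
    for l in range(n_loci):
        gl = genotypes[:, l, :]
        a_sum = b_sum = c_sum = 0.0
        for al in np.unique(gl):
            x = (gl == al).astype(float)          # (n, 2) indicators
            xbar_ind = x.mean(axis=1)
            ssg = np.sum((x - xbar_ind[:, None]) ** 2)
            ssi = ssp = 0.0
            xbar_all = x.mean()
            for lab, ni in zip(labels, n_i):
                sel = groups == lab
                xbar_pop = x[sel].mean()
                ssi += 2.0 * np.sum((xbar_ind[sel] - xbar_pop) ** 2)
                ssp += 2.0 * ni * (xbar_pop - xbar_all) ** 2
            msg = ssg / n_tot
            msi = ssi / (n_tot - r)
            msp = ssp / (r - 1)
            a = (msp - msi) / (2.0 * nc)
            b = (msi - msg) / 2.0
            c = msg
            a_sum += a
            b_sum += b
            c_sum += c
        denom = a_sum + b_sum + c_sum
        theta_per_locus[l] = a_sum / denom if denom != 0 else np.nan
        tot_a += a_sum
        tot_bc += b_sum + c_sum
    return theta_per_locus, tot_a / (tot_a + tot_bc)


def random_two_group_sample(rng, n_per_group=10, n_loci=4, n_alleles=5):
    """Small random two-group diploid fixture for estimator cross-checks."""
    from landbound.lattice import SampleSet

    n = 2 * n_per_group
    genotypes = rng.integers(0, n_alleles, size=(n, n_loci, 2))
    groups = np.repeat([0, 1], n_per_group)
    coords = np.column_stack([rng.permutation(n), rng.permutation(n)])
    return SampleSet(coords=coords, genotypes=genotypes, generation=1,
                     quadrant=groups)
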