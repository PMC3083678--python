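"""Forward-time Monte-Carlo evolution of the genotype lattice.

Every cell of a ``grid_height x grid_width`` lattice holds exactly one
diploid hermaphrodite.  Generations are synchronous and non-overlapping: each
cell of the new generation is filled by drawing two parents from the old
generation with a bivariate-normal dispersal kernel centered on the cell,
taking one uniformly chosen allele per locus from each parent, and mutating
each transmitted allele with probability ``mu`` to a brand-new allelic state
(infinite-alleles model).

Parent draws are rounded to the nearest cell.  Draws falling outside the
lattice are rejected and redrawn (the landscape is bounded, not toroidal).
With an active barrier, a draw landing in a different quadrant than the
focal cell is accepted with probability ``b`` and otherwise the whole draw
(both coordinates) is repeated.  The two parent draws are independent, so
self-fertilisation is possible.

The per-generation kernel is JIT-compiled; allele pairs are stored as two
int32 lanes of one int64 word inside the kernel for speed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .params import BarrierSpec, SimulationParams

logger = logging.getLogger(__name__)

_ALLELE_DTYPE = np.int32

# phase indices used to split one master seed into independent streams
_PHASES = {"burn_in": 0, "post_barrier": 1, "sampling": 2}


def phase_rng(seed: int, replicate: int, phase: str) -> np.random.Generator:
    """Deterministic per-replicate, per-phase random stream.

    One master seed fully determines every stream: the (replicate, phase)
    pair is used as the spawn key of a :class:`numpy.random.SeedSequence`.
    """
    ss = np.random.SeedSequence(entropy=seed,
                                spawn_key=(replicate, _PHASES[phase]))
    return np.random.default_rng(ss)


@dataclass
class GenotypeLattice:
    """The evolving landscape: allele IDs for every cell, locus, allele copy.

    ``alleles`` has shape ``(grid_height, grid_width, n_loci, 2)`` and dtype
    int32.  ``next_allele_id[l]`` counts the allelic states ever created at
    locus ``l``; mutation always assigns a fresh ID, so every allele ID at
    locus ``l`` is strictly below ``next_allele_id[l]``.
    """

    alleles: np.ndarray
    generation: int
    next_allele_id: np.ndarray

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.alleles.shape

    def copy(self) -> "GenotypeLattice":
        return GenotypeLattice(self.alleles.copy(), self.generation,
                               self.next_allele_id.copy())


def init_lattice(params: SimulationParams) -> GenotypeLattice:
    """All individuals identical homozygotes (allele 0 at every locus).

    This is the maximally inbred starting state (gene diversity 0); the
    burn-in lets mutation and drift take the lattice to quasi-equilibrium.
    """
    alleles = np.zeros(
        (params.grid_height, params.grid_width, params.n_loci, 2),
        dtype=_ALLELE_DTYPE,
    )
    next_allele_id = np.ones(params.n_loci, dtype=np.int64)
    return GenotypeLattice(alleles, 0, next_allele_id)


@njit(cache=True)
def _draw_parent(x, y, sigma, W, H, barrier_active, split_x, split_y, b, rng):
    """One accepted parent cell for focal cell (x, y); rejection sampling.

    The focal cell itself is always acceptable, so the loop terminates with
    probability one.
    """
    fq = (1 if x >= split_x else 0) + 2 * (1 if y >= split_y else 0)
    while True:
        px = int(np.floor(x + sigma * rng.standard_normal() + 0.5))
        py = int(np.floor(y + sigma * rng.standard_normal() + 0.5))
        if px < 0 or px >= W or py < 0 or py >= H:
            continue
        if barrier_active:
            pq = (1 if px >= split_x else 0) + 2 * (1 if py >= split_y else 0)
            if pq != fq and rng.random() >= b:
                continue
        return px, py


@njit(cache=True)
def _step_kernel(old64, new64, next_ids, sigma, mu, b, barrier_active,
                 split_x, split_y, rng):
    """Advance one synchronous generation.

    ``old64``/``new64`` view the (H, W, L, 2) int32 allele array as
    (H, W, L) int64: allele copy 0 in the low 32 bits, copy 1 in the high
    bits.  Mutations along the fixed stream of ``H*W*L*2`` transmissions are
    located by geometric skips, which is exact for independent Bernoulli(mu)
    trials and cheap when mu is small.
    """
    H, W, L = old64.shape
    two_l = 1 << L
    if mu >= 1.0:
        next_mut = -2  # every transmission mutates
        log1m = 0.0
    elif mu > 0.0:
        log1m = np.log1p(-mu)
        next_mut = int(np.floor(np.log(rng.random()) / log1m))
    else:
        next_mut = -1  # no mutation
        log1m = 0.0
    t = 0  # transmission counter: (cell, locus, parent) in fixed order
    for y in range(H):
        for x in range(W):
            px0, py0 = _draw_parent(x, y, sigma, W, H, barrier_active,
                                    split_x, split_y, b, rng)
            px1, py1 = _draw_parent(x, y, sigma, W, H, barrier_active,
                                    split_x, split_y, b, rng)
            # one uniform supplies L independent gamete-choice bits
            bits0 = int(rng.random() * two_l)
            bits1 = int(rng.random() * two_l)
            src0 = old64[py0, px0]
            src1 = old64[py1, px1]
            dst = new64[y, x]
            if next_mut == -2 or (next_mut >= 0 and next_mut < t + 2 * L):
                for l in range(L):
                    a0 = (src0[l] >> (32 * ((bits0 >> l) & 1))) & 0x7FFFFFFF
                    if next_mut == -2 or t == next_mut:
                        a0 = next_ids[l]
                        next_ids[l] += 1
                        if next_mut >= 0:
                            next_mut = t + 1 + int(
                                np.floor(np.log(rng.random()) / log1m))
                    t += 1
                    a1 = (src1[l] >> (32 * ((bits1 >> l) & 1))) & 0x7FFFFFFF
                    if next_mut == -2 or t == next_mut:
                        a1 = next_ids[l]
                        next_ids[l] += 1
                        if next_mut >= 0:
                            next_mut = t + 1 + int(
                                np.floor(np.log(rng.random()) / log1m))
                    t += 1
                    dst[l] = a0 | (a1 << 32)
            else:
                for l in range(L):
                    a0 = (src0[l] >> (32 * ((bits0 >> l) & 1))) & 0x7FFFFFFF
                    a1 = (src1[l] >> (32 * ((bits1 >> l) & 1))) & 0x7FFFFFFF
                    dst[l] = a0 | (a1 << 32)
                t += 2 * L


def draw_parent_cell(x: int, y: int, sigma: float,
                     barrier: BarrierSpec | None,
                     rng: np.random.Generator,
                     grid_width: int, grid_height: int) -> tuple[int, int]:
    """Draw one parent cell for focal cell ``(x, y)``.

    Exposes the exact rule used inside the generation kernel: bivariate
    normal with scale ``sigma`` rounded to the nearest cell, out-of-grid
    draws redrawn, and barrier crossings accepted with probability ``b``.
    """
    if not (0 <= x < grid_width and 0 <= y < grid_height):
        raise ValueError(f"focal cell ({x}, {y}) outside grid")
    if barrier is not None and barrier.active:
        active, sx, sy, b = True, barrier.split_x, barrier.split_y, barrier.b
    else:
        active, sx, sy, b = False, 0, 0, 1.0
    return _draw_parent(x, y, sigma, grid_width, grid_height,
                        active, sx, sy, b, rng)


def _as64(alleles: np.ndarray) -> np.ndarray:
    h, w, l, _ = alleles.shape
    return np.ascontiguousarray(alleles).view(np.int64).reshape(h, w, l)


def step_generation(lattice: GenotypeLattice, params: SimulationParams,
                    barrier: BarrierSpec | None,
                    rng: np.random.Generator) -> GenotypeLattice:
    """One synchronous, non-overlapping generation; returns a new lattice."""
    if barrier is not None and barrier.active:
        active, sx, sy, b = True, barrier.split_x, barrier.split_y, barrier.b
    else:
        active, sx, sy, b = False, 0, 0, 1.0
    old64 = _as64(lattice.alleles)
    new64 = np.empty_like(old64)
    next_ids = lattice.next_allele_id.copy()
    _step_kernel(old64, new64, next_ids, params.sigma, params.mu, b,
                 active, sx, sy, rng)
    h, w, l = new64.shape
    new = new64.view(_ALLELE_DTYPE).reshape(h, w, l, 2)
    return GenotypeLattice(new, lattice.generation + 1, next_ids)


def _advance(lattice: GenotypeLattice, n_generations: int,
             params: SimulationParams, barrier: BarrierSpec | None,
             rng: np.random.Generator) -> GenotypeLattice:
    """Advance ``n_generations`` steps in place-efficient double buffering."""
    if barrier is not None and barrier.active:
        active, sx, sy, b = True, barrier.split_x, barrier.split_y, barrier.b
    else:
        active, sx, sy, b = False, 0, 0, 1.0
    old64 = _as64(lattice.alleles).copy()
    new64 = np.empty_like(old64)
    next_ids = lattice.next_allele_id.copy()
    for _ in range(n_generations):
        _step_kernel(old64, new64, next_ids, params.sigma, params.mu, b,
                     active, sx, sy, rng)
        old64, new64 = new64, old64
    h, w, l = old64.shape
    alleles = old64.view(_ALLELE_DTYPE).reshape(h, w, l, 2).copy()
    return GenotypeLattice(alleles, lattice.generation + n_generations,
                           next_ids)


def lattice_diversity(lattice: GenotypeLattice) -> tuple[float, float]:
    """Lattice-wide mean allele count and gene diversity (no sampling)."""
    h, w, l, _ = lattice.alleles.shape
    flat = lattice.alleles.reshape(-1, l)
    nas = np.empty(l)
    hs = np.empty(l)
    for loc in range(l):
        _, counts = np.unique(flat[:, loc], return_counts=True)
        p = counts / counts.sum()
        nas[loc] = len(counts)
        hs[loc] = 1.0 - np.sum(p * p)
    return float(nas.mean()), float(hs.mean())


def run_burn_in(params: SimulationParams, rng: np.random.Generator,
                n_checkpoints: int = 20):
    """Advance the monomorphic lattice to quasi-equilibrium.

    Returns ``(lattice, diagnostics)`` where diagnostics is a list of
    ``(generation, mean_Na, mean_H)`` checkpoints for equilibrium
    inspection.  A warning is logged (never raised) when the final
    lattice-wide allele count or gene diversity sits more than three
    standard deviations from the panmictic Ewens / Nei expectation; spatial
    structure (small delta) legitimately shifts both, so the check is
    advisory only.
    """
    from .sumstats import (ewens_expected_alleles, ewens_alleles_sd,
                           expected_heterozygosity, heterozygosity_sd)

    lattice = init_lattice(params)
    total = params.burn_in_generations
    diagnostics = []
    if total == 0:
        return lattice, diagnostics
    chunk = max(1, total // max(1, n_checkpoints))
    done = 0
    while done < total:
        n = min(chunk, total - done)
        lattice = _advance(lattice, n, params, None, rng)
        done += n
        na, h = lattice_diversity(lattice)
        diagnostics.append((lattice.generation, na, h))
    theta = params.theta
    if theta > 0:
        n_genes = 2 * params.n_individuals
        exp_na = ewens_expected_alleles(theta, n_genes)
        sd_na = ewens_alleles_sd(theta, n_genes)
        exp_h = expected_heterozygosity(theta)
        sd_h = heterozygosity_sd(theta)
        na, h = diagnostics[-1][1], diagnostics[-1][2]
        if abs(na - exp_na) > 3 * max(sd_na, 1e-12):
            logger.warning(
                "burn-in mean Na %.2f deviates >3 SD from panmictic "
                "expectation %.2f (SD %.2f); expected under strong spatial "
                "structure", na, exp_na, sd_na)
        if abs(h - exp_h) > 3 * max(sd_h, 1e-12):
            logger.warning(
                "burn-in mean H %.3f deviates >3 SD from panmictic "
                "expectation %.3f (SD %.3f); expected under strong spatial "
                "structure", h, exp_h, sd_h)
    return lattice, diagnostics


def run_post_barrier(lattice: GenotypeLattice, params: SimulationParams,
                     barrier: BarrierSpec,
                     rng: np.random.Generator) -> list[GenotypeLattice]:
    """Impose the barrier and snapshot at each export generation.

    The generation clock restarts at 0 when the barrier is imposed; the
    generation-0 snapshot is the pre-barrier state itself.
    """
    snapshots = []
    current = GenotypeLattice(lattice.alleles.copy(), 0,
                              lattice.next_allele_id.copy())
    prev = 0
    for gen in params.export_generations:
        if gen > prev:
            current = _advance(current, gen - prev, params, barrier, rng)
            prev = gen
        snap = current.copy()
        snap.generation = gen
        snapshots.append(snap)
    return snapshots


@dataclass
class SampleSet:
    """A georeferenced sample of individuals from one lattice snapshot.

    ``coords`` is an (n, 2) integer array of (x, y) cell coordinates,
    ``genotypes`` an (n, n_loci, 2) allele-ID array, and ``quadrant`` the
    true landscape-subsection label of each individual.
    """

    coords: np.ndarray
    genotypes: np.ndarray
    generation: int
    quadrant: np.ndarray
    replicate_id: int = 0

    @property
    def n_individuals(self) -> int:
        return len(self.coords)

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]


def sample_individuals(snapshots: list[GenotypeLattice], sample_size: int,
                       rng: np.random.Generator,
                       barrier: BarrierSpec,
                       replicate_id: int = 0) -> list[SampleSet]:
    """Sample the same coordinate set from every snapshot of a replicate.

    Coordinates are drawn once without replacement and reused for all
    snapshots, so temporal comparisons are not confounded by sampling
    location.  Quadrant labels come from the barrier geometry.
    """
    h, w, n_loci, _ = snapshots[0].alleles.shape
    n = h * w
    if sample_size > n:
        raise ValueError(f"sample_size {sample_size} exceeds lattice size {n}")
    flat_idx = rng.choice(n, size=sample_size, replace=False)
    ys, xs = np.unravel_index(flat_idx, (h, w))
    coords = np.column_stack([xs, ys]).astype(np.int64)
    quad = barrier.quadrant(xs, ys)
    out = []
    for snap in snapshots:
        genotypes = snap.alleles[ys, xs].copy()
        out.append(SampleSet(coords=coords.copy(), genotypes=genotypes,
                             generation=snap.generation, quadrant=quad.copy(),
                             replicate_id=replicate_id))
    return out


@dataclass
class ReplicateResult:
    """Everything produced by one seeded replicate of one condition."""

    params: SimulationParams
    replicate: int
    samples: list[SampleSet]
    burn_in_diagnostics: list[tuple[int, float, float]] = field(
        default_factory=list)
    snapshots: list[GenotypeLattice] | None = None


def run_replicate(params: SimulationParams, replicate: int = 0,
                  keep_snapshots: bool = False) -> ReplicateResult:
    """Burn-in, barrier imposition, snapshot export, and sampling for one
    replicate, with deterministic per-phase random streams."""
    rng_burn = phase_rng(params.seed, replicate, "burn_in")
    lattice, diag = run_burn_in(params, rng_burn)
    barrier = BarrierSpec.from_params(params, active=True)
    rng_post = phase_rng(params.seed, replicate, "post_barrier")
    snapshots = run_post_barrier(lattice, params, barrier, rng_post)
    rng_samp = phase_rng(params.seed, replicate, "sampling")
    samples = sample_individuals(snapshots, params.sample_size, rng_samp,
                                 barrier, replicate)
    return ReplicateResult(params, replicate, samples, diag,
                           snapshots if keep_snapshots else None)
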