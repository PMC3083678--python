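"""Diversity, differentiation and isolation-by-distance descriptors.

Closed-form neutral-equilibrium expectations (Ewens allele number, Nei gene
diversity) serve as analytic anchors for the simulator; Weir-Cockerham
variance components quantify differentiation among the four landscape
quadrants; and individual-based isolation by distance is summarised by the
slope of pairwise genetic distance on log geographic distance with a Mantel
permutation test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .lattice import SampleSet

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# analytic equilibrium expectations
# ---------------------------------------------------------------------------

def ewens_expected_alleles(theta: float, n_genes: int) -> float:
    """Expected number of distinct alleles in a sample of ``n_genes`` gene
    copies at mutation-drift equilibrium under the infinite-alleles model:
    ``sum_{i=0}^{n_genes-1} theta / (theta + i)``."""
    if theta <= 0:
        raise ValueError(f"theta must be positive, got {theta}")
    if n_genes < 1:
        raise ValueError(f"n_genes must be >= 1, got {n_genes}")
    i = np.arange(n_genes, dtype=float)
    return float(np.sum(theta / (theta + i)))


def ewens_alleles_sd(theta: float, n_genes: int) -> float:
    """Standard deviation of the Ewens allele count: each of the ``n_genes``
    terms is an independent Bernoulli(theta/(theta+i)) indicator."""
    if theta <= 0 or n_genes < 1:
        raise ValueError("theta must be positive and n_genes >= 1")
    i = np.arange(n_genes, dtype=float)
    p = theta / (theta + i)
    return float(np.sqrt(np.sum(p * (1.0 - p))))


def expected_heterozygosity(theta: float) -> float:
    """Equilibrium gene diversity under the infinite-alleles model:
    ``theta / (1 + theta)``."""
    if theta < 0:
        raise ValueError(f"theta must be >= 0, got {theta}")
    return theta / (1.0 + theta)


def heterozygosity_sd(theta: float) -> float:
    """Stationary standard deviation of single-locus gene diversity under
    the infinite-alleles model (Stewart's variance formula)."""
    if theta < 0:
        raise ValueError(f"theta must be >= 0, got {theta}")
    var = 2.0 * theta / ((1.0 + theta) ** 2 * (2.0 + theta) * (3.0 + theta))
    return float(np.sqrt(var))


# ---------------------------------------------------------------------------
# sample diversity
# ---------------------------------------------------------------------------

@dataclass
class DiversityStats:
    na_per_locus: np.ndarray
    h_per_locus: np.ndarray
    mean_na: float
    mean_h: float


def diversity(sample: SampleSet) -> DiversityStats:
    """Per-locus allele count and unbiased gene diversity.

    Gene diversity uses Nei's small-sample correction
    ``(2n / (2n - 1)) * (1 - sum p_a^2)`` over the ``2n`` sampled gene
    copies at each locus, averaged over loci.
    """
    if sample.n_individuals == 0:
        raise ValueError("empty sample")
    g = sample.genotypes
    n_loci = g.shape[1]
    two_n = 2 * g.shape[0]
    na = np.empty(n_loci)
    h = np.empty(n_loci)
    for l in range(n_loci):
        _, counts = np.unique(g[:, l, :], return_counts=True)
        p = counts / two_n
        na[l] = len(counts)
        h[l] = (two_n / (two_n - 1)) * (1.0 - np.sum(p * p))
    return DiversityStats(na, h, float(na.mean()), float(h.mean()))


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST among groups
# ---------------------------------------------------------------------------

@dataclass
class FstResult:
    theta_per_locus: np.ndarray
    theta_global: float
    n_groups: int


def wc_fst(sample: SampleSet, groups: np.ndarray | None = None) -> FstResult:
    """Weir-Cockerham variance-components estimator of F_ST among groups.

    ``groups`` defaults to the sample's quadrant labels.  Per-locus theta is
    the ratio of the among-group component to the total; the multilocus
    global estimate is the ratio of the summed components over loci and
    alleles.  Negative per-locus estimates are retained (not truncated).
    Groups with fewer than two individuals are excluded with a warning.
    """
    if groups is None:
        groups = sample.quadrant
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    small = labels[counts < 2]
    if len(small):
        logger.warning("excluding groups with <2 individuals: %s",
                       small.tolist())
        keep = ~np.isin(groups, small)
        groups = groups[keep]
        g = sample.genotypes[keep]
        labels = labels[counts >= 2]
    else:
        g = sample.genotypes
    r = len(labels)
    if r < 2:
        raise ValueError("need at least two groups with >= 2 individuals")
    n_loci = g.shape[1]
    n_i = np.array([(groups == lab).sum() for lab in labels], dtype=float)
    nbar = n_i.mean()
    nc = (r * nbar - np.sum(n_i ** 2) / (r * nbar)) / (r - 1)

    theta_per_locus = np.empty(n_loci)
    sum_a = sum_bc = 0.0
    for l in range(n_loci):
        gl = g[:, l, :]
        alleles = np.unique(gl)
        a_sum = b_sum = c_sum = 0.0
        for al in alleles:
            ind = (gl == al)
            # per-group allele frequency and observed heterozygote frequency
            p_i = np.empty(r)
            h_i = np.empty(r)
            for k, lab in enumerate(labels):
                sel = groups == lab
                p_i[k] = ind[sel].mean()
                h_i[k] = (ind[sel].sum(axis=1) == 1).mean()
            pbar = np.sum(n_i * p_i) / (r * nbar)
            s2 = np.sum(n_i * (p_i - pbar) ** 2) / ((r - 1) * nbar)
            hbar = np.sum(n_i * h_i) / (r * nbar)
            a = (nbar / nc) * (
                s2 - (1.0 / (nbar - 1.0)) * (
                    pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0))
            b = (nbar / (nbar - 1.0)) * (
                pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2
                - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar)
            c = hbar / 2.0
            a_sum += a
            b_sum += b
            c_sum += c
        denom = a_sum + b_sum + c_sum
        theta_per_locus[l] = a_sum / denom if denom != 0 else np.nan
        sum_a += a_sum
        sum_bc += b_sum + c_sum
    total = sum_a + sum_bc
    theta_global = sum_a / total if total != 0 else np.nan
    return FstResult(theta_per_locus, float(theta_global), r)


# ---------------------------------------------------------------------------
# pairwise genetic distances between individuals
# ---------------------------------------------------------------------------

def _pair_identity(genotypes: np.ndarray) -> tuple[np.ndarray, float]:
    """Between-individual gene identity Q_ij (mean over loci of the four
    cross-individual allele comparisons) and mean within-individual identity
    Q_w."""
    g = genotypes
    n, n_loci, _ = g.shape
    q = np.zeros((n, n))
    for l in range(n_loci):
        gl = g[:, l, :]
        eq = (gl[:, None, :, None] == gl[None, :, None, :])
        q += eq.mean(axis=(2, 3))
    q /= n_loci
    qw = float(np.mean(g[:, :, 0] == g[:, :, 1]))
    return q, qw


def rousset_a(genotypes: np.ndarray) -> np.ndarray:
    """Rousset's a-statistic between individuals, estimated from gene
    identities: ``a_ij = (Q_w - Q_ij) / (1 - Q_w)`` with ``Q_w`` the mean
    within-individual identity over the whole sample.  Can be negative for
    pairs more similar than the within-individual average."""
    q, qw = _pair_identity(genotypes)
    if qw >= 1.0:
        # monomorphic data: no information, distance 0 everywhere
        return np.zeros_like(q)
    a = (qw - q) / (1.0 - qw)
    np.fill_diagonal(a, 0.0)
    return a


def allele_sharing_distance(genotypes: np.ndarray) -> np.ndarray:
    """1 - proportion of shared alleles, averaged over loci.

    Per locus the shared proportion is the multiset intersection of the two
    diploid genotypes divided by 2 (0, 0.5 or 1).
    """
    g = genotypes
    n, n_loci, _ = g.shape
    shared = np.zeros((n, n))
    for l in range(n_loci):
        a1 = g[:, l, 0]
        a2 = g[:, l, 1]
        # multiset intersection of {a1,a2} x {b1,b2} = max over the two
        # perfect matchings of the number of agreeing positions
        m1 = (a1[:, None] == a1[None, :]).astype(np.int8) + \
             (a2[:, None] == a2[None, :]).astype(np.int8)
        m2 = (a1[:, None] == a2[None, :]).astype(np.int8) + \
             (a2[:, None] == a1[None, :]).astype(np.int8)
        shared += np.maximum(m1, m2) / 2.0
    d = 1.0 - shared / n_loci
    np.fill_diagonal(d, 0.0)
    return d


GENETIC_DISTANCES = {
    "rousset": rousset_a,
    "allele_sharing": allele_sharing_distance,
}


# ---------------------------------------------------------------------------
# isolation by distance
# ---------------------------------------------------------------------------

@dataclass
class IBDResult:
    slope: float
    intercept: float
    mantel_p: float
    mantel_r: float
    n_pairs: int


def mantel_test(x: np.ndarray, y: np.ndarray, n_permutations: int = 999,
                rng: np.random.Generator | None = None) -> tuple[float, float]:
    """One-sided Mantel test of positive association between two square
    distance matrices, permuting individuals jointly.

    Returns ``(r, p)`` with ``p = (1 + #{r_perm >= r_obs}) /
    (n_permutations + 1)``.
    """
    if rng is None:
        rng = np.random.default_rng()
    n = x.shape[0]
    iu = np.triu_indices(n, k=1)
    xv = x[iu]
    xv = (xv - xv.mean())
    sx = np.sqrt(np.sum(xv ** 2))
    yv = y[iu]
    yv = yv - yv.mean()
    sy = np.sqrt(np.sum(yv ** 2))
    if sx == 0 or sy == 0:
        return 0.0, 1.0
    r_obs = float(np.sum(xv * yv) / (sx * sy))
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        yp = y[np.ix_(perm, perm)][iu]
        yp = yp - yp.mean()
        r_perm = np.sum(xv * yp) / (sx * np.sqrt(np.sum(yp ** 2)))
        if r_perm >= r_obs:
            count += 1
    p = (1.0 + count) / (n_permutations + 1.0)
    return r_obs, p


def ibd_regression(sample: SampleSet, n_permutations: int = 999,
                   metric: str = "rousset",
                   rng: np.random.Generator | None = None) -> IBDResult:
    """Isolation-by-distance regression between individuals.

    Least-squares slope of pairwise genetic distance (Rousset's a-statistic
    by default) on the natural log of pairwise Euclidean geographic
    distance; significance by a one-sided Mantel permutation test (genetic
    distance increasing with distance).  Pairs at identical coordinates are
    dropped with a warning (log distance undefined).
    """
    if sample.n_individuals < 3:
        raise ValueError("need at least 3 individuals")
    coords = sample.coords.astype(float)
    gd = GENETIC_DISTANCES[metric](sample.genotypes)
    diff = coords[:, None, :] - coords[None, :, :]
    geo = np.sqrt((diff ** 2).sum(axis=-1))
    n = len(coords)
    iu = np.triu_indices(n, k=1)
    zero_pairs = geo[iu] == 0
    if zero_pairs.any():
        logger.warning("dropping %d coincident-coordinate pairs",
                       int(zero_pairs.sum()))
    log_geo = np.zeros_like(geo)
    np.log(geo, out=log_geo, where=geo > 0)
    xv = log_geo[iu][~zero_pairs]
    yv = gd[iu][~zero_pairs]
    if np.ptp(xv) == 0:
        raise ValueError("need at least 2 distinct locations")
    if np.ptp(yv) == 0:
        slope, intercept = 0.0, float(yv[0])
        r_obs, p = 0.0, 1.0
    else:
        res = stats.linregress(xv, yv)
        slope, intercept = float(res.slope), float(res.intercept)
        # Mantel on the full matrices so permutation respects individuals
        r_obs, p = mantel_test(log_geo, gd, n_permutations, rng)
    return IBDResult(slope, intercept, p, r_obs, int((~zero_pairs).sum()))
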