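"""Scoring protocol: is an inferred boundary (or cluster partition) correct?

Clustering output is correct after barrier imposition when exactly four
clusters are found and every individual is assigned to its true landscape
quadrant (up to label permutation); at generation 0 (no barrier yet) it is
correct when a single cluster is found.

Edge-detection output is judged by a quantified surrogate for the visual
check used with such methods: detected boundary elements must trace the two
true midlines and not lie elsewhere.  A replicate is correct (generation > 0)
when the detections that accurately follow the barriers (at least 80% of
their elements within ``tolerance`` map units of a true midline) mark both
midlines, each over at least 10% of its length; stray extra barriers are
disregarded, as an operator would.  At generation 0 a replicate is correct
only when nothing is detected (barrier paths shorter than
``min_path_length`` are treated as no detection).  Percent-correct tables
aggregate replicates per (condition, generation, method).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lattice import SampleSet, run_replicate
from .monmonier import BoundaryPath, build_graph, trace_barriers
from .params import BarrierSpec, SimulationParams
from .wombling import SystemicSurface, WomblingParams, womble

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# clustering scoring
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """Hard cluster assignment per individual (Q-matrices are hardened by
    argmax before scoring)."""

    k_estimated: int
    membership: np.ndarray
    source: str = ""


@dataclass
class EvaluationRecord:
    method: str
    parameter_combo: str
    generation: int
    replicate: int
    correct: bool
    k_estimated: int | None = None
    midline_coverage: float | None = None
    detection_precision: float | None = None


def score_clustering(result: ClusterResult, truth: SampleSet,
                     generation: int | None = None) -> bool:
    """Correct iff K = 4 with a perfect quadrant partition (generation > 0)
    or K = 1 (generation 0).  Label permutations do not matter."""
    membership = np.asarray(result.membership)
    if len(membership) != truth.n_individuals:
        raise ValueError(
            f"membership covers {len(membership)} individuals, "
            f"sample has {truth.n_individuals}")
    gen = truth.generation if generation is None else generation
    k = result.k_estimated
    if gen == 0:
        return k == 1 and len(np.unique(membership)) == 1
    if k != 4:
        return False
    # bijection test: each cluster maps to exactly one quadrant and back
    pairs = set(zip(membership.tolist(), truth.quadrant.tolist()))
    clusters = {c for c, _ in pairs}
    quads = {q for _, q in pairs}
    return (len(pairs) == 4 and len(clusters) == 4 and len(quads) == 4
            and len(np.unique(membership)) == 4)


# ---------------------------------------------------------------------------
# edge-method scoring
# ---------------------------------------------------------------------------

def true_midlines(barrier: BarrierSpec, grid_width: int, grid_height: int
                  ) -> list[tuple[tuple[float, float], tuple[float, float]]]:
    """The two barrier segments in map coordinates (cell centers at
    integers, so the split between columns ``s-1`` and ``s`` is at
    ``x = s - 0.5``)."""
    vx = barrier.split_x - 0.5
    hy = barrier.split_y - 0.5
    return [((vx, -0.5), (vx, grid_height - 0.5)),
            ((-0.5, hy), (grid_width - 0.5, hy))]


def _sample_segment(p1, p2, step: float = 1.0) -> np.ndarray:
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    length = np.linalg.norm(p2 - p1)
    n = max(2, int(np.ceil(length / step)) + 1)
    t = np.linspace(0.0, 1.0, n)
    return p1[None, :] + t[:, None] * (p2 - p1)[None, :]


def _clip_segment_to_box(p1, p2, xmin, xmax, ymin, ymax):
    """Liang-Barsky clipping; returns None when fully outside."""
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    d = p2 - p1
    t0, t1 = 0.0, 1.0
    for dim, (lo, hi) in enumerate(((xmin, xmax), (ymin, ymax))):
        if d[dim] == 0:
            if p1[dim] < lo or p1[dim] > hi:
                return None
            continue
        ta = (lo - p1[dim]) / d[dim]
        tb = (hi - p1[dim]) / d[dim]
        ta, tb = min(ta, tb), max(ta, tb)
        t0, t1 = max(t0, ta), min(t1, tb)
        if t0 > t1:
            return None
    return p1 + t0 * d, p1 + t1 * d


def detected_points_from_paths(paths: list[BoundaryPath],
                               grid_width: int, grid_height: int,
                               min_path_length: float = 10.0,
                               step: float = 1.0,
                               per_path: bool = False):
    """Boundary elements of traced barriers: points sampled every ``step``
    units along the Voronoi segments, clipped to the landscape.  Paths whose
    clipped length falls below ``min_path_length`` are treated as noise
    (equivalent to no detection), which gives the tracing algorithm a way to
    output 'no boundary'.  With ``per_path`` the points are returned as one
    group per surviving path (the grouping :func:`score_edges` uses to
    identify stray barriers)."""
    box = (-0.5, grid_width - 0.5, -0.5, grid_height - 0.5)
    groups: list[np.ndarray] = []
    for path in paths:
        clipped = []
        total = 0.0
        for p1, p2 in path.segments:
            seg = _clip_segment_to_box(p1, p2, *box)
            if seg is None:
                continue
            clipped.append(seg)
            total += float(np.linalg.norm(seg[1] - seg[0]))
        if total < min_path_length or not clipped:
            continue
        groups.append(np.vstack([_sample_segment(p1, p2, step)
                                 for p1, p2 in clipped]))
    if per_path:
        return groups
    if not groups:
        return np.empty((0, 2))
    return np.vstack(groups)


def detected_points_from_mask(surface: SystemicSurface) -> np.ndarray:
    """Significant wombling pixels as map-coordinate boundary elements."""
    if surface.significance_mask is None:
        raise ValueError("run boundary_test first")
    yy, xx = np.nonzero(surface.significance_mask)
    if len(yy) == 0:
        return np.empty((0, 2))
    return np.column_stack([surface.grid_x[xx], surface.grid_y[yy]])


def _min_dist_to_points(query: np.ndarray, ref: np.ndarray) -> np.ndarray:
    from scipy.spatial import cKDTree

    tree = cKDTree(ref)
    d, _ = tree.query(query)
    return d


def score_edges(detected: np.ndarray | list[np.ndarray],
                barrier: BarrierSpec,
                grid_width: int, grid_height: int,
                generation: int, tolerance: float = 5.0,
                precision_required: float = 0.8,
                min_line_coverage: float = 0.1
                ) -> tuple[bool, float, float]:
    """Surrogate for the visual boundary-correctness check.

    ``detected`` is either one array of boundary-element points or a list of
    groups (one per traced barrier).  Groups whose own precision -- the
    fraction of their points within ``tolerance`` of a true midline -- falls
    below ``precision_required`` are *stray* detections: a boundary an
    operator would disregard as not tracing the imposed barriers.  After
    barrier imposition (generation > 0) the inference is correct when at
    least one non-stray group remains and the non-stray elements mark both
    true midlines, covering at least ``min_line_coverage`` of the length of
    each within ``tolerance``.  Stray groups do not void a correct
    inference (tracing always returns the requested number of barriers, so
    weak supernumerary paths are inevitable) but contribute nothing to
    coverage.  At generation 0 there is no true boundary and the inference
    is correct only when nothing at all was detected.

    Returns ``(correct, line_coverage, precision)``: the minimum midline
    coverage by non-stray elements and the precision of the full detection
    set.
    """
    if isinstance(detected, np.ndarray):
        groups = [detected.reshape(-1, 2)] if detected.size else []
    else:
        groups = [np.asarray(g, float).reshape(-1, 2)
                  for g in detected if np.asarray(g).size]
    n_detected = int(sum(len(g) for g in groups))
    if generation == 0:
        return n_detected == 0, np.nan, np.nan
    if n_detected == 0:
        return False, 0.0, np.nan
    midlines = true_midlines(barrier, grid_width, grid_height)
    line_pts_per = [_sample_segment(p1, p2, step=1.0) for p1, p2 in midlines]
    line_pts = np.vstack(line_pts_per)
    retained = []
    for g in groups:
        prec_g = float(np.mean(_min_dist_to_points(g, line_pts) <= tolerance))
        if prec_g >= precision_required:
            retained.append(g)
    all_pts = np.vstack(groups)
    precision = float(np.mean(
        _min_dist_to_points(all_pts, line_pts) <= tolerance))
    if not retained:
        return False, 0.0, precision
    kept = np.vstack(retained)
    coverage = min(
        float(np.mean(_min_dist_to_points(lp, kept) <= tolerance))
        for lp in line_pts_per)
    correct = coverage >= min_line_coverage
    return correct, coverage, precision


# ---------------------------------------------------------------------------
# benchmark driver
# ---------------------------------------------------------------------------

@dataclass
class MethodSpec:
    """Internal edge methods and their scoring parameters."""

    name: str               # 'monmonier' or 'wombling'
    distance: str = "residual"          # monmonier edge weights
    n_barriers: int = 4
    wombling: WomblingParams | None = None
    tolerance: float = 5.0
    min_path_length: float = 10.0


def _default_wombling(params: SimulationParams) -> WomblingParams:
    return WomblingParams(
        grid_nx=100, grid_ny=100, bandwidth=7.0, percentile_p=0.3,
        alpha=0.05,
        extent=(0.0, params.grid_width - 1.0, 0.0, params.grid_height - 1.0),
    )


def evaluate_sample(sample: SampleSet, params: SimulationParams,
                    method: MethodSpec) -> EvaluationRecord:
    """Run one edge method on one sample and score it."""
    barrier = BarrierSpec.from_params(params)
    if method.name == "monmonier":
        graph = build_graph(sample.coords, sample.genotypes,
                            distance=method.distance)
        paths = trace_barriers(graph, n_barriers=method.n_barriers)
        detected = detected_points_from_paths(
            paths, params.grid_width, params.grid_height,
            min_path_length=method.min_path_length, per_path=True)
    elif method.name == "wombling":
        wp = method.wombling or _default_wombling(params)
        surface = womble(sample, wp)
        detected = detected_points_from_mask(surface)
    else:
        raise ValueError(f"unknown method {method.name!r}")
    correct, cov, prec = score_edges(
        detected, barrier, params.grid_width, params.grid_height,
        sample.generation, tolerance=method.tolerance)
    return EvaluationRecord(
        method=method.name, parameter_combo="", generation=sample.generation,
        replicate=sample.replicate_id, correct=correct,
        midline_coverage=cov, detection_precision=prec)


def score_external_memberships(results: dict[int, ClusterResult],
                               samples: list[SampleSet]) -> list[EvaluationRecord]:
    """Score externally produced cluster memberships (one per generation)."""
    records = []
    for s in samples:
        if s.generation not in results:
            logger.warning("no external membership for generation %d; "
                           "skipped", s.generation)
            continue
        res = results[s.generation]
        records.append(EvaluationRecord(
            method=res.source or "external", parameter_combo="",
            generation=s.generation, replicate=s.replicate_id,
            correct=score_clustering(res, s), k_estimated=res.k_estimated))
    return records


def run_benchmark(combos: dict[str, SimulationParams],
                  methods: list[MethodSpec],
                  n_replicates: int | None = None) -> pd.DataFrame:
    """Full factorial benchmark: combos x generations x replicates x methods.

    Returns a tidy percent-correct table with one row per (combo,
    generation) and one column per method, mirroring the layout in which
    such comparisons are reported.  Fully deterministic given the combos'
    seeds.
    """
    rows = []
    for combo_name, params in combos.items():
        reps = params.n_replicates if n_replicates is None else n_replicates
        records: list[EvaluationRecord] = []
        for rep in range(reps):
            result = run_replicate(params, replicate=rep)
            for sample in result.samples:
                for method in methods:
                    rec = evaluate_sample(sample, params, method)
                    rec.parameter_combo = combo_name
                    records.append(rec)
        for gen in params.export_generations:
            row = {"combo": combo_name, "generation": gen}
            for method in methods:
                vals = [r.correct for r in records
                        if r.generation == gen and r.method == method.name]
                row[method.name] = (100.0 * np.mean(vals)) if vals else np.nan
            rows.append(row)
    return pd.DataFrame(rows)
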