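"""Neighbor-enrichment test for convergent clonotype selection.

For each clonotype the observed number of same-(V, J), same-length CDR3
amino-acid sequences within Hamming distance 1 is compared against the
expectation under the recombination null.  Clonotypes whose BH-adjusted
upper-tail Poisson p-value falls below ``alpha`` (default 0.001) are hits.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .generative_model import PgenEstimate, RecombinationModel, SimulationCache
from .repertoire_io import ClonotypeKey, Repertoire, remove_singletons

__all__ = [
    "NeighborTestResult",
    "count_neighbors",
    "neighbor_pvalue",
    "bh_adjust",
    "run_alice",
    "normalized_hits",
]

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.001
DEFAULT_N_SIM = 5_000_000
DEFAULT_N_BATCHES = 20


@dataclass(frozen=True)
class NeighborTestResult:
    key: ClonotypeKey
    d_obs: int
    ball_pgen: Optional[PgenEstimate]
    lambda_expected: float
    p_value: float
    q_value: float
    is_hit: bool


def count_neighbors(rep: Repertoire) -> Dict[ClonotypeKey, int]:
    """Observed neighbor counts within (V, J, length) classes.

    Two clonotypes are neighbors when they share V gene, J gene, and CDR3
    length, and their CDR3s differ at no more than one position.  Uses the
    position-masking hash-bucket method: within a class, two distinct
    sequences fall in the same masked bucket for exactly one position iff
    they are Hamming-distance-1 neighbors.
    """
    keys = [c.key for c in rep.clonotypes]
    if len(set(keys)) != len(keys):
        raise ValueError("repertoire must be deduplicated on (cdr3_aa, v, j)")
    d_obs = {k: 0 for k in keys}
    classes: Dict[Tuple[str, str, int], List[str]] = defaultdict(list)
    for aa, v, j in keys:
        classes[(v, j, len(aa))].append(aa)
    for (v, j, L), seqs in classes.items():
        for pos in range(L):
            buckets: Dict[str, List[str]] = defaultdict(list)
            for s in seqs:
                buckets[s[:pos] + s[pos + 1 :]].append(s)
            for group in buckets.values():
                if len(group) > 1:
                    for s in group:
                        d_obs[(s, v, j)] += len(group) - 1
    return d_obs


def neighbor_pvalue(d_obs: int, lambda_expected: float) -> float:
    """Upper-tail Poisson probability P(X >= d_obs) at mean lambda_expected."""
    if d_obs < 0 or lambda_expected < 0:
        raise ValueError("d_obs and lambda_expected must be non-negative")
    if d_obs == 0:
        return 1.0
    return float(stats.poisson.sf(d_obs - 1, lambda_expected))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _calibrate_q_factor(raw, min_points: int = 10) -> float:
    """Self-calibration of the selection/attrition constant.

    The median of ``d_obs / base_lambda`` over low-Pgen clonotypes with at
    least one observed neighbor; low-Pgen means ball Pgen below the median
    among those clonotypes.  Falls back to 1.0 with too few points.
    """
    pts = [(est.point, d / lam) for _, d, est, lam in raw if d > 0 and lam > 0]
    if len(pts) < min_points:
        return 1.0
    pts.sort()
    low = pts[: max(min_points, len(pts) // 2)]
    return float(np.median([r for _, r in low]))


def run_alice(
    rep: Repertoire,
    model: RecombinationModel,
    alpha: float = DEFAULT_ALPHA,
    n_sim: int = DEFAULT_N_SIM,
    n_batches: int = DEFAULT_N_BATCHES,
    q_factor: "float | str" = 1.0,
    seed: int = 0,
    sim_cache: Optional[SimulationCache] = None,
) -> List[NeighborTestResult]:
    """Run the neighbor-enrichment test on one repertoire.

    Singletons are removed first (the test's stated precondition).  For a
    clonotype in a VJ class of size N the null expectation is
    ``q_factor * (N - 1) * (ball_pgen - point_pgen)``: the probability mass
    of the Hamming-1 neighborhood excluding the center itself, scaled by the
    number of co-occurring same-VJ clonotypes.  Ball Pgens are only needed
    for clonotypes with at least one observed neighbor (otherwise p = 1), so
    simulation is restricted to the VJ classes containing such clonotypes.
    VJ pairs absent from the model are skipped with a warning.  BH
    correction is applied jointly over all tested clonotypes; results are
    sorted by (q, key).
    """
    dedup = rep.aggregated()
    filtered = remove_singletons(dedup)
    logger.info(
        "singleton removal: %d -> %d clonotypes (%s)",
        len(dedup),
        len(filtered),
        rep.sample_id,
    )
    d_obs = count_neighbors(filtered)

    class_size: Dict[Tuple[str, str], int] = defaultdict(int)
    for aa, v, j in d_obs:
        class_size[(v, j)] += 1

    if sim_cache is None:
        batch = max(1, n_sim // n_batches)
        sim_cache = SimulationCache(model, batch * n_batches, n_batches, seed)

    skipped_vj = set()
    raw = []  # (key, d, pgen_estimate_or_None, base_lambda)
    for c in filtered.clonotypes:
        aa, v, j = c.key
        if (v, j) not in model.vj_usage:
            if (v, j) not in skipped_vj:
                skipped_vj.add((v, j))
                logger.warning("VJ pair (%s, %s) absent from model; class skipped", v, j)
            continue
        d = d_obs[c.key]
        if d == 0:
            raw.append((c.key, 0, None, 0.0))
            continue
        sims = sim_cache.get(v, j)
        ball, point, se = sims.ball_stats(aa)
        n_class = class_size[(v, j)]
        # floor at one pseudo-simulation so a sparse MC estimate cannot
        # produce lambda = 0 (which would force p = 0 for any d >= 1)
        neighbor_mass = max(ball - point, 1.0 / sims.n_sim)
        est = PgenEstimate(ball, se, sims.n_sim, sims.n_batches)
        raw.append((c.key, d, est, (n_class - 1) * neighbor_mass))

    if q_factor == "auto":
        q_factor = _calibrate_q_factor(raw)
        logger.info("self-calibrated q_factor = %.3f", q_factor)

    entries = []  # (key, d, est, lam, p)
    for key, d, est, base_lam in raw:
        lam = q_factor * base_lam
        entries.append((key, d, est, lam, neighbor_pvalue(d, lam)))

    q_values = bh_adjust([e[4] for e in entries])
    results = [
        NeighborTestResult(
            key=key,
            d_obs=d,
            ball_pgen=est,
            lambda_expected=lam,
            p_value=p,
            q_value=float(q),
            is_hit=bool(q < alpha),
        )
        for (key, d, est, lam, p), q in zip(entries, q_values)
    ]
    results.sort(key=lambda r: (r.q_value, r.key))
    return results


def normalized_hits(results: Sequence[NeighborTestResult], n_input_clonotypes: int) -> float:
    """Hit count divided by the clonotype count of the *initial* input
    (before singleton removal)."""
    if n_input_clonotypes < 1:
        raise ValueError("n_input_clonotypes must be >= 1")
    return sum(r.is_hit for r in results) / n_input_clonotypes
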