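"""Replicate-based differential clonotype expansion between two conditions.

A self-contained negative-binomial exact test: median-of-ratios library
normalization, method-of-moments dispersion with trended shrinkage, and a
conditional two-group NB exact test on group-summed pseudocounts.  Clonotypes
are called expanded at BH-adjusted p < 0.01 and log2 fold-change > 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .alice_stat import bh_adjust

__all__ = [
    "ExpansionResult",
    "normalize_libraries",
    "estimate_dispersion",
    "nb_exact_test",
    "call_expanded",
]

logger = logging.getLogger(__name__)

DEFAULT_FDR = 0.01
DEFAULT_LFC = 1.0
DISPERSION_FLOOR = 1e-6


@dataclass(frozen=True)
class ExpansionResult:
    key: str
    log2fc: float
    p_value: float
    q_value: float
    called: bool


def normalize_libraries(counts: pd.DataFrame) -> Tuple[pd.Series, pd.Series]:
    """Median-of-ratios normalization.

    Per column: the median ratio of its counts to the row-wise geometric
    mean, over rows with all-positive counts.  Factors are rescaled to
    geometric mean 1; effective library sizes are the factors multiplied by
    the geometric-mean raw library size, so identical columns get equal
    effective sizes and a doubled column gets a doubled one.

    Returns ``(factors, effective_sizes)`` indexed by column.
    """
    if counts.shape[1] < 1:
        raise ValueError("count matrix must have at least one column")
    mat = counts.to_numpy(dtype=float)
    lib_sizes = mat.sum(axis=0)
    positive = np.all(mat > 0, axis=1)
    if not positive.any():
        logger.warning("no all-positive row; normalization factors default to 1")
        factors = np.ones(mat.shape[1])
    else:
        sub = mat[positive]
        log_ref = np.log(sub).mean(axis=1)
        ratios = np.log(sub) - log_ref[:, None]
        factors = np.exp(np.median(ratios, axis=0))
        factors = factors / np.exp(np.mean(np.log(factors)))
    geo_lib = float(np.exp(np.mean(np.log(np.maximum(lib_sizes, 1.0)))))
    eff = factors * geo_lib
    return (
        pd.Series(factors, index=counts.columns, name="factor"),
        pd.Series(eff, index=counts.columns, name="effective_size"),
    )


def _normalized_counts(counts: pd.DataFrame, eff: pd.Series) -> np.ndarray:
    scale = float(np.exp(np.mean(np.log(eff.to_numpy()))))
    return counts.to_numpy(dtype=float) / eff.to_numpy() * scale


def estimate_dispersion(
    counts: pd.DataFrame,
    design: Mapping[str, str],
    n_bins: int = 10,
) -> pd.Series:
    """Per-clonotype NB dispersion by the method of moments.

    Within-condition mean/variance on normalized counts gives a raw
    per-clonotype estimate ``(var - mean) / mean^2`` (pooled over conditions
    with replication), which is then shrunk 50/50 toward the median raw
    dispersion of its abundance bin and floored at 1e-6.
    """
    conditions: Dict[str, List[str]] = {}
    for sample, cond in design.items():
        conditions.setdefault(cond, []).append(sample)
    replicated = {c: s for c, s in conditions.items() if len(s) >= 2}
    if not replicated:
        raise ValueError(
            "no condition has >= 2 replicates; supply a dispersion explicitly"
        )
    _, eff = normalize_libraries(counts)
    z = _normalized_counts(counts, eff)
    col_idx = {s: i for i, s in enumerate(counts.columns)}

    num = np.zeros(len(counts))
    den = np.zeros(len(counts))
    abundance = z.mean(axis=1)
    for cond, samples in replicated.items():
        idx = [col_idx[s] for s in samples]
        sub = z[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        df = len(idx) - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = np.where(m > 0, (v - m) / np.maximum(m, 1e-12) ** 2, 0.0)
        num += df * phi
        den += df
    raw = np.maximum(num / den, DISPERSION_FLOOR)

    # trended shrinkage: median raw dispersion per abundance bin
    order = np.argsort(abundance, kind="stable")
    bins = np.array_split(order, n_bins)
    trend = np.empty(len(counts))
    for b in bins:
        if len(b):
            trend[b] = np.median(raw[b])
    shrunk = np.maximum(0.5 * raw + 0.5 * trend, DISPERSION_FLOOR)
    return pd.Series(shrunk, index=counts.index, name="dispersion")


def _conditional_nb_pvalue(
    y_a: int, y_b: int, n_a: int, n_b: int, phi: float
) -> float:
    """Two-sided (doubled smaller tail) conditional NB exact test.

    Under the null of equal per-sample means, the group sums are NB with
    sizes ``n_g / phi`` and common per-sample mean ``t / (n_a + n_b)``; the
    p-value conditions on the observed total ``t``.
    """
    t = y_a + y_b
    if t == 0:
        return 1.0
    mu = t / (n_a + n_b)
    r_a = n_a / phi
    r_b = n_b / phi
    a = np.arange(t + 1)
    # log NB pmf up to constants, via sum(log(r+i)) rather than gammaln
    # differences, which lose precision for the huge r of tiny dispersions
    i = np.arange(t, dtype=float)
    cum_a = np.concatenate(([0.0], np.cumsum(np.log(r_a + i))))
    cum_b = np.concatenate(([0.0], np.cumsum(np.log(r_b + i))))
    log_q_a = math.log(n_a * mu) - math.log(r_a + n_a * mu)
    log_q_b = math.log(n_b * mu) - math.log(r_b + n_b * mu)
    logw = (
        cum_a[a]
        - gammaln(a + 1)
        + a * log_q_a
        + cum_b[t - a]
        - gammaln(t - a + 1)
        + (t - a) * log_q_b
    )
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()
    left = w[: y_a + 1].sum()
    right = w[y_a:].sum()
    return float(min(1.0, 2.0 * min(left, right)))


def nb_exact_test(
    counts: pd.DataFrame,
    design: Mapping[str, str],
    dispersions: Optional[pd.Series] = None,
    focal_condition: Optional[str] = None,
    fdr: float = DEFAULT_FDR,
    lfc: float = DEFAULT_LFC,
) -> List[ExpansionResult]:
    """Per-clonotype two-group NB exact test.

    ``log2fc`` is focal condition over reference, computed from normalized
    condition means with a 0.5 pseudo-count.  Pseudocounts are counts scaled
    to a common effective library size before group summation.  A two-sided
    p-value is retained; calling is one-sided via the ``log2fc > lfc`` gate.
    """
    condition_labels = sorted(set(design.values()))
    if len(condition_labels) != 2:
        raise ValueError(f"exactly two conditions required, got {condition_labels}")
    if focal_condition is None:
        focal_condition = condition_labels[1]
    if focal_condition not in condition_labels:
        raise ValueError(f"focal condition {focal_condition!r} not in design")
    ref_condition = next(c for c in condition_labels if c != focal_condition)
    cols_ref = [s for s in counts.columns if design[s] == ref_condition]
    cols_foc = [s for s in counts.columns if design[s] == focal_condition]
    if not cols_ref or not cols_foc:
        raise ValueError("each condition needs at least one sample")

    if dispersions is None:
        dispersions = estimate_dispersion(counts, design)
    phi_arr = np.maximum(
        dispersions.reindex(counts.index).to_numpy(dtype=float), 1e-12
    )

    _, eff = normalize_libraries(counts)
    z = _normalized_counts(counts, eff)
    col_idx = {s: i for i, s in enumerate(counts.columns)}
    idx_ref = [col_idx[s] for s in cols_ref]
    idx_foc = [col_idx[s] for s in cols_foc]

    pvals = np.empty(len(counts))
    lfcs = np.empty(len(counts))
    for i in range(len(counts)):
        pseudo_ref = z[i, idx_ref]
        pseudo_foc = z[i, idx_foc]
        y_ref = int(round(pseudo_ref.sum()))
        y_foc = int(round(pseudo_foc.sum()))
        m_ref = pseudo_ref.mean()
        m_foc = pseudo_foc.mean()
        lfcs[i] = math.log2((m_foc + 0.5) / (m_ref + 0.5))
        if y_ref + y_foc == 0:
            pvals[i] = 1.0
            lfcs[i] = 0.0
            continue
        pvals[i] = _conditional_nb_pvalue(
            y_foc, y_ref, len(idx_foc), len(idx_ref), float(phi_arr[i])
        )
    qvals = bh_adjust(pvals)
    return [
        ExpansionResult(
            key=str(key),
            log2fc=float(l),
            p_value=float(p),
            q_value=float(q),
            called=bool(q < fdr and l > lfc),
        )
        for key, l, p, q in zip(counts.index, lfcs, pvals, qvals)
    ]


def call_expanded(
    results: Sequence[ExpansionResult],
    fdr: float = DEFAULT_FDR,
    lfc: float = DEFAULT_LFC,
) -> Set[str]:
    """Keys expanded in the focal condition: q < fdr and log2fc > lfc."""
    return {r.key for r in results if r.q_value < fdr and r.log2fc > lfc}
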