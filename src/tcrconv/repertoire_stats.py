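"""Diversity/clonality metrics and cross-repertoire clonotype matching."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .repertoire_io import ClonotypeKey, Repertoire

__all__ = ["DiversitySummary", "clonality", "subset_match_count"]


@dataclass(frozen=True)
class DiversitySummary:
    richness: int
    shannon: float
    normalized_shannon: float
    clonality: float


def clonality(rep: Repertoire) -> DiversitySummary:
    """Clonality = 1 - normalized Shannon-Wiener index (natural log).

    ``H = -sum f ln f`` over positive frequencies, normalized by
    ``ln(richness)``; a single-clonotype repertoire has clonality 1 by
    convention.
    """
    freqs = [c.freq for c in rep.clonotypes if c.freq > 0]
    if not freqs:
        raise ValueError("repertoire has no clonotype with positive frequency")
    total = sum(freqs)
    freqs = [f / total for f in freqs]
    richness = len(freqs)
    shannon = -sum(f * math.log(f) for f in freqs)
    if richness >= 2:
        normalized = shannon / math.log(richness)
    else:
        normalized = 0.0
    return DiversitySummary(
        richness=richness,
        shannon=shannon,
        normalized_shannon=normalized,
        clonality=1.0 - normalized,
    )


def subset_match_count(
    query_keys: Sequence[ClonotypeKey],
    reference: Repertoire,
    top_n: Optional[int] = None,
) -> int:
    """Number of query keys found among the top-``top_n`` reference
    clonotypes ranked by frequency (ties broken lexicographically by key).

    ``top_n=None`` matches against the whole reference.
    """
    if top_n is not None and top_n < 1:
        raise ValueError("top_n must be >= 1")
    ranked = sorted(reference.clonotypes, key=lambda c: (-c.freq, c.key))
    if top_n is not None:
        ranked = ranked[:top_n]
    top_keys = {c.key for c in ranked}
    return sum(1 for k in set(tuple(q) for q in query_keys) if k in top_keys)
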