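"""V(D)J recombination generative model.

A D-less rearrangement model: the CDR3 nucleotide sequence is the
concatenation of a trimmed V 3' contribution, a random N-insert, and a
trimmed J 5' contribution.  A rearrangement is *productive* when the
junction is in frame, stop-free, and anchored by an N-terminal C and a
C-terminal F or W.  The model serves three roles:

* Monte-Carlo null for the neighbor-enrichment statistic
  (:func:`estimate_ball_pgen`, :class:`VJSimulations`),
* an exact-enumeration oracle on small configurations
  (:func:`exact_ball_pgen`, :func:`enumerate_rearrangements`),
* synthetic-data generator (:func:`generate_null_repertoire`,
  :func:`plant_convergent_cluster`, :func:`generate_study`).

Generation probabilities are conditional on the (V, J) pair and on
productivity, matching a per-VJ simulation of productive sequences.
"""

from __future__ import annotations

import itertools
import math
from collections import defaultdict
from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import yaml

from .repertoire_io import (
    AA_ALPHABET,
    CODON_TO_AA,
    Clonotype,
    Repertoire,
    translate_nt,
)

__all__ = [
    "RecombinationModel",
    "PgenEstimate",
    "SyntheticStudy",
    "CapacityError",
    "VJSimulations",
    "sample_rearrangement",
    "simulate_productive",
    "estimate_ball_pgen",
    "exact_ball_pgen",
    "enumerate_rearrangements",
    "generate_null_repertoire",
    "plant_convergent_cluster",
    "generate_study",
    "toy_model",
    "toy_insertion_model",
    "human_like_model",
]

_BASES = "ACGT"
_AA_LIST = sorted(AA_ALPHABET)
_BASE_CODE = {b: i for i, b in enumerate(_BASES)}

# codon index (16*a + 4*b + c over base codes) -> amino-acid byte; stop = '*'
_CODON_AA_BYTES = np.zeros(64, dtype=np.uint8)
for _codon, _aa in CODON_TO_AA.items():
    _idx = 16 * _BASE_CODE[_codon[0]] + 4 * _BASE_CODE[_codon[1]] + _BASE_CODE[_codon[2]]
    _CODON_AA_BYTES[_idx] = ord(_aa)


def _nt_codes(nt: str) -> np.ndarray:
    return np.array([_BASE_CODE[b] for b in nt], dtype=np.int64)


class CapacityError(RuntimeError):
    """Raised when an enumeration or sampling request exceeds model capacity."""


def _as_probs(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-d probability vector")
    if np.any(arr < 0) or abs(arr.sum() - 1.0) > 1e-12:
        raise ValueError(f"{name} must be non-negative and sum to 1")
    return arr


@dataclass
class RecombinationModel:
    """Parameter set of the D-less V(D)J rearrangement model.

    Deletion distributions are probability vectors indexed by the number of
    nucleotides trimmed (index 0 = no trimming); the insertion length
    distribution is indexed by insert length in nucleotides; insertion bases
    are i.i.d. over ``ACGT``.
    """

    v_segments: Dict[str, str]
    j_segments: Dict[str, str]
    v_deletion_dist: np.ndarray
    j_deletion_dist: np.ndarray
    insertion_length_dist: np.ndarray
    insertion_base_probs: np.ndarray
    vj_usage: Dict[Tuple[str, str], float]

    def __post_init__(self) -> None:
        self.v_deletion_dist = _as_probs(self.v_deletion_dist, "v_deletion_dist")
        self.j_deletion_dist = _as_probs(self.j_deletion_dist, "j_deletion_dist")
        self.insertion_length_dist = _as_probs(
            self.insertion_length_dist, "insertion_length_dist"
        )
        self.insertion_base_probs = _as_probs(
            self.insertion_base_probs, "insertion_base_probs"
        )
        if self.insertion_base_probs.size != 4:
            raise ValueError("insertion_base_probs must have 4 entries (ACGT)")
        if not self.vj_usage:
            raise ValueError("vj_usage support is empty")
        total = sum(self.vj_usage.values())
        if abs(total - 1.0) > 1e-12 or any(p < 0 for p in self.vj_usage.values()):
            raise ValueError("vj_usage must be non-negative and sum to 1")
        max_vdel = self.v_deletion_dist.size - 1
        max_jdel = self.j_deletion_dist.size - 1
        for (v, j), p in self.vj_usage.items():
            if v not in self.v_segments:
                raise ValueError(f"vj_usage references unknown V segment {v!r}")
            if j not in self.j_segments:
                raise ValueError(f"vj_usage references unknown J segment {j!r}")
            if p > 0 and max_vdel > len(self.v_segments[v]):
                raise ValueError(f"v deletions exceed length of segment {v!r}")
            if p > 0 and max_jdel > len(self.j_segments[j]):
                raise ValueError(f"j deletions exceed length of segment {j!r}")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "v_segments": dict(self.v_segments),
            "j_segments": dict(self.j_segments),
            "v_deletion_dist": [float(x) for x in self.v_deletion_dist],
            "j_deletion_dist": [float(x) for x in self.j_deletion_dist],
            "insertion_length_dist": [float(x) for x in self.insertion_length_dist],
            "insertion_base_probs": [float(x) for x in self.insertion_base_probs],
            "vj_usage": {f"{v}|{j}": float(p) for (v, j), p in sorted(self.vj_usage.items())},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RecombinationModel":
        usage = {}
        for k, p in d["vj_usage"].items():
            v, j = k.split("|")
            usage[(v, j)] = float(p)
        return cls(
            v_segments=dict(d["v_segments"]),
            j_segments=dict(d["j_segments"]),
            v_deletion_dist=d["v_deletion_dist"],
            j_deletion_dist=d["j_deletion_dist"],
            insertion_length_dist=d["insertion_length_dist"],
            insertion_base_probs=d["insertion_base_probs"],
            vj_usage=usage,
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path) -> "RecombinationModel":
        return cls.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))


@dataclass(frozen=True)
class PgenEstimate:
    """Monte-Carlo estimate of the Hamming-<=1 ball generation probability."""

    point: float
    std_error: float
    n_sim: int
    n_batches: int


@dataclass
class SyntheticStudy:
    """A synthetic multi-sample study with complete ground truth.

    ``truth`` maps ``"cdr3|v|j"`` strings to label dicts with any of the
    keys ``planted_cluster_id``, ``specificity``, ``true_log2fc``.
    """

    repertoires: Dict[str, Repertoire]
    counts: "object"  # pandas.DataFrame rows=keys, cols=sample ids
    design: Dict[str, str]  # sample id -> condition label
    truth: Dict[str, dict]


def _is_productive(aa: str) -> bool:
    return aa.startswith("C") and aa.endswith(("F", "W")) and "*" not in aa


def _translate(nt: str) -> Optional[str]:
    if len(nt) % 3:
        return None
    return "".join(CODON_TO_AA[nt[i : i + 3]] for i in range(0, len(nt), 3))


def _sample_batch(
    model: RecombinationModel,
    rng: np.random.Generator,
    m: int,
    v_gene: Optional[str] = None,
    j_gene: Optional[str] = None,
) -> List[Tuple[str, str, str, str]]:
    """Draw ``m`` rearrangement events; return the productive ones.

    When ``v_gene``/``j_gene`` are given the VJ pair is fixed (conditional
    simulation); otherwise pairs are drawn from ``vj_usage``.
    """
    if v_gene is None:
        pairs = sorted(model.vj_usage)
        probs = np.array([model.vj_usage[p] for p in pairs])
        probs = probs / probs.sum()
        pair_idx = rng.choice(len(pairs), size=m, p=probs)
    else:
        pairs = [(v_gene, j_gene)]
        pair_idx = np.zeros(m, dtype=int)

    vdel = rng.choice(model.v_deletion_dist.size, size=m, p=model.v_deletion_dist)
    jdel = rng.choice(model.j_deletion_dist.size, size=m, p=model.j_deletion_dist)
    ilen = rng.choice(model.insertion_length_dist.size, size=m, p=model.insertion_length_dist)
    max_ins = int(ilen.max()) if m else 0
    if max_ins:
        base_idx = rng.choice(4, size=(m, max_ins), p=model.insertion_base_probs)
    else:
        base_idx = np.zeros((m, 0), dtype=int)

    out = []
    for i in range(m):
        v, j = pairs[pair_idx[i]]
        v_nt = model.v_segments[v]
        j_nt = model.j_segments[j]
        if vdel[i] > len(v_nt) or jdel[i] > len(j_nt):
            continue
        ins = "".join(_BASES[b] for b in base_idx[i, : ilen[i]])
        nt = v_nt[: len(v_nt) - vdel[i]] + ins + j_nt[jdel[i] :]
        aa = _translate(nt)
        if aa and _is_productive(aa):
            out.append((v, j, nt, aa))
    return out


def sample_rearrangement(
    model: RecombinationModel, rng_seed: int
) -> Optional[Tuple[str, str, str, str]]:
    """Draw one rearrangement event; ``None`` marks a non-productive rejection."""
    rng = np.random.default_rng(rng_seed)
    drawn = _sample_batch(model, rng, 1)
    return drawn[0] if drawn else None


def _simulate_groups(
    model: RecombinationModel,
    v_gene: str,
    j_gene: str,
    n: int,
    rng: np.random.Generator,
) -> Dict[int, Tuple[np.ndarray, np.ndarray]]:
    """Vectorized conditional simulation of ``n`` productive CDR3s.

    Returns a map CDR3 length -> ``(aa_matrix, ranks)`` where ``aa_matrix``
    holds one amino-acid byte row per simulated sequence and ``ranks`` gives
    each row's position (0-based) in the overall productive draw order.
    """
    if (v_gene, j_gene) not in model.vj_usage:
        raise ValueError(f"VJ pair ({v_gene!r}, {j_gene!r}) absent from model support")
    v_codes = _nt_codes(model.v_segments[v_gene])
    j_codes = _nt_codes(model.j_segments[j_gene])
    lv, lj = len(v_codes), len(j_codes)
    max_ins = model.insertion_length_dist.size - 1

    pieces: List[Tuple[int, np.ndarray, np.ndarray]] = []  # (L, orders, aa_rows)
    count = 0
    draws_so_far = 0
    acceptance = 0.3
    guard = 0
    while count < n:
        m = int((n - count) / max(acceptance, 0.02)) + 128
        vdel = rng.choice(model.v_deletion_dist.size, size=m, p=model.v_deletion_dist)
        jdel = rng.choice(model.j_deletion_dist.size, size=m, p=model.j_deletion_dist)
        ilen = rng.choice(
            model.insertion_length_dist.size, size=m, p=model.insertion_length_dist
        )
        if max_ins:
            ins = rng.choice(4, size=(m, max_ins), p=model.insertion_base_probs)
        else:
            ins = np.zeros((m, 1), dtype=np.int64)

        a = lv - vdel  # V-part length per draw
        b = a + ilen
        tot = b + lj - jdel
        keep = tot % 3 == 0

        l_max = int(tot[keep].max()) if keep.any() else 0
        if l_max:
            cols = np.arange(l_max)[None, :]
            v_part = v_codes[np.clip(cols, 0, lv - 1)]
            ins_part = np.take_along_axis(
                ins, np.clip(cols - a[:, None], 0, max(ins.shape[1] - 1, 0)), axis=1
            )
            j_idx = np.clip(jdel[:, None] + cols - b[:, None], 0, lj - 1)
            j_part = j_codes[j_idx]
            mat = np.where(
                cols < a[:, None], v_part, np.where(cols < b[:, None], ins_part, j_part)
            )
            for L in np.unique(tot[keep]):
                L = int(L)
                if L == 0:
                    continue
                rows = np.nonzero(keep & (tot == L))[0]
                sub = mat[rows, :L]
                codons = 16 * sub[:, 0::3] + 4 * sub[:, 1::3] + sub[:, 2::3]
                aa = _CODON_AA_BYTES[codons]
                ok = (
                    (aa[:, 0] == ord("C"))
                    & ((aa[:, -1] == ord("F")) | (aa[:, -1] == ord("W")))
                    & ~(aa == ord("*")).any(axis=1)
                )
                if ok.any():
                    pieces.append((L // 3, draws_so_far + rows[ok], aa[ok]))
                    count += int(ok.sum())
        draws_so_far += m
        acceptance = max(count / draws_so_far, 1e-3)
        guard += 1
        if guard > 10_000:
            raise CapacityError(
                f"productive acceptance rate too low for VJ pair ({v_gene}, {j_gene})"
            )

    # rank all productive draws by draw order and keep the first n
    all_orders = np.concatenate([orders for _, orders, _ in pieces])
    rank_of = {o: r for r, o in enumerate(np.sort(all_orders))}
    groups: Dict[int, Tuple[np.ndarray, np.ndarray]] = {}
    for L, orders, aa in pieces:
        ranks = np.array([rank_of[o] for o in orders], dtype=np.int64)
        sel = ranks < n
        if not sel.any():
            continue
        if L in groups:
            prev_aa, prev_r = groups[L]
            groups[L] = (np.vstack([prev_aa, aa[sel]]), np.concatenate([prev_r, ranks[sel]]))
        else:
            groups[L] = (aa[sel], ranks[sel])
    return groups


def simulate_productive(
    model: RecombinationModel,
    v_gene: str,
    j_gene: str,
    n: int,
    rng: np.random.Generator,
) -> List[str]:
    """Simulate ``n`` productive CDR3 amino-acid sequences for one VJ pair."""
    groups = _simulate_groups(model, v_gene, j_gene, n, rng)
    seqs: List[Optional[str]] = [None] * n
    for L, (aa, ranks) in groups.items():
        for row, r in zip(aa, ranks):
            seqs[int(r)] = row.tobytes().decode("ascii")
    return [s for s in seqs if s is not None]


class VJSimulations:
    """Productive simulations for one VJ pair, indexed for fast ball queries.

    Sequences are grouped by length into byte matrices so the Hamming-<=1
    ball fraction of any query is a single vectorized comparison.
    """

    def __init__(self, seqs: Sequence[str], n_batches: int):
        if len(seqs) % n_batches:
            raise ValueError("n_sim must be divisible by n_batches")
        self.n_sim = len(seqs)
        self.n_batches = n_batches
        self.batch_size = len(seqs) // n_batches
        by_len: Dict[int, List[int]] = defaultdict(list)
        for i, s in enumerate(seqs):
            by_len[len(s)].append(i)
        self._mats: Dict[int, Tuple[np.ndarray, np.ndarray]] = {}
        for L, idx in by_len.items():
            mat = np.frombuffer(
                "".join(seqs[i] for i in idx).encode("ascii"), dtype=np.uint8
            ).reshape(len(idx), L)
            batch_ids = np.asarray(idx, dtype=np.int64) // self.batch_size
            self._mats[L] = (mat, batch_ids)

    @classmethod
    def from_groups(
        cls,
        groups: Mapping[int, Tuple[np.ndarray, np.ndarray]],
        n_sim: int,
        n_batches: int,
    ) -> "VJSimulations":
        """Build directly from the vectorized simulation output."""
        if n_sim % n_batches:
            raise ValueError("n_sim must be divisible by n_batches")
        obj = cls.__new__(cls)
        obj.n_sim = n_sim
        obj.n_batches = n_batches
        obj.batch_size = n_sim // n_batches
        obj._mats = {
            L: (aa, ranks // obj.batch_size) for L, (aa, ranks) in groups.items()
        }
        return obj

    def ball_stats(self, cdr3_aa: str) -> Tuple[float, float, float]:
        """Return ``(ball_fraction, point_fraction, std_error_of_ball)``."""
        L = len(cdr3_aa)
        entry = self._mats.get(L)
        if entry is None:
            return 0.0, 0.0, 0.0
        mat, batch_ids = entry
        q = np.frombuffer(cdr3_aa.encode("ascii"), dtype=np.uint8)
        mism = (mat != q).sum(axis=1)
        in_ball = mism <= 1
        exact = mism == 0
        ball_frac = in_ball.sum() / self.n_sim
        point_frac = exact.sum() / self.n_sim
        per_batch = np.bincount(batch_ids[in_ball], minlength=self.n_batches) / self.batch_size
        if self.n_batches > 1:
            se = float(per_batch.std(ddof=1) / math.sqrt(self.n_batches))
        else:
            se = 0.0
        return float(ball_frac), float(point_frac), se


class SimulationCache:
    """Per-(V, J) simulation store shared across repertoires of one analysis."""

    def __init__(self, model: RecombinationModel, n_sim: int, n_batches: int, seed: int):
        self.model = model
        self.n_sim = n_sim
        self.n_batches = n_batches
        self.seed = seed
        self._store: Dict[Tuple[str, str], VJSimulations] = {}

    def get(self, v_gene: str, j_gene: str) -> VJSimulations:
        key = (v_gene, j_gene)
        if key not in self._store:
            # per-pair child seed keeps results independent of query order
            ss = np.random.SeedSequence(
                [self.seed, abs(hash(v_gene)) % 2**31, abs(hash(j_gene)) % 2**31]
            )
            rng = np.random.default_rng(ss)
            groups = _simulate_groups(self.model, v_gene, j_gene, self.n_sim, rng)
            self._store[key] = VJSimulations.from_groups(groups, self.n_sim, self.n_batches)
        return self._store[key]


def estimate_ball_pgen(
    model: RecombinationModel,
    cdr3_aa: str,
    v_gene: str,
    j_gene: str,
    n_sim: int,
    n_batches: int,
    seed: int,
) -> PgenEstimate:
    """Monte-Carlo ball Pgen of ``cdr3_aa`` conditional on the VJ pair.

    The ball is the set of same-length amino-acid sequences within Hamming
    distance 1 of the query, the query itself included.  The point estimate
    is the pooled fraction over ``n_batches`` equal batches; the standard
    error comes from the between-batch spread.
    """
    if n_sim < 1 or n_batches < 1:
        raise ValueError("n_sim and n_batches must be >= 1")
    batch = max(1, n_sim // n_batches)
    cache = SimulationCache(model, batch * n_batches, n_batches, seed)
    sims = cache.get(v_gene, j_gene)
    ball, _, se = sims.ball_stats(cdr3_aa)
    return PgenEstimate(point=ball, std_error=se, n_sim=sims.n_sim, n_batches=n_batches)


def enumerate_rearrangements(
    model: RecombinationModel,
    v_gene: str,
    j_gene: str,
    max_events: int = 10_000_000,
) -> Tuple[Dict[str, float], float]:
    """Enumerate every rearrangement event for one VJ pair.

    Returns ``(aa_probs, rejection_mass)`` where ``aa_probs`` maps each
    productive CDR3 amino-acid sequence to its unconditional probability
    (given the VJ pair) and ``rejection_mass`` is the total probability of
    non-productive events; the two sum to 1.
    """
    if (v_gene, j_gene) not in model.vj_usage:
        raise ValueError(f"VJ pair ({v_gene!r}, {j_gene!r}) absent from model support")
    v_nt = model.v_segments[v_gene]
    j_nt = model.j_segments[j_gene]
    vdels = [(d, p) for d, p in enumerate(model.v_deletion_dist) if p > 0]
    jdels = [(d, p) for d, p in enumerate(model.j_deletion_dist) if p > 0]
    ilens = [(l, p) for l, p in enumerate(model.insertion_length_dist) if p > 0]
    n_events = len(vdels) * len(jdels) * sum(4**l for l, _ in ilens)
    if n_events > max_events:
        raise CapacityError(f"enumeration of {n_events} events exceeds cap {max_events}")

    base_p = {b: model.insertion_base_probs[i] for i, b in enumerate(_BASES)}
    aa_probs: Dict[str, float] = defaultdict(float)
    reject = 0.0
    for ins_len, p_len in ilens:
        for ins in itertools.product(_BASES, repeat=ins_len):
            p_ins = p_len * math.prod(base_p[b] for b in ins)
            if p_ins == 0.0:
                continue
            ins_s = "".join(ins)
            for vd, p_v in vdels:
                left = v_nt[: len(v_nt) - vd]
                for jd, p_j in jdels:
                    p = p_ins * p_v * p_j
                    nt = left + ins_s + j_nt[jd:]
                    aa = _translate(nt)
                    if aa is not None and _is_productive(aa):
                        aa_probs[aa] += p
                    else:
                        reject += p
    return dict(aa_probs), reject


def exact_ball_pgen(
    model: RecombinationModel, cdr3_aa: str, v_gene: str, j_gene: str
) -> float:
    """Exhaustive-enumeration ball Pgen, conditional on VJ pair and productivity."""
    aa_probs, _ = enumerate_rearrangements(model, v_gene, j_gene)
    productive_mass = sum(aa_probs.values())
    if productive_mass == 0.0:
        return 0.0
    L = len(cdr3_aa)
    ball = sum(
        p
        for s, p in aa_probs.items()
        if len(s) == L and sum(a != b for a, b in zip(s, cdr3_aa)) <= 1
    )
    return ball / productive_mass


# -- synthetic-data generators -------------------------------------------


def _draw_counts(
    rng: np.random.Generator, n: int, count_law: Tuple[str, float]
) -> np.ndarray:
    """Clone-size law with support on counts >= 2."""
    law, param = count_law
    if law == "geometric":
        return 1 + rng.geometric(param, size=n)
    if law == "power_law":
        return 1 + rng.zipf(param, size=n)
    raise ValueError(f"unknown count law {law!r}")


def generate_null_repertoire(
    model: RecombinationModel,
    n_clonotypes: int,
    count_law: Tuple[str, float] = ("geometric", 0.5),
    seed: int = 0,
    sample_id: str = "null",
) -> Repertoire:
    """Draw ``n_clonotypes`` distinct productive clonotypes from the model."""
    if n_clonotypes < 1:
        raise ValueError("n_clonotypes must be >= 1")
    rng = np.random.default_rng(seed)
    seen: Dict[Tuple[str, str, str], str] = {}
    attempts = 0
    while len(seen) < n_clonotypes:
        batch = _sample_batch(model, rng, max(4 * (n_clonotypes - len(seen)), 256))
        for v, j, nt, aa in batch:
            key = (aa, v, j)
            if key not in seen:
                seen[key] = nt
                if len(seen) == n_clonotypes:
                    break
        attempts += 1
        if attempts > 2000:
            raise CapacityError(
                f"model support appears smaller than n_clonotypes={n_clonotypes}"
            )
    counts = _draw_counts(rng, n_clonotypes, count_law)
    clonotypes = [
        Clonotype(cdr3_aa=aa, v_gene=v, j_gene=j, count=int(c), freq=0.0, cdr3_nt=nt)
        for ((aa, v, j), nt), c in zip(seen.items(), counts)
    ]
    return Repertoire(sample_id, clonotypes).renormalized()


_CENTRAL_LO = 4  # first central CDR3 position, 1-based
_CENTRAL_HI_OFFSET = 3  # last central position is L - 3


def _central_positions(L: int) -> range:
    """0-based central positions (1-based 4 .. L-3)."""
    return range(_CENTRAL_LO - 1, L - _CENTRAL_HI_OFFSET)


def plant_convergent_cluster(
    rep: Repertoire,
    model: RecombinationModel,
    cluster_size: int,
    target_freq: float,
    seed: int,
    cluster_id: str = "cluster1",
    specificity: Optional[str] = None,
    n_candidates: int = 60,
    pgen_n_sim: int = 4000,
) -> Tuple[Repertoire, Dict[str, dict]]:
    """Plant a star-shaped convergent cluster around a low-Pgen seed CDR3.

    The planted set is the seed plus ``cluster_size - 1`` single-substitution
    variants at distinct central positions, all sharing the seed's (V, J).
    Member frequencies sum to ``target_freq`` exactly (integer count scaling
    via rational arithmetic).  Returns the new repertoire and truth labels
    keyed by ``"cdr3|v|j"``.
    """
    if cluster_size < 2:
        raise ValueError("cluster_size must be >= 2")
    if not (0 < target_freq < 1):
        raise ValueError("target_freq must be in (0, 1)")
    rng = np.random.default_rng(seed)

    # candidate seeds: distinct productive draws, long enough for the variants
    candidates: List[Tuple[str, str, str, str]] = []
    seen = set()
    guard = 0
    while len(candidates) < n_candidates:
        for v, j, nt, aa in _sample_batch(model, rng, 4 * n_candidates):
            if aa in seen:
                continue
            seen.add(aa)
            if (cluster_size - 1) <= len(_central_positions(len(aa))) * 19:
                candidates.append((v, j, nt, aa))
        guard += 1
        if guard > 500:
            raise ValueError(
                f"cluster_size {cluster_size} exceeds available central positions x 19"
            )

    # rank candidates by ball Pgen, keep the bottom decile
    cache: Dict[Tuple[str, str], VJSimulations] = {}
    pgens = []
    for v, j, nt, aa in candidates:
        if (v, j) not in cache:
            sub = np.random.default_rng(rng.integers(2**63))
            cache[(v, j)] = VJSimulations(
                simulate_productive(model, v, j, pgen_n_sim, sub), n_batches=1
            )
        ball, _, _ = cache[(v, j)].ball_stats(aa)
        pgens.append(ball)
    order = np.lexsort((np.arange(len(pgens)), np.asarray(pgens)))
    n_keep = max(1, len(candidates) // 10)
    v, j, seed_nt, seed_aa = candidates[order[int(rng.integers(n_keep))]]

    positions = list(_central_positions(len(seed_aa)))
    if cluster_size - 1 > len(positions) * 19:
        raise ValueError(
            f"cluster_size {cluster_size} exceeds available central positions x 19"
        )
    existing = set(c.key for c in rep.clonotypes)
    members = [seed_aa]
    rng.shuffle(positions)
    for pos in itertools.islice(itertools.cycle(positions), len(positions) * 19):
        if len(members) == cluster_size:
            break
        for res in rng.permutation(_AA_LIST):
            variant = seed_aa[:pos] + str(res) + seed_aa[pos + 1 :]
            if variant == seed_aa or variant in members or (variant, v, j) in existing:
                continue
            members.append(variant)
            break
    if len(members) < cluster_size:
        raise ValueError(
            f"could not place {cluster_size} variants without key collisions"
        )

    # exact frequency planting: scale existing counts so planted counts are
    # integers >= 2 and sum of planted freqs equals target_freq exactly
    frac = Fraction(target_freq).limit_denominator(10**6)
    k = cluster_size
    total0 = rep.total_reads
    per_member = frac / (k * (1 - frac))  # planted count = per_member * scaled total
    a, b = per_member.numerator, per_member.denominator
    s = b // math.gcd(b, total0 * a) if total0 else b
    c_planted = total0 * s * a // b
    if c_planted < 2:
        boost = -(-2 * b // max(total0 * s * a, 1))  # ceil
        s *= boost
        c_planted = total0 * s * a // b
    if s > 10**6:
        raise ValueError(f"target_freq {target_freq} requires impractical count scaling")

    scaled = [c.count * s for c in rep.clonotypes] + [int(c_planted)] * cluster_size
    g = math.gcd(*scaled) if scaled else 1
    if g > 1 and c_planted // g < 2:
        g = 1
    clonotypes = [replace(c, count=c.count * s // g) for c in rep.clonotypes]
    c_planted //= g
    truth: Dict[str, dict] = {}
    for aa in members:
        clonotypes.append(
            Clonotype(cdr3_aa=aa, v_gene=v, j_gene=j, count=int(c_planted), freq=0.0)
        )
        truth["|".join((aa, v, j))] = {
            "planted_cluster_id": cluster_id,
            "specificity": specificity,
            "is_seed": aa == seed_aa,
        }
    out = Repertoire(rep.sample_id, clonotypes, dict(rep.metadata)).renormalized()
    return out, truth


def generate_study(
    model: RecombinationModel,
    design: Optional[dict] = None,
    seed: int = 0,
) -> SyntheticStudy:
    """Generate a full synthetic study: bulk, DP/non-DP subsets, replicates.

    Design keys (with defaults): ``n_background`` 800, ``n_dp_background``
    300, ``n_nondp_background`` 600, ``n_clusters`` 2, ``cluster_size`` 10,
    ``cluster_freq`` 0.02, ``enrichment`` 10.0, ``n_replicates`` 6,
    ``n_matrix_rows`` 400, ``n_expanded`` 20, ``dp_expanded_fraction`` 0.6,
    ``log2fc`` 3.0, ``dispersion`` 0.1, ``mean_depth`` 50.0,
    ``conditions`` ("IL2high", "IL21combo").

    The DP subset carries the same planted clusters as non-DP at
    ``enrichment`` times the frequency, over a smaller background (sorted
    double-positive cells are less diverse and more clonal); a
    ``dp_expanded_fraction`` share of the truly expanded clonotypes is drawn
    from planted cluster members so expansion calls overlap the DP subset.
    """
    import pandas as pd

    d = {
        "n_background": 800,
        "n_dp_background": 300,
        "n_nondp_background": 600,
        "n_clusters": 2,
        "cluster_size": 10,
        "cluster_freq": 0.02,
        "enrichment": 10.0,
        "n_replicates": 6,
        "n_matrix_rows": 400,
        "n_expanded": 20,
        "dp_expanded_fraction": 0.6,
        "log2fc": 3.0,
        "dispersion": 0.1,
        "mean_depth": 50.0,
        "conditions": ("IL2high", "IL21combo"),
    }
    d.update(design or {})
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(8)]
    antigens = ["MelanA", "NYESO1", "gp100", "MAGEA3"]

    truth: Dict[str, dict] = {}

    bulk = generate_null_repertoire(
        model, d["n_background"], seed=seeds[0], sample_id="FFT"
    )
    bulk.metadata.update(subset="FFT")
    nondp = generate_null_repertoire(
        model, d["n_nondp_background"], seed=seeds[1], sample_id="nonDP"
    )
    nondp.metadata.update(subset="non-DP")
    dp = generate_null_repertoire(
        model, d["n_dp_background"], seed=seeds[2], sample_id="DP"
    )
    dp.metadata.update(subset="DP")

    f = d["cluster_freq"]
    f_dp = min(f * d["enrichment"], 0.5)
    for ci in range(d["n_clusters"]):
        antigen = antigens[ci % len(antigens)]
        cid = f"planted{ci + 1}"
        plant_seed = seeds[3] + ci
        bulk, t_bulk = plant_convergent_cluster(
            bulk, model, d["cluster_size"], f, plant_seed, cluster_id=cid, specificity=antigen
        )
        nondp, t_non = plant_convergent_cluster(
            nondp, model, d["cluster_size"], f, plant_seed, cluster_id=cid, specificity=antigen
        )
        dp, t_dp = plant_convergent_cluster(
            dp, model, d["cluster_size"], f_dp, plant_seed, cluster_id=cid, specificity=antigen
        )
        for t in (t_bulk, t_non, t_dp):
            truth.update(t)

    # replicate count matrices: planted cluster members first, then background
    rng = np.random.default_rng(seeds[4])
    planted_keys = {k for k, t in truth.items() if t.get("planted_cluster_id")}
    planted_rows = [c for c in bulk.clonotypes if "|".join(c.key) in planted_keys]
    background_rows = [c for c in bulk.clonotypes if "|".join(c.key) not in planted_keys]
    rows = planted_rows + background_rows[: max(0, d["n_matrix_rows"] - len(planted_rows))]
    row_keys = ["|".join(c.key) for c in rows]
    base_freq = np.array([c.freq for c in rows])
    base_freq = base_freq / base_freq.sum()
    mean_counts = base_freq * len(rows) * d["mean_depth"]

    n_from_planted = min(
        int(round(d["dp_expanded_fraction"] * d["n_expanded"])), len(planted_rows)
    )
    expanded_idx = np.concatenate(
        [
            rng.choice(len(planted_rows), size=n_from_planted, replace=False),
            len(planted_rows)
            + rng.choice(
                len(rows) - len(planted_rows),
                size=d["n_expanded"] - n_from_planted,
                replace=False,
            ),
        ]
    )
    lfc = np.zeros(len(rows))
    lfc[expanded_idx] = d["log2fc"]
    cond_a, cond_b = d["conditions"]

    phi = d["dispersion"]
    cols = {}
    design_map = {}
    for r in range(d["n_replicates"]):
        for cond, mult in ((cond_a, 1.0), (cond_b, 2.0 ** lfc)):
            mu = np.maximum(mean_counts * mult, 1e-9)
            if phi > 0:
                size = 1.0 / phi
                counts = rng.negative_binomial(size, size / (size + mu))
            else:
                counts = rng.poisson(mu)
            sample = f"{cond}_r{r + 1}"
            cols[sample] = counts.astype(np.int64)
            design_map[sample] = cond
    counts_df = pd.DataFrame(cols, index=row_keys)

    for i in expanded_idx:
        entry = truth.setdefault(row_keys[i], {})
        entry["true_log2fc"] = {cond_b: float(d["log2fc"])}

    return SyntheticStudy(
        repertoires={"FFT": bulk, "DP": dp, "nonDP": nondp},
        counts=counts_df,
        design=design_map,
        truth=truth,
    )


# -- packaged models -----------------------------------------------------


def toy_model() -> RecombinationModel:
    """Four-event enumerable toy: emits CASSGFF, CASSFF, CASGFF, CASFF at 1/4 each."""
    return RecombinationModel(
        v_segments={"TRBV1": "TGTGCCAGCAGT"},  # CASS
        j_segments={"TRBJ1": "GGTTTTTTC"},  # GFF
        v_deletion_dist=[0.5, 0.0, 0.0, 0.5],
        j_deletion_dist=[0.5, 0.0, 0.0, 0.5],
        insertion_length_dist=[1.0],
        insertion_base_probs=[0.25, 0.25, 0.25, 0.25],
        vj_usage={("TRBV1", "TRBJ1"): 1.0},
    )


def toy_insertion_model() -> RecombinationModel:
    """Toy with a random inserted codon: CAS + {0,1 aa} + FF."""
    return RecombinationModel(
        v_segments={"TRBV1": "TGTGCCAGC"},  # CAS
        j_segments={"TRBJ1": "TTTTTC"},  # FF
        v_deletion_dist=[1.0],
        j_deletion_dist=[1.0],
        insertion_length_dist=[0.5, 0.0, 0.0, 0.5],
        insertion_base_probs=[0.25, 0.25, 0.25, 0.25],
        vj_usage={("TRBV1", "TRBJ1"): 1.0},
    )


def human_like_model(n_v: int = 48, n_j: int = 13) -> RecombinationModel:
    """Deterministic human-like fixture: 48 V / 13 J labels, geometric
    deletions (mean ~4 nt), inserts of 0-20 nt."""
    rng = np.random.default_rng(20220404)
    codons = sorted(c for c, aa in CODON_TO_AA.items() if aa != "*")

    v_segments = {}
    for i in range(n_v):
        body = "".join(codons[k] for k in rng.integers(len(codons), size=3))
        v_segments[f"TRBV{i + 1}"] = "TGTGCCAGC" + body  # CAS + 3 random aa
    j_segments = {}
    for i in range(n_j):
        body = "".join(codons[k] for k in rng.integers(len(codons), size=3))
        end = "TTC" if i % 2 == 0 else "TGG"  # F or W anchor
        j_segments[f"TRBJ{i + 1}"] = body + "GGGACC" + end

    p_del = 0.2  # geometric with mean ~4 nt
    dels = p_del * (1 - p_del) ** np.arange(10)
    dels = dels / dels.sum()
    p_ins = 0.22
    ins = p_ins * (1 - p_ins) ** np.arange(21)
    ins = ins / ins.sum()

    raw = rng.dirichlet(np.full(n_v * n_j, 0.6))
    usage = {}
    pairs = [(f"TRBV{i + 1}", f"TRBJ{j + 1}") for i in range(n_v) for j in range(n_j)]
    for pair, p in zip(pairs, raw):
        usage[pair] = float(p)
    return RecombinationModel(
        v_segments=v_segments,
        j_segments=j_segments,
        v_deletion_dist=dels,
        j_deletion_dist=dels,
        insertion_length_dist=ins,
        insertion_base_probs=[0.22, 0.28, 0.28, 0.22],
        vj_usage=usage,
    )
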