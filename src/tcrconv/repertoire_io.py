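"""Read, write, and pre-process clonotype tables.

The on-disk dialect is a VDJtools-style tab-separated table with header
``count freq cdr3nt cdr3aa v d j``.  An absent D segment (or absent CDR3
nucleotide sequence) is written as ``.``.  Clonotype identity throughout the
package is the triple ``(cdr3_aa, v_gene, j_gene)`` with allele suffixes
stripped from the gene labels; the nucleotide sequence is carried but never
used as part of the key.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

__all__ = [
    "AA_ALPHABET",
    "Clonotype",
    "Repertoire",
    "RepertoireFormatError",
    "translate_nt",
    "strip_allele",
    "read_repertoire",
    "write_repertoire",
    "remove_singletons",
    "downsample",
    "pool",
]

#: The 20 standard amino acids.
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
#: Codon -> amino acid map (stop codons map to ``*``).
CODON_TO_AA = dict(_STANDARD_TABLE.forward_table)
CODON_TO_AA.update({codon: "*" for codon in _STANDARD_TABLE.stop_codons})

#: Fixed column order of the dialect.
COLUMNS = ("count", "freq", "cdr3nt", "cdr3aa", "v", "d", "j")
_REQUIRED = ("count", "cdr3aa", "v", "j")

ClonotypeKey = Tuple[str, str, str]


class RepertoireFormatError(ValueError):
    """Raised when a clonotype table violates the dialect contract."""


def translate_nt(nt: str) -> str:
    """Translate an in-frame nucleotide string; stop codons become ``*``."""
    if len(nt) % 3 != 0:
        raise ValueError(f"nucleotide length {len(nt)} not divisible by 3")
    return "".join(CODON_TO_AA[nt[i : i + 3]] for i in range(0, len(nt), 3))


def strip_allele(gene: str) -> str:
    """Drop the ``*NN`` allele suffix: ``TRBV20-1*01`` -> ``TRBV20-1``."""
    return gene.split("*", 1)[0]


@dataclass(frozen=True)
class Clonotype:
    """A single TCRbeta clonotype: CDR3 amino-acid sequence with V/J call.

    ``freq`` is the fraction of the parent repertoire; it is maintained by
    the repertoire-level operations rather than by the clonotype itself.
    """

    cdr3_aa: str
    v_gene: str
    j_gene: str
    count: int
    freq: float
    cdr3_nt: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.cdr3_aa:
            raise ValueError("cdr3_aa must be non-empty")
        bad = set(self.cdr3_aa) - AA_ALPHABET
        if bad:
            raise ValueError(f"cdr3_aa contains invalid symbols: {sorted(bad)}")
        if int(self.count) != self.count or self.count < 0:
            raise ValueError(f"count must be a non-negative integer, got {self.count!r}")
        if self.freq < 0:
            raise ValueError(f"freq must be >= 0, got {self.freq!r}")
        if self.cdr3_nt is not None and translate_nt(self.cdr3_nt) != self.cdr3_aa:
            raise ValueError(
                f"cdr3_nt {self.cdr3_nt!r} does not translate to cdr3_aa {self.cdr3_aa!r}"
            )
        object.__setattr__(self, "v_gene", strip_allele(self.v_gene))
        object.__setattr__(self, "j_gene", strip_allele(self.j_gene))
        object.__setattr__(self, "count", int(self.count))

    @property
    def key(self) -> ClonotypeKey:
        return (self.cdr3_aa, self.v_gene, self.j_gene)


@dataclass
class Repertoire:
    """One sample's clonotype list plus free-form metadata."""

    sample_id: str
    clonotypes: list[Clonotype] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def total_reads(self) -> int:
        return sum(c.count for c in self.clonotypes)

    def __len__(self) -> int:
        return len(self.clonotypes)

    def keys(self) -> list[ClonotypeKey]:
        return [c.key for c in self.clonotypes]

    def renormalized(self) -> "Repertoire":
        """Return a copy with ``freq`` recomputed as ``count / total_reads``."""
        total = self.total_reads
        clonotypes = [
            replace(c, freq=(c.count / total if total else 0.0)) for c in self.clonotypes
        ]
        return Repertoire(self.sample_id, clonotypes, dict(self.metadata))

    def aggregated(self) -> "Repertoire":
        """Merge duplicate keys (counts summed) and renormalize frequencies."""
        return pool([self], sample_id=self.sample_id, metadata=dict(self.metadata))


def read_repertoire(path, dialect: str = "vdjtools") -> Repertoire:
    """Read one clonotype table.

    Frequencies are recomputed from counts when the column is absent or
    inconsistent with counts beyond 1e-6.  Missing required columns and
    non-integer counts raise :class:`RepertoireFormatError`.
    """
    if dialect != "vdjtools":
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in _REQUIRED:
        if col not in df.columns:
            raise RepertoireFormatError(f"missing required column {col!r} in {path}")

    counts = np.empty(len(df), dtype=np.int64)
    for i, raw in enumerate(df["count"]):
        try:
            counts[i] = int(raw)
        except (TypeError, ValueError):
            raise RepertoireFormatError(
                f"non-integer count {raw!r} at data row {i + 1} of {path}"
            ) from None
    total = int(counts.sum())

    freqs = None
    if "freq" in df.columns and len(df):
        try:
            freqs = df["freq"].astype(float).to_numpy()
        except ValueError:
            freqs = None
    expected = counts / total if total else np.zeros(len(df))
    if freqs is None or np.any(np.abs(freqs - expected) > 1e-6):
        freqs = expected

    clonotypes = []
    for i in range(len(df)):
        nt = df["cdr3nt"].iloc[i] if "cdr3nt" in df.columns else "."
        clonotypes.append(
            Clonotype(
                cdr3_aa=df["cdr3aa"].iloc[i],
                v_gene=df["v"].iloc[i],
                j_gene=df["j"].iloc[i],
                count=int(counts[i]),
                freq=float(freqs[i]),
                cdr3_nt=None if nt in (".", "") else nt,
            )
        )
    return Repertoire(sample_id=path.stem, clonotypes=clonotypes)


def write_repertoire(rep: Repertoire, path) -> None:
    """Write a clonotype table in the package dialect (9 significant digits)."""
    path = Path(path)
    lines = ["\t".join(COLUMNS)]
    for c in rep.clonotypes:
        lines.append(
            "\t".join(
                (
                    str(c.count),
                    format(c.freq, ".9g"),
                    c.cdr3_nt if c.cdr3_nt is not None else ".",
                    c.cdr3_aa,
                    c.v_gene,
                    ".",
                    c.j_gene,
                )
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def remove_singletons(rep: Repertoire) -> Repertoire:
    """Drop clonotypes with ``count <= 1`` and renormalize the survivors."""
    survivors = [c for c in rep.clonotypes if c.count > 1]
    out = Repertoire(rep.sample_id, survivors, dict(rep.metadata))
    return out.renormalized()


def downsample(rep: Repertoire, n_reads: int, seed: int) -> Repertoire:
    """Sample ``n_reads`` reads without replacement (multivariate hypergeometric)."""
    total = rep.total_reads
    if n_reads > total:
        raise ValueError(f"n_reads={n_reads} exceeds total reads {total}")
    rng = np.random.default_rng(seed)
    counts = np.array([c.count for c in rep.clonotypes], dtype=np.int64)
    sampled = rng.multivariate_hypergeometric(counts, n_reads)
    clonotypes = [
        replace(c, count=int(k), freq=0.0)
        for c, k in zip(rep.clonotypes, sampled)
        if k > 0
    ]
    out = Repertoire(rep.sample_id, clonotypes, dict(rep.metadata))
    return out.renormalized()


def pool(
    reps: Sequence[Repertoire],
    sample_id: str = "pooled",
    metadata: Optional[Mapping] = None,
) -> Repertoire:
    """Merge repertoires on the clonotype key, summing counts."""
    if not reps:
        raise ValueError("pool requires at least one repertoire")
    merged: dict[ClonotypeKey, Clonotype] = {}
    for rep in reps:
        for c in rep.clonotypes:
            prev = merged.get(c.key)
            if prev is None:
                merged[c.key] = c
            else:
                nt = prev.cdr3_nt if prev.cdr3_nt is not None else c.cdr3_nt
                merged[c.key] = replace(prev, count=prev.count + c.count, cdr3_nt=nt)
    out = Repertoire(sample_id, list(merged.values()), dict(metadata or {}))
    return out.renormalized()
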