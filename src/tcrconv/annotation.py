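"""Specificity annotation against a TCR database and cluster propagation.

A database record matches a query clonotype when the CDR3s are identical,
or differ by exactly one substitution at a central position (1-based
positions 4 .. L-3) between residues of the same physicochemical group, and
— when the patient's HLA alleles are known — the record's HLA restriction is
compatible with one of them.  V/J gene agreement is reported but not
required.  Clusters whose matched members predominantly share one antigen
inherit that antigen as a whole.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set

import pandas as pd

from .repertoire_io import AA_ALPHABET, Clonotype, ClonotypeKey, Repertoire, strip_allele

__all__ = [
    "AA_GROUPS",
    "SpecificityRecord",
    "MatchResult",
    "aa_group",
    "match_clonotype",
    "propagate_cluster_specificity",
    "cumulative_specific_frequency",
    "read_specificity_db",
    "write_specificity_db",
]

#: Physicochemical groups used for the central-substitution rule.  The group
#: names follow the usual R-property classification; membership is the
#: package's declared convention and can be overridden per call.
AA_GROUPS: Dict[str, str] = {}
for _grp, _members in {
    "aliphatic": "GAVLIPM",
    "aromatic": "FWY",
    "polar": "STCNQ",
    "positive": "KRH",
    "negative": "DE",
}.items():
    for _aa in _members:
        AA_GROUPS[_aa] = _grp


@dataclass(frozen=True)
class SpecificityRecord:
    """One database row: a TCR with known epitope specificity."""

    cdr3_aa: str
    v_gene: str
    j_gene: str
    epitope: str
    antigen: str
    hla_restriction: str


@dataclass(frozen=True)
class MatchResult:
    query_key: ClonotypeKey
    record: SpecificityRecord
    match_type: str  # "exact" | "central_substitution"
    hla_pass: bool
    v_match: bool
    j_match: bool


def aa_group(residue: str, groups: Optional[Mapping[str, str]] = None) -> str:
    """Physicochemical group of one amino-acid letter."""
    table = groups or AA_GROUPS
    if residue not in AA_ALPHABET:
        raise ValueError(f"not a standard amino acid: {residue!r}")
    return table[residue]


def _hla_compatible(record_allele: str, patient_alleles: Sequence[str]) -> bool:
    """Gene-level records (``A*02``) match any patient allele of the group;
    four-digit records (``A*02:01``) require four-digit equality."""
    r = record_allele.strip()
    if not r:
        return False
    for a in patient_alleles:
        a = a.strip()
        if ":" in r:
            if a == r:
                return True
        else:
            if a == r or a.split(":")[0] == r:
                return True
    return False


def _cdr3_match(query: str, ref: str, central_lo: int, central_hi_offset: int,
                groups: Optional[Mapping[str, str]]) -> Optional[str]:
    """Return the match type for a CDR3 pair, or None."""
    if len(query) != len(ref):
        return None
    if query == ref:
        return "exact"
    mismatches = [i for i, (a, b) in enumerate(zip(query, ref)) if a != b]
    if len(mismatches) != 1:
        return None
    pos = mismatches[0]  # 0-based
    L = len(query)
    if not (central_lo - 1 <= pos <= L - 1 - central_hi_offset):
        return None
    if aa_group(query[pos], groups) != aa_group(ref[pos], groups):
        return None
    return "central_substitution"


def match_clonotype(
    query: Clonotype,
    db: Sequence[SpecificityRecord],
    patient_hla: Optional[Sequence[str]] = None,
    central_lo: int = 4,
    central_hi_offset: int = 3,
    groups: Optional[Mapping[str, str]] = None,
) -> List[MatchResult]:
    """All database records matching one query clonotype."""
    if not db:
        raise ValueError("specificity database is empty")
    results = []
    for rec in db:
        mtype = _cdr3_match(query.cdr3_aa, rec.cdr3_aa, central_lo, central_hi_offset, groups)
        if mtype is None:
            continue
        if patient_hla is not None:
            hla_pass = _hla_compatible(rec.hla_restriction, patient_hla)
            if not hla_pass:
                continue
        else:
            hla_pass = True
        results.append(
            MatchResult(
                query_key=query.key,
                record=rec,
                match_type=mtype,
                hla_pass=hla_pass,
                v_match=strip_allele(rec.v_gene) == query.v_gene,
                j_match=strip_allele(rec.j_gene) == query.j_gene,
            )
        )
    return results


def propagate_cluster_specificity(
    cluster_members: Sequence[ClonotypeKey],
    matches: Mapping[ClonotypeKey, Sequence[MatchResult]],
    majority_threshold: float = 0.5,
) -> str:
    """Cluster-level antigen label by strict majority of matched members.

    Among members with at least one match, if a single antigen is shared by
    a fraction strictly greater than ``majority_threshold`` and no other
    antigen ties it, that antigen labels the whole cluster (matched and
    unmatched members alike); otherwise the cluster is ``"unassigned"``.
    """
    member_antigens: List[Set[str]] = []
    for key in cluster_members:
        hits = matches.get(tuple(key), ())
        antigens = {m.record.antigen for m in hits}
        if antigens:
            member_antigens.append(antigens)
    if not member_antigens:
        return "unassigned"
    counts = Counter()
    for antigens in member_antigens:
        for a in antigens:
            counts[a] += 1
    n_matched = len(member_antigens)
    best_count = max(counts.values())
    best = [a for a, c in counts.items() if c == best_count]
    if len(best) > 1 or best_count / n_matched <= majority_threshold:
        return "unassigned"
    return best[0]


def cumulative_specific_frequency(
    rep: Repertoire,
    labeled_keys: Set[ClonotypeKey],
    scope: str = "bulk",
    cluster_keys: Optional[Set[ClonotypeKey]] = None,
) -> float:
    """Cumulative frequency of labeled clonotypes, as a proportion of the
    whole repertoire.

    ``scope="bulk"`` sums over every labeled clonotype; ``"cluster_related"``
    restricts the numerator to labeled clonotypes that are also cluster
    members (the denominator remains the full repertoire).
    """
    labeled = {tuple(k) for k in labeled_keys}
    if scope == "bulk":
        keep = labeled
    elif scope == "cluster_related":
        if cluster_keys is None:
            raise ValueError("cluster_related scope requires cluster_keys")
        keep = labeled & {tuple(k) for k in cluster_keys}
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return float(sum(c.freq for c in rep.clonotypes if c.key in keep))


_DB_COLUMNS = ("cdr3_aa", "v", "j", "epitope", "antigen", "hla")


def read_specificity_db(path) -> List[SpecificityRecord]:
    """Read a VDJdb-export-compatible TSV (cdr3_aa, v, j, epitope, antigen, hla)."""
    df = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in _DB_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"specificity database missing columns {missing}")
    return [
        SpecificityRecord(
            cdr3_aa=row.cdr3_aa,
            v_gene=row.v,
            j_gene=row.j,
            epitope=row.epitope,
            antigen=row.antigen,
            hla_restriction=row.hla,
        )
        for row in df.itertuples()
    ]


def write_specificity_db(records: Sequence[SpecificityRecord], path) -> None:
    lines = ["\t".join(_DB_COLUMNS)]
    for r in records:
        lines.append(
            "\t".join((r.cdr3_aa, r.v_gene, r.j_gene, r.epitope, r.antigen, r.hla_restriction))
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
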