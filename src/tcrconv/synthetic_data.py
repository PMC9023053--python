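"""Packaged synthetic study emulating the analysis's data shapes.

One call writes a study directory containing a bulk repertoire, DP/non-DP
sorted-subset repertoires with convergent-cluster enrichment in DP,
replicate count matrices across two culture conditions with planted
fold-changes, a small specificity database covering half of each planted
cluster, and a ground-truth JSON.  Everything is deterministic from the
seed; all files are plain text.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional

import pandas as pd

from .annotation import SpecificityRecord, write_specificity_db
from .generative_model import (
    RecombinationModel,
    SyntheticStudy,
    generate_study,
    human_like_model,
)
from .repertoire_io import write_repertoire

__all__ = ["make_paper_shaped_study", "DEFAULT_STUDY_DESIGN", "ANTIGEN_EPITOPES"]

#: Epitopes attached to synthetic database records, per antigen label.
ANTIGEN_EPITOPES = {
    "MelanA": "ELAGIGILTV",
    "NYESO1": "SLLMWITQC",
    "gp100": "KTWGQYWQV",
    "MAGEA3": "FLWGPRALV",
}

DEFAULT_STUDY_DESIGN = {
    "n_background": 2940,
    "n_dp_background": 300,
    "n_nondp_background": 600,
    "n_clusters": 3,
    "cluster_size": 10,
    "cluster_freq": 0.02,
    "enrichment": 10.0,
    "n_replicates": 6,
    "n_matrix_rows": 400,
    "n_expanded": 20,
    "log2fc": 3.0,
    "dispersion": 0.1,
    "mean_depth": 50.0,
    "conditions": ("IL2high", "IL21combo"),
}


def make_paper_shaped_study(
    seed: int,
    out_dir,
    model: Optional[RecombinationModel] = None,
    design: Optional[dict] = None,
) -> SyntheticStudy:
    """Generate the default synthetic study and write it to ``out_dir``.

    Files written: ``<sample>.txt`` clonotype tables (FFT, DP, nonDP),
    ``counts.tsv``, ``design.tsv``, ``specificity_db.tsv``, ``truth.json``,
    and ``model.yaml``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if model is None:
        model = human_like_model()
    merged = dict(DEFAULT_STUDY_DESIGN)
    merged.update(design or {})
    study = generate_study(model, merged, seed=seed)

    for name, rep in sorted(study.repertoires.items()):
        write_repertoire(rep, out / f"{name}.txt")

    counts = study.counts.copy()
    counts.index.name = "key"
    counts.to_csv(out / "counts.tsv", sep="\t")
    design_df = pd.DataFrame(
        sorted(study.design.items()), columns=["sample", "condition"]
    )
    design_df.to_csv(out / "design.tsv", sep="\t", index=False)

    # database records for half of each planted cluster (exercises
    # cluster-level propagation to the uncovered half)
    by_cluster: Dict[str, list] = {}
    for key, labels in sorted(study.truth.items()):
        cid = labels.get("planted_cluster_id")
        if cid is not None:
            by_cluster.setdefault(cid, []).append((key, labels))
    records = []
    for cid, members in sorted(by_cluster.items()):
        # one truth entry per key; members appear in several repertoires but
        # keys are unique within the truth map
        half = members[: max(1, len(members) // 2)]
        for key, labels in half:
            aa, v, j = key.split("|")
            antigen = labels.get("specificity") or "unknown"
            records.append(
                SpecificityRecord(
                    cdr3_aa=aa,
                    v_gene=v,
                    j_gene=j,
                    epitope=ANTIGEN_EPITOPES.get(antigen, "X" * 9),
                    antigen=antigen,
                    hla_restriction="A*02",
                )
            )
    write_specificity_db(records, out / "specificity_db.tsv")

    model.to_yaml(out / "model.yaml")
    (out / "truth.json").write_text(
        json.dumps(study.truth, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return study
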