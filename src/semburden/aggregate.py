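"""CpG-to-feature annotation and per-sample epimutation burden counts.

Feature sets (transcription-factor binding sites, pathways) arrive as GMT
files whose members are CpG probe ids; a companion two-column TSV maps CpGs
to genes, and a second GMT maps each TF to its target genes. Aggregation
turns a binary SEM call matrix into a samples x features count matrix: the
number of epimutated CpGs of each sample that fall inside each feature's
CpG set (set semantics — a CpG counts once per feature it belongs to).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureAnnotation",
    "load_annotation",
    "read_gmt",
    "write_gmt",
    "read_cpg2gene",
    "count_sems_by_feature",
]

TFBS = "TFBS"
PATHWAY = "PATHWAY"


@dataclass
class FeatureAnnotation:
    """CpG feature sets plus the CpG->gene and TF->target-gene maps.

    features
        feature id -> frozenset of CpG ids.
    kind
        feature id -> ``TFBS`` or ``PATHWAY``.
    cpg2gene
        partial map CpG id -> gene id (a CpG maps to at most one gene).
    tf_targets
        TF (feature) id -> frozenset of target gene ids.
    unknown_members
        GMT members not found in the declared CpG universe (kept, flagged).
    """

    features: dict = field(default_factory=dict)
    kind: dict = field(default_factory=dict)
    cpg2gene: dict = field(default_factory=dict)
    tf_targets: dict = field(default_factory=dict)
    unknown_members: set = field(default_factory=set)

    def feature_ids(self, kind: str | None = None) -> list[str]:
        if kind is None:
            return list(self.features)
        return [f for f in self.features if self.kind.get(f) == kind]

    def __post_init__(self) -> None:
        empty = [f for f, s in self.features.items() if not s]
        if empty:
            raise ValueError(f"empty feature sets are not allowed: {empty[:5]}")


def read_gmt(path) -> dict[str, frozenset]:
    """Parse a GMT file (name, description, members...) into feature sets.

    Duplicate members within a line are deduplicated with a warning;
    a line with fewer than three fields is malformed.
    """
    sets: dict[str, frozenset] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: malformed GMT line (needs >=3 fields)")
            name, _desc, *members = parts
            members = [m for m in members if m]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate feature {name!r}")
            if len(set(members)) < len(members):
                warnings.warn(f"GMT feature {name!r} has duplicate members; deduplicated")
            sets[name] = frozenset(members)
    return sets


def write_gmt(sets: dict, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


def read_cpg2gene(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("cpg2gene map needs two columns (cpg_id, gene_id)")
    cpg_col, gene_col = df.columns[:2]
    if df[cpg_col].duplicated().any():
        raise ValueError("a CpG may map to at most one gene")
    return dict(zip(df[cpg_col], df[gene_col]))


def load_annotation(
    cpg_map_path,
    feature_sets_path,
    kind: str = TFBS,
    cpg_universe=None,
    tf_targets_path=None,
) -> FeatureAnnotation:
    """Load a GMT of CpG feature sets plus the CpG->gene map.

    Members outside ``cpg_universe`` (when given) are retained but flagged in
    ``unknown_members``. When the feature sets are TF binding sites and no
    explicit TF->targets GMT is given, each TF's target set is derived from
    the genes of its member CpGs.
    """
    sets = read_gmt(feature_sets_path)
    cpg2gene = read_cpg2gene(cpg_map_path) if cpg_map_path is not None else {}
    unknown: set = set()
    if cpg_universe is not None:
        universe = set(cpg_universe)
        for members in sets.values():
            unknown |= members - universe
    tf_targets: dict = {}
    if tf_targets_path is not None:
        tf_targets = {tf: frozenset(g) for tf, g in read_gmt(tf_targets_path).items()}
    elif kind == TFBS and cpg2gene:
        tf_targets = {
            tf: frozenset(cpg2gene[c] for c in members if c in cpg2gene)
            for tf, members in sets.items()
        }
    return FeatureAnnotation(
        features=dict(sets),
        kind={f: kind for f in sets},
        cpg2gene=cpg2gene,
        tf_targets=tf_targets,
        unknown_members=unknown,
    )


def count_sems_by_feature(
    sems, ann: FeatureAnnotation, kind: str | None = None
) -> pd.DataFrame:
    """Per-sample SEM counts per feature (samples x features DataFrame).

    ``count[s, f]`` sums the binary SEM calls of sample ``s`` over the CpGs of
    feature ``f`` present in the call matrix. A CpG belonging to several
    features contributes once to each.
    """
    calls = sems.calls if hasattr(sems, "calls") else sems
    feature_ids = ann.feature_ids(kind)
    cpg_index = pd.Index(calls.index)
    data = {}
    arr = calls.to_numpy()
    for f in feature_ids:
        pos = cpg_index.get_indexer_for(sorted(ann.features[f] & set(cpg_index)))
        pos = pos[pos >= 0]
        data[f] = arr[pos].sum(axis=0) if len(pos) else np.zeros(arr.shape[1], dtype=arr.dtype)
    out = pd.DataFrame(data, index=calls.columns)
    out.index.name = "sample_id"
    return out.astype(int)
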