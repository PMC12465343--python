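"""From consensus TFBSs to an expression-filtered up/down gene signature.

Hub genes are genes targeted by many of the consensus-selected TFs;
candidates must be targeted by at least half of them. Candidates are then
filtered by two-group differential expression (Welch contrast, BH FDR within
the candidate list), split into up-/down-regulated lists, and exported in
the two-list + GMT form a connectivity-map query expects. Exported CMAP
result tables are filtered on FDR q, negative normalized connectivity score
and an allowed cell-line set; external validation effects are pooled with a
DerSimonian-Laird random-effects meta-analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .skato import bh_fdr

__all__ = [
    "hub_frequencies",
    "candidate_genes",
    "differential_expression",
    "meta_analyze",
    "Signature",
    "write_signature",
    "read_signature",
    "read_cmap_table",
    "filter_cmap",
    "DEFAULT_CMAP_CELL_LINES",
]

DEFAULT_CMAP_CELL_LINES = frozenset(
    {"JURKAT", "THP1", "K562", "HL60", "BJAB", "NALM6", "CD34"}
)

CMAP_REQUIRED_COLUMNS = ("cell_name", "normalized_score", "fdr_q")


def hub_frequencies(consensus_tfs, tf_targets: dict) -> pd.DataFrame:
    """Per gene: how many (and what fraction) of the consensus TFs target it.

    Genes targeted by no consensus TF are absent from the table.
    """
    consensus_tfs = list(consensus_tfs)
    if not consensus_tfs:
        raise ValueError("consensus TF list is empty")
    missing = [tf for tf in consensus_tfs if tf not in tf_targets]
    if missing:
        raise ValueError(f"no target set for TF(s): {missing[:5]}")
    counts: dict[str, int] = {}
    for tf in consensus_tfs:
        for g in tf_targets[tf]:
            counts[g] = counts.get(g, 0) + 1
    n = len(consensus_tfs)
    out = pd.DataFrame(
        {
            "gene_id": list(counts),
            "n_tfs_targeting": list(counts.values()),
        }
    )
    out["fraction"] = out["n_tfs_targeting"] / n
    return out.sort_values(
        ["n_tfs_targeting", "gene_id"], ascending=[False, True]
    ).reset_index(drop=True)


def candidate_genes(hub: pd.DataFrame, min_fraction: float = 0.5) -> list:
    """Genes targeted by at least ``min_fraction`` of the consensus TFs
    (inclusive boundary)."""
    keep = hub.loc[hub["fraction"] >= min_fraction]
    return keep["gene_id"].tolist()


def differential_expression(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    genes,
    q_max: float = 0.2,
    correct: bool = True,
) -> pd.DataFrame:
    """Two-group Welch contrast per candidate gene with BH FDR in-list.

    Effect is the NO_ID - ID mean difference on the analysis scale; BH
    adjustment runs within the candidate set only. ``correct=False`` flags
    significance on the raw p instead (the FDR column is still reported).
    """
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    samples = [s for s in meta.index if s in expr.columns]
    meta = meta.loc[samples]
    g_noid = meta.index[meta["group"] == "NO_ID"]
    g_id = meta.index[meta["group"] == "ID"]
    if len(g_noid) < 2 or len(g_id) < 2:
        raise ValueError("both groups need at least two samples")
    genes = list(genes)
    present = [g for g in genes if g in expr.index]
    absent = set(genes) - set(present)
    if absent:
        import warnings

        warnings.warn(f"{len(absent)} candidate gene(s) absent from expression matrix")
    if not present:
        raise ValueError("no candidate genes present in the expression matrix")
    a = expr.loc[present, g_noid].to_numpy(dtype=float)
    b = expr.loc[present, g_id].to_numpy(dtype=float)
    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    se = np.sqrt(v1 / n1 + v2 / n2)
    t = (m1 - m2) / se
    df = (v1 / n1 + v2 / n2) ** 2 / (
        (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
    )
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    out = pd.DataFrame(
        {
            "gene_id": present,
            "effect": m1 - m2,
            "se": se,
            "t": t,
            "p": p,
            "q": bh_fdr(p),
        }
    )
    out["direction"] = np.where(out["effect"] > 0, "up", "down")
    crit = out["q"] if correct else out["p"]
    out["significant"] = crit < q_max
    return out.sort_values("p").reset_index(drop=True)


def meta_analyze(
    per_study: pd.DataFrame, reference_direction: dict | None = None
) -> pd.DataFrame:
    """DerSimonian-Laird random-effects pooling of per-gene study effects.

    ``per_study`` has columns gene_id, study, effect, se (>= 2 studies per
    gene). Returns pooled effect, pooled SE, tau2, normal-approximation p and
    BH q per gene. ``reference_direction`` (gene -> "up"/"down", e.g. from a
    discovery signature) adds a ``consistent`` flag comparing the sign of the
    pooled effect with the discovery direction; magnitudes are not compared
    across platforms.
    """
    if (per_study["se"] <= 0).any():
        raise ValueError("standard errors must be positive")
    rows = []
    for gene, grp in per_study.groupby("gene_id", sort=True):
        y = grp["effect"].to_numpy(dtype=float)
        se = grp["se"].to_numpy(dtype=float)
        k = len(y)
        if k < 2:
            raise ValueError(f"gene {gene!r} has fewer than two studies")
        w = 1.0 / se**2
        fixed = np.sum(w * y) / np.sum(w)
        q_stat = np.sum(w * (y - fixed) ** 2)
        c = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (q_stat - (k - 1)) / c)
        w_re = 1.0 / (se**2 + tau2)
        pooled = np.sum(w_re * y) / np.sum(w_re)
        pooled_se = np.sqrt(1.0 / np.sum(w_re))
        z = pooled / pooled_se
        rows.append(
            {
                "gene_id": gene,
                "pooled_effect": pooled,
                "pooled_se": pooled_se,
                "tau2": tau2,
                "p": 2.0 * stats.norm.sf(abs(z)),
            }
        )
    out = pd.DataFrame(rows)
    out["p"] = np.clip(out["p"], np.finfo(float).tiny, 1.0)
    out["q"] = bh_fdr(out["p"].to_numpy())
    if reference_direction is not None:
        signs = np.where(out["pooled_effect"] > 0, "up", "down")
        out["consistent"] = [
            reference_direction.get(g) == s
            for g, s in zip(out["gene_id"], signs)
        ]
    return out


@dataclass(frozen=True)
class Signature:
    """Ordered up/down gene lists with provenance of how they were derived."""

    up: tuple
    down: tuple
    provenance: dict

    def __post_init__(self) -> None:
        overlap = set(self.up) & set(self.down)
        if overlap:
            raise ValueError(f"genes in both directions: {sorted(overlap)[:5]}")


def build_signature(de: pd.DataFrame, provenance: dict | None = None) -> Signature:
    sig = de.loc[de["significant"]]
    if sig.empty:
        raise ValueError("no significant genes; signature would be empty")
    up = sig.loc[sig["direction"] == "up"].sort_values(
        "effect", key=np.abs, ascending=False
    )["gene_id"]
    down = sig.loc[sig["direction"] == "down"].sort_values(
        "effect", key=np.abs, ascending=False
    )["gene_id"]
    return Signature(up=tuple(up), down=tuple(down), provenance=provenance or {})


def write_signature(sig_or_de, out_dir, provenance: dict | None = None) -> Signature:
    """Write up.txt / down.txt (one symbol per line) and signature.gmt.

    Accepts either a DE result table (significant rows are used, ordered by
    absolute effect) or a ready :class:`Signature`.
    """
    from pathlib import Path

    sig = (
        sig_or_de
        if isinstance(sig_or_de, Signature)
        else build_signature(sig_or_de, provenance)
    )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "up.txt").write_text("\n".join(sig.up) + "\n")
    (out / "down.txt").write_text("\n".join(sig.down) + "\n")
    with open(out / "signature.gmt", "w") as fh:
        fh.write("\t".join(["signature_up", "na", *sig.up]) + "\n")
        fh.write("\t".join(["signature_down", "na", *sig.down]) + "\n")
    return sig


def read_signature(out_dir) -> Signature:
    from pathlib import Path

    out = Path(out_dir)
    up = tuple(out.joinpath("up.txt").read_text().split())
    down = tuple(out.joinpath("down.txt").read_text().split())
    return Signature(up=up, down=down, provenance={})


def read_cmap_table(path) -> pd.DataFrame:
    """Read a connectivity-map result TSV (one row per compound/cell line)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CMAP_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"CMAP table is missing columns: {missing}")
    return df


def filter_cmap(
    rows: pd.DataFrame,
    q_max: float = 0.05,
    cell_lines=DEFAULT_CMAP_CELL_LINES,
) -> pd.DataFrame:
    """Keep rows with FDR q < q_max, negative normalized connectivity score
    and a cell line in the allowed set."""
    missing = [c for c in CMAP_REQUIRED_COLUMNS if c not in rows.columns]
    if missing:
        raise ValueError(f"CMAP table is missing columns: {missing}")
    keep = (
        (rows["fdr_q"] < q_max)
        & (rows["normalized_score"] < 0)
        & rows["cell_name"].isin(set(cell_lines))
    )
    return rows.loc[keep].reset_index(drop=True)
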