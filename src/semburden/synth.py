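"""Synthetic methylome + expression cohorts with known epimutation ground truth.

The generator emulates the discovery study's structure: two patient groups
(ID = sustained inactive disease, NO_ID = reactivated), beta-value
methylation at two timepoints (T0 = therapy withdrawal, Tend = eight months
later), a bimodal per-CpG methylome, rare stochastic outliers ("SEMs")
injected at a low base rate everywhere and at an elevated rate for NO_ID
samples inside a designated set of enriched TF-binding-site features, and a
log-scale expression matrix whose true differentially expressed genes sit
downstream of the enriched features. Every draw is deterministic given the
config seed; independent substreams keep each operation reproducible on its
own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aggregate import PATHWAY, TFBS, FeatureAnnotation

__all__ = ["SimConfig", "SimTruth", "simulate_annotation", "simulate_methylome",
           "simulate_expression", "simulate_dataset"]


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the synthetic cohort.

    Group sizes, ages and sex balance follow the discovery cohort (30 ID vs
    14 NO_ID; ID age 9.91 (3.55) years, NO_ID 13.42 (3.69); ~70% female in
    both groups). ``base_sem_rate`` is the per-CpG per-sample outlier
    probability; NO_ID samples get ``base_sem_rate * enrichment_factor``
    inside enriched features. ``de_effect_size`` is the log-expression shift
    of true DE genes in NO_ID at Tend.
    """

    n_id: int = 30
    n_noid: int = 14
    n_cpg: int = 20000
    n_tfbs: int = 40
    n_pathway: int = 60
    cpgs_per_feature: int = 500
    base_sem_rate: float = 1e-3
    enrichment_factor: float = 5.0
    n_enriched_features: int = 5
    n_genes: int = 2000
    n_de_genes: int = 40
    de_effect_size: float = 2.0
    expression_noise_sd: float = 0.5
    age_params: dict = field(
        default_factory=lambda: {"ID": (9.91, 3.55), "NO_ID": (13.42, 3.69)}
    )
    sex_p_female: float = 0.70
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_id", "n_noid", "n_cpg", "n_tfbs", "n_pathway",
                     "cpgs_per_feature", "n_enriched_features", "n_genes",
                     "n_de_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive count")
        if not (0.0 < self.base_sem_rate <= 0.05):
            raise ValueError("base_sem_rate must lie in (0, 0.05]")
        if self.enrichment_factor < 1.0:
            raise ValueError("enrichment_factor must be >= 1")
        if self.base_sem_rate * self.enrichment_factor > 1.0:
            raise ValueError("injection probability exceeds 1 after enrichment")
        if self.expression_noise_sd <= 0:
            raise ValueError("expression_noise_sd must be positive")
        if self.n_cpg < self.n_tfbs:
            raise ValueError("need at least one CpG per TFBS feature")
        if self.n_enriched_features > self.n_tfbs:
            raise ValueError("cannot enrich more features than exist")


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort.

    ``injected_sems`` maps timepoint -> boolean CpG x sample DataFrame;
    ``true_de_genes`` maps gene id -> +1 (up in NO_ID) or -1 (down).
    """

    enriched_feature_ids: frozenset
    injected_sems: dict
    true_de_genes: dict


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _cpg_ids(n: int) -> list[str]:
    return [f"cg{i:07d}" for i in range(n)]


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def simulate_annotation(config: SimConfig) -> FeatureAnnotation:
    """Random CpG feature sets, CpG->gene map and TF->target-gene map.

    TFBS features preferentially sample from a shared "hub" CpG pool so that
    hub genes (genes downstream of many TFs) arise, as they do in real
    ChIP-seq annotations where master regulators co-bind target promoters.
    """
    if config.cpgs_per_feature == 0:
        raise ValueError("cpgs_per_feature must be positive (empty features rejected)")
    rng = _rng(config, 1)
    cpgs = np.array(_cpg_ids(config.n_cpg))
    genes = np.array(_gene_ids(config.n_genes))

    # ~80% of CpGs map to a gene, at most one gene per CpG
    mapped = rng.random(config.n_cpg) < 0.8
    gene_of = rng.integers(0, config.n_genes, size=config.n_cpg)
    cpg2gene = {c: genes[g] for c, g, m in zip(cpgs, gene_of, mapped) if m}

    hub_pool = rng.choice(config.n_cpg, size=max(config.n_cpg // 20, 1), replace=False)
    other_pool = np.setdiff1d(np.arange(config.n_cpg), hub_pool)

    features: dict[str, frozenset] = {}
    kind: dict[str, str] = {}
    size = min(config.cpgs_per_feature, config.n_cpg)
    n_hub = min(int(round(0.3 * size)), len(hub_pool))
    for i in range(config.n_tfbs):
        chosen = np.concatenate([
            rng.choice(hub_pool, size=n_hub, replace=False),
            rng.choice(other_pool, size=size - n_hub, replace=False),
        ])
        fid = f"TF{i:03d}"
        features[fid] = frozenset(cpgs[chosen])
        kind[fid] = TFBS
    for i in range(config.n_pathway):
        chosen = rng.choice(config.n_cpg, size=size, replace=False)
        fid = f"PW{i:03d}"
        features[fid] = frozenset(cpgs[chosen])
        kind[fid] = PATHWAY

    tf_targets = {
        f: frozenset(cpg2gene[c] for c in members if c in cpg2gene)
        for f, members in features.items()
        if kind[f] == TFBS
    }
    return FeatureAnnotation(features=features, kind=kind, cpg2gene=cpg2gene,
                             tf_targets=tf_targets)


def _sample_meta(config: SimConfig) -> pd.DataFrame:
    rng = _rng(config, 2)
    rows = []
    for group, n in (("ID", config.n_id), ("NO_ID", config.n_noid)):
        mean, sd = config.age_params[group]
        ages = np.clip(rng.normal(mean, sd, size=n), 2.0, 18.0)
        sexes = np.where(rng.random(n) < config.sex_p_female, "F", "M")
        for i in range(n):
            subj = f"{group}{i:03d}"
            for tp in ("T0", "Tend"):
                rows.append({
                    "sample_id": f"{subj}_{tp}", "subject_id": subj,
                    "group": group, "timepoint": tp,
                    "age": round(float(ages[i]), 2), "sex": str(sexes[i]),
                })
    return pd.DataFrame(rows)


def simulate_methylome(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SimTruth]:
    """Beta matrices at T0 and Tend, sample metadata, and ground truth.

    Baseline values are Beta-distributed around bimodal CpG-specific means.
    Injected SEMs replace the baseline value with a uniform draw strictly
    outside the 3xIQR bounds pre-estimated from the simulated ID-at-T0
    baseline (choosing the side with room); NO_ID samples get the enriched
    rate inside enriched features at both timepoints.
    """
    ann = simulate_annotation(config)
    meta = _sample_meta(config)
    rng = _rng(config, 3)

    tf_ids = sorted(f for f, k in ann.kind.items() if k == TFBS)
    enriched = frozenset(rng.choice(tf_ids, size=config.n_enriched_features,
                                    replace=False).tolist())

    # bimodal methylome: mostly low- or high-methylated CpGs
    comp = rng.random(config.n_cpg)
    means = np.where(
        comp < 0.45, rng.uniform(0.03, 0.20, config.n_cpg),
        np.where(comp < 0.90, rng.uniform(0.80, 0.97, config.n_cpg),
                 rng.uniform(0.20, 0.80, config.n_cpg)),
    )
    conc = rng.uniform(30.0, 120.0, config.n_cpg)
    a_par, b_par = means * conc, (1.0 - means) * conc

    cpgs = _cpg_ids(config.n_cpg)
    samples = {tp: meta.loc[meta.timepoint == tp, "sample_id"].tolist()
               for tp in ("T0", "Tend")}
    n_per_tp = len(samples["T0"])
    values = {
        tp: rng.beta(a_par[:, None], b_par[:, None], size=(config.n_cpg, n_per_tp))
        for tp in ("T0", "Tend")
    }

    # pilot 3xIQR bounds from the ID-at-T0 baseline draw
    id_t0_cols = [i for i, s in enumerate(samples["T0"]) if s.startswith("ID")]
    ref = values["T0"][:, id_t0_cols]
    q1, q3 = np.quantile(ref, [0.25, 0.75], axis=1)
    iqr = q3 - q1
    lower, upper = q1 - 3.0 * iqr, q3 + 3.0 * iqr

    enriched_cpg_mask = np.zeros(config.n_cpg, dtype=bool)
    cpg_pos = {c: i for i, c in enumerate(cpgs)}
    for f in enriched:
        enriched_cpg_mask[[cpg_pos[c] for c in ann.features[f]]] = True

    room_low = np.maximum(lower, 0.0)            # space below the lower bound
    room_high = np.maximum(1.0 - upper, 0.0)     # space above the upper bound
    injectable = (room_low > 1e-6) | (room_high > 1e-6)

    is_noid = {tp: np.array([s.startswith("NO_ID") for s in samples[tp]])
               for tp in ("T0", "Tend")}
    truth_masks = {}
    for tp in ("T0", "Tend"):
        rate = np.full((config.n_cpg, n_per_tp), config.base_sem_rate)
        rate[np.ix_(enriched_cpg_mask, is_noid[tp])] *= config.enrichment_factor
        inject = (rng.random((config.n_cpg, n_per_tp)) < rate) & injectable[:, None]
        rows, cols = np.nonzero(inject)
        high_side = room_high[rows] >= room_low[rows]
        u = rng.random(rows.size)
        lo_edge = np.where(high_side, upper[rows] + 0.05 * room_high[rows], 0.0)
        hi_edge = np.where(high_side, 1.0, np.maximum(lower[rows] - 0.05 * room_low[rows], 0.0))
        values[tp][rows, cols] = lo_edge + u * (hi_edge - lo_edge)
        truth = np.zeros((config.n_cpg, n_per_tp), dtype=bool)
        truth[rows, cols] = True
        truth_masks[tp] = pd.DataFrame(truth, index=cpgs, columns=samples[tp])

    # true DE genes: hub genes downstream of >=50% of the enriched TFs
    gene_freq: dict[str, int] = {}
    for f in enriched:
        for g in ann.tf_targets[f]:
            gene_freq[g] = gene_freq.get(g, 0) + 1
    eligible = sorted(g for g, k in gene_freq.items() if k >= 0.5 * len(enriched))
    n_de = min(config.n_de_genes, len(eligible))
    de_genes = rng.choice(eligible, size=n_de, replace=False) if n_de else []
    signs = rng.choice([1, -1], size=n_de)
    true_de = {g: int(s) for g, s in zip(de_genes, signs)}

    beta0 = pd.DataFrame(values["T0"], index=cpgs, columns=samples["T0"])
    beta_end = pd.DataFrame(values["Tend"], index=cpgs, columns=samples["Tend"])
    truth = SimTruth(enriched_feature_ids=enriched, injected_sems=truth_masks,
                     true_de_genes=true_de)
    return beta0, beta_end, meta, truth


def simulate_expression(
    config: SimConfig, truth: SimTruth, meta: pd.DataFrame
) -> pd.DataFrame:
    """Gaussian log-expression for all samples in ``meta`` (column order kept).

    True DE genes are shifted by +/- ``de_effect_size`` in NO_ID samples at
    Tend only.
    """
    rng = _rng(config, 4)
    genes = _gene_ids(config.n_genes)
    base = rng.normal(7.0, 1.0, size=config.n_genes)
    sample_ids = meta["sample_id"].tolist()
    vals = base[:, None] + rng.normal(
        0.0, config.expression_noise_sd, size=(config.n_genes, len(sample_ids))
    )
    shifted_cols = np.array([
        (g == "NO_ID") and (t == "Tend")
        for g, t in zip(meta["group"], meta["timepoint"])
    ])
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g, sign in truth.true_de_genes.items():
        vals[gene_pos[g], shifted_cols] += sign * config.de_effect_size
    return pd.DataFrame(vals, index=genes, columns=sample_ids)


def simulate_dataset(config: SimConfig):
    """Convenience wrapper returning (beta0, beta_end, expr, meta, ann, truth)."""
    ann = simulate_annotation(config)
    beta0, beta_end, meta, truth = simulate_methylome(config)
    expr = simulate_expression(config, truth, meta)
    return beta0, beta_end, expr, meta, ann, truth
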