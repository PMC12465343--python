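"""End-to-end SEM pipeline on a (synthetic or real) cohort.

Stages: reference bounds from ID-at-T0 -> SEM calls at both timepoints ->
EML and its age/sex-adjusted association with activity -> per-feature burden
counts -> three-way feature selection (SKAT-O, elastic-net logistic,
gradient-boosted trees) -> consensus TFBSs -> hub genes -> candidate-gene
differential expression at Tend -> up/down signature. All stages are
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import aggregate, prioritize, select, sem, skato
from .synth import SimConfig, simulate_dataset

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    config: SimConfig
    bounds: sem.ReferenceBounds
    eml: dict
    association: dict
    counts_tfbs: pd.DataFrame
    skato_tfbs: pd.DataFrame
    skato_pathway: pd.DataFrame
    logistic: select.SelectionResult
    gbt: select.SelectionResult
    consensus: list
    hub: pd.DataFrame | None
    candidates: list
    de: pd.DataFrame | None
    signature: prioritize.Signature | None
    truth: object = None

    def summary(self) -> pd.DataFrame:
        a0, ae = self.association["T0"], self.association["Tend"]
        rows = {
            "eml_effect_T0_sd": a0.beta,
            "eml_p_T0": a0.p,
            "eml_effect_Tend_sd": ae.beta,
            "eml_p_Tend": ae.p,
            "n_tfbs_skato_significant": int((self.skato_tfbs["q"] < 0.1).sum()),
            "n_tfbs_logistic": len(self.logistic.selected_features),
            "n_tfbs_gbt": len(self.gbt.selected_features),
            "n_consensus_tfbs": len(self.consensus),
            "n_candidate_genes": len(self.candidates),
            "n_signature_up": len(self.signature.up) if self.signature else 0,
            "n_signature_down": len(self.signature.down) if self.signature else 0,
        }
        return pd.DataFrame({"value": rows})


def run_pipeline(
    config: SimConfig | None = None,
    seed: int | None = None,
    skat_cfg: skato.SkatConfig | None = None,
    sel_cfg: select.SelectionConfig | None = None,
    fdr_q_max: float = 0.1,
    de_q_max: float = 0.2,
) -> PipelineResult:
    """Simulate a cohort and run every stage of the SEM pipeline on it."""
    config = config or SimConfig()
    if seed is not None:
        config = SimConfig(**{**config.__dict__, "seed": seed})
    skat_cfg = skat_cfg or skato.SkatConfig(fdr_q_max=fdr_q_max)
    sel_cfg = sel_cfg or select.SelectionConfig(seed=config.seed)

    beta0, beta_end, expr, meta, ann, truth = simulate_dataset(config)

    ref_samples = meta.loc[
        (meta.group == "ID") & (meta.timepoint == "T0"), "sample_id"
    ]
    bounds = sem.reference_bounds(beta0, ref_samples, k=3.0)
    sems = {"T0": sem.call_sems(beta0, bounds), "Tend": sem.call_sems(beta_end, bounds)}

    eml_tables, assoc = {}, {}
    for tp in ("T0", "Tend"):
        tbl = sem.eml(sems[tp])
        eml_tables[tp] = tbl
        m = meta.loc[meta.timepoint == tp]
        assoc[tp] = sem.associate_biomarker(tbl["eml"], m)

    meta_end = meta.loc[meta.timepoint == "Tend"]
    counts_tfbs = aggregate.count_sems_by_feature(sems["Tend"], ann, kind=aggregate.TFBS)
    skato_tfbs = skato.skat_test_features(
        sems["Tend"], ann, meta_end, skat_cfg, kind=aggregate.TFBS, seed=config.seed
    )
    skato_pathway = skato.skat_test_features(
        sems["Tend"], ann, meta_end, skat_cfg, kind=aggregate.PATHWAY, seed=config.seed
    )

    X = select.standardize(counts_tfbs.loc[meta_end["sample_id"]])
    y = (meta_end["group"] == "NO_ID").to_numpy(dtype=int)
    logistic = select.select_penalized_logistic(X, y, sel_cfg)
    gbt = select.select_gbt(X, y, sel_cfg)
    consensus = select.intersect_selections(
        [logistic, gbt, skato_tfbs], fdr_q_max=skat_cfg.fdr_q_max
    )

    hub = candidates = de = signature = None
    cand_list: list = []
    if consensus:
        hub = prioritize.hub_frequencies(consensus, ann.tf_targets)
        cand_list = prioritize.candidate_genes(hub, min_fraction=0.5)
        if cand_list:
            de = prioritize.differential_expression(
                expr, meta_end, cand_list, q_max=de_q_max
            )
            if de["significant"].any():
                signature = prioritize.build_signature(
                    de, provenance={"consensus_tfbs": consensus, "de_q_max": de_q_max}
                )
    return PipelineResult(
        config=config,
        bounds=bounds,
        eml=eml_tables,
        association=assoc,
        counts_tfbs=counts_tfbs,
        skato_tfbs=skato_tfbs,
        skato_pathway=skato_pathway,
        logistic=logistic,
        gbt=gbt,
        consensus=consensus,
        hub=hub,
        candidates=cand_list,
        de=de,
        signature=signature,
        truth=truth,
    )
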