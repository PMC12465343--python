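"""Stochastic epigenetic mutation (SEM) calling and epigenetic mutation load.

A SEM is a rare, individual-specific methylation outlier: at a given CpG, a
beta value strictly below ``Q1 - k*IQR`` or strictly above ``Q3 + k*IQR``,
where the quartiles are computed over a fixed reference cohort (here the
inactive-disease patients at baseline) and ``k`` defaults to 3. The
epigenetic mutation load (EML) of a sample is the natural logarithm of its
total SEM count. Group differences in EML (or any per-sample epigenetic
biomarker) are tested with an age- and sex-adjusted linear model on the
standardized biomarker, so effects read as standard-deviation differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm_api

__all__ = [
    "ReferenceBounds",
    "SEMMatrix",
    "reference_bounds",
    "call_sems",
    "eml",
    "AssociationResult",
    "associate_biomarker",
    "EMLAssociation",
    "EMLAssociationResults",
]


@dataclass(frozen=True)
class ReferenceBounds:
    """Per-CpG quartiles and outlier thresholds from the reference cohort.

    ``table`` has columns q1, q3, iqr, lower, upper indexed by CpG id;
    ``k`` is the IQR multiplier; ``quantile_method`` records the quantile
    interpolation convention (SEM counts depend on it).
    """

    table: pd.DataFrame
    k: float = 3.0
    quantile_method: str = "linear"
    n_reference: int = 0

    def __post_init__(self) -> None:
        t = self.table
        if (t["q1"] > t["q3"]).any():
            raise ValueError("q1 > q3 for some CpG")


@dataclass
class SEMMatrix:
    """Binary SEM calls with side information.

    ``calls`` is a CpG x sample 0/1 matrix; ``side`` holds -1 (below the
    lower bound), +1 (above the upper bound) or 0.
    """

    calls: pd.DataFrame
    side: pd.DataFrame

    def counts(self) -> pd.Series:
        """Total SEMs per sample."""
        return self.calls.sum(axis=0).astype(int)


def reference_bounds(
    beta: pd.DataFrame,
    reference_samples,
    k: float = 3.0,
    quantile_method: str = "linear",
) -> ReferenceBounds:
    """Per-CpG Q1/Q3/IQR and outlier bounds over the reference samples only.

    Quartiles use linear interpolation between order statistics by default
    (the common convention in mainstream statistical environments).
    """
    reference_samples = list(reference_samples)
    missing = set(reference_samples) - set(beta.columns)
    if missing:
        raise ValueError(f"reference samples not in matrix: {sorted(missing)[:5]}")
    if len(reference_samples) < 4:
        raise ValueError("at least 4 reference samples are required")
    vals = beta[reference_samples].to_numpy(dtype=float)
    q1, q3 = np.quantile(vals, [0.25, 0.75], axis=1, method=quantile_method)
    iqr = q3 - q1
    table = pd.DataFrame(
        {
            "q1": q1,
            "q3": q3,
            "iqr": iqr,
            "lower": q1 - k * iqr,
            "upper": q3 + k * iqr,
        },
        index=beta.index,
    )
    return ReferenceBounds(
        table=table, k=k, quantile_method=quantile_method,
        n_reference=len(reference_samples),
    )


def call_sems(beta: pd.DataFrame, bounds: ReferenceBounds) -> SEMMatrix:
    """Call SEMs for any sample set against fixed reference bounds.

    A value is a SEM iff it is strictly below the lower or strictly above the
    upper bound of its CpG; values exactly on a bound are not SEMs.
    """
    missing = beta.index.difference(bounds.table.index)
    if len(missing):
        raise ValueError(f"CpGs missing from bounds: {list(missing[:5])}")
    t = bounds.table.loc[beta.index]
    vals = beta.to_numpy(dtype=float)
    lower = t["lower"].to_numpy()[:, None]
    upper = t["upper"].to_numpy()[:, None]
    side = np.zeros(vals.shape, dtype=np.int8)
    side[vals < lower] = -1
    side[vals > upper] = 1
    calls = (side != 0).astype(np.int8)
    return SEMMatrix(
        calls=pd.DataFrame(calls, index=beta.index, columns=beta.columns),
        side=pd.DataFrame(side, index=beta.index, columns=beta.columns),
    )


def eml(sems: SEMMatrix | pd.DataFrame, zero_policy: str = "add_one") -> pd.DataFrame:
    """Per-sample SEM count and epigenetic mutation load ln(count).

    ``zero_policy`` governs samples with zero SEMs: ``add_one`` (default)
    reports ln(count + 1) = 0 for them with a warning, leaving samples with
    count >= 1 at ln(count); ``strict`` reports a missing EML for them.
    """
    counts = sems.counts() if isinstance(sems, SEMMatrix) else sems.sum(axis=0).astype(int)
    c = counts.to_numpy(dtype=float)
    load = np.full(c.shape, np.nan)
    pos = c >= 1
    load[pos] = np.log(c[pos])
    if (~pos).any():
        if zero_policy == "add_one":
            warnings.warn(
                f"{int((~pos).sum())} sample(s) with zero SEMs assigned EML=ln(1)=0"
            )
            load[~pos] = 0.0
        elif zero_policy == "strict":
            warnings.warn(f"{int((~pos).sum())} sample(s) with zero SEMs have missing EML")
        else:
            raise ValueError(f"unknown zero_policy {zero_policy!r}")
    out = pd.DataFrame({"sem_count": counts.astype(int), "eml": load})
    out.index.name = "sample_id"
    return out


@dataclass(frozen=True)
class AssociationResult:
    """Standardized group effect on a biomarker, adjusted for covariates.

    ``beta`` is in standard-deviation units of the biomarker over the
    analysis sample; the 95% CI and two-sided p come from the t distribution
    with residual degrees of freedom.
    """

    beta: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    covariates: tuple

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValueError("confidence interval must bracket the estimate")


def _design(meta: pd.DataFrame, covariates) -> pd.DataFrame:
    X = pd.DataFrame(index=meta.index)
    X["activity"] = (meta["group"] == "NO_ID").astype(float)
    for cov in covariates:
        if cov == "sex":
            X["sex"] = (meta["sex"] == "M").astype(float)
        else:
            X[cov] = meta[cov].astype(float)
    return sm_api.add_constant(X, prepend=True)


def associate_biomarker(
    biomarker: pd.Series,
    meta: pd.DataFrame,
    covariates=("age", "sex"),
    standardize: bool = True,
) -> AssociationResult:
    """OLS of the standardized biomarker on disease activity + covariates.

    The biomarker is the dependent variable; the predictor is the activity
    indicator (NO_ID = 1). Standardization divides by the biomarker SD over
    the full analysis sample (ddof=1), so the coefficient is a
    standard-deviation difference between groups.
    """
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    common = [s for s in meta.index if s in biomarker.index]
    meta = meta.loc[common]
    y = biomarker.loc[common].astype(float)
    groups = set(meta["group"])
    if not {"ID", "NO_ID"} <= groups:
        raise ValueError("both ID and NO_ID groups must be present")
    if len(common) < len(covariates) + 3:
        raise ValueError("too few samples for the requested covariate set")
    if standardize:
        sd = y.std(ddof=1)
        if sd == 0:
            raise ValueError("biomarker is constant; cannot standardize")
        y = (y - y.mean()) / sd
    X = _design(meta, covariates)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("singular design matrix")
    fit = sm_api.OLS(y.to_numpy(), X.to_numpy()).fit()
    j = list(X.columns).index("activity")
    ci = fit.conf_int(alpha=0.05)
    return AssociationResult(
        beta=float(fit.params[j]),
        ci_low=float(ci[j][0]),
        ci_high=float(ci[j][1]),
        p=float(fit.pvalues[j]),
        n=int(len(common)),
        covariates=tuple(covariates),
    )


class EMLAssociation:
    """Model-style wrapper: biomarker ~ activity + covariates.

    Built from a per-sample biomarker vector and sample metadata;
    :meth:`fit` returns :class:`EMLAssociationResults`.
    """

    def __init__(self, biomarker: pd.Series, meta: pd.DataFrame,
                 covariates=("age", "sex")):
        self.biomarker = biomarker
        self.meta = meta
        self.covariates = tuple(covariates)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, biomarker_col: str = "eml",
                       covariates=("age", "sex")):
        """Build from one DataFrame holding the biomarker and metadata columns."""
        meta_cols = [c for c in df.columns if c != biomarker_col]
        return cls(df[biomarker_col], df[meta_cols], covariates=covariates)

    def fit(self, standardize: bool = True) -> "EMLAssociationResults":
        res = associate_biomarker(
            self.biomarker, self.meta, covariates=self.covariates,
            standardize=standardize,
        )
        return EMLAssociationResults(res)


@dataclass(frozen=True)
class EMLAssociationResults:
    result: AssociationResult

    def summary(self) -> pd.DataFrame:
        r = self.result
        return pd.DataFrame(
            {
                "estimate_sd_units": [r.beta],
                "ci_low": [r.ci_low],
                "ci_high": [r.ci_high],
                "p": [r.p],
                "n": [r.n],
                "covariates": ["+".join(r.covariates)],
            },
            index=["activity"],
        )
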