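"""Patient stratification by master-regulator activity.

A patient is called regulator-active when all three criteria hold
simultaneously: (1) regulator expression strictly above a threshold that
defaults to the cohort mean of the regulator's log2 expression, (2) copy
number segment mean at the regulator locus strictly above 0.5, and
(3) mean promoter-CpG methylation beta at most 0.4 (hypomethylated).
Everyone else is inactive, so the partition is exactly two-way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class OmicsCohort:
    """Aligned expression / CNV / methylation matrices for one cohort.

    ``expression`` is gene x patient (log2 units), ``cnv`` is locus x patient
    segment means, ``methylation`` is CpG x patient beta-values in [0, 1].
    ``promoter_cpgs`` lists the CpG IDs mapped to the regulator's promoter.
    Patient columns must be identical and identically ordered across the
    three matrices.
    """

    expression: pd.DataFrame
    cnv: pd.DataFrame
    methylation: pd.DataFrame
    promoter_cpgs: list[str]
    patient_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.patient_ids:
            self.patient_ids = list(self.expression.columns)
        for name, df in (("expression", self.expression), ("cnv", self.cnv),
                         ("methylation", self.methylation)):
            if list(df.columns) != self.patient_ids:
                raise ValueError(
                    f"{name} patient columns misaligned with cohort patient_ids")
        meth = self.methylation.to_numpy(float)
        if np.nanmin(meth) < 0 or np.nanmax(meth) > 1:
            raise ValueError("methylation beta-values must lie in [0, 1]")


@dataclass
class Thresholds:
    """Activity-call thresholds; ``expr`` of None means use the cohort mean."""

    expr: float | None = None
    cnv: float = 0.5
    beta: float = 0.4
    meth_agg: str = "mean"  # mean | median | all


@dataclass
class ActivityPartition:
    """Per-patient criterion flags and the conjunctive activity call."""

    flags: pd.DataFrame  # columns: expr_high, cnv_amp, hypometh, active
    expr_threshold: float
    cnv_threshold: float
    beta_threshold: float

    @property
    def active_patients(self) -> list[str]:
        return list(self.flags.index[self.flags["active"]])

    @property
    def inactive_patients(self) -> list[str]:
        return list(self.flags.index[~self.flags["active"]])

    @property
    def n_active(self) -> int:
        return int(self.flags["active"].sum())

    @property
    def n_inactive(self) -> int:
        return int((~self.flags["active"]).sum())


def promoter_methylation(cohort: OmicsCohort, agg: str = "mean") -> pd.Series:
    """Per-patient summary beta across the regulator's promoter CpGs.

    ``agg`` selects the summary: unweighted ``mean`` (default) or ``median``.
    Unknown CpG IDs are a hard error listing the missing ones.
    """
    if not cohort.promoter_cpgs:
        raise ValueError("promoter CpG list is empty")
    missing = [c for c in cohort.promoter_cpgs if c not in cohort.methylation.index]
    if missing:
        raise KeyError(f"promoter CpGs absent from methylation matrix: {missing}")
    sub = cohort.methylation.loc[cohort.promoter_cpgs]
    if agg == "mean":
        return sub.mean(axis=0)
    if agg == "median":
        return sub.median(axis=0)
    raise ValueError(f"unknown aggregation {agg!r}")


def call_activity(
    cohort: OmicsCohort,
    regulator_gene_id: str,
    thresholds: Thresholds | None = None,
) -> ActivityPartition:
    """Three-criterion activity partition of the cohort.

    Criterion flags use the printed boundary conventions: strictly greater
    for expression and CNV, less-or-equal for promoter beta. With
    ``meth_agg='all'`` the hypomethylation flag requires every promoter CpG
    to pass individually instead of their summary.
    """
    thr = thresholds or Thresholds()
    if regulator_gene_id not in cohort.expression.index:
        raise KeyError(f"regulator {regulator_gene_id!r} not in expression matrix")
    reg_expr = cohort.expression.loc[regulator_gene_id]
    expr_threshold = float(reg_expr.mean()) if thr.expr is None else float(thr.expr)

    if cohort.cnv.shape[0] == 1:
        cnv = cohort.cnv.iloc[0]
    elif regulator_gene_id in cohort.cnv.index:
        cnv = cohort.cnv.loc[regulator_gene_id]
    else:
        raise KeyError(
            "cnv matrix must have a single locus row or a row named after "
            "the regulator")

    if thr.meth_agg == "all":
        missing = [c for c in cohort.promoter_cpgs
                   if c not in cohort.methylation.index]
        if missing:
            raise KeyError(f"promoter CpGs absent from methylation matrix: {missing}")
        hypometh = (cohort.methylation.loc[cohort.promoter_cpgs]
                    <= thr.beta).all(axis=0)
    else:
        beta = promoter_methylation(cohort, agg=thr.meth_agg)
        hypometh = beta <= thr.beta

    flags = pd.DataFrame({
        "expr_high": reg_expr > expr_threshold,
        "cnv_amp": cnv > thr.cnv,
        "hypometh": hypometh,
    }, index=cohort.patient_ids)
    flags["active"] = flags["expr_high"] & flags["cnv_amp"] & flags["hypometh"]
    return ActivityPartition(
        flags=flags,
        expr_threshold=expr_threshold,
        cnv_threshold=thr.cnv,
        beta_threshold=thr.beta,
    )
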