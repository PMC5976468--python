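"""Genomic-context and clinical annotation of candidate variants.

Covers same-TAD membership of a variant and its target gene, regulator
ChIP-seq peak overlap with the gene's promoter window, per-subgroup minor
allele frequencies, and genotype-by-clinical-feature association tests.
Internal coordinates are 0-based half-open; 1-based point positions (VCF /
TSS) are converted on entry.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class IntervalSet:
    """Named genomic intervals, 0-based half-open, sorted per chromosome.

    ``require_disjoint`` enforces the TAD-set contract that intervals on a
    chromosome do not overlap (touching ends are fine).
    """

    intervals: pd.DataFrame  # columns: chrom, start, end, name
    require_disjoint: bool = False

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "name"}
        if not required.issubset(self.intervals.columns):
            raise ValueError(f"interval table needs columns {sorted(required)}")
        if (self.intervals["start"] >= self.intervals["end"]).any():
            raise ValueError("intervals need start < end")
        self.intervals = (self.intervals
                          .sort_values(["chrom", "start", "end"], kind="mergesort")
                          .reset_index(drop=True))
        if self.require_disjoint:
            for chrom, sub in self.intervals.groupby("chrom"):
                if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
                    raise ValueError(f"overlapping intervals on {chrom}")

    def __len__(self) -> int:
        return len(self.intervals)

    def containing(self, chrom: str, pos: int) -> list[str]:
        """Names of intervals containing the 0-based point ``pos``."""
        sub = self.intervals[self.intervals["chrom"] == chrom]
        if sub.empty:
            return []
        starts = sub["start"].to_numpy()
        i = bisect.bisect_right(starts, pos) - 1
        if self.require_disjoint:
            if i >= 0 and sub.iloc[i]["end"] > pos:
                return [sub.iloc[i]["name"]]
            return []
        hits = sub[(sub["start"] <= pos) & (sub["end"] > pos)]
        return list(hits["name"])

    def overlapping(self, chrom: str, start: int, end: int) -> pd.DataFrame:
        """Intervals intersecting the half-open query [start, end)."""
        sub = self.intervals[self.intervals["chrom"] == chrom]
        return sub[(sub["start"] < end) & (sub["end"] > start)].reset_index(drop=True)


def same_tad(
    tads: IntervalSet,
    point_a: tuple[str, int],
    point_b: tuple[str, int],
) -> tuple[bool, list[str]]:
    """Whether one TAD contains both 0-based points; returns its name(s).

    A point on a boundary belongs to the interval whose half-open range
    contains it. A point inside no TAD yields False with an empty name list
    (unassigned), not an error.
    """
    tads_a = set(tads.containing(*point_a))
    tads_b = set(tads.containing(*point_b))
    common = sorted(tads_a & tads_b)
    return bool(common), common


def promoter_window(
    tss: tuple[str, int, str],
    upstream_bp: int = 2000,
    downstream_bp: int = 500,
) -> tuple[str, int, int]:
    """Strand-aware half-open promoter window around a 1-based TSS.

    On the + strand "upstream" extends to lower coordinates; on the - strand
    to higher coordinates. The TSS base itself is always inside the window.
    """
    chrom, pos_1based, strand = tss
    t = pos_1based - 1
    if strand == "+":
        start, end = t - upstream_bp, t + downstream_bp + 1
    elif strand == "-":
        start, end = t - downstream_bp, t + upstream_bp + 1
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    return chrom, max(start, 0), end


def promoter_overlap(
    peaks: IntervalSet,
    tss: tuple[str, int, str],
    upstream_bp: int = 2000,
    downstream_bp: int = 500,
) -> pd.DataFrame:
    """Peaks intersecting the promoter window of a gene's TSS."""
    chrom, start, end = promoter_window(tss, upstream_bp, downstream_bp)
    return peaks.overlapping(chrom, start, end)


# ---------------------------------------------------------------------------
# allele frequencies and clinical association
# ---------------------------------------------------------------------------

def minor_allele(dosages: np.ndarray) -> tuple[str, float]:
    """Cohort-wide minor allele ('ref' or 'alt') and its frequency.

    Ties (alt frequency exactly 0.5) break to 'alt'.
    """
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValueError("no called genotypes")
    alt_freq = d.sum() / (2 * d.size)
    if alt_freq <= 0.5:
        return "alt", float(alt_freq)
    return "ref", float(1 - alt_freq)


def maf_by_group(geno, snp_id: str, grouping: pd.Series) -> pd.Series:
    """Frequency of the cohort-level minor allele within each category.

    ``grouping`` maps patient ID to a category. The minor allele is fixed on
    the whole cohort first, so per-category values are comparable. Empty or
    all-missing categories are omitted with a warning.
    """
    dos = pd.Series(geno.dosage(snp_id), index=geno.patient_ids)
    which, _ = minor_allele(dos.to_numpy())
    out = {}
    for cat, patients in grouping.groupby(grouping):
        d = dos.loc[patients.index.intersection(dos.index)].dropna()
        if d.empty:
            logger.warning("category %r has no called genotypes; omitted", cat)
            continue
        alt_freq = d.sum() / (2 * len(d))
        out[cat] = float(alt_freq if which == "alt" else 1 - alt_freq)
    return pd.Series(out, name=f"maf_{snp_id}")


def carrier_status(dosages: np.ndarray, minor: str) -> np.ndarray:
    """Dominant coding: True for carriers of >= 1 minor allele."""
    d = np.asarray(dosages, dtype=float)
    if minor == "alt":
        return d >= 1
    return d <= 1


@dataclass
class AssociationResult:
    table: pd.DataFrame
    statistic: float
    p_value: float
    method: str  # chi2 | fisher


def genotype_feature_association(
    clinical: pd.DataFrame,
    feature: str,
    carrier_col: str = "carrier",
) -> AssociationResult:
    """Carrier-status x categorical-feature association test.

    Pearson chi-square without continuity correction; falls back to Fisher's
    exact test when the table is 2x2 and any expected cell count is below 5,
    with the method used reported in the result.
    """
    sub = clinical[[carrier_col, feature]].dropna()
    if sub[feature].nunique() < 2:
        raise ValueError(f"feature {feature!r} has a single level")
    table = pd.crosstab(sub[carrier_col], sub[feature])
    obs = table.to_numpy(float)
    expected = stats.contingency.expected_freq(obs)
    if obs.shape == (2, 2) and (expected < 5).any():
        odds, p = stats.fisher_exact(obs)
        return AssociationResult(table, float(odds), float(p), "fisher")
    chi2, p, _, _ = stats.chi2_contingency(obs, correction=False)
    return AssociationResult(table, float(chi2), float(p), "chi2")


def clinical_summary(clinical: pd.DataFrame, carrier_col: str = "carrier") -> dict:
    """Descriptive summaries plus the unnamed-test conventions for age/stage.

    Age is compared between carriers and non-carriers with a two-sample
    Welch t-test; stage with a chi-square; both are reported alongside
    quartile tables.
    """
    out: dict = {}
    if "age" in clinical.columns:
        by = clinical.groupby(carrier_col)["age"]
        out["age_summary"] = by.describe()
        groups = [g.dropna().to_numpy() for _, g in by]
        if len(groups) == 2 and all(len(g) >= 2 for g in groups):
            t, p = stats.ttest_ind(*groups, equal_var=False)
            out["age_test"] = {"t": float(t), "p_value": float(p),
                               "method": "welch_t"}
    if "stage" in clinical.columns and clinical["stage"].nunique() >= 2:
        res = genotype_feature_association(clinical, "stage", carrier_col)
        out["stage_test"] = {"statistic": res.statistic, "p_value": res.p_value,
                             "method": res.method}
    return out
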