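"""Per-group cis-eQTL association scanning.

The scan mirrors the Matrix-eQTL workflow: enumerate all SNP-gene pairs on
the same chromosome within a cis window of the gene's TSS, fit an additive
linear model (expression ~ intercept + alt-allele dosage) per pair within a
patient group, control the false-discovery rate with Benjamini-Hochberg over
every pair tested in that group, and finally compare the active and inactive
groups' significant sets to isolate group-unique associations.

No covariates enter the model by default; ``residualize`` offers a hook for
pre-regressing known covariates out of the expression matrix before scanning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Smallest p-value reported; a numerically perfect fit yields t -> inf and
#: a tail probability of exactly 0, which is clipped into (0, 1].
_P_FLOOR = np.nextafter(0.0, 1.0)


class MonomorphicError(ValueError):
    """Dosage vector is constant within the group; the slope is undefined."""


@dataclass
class GenotypeMatrix:
    """SNP x patient alt-allele dosage matrix with variant metadata.

    Parameters
    ----------
    dosages
        Array of shape ``(n_snps, n_patients)`` holding alt-allele counts in
        {0, 1, 2}; ``nan`` marks a missing genotype.
    variants
        DataFrame with columns ``id, chrom, pos, ref, alt`` (``pos`` 1-based),
        one row per SNP in dosage row order.
    patient_ids
        Column labels for ``dosages``.
    haplotypes
        Optional phased binary matrix of shape ``(n_snps, 2 * n_patients)``;
        column ``2i``/``2i+1`` are the two haplotypes of patient ``i``.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    patient_ids: list[str]
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (snps x patients)")
        n_snps, n_patients = self.dosages.shape
        if len(self.variants) != n_snps:
            raise ValueError("variant table length does not match dosage rows")
        if len(self.patient_ids) != n_patients:
            raise ValueError("patient_ids length does not match dosage columns")
        required = {"id", "chrom", "pos", "ref", "alt"}
        if not required.issubset(self.variants.columns):
            raise ValueError(f"variant table needs columns {sorted(required)}")
        if (self.variants["pos"] < 1).any():
            raise ValueError("variant positions are 1-based and must be >= 1")
        if (self.variants["ref"].str.len() == 0).any() or (
            self.variants["alt"].str.len() == 0
        ).any():
            raise ValueError("ref/alt alleles must be non-empty")
        vals = self.dosages[~np.isnan(self.dosages)]
        if not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be in {0, 1, 2} or missing")
        if self.haplotypes is not None:
            self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
            if self.haplotypes.shape != (n_snps, 2 * n_patients):
                raise ValueError("haplotypes must have shape (n_snps, 2*n_patients)")

    @property
    def snp_ids(self) -> list[str]:
        return list(self.variants["id"])

    def dosage(self, snp_id: str) -> np.ndarray:
        """Dosage vector for one SNP, indexed by patient order."""
        idx = self.variants.index[self.variants["id"] == snp_id]
        if len(idx) == 0:
            raise KeyError(f"unknown SNP {snp_id!r}")
        return self.dosages[self.variants.index.get_loc(idx[0])]

    def subset_patients(self, patient_ids: list[str]) -> "GenotypeMatrix":
        pos = {p: i for i, p in enumerate(self.patient_ids)}
        missing = [p for p in patient_ids if p not in pos]
        if missing:
            raise KeyError(f"patients not in genotype matrix: {missing[:5]}")
        cols = [pos[p] for p in patient_ids]
        hap = None
        if self.haplotypes is not None:
            hap_cols = [c for i in cols for c in (2 * i, 2 * i + 1)]
            hap = self.haplotypes[:, hap_cols]
        return GenotypeMatrix(
            self.dosages[:, cols], self.variants.reset_index(drop=True),
            list(patient_ids), hap,
        )


@dataclass
class CisPair:
    """One SNP-gene association record within a patient group."""

    snp_id: str
    gene_id: str
    distance: int
    beta: float
    t_stat: float
    p_value: float
    fdr: float
    group: str


@dataclass
class EqtlComparison:
    """Group-unique and shared significant cis pairs, keyed by (snp, gene)."""

    unique_to_active: pd.DataFrame
    unique_to_inactive: pd.DataFrame
    shared: pd.DataFrame
    fdr_threshold: float
    rule: str = "fdr_both_groups"


# ---------------------------------------------------------------------------
# candidate enumeration
# ---------------------------------------------------------------------------

def enumerate_cis_pairs(
    variants: pd.DataFrame,
    gene_positions: pd.DataFrame,
    window_bp: int = 1_000_000,
) -> pd.DataFrame:
    """All same-chromosome SNP-gene pairs with |SNP pos - TSS| <= window.

    ``gene_positions`` needs columns ``gene_id, chrom, tss`` (TSS 1-based).
    Distance is signed: SNP position minus TSS, strand-agnostic.
    """
    out = []
    for chrom, vsub in variants.groupby("chrom", sort=False):
        gsub = gene_positions[gene_positions["chrom"] == chrom]
        if gsub.empty:
            continue
        pos = vsub["pos"].to_numpy()[:, None]
        tss = gsub["tss"].to_numpy()[None, :]
        dist = pos - tss
        si, gi = np.nonzero(np.abs(dist) <= window_bp)
        out.append(pd.DataFrame({
            "snp_id": vsub["id"].to_numpy()[si],
            "gene_id": gsub["gene_id"].to_numpy()[gi],
            "distance": dist[si, gi].astype(int),
        }))
    if not out:
        return pd.DataFrame(columns=["snp_id", "gene_id", "distance"])
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# per-pair model fits
# ---------------------------------------------------------------------------

def fit_additive(dosage: np.ndarray, expression: np.ndarray) -> tuple[float, float, float]:
    """OLS slope of expression on dosage with intercept; two-sided t test.

    Missing values (nan in either vector) are dropped pairwise. Returns
    ``(beta, t_stat, p_value)`` with df = n - 2. Raises
    :class:`MonomorphicError` if the dosage is constant and ``ValueError``
    with fewer than 3 complete observations.
    """
    g = np.asarray(dosage, dtype=float)
    y = np.asarray(expression, dtype=float)
    ok = ~(np.isnan(g) | np.isnan(y))
    g, y = g[ok], y[ok]
    n = g.size
    if n < 3:
        raise ValueError("need >= 3 complete observations")
    gc = g - g.mean()
    sxx = float(gc @ gc)
    if sxx == 0.0:
        raise MonomorphicError("dosage constant in group")
    yc = y - y.mean()
    beta = float(gc @ yc) / sxx
    resid = yc - beta * gc
    df = n - 2
    s2 = float(resid @ resid) / df
    if s2 <= 0.0:
        # perfect fit: the t statistic diverges and the tail mass vanishes
        t = np.inf if beta > 0 else (-np.inf if beta < 0 else 0.0)
        p = 1.0 if beta == 0 else _P_FLOOR
        return beta, t, p
    se = np.sqrt(s2 / sxx)
    t = beta / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return beta, float(t), float(max(p, _P_FLOOR))


def fit_anova(dosage: np.ndarray, expression: np.ndarray) -> tuple[float, float]:
    """One-way ANOVA of expression across genotype classes {0, 1, 2}.

    Each class present must contain >= 2 patients and >= 2 classes must be
    present, otherwise ``ValueError`` is raised.
    """
    g = np.asarray(dosage, dtype=float)
    y = np.asarray(expression, dtype=float)
    ok = ~(np.isnan(g) | np.isnan(y))
    g, y = g[ok], y[ok]
    groups = [y[g == level] for level in (0.0, 1.0, 2.0) if np.any(g == level)]
    if len(groups) < 2:
        raise ValueError("need >= 2 genotype classes for ANOVA")
    if any(len(grp) < 2 for grp in groups):
        raise ValueError("each genotype class needs >= 2 patients")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def pairwise_t_tests(dosage: np.ndarray, expression: np.ndarray) -> pd.DataFrame:
    """Welch t-tests between every pair of genotype classes.

    Companion to :func:`fit_anova` for genotype-class comparisons reported
    as t-tests rather than a single F statistic.
    """
    g = np.asarray(dosage, dtype=float)
    y = np.asarray(expression, dtype=float)
    levels = [lv for lv in (0.0, 1.0, 2.0) if np.sum(g == lv) >= 2]
    rows = []
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            t, p = stats.ttest_ind(y[g == a], y[g == b], equal_var=False)
            rows.append({"class_a": int(a), "class_b": int(b),
                         "t_stat": float(t), "p_value": float(p)})
    return pd.DataFrame(rows, columns=["class_a", "class_b", "t_stat", "p_value"])


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_i = min_{j >= i} (p_(j) * m / j) over the ascending order statistics,
    capped at 1. Input p-values must lie in (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if p.size == 0:
        return p.copy()
    if np.any(~(p > 0.0) | (p > 1.0)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# group scans
# ---------------------------------------------------------------------------

def residualize(expression: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Replace each gene's expression by OLS residuals on the covariates.

    Covariate hook for the scan (off by default): ``covariates`` is
    patient x covariate, aligned to the expression columns.
    """
    X = np.column_stack([np.ones(len(covariates)), covariates.to_numpy(float)])
    Y = expression.to_numpy(float).T
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    return pd.DataFrame(resid.T, index=expression.index, columns=expression.columns)


def scan_group(
    geno: GenotypeMatrix,
    expression: pd.DataFrame,
    patients_in_group: list[str],
    gene_positions: pd.DataFrame,
    window_bp: int = 1_000_000,
    p_out_threshold: float = 0.05,
    group_label: str = "active",
) -> pd.DataFrame:
    """Additive cis scan within one patient group.

    Every candidate pair from :func:`enumerate_cis_pairs` is fit with
    :func:`fit_additive`; SNPs monomorphic within the group are skipped (and
    logged). FDR is computed over **all** pairs tested in the group, then
    pairs with ``p < p_out_threshold`` are returned sorted by p-value.

    Returns a DataFrame with columns
    ``snp_id, gene_id, distance, beta, t_stat, p_value, fdr, group`` and
    attrs ``n_tested``, ``n_skipped``.
    """
    if len(patients_in_group) == 0:
        raise ValueError("patient group is empty")
    sub = geno.subset_patients(list(patients_in_group))
    expr = expression.loc[:, list(patients_in_group)]
    candidates = enumerate_cis_pairs(sub.variants, gene_positions, window_bp)
    candidates = candidates[candidates["gene_id"].isin(expr.index)]

    rows: list[tuple] = []
    n_skipped = 0
    E = expr.to_numpy(float)
    gene_row = {g: i for i, g in enumerate(expr.index)}
    snp_row = {s: i for i, s in enumerate(sub.variants["id"])}
    has_missing = np.isnan(sub.dosages).any() or np.isnan(E).any()

    for snp_id, snp_cand in candidates.groupby("snp_id", sort=False):
        g = sub.dosages[snp_row[snp_id]]
        gi = np.array([gene_row[gg] for gg in snp_cand["gene_id"]])
        if has_missing:
            for (_, cand), row in zip(snp_cand.iterrows(), gi):
                try:
                    beta, t, p = fit_additive(g, E[row])
                except MonomorphicError:
                    n_skipped += 1
                    logger.debug("skipping %s (monomorphic in %s group)",
                                 snp_id, group_label)
                    continue
                except ValueError:
                    n_skipped += 1
                    continue
                rows.append((snp_id, cand["gene_id"], cand["distance"], beta, t, p))
            continue
        gc = g - g.mean()
        sxx = float(gc @ gc)
        if sxx == 0.0:
            n_skipped += len(snp_cand)
            logger.debug("skipping %s (monomorphic in %s group)", snp_id, group_label)
            continue
        Y = E[gi]
        Yc = Y - Y.mean(axis=1, keepdims=True)
        beta = (Yc @ gc) / sxx
        resid = Yc - beta[:, None] * gc[None, :]
        df = g.size - 2
        s2 = np.einsum("ij,ij->i", resid, resid) / df
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta / np.sqrt(s2 / sxx)
        p = 2.0 * stats.t.sf(np.abs(t), df)
        p = np.where(np.isfinite(t), np.maximum(p, _P_FLOOR), _P_FLOOR)
        t = np.where(np.isfinite(t), t, np.sign(beta) * np.inf)
        for (_, cand), b_, t_, p_ in zip(snp_cand.iterrows(), beta, t, p):
            rows.append((snp_id, cand["gene_id"], cand["distance"],
                         float(b_), float(t_), float(p_)))

    result = pd.DataFrame(
        rows, columns=["snp_id", "gene_id", "distance", "beta", "t_stat", "p_value"]
    )
    n_tested = len(result)
    if n_tested:
        result["fdr"] = bh_fdr(result["p_value"].to_numpy())
    else:
        result["fdr"] = pd.Series(dtype=float)
    result["group"] = group_label
    full = result.sort_values(
        ["p_value", "snp_id", "gene_id"], kind="mergesort"
    ).reset_index(drop=True)
    result = full[full["p_value"] < p_out_threshold].reset_index(drop=True)
    result.attrs["n_tested"] = n_tested
    result.attrs["n_skipped"] = n_skipped
    result.attrs["all_tested"] = full
    logger.info("%s group: %d pairs tested, %d skipped, %d below p<%g",
                group_label, n_tested, n_skipped, len(result), p_out_threshold)
    return result


def compare_groups(
    active_pairs: pd.DataFrame,
    inactive_pairs: pd.DataFrame,
    fdr_threshold: float = 0.01,
) -> EqtlComparison:
    """Split significant pairs into group-unique and shared sets.

    A pair is significant in a group when its BH FDR there is below
    ``fdr_threshold``; a pair absent from a group's scan (e.g. monomorphic)
    is not significant there. The three output sets are disjoint by
    (snp_id, gene_id).
    """
    def sig_keys(df: pd.DataFrame) -> set[tuple[str, str]]:
        if df.empty:
            return set()
        hit = df[df["fdr"] < fdr_threshold]
        return set(zip(hit["snp_id"], hit["gene_id"]))

    act, inact = sig_keys(active_pairs), sig_keys(inactive_pairs)

    def take(df: pd.DataFrame, keys: set[tuple[str, str]]) -> pd.DataFrame:
        if df.empty or not keys:
            return df.iloc[0:0]
        mask = [k in keys for k in zip(df["snp_id"], df["gene_id"])]
        return df[mask].reset_index(drop=True)

    return EqtlComparison(
        unique_to_active=take(active_pairs, act - inact),
        unique_to_inactive=take(inactive_pairs, inact - act),
        shared=take(active_pairs, act & inact),
        fdr_threshold=fdr_threshold,
    )
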