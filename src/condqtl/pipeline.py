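"""End-to-end orchestration of the condition-specific eQTL workflow.

Stage order: stratify the cohort by regulator activity; run the cis scan in
each group; keep pairs significant only in the active group; drop pairs
whose gene does not respond to regulator knockdown; find strong-LD partners
of the surviving SNPs and score allele-specific motif disruption where a
flank and PWM are provided; annotate same-TAD membership, promoter peak
overlap, and the clinical genotype association. Every stage's input/output
counts go into a machine-readable run manifest, and identical inputs produce
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import io as cio
from .annotate import (IntervalSet, carrier_status, genotype_feature_association,
                       maf_by_group, minor_allele, promoter_overlap, same_tad)
from .eqtl import GenotypeMatrix, compare_groups, scan_group
from .knockdown import downregulated_genes, filter_pairs_by_de
from .ldmotif import allele_delta, strong_ld_partners
from .simulate import SyntheticStudy
from .stratify import OmicsCohort, Thresholds, call_activity

logger = logging.getLogger(__name__)

NOT_EVALUATED = "not_evaluated"


@dataclass
class PipelineThresholds:
    """Every tunable cut of the workflow, defaulting to the study's values."""

    cnv: float = 0.5
    beta: float = 0.4
    expr: float | None = None          # None: cohort mean of the regulator
    cis_window_bp: int = 1_000_000
    p_out: float = 0.05
    fdr: float = 0.01
    de_difference: float = 1.0
    r2: float = 0.8
    ld_window_bp: int = 250_000
    promoter_upstream_bp: int = 2000
    promoter_downstream_bp: int = 500

    def __post_init__(self) -> None:
        if not 0 < self.p_out <= 1 or not 0 <= self.fdr <= 1:
            raise ValueError("p_out must be in (0,1] and fdr in [0,1]")
        if self.cis_window_bp < 0 or self.ld_window_bp < 0:
            raise ValueError("windows must be non-negative")


@dataclass
class PipelineConfig:
    """File paths plus thresholds for a file-driven run."""

    vcf: str
    expression: str
    cnv: str
    methylation: str
    promoter_cpgs: str
    genes: str
    knockdown: str
    knockdown_samples: str
    regulator: str = "SOX2"
    flank: str | None = None
    pfm: str | None = None
    tads: str | None = None
    peaks: str | None = None
    clinical: str | None = None
    thresholds: PipelineThresholds = field(default_factory=PipelineThresholds)
    de_filter: bool = True
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        thr = PipelineThresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=thr, **raw)


@dataclass
class PipelineResult:
    report: pd.DataFrame
    manifest: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.report.to_csv(out / "report.tsv", sep="\t", index=False,
                           float_format="%.10g")
        with open(out / "report.json", "w") as fh:
            json.dump(self.report.to_dict(orient="records"), fh, indent=2,
                      sort_keys=True, default=str)
            fh.write("\n")
        with open(out / "run_manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """File-driven run: load all inputs, delegate to :func:`run_stages`."""
    geno = cio.read_vcf(cfg.vcf)
    cohort = cio.read_cohort(cfg.expression, cfg.cnv, cfg.methylation,
                             cfg.promoter_cpgs)
    gene_positions = cio.read_gene_positions(cfg.genes)
    kd = cio.read_knockdown(cfg.knockdown, cfg.knockdown_samples)
    motif_info = None
    if cfg.flank and cfg.pfm:
        flanks = cio.read_fasta(cfg.flank)
        name, seq = next(iter(flanks.items()))
        meta = cio.parse_flank_header(name)
        motif_info = {"snp_id": meta["snp_id"], "flank": seq,
                      "offset": meta["offset"], "ref": meta["ref"],
                      "alt": meta["alt"], "pwm": cio.read_pfm(cfg.pfm)}
    tads = cio.read_bed(cfg.tads, require_disjoint=True) if cfg.tads else None
    peaks = cio.read_bed(cfg.peaks) if cfg.peaks else None
    clinical = (pd.read_csv(cfg.clinical, sep="\t", index_col=0)
                if cfg.clinical else None)
    result = run_stages(
        geno=geno, cohort=cohort, gene_positions=gene_positions,
        knockdown=kd, regulator=cfg.regulator, thresholds=cfg.thresholds,
        motif_info=motif_info, tads=tads, peaks=peaks, clinical=clinical,
        de_filter=cfg.de_filter,
    )
    if cfg.out_dir:
        result.write(cfg.out_dir)
    return result


def run_study(study: SyntheticStudy,
              thresholds: PipelineThresholds | None = None,
              de_filter: bool = True) -> PipelineResult:
    """In-memory run on a synthetic study bundle."""
    motif_info = {
        "snp_id": study.truth.motif_snp_id, "flank": study.flank,
        "offset": study.flank_offset, "ref": study.motif_ref,
        "alt": study.motif_alt, "pwm": study.pwm,
    }
    return run_stages(
        geno=study.genotypes, cohort=study.cohort,
        gene_positions=study.gene_positions, knockdown=study.knockdown,
        regulator="SOX2", thresholds=thresholds or PipelineThresholds(),
        motif_info=motif_info, tads=study.tads, peaks=study.peaks,
        clinical=study.clinical, de_filter=de_filter,
    )


def run_stages(
    geno: GenotypeMatrix,
    cohort: OmicsCohort,
    gene_positions: pd.DataFrame,
    knockdown,
    regulator: str,
    thresholds: PipelineThresholds,
    motif_info: dict | None = None,
    tads: IntervalSet | None = None,
    peaks: IntervalSet | None = None,
    clinical: pd.DataFrame | None = None,
    de_filter: bool = True,
) -> PipelineResult:
    thr = thresholds
    counts: dict[str, int] = {"patients": len(geno.patient_ids),
                              "snps": len(geno.variants),
                              "genes": len(gene_positions)}

    # 1. stratification -----------------------------------------------------
    partition = _stage("stratification")(call_activity)(
        cohort, regulator,
        Thresholds(expr=thr.expr, cnv=thr.cnv, beta=thr.beta))
    counts["active_patients"] = partition.n_active
    counts["inactive_patients"] = partition.n_inactive
    logger.info("stratification: %d active / %d inactive",
                partition.n_active, partition.n_inactive)

    # 2. per-group cis scans ------------------------------------------------
    expr = cohort.expression.drop(index=regulator, errors="ignore")
    scan = _stage("eqtl_scan")(scan_group)
    active_pairs = scan(geno, expr, partition.active_patients, gene_positions,
                        thr.cis_window_bp, thr.p_out, "active")
    inactive_pairs = scan(geno, expr, partition.inactive_patients,
                          gene_positions, thr.cis_window_bp, thr.p_out,
                          "inactive")
    counts["active_pairs_tested"] = active_pairs.attrs["n_tested"]
    counts["inactive_pairs_tested"] = inactive_pairs.attrs["n_tested"]
    counts["active_pairs_p_out"] = len(active_pairs)
    counts["inactive_pairs_p_out"] = len(inactive_pairs)

    # 3. group comparison ---------------------------------------------------
    comparison = _stage("comparison")(compare_groups)(
        active_pairs, inactive_pairs, thr.fdr)
    unique_active = comparison.unique_to_active
    counts["unique_to_active"] = len(unique_active)
    counts["unique_to_inactive"] = len(comparison.unique_to_inactive)
    counts["shared"] = len(comparison.shared)

    # 4. knockdown DE filter ------------------------------------------------
    if de_filter:
        de_genes = _stage("knockdown_de")(downregulated_genes)(
            knockdown, threshold=thr.de_difference)
        candidates = filter_pairs_by_de(unique_active, de_genes)
    else:
        de_genes = set()
        candidates = unique_active.reset_index(drop=True)
    counts["de_genes"] = len(de_genes)
    counts["candidates"] = len(candidates)
    logger.info("candidates after DE filter: %d", len(candidates))

    # 5. LD partners + motif, 6. annotation --------------------------------
    inactive_all = inactive_pairs.attrs.get("all_tested", inactive_pairs)
    inactive_lookup = {
        (s, g): (p, f) for s, g, p, f in zip(
            inactive_all["snp_id"], inactive_all["gene_id"],
            inactive_all["p_value"], inactive_all["fdr"])
    }
    kd_diff = None
    if de_filter:
        from .knockdown import combined_difference
        kd_diff = combined_difference(knockdown)

    clinical_assoc = _clinical_association(clinical)

    rows = []
    for _, pair in candidates.iterrows():
        row: dict = {
            "snp_id": pair["snp_id"], "gene_id": pair["gene_id"],
            "distance": pair["distance"],
            "beta_active": pair["beta"], "t_active": pair["t_stat"],
            "p_active": pair["p_value"], "fdr_active": pair["fdr"],
        }
        inact = inactive_lookup.get((pair["snp_id"], pair["gene_id"]))
        row["p_inactive"] = inact[0] if inact else NOT_EVALUATED
        row["fdr_inactive"] = inact[1] if inact else NOT_EVALUATED
        row["combined_difference"] = (
            float(kd_diff.get(pair["gene_id"])) if kd_diff is not None
            and pair["gene_id"] in kd_diff.index else NOT_EVALUATED)

        partners = _stage("ld_motif")(strong_ld_partners)(
            geno, [pair["snp_id"]], thr.r2, thr.ld_window_bp)
        row["ld_partners"] = ";".join(
            f"{p}(r2={res.r2:.3f},D'={res.D_prime:.3f})"
            for _, p, res in partners) or "none"

        row.update(_motif_fields(pair["snp_id"], partners, motif_info))
        row.update(_tad_fields(tads, geno, gene_positions, pair))
        row.update(_peak_fields(peaks, gene_positions, pair, thr))
        row["clinical_location_p"] = clinical_assoc.get("p", NOT_EVALUATED)
        row["clinical_method"] = clinical_assoc.get("method", NOT_EVALUATED)
        rows.append(row)

    report = pd.DataFrame(rows)
    if not report.empty:
        report = report.sort_values(
            ["fdr_active", "snp_id", "gene_id"], kind="mergesort"
        ).reset_index(drop=True)

    manifest = {
        "thresholds": asdict(thr),
        "regulator": regulator,
        "de_filter": de_filter,
        "stage_counts": counts,
        "stage_order": ["stratification", "eqtl_scan", "comparison",
                        "knockdown_de", "ld_motif", "annotation"],
    }
    return PipelineResult(report=report, manifest=manifest)


def _motif_fields(snp_id: str, partners, motif_info) -> dict:
    if motif_info is None:
        return {"motif_snp": NOT_EVALUATED, "motif_delta": NOT_EVALUATED,
                "motif_disrupted": NOT_EVALUATED}
    in_ld = {p for _, p, _ in partners} | {snp_id}
    if motif_info["snp_id"] not in in_ld:
        return {"motif_snp": NOT_EVALUATED, "motif_delta": NOT_EVALUATED,
                "motif_disrupted": NOT_EVALUATED}
    res = allele_delta(
        motif_info["flank"], motif_info["offset"], motif_info["ref"],
        motif_info["alt"], motif_info["pwm"], snp_id=motif_info["snp_id"])
    return {"motif_snp": res.snp_id, "motif_delta": res.delta,
            "motif_disrupted": res.disrupted}


def _tad_fields(tads, geno, gene_positions, pair) -> dict:
    if tads is None:
        return {"same_tad": NOT_EVALUATED, "tad_id": NOT_EVALUATED}
    var = geno.variants[geno.variants["id"] == pair["snp_id"]].iloc[0]
    gene = gene_positions[gene_positions["gene_id"] == pair["gene_id"]].iloc[0]
    flag, names = same_tad(
        tads, (var["chrom"], int(var["pos"]) - 1),
        (gene["chrom"], int(gene["tss"]) - 1))
    return {"same_tad": bool(flag), "tad_id": names[0] if names else "unassigned"}


def _peak_fields(peaks, gene_positions, pair, thr) -> dict:
    if peaks is None:
        return {"promoter_peaks": NOT_EVALUATED, "promoter_peak_overlap":
                NOT_EVALUATED}
    gene = gene_positions[gene_positions["gene_id"] == pair["gene_id"]].iloc[0]
    hits = promoter_overlap(
        peaks, (gene["chrom"], int(gene["tss"]), gene.get("strand", "+")),
        thr.promoter_upstream_bp, thr.promoter_downstream_bp)
    return {"promoter_peaks": ";".join(hits["name"]) or "none",
            "promoter_peak_overlap": bool(len(hits))}


def _clinical_association(clinical: pd.DataFrame | None) -> dict:
    if clinical is None or "carrier" not in getattr(clinical, "columns", []):
        return {}
    feature = "side" if "side" in clinical.columns else (
        "location" if "location" in clinical.columns else None)
    if feature is None:
        return {}
    try:
        res = genotype_feature_association(clinical, feature)
    except ValueError:
        return {}
    return {"p": res.p_value, "method": res.method, "feature": feature}
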