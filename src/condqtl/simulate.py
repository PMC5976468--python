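"""Synthetic cohorts with a planted, regulator-conditional cis-eQTL.

The generator emulates the study design end to end: a patient cohort with
three correlated regulator-activity readouts (expression, copy-number
segment mean, promoter methylation), Hardy-Weinberg genotypes including a
perfect-LD tag/indel SNP pair, gene expression carrying an additive dosage
effect on one target gene in regulator-active patients only, paired
control/siRNA knockdown profiles for two cell lines in which the target gene
responds, a motif PWM plus a 59-nt flank in which the reference allele of
the indel completes the motif, TADs tiling the chromosome with the planted
SNP and target TSS sharing one, a regulator peak on the target promoter, and
a clinical table. All randomness flows from ``SimConfig.seed`` and identical
configs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .annotate import IntervalSet
from .eqtl import GenotypeMatrix
from .knockdown import KnockdownExperiment
from .ldmotif import PWM, allele_delta
from .stratify import OmicsCohort

REGULATOR = "SOX2"
N_PROMOTER_CPGS = 14
FLANK_RADIUS = 29  # nt on each side of the variant -> 59-nt ref flank


@dataclass
class SimConfig:
    """Study-design parameters for one synthetic cohort.

    Defaults encode the scan's reference conditions: 300 patients split
    evenly into active/inactive (150 per group), planted-SNP minor allele
    frequency 0.3 (midpoint of ``maf_range``), a conditional effect of 0.8
    expression units per alt allele against unit residual noise, and a
    single 10-Mb chromosome.
    """

    n_patients: int = 300
    frac_active: float = 0.5
    n_snps: int = 30
    n_genes: int = 15
    maf_range: tuple[float, float] = (0.1, 0.5)
    effect_beta: float = 0.8
    noise_sd: float = 1.0
    n_null_pairs: int = 100
    seed: int = 0
    chrom_length: int = 10_000_000
    chrom: str = "chr8"
    active_shift: float = 1.0        # target-gene mean shift in active patients
    missing_rate: float = 0.0        # genotype missingness (off by default)

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not 0.0 < self.frac_active < 1.0:
            raise ValueError("frac_active must lie in (0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5] with lo <= hi")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        for name in ("n_snps", "n_genes", "n_null_pairs", "chrom_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")


@dataclass
class PlantedTruth:
    """Ground truth of the planted conditional eQTL."""

    tag_snp_id: str
    motif_snp_id: str
    target_gene_id: str
    beta_active: float
    beta_inactive: float = 0.0
    tad_id: str = ""


@dataclass
class SyntheticStudy:
    """Bundle of every synthetic input the pipeline consumes."""

    config: SimConfig
    genotypes: GenotypeMatrix
    truth: PlantedTruth
    cohort: OmicsCohort
    true_active: pd.Series          # bool per patient
    gene_positions: pd.DataFrame    # gene_id, chrom, tss, strand
    knockdown: KnockdownExperiment
    flank: str
    flank_offset: int               # 0-based offset of the variant in the flank
    motif_ref: str
    motif_alt: str
    pwm: PWM
    tads: IntervalSet
    peaks: IntervalSet
    clinical: pd.DataFrame


def _planted_layout(cfg: SimConfig) -> dict:
    """Deterministic genomic layout of the planted elements."""
    tag_pos = int(cfg.chrom_length * 0.40)
    return {
        "tag_pos": tag_pos,
        "motif_pos": tag_pos + min(50_000, cfg.chrom_length // 20),
        "target_tss": tag_pos + min(400_000, cfg.chrom_length // 4),
    }


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(cfg: SimConfig) -> tuple[GenotypeMatrix, PlantedTruth]:
    """Hardy-Weinberg genotypes with a planted perfect-LD tag/indel pair.

    Each SNP's two haplotypes per patient are independent Bernoulli(maf)
    draws, so dosages are Binomial(2, maf). The designated tag SNP and motif
    SNP share an identical haplotype (hence dosage) vector — perfect LD,
    r^2 = 1 — and the motif SNP's alt allele is a one-base insertion (T ->
    TA). Positions are strictly increasing along the chromosome.
    """
    rng = np.random.default_rng(cfg.seed)
    layout = _planted_layout(cfg)
    n, m = cfg.n_patients, cfg.n_snps

    reserved = {layout["tag_pos"], layout["motif_pos"]}
    n_bg = max(m - 2, 0)
    positions: set[int] = set()
    while len(positions) < n_bg:
        draw = rng.integers(1, cfg.chrom_length + 1, size=n_bg - len(positions))
        positions.update(int(p) for p in draw if int(p) not in reserved)
    all_pos = sorted(positions | reserved)

    lo, hi = cfg.maf_range
    planted_maf = (lo + hi) / 2
    mafs = {p: float(rng.uniform(lo, hi)) for p in all_pos}
    mafs[layout["tag_pos"]] = planted_maf
    mafs[layout["motif_pos"]] = planted_maf

    # tag haplotypes first so the planted pair is identical by construction;
    # redrawn (deterministically) if a draw lands monomorphic
    tag_hap = rng.binomial(1, planted_maf, size=2 * n)
    while tag_hap.sum() in (0, 2 * n):
        tag_hap = rng.binomial(1, planted_maf, size=2 * n)

    haps = np.empty((len(all_pos), 2 * n), dtype=np.int8)
    ids, refs, alts = [], [], []
    bases = np.array(list("ACGT"))
    k = 0
    for i, pos in enumerate(all_pos):
        if pos == layout["tag_pos"]:
            ids.append("snp_tag")
            refs.append("G")
            alts.append("T")
            haps[i] = tag_hap
        elif pos == layout["motif_pos"]:
            ids.append("snp_motif")
            refs.append("T")
            alts.append("TA")   # insertion relative to ref
            haps[i] = tag_hap
        else:
            k += 1
            ids.append(f"snp{k:04d}")
            ref, alt = rng.choice(4, size=2, replace=False)
            refs.append(str(bases[ref]))
            alts.append(str(bases[alt]))
            haps[i] = rng.binomial(1, mafs[pos], size=2 * n)

    dosages = haps[:, 0::2] + haps[:, 1::2]
    dosages = dosages.astype(float)
    if cfg.missing_rate > 0:
        mask = rng.random(dosages.shape) < cfg.missing_rate
        dosages[mask] = np.nan
    variants = pd.DataFrame({
        "id": ids, "chrom": cfg.chrom, "pos": all_pos, "ref": refs, "alt": alts,
    })
    geno = GenotypeMatrix(
        dosages, variants,
        [f"patient{i:04d}" for i in range(n)],
        haplotypes=haps,
    )
    truth = PlantedTruth(
        tag_snp_id="snp_tag", motif_snp_id="snp_motif",
        target_gene_id="gene000",
        beta_active=cfg.effect_beta, beta_inactive=0.0,
    )
    return geno, truth


# ---------------------------------------------------------------------------
# activity omics
# ---------------------------------------------------------------------------

def simulate_activity_omics(cfg: SimConfig) -> tuple[OmicsCohort, pd.Series]:
    """Cohort omics whose three activity criteria agree on a planted split.

    ``round(frac_active * n_patients)`` patients are truly active. Each
    criterion observes the shared activity state through its own noise, so
    the three flags are correlated but not identical and some patients meet
    only one or two criteria. Active patients have regulator expression well
    above the cohort mean, CNV segment means above 0.5, and promoter-CpG
    betas concentrated below 0.4; betas are clipped to [0, 1].

    The returned cohort's expression matrix holds only the regulator's row;
    :func:`simulate_expression` supplies the scanned genes.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    n = cfg.n_patients
    patients = [f"patient{i:04d}" for i in range(n)]
    n_active = int(round(cfg.frac_active * n))
    n_active = min(max(n_active, 1), n - 1)
    active = np.zeros(n, dtype=bool)
    active[rng.permutation(n)[:n_active]] = True

    # regulator log2 expression: bimodal around the cohort mean
    expr = np.where(active,
                    rng.normal(11.8, 0.45, n),
                    rng.normal(10.0, 0.45, n))
    cnv = np.where(active,
                   rng.normal(1.0, 0.22, n),
                   rng.normal(0.05, 0.22, n))
    beta_center = np.where(active, 0.22, 0.55)
    meth = np.clip(
        beta_center[None, :] + rng.normal(0.0, 0.07, (N_PROMOTER_CPGS, n)),
        0.0, 1.0)

    promoter_cpgs = [f"cg{i:08d}" for i in range(N_PROMOTER_CPGS)]
    cohort = OmicsCohort(
        expression=pd.DataFrame(expr[None, :], index=[REGULATOR],
                                columns=patients),
        cnv=pd.DataFrame(cnv[None, :], index=[f"{REGULATOR}_locus"],
                         columns=patients),
        methylation=pd.DataFrame(meth, index=promoter_cpgs, columns=patients),
        promoter_cpgs=promoter_cpgs,
    )
    return cohort, pd.Series(active, index=patients, name="true_active")


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_gene_positions(cfg: SimConfig, truth: PlantedTruth) -> pd.DataFrame:
    """TSS layout: the target gene at its planted position, the rest uniform."""
    rng = np.random.default_rng(cfg.seed + 2)
    layout = _planted_layout(cfg)
    taken = {layout["target_tss"]}
    tss: list[int] = []
    while len(tss) < cfg.n_genes - 1:
        draw = int(rng.integers(1, cfg.chrom_length + 1))
        if draw not in taken:
            taken.add(draw)
            tss.append(draw)
    genes = [truth.target_gene_id] + [f"gene{i:03d}" for i in range(1, cfg.n_genes)]
    positions = [layout["target_tss"]] + tss
    strands = ["+"] + [str(s) for s in rng.choice(["+", "-"], cfg.n_genes - 1)]
    return pd.DataFrame({"gene_id": genes, "chrom": cfg.chrom,
                         "tss": positions, "strand": strands})


def simulate_expression(
    geno: GenotypeMatrix,
    labels: pd.Series,
    truth: PlantedTruth,
    cfg: SimConfig,
) -> pd.DataFrame:
    """Gene x patient expression with the conditional planted effect.

    The target gene follows ``mu + beta_active * dosage`` in active patients
    and ``mu + beta_inactive * dosage`` in inactive ones, plus an
    ``active_shift`` mean offset for active patients and N(0, noise_sd)
    noise. Null genes are baseline plus noise with no genotype term.
    """
    if list(labels.index) != list(geno.patient_ids):
        raise ValueError("patient sets of genotypes and labels are misaligned")
    rng = np.random.default_rng(cfg.seed + 3)
    n = len(geno.patient_ids)
    genes = [truth.target_gene_id] + [f"gene{i:03d}" for i in range(1, cfg.n_genes)]
    base = rng.normal(8.0, 1.0, cfg.n_genes)
    expr = base[:, None] + rng.normal(0.0, cfg.noise_sd, (cfg.n_genes, n))

    dosage = np.nan_to_num(geno.dosage(truth.tag_snp_id), nan=0.0)
    active = labels.to_numpy(bool)
    beta = np.where(active, truth.beta_active, truth.beta_inactive)
    expr[0] += beta * dosage + cfg.active_shift * active
    return pd.DataFrame(expr, index=genes, columns=geno.patient_ids)


# ---------------------------------------------------------------------------
# knockdown
# ---------------------------------------------------------------------------

def simulate_knockdown(
    truth: PlantedTruth,
    cfg: SimConfig,
    cell_lines: tuple[str, str] = ("H520", "LK2"),
    per_line_effect: float = 0.75,
    noise_sd: float = 0.05,
) -> KnockdownExperiment:
    """Paired control/siRNA profiles in which only the target gene responds.

    The target gene's control-minus-siRNA difference is ``per_line_effect``
    in each cell line (combined difference 1.5 > 1.0 by default); null
    genes differ only by noise centered at zero.
    """
    rng = np.random.default_rng(cfg.seed + 4)
    genes = [truth.target_gene_id] + [f"gene{i:03d}" for i in range(1, cfg.n_genes)]
    base = rng.normal(0.0, 1.0, cfg.n_genes)
    cols, names, meta = [], [], []
    for line in cell_lines:
        ctrl = base + rng.normal(0.0, noise_sd, cfg.n_genes)
        sirna = base + rng.normal(0.0, noise_sd, cfg.n_genes)
        sirna[0] = ctrl[0] - per_line_effect
        for cond, vals in (("control", ctrl), ("siRNA", sirna)):
            name = f"{line}_{cond}"
            cols.append(vals)
            names.append(name)
            meta.append({"sample": name, "cell_line": line, "condition": cond})
    expr = pd.DataFrame(np.column_stack(cols), index=genes, columns=names)
    return KnockdownExperiment(expr, pd.DataFrame(meta))


# ---------------------------------------------------------------------------
# sequence and PWM
# ---------------------------------------------------------------------------

def simulate_sequence_and_pwm(
    truth: PlantedTruth,
    cfg: SimConfig,
) -> tuple[str, int, PWM]:
    """59-nt flank centered on the motif SNP plus a motif the ref completes.

    The PWM is a sharply peaked HMG-box-like matrix (consensus CATTGTT).
    The flank carries one consensus instance positioned so the variant's
    reference base is the instance's fourth position; the alt allele (an
    inserted A) breaks the instance and shifts everything downstream. The
    construction is verified at generation time: the reference allele must
    out-score the alternative, otherwise the background is redrawn.
    """
    rng = np.random.default_rng(cfg.seed + 5)
    consensus = "CATTGTT"
    width = len(consensus)
    counts = np.full((4, width), 4.0)
    for i, base in enumerate(consensus):
        counts["ACGT".index(base), i] = 88.0
    pwm = PWM(counts, name=f"{REGULATOR}_motif")

    offset = FLANK_RADIUS                 # variant at the flank center
    motif_start = offset - 3              # ref base is consensus position 4
    for _ in range(64):
        flank = list(rng.choice(list("ACGT"), 2 * FLANK_RADIUS + 1))
        flank[motif_start:motif_start + width] = list(consensus)
        seq = "".join(flank)
        assert seq[offset] == "T"         # consensus[3]
        res = allele_delta(seq, offset, "T", "TA", pwm,
                           snp_id=truth.motif_snp_id, require_overlap=True)
        if res.delta > 0:
            return seq, offset, pwm
    raise RuntimeError("could not construct a ref-stronger flank")  # pragma: no cover


# ---------------------------------------------------------------------------
# intervals
# ---------------------------------------------------------------------------

def simulate_intervals(
    truth: PlantedTruth,
    cfg: SimConfig,
    gene_positions: pd.DataFrame,
    variants: pd.DataFrame,
) -> tuple[IntervalSet, IntervalSet]:
    """TADs tiling the chromosome plus regulator peaks.

    TAD boundaries are laid out so the planted tag SNP, motif SNP and target
    TSS fall inside a single TAD; the rest of the chromosome is tiled with
    ~1-Mb domains. One peak sits on the target gene's promoter; a handful of
    decoys are placed far from every gene.
    """
    layout = _planted_layout(cfg)
    lo = min(layout["tag_pos"], layout["motif_pos"], layout["target_tss"])
    hi = max(layout["tag_pos"], layout["motif_pos"], layout["target_tss"])
    tad_start = max(lo - 50_000, 0)
    tad_end = min(hi + 50_000, cfg.chrom_length)

    boundaries = [0]
    step = max(cfg.chrom_length // 10, 1)
    pos = 0
    while pos < tad_start:
        pos += step
        boundaries.append(min(pos, tad_start))
    if boundaries[-1] != tad_start:
        boundaries.append(tad_start)
    boundaries.append(tad_end)
    pos = tad_end
    while pos < cfg.chrom_length:
        pos += step
        boundaries.append(min(pos, cfg.chrom_length))
    boundaries = sorted(set(boundaries))

    rows = []
    for i, (s, e) in enumerate(zip(boundaries[:-1], boundaries[1:])):
        name = f"tad{i:03d}"
        if s == tad_start and e == tad_end:
            truth.tad_id = name
        rows.append({"chrom": cfg.chrom, "start": s, "end": e, "name": name})
    tads = IntervalSet(pd.DataFrame(rows), require_disjoint=True)

    target_tss = layout["target_tss"]
    peak_rows = [{
        "chrom": cfg.chrom,
        "start": max(target_tss - 1 - 500, 0),   # TSS is 1-based
        "end": target_tss - 1 + 200,
        "name": "peak_target_promoter",
    }]
    # decoy peaks in the first chromosome tenth, away from the planted region
    decoy_gap = max(cfg.chrom_length // 50, 1000)
    for j in range(3):
        start = j * decoy_gap + 10
        peak_rows.append({"chrom": cfg.chrom, "start": start,
                          "end": start + 300, "name": f"peak_decoy{j}"})
    peaks = IntervalSet(pd.DataFrame(peak_rows))
    return tads, peaks


# ---------------------------------------------------------------------------
# clinical table
# ---------------------------------------------------------------------------

def simulate_clinical(
    geno: GenotypeMatrix,
    truth: PlantedTruth,
    cfg: SimConfig,
) -> pd.DataFrame:
    """Clinical covariates with a carrier-linked tumor-location skew.

    Race, tumor location, stage and age at diagnosis per patient. Carriers
    of the tag SNP's minor allele are biased toward right-sided tumors so
    the genotype-location association is detectable on large cohorts.
    """
    rng = np.random.default_rng(cfg.seed + 6)
    n = len(geno.patient_ids)
    dosage = np.nan_to_num(geno.dosage(truth.tag_snp_id), nan=0.0)
    carrier = dosage >= 1

    race = rng.choice(["White", "Black or African American", "Asian"],
                      size=n, p=[0.76, 0.18, 0.06])
    right_prob = np.where(carrier, 0.76, 0.53)
    side = np.where(rng.random(n) < right_prob, "Right", "Left")
    lobe = rng.choice(["Lower", "Upper"], size=n)
    location = np.char.add(np.char.add(side.astype(str), "-"), lobe.astype(str))
    stage = rng.choice(["i", "ii", "iii", "iv"], size=n,
                       p=[0.49, 0.32, 0.17, 0.02])
    age = np.clip(np.round(rng.normal(67.0, 9.0, n)), 39, 90).astype(int)
    return pd.DataFrame({
        "patient_id": geno.patient_ids,
        "race": race, "location": location, "side": side,
        "stage": stage, "age": age,
        "carrier": carrier,
    }).set_index("patient_id")


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

def simulate_study(cfg: SimConfig) -> SyntheticStudy:
    """Generate every input layer of the analysis for one configuration."""
    geno, truth = simulate_genotypes(cfg)
    cohort, labels = simulate_activity_omics(cfg)
    gene_positions = simulate_gene_positions(cfg, truth)
    expr = simulate_expression(geno, labels, truth, cfg)
    full_expr = pd.concat([cohort.expression, expr])
    cohort = OmicsCohort(
        expression=full_expr, cnv=cohort.cnv, methylation=cohort.methylation,
        promoter_cpgs=cohort.promoter_cpgs,
    )
    kd = simulate_knockdown(truth, cfg)
    flank, flank_offset, pwm = simulate_sequence_and_pwm(truth, cfg)
    tads, peaks = simulate_intervals(truth, cfg, gene_positions, geno.variants)
    clinical = simulate_clinical(geno, truth, cfg)
    motif_row = geno.variants[geno.variants["id"] == truth.motif_snp_id].iloc[0]
    return SyntheticStudy(
        config=cfg, genotypes=geno, truth=truth, cohort=cohort,
        true_active=labels, gene_positions=gene_positions, knockdown=kd,
        flank=flank, flank_offset=flank_offset,
        motif_ref=motif_row["ref"], motif_alt=motif_row["alt"], pwm=pwm,
        tads=tads, peaks=peaks, clinical=clinical,
    )


def null_config(seed: int = 0, n_pairs: int = 2000, n_patients: int = 300) -> SimConfig:
    """Config for type-I-error calibration: no genotype effects anywhere.

    All SNPs and genes share a 1-Mb chromosome so every SNP-gene pair is a
    cis candidate; SNP and gene counts are chosen to give at least
    ``n_pairs`` candidate pairs.
    """
    n_snps = 25
    n_genes = int(np.ceil(n_pairs / n_snps))
    return SimConfig(
        n_patients=n_patients, frac_active=0.5, n_snps=n_snps, n_genes=n_genes,
        effect_beta=0.0, active_shift=0.0, noise_sd=1.0,
        n_null_pairs=n_pairs, seed=seed, chrom_length=1_000_000,
    )


def config_to_dict(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    d["maf_range"] = list(d["maf_range"])
    return d
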