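"""Readers and writers for the standard-format inputs and fixtures.

All coordinate conversions live here: VCF and TSS positions are 1-based on
disk and converted to the package's 0-based half-open convention only where
interval arithmetic needs it; BED files are consumed and produced natively
0-based half-open.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

from .annotate import IntervalSet
from .eqtl import GenotypeMatrix
from .knockdown import KnockdownExperiment
from .ldmotif import PWM
from .simulate import PlantedTruth, SyntheticStudy, config_to_dict
from .stratify import OmicsCohort

# ---------------------------------------------------------------------------
# TSV matrices
# ---------------------------------------------------------------------------

def write_matrix_tsv(df: pd.DataFrame, path) -> None:
    """Row-feature x column-sample matrix with a header of sample IDs."""
    df.to_csv(path, sep="\t", index_label="id", float_format="%.10g")


def read_matrix_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return df


def read_gene_positions(path) -> pd.DataFrame:
    """Gene annotation TSV with columns gene_id, chrom, tss[, strand]."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "tss"}
    if not required.issubset(df.columns):
        raise ValueError(f"gene annotation needs columns {sorted(required)}")
    if "strand" not in df.columns:
        df["strand"] = "+"
    return df


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(geno: GenotypeMatrix, path, phased: bool = False) -> None:
    """Minimal VCF v4.2 with GT genotypes; '|' separators when phased."""
    if phased and geno.haplotypes is None:
        raise ValueError("phased output requested but no haplotypes present")
    sep = "|" if phased else "/"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(geno.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.patient_ids) + "\n")
        for i, row in geno.variants.iterrows():
            calls = []
            for j in range(len(geno.patient_ids)):
                if phased:
                    a, b = geno.haplotypes[i, 2 * j], geno.haplotypes[i, 2 * j + 1]
                    calls.append(f"{a}{sep}{b}")
                else:
                    d = geno.dosages[i, j]
                    if np.isnan(d):
                        calls.append("./.")
                    else:
                        calls.append({0: "0/0", 1: "0/1", 2: "1/1"}[int(d)])
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t"
                     f"{row['alt']}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n")


def read_vcf(path) -> GenotypeMatrix:
    """Load a biallelic VCF into a dosage matrix (haplotypes kept if phased)."""
    vcf = VCF(str(path))
    patients = list(vcf.samples)
    rows, dosages, haps = [], [], []
    all_phased = True
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"multi-allelic site {var.ID} not supported")
        rows.append({"id": var.ID or f"{var.CHROM}:{var.POS}",
                     "chrom": var.CHROM, "pos": var.POS,
                     "ref": var.REF, "alt": var.ALT[0]})
        dose, hap = [], []
        for call in var.genotypes:
            a, b, phased = call[0], call[1], call[2]
            if a < 0 or b < 0:
                dose.append(np.nan)
                hap.extend([0, 0])
                all_phased = False
            else:
                dose.append(float(a + b))
                hap.extend([a, b])
                all_phased = all_phased and bool(phased)
        dosages.append(dose)
        haps.append(hap)
    return GenotypeMatrix(
        np.array(dosages, dtype=float),
        pd.DataFrame(rows),
        patients,
        haplotypes=np.array(haps, dtype=np.int8) if all_phased else None,
    )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_bed(intervals: IntervalSet, path) -> None:
    intervals.intervals.to_csv(
        path, sep="\t", header=False, index=False,
        columns=["chrom", "start", "end", "name"])


def read_bed(path, require_disjoint: bool = False) -> IntervalSet:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name"],
                     dtype={"chrom": str})
    if df["name"].isna().any():
        df["name"] = [f"iv{i}" for i in range(len(df))]
    return IntervalSet(df, require_disjoint=require_disjoint)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# PFM / JASPAR
# ---------------------------------------------------------------------------

def write_pfm(pwm: PWM, path) -> None:
    """Four labeled count rows (A/C/G/T), whitespace-separated."""
    with open(path, "w") as fh:
        fh.write(f">{pwm.name}\n")
        for base, row in zip("ACGT", pwm.counts):
            fh.write(base + "  " + "  ".join(f"{v:g}" for v in row) + "\n")


def read_pfm(path, pseudocount: float = 0.8) -> PWM:
    """Read the PFM text format or a minimal JASPAR-style file.

    Accepts an optional ``>name`` header and rows like ``A 1 2 3`` or
    ``A [ 1 2 3 ]``.
    """
    name = "motif"
    rows: dict[str, list[float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                continue
            base = line[0].upper()
            if base not in "ACGT":
                raise ValueError(f"unexpected PFM row: {line!r}")
            body = line[1:].replace(":", " ").replace("[", " ").replace("]", " ")
            rows[base] = [float(x) for x in body.split()]
    if set(rows) != set("ACGT"):
        raise ValueError("PFM must contain exactly the rows A, C, G, T")
    counts = np.array([rows[b] for b in "ACGT"])
    return PWM(counts, name=name, pseudocount=pseudocount)


# ---------------------------------------------------------------------------
# study fixtures
# ---------------------------------------------------------------------------

def write_truth(truth: PlantedTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.__dict__, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_truth(path) -> PlantedTruth:
    with open(path) as fh:
        return PlantedTruth(**json.load(fh))


def write_study(study: SyntheticStudy, outdir) -> dict[str, str]:
    """Write every fixture of a synthetic study; returns a path manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "expression": out / "expression.tsv",
        "cnv": out / "cnv.tsv",
        "methylation": out / "methylation.tsv",
        "promoter_cpgs": out / "promoter_cpgs.txt",
        "genes": out / "genes.tsv",
        "knockdown": out / "knockdown.tsv",
        "knockdown_samples": out / "knockdown_samples.tsv",
        "flank": out / "flank.fa",
        "pfm": out / "motif.pfm",
        "tads": out / "tads.bed",
        "peaks": out / "peaks.bed",
        "clinical": out / "clinical.tsv",
        "truth": out / "truth.json",
        "config": out / "sim_config.json",
    }
    write_vcf(study.genotypes, paths["vcf"],
              phased=study.genotypes.haplotypes is not None)
    write_matrix_tsv(study.cohort.expression, paths["expression"])
    write_matrix_tsv(study.cohort.cnv, paths["cnv"])
    write_matrix_tsv(study.cohort.methylation, paths["methylation"])
    Path(paths["promoter_cpgs"]).write_text(
        "\n".join(study.cohort.promoter_cpgs) + "\n")
    study.gene_positions.to_csv(paths["genes"], sep="\t", index=False)
    write_matrix_tsv(study.knockdown.expression, paths["knockdown"])
    study.knockdown.samples.to_csv(paths["knockdown_samples"], sep="\t",
                                   index=False)
    flank_name = (f"{study.truth.motif_snp_id}|offset={study.flank_offset}"
                  f"|ref={study.motif_ref}|alt={study.motif_alt}")
    write_fasta({flank_name: study.flank}, paths["flank"])
    write_pfm(study.pwm, paths["pfm"])
    write_bed(study.tads, paths["tads"])
    write_bed(study.peaks, paths["peaks"])
    study.clinical.to_csv(paths["clinical"], sep="\t")
    write_truth(study.truth, paths["truth"])
    with open(paths["config"], "w") as fh:
        json.dump(config_to_dict(study.config), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {k: str(v) for k, v in paths.items()}


def read_knockdown(expr_path, samples_path) -> KnockdownExperiment:
    return KnockdownExperiment(
        read_matrix_tsv(expr_path),
        pd.read_csv(samples_path, sep="\t"),
    )


def read_cohort(expr_path, cnv_path, meth_path, promoter_cpgs_path) -> OmicsCohort:
    cpgs = [ln.strip() for ln in Path(promoter_cpgs_path).read_text().splitlines()
            if ln.strip()]
    return OmicsCohort(
        expression=read_matrix_tsv(expr_path),
        cnv=read_matrix_tsv(cnv_path),
        methylation=read_matrix_tsv(meth_path),
        promoter_cpgs=cpgs,
    )


def parse_flank_header(name: str) -> dict:
    """Recover variant placement from a flank FASTA record ID.

    Record IDs written by :func:`write_study` look like
    ``snp_motif|offset=29|ref=T|alt=TA``.
    """
    parts = name.split("|")
    out = {"snp_id": parts[0]}
    for p in parts[1:]:
        k, v = p.split("=", 1)
        out[k] = int(v) if k == "offset" else v
    return out
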