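"""Linkage disequilibrium and allele-specific motif-disruption scoring.

Two LD routes are provided: the definitional haplotype-frequency route when
phased haplotypes are available, and a two-locus EM estimator that recovers
haplotype frequencies from unphased genotype dosages (the double heterozygote
is the only ambiguous configuration). Motif scoring is log2-odds PWM scanning
over both strands, with indel alleles handled by re-scanning the substituted
sequence so that downstream placement shifts are accounted for.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

@dataclass
class LDResult:
    """Pairwise LD summary between two biallelic loci.

    ``D`` is the haplotype-frequency covariance p_AB - p_A p_B, ``D_prime``
    its normalization to the admissible bound, and ``r2`` the squared allele
    correlation. ``n`` is the number of haplotypes (phased route) or
    individuals (EM route); ``method`` records which route produced it.
    """

    snp_a: str
    snp_b: str
    D: float
    D_prime: float
    r2: float
    n: int
    method: str = "haplotype"
    converged: bool = True
    ambiguous: bool = False


def _ld_from_freqs(p_ab: float, p_a: float, p_b: float) -> tuple[float, float, float]:
    D = p_ab - p_a * p_b
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    if denom <= 0:
        raise ValueError("monomorphic locus: LD undefined")
    r2 = D * D / denom
    if D > 0:
        dmax = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    elif D < 0:
        dmax = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    else:
        dmax = 1.0
    d_prime = D / dmax if dmax > 0 else 0.0
    return D, d_prime, r2


def ld_from_haplotypes(hap_a, hap_b, snp_a: str = "a", snp_b: str = "b") -> LDResult:
    """D, D' and r2 from two aligned binary haplotype vectors.

    Vectors are 0/1 indicators of the focal (alt) allele, one entry per
    haplotype. Both loci must be polymorphic.
    """
    a = np.asarray(hap_a, dtype=float)
    b = np.asarray(hap_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("haplotype vectors must be equal-length 1-D")
    if a.size < 2:
        raise ValueError("need >= 2 haplotypes")
    p_a, p_b = float(a.mean()), float(b.mean())
    p_ab = float((a * b).mean())
    D, d_prime, r2 = _ld_from_freqs(p_ab, p_a, p_b)
    return LDResult(snp_a, snp_b, D, d_prime, r2, n=a.size, method="haplotype")


def em_haplotype_freq(
    geno_a,
    geno_b,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> tuple[np.ndarray, dict]:
    """Two-locus EM haplotype-frequency estimate from unphased dosages.

    Returns frequencies ``[p_AB, p_Ab, p_aB, p_ab]`` where the capital letter
    denotes the alt allele at each locus, plus an info dict with the
    log-likelihood trajectory, iteration count, a convergence flag, and an
    ambiguity flag raised when every individual is doubly heterozygous (the
    likelihood is then symmetric and the equilibrium start decides the mode).

    Initialization is at linkage equilibrium (product of allele
    frequencies), which is deterministic and documented.
    """
    ga = np.asarray(geno_a, dtype=float)
    gb = np.asarray(geno_b, dtype=float)
    ok = ~(np.isnan(ga) | np.isnan(gb))
    ga, gb = ga[ok], gb[ok]
    n = ga.size
    if n < 2:
        raise ValueError("need >= 2 individuals")
    counts = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            counts[i, j] = np.sum((ga == i) & (gb == j))

    p_a = ga.sum() / (2 * n)
    p_b = gb.sum() / (2 * n)
    # order: AB, Ab, aB, ab  (A/B = alt allele present on the haplotype)
    f = np.array([p_a * p_b, p_a * (1 - p_b), (1 - p_a) * p_b,
                  (1 - p_a) * (1 - p_b)])
    f = np.clip(f, 1e-12, None)
    f /= f.sum()

    n_dh = counts[1, 1]
    ambiguous = n_dh == n

    def loglik(fr: np.ndarray) -> float:
        ll = 0.0
        for i in range(3):
            for j in range(3):
                if counts[i, j] == 0:
                    continue
                ll += counts[i, j] * np.log(_geno_prob(fr, i, j))
        return ll

    lls = [loglik(f)]
    converged = False
    for _ in range(max_iter):
        # E-step: only (1,1) genotypes are phase-ambiguous
        hap_counts = np.zeros(4)
        # unambiguous contributions: genotype (i,j) carries a determined
        # number of each haplotype except for the double heterozygote
        for i in range(3):
            for j in range(3):
                c = counts[i, j]
                if c == 0 or (i == 1 and j == 1):
                    continue
                hap_counts += c * _determined_haps(i, j)
        if n_dh:
            w_cis = f[0] * f[3]          # AB/ab
            w_trans = f[1] * f[2]        # Ab/aB
            tot = w_cis + w_trans
            frac = 0.5 if tot == 0 else w_cis / tot
            hap_counts += n_dh * np.array([frac, 1 - frac, 1 - frac, frac])
        new = hap_counts / (2 * n)
        new = np.clip(new, 0.0, None)
        new /= new.sum()
        lls.append(loglik(np.clip(new, 1e-300, None)))
        delta = np.max(np.abs(new - f))
        f = new
        if delta < tol:
            converged = True
            break
    info = {
        "loglik": np.array(lls),
        "n_iter": len(lls) - 1,
        "converged": converged,
        "ambiguous": bool(ambiguous),
        "n": n,
    }
    return f, info


def _determined_haps(i: int, j: int) -> np.ndarray:
    """Haplotype counts [AB, Ab, aB, ab] carried by genotype (i, j) != (1,1)."""
    # locus A contributes i alt alleles, locus B contributes j; with at most
    # one heterozygous locus the pairing is unique: alt-alt haplotypes first
    ab = min(i, j)
    a_only = i - ab
    b_only = j - ab
    neither = 2 - ab - a_only - b_only
    return np.array([ab, a_only, b_only, neither], dtype=float)


def _geno_prob(f: np.ndarray, i: int, j: int) -> float:
    """P(genotype pair (i, j)) under HWE given haplotype frequencies."""
    p_ab, p_a_, p_b_, p__ = f
    h = {(1, 1): p_ab, (1, 0): p_a_, (0, 1): p_b_, (0, 0): p__}
    prob = 0.0
    for (a1, b1), f1 in h.items():
        for (a2, b2), f2 in h.items():
            if a1 + a2 == i and b1 + b2 == j:
                prob += f1 * f2
    return max(prob, 1e-300)


def ld_from_genotypes(geno_a, geno_b, snp_a: str = "a", snp_b: str = "b",
                      **em_kwargs) -> LDResult:
    """LD via EM haplotype frequencies on unphased dosage vectors."""
    f, info = em_haplotype_freq(geno_a, geno_b, **em_kwargs)
    p_a = f[0] + f[1]
    p_b = f[0] + f[2]
    D, d_prime, r2 = _ld_from_freqs(f[0], p_a, p_b)
    return LDResult(snp_a, snp_b, D, d_prime, r2, n=info["n"], method="em",
                    converged=info["converged"], ambiguous=info["ambiguous"])


def strong_ld_partners(
    geno,
    focal_snps: list[str],
    r2_threshold: float = 0.8,
    window_bp: int = 250_000,
) -> list[tuple[str, str, LDResult]]:
    """Partners of each focal SNP with r2 above threshold within the window.

    Uses the phased haplotype route when ``geno.haplotypes`` is present,
    otherwise the two-locus EM on dosages. Partners must be on the same
    chromosome within ``window_bp``. Monomorphic partners are skipped.
    """
    results = []
    var = geno.variants
    for focal in focal_snps:
        frow = var[var["id"] == focal]
        if frow.empty:
            raise KeyError(f"unknown focal SNP {focal!r}")
        fi = frow.index[0]
        fchrom, fpos = frow.iloc[0]["chrom"], frow.iloc[0]["pos"]
        near = var[(var["chrom"] == fchrom)
                   & (var["id"] != focal)
                   & ((var["pos"] - fpos).abs() <= window_bp)]
        for pi, prow in near.iterrows():
            try:
                if geno.haplotypes is not None:
                    res = ld_from_haplotypes(
                        geno.haplotypes[fi], geno.haplotypes[pi],
                        snp_a=focal, snp_b=prow["id"])
                else:
                    res = ld_from_genotypes(
                        geno.dosages[fi], geno.dosages[pi],
                        snp_a=focal, snp_b=prow["id"])
            except ValueError:
                continue
            if res.r2 > r2_threshold:
                results.append((focal, prow["id"], res))
    return results


# ---------------------------------------------------------------------------
# PWM scoring
# ---------------------------------------------------------------------------

@dataclass
class PWM:
    """Position-frequency matrix with background model, scored as log2 odds.

    ``counts`` is a 4 x width array in A, C, G, T row order. Probabilities are
    regularized with a pseudocount split in proportion to the background:
    p[b, i] = (counts[b, i] + pseudocount * bg[b]) / (col_total + pseudocount).
    """

    counts: np.ndarray
    name: str = "motif"
    pseudocount: float = 0.8
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError("counts must be 4 x width (A, C, G, T rows)")
        if (self.background <= 0).any():
            raise ValueError("background frequencies must be strictly positive")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background frequencies must sum to 1")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def probabilities(self) -> np.ndarray:
        tot = self.counts.sum(axis=0)
        return (self.counts + self.pseudocount * self.background[:, None]) / (
            tot + self.pseudocount)

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.probabilities / self.background[:, None])

    @property
    def consensus(self) -> str:
        bases = "ACGT"
        return "".join(bases[i] for i in self.probabilities.argmax(axis=0))

    def reverse_complement(self) -> "PWM":
        return PWM(self.counts[::-1, ::-1].copy(), name=self.name + "_rc",
                   pseudocount=self.pseudocount,
                   background=self.background[::-1].copy())

    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())


def pwm_score(window: str, pwm: PWM) -> float:
    """Log2-odds score of one window of exactly PWM width.

    ``N`` bases contribute 0 (background odds); other characters are
    rejected.
    """
    window = window.upper()
    if len(window) != pwm.width:
        raise ValueError(f"window length {len(window)} != PWM width {pwm.width}")
    lo = pwm.log_odds
    score = 0.0
    for i, base in enumerate(window):
        if base == "N":
            continue
        try:
            score += lo[_BASE_INDEX[base], i]
        except KeyError:
            raise ValueError(f"invalid base {base!r} in window") from None
    return float(score)


def scan_best(
    sequence: str,
    pwm: PWM,
    eligible_offsets=None,
) -> tuple[float, int, str]:
    """Best PWM placement over all offsets on both strands.

    Returns ``(score, offset, strand)`` with offsets 0-based on the forward
    sequence; the reverse-strand score at offset ``o`` is the score of the
    reverse complement of ``sequence[o:o+width]``. Ties break to the smallest
    offset, forward strand first. ``eligible_offsets`` optionally restricts
    the scanned placements.
    """
    seq = sequence.upper()
    w = pwm.width
    if len(seq) < w:
        raise ValueError("sequence shorter than PWM width")
    offsets = range(len(seq) - w + 1)
    if eligible_offsets is not None:
        offsets = [o for o in offsets if o in set(eligible_offsets)]
        if not offsets:
            raise ValueError("no eligible placements")
    best: tuple[float, int, str] | None = None
    for o in offsets:
        window = seq[o:o + w]
        for strand, score in (("+", pwm_score(window, pwm)),
                              ("-", pwm_score(reverse_complement(window), pwm))):
            if best is None or score > best[0]:
                best = (score, o, strand)
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# allele-specific disruption
# ---------------------------------------------------------------------------

@dataclass
class AlleleMotifDelta:
    """Best-placement PWM scores of the two alleles of one variant."""

    snp_id: str
    motif: str
    best_score_ref: float
    best_score_alt: float
    delta: float
    ref_offset: int
    ref_strand: str
    alt_offset: int
    alt_strand: str
    disrupted: bool


def apply_allele(flank: str, offset: int, ref: str, alt: str) -> tuple[str, str]:
    """Ref and alt versions of a flank sequence around a variant.

    ``offset`` is the 0-based position of the first ref base within the
    flank. The ref sequence is the flank unchanged; the alt sequence splices
    in the alt allele (its length may differ, e.g. T -> TA insertions). A
    flank that does not actually carry the ref allele at the stated offset is
    a coordinate bug and raises.
    """
    flank = flank.upper()
    ref, alt = ref.upper(), alt.upper()
    if flank[offset:offset + len(ref)] != ref:
        raise ValueError(
            f"flank has {flank[offset:offset + len(ref)]!r} at offset {offset}, "
            f"expected ref {ref!r}")
    return flank, flank[:offset] + alt + flank[offset + len(ref):]


def allele_delta(
    flank: str,
    offset: int,
    ref: str,
    alt: str,
    pwm: PWM,
    snp_id: str = "snp",
    require_overlap: bool = True,
    min_delta: float = 0.0,
) -> AlleleMotifDelta:
    """Allele-specific best motif scores and their difference.

    When ``require_overlap`` is set (default), only placements whose window
    covers at least one base of the variant allele are eligible, matching
    the convention that a reported motif change must overlap the variant.
    ``delta = best_ref - best_alt``; positive delta means the reference
    allele forms the stronger motif instance. ``disrupted`` flags
    ``|delta| >= min_delta`` (default 0: any change reported).
    """
    ref_seq, alt_seq = apply_allele(flank, offset, ref, alt)
    w = pwm.width

    def eligible(seq: str, var_len: int):
        if not require_overlap:
            return None
        start, end = offset, offset + max(var_len, 1)
        return [o for o in range(len(seq) - w + 1) if o < end and o + w > start]

    s_ref, o_ref, st_ref = scan_best(ref_seq, pwm, eligible(ref_seq, len(ref)))
    s_alt, o_alt, st_alt = scan_best(alt_seq, pwm, eligible(alt_seq, len(alt)))
    delta = s_ref - s_alt
    return AlleleMotifDelta(
        snp_id=snp_id, motif=pwm.name,
        best_score_ref=s_ref, best_score_alt=s_alt, delta=delta,
        ref_offset=o_ref, ref_strand=st_ref,
        alt_offset=o_alt, alt_strand=st_alt,
        disrupted=abs(delta) >= min_delta,
    )
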