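"""LD statistics, two-locus EM, and PWM motif-disruption scoring."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from condqtl import (PWM, allele_delta, apply_allele, em_haplotype_freq,
                     ld_from_genotypes, ld_from_haplotypes, pwm_score,
                     reverse_complement, scan_best, strong_ld_partners)


def haps_from_counts(ab, aB, Ab, ab_):
    """Haplotype vectors from counts of AB / aB / Ab / ab configurations."""
    hap_a = np.array([1] * ab + [1] * aB + [0] * Ab + [0] * ab_)
    return hap_a, None


class TestLdFromHaplotypes:
    def test_hand_computed_example(self):
        """AB=40, Ab=10, aB=10, ab=40 -> D=0.15, D'=0.6, r2=0.36."""
        hap_a = np.array([1] * 50 + [0] * 50)
        hap_b = np.array([1] * 40 + [0] * 10 + [1] * 10 + [0] * 40)
        res = ld_from_haplotypes(hap_a, hap_b)
        assert res.D == pytest.approx(0.15)
        assert res.D_prime == pytest.approx(0.6)
        assert res.r2 == pytest.approx(0.36)

    def test_identical_vectors_perfect_ld(self):
        hap = np.array([1, 0, 1, 0, 1, 1, 0, 0])
        res = ld_from_haplotypes(hap, hap)
        assert res.r2 == pytest.approx(1.0)
        assert abs(res.D_prime) == pytest.approx(1.0)

    def test_equilibrium_zero(self):
        # p_AB = p_A * p_B exactly: 2x2 balanced design
        hap_a = np.array([1, 1, 0, 0])
        hap_b = np.array([1, 0, 1, 0])
        res = ld_from_haplotypes(hap_a, hap_b)
        assert res.D == pytest.approx(0.0)
        assert res.r2 == pytest.approx(0.0)

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError):
            ld_from_haplotypes([1, 1, 1], [1, 0, 1])

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 10**6))
    def test_allele_relabel_negates_d_keeps_r2(self, seed):
        rng = np.random.default_rng(seed)
        hap_a = rng.integers(0, 2, 40)
        hap_b = rng.integers(0, 2, 40)
        if hap_a.sum() in (0, 40) or hap_b.sum() in (0, 40):
            hap_a[0], hap_a[1] = 0, 1
            hap_b[0], hap_b[1] = 0, 1
        res = ld_from_haplotypes(hap_a, hap_b)
        flipped = ld_from_haplotypes(1 - hap_a, hap_b)
        assert flipped.D == pytest.approx(-res.D, abs=1e-12)
        assert flipped.D_prime == pytest.approx(-res.D_prime, abs=1e-12)
        assert flipped.r2 == pytest.approx(res.r2, abs=1e-12)


class TestEmHaplotypeFreq:
    def test_no_double_heterozygotes_equals_counting(self):
        # genotypes chosen with no (1,1) pairs: phase is fully determined
        ga = np.array([0, 0, 2, 2, 1, 1, 0, 2])
        gb = np.array([0, 2, 0, 2, 0, 2, 1, 1])
        f, info = em_haplotype_freq(ga, gb)
        # direct haplotype counting
        counts = np.zeros(4)
        for a, b in zip(ga, gb):
            ab = min(a, b); a_only = a - ab; b_only = b - ab
            counts += [ab, a_only, b_only, 2 - ab - a_only - b_only]
        np.testing.assert_allclose(f, counts / counts.sum(), atol=1e-8)
        assert info["converged"]

    def test_recovers_generating_frequencies(self):
        """n=500 draws from known haplotype frequencies recovered within 0.05."""
        rng = np.random.default_rng(42)
        f_true = np.array([0.4, 0.1, 0.1, 0.4])
        haps = rng.choice(4, size=(500, 2), p=f_true)
        ga = np.isin(haps, [0, 1]).sum(axis=1)
        gb = np.isin(haps, [0, 2]).sum(axis=1)
        f, info = em_haplotype_freq(ga, gb)
        assert np.abs(f - f_true).max() < 0.05
        assert info["converged"]

    def test_loglik_nondecreasing(self):
        rng = np.random.default_rng(5)
        ga = rng.integers(0, 3, 200)
        gb = rng.integers(0, 3, 200)
        _, info = em_haplotype_freq(ga, gb)
        assert (np.diff(info["loglik"]) >= -1e-9).all()

    def test_all_double_heterozygous_flagged_ambiguous(self):
        f, info = em_haplotype_freq([1] * 10, [1] * 10)
        assert info["ambiguous"]
        assert f == pytest.approx([0.25, 0.25, 0.25, 0.25], abs=1e-6)

    def test_em_matches_exhaustive_likelihood_grid(self):
        """EM's optimum beats every point of a coarse frequency lattice."""
        from condqtl.ldmotif import _geno_prob

        rng = np.random.default_rng(7)
        haps = rng.choice(4, size=(120, 2), p=[0.35, 0.15, 0.2, 0.3])
        ga = np.isin(haps, [0, 1]).sum(axis=1)
        gb = np.isin(haps, [0, 2]).sum(axis=1)
        f_em, info = em_haplotype_freq(ga, gb)

        def ll(f):
            return sum(np.log(_geno_prob(np.asarray(f), a, b))
                       for a, b in zip(ga, gb))

        grid = np.arange(0.05, 1.0, 0.05)
        best_grid = max(
            ll((w, x, y, 1 - w - x - y))
            for w, x, y in itertools.product(grid, grid, grid)
            if 1 - w - x - y > 0.01)
        assert ll(f_em) >= best_grid - 1e-9

    def test_phased_and_em_agree_on_r2(self, study):
        """At n >= 500 haplotypes the two LD routes agree within 0.02."""
        geno = study.genotypes
        i, j = 0, 1
        res_h = ld_from_haplotypes(geno.haplotypes[i], geno.haplotypes[j])
        res_e = ld_from_genotypes(geno.dosages[i], geno.dosages[j])
        assert res_e.r2 == pytest.approx(res_h.r2, abs=0.02)


class TestStrongLdPartners:
    def test_planted_pair_returned_with_r2_one(self, study):
        hits = strong_ld_partners(study.genotypes, [study.truth.tag_snp_id])
        partners = {p: res for _, p, res in hits}
        assert study.truth.motif_snp_id in partners
        assert partners[study.truth.motif_snp_id].r2 == pytest.approx(1.0)

    def test_impossible_threshold_empty(self, study):
        assert strong_ld_partners(study.genotypes, [study.truth.tag_snp_id],
                                  r2_threshold=1.01) == []

    def test_partner_beyond_window_excluded(self, study):
        hits = strong_ld_partners(study.genotypes, [study.truth.tag_snp_id],
                                  window_bp=10)
        assert hits == []

    def test_em_route_finds_planted_pair(self, study):
        geno = study.genotypes
        unphased = type(geno)(geno.dosages, geno.variants, geno.patient_ids,
                              haplotypes=None)
        hits = strong_ld_partners(unphased, [study.truth.tag_snp_id])
        partners = {p: res for _, p, res in hits}
        assert study.truth.motif_snp_id in partners
        assert partners[study.truth.motif_snp_id].method == "em"
        assert partners[study.truth.motif_snp_id].r2 == pytest.approx(1.0, abs=1e-4)


class TestApplyAllele:
    def test_insertion_splice(self):
        ref_seq, alt_seq = apply_allele("ACGTACG", 3, "T", "TA")
        assert ref_seq == "ACGTACG"
        assert alt_seq == "ACGTAACG"

    def test_identity_when_ref_equals_alt(self):
        ref_seq, alt_seq = apply_allele("ACGTACG", 3, "T", "T")
        assert ref_seq == alt_seq

    def test_mismatched_ref_is_hard_error(self):
        with pytest.raises(ValueError, match="expected ref"):
            apply_allele("ACGCACG", 3, "T", "TA")


def uniform_pwm(width=4):
    return PWM(np.ones((4, width)), pseudocount=0.0)


class TestPwmScore:
    def test_uniform_pwm_scores_zero(self):
        pwm = uniform_pwm()
        assert pwm_score("ACGT", pwm) == pytest.approx(0.0)
        assert pwm_score("TTTT", pwm) == pytest.approx(0.0)

    def test_hand_summed_three_mer(self):
        counts = np.array([[8.0, 1.0, 1.0],
                           [1.0, 8.0, 1.0],
                           [0.0, 0.0, 0.0],
                           [1.0, 1.0, 8.0]])
        pwm = PWM(counts, pseudocount=0.8)
        probs = (counts + 0.8 * 0.25) / (counts.sum(axis=0) + 0.8)
        expected = sum(np.log2(probs[i, j] / 0.25)
                       for j, i in enumerate((0, 1, 3)))  # window "ACT"
        assert pwm_score("ACT", pwm) == pytest.approx(expected, abs=1e-12)

    def test_n_contributes_zero(self):
        counts = np.array([[8.0], [1.0], [1.0], [0.0]])
        pwm = PWM(counts)
        assert pwm_score("N", pwm) == pytest.approx(0.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pwm_score("ACGTA", uniform_pwm(4))

    def test_strand_consistency(self):
        rng = np.random.default_rng(3)
        pwm = PWM(rng.uniform(0, 10, (4, 6)))
        window = "ACGTTG"
        assert pwm_score(window, pwm) == pytest.approx(
            pwm_score(reverse_complement(window), pwm.reverse_complement()),
            abs=1e-12)


def brute_force_scan(sequence, pwm):
    """Independent enumeration oracle over all offsets and strands."""
    best = None
    for o in range(len(sequence) - pwm.width + 1):
        window = sequence[o:o + pwm.width]
        for strand, win in (("+", window), ("-", reverse_complement(window))):
            s = sum(pwm.log_odds["ACGT".index(b), i]
                    for i, b in enumerate(win))
            cand = (s, o, strand)
            if best is None or s > best[0] + 1e-15:
                best = cand
    return best


class TestScanBest:
    def test_consensus_at_origin(self, study):
        pwm = study.pwm
        score, offset, strand = scan_best(pwm.consensus, pwm)
        assert (offset, strand) == (0, "+")
        assert score == pytest.approx(pwm.max_score())

    def test_reverse_complement_found_on_minus(self, study):
        pwm = study.pwm
        seq = "AAAA" + reverse_complement(pwm.consensus) + "AAAA"
        score, offset, strand = scan_best(seq, pwm)
        assert strand == "-"
        assert offset == 4
        assert score == pytest.approx(pwm.max_score())

    def test_too_short_sequence_rejected(self, study):
        with pytest.raises(ValueError):
            scan_best("ACG", study.pwm)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 10**6))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        width = int(rng.integers(4, 10))
        seq = "".join(rng.choice(list("ACGT"), 60))
        pwm = PWM(rng.uniform(0, 20, (4, width)))
        score, offset, strand = scan_best(seq, pwm)
        s0, o0, st0 = brute_force_scan(seq, pwm)
        assert score == pytest.approx(s0, abs=1e-10)
        assert (offset, strand) == (o0, st0)


class TestAlleleDelta:
    def test_constructed_ref_stronger(self, study):
        res = allele_delta(study.flank, study.flank_offset, study.motif_ref,
                           study.motif_alt, study.pwm)
        assert res.delta > 0
        assert res.best_score_ref > res.best_score_alt
        assert res.disrupted

    def test_identical_alleles_zero_delta(self, study):
        res = allele_delta(study.flank, study.flank_offset, study.motif_ref,
                           study.motif_ref, study.pwm)
        assert res.delta == pytest.approx(0.0)

    def test_delta_matches_enumeration_without_overlap(self, study):
        res = allele_delta(study.flank, study.flank_offset, study.motif_ref,
                           study.motif_alt, study.pwm, require_overlap=False)
        ref_seq, alt_seq = apply_allele(study.flank, study.flank_offset,
                                        study.motif_ref, study.motif_alt)
        s_ref = brute_force_scan(ref_seq, study.pwm)[0]
        s_alt = brute_force_scan(alt_seq, study.pwm)[0]
        assert res.delta == pytest.approx(s_ref - s_alt, abs=1e-10)

    def test_overlap_restriction_limits_placements(self, study):
        """With require_overlap the best window must cover the variant."""
        res = allele_delta(study.flank, study.flank_offset, study.motif_ref,
                           study.motif_alt, study.pwm, require_overlap=True)
        w = study.pwm.width
        assert res.ref_offset <= study.flank_offset < res.ref_offset + w
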