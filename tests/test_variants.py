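"""Parental SNP criteria, Bayesian genotyping, marker presence filters."""

import math

import numpy as np
import pytest

from ddradmap.reference import ConsensusTag, align_to_tags
from ddradmap.variants import (GEN_A, GEN_B, GEN_H, GEN_MISSING,
                               build_genotype_matrix, call_genotype,
                               call_genotypes_array, call_parental_snps,
                               drop_high_het_markers, pileup_counts,
                               reduce_reference)

BASES = "ACGT"


def _pile(n_tags, length, entries):
    """Pileup array from {(tag, pos, base): count} entries."""
    pile = np.zeros((n_tags, length, 4), dtype=np.int32)
    for (t, p, b), n in entries.items():
        pile[t, p, BASES.index(b)] = n
    return pile


def _cover(pile, base, depth, skip=()):
    """Fill every uncovered position with `depth` reads of `base`."""
    for t in range(pile.shape[0]):
        for p in range(pile.shape[1]):
            if (t, p) not in skip and pile[t, p].sum() == 0:
                pile[t, p, BASES.index(base)] = depth
    return pile


# ---------------------------------------------------------------- pileups

def test_single_read_pileup_covers_every_position():
    tag = ConsensusTag("t0", "ACGTA" * 18, 1)     # 90 bp
    res = align_to_tags([("r0", tag.sequence)], [tag])
    pile = pileup_counts(res, [tag.sequence], 1, 90)
    assert pile.sum() == 90
    assert (pile.sum(axis=2)[0] == 1).all()


def test_pileup_matches_manual_tally():
    tag_seq = "ACGTACGTAC"
    reads = [tag_seq, tag_seq,
             "ACGAACGTAC",                        # A at position 3
             "ACGTACGTAT",                        # T at position 9
             "GTACGTACGT"]                        # revcomp of tag_seq
    tag = ConsensusTag("t0", tag_seq, 5)
    res = align_to_tags([(i, s) for i, s in enumerate(reads)], [tag])
    pile = pileup_counts(res, reads, 1, 10)
    # manual tally: 5 reads cover all 10 positions (revcomp corrected)
    assert (pile.sum(axis=2)[0] == 5).all()
    assert pile[0, 3, BASES.index("A")] == 1
    assert pile[0, 3, BASES.index("T")] == 4
    assert pile[0, 9, BASES.index("T")] == 1
    assert pile[0, 9, BASES.index("C")] == 4


# ---------------------------------------------------------- parental SNPs

def _two_parent_piles(p1_entries, p2_entries, n_tags=1, length=10):
    tags = [ConsensusTag(f"t{i}", "A" * length, 10) for i in range(n_tags)]
    pile1 = _cover(_pile(n_tags, length, p1_entries), "A", 10,
                   skip={(t, p) for t, p, _ in p1_entries})
    pile2 = _cover(_pile(n_tags, length, p2_entries), "A", 10,
                   skip={(t, p) for t, p, _ in p2_entries})
    return pile1, pile2, tags


def test_fixed_difference_is_a_snp():
    pile1, pile2, tags = _two_parent_piles({(0, 4, "A"): 10},
                                           {(0, 4, "G"): 8})
    snps, tally = call_parental_snps(pile1, pile2, tags)
    assert [(s.tag_id, s.position, s.allele_p1, s.allele_p2)
            for s in snps] == [("t0", 4, "A", "G")]
    assert sum(tally.values()) == 0


def test_heterozygous_parent_rejected():
    pile1, pile2, tags = _two_parent_piles(
        {(0, 4, "A"): 7, (0, 4, "G"): 3}, {(0, 4, "G"): 8})
    snps, tally = call_parental_snps(pile1, pile2, tags)
    assert snps == []
    assert tally["heterozygous_in_parent"] == 1


def test_low_depth_rejected():
    pile1, pile2, tags = _two_parent_piles({(0, 4, "A"): 3},
                                           {(0, 4, "G"): 9})
    snps, tally = call_parental_snps(pile1, pile2, tags)
    assert snps == []
    assert tally["low_depth"] == 1
    # boundary: exactly four reads in each parent passes
    pile1, pile2, tags = _two_parent_piles({(0, 4, "A"): 4},
                                           {(0, 4, "G"): 4})
    snps, _ = call_parental_snps(pile1, pile2, tags)
    assert len(snps) == 1


def test_multi_allelic_rejected():
    pile1, pile2, tags = _two_parent_piles(
        {(0, 4, "A"): 5, (0, 4, "C"): 5}, {(0, 4, "G"): 8})
    snps, tally = call_parental_snps(pile1, pile2, tags)
    assert snps == []
    assert tally["multi_allelic"] == 1


# ------------------------------------------------------- reduced reference

def test_reduce_reference_keeps_exactly_snp_tags():
    tags = [ConsensusTag(f"t{i}", "ACGT", 5) for i in range(100)]
    from ddradmap.variants import ParentalSNP
    snps = [ParentalSNP(f"t{i}", 1, "C", "T") for i in range(0, 24, 2)]
    reduced = reduce_reference(tags, snps)
    assert len(reduced) == 12
    assert {t.id for t in reduced} == {s.tag_id for s in snps}
    with pytest.raises(ValueError, match="reduced reference is empty"):
        reduce_reference(tags, [])
    with pytest.raises(ValueError, match="unknown tags"):
        reduce_reference(tags, [ParentalSNP("nope", 0, "A", "C")])


# ------------------------------------------------------------- genotyping

def bayes_oracle(na, nb, e=0.01, prior=(1 / 3, 1 / 3, 1 / 3)):
    """Independent posterior computation from the three likelihoods."""
    laa = (1 - e) ** na * e ** nb * prior[0]
    lab = 0.5 ** (na + nb) * prior[1]
    lbb = e ** na * (1 - e) ** nb * prior[2]
    z = laa + lab + lbb
    return laa / z, lab / z, lbb / z


def test_strong_homozygote_call_matches_bayes_oracle():
    call = call_genotype(10, 0, error_rate=0.01)
    p_aa, _, _ = bayes_oracle(10, 0)
    assert call.code == "a"
    assert call.posterior > 0.99
    assert math.isclose(call.posterior, p_aa, rel_tol=1e-9)


def test_balanced_counts_are_heterozygous_then_masked():
    # likelihoods: L(ab) = 2^-10 ~ 9.8e-4 >> L(aa) = .99^5 * .01^5 ~ 9.5e-11
    assert 0.5 ** 10 > 0.99 ** 5 * 0.01 ** 5
    masked = call_genotype(5, 5, het_policy="mask")
    assert masked.code == "-"
    kept = call_genotype(5, 5, het_policy="keep")
    assert kept.code == "h"
    _, p_ab, _ = bayes_oracle(5, 5)
    assert math.isclose(kept.posterior, p_ab, rel_tol=1e-9)


def test_homozygote_below_depth_rule_is_missing():
    assert call_genotype(2, 0).code == "-"
    assert call_genotype(4, 0).code == "a"      # "no less than four reads"
    assert call_genotype(0, 4).code == "b"
    assert call_genotype(0, 0).code == "-"


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        call_genotype(-1, 3)


def test_posterior_monotone_in_supporting_depth():
    nas = np.arange(4, 40)
    codes, post = call_genotypes_array(nas, np.zeros_like(nas))
    assert (codes == GEN_A).all()
    assert (np.diff(post) >= -1e-12).all()
    assert post[-1] > 1 - 1e-6


def test_f9_prior_shifts_het_boundary():
    from ddradmap.variants import f9_prior
    prior = f9_prior(8)
    assert math.isclose(prior[1], 2 ** -8)
    # (6, 2): L(ab)/L(aa) ~ 41, so the uniform prior calls het while the
    # 2^-8 residual-het prior tips the call to the homozygote
    uni = call_genotype(6, 2, het_policy="keep")
    f9 = call_genotype(6, 2, prior=prior, het_policy="keep")
    assert uni.code == "h"
    assert f9.code == "a"


# ------------------------------------------------------ presence filters

def _codes(n_a, n_b, n_h, n_missing):
    row = ([GEN_A] * n_a + [GEN_B] * n_b + [GEN_H] * n_h
           + [GEN_MISSING] * n_missing)
    return np.array([row], dtype=np.int8)


def test_mmd_boundary_at_25_percent_of_166():
    # 42 missing of 166 exceeds 41.5; 41 does not
    dropped, tally = build_genotype_matrix(
        _codes(62, 62, 0, 42), ["m1"], [f"i{k}" for k in range(166)],
        mmd=0.25, min_allele_individuals=30)
    assert tally["dropped_mmd"] == 1 and dropped.n_markers == 0
    kept, tally = build_genotype_matrix(
        _codes(63, 62, 0, 41), ["m1"], [f"i{k}" for k in range(166)],
        mmd=0.25, min_allele_individuals=30)
    assert tally["retained"] == 1 and kept.n_markers == 1


def test_minor_allele_boundary_at_30_individuals():
    dropped, tally = build_genotype_matrix(
        _codes(137, 29, 0, 0), ["m1"], [f"i{k}" for k in range(166)],
        mmd=0.25, min_allele_individuals=30)
    assert tally["dropped_minor_allele"] == 1
    kept, tally = build_genotype_matrix(
        _codes(136, 30, 0, 0), ["m1"], [f"i{k}" for k in range(166)],
        mmd=0.25, min_allele_individuals=30)
    assert tally["retained"] == 1
    # heterozygotes carry both alleles
    kept, tally = build_genotype_matrix(
        _codes(136, 29, 1, 0), ["m1"], [f"i{k}" for k in range(166)],
        mmd=0.25, min_allele_individuals=30)
    assert tally["retained"] == 1


def test_filter_tally_conserves_markers(rng):
    codes = rng.choice([GEN_A, GEN_B, GEN_MISSING], size=(200, 166),
                       p=[0.45, 0.45, 0.10]).astype(np.int8)
    matrix, tally = build_genotype_matrix(
        codes, [f"m{k}" for k in range(200)],
        [f"i{k}" for k in range(166)])
    assert tally["markers_in"] == (tally["retained"] + tally["dropped_mmd"]
                                   + tally["dropped_minor_allele"]) == 200
    assert matrix.n_markers == tally["retained"]


def test_strict_het_policy_drops_high_het_loci():
    codes = np.array([[GEN_A] * 80 + [GEN_H] * 20,
                      [GEN_A] * 95 + [GEN_H] * 5], dtype=np.int8)
    keep = drop_high_het_markers(codes, threshold=0.1)
    assert keep.tolist() == [False, True]


# -------------------------------------------------- end-to-end properties

def test_paralog_suppression_no_snp_from_homoeolog_tags(tmp_path):
    """Homoeologous duplicates diverged within the mismatch radius must
    never yield a SNP: their merged clusters fail the 100%-within-parent
    criterion, so the called set stays false-positive-free."""
    from conftest import small_sim_overrides
    from ddradmap import evaluate as ev
    from ddradmap.config import config_from_dict
    from ddradmap.pipeline import run_pipeline

    cfg = config_from_dict({
        "mode": "simulate", "outdir": str(tmp_path), "seed": 17,
        "sim": small_sim_overrides(paralog_fraction=0.3, seed=17),
        "variants": {"min_allele_individuals": 6},
        "linkage": {"min_informative": 10, "min_shared": 10},
    })
    res = run_pipeline(cfg)
    truth = res.truth
    L = res.summary["stages"]["qc"]["cluster_length"]
    origins = ev.map_tags_to_truth(res.tags, truth, L)
    score = ev.score_snp_calls(res.snps, origins, truth, L, radius=2)
    assert score["fdr"] == 0.0
    # no called SNP may sit on a homoeolog divergence position
    paralog_frags = set(truth.paralog_source)
    for s in res.snps:
        assert origins[s.tag_id].fragment not in paralog_frags
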