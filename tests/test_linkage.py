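"""Two-point linkage, grouping, bins, ordering, distortion, map stats."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

from ddradmap.linkage import (GeneticMap, LinkageGroup, PairwiseResult,
                              bonferroni_lod, build_map, collapse_bins,
                              detect_sdrs, estimate_pairwise, group_markers,
                              group_statistics, kosambi_cM, kosambi_inverse,
                              map_statistics, order_and_place,
                              ril_to_meiotic_r, segregation_test,
                              DistortionTest)
from ddradmap.simulate import SimConfig, simulate_founders, \
    simulate_ril_population
from ddradmap.variants import GEN_A, GEN_B, GEN_MISSING, GenotypeMatrix

from conftest import small_sim_overrides


def _matrix(codes):
    codes = np.asarray(codes, dtype=np.int8)
    return GenotypeMatrix(
        marker_ids=[f"m{i}" for i in range(codes.shape[0])],
        individuals=[f"i{j}" for j in range(codes.shape[1])],
        codes=codes)


def _matrix_from_truth(truth):
    """Genotype matrix straight from simulated truth (hets masked)."""
    codes = truth.true_genotypes.T.astype(np.int8).copy()
    codes[codes == 1] = GEN_MISSING      # het -> missing
    codes[codes == 2] = GEN_B
    m = _matrix(codes)
    return m


# ------------------------------------------------------------ map functions

def test_ril_correction_values():
    assert ril_to_meiotic_r(0.0) == 0.0
    assert ril_to_meiotic_r(0.5) == 0.5
    assert math.isclose(ril_to_meiotic_r(0.3873), 0.3161, abs_tol=5e-4)
    with pytest.raises(ValueError):
        ril_to_meiotic_r(1.2)


@given(st.floats(0.0, 0.4999))
@settings(deadline=None, max_examples=200, derandomize=True)
def test_ril_correction_inverts_haldane_waddington(r):
    R = 2 * r / (1 + 2 * r)
    assert math.isclose(ril_to_meiotic_r(R), r, abs_tol=1e-12)


def test_kosambi_values():
    assert kosambi_cM(0.0) == 0.0
    assert math.isclose(kosambi_cM(0.1), 25 * math.log(1.2 / 0.8),
                        rel_tol=1e-12)
    assert math.isclose(kosambi_cM(0.25), 25 * math.log(1.5 / 0.5),
                        rel_tol=1e-12)
    assert round(kosambi_cM(0.1), 2) == 10.14
    assert round(kosambi_cM(0.25), 2) == 27.47


@given(st.floats(0.0, 0.4999))
@settings(deadline=None, max_examples=200, derandomize=True)
def test_kosambi_round_trip_and_bounds(r):
    d = kosambi_cM(r)
    assert math.isclose(kosambi_inverse(d), r, abs_tol=1e-10)
    assert d >= 100 * r - 1e-9            # Kosambi expands distances


# ------------------------------------------------------- pairwise linkage

def test_identical_markers_lod_closed_form():
    codes = np.tile([GEN_A] * 50 + [GEN_B] * 50, (2, 1))
    pw = estimate_pairwise(_matrix(codes), min_informative=10)
    assert pw.R_hat[0, 1] == 0.0
    assert pw.r_hat[0, 1] == 0.0
    assert math.isclose(pw.lod[0, 1], 100 * math.log10(2), rel_tol=1e-12)


def test_independent_markers_have_no_linkage_signal(rng):
    codes = rng.choice([GEN_A, GEN_B], size=(2, 2000)).astype(np.int8)
    pw = estimate_pairwise(_matrix(codes))
    assert abs(pw.R_hat[0, 1] - 0.5) < 3 * math.sqrt(0.25 / 2000)
    assert pw.lod[0, 1] < 3.0


def test_pairwise_matches_brute_force_tally(rng):
    codes = rng.choice([GEN_A, GEN_B, GEN_MISSING], size=(10, 6),
                       p=[0.4, 0.4, 0.2]).astype(np.int8)
    pw = estimate_pairwise(_matrix(codes), min_informative=1)
    for i in range(10):
        for j in range(10):
            inf = rec = 0
            for k in range(6):
                a, b = codes[i, k], codes[j, k]
                if a != GEN_MISSING and b != GEN_MISSING:
                    inf += 1
                    rec += a != b
            assert pw.n_informative[i, j] == inf
            assert pw.n_recombinant[i, j] == rec


def test_low_information_markers_warn_and_unusable():
    codes = np.array([[GEN_A] * 6,
                      [GEN_MISSING] * 5 + [GEN_A]], dtype=np.int8)
    with pytest.warns(UserWarning, match="informative"):
        pw = estimate_pairwise(_matrix(codes), min_informative=1)
    assert not pw.usable[0, 1]


# ----------------------------------------------------------------- grouping

def _pairwise_from(r, lod, n=None):
    r = np.asarray(r, float)
    lod = np.asarray(lod, float)
    k = r.shape[0]
    n_inf = np.full((k, k), 100) if n is None else np.asarray(n)
    usable = np.ones((k, k), dtype=bool)
    np.fill_diagonal(usable, False)
    return PairwiseResult([f"m{i}" for i in range(k)], n_inf,
                          np.zeros((k, k), int), r.copy(), r, lod, usable)


def test_grouping_thresholds_are_inclusive():
    r = np.array([[0.0, 0.45], [0.45, 0.0]])
    lod = np.array([[0.0, 2.0], [2.0, 0.0]])
    groups, unlinked = group_markers(_pairwise_from(r, lod),
                                     max_rf=0.45, min_lod=2.0)
    assert groups == [[0, 1]] and unlinked == []
    # one hair past either threshold breaks the edge
    groups, unlinked = group_markers(
        _pairwise_from(r + 1e-9, lod), max_rf=0.45, min_lod=2.0)
    assert groups == [] and unlinked == [0, 1]
    groups, unlinked = group_markers(
        _pairwise_from(r, lod - 1e-9), max_rf=0.45, min_lod=2.0)
    assert groups == [] and unlinked == [0, 1]


def test_unlinked_markers_stay_singletons():
    r = np.full((4, 4), 0.5)
    lod = np.zeros((4, 4))
    groups, unlinked = group_markers(_pairwise_from(r, lod))
    assert groups == [] and unlinked == [0, 1, 2, 3]


def test_grouping_recovers_true_chromosomes():
    from sklearn.metrics import adjusted_rand_score
    cfg = SimConfig(**small_sim_overrides(
        n_chromosomes=3, chrom_length_cM=60.0, n_tags=90,
        n_individuals=166, seed=31))
    truth = simulate_founders(cfg)
    simulate_ril_population(truth, cfg)
    matrix = _matrix_from_truth(truth)
    pw = estimate_pairwise(matrix)
    groups, unlinked = group_markers(pw, min_lod="auto")
    labels = {}
    for gi, group in enumerate(groups):
        for m in group:
            labels[m] = gi
    true = [truth.chrom_of_tag[t] for t in truth.mapped_tags]
    called = [labels.get(m, -1 - m) for m in range(len(true))]
    assert adjusted_rand_score(true, called) == 1.0


def test_bonferroni_lod_scales_with_marker_count():
    assert bonferroni_lod(10) < bonferroni_lod(100) < bonferroni_lod(2000)
    assert 4.0 < bonferroni_lod(453) < 7.0


# --------------------------------------------------------------------- bins

def test_duplicate_markers_share_a_bin():
    row = [GEN_A] * 12 + [GEN_B] * 12
    codes = np.array([row, row, row[::-1]], dtype=np.int8)
    bins = collapse_bins(_matrix(codes), [0, 1, 2], min_shared=10)
    sizes = sorted(len(b["markers"]) for b in bins)
    assert sizes == [1, 2]


def test_single_shared_disagreement_splits_bins():
    row = [GEN_A] * 12 + [GEN_B] * 12
    row2 = row.copy()
    row2[0] = GEN_B
    bins = collapse_bins(_matrix(np.array([row, row2], dtype=np.int8)),
                         [0, 1], min_shared=10)
    assert len(bins) == 2


def test_bins_match_exhaustive_pairwise_comparison(rng):
    base = rng.choice([GEN_A, GEN_B], size=30).astype(np.int8)
    rows = []
    for _ in range(12):
        row = base.copy()
        if rng.random() < 0.5:
            row[rng.integers(0, 30)] = GEN_B if rng.random() < .5 else GEN_A
        mask = rng.random(30) < 0.15
        row[mask] = GEN_MISSING
        rows.append(row)
    codes = np.array(rows)
    bins = collapse_bins(_matrix(codes), list(range(12)), min_shared=5)

    # oracle: union-find over the stated pair relation
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(range(12))
    for i in range(12):
        for j in range(i + 1, 12):
            both = (codes[i] != GEN_MISSING) & (codes[j] != GEN_MISSING)
            if both.sum() >= 5 and (codes[i][both] == codes[j][both]).all():
                g.add_edge(i, j)
    oracle = {frozenset(c) for c in nx.connected_components(g)}
    assert {frozenset(b["markers"]) for b in bins} == oracle


# ----------------------------------------------------------------- ordering

def _ril_matrix_one_chromosome(n_loci, length_cm, n_ind, seed):
    cfg = SimConfig(**small_sim_overrides(
        n_chromosomes=1, chrom_length_cM=length_cm, n_tags=n_loci,
        n_individuals=n_ind, seed=seed))
    truth = simulate_founders(cfg)
    simulate_ril_population(truth, cfg)
    return truth, _matrix_from_truth(truth)


def test_order_recovery_on_one_chromosome():
    truth, matrix = _ril_matrix_one_chromosome(10, 50.0, 200, seed=5)
    pw = estimate_pairwise(matrix)
    bins = collapse_bins(matrix, list(range(10)), min_shared=20)
    ordered, positions = order_and_place(bins, pw)
    rep_order = [b["representative"] for b in ordered]
    true_pos = [truth.cm_of_tag[truth.mapped_tags[m]] for m in rep_order]
    rho = spearmanr(positions, true_pos).statistic
    assert abs(rho) > 1.0 - 1e-9      # exact rank agreement up to fp noise


def test_two_bins_trivial_order_and_length():
    codes = np.array([[GEN_A] * 20 + [GEN_B] * 20,
                      [GEN_A] * 19 + [GEN_B] * 21], dtype=np.int8)
    m = _matrix(codes)
    pw = estimate_pairwise(m, min_informative=10)
    bins = collapse_bins(m, [0, 1], min_shared=10)
    assert len(bins) == 2
    ordered, positions = order_and_place(bins, pw)
    assert positions[0] == 0.0
    assert math.isclose(positions[1], kosambi_cM(pw.r_hat[0, 1]))
    single, pos = order_and_place(bins[:1], pw)
    assert pos == [0.0]


def test_ordering_deterministic_under_input_permutation():
    truth, matrix = _ril_matrix_one_chromosome(12, 60.0, 120, seed=6)
    pw = estimate_pairwise(matrix)
    bins = collapse_bins(matrix, list(range(12)), min_shared=20)
    ordered1, pos1 = order_and_place(bins, pw)
    ordered2, pos2 = order_and_place(list(reversed(bins)), pw)
    reps1 = [b["representative"] for b in ordered1]
    reps2 = [b["representative"] for b in ordered2]
    assert reps1 == reps2 or reps1 == reps2[::-1]
    assert np.allclose(sorted(np.diff(pos1)), sorted(np.diff(pos2)))


# --------------------------------------------------------------- distortion

def test_balanced_marker_not_distorted():
    t = segregation_test(_matrix(_row(83, 83)))[0]
    assert t.chi2 == 0.0 and not t.distorted and t.direction == ""


def _row(n_a, n_b, n_missing=0):
    return np.array([[GEN_A] * n_a + [GEN_B] * n_b
                     + [GEN_MISSING] * n_missing], dtype=np.int8)


def test_distorted_marker_chi_square_value():
    t = segregation_test(_matrix(_row(100, 66)))[0]
    assert math.isclose(t.chi2, 34 ** 2 / 166, rel_tol=1e-12)
    assert round(t.chi2, 2) == 6.96
    assert t.distorted and t.direction == "a"
    assert t.p_value < 0.01


def test_mildly_skewed_marker_not_distorted():
    t = segregation_test(_matrix(_row(90, 76)))[0]
    assert math.isclose(t.chi2, 14 ** 2 / 166, rel_tol=1e-12)
    assert not t.distorted


def test_untestable_marker_flagged():
    t = segregation_test(_matrix(_row(1, 0, 165)))[0]
    assert not t.testable


def _flags(spec):
    """DistortionTest list from compact 'a'/'b'/'.' strings."""
    out = []
    for ch in spec:
        if ch == ".":
            out.append(DistortionTest(0.0, 1.0, False, "", True))
        else:
            out.append(DistortionTest(9.0, 0.001, True, ch, True))
    return out


def test_sdr_detection_rules():
    sdrs = detect_sdrs("LG1", _flags(".aaa."))
    assert len(sdrs) == 1 and (sdrs[0].start, sdrs[0].end) == (1, 3)
    assert sdrs[0].direction == "a" and sdrs[0].n_markers == 3
    assert detect_sdrs("LG1", _flags("..a..")) == []
    assert detect_sdrs("LG1", _flags(".aba.")) == []
    assert detect_sdrs("LG1", _flags("bbbbaaa"))[0].direction == "b"
    assert len(detect_sdrs("LG1", _flags("bbbbaaa"))) == 2


# ------------------------------------------------------------- statistics

def test_group_statistics_worked_example():
    s = group_statistics([0.0, 3.0, 10.0, 22.0])
    assert s["length_cM"] == 22.0
    assert s["largest_gap_cM"] == 12.0
    assert math.isclose(s["gap_le_5_fraction"], 1 / 3)
    assert math.isclose(s["density_cM_per_locus"], 22 / 3)


def test_single_marker_group_statistics_blank():
    s = group_statistics([0.0])
    assert s["length_cM"] == 0.0
    assert math.isnan(s["density_cM_per_locus"])
    assert math.isnan(s["gap_le_5_fraction"])


def test_gap_comparator_configurable():
    s_le = group_statistics([0.0, 5.0, 11.0], gap_comparator="le")
    s_lt = group_statistics([0.0, 5.0, 11.0], gap_comparator="lt")
    assert s_le["gap_le_5_fraction"] == 0.5
    assert s_lt["gap_le_5_fraction"] == 0.0


def test_reversed_group_has_same_length_and_gap_stats():
    pos = [0.0, 3.0, 10.0, 22.0]
    rev = [22.0 - p for p in reversed(pos)]
    assert group_statistics(pos) == group_statistics(rev)


def test_map_statistics_totals_are_self_consistent():
    g1 = LinkageGroup("LG1", ["a", "b", "c"], [0.0, 4.0, 10.0],
                      bins=[["a"], ["b"], ["c"]],
                      distortion=_flags("..."))
    g2 = LinkageGroup("LG2", ["d", "e"], [0.0, 7.0], bins=[["d"], ["e"]],
                      distortion=_flags("aa"))
    gm = GeneticMap([g1, g2])
    df = map_statistics(gm)
    assert math.isclose(df.loc["Total", "length_cM"],
                        df.loc[["LG1", "LG2"], "length_cM"].sum())
    assert df.loc["Total", "n_loci"] == 5
    assert df.loc["Total", "n_distorted"] == 2
    assert math.isclose(gm.total_length, 17.0)


def test_build_map_end_to_end_on_truth_matrix():
    cfg = SimConfig(**small_sim_overrides(
        n_chromosomes=2, chrom_length_cM=50.0, n_tags=40,
        n_individuals=166, seed=8))
    truth = simulate_founders(cfg)
    simulate_ril_population(truth, cfg)
    gm = build_map(_matrix_from_truth(truth), min_lod="auto")
    assert len(gm.groups) == 2
    for g in gm.groups:
        assert g.positions[0] == 0.0
        assert all(b >= a for a, b in zip(g.positions, g.positions[1:]))
        stats = group_statistics(g.positions)
        assert stats["length_cM"] <= 50.0 * 1.3
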