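"""Two-point linkage mapping for a selfed RIL population.

The observed recombinant fraction R between two markers in an F-infinity
RIL relates to the meiotic recombination fraction r through the
Haldane-Waddington correction R = 2r/(1+2r).  Markers are grouped by
single-linkage over pairs with corrected r <= 0.45 and LOD >= 2.0
(inclusive), co-segregating markers are collapsed into bins, bins are
ordered by greedy chain insertion with a sliding-window polish, and map
distances come from the Kosambi function d = 25 ln((1+2r)/(1-2r)) cM.
Segregation distortion is tested per marker against the 1:1 expectation
by a 1-df chi-square; runs of >= 3 consecutive same-direction distorted
markers form segregation distortion regions (SDRs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats as sps

import networkx as nx

from .variants import GEN_A, GEN_B, GEN_H, GEN_MISSING, GenotypeMatrix


# ---------------------------------------------------------------- map math

def ril_to_meiotic_r(R_hat):
    """Invert R = 2r/(1+2r): r = R/(2(1-R)), clamped to [0, 0.5]."""
    R = np.asarray(R_hat, dtype=float)
    if (R < 0).any() or (R > 1).any():
        raise ValueError("R_hat must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(R >= 0.5, 0.5, R / (2.0 * (1.0 - R)))
    r = np.clip(r, 0.0, 0.5)
    return float(r) if np.isscalar(R_hat) or np.ndim(R_hat) == 0 else r


def kosambi_cM(r):
    """Kosambi map distance d = 25 ln((1+2r)/(1-2r)) in cM.

    r is clamped to 0.4999 before the transform so unlinked-looking
    pairs map to a large finite distance.
    """
    r_arr = np.clip(np.asarray(r, dtype=float), 0.0, 0.4999)
    d = 25.0 * np.log((1 + 2 * r_arr) / (1 - 2 * r_arr))
    return float(d) if np.ndim(r) == 0 else d


def kosambi_inverse(d):
    """Recombination fraction from a Kosambi distance: r = tanh(d/50)/2."""
    r = 0.5 * np.tanh(np.asarray(d, dtype=float) / 50.0)
    return float(r) if np.ndim(d) == 0 else r


# --------------------------------------------------------- pairwise linkage

@dataclass
class PairwiseLinkage:
    marker_i: str
    marker_j: str
    n_informative: int
    n_recombinant: int
    R_hat: float
    r_hat: float
    lod: float


@dataclass
class PairwiseResult:
    """All-pairs two-point estimates as dense matrices."""

    marker_ids: list
    n_informative: np.ndarray
    n_recombinant: np.ndarray
    R_hat: np.ndarray
    r_hat: np.ndarray
    lod: np.ndarray
    usable: np.ndarray          # n_informative >= min_informative

    def pair(self, i: int, j: int) -> PairwiseLinkage:
        return PairwiseLinkage(
            self.marker_ids[i], self.marker_ids[j],
            int(self.n_informative[i, j]), int(self.n_recombinant[i, j]),
            float(self.R_hat[i, j]), float(self.r_hat[i, j]),
            float(self.lod[i, j]))


def _signed_codes(codes: np.ndarray) -> np.ndarray:
    """a -> +1, b -> -1, h/missing -> 0 (hets carry no RIL phase info)."""
    x = np.zeros(codes.shape, dtype=np.int32)
    x[codes == GEN_A] = 1
    x[codes == GEN_B] = -1
    return x


def estimate_pairwise(matrix: GenotypeMatrix,
                      min_informative: int = 20) -> PairwiseResult:
    """Two-point R, RIL-corrected r and linkage LOD for all marker pairs.

    Recombinants are counted over individuals non-missing at both
    markers; LOD = n_nr log10(2(1-R)) + n_r log10(2R) with 0 log 0 = 0.
    Markers with fewer than 2 informative individuals overall are
    excluded with a warning (their rows are marked unusable).
    """
    x = _signed_codes(matrix.codes)
    informative_per_marker = np.abs(x).sum(axis=1)
    bad = informative_per_marker < 2
    if bad.any():
        warnings.warn(f"{int(bad.sum())} markers with < 2 informative "
                      "individuals excluded from pairwise linkage")
    a = np.abs(x)
    n_inf = a @ a.T
    s = x @ x.T                              # agreements - disagreements
    n_rec = (n_inf - s) // 2
    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.where(n_inf > 0, n_rec / np.maximum(n_inf, 1), np.nan)
    r = np.where(np.isnan(R), np.nan,
                 np.where(R >= 0.5, 0.5,
                          R / (2.0 * np.maximum(1.0 - R, 1e-12))))
    r = np.clip(r, 0.0, 0.5)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (n_inf - n_rec) * np.nan_to_num(np.log10(2.0 * (1.0 - R)),
                                             neginf=0.0, nan=0.0)
        t1[(n_inf - n_rec) == 0] = 0.0
        t2 = n_rec * np.nan_to_num(np.log10(2.0 * R), neginf=0.0, nan=0.0)
        t2[n_rec == 0] = 0.0
    lod = np.where(n_inf > 0, t1 + t2, 0.0)
    usable = (n_inf >= min_informative) & ~bad[:, None] & ~bad[None, :]
    np.fill_diagonal(usable, False)
    return PairwiseResult(list(matrix.marker_ids), n_inf, n_rec, R, r,
                          lod, usable)


# ----------------------------------------------------------------- grouping

def bonferroni_lod(n_markers: int, alpha: float = 0.05) -> float:
    """Grouping LOD controlling family-wise false linkage at ``alpha``.

    Under no linkage 2 ln10 x LOD is asymptotically chi-square(1), so a
    per-pair test at alpha / C(n,2) keeps the expected number of false
    single-linkage edges below alpha.  At small marker counts this
    converges to the conventional threshold; at thousands of markers it
    rises to ~5-6, matching the stepwise grouping LODs mapping software
    asks the user to raise until groups stabilise.
    """
    n_pairs = max(n_markers * (n_markers - 1) // 2, 1)
    q = sps.chi2.isf(min(alpha / n_pairs, 1.0), df=1)
    return float(q / (2.0 * np.log(10.0)))


def group_markers(pairwise: PairwiseResult, max_rf: float = 0.45,
                  min_lod=2.0):
    """Single-linkage partition over r <= max_rf and LOD >= min_lod.

    Both thresholds are inclusive.  ``min_lod='auto'`` substitutes the
    Bonferroni-calibrated threshold of :func:`bonferroni_lod`.  Returns
    (groups, unlinked): groups of >= 2 markers sorted by decreasing
    size, and singleton marker indices.
    """
    n = len(pairwise.marker_ids)
    if min_lod == "auto":
        min_lod = bonferroni_lod(n)
    with np.errstate(invalid="ignore"):
        adj = pairwise.usable & (pairwise.r_hat <= max_rf) \
            & (pairwise.lod >= min_lod)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    ii, jj = np.nonzero(np.triu(adj, 1))
    g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    groups = [c for c in comps if len(c) >= 2]
    unlinked = [c[0] for c in comps if len(c) == 1]
    return groups, unlinked


# --------------------------------------------------------------------- bins

def collapse_bins(matrix: GenotypeMatrix, group, min_shared: int = 20):
    """Transitive closure of the 'no observed recombination' relation.

    Two markers share a bin iff their genotype vectors agree on every
    individual where both are non-missing and they share at least
    ``min_shared`` informative individuals.  The bin representative is
    the member with fewest missing entries (ties by marker id).
    """
    group = list(group)
    x = _signed_codes(matrix.codes[group])
    a = np.abs(x)
    n_inf = a @ a.T
    n_rec = (n_inf - x @ x.T) // 2
    adj = (n_rec == 0) & (n_inf >= min_shared)
    g = nx.Graph()
    g.add_nodes_from(range(len(group)))
    ii, jj = np.nonzero(np.triu(adj, 1))
    g.add_edges_from(zip(ii.tolist(), jj.tolist()))

    missing = (matrix.codes[group] == GEN_MISSING).sum(axis=1)
    bins = []
    for comp in nx.connected_components(g):
        members = sorted(comp)
        rep = min(members, key=lambda m: (missing[m],
                                          matrix.marker_ids[group[m]]))
        bins.append({"markers": [group[m] for m in members],
                     "representative": group[rep]})
    # deterministic bin order: by representative's position in the group
    bins.sort(key=lambda b: group.index(b["representative"]))
    return bins


# ----------------------------------------------------------------- ordering

def _chain_cost(chain, r):
    return sum(r[chain[k], chain[k + 1]] for k in range(len(chain) - 1))


def order_and_place(bins, pairwise: PairwiseResult):
    """Order bins along the group and assign cumulative Kosambi positions.

    Seeding with the pair of smallest r (ties: larger LOD, then ids),
    the chain grows by inserting the unplaced bin that least increases
    the sum of adjacent r; a sliding window-3 permutation polish runs to
    convergence.  Deterministic.  Returns (ordered bin list, positions
    in cM starting at 0).
    """
    reps = [b["representative"] for b in bins]
    k = len(reps)
    if k == 1:
        return list(bins), [0.0]
    r = pairwise.r_hat[np.ix_(reps, reps)].copy()
    lod = pairwise.lod[np.ix_(reps, reps)]
    r = np.where(np.isnan(r), 0.5, r)

    best = None
    for i in range(k):
        for j in range(i + 1, k):
            key = (r[i, j], -lod[i, j], i, j)
            if best is None or key < best:
                best = key
                seed = (i, j)
    chain = list(seed)
    unplaced = [i for i in range(k) if i not in chain]
    while unplaced:
        best = None
        for u in unplaced:
            for pos in range(len(chain) + 1):
                if pos == 0:
                    inc = r[u, chain[0]]
                elif pos == len(chain):
                    inc = r[chain[-1], u]
                else:
                    left, right = chain[pos - 1], chain[pos]
                    inc = r[left, u] + r[u, right] - r[left, right]
                key = (inc, u, pos)
                if best is None or key < best:
                    best = key
        _, u, pos = best
        chain.insert(pos, u)
        unplaced.remove(u)

    # window-3 permutation polish
    improved = True
    guard = 0
    while improved and guard < 100:
        improved = False
        guard += 1
        for i in range(len(chain) - 2):
            window = chain[i:i + 3]
            base = _chain_cost(chain, r)
            for perm in permutations(window):
                cand = chain[:i] + list(perm) + chain[i + 3:]
                if _chain_cost(cand, r) < base - 1e-12:
                    chain = cand
                    base = _chain_cost(chain, r)
                    improved = True

    ordered = [bins[i] for i in chain]
    positions = [0.0]
    for k2 in range(1, len(chain)):
        d = kosambi_cM(r[chain[k2 - 1], chain[k2]])
        positions.append(positions[-1] + d)
    return ordered, positions


# ------------------------------------------------- distortion, SDRs, stats

@dataclass
class DistortionTest:
    chi2: float
    p_value: float
    distorted: bool
    direction: str          # 'a' | 'b' | ''
    testable: bool


def segregation_test(matrix: GenotypeMatrix, alpha: float = 0.05):
    """Per-marker chi-square against 1:1 on non-missing a/b calls (df=1)."""
    out = []
    for row in matrix.codes:
        na = int((row == GEN_A).sum())
        nb = int((row == GEN_B).sum())
        n = na + nb
        if n < 2:
            out.append(DistortionTest(float("nan"), float("nan"), False,
                                      "", False))
            continue
        chi2 = (na - nb) ** 2 / n
        p = float(sps.chi2.sf(chi2, df=1))
        direction = "a" if na > nb else ("b" if nb > na else "")
        out.append(DistortionTest(float(chi2), p, p < alpha, direction,
                                  True))
    return out


@dataclass
class SDR:
    group_id: str
    start: int              # index into the group's ordered marker list
    end: int                # inclusive
    direction: str

    @property
    def n_markers(self) -> int:
        return self.end - self.start + 1


def detect_sdrs(group_id: str, tests, min_sdr_markers: int = 3):
    """Maximal runs of >= k consecutive distorted markers, one direction."""
    sdrs = []
    i = 0
    n = len(tests)
    while i < n:
        t = tests[i]
        if not (t.testable and t.distorted and t.direction):
            i += 1
            continue
        j = i
        while (j + 1 < n and tests[j + 1].testable and tests[j + 1].distorted
               and tests[j + 1].direction == t.direction):
            j += 1
        if j - i + 1 >= min_sdr_markers:
            sdrs.append(SDR(group_id, i, j, t.direction))
        i = j + 1
    return sdrs


@dataclass
class LinkageGroup:
    id: str
    marker_ids: list
    positions: list          # per marker, cM, nondecreasing from 0
    bins: list               # list of marker-id lists
    distortion: list = field(default_factory=list)   # DistortionTest per marker
    sdrs: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.positions and abs(self.positions[0]) > 1e-9:
            raise ValueError("positions must start at 0")
        if any(b - a < -1e-9 for a, b in zip(self.positions,
                                             self.positions[1:])):
            raise ValueError("positions must be nondecreasing")

    @property
    def length(self) -> float:
        return self.positions[-1] if self.positions else 0.0


@dataclass
class GeneticMap:
    groups: list
    unlinked_markers: list = field(default_factory=list)

    @property
    def total_length(self) -> float:
        return sum(g.length for g in self.groups)


def group_statistics(positions, distortion=None, n_bins=None,
                     gap_comparator: str = "le"):
    """Table-style statistics for one ordered group.

    length = last position; density = length/(n_loci - 1) (undefined,
    reported as NaN, for a single-locus group); largest gap = max
    adjacent distance; 'gap <= 5' = share of adjacent distances <= 5 cM
    (``gap_comparator='lt'`` switches to strictly-less-than).
    """
    positions = list(positions)
    n = len(positions)
    gaps = [b - a for a, b in zip(positions, positions[1:])]
    length = positions[-1] - positions[0] if positions else 0.0
    cmp = (lambda gap: gap <= 5.0) if gap_comparator == "le" \
        else (lambda gap: gap < 5.0)
    stats = {
        "length_cM": length,
        "n_loci": n,
        "n_bins": n_bins if n_bins is not None else
        len({round(p, 9) for p in positions}),
        "density_cM_per_locus": (length / (n - 1)) if n > 1 else float("nan"),
        "largest_gap_cM": max(gaps) if gaps else 0.0,
        "gap_le_5_fraction": (sum(1 for gap in gaps if cmp(gap)) / len(gaps))
        if gaps else float("nan"),
    }
    if distortion is not None:
        stats["n_distorted"] = sum(1 for t in distortion
                                   if t.testable and t.distorted)
    return stats


def map_statistics(genetic_map: GeneticMap,
                   gap_comparator: str = "le") -> pd.DataFrame:
    """Per-group and total statistics table (Table-3 style)."""
    rows = []
    for g in genetic_map.groups:
        s = group_statistics(g.positions, g.distortion or None,
                             n_bins=len(g.bins), gap_comparator=gap_comparator)
        s["group"] = g.id
        s["n_sdrs"] = len(g.sdrs)
        rows.append(s)
    df = pd.DataFrame(rows).set_index("group")
    total = {
        "length_cM": df["length_cM"].sum(),
        "n_loci": int(df["n_loci"].sum()),
        "n_bins": int(df["n_bins"].sum()),
        "density_cM_per_locus": df["length_cM"].sum()
        / max(int(df["n_loci"].sum()) - len(df), 1),
        "largest_gap_cM": df["largest_gap_cM"].max(),
        "gap_le_5_fraction": df["gap_le_5_fraction"].mean(),
        "n_sdrs": int(df["n_sdrs"].sum()),
    }
    if "n_distorted" in df:
        total["n_distorted"] = int(df["n_distorted"].sum())
    df.loc["Total"] = pd.Series(total)
    return df


# ------------------------------------------------------------ full mapping

def build_map(matrix: GenotypeMatrix, max_rf: float = 0.45,
              min_lod=2.0, min_informative: int = 20,
              min_shared: int = 20, alpha: float = 0.05,
              min_sdr_markers: int = 3) -> GeneticMap:
    """Genotype matrix -> ordered, positioned, distortion-annotated map.

    Heterozygote codes are masked to missing first (two-point RIL
    linkage uses a/b calls only).  Groups are labelled LG1..LGn by
    decreasing marker count.
    """
    masked = matrix.mask_hets()
    pairwise = estimate_pairwise(masked, min_informative=min_informative)
    groups, unlinked = group_markers(pairwise, max_rf=max_rf,
                                     min_lod=min_lod)
    tests_all = segregation_test(masked, alpha=alpha)

    lgs = []
    for gi, group in enumerate(groups):
        bins = collapse_bins(masked, group, min_shared=min_shared)
        ordered_bins, bin_pos = order_and_place(bins, pairwise)
        marker_ids, positions, tests = [], [], []
        for b, p in zip(ordered_bins, bin_pos):
            for m in sorted(b["markers"],
                            key=lambda m: masked.marker_ids[m]):
                marker_ids.append(masked.marker_ids[m])
                positions.append(p)
                tests.append(tests_all[m])
        lg = LinkageGroup(
            id=f"LG{gi + 1}", marker_ids=marker_ids, positions=positions,
            bins=[[masked.marker_ids[m] for m in b["markers"]]
                  for b in ordered_bins],
            distortion=tests)
        lg.sdrs = detect_sdrs(lg.id, tests, min_sdr_markers=min_sdr_markers)
        lgs.append(lg)
    return GeneticMap(groups=lgs,
                      unlinked_markers=[masked.marker_ids[m]
                                        for m in unlinked])
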