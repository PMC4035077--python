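"""De novo consensus reference from reads, and gapless read alignment.

Reads from a reduced-representation library all start at a restriction
cut, so loci can be reconstructed reference-free by clustering
equal-length reads at a small Hamming radius and taking per-cluster
consensus ("tags").  Reads are then aligned back to the tags gaplessly;
reads matching one tag are *unique* and carry all downstream evidence,
reads matching several tags (homoeologs in an allopolyploid) are
*multi*, and reads matching more than ``repeat_hit_limit`` tags are
*repetitive* contamination.  All three non-unique classes are excluded
from SNP calling.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter

import numpy as np

# A=0 C=1 G=2 T=3; complement is 3 - code
_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_LUT[_b] = _i
_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode_sequences(seqs) -> np.ndarray:
    """Encode equal-length DNA strings to an (n, L) uint8 code matrix."""
    seqs = list(seqs)
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    L = len(seqs[0])
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
    return _CODE_LUT[arr].reshape(len(seqs), L)


def decode_row(row: np.ndarray) -> str:
    return _BASE_ARR[row].tobytes().decode()


def revcomp_codes(arr: np.ndarray) -> np.ndarray:
    return (3 - arr)[..., ::-1]


@dataclass
class Cluster:
    centroid: str
    members: list          # (sequence, count) pairs, centroid first
    depth: int


@dataclass
class ConsensusTag:
    id: str
    sequence: str
    depth: int


@dataclass
class AlignmentHit:
    read_id: str
    tag_id: str
    offset: int
    strand: str
    mismatches: int
    hit_class: str


CLASS_NAMES = ("unaligned", "unique", "multi", "repetitive")
CLASS_UNALIGNED, CLASS_UNIQUE, CLASS_MULTI, CLASS_REPETITIVE = range(4)


@dataclass
class AlignmentResult:
    """Array-backed alignment outcome: classes plus unique-class hits.

    Kept columnar so that genome-scale read sets do not materialise one
    object per read; :attr:`hits` and :attr:`read_class` provide the
    object view for small inputs and tests.
    """

    ids: list                       # read ids, input order
    tag_ids: list                   # tag ids, input order
    classes: np.ndarray             # int8 per read, CLASS_* codes
    u_read: np.ndarray              # indices into ids (unique reads only)
    u_tag: np.ndarray               # indices into tag_ids
    u_strand: np.ndarray            # 0 = '+', 1 = '-'
    u_mism: np.ndarray
    u_offset: np.ndarray

    @property
    def class_counts(self) -> Counter:
        c = Counter()
        for code, name in enumerate(CLASS_NAMES):
            n = int(np.count_nonzero(self.classes == code))
            if n:
                c[name] = n
        return c

    @property
    def read_class(self) -> dict:
        return {rid: CLASS_NAMES[c] for rid, c in zip(self.ids, self.classes)}

    @property
    def hits(self) -> list:
        return [AlignmentHit(read_id=self.ids[int(r)],
                             tag_id=self.tag_ids[int(t)],
                             offset=int(o),
                             strand="+" if s == 0 else "-",
                             mismatches=int(m), hit_class="unique")
                for r, t, s, m, o in zip(self.u_read, self.u_tag,
                                         self.u_strand, self.u_mism,
                                         self.u_offset)]


def _seed_blocks(length: int, n_blocks: int):
    k = length // n_blocks
    return [(b * k, b * k + k) for b in range(n_blocks)]


def _seed_values(codes: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Pack a code-matrix slice into one integer per row (2 bits/base)."""
    width = hi - lo
    pow4 = (4 ** np.arange(width, dtype=np.uint64))[::-1]
    return codes[:, lo:hi].astype(np.uint64) @ pow4


def cluster_reads(reads, radius: int = 2, min_cluster_depth: int = 4):
    """Greedy star clustering of equal-length sequences.

    Unique sequences are visited in order of decreasing abundance (ties
    by lexicographic sequence); each either joins the first existing
    centroid within Hamming distance ``radius`` or founds a new cluster.
    Clusters with total depth below ``min_cluster_depth`` are discarded.
    Deterministic by construction: the visiting order is a pure function
    of the multiset of input sequences.
    """
    counts = Counter(reads)
    if not counts:
        return []
    lengths = {len(s) for s in counts}
    if len(lengths) != 1:
        raise ValueError("cluster_reads requires uniform read length")
    L = lengths.pop()

    order = sorted(counts, key=lambda s: (-counts[s], s))
    codes = encode_sequences(order)
    n_blocks = radius + 1
    blocks = _seed_blocks(L, n_blocks)
    seeds = [_seed_values(codes, lo, hi) for lo, hi in blocks]

    index: list[dict] = [dict() for _ in blocks]  # seed value -> [centroid rows]
    centroid_rows: list[int] = []
    members: list[list[int]] = []

    for i in range(len(order)):
        cand: set[int] = set()
        for b in range(n_blocks):
            cand.update(index[b].get(int(seeds[b][i]), ()))
        joined = False
        for c in sorted(cand):  # centroid creation order
            row = centroid_rows[c]
            if int(np.count_nonzero(codes[i] != codes[row])) <= radius:
                members[c].append(i)
                joined = True
                break
        if not joined:
            c = len(centroid_rows)
            centroid_rows.append(i)
            members.append([i])
            for b in range(n_blocks):
                index[b].setdefault(int(seeds[b][i]), []).append(c)

    clusters = []
    for c, rows in enumerate(members):
        depth = sum(counts[order[r]] for r in rows)
        if depth < min_cluster_depth:
            continue
        clusters.append(Cluster(
            centroid=order[centroid_rows[c]],
            members=[(order[r], counts[order[r]]) for r in rows],
            depth=depth))
    return clusters


def build_consensus(clusters) -> list[ConsensusTag]:
    """Abundance-weighted per-position majority consensus of each cluster.

    Ties go to the lexicographically smallest base.  Tag ids follow the
    deterministic cluster order.
    """
    tags = []
    for i, cl in enumerate(clusters):
        codes = encode_sequences([seq for seq, _ in cl.members])
        weights = np.array([n for _, n in cl.members])
        tally = np.zeros((codes.shape[1], 4), dtype=np.int64)
        for b in range(4):
            tally[:, b] = ((codes == b) * weights[:, None]).sum(axis=0)
        cons = decode_row(np.argmax(tally, axis=1).astype(np.uint8))
        tags.append(ConsensusTag(id=f"tag{i:06d}", sequence=cons,
                                 depth=cl.depth))
    return tags


def _candidate_pairs(read_seeds: np.ndarray, tag_seeds: np.ndarray):
    """All (read, tag) index pairs whose seed values match, vectorized."""
    order = np.argsort(tag_seeds, kind="stable")
    sorted_seeds = tag_seeds[order]
    left = np.searchsorted(sorted_seeds, read_seeds, side="left")
    right = np.searchsorted(sorted_seeds, read_seeds, side="right")
    counts = right - left
    total = int(counts.sum())
    if total == 0:
        return (np.empty(0, dtype=np.int64),) * 2
    reads_idx = np.repeat(np.arange(len(read_seeds)), counts)
    shift = np.repeat(np.cumsum(counts) - counts, counts)
    within = np.arange(total) - shift + np.repeat(left, counts)
    return reads_idx, order[within]


def _verify_pairs(read_codes, tag_codes, r_idx, t_idx, chunk=1_000_000):
    mism = np.empty(len(r_idx), dtype=np.int32)
    for s in range(0, len(r_idx), chunk):
        e = s + chunk
        mism[s:e] = (read_codes[r_idx[s:e]] != tag_codes[t_idx[s:e]]
                     ).sum(axis=1)
    return mism


def _classify(n_hits: int, repeat_hit_limit: int) -> str:
    if n_hits == 0:
        return "unaligned"
    if n_hits == 1:
        return "unique"
    if n_hits <= repeat_hit_limit:
        return "multi"
    return "repetitive"


def align_to_tags(reads, tags, max_mismatches: int = 2,
                  repeat_hit_limit: int = 50) -> AlignmentResult:
    """Gapless alignment of reads against consensus tags, both strands.

    Every tag within Hamming distance ``max_mismatches`` of the read (on
    either strand) is a hit; the read class follows the hit count
    (unique = 1, multi = 2..``repeat_hit_limit``, repetitive above
    that).  Reads and tags of equal length go through a pigeonhole
    seed index (``max_mismatches + 1`` disjoint blocks, so no true hit
    can be missed); other length combinations fall back to an offset
    scan.  Reads longer than every tag are unaligned.

    ``reads``: iterable of (id, sequence); ``tags``: ConsensusTag list.
    """
    reads = list(reads)
    ids = [r[0] for r in reads]
    seqs = [r[1] for r in reads]
    tag_seqs = [t.sequence for t in tags]
    empty = np.empty(0, dtype=np.int64)
    result = AlignmentResult(
        ids=ids, tag_ids=[t.id for t in tags],
        classes=np.zeros(len(ids), dtype=np.int8),
        u_read=empty, u_tag=empty, u_strand=empty.copy(),
        u_mism=empty.copy(), u_offset=empty.copy())
    if not reads or not tags:
        return result

    tag_len = {len(s) for s in tag_seqs}
    fast = len(tag_len) == 1 and all(len(s) == next(iter(tag_len))
                                     for s in seqs)
    if fast:
        _align_equal_length(result, seqs, tag_seqs, max_mismatches,
                            repeat_hit_limit)
    else:
        _align_general(result, seqs, tag_seqs, max_mismatches,
                       repeat_hit_limit)
    return result


def _align_equal_length(result, seqs, tag_seqs, max_mismatches,
                        repeat_hit_limit):
    L = len(seqs[0])
    read_codes = encode_sequences(seqs)
    tag_codes = encode_sequences(tag_seqs)
    rc_codes = np.ascontiguousarray(revcomp_codes(read_codes))
    blocks = _seed_blocks(L, max_mismatches + 1)
    tag_seeds = [_seed_values(tag_codes, lo, hi) for lo, hi in blocks]

    n_tags = len(tag_seqs)
    keyed = []
    for strand, codes in ((0, read_codes), (1, rc_codes)):
        for b, (lo, hi) in enumerate(blocks):
            r_idx, t_idx = _candidate_pairs(_seed_values(codes, lo, hi),
                                            tag_seeds[b])
            if len(r_idx):
                keyed.append(r_idx * (2 * n_tags) + strand * n_tags + t_idx)

    if keyed:
        keys = np.unique(np.concatenate(keyed))
        r_idx = keys // (2 * n_tags)
        strand = (keys % (2 * n_tags)) // n_tags
        t_idx = keys % n_tags
        mism = np.empty(len(keys), dtype=np.int32)
        plus = strand == 0
        mism[plus] = _verify_pairs(read_codes, tag_codes,
                                   r_idx[plus], t_idx[plus])
        mism[~plus] = _verify_pairs(rc_codes, tag_codes,
                                    r_idx[~plus], t_idx[~plus])
        ok = mism <= max_mismatches
        r_idx, t_idx, strand, mism = (r_idx[ok], t_idx[ok], strand[ok],
                                      mism[ok])
    else:
        r_idx = t_idx = strand = np.empty(0, dtype=np.int64)
        mism = np.empty(0, dtype=np.int32)

    # a read hitting the same tag on both strands counts one hit (best)
    pair_key = r_idx * n_tags + t_idx
    order = np.lexsort((strand, mism, pair_key))
    pair_key, r_idx, t_idx, strand, mism = (a[order] for a in
                                            (pair_key, r_idx, t_idx,
                                             strand, mism))
    first = np.ones(len(pair_key), dtype=bool)
    first[1:] = pair_key[1:] != pair_key[:-1]
    r_idx, t_idx, strand, mism = (a[first] for a in
                                  (r_idx, t_idx, strand, mism))

    hit_count = np.bincount(r_idx, minlength=len(result.ids))
    n_hits_clipped = np.minimum(hit_count, repeat_hit_limit + 1)
    classes = np.full(len(result.ids), CLASS_MULTI, dtype=np.int8)
    classes[n_hits_clipped == 0] = CLASS_UNALIGNED
    classes[n_hits_clipped == 1] = CLASS_UNIQUE
    classes[hit_count > repeat_hit_limit] = CLASS_REPETITIVE
    result.classes = classes

    uniq = hit_count[r_idx] == 1
    result.u_read = r_idx[uniq]
    result.u_tag = t_idx[uniq]
    result.u_strand = strand[uniq].astype(np.int8)
    result.u_mism = mism[uniq]
    result.u_offset = np.zeros(int(uniq.sum()), dtype=np.int32)


def _align_general(result, seqs, tag_seqs, max_mismatches,
                   repeat_hit_limit):
    """Offset-scanning fallback for mixed lengths (small inputs)."""
    from .enzymes import revcomp

    u_read, u_tag, u_strand, u_mism, u_offset = [], [], [], [], []
    for i, seq in enumerate(seqs):
        best = {}
        for t_i, ts in enumerate(tag_seqs):
            if len(seq) > len(ts):
                continue
            for query, strand in ((seq, 0), (revcomp(seq), 1)):
                for off in range(len(ts) - len(seq) + 1):
                    m = sum(1 for a, b in zip(query, ts[off:off + len(query)])
                            if a != b)
                    if m <= max_mismatches:
                        cur = best.get(t_i)
                        if cur is None or m < cur[0]:
                            best[t_i] = (m, off, strand)
        cls = _classify(len(best), repeat_hit_limit)
        result.classes[i] = CLASS_NAMES.index(cls)
        if cls == "unique":
            t_i, (m, off, strand) = next(iter(best.items()))
            u_read.append(i)
            u_tag.append(t_i)
            u_strand.append(strand)
            u_mism.append(m)
            u_offset.append(off)
    result.u_read = np.array(u_read, dtype=np.int64)
    result.u_tag = np.array(u_tag, dtype=np.int64)
    result.u_strand = np.array(u_strand, dtype=np.int8)
    result.u_mism = np.array(u_mism, dtype=np.int32)
    result.u_offset = np.array(u_offset, dtype=np.int32)
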