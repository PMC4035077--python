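"""Parental SNP calling, reduced reference, and Bayesian RIL genotyping.

Between two fully homozygous parents a position is accepted as a SNP
only if (i) reads align with at most two mismatches, (ii) only uniquely
aligned reads are used, (iii) each parent shows a single base at 100%
frequency, and (iv) each allele is supported by at least four reads.
Tags carrying at least one SNP form the *reduced* reference against
which the RIL population is genotyped: per individual and locus the
genotype with the highest posterior probability under a simple
binomial error model is called, homozygous calls additionally require
the allele depth rule, and residual heterozygotes (expected at rate
2^-g after g selfing generations) are masked by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .reference import AlignmentResult, encode_sequences, revcomp_codes

GEN_A, GEN_H, GEN_B, GEN_MISSING = 0, 1, 2, -1
CODE_CHARS = {GEN_A: "a", GEN_H: "h", GEN_B: "b", GEN_MISSING: "-"}
CHAR_CODES = {v: k for k, v in CODE_CHARS.items()}
_BASES = "ACGT"


@dataclass
class ParentalSNP:
    tag_id: str
    position: int          # 0-based on the tag
    allele_p1: str
    allele_p2: str
    flank: str = ""        # full tag sequence context

    def __post_init__(self) -> None:
        if self.allele_p1 == self.allele_p2:
            raise ValueError("SNP alleles must differ")


@dataclass
class GenotypeCall:
    code: str              # a | b | h | -
    posterior: float
    depth_a: int
    depth_b: int


@dataclass
class GenotypeMatrix:
    """Markers x individuals genotype codes with per-marker metadata."""

    marker_ids: list
    individuals: list
    codes: np.ndarray      # int8 (n_markers, n_individuals), GEN_* codes
    snps: list = field(default_factory=list)   # ParentalSNP per marker

    def __post_init__(self) -> None:
        if self.codes.shape != (len(self.marker_ids), len(self.individuals)):
            raise ValueError("codes shape inconsistent with ids")

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def to_chars(self) -> np.ndarray:
        out = np.empty(self.codes.shape, dtype="U1")
        for code, ch in CODE_CHARS.items():
            out[self.codes == code] = ch
        return out

    def mask_hets(self) -> "GenotypeMatrix":
        codes = self.codes.copy()
        codes[codes == GEN_H] = GEN_MISSING
        return GenotypeMatrix(self.marker_ids, self.individuals, codes,
                              self.snps)


def strand_corrected_read_codes(result: AlignmentResult, read_seqs):
    """Code matrix of unique-hit reads in tag orientation.

    Only valid for the equal-length pipeline path (offset 0).
    """
    if len(result.u_read) == 0:
        return np.empty((0, 0), dtype=np.uint8)
    seqs = [read_seqs[int(i)] for i in result.u_read]
    codes = encode_sequences(seqs)
    minus = np.flatnonzero(result.u_strand == 1)
    if len(minus):
        codes[minus] = revcomp_codes(codes[minus])
    return codes


def pileup_counts(result: AlignmentResult, read_seqs, n_tags: int,
                  tag_length: int) -> np.ndarray:
    """Per-tag, per-position, per-base unique-read counts for one sample.

    Returns an (n_tags, tag_length, 4) int32 array; the sum over bases
    at a position equals the number of unique reads covering it.
    """
    pile = np.zeros((n_tags, tag_length, 4), dtype=np.int32)
    codes = strand_corrected_read_codes(result, read_seqs)
    if codes.size == 0:
        return pile
    pos = np.arange(tag_length)[None, :]
    tag_idx = result.u_tag[:, None].astype(np.int64)
    np.add.at(pile, (tag_idx, pos, codes.astype(np.int64)), 1)
    return pile


def call_parental_snps(pileup_p1: np.ndarray, pileup_p2: np.ndarray,
                       tags, min_allele_depth: int = 4):
    """Apply the four-criteria SNP filter to the two parents' pileups.

    A position is a SNP iff each parent shows exactly one base (100% of
    its unique reads), both supporting depths are >= ``min_allele_depth``
    and the bases differ.  Returns (ParentalSNP list, rejection tally).
    """
    if pileup_p1.shape != pileup_p2.shape:
        raise ValueError("parent pileups must cover the same tag set")
    tally = {"heterozygous_in_parent": 0, "low_depth": 0, "multi_allelic": 0}
    snps: list[ParentalSNP] = []

    cov1 = pileup_p1 > 0
    cov2 = pileup_p2 > 0
    nb1 = cov1.sum(axis=2)      # distinct bases seen per parent
    nb2 = cov2.sum(axis=2)
    for t, tag in enumerate(tags):
        for p in range(pileup_p1.shape[1]):
            k1, k2 = int(nb1[t, p]), int(nb2[t, p])
            if k1 == 0 or k2 == 0:
                continue
            if k1 > 1 or k2 > 1:
                union = int(np.count_nonzero(cov1[t, p] | cov2[t, p]))
                if union > 2:
                    tally["multi_allelic"] += 1
                else:
                    tally["heterozygous_in_parent"] += 1
                continue
            b1 = int(np.argmax(pileup_p1[t, p]))
            b2 = int(np.argmax(pileup_p2[t, p]))
            if b1 == b2:
                continue
            if (pileup_p1[t, p, b1] < min_allele_depth
                    or pileup_p2[t, p, b2] < min_allele_depth):
                tally["low_depth"] += 1
                continue
            snps.append(ParentalSNP(tag.id, p, _BASES[b1], _BASES[b2],
                                    flank=tag.sequence))
    return snps, tally


def reduce_reference(tags, snps):
    """Keep exactly the tags that carry at least one SNP.

    Raises a clear diagnostic when no SNPs exist — the pipeline cannot
    proceed to genotyping without polymorphic tags.
    """
    with_snp = {s.tag_id for s in snps}
    unknown = with_snp - {t.id for t in tags}
    if unknown:
        raise ValueError(f"SNPs reference unknown tags: {sorted(unknown)[:5]}")
    if not with_snp:
        raise ValueError("no SNP-bearing tags: reduced reference is empty")
    return [t for t in tags if t.id in with_snp]


def genotype_log_likelihoods(na, nb, error_rate: float = 0.01):
    """Log10 likelihoods of (aa, ab, bb) given biallelic read counts.

    L(aa) = (1-e)^na e^nb, L(bb) = e^na (1-e)^nb, L(ab) = (1/2)^(na+nb);
    the shared binomial coefficient cancels in the posterior.
    """
    na = np.asarray(na, dtype=float)
    nb = np.asarray(nb, dtype=float)
    if (na < 0).any() or (nb < 0).any():
        raise ValueError("read counts must be non-negative")
    # clamp away from 0/1 so homozygote likelihoods stay finite
    e = min(max(error_rate, 1e-12), 0.5)
    l_aa = na * np.log10(1 - e) + nb * np.log10(e)
    l_bb = na * np.log10(e) + nb * np.log10(1 - e)
    l_ab = (na + nb) * np.log10(0.5)
    return np.stack([l_aa, l_ab, l_bb], axis=-1)


def f9_prior(selfing_generations: int = 8):
    """RIL-informed prior: residual het probability 2^-g, homozygotes equal."""
    h = 0.5 ** selfing_generations
    return ((1 - h) / 2, h, (1 - h) / 2)


def call_genotypes_array(na, nb, error_rate: float = 0.01,
                         prior=(1 / 3, 1 / 3, 1 / 3),
                         min_allele_depth: int = 4,
                         het_policy: str = "mask"):
    """Vectorised Bayesian genotype calls.

    Returns (codes int8 array, posterior array).  The maximum-posterior
    genotype is called; homozygous calls require the supporting allele
    depth >= ``min_allele_depth`` (else missing); heterozygous calls are
    masked to missing under the default policy (``het_policy='keep'``
    retains them).
    """
    if het_policy not in ("mask", "keep"):
        raise ValueError("het_policy must be 'mask' or 'keep'")
    na = np.asarray(na)
    nb = np.asarray(nb)
    ll = genotype_log_likelihoods(na, nb, error_rate)
    ll = ll + np.log10(np.asarray(prior, dtype=float))
    ll -= ll.max(axis=-1, keepdims=True)
    post = 10.0 ** ll
    post /= post.sum(axis=-1, keepdims=True)
    best = np.argmax(post, axis=-1)
    posterior = np.take_along_axis(post, best[..., None], axis=-1)[..., 0]

    codes = np.full(na.shape, GEN_MISSING, dtype=np.int8)
    codes[(best == 0) & (na >= min_allele_depth)] = GEN_A
    codes[(best == 2) & (nb >= min_allele_depth)] = GEN_B
    codes[best == 1] = GEN_H if het_policy == "keep" else GEN_MISSING
    nocov = (na + nb) == 0
    codes[nocov] = GEN_MISSING
    posterior = np.where(codes == GEN_MISSING, np.nan, posterior)
    return codes, posterior


def call_genotype(counts_a: int, counts_b: int, error_rate: float = 0.01,
                  prior=(1 / 3, 1 / 3, 1 / 3), min_allele_depth: int = 4,
                  het_policy: str = "mask") -> GenotypeCall:
    """Single-locus, single-individual genotype call (scalar wrapper)."""
    codes, post = call_genotypes_array(
        np.array([counts_a]), np.array([counts_b]), error_rate, prior,
        min_allele_depth, het_policy)
    code = int(codes[0])
    return GenotypeCall(code=CODE_CHARS[code],
                        posterior=float(post[0]) if code != GEN_MISSING
                        else float("nan"),
                        depth_a=int(counts_a), depth_b=int(counts_b))


def allele_counts_for_sample(result: AlignmentResult, read_seqs,
                             snp_tag_idx: np.ndarray, snp_pos: np.ndarray,
                             snp_a: np.ndarray, snp_b: np.ndarray,
                             n_tags: int):
    """Per-SNP counts of parental alleles a and b for one individual.

    Reads showing a base other than the two parental alleles are
    discarded before counting (biallelic collapse); their counts are
    returned separately so loci with heavy third-allele contamination
    can be flagged.
    """
    n_snps = len(snp_tag_idx)
    ca = np.zeros(n_snps, dtype=np.int32)
    cb = np.zeros(n_snps, dtype=np.int32)
    cother = np.zeros(n_snps, dtype=np.int32)
    if len(result.u_read) == 0 or n_snps == 0:
        return ca, cb, cother
    codes = strand_corrected_read_codes(result, read_seqs)

    order = np.argsort(snp_tag_idx, kind="stable")
    sorted_tag = snp_tag_idx[order]
    starts = np.searchsorted(sorted_tag, np.arange(n_tags), side="left")
    ends = np.searchsorted(sorted_tag, np.arange(n_tags), side="right")
    per_hit = ends[result.u_tag] - starts[result.u_tag]
    total = int(per_hit.sum())
    if total == 0:
        return ca, cb, cother
    hit_rows = np.repeat(np.arange(len(result.u_tag)), per_hit)
    shift = np.repeat(np.cumsum(per_hit) - per_hit, per_hit)
    within = np.arange(total) - shift + np.repeat(starts[result.u_tag],
                                                  per_hit)
    snp_rows = order[within]
    bases = codes[hit_rows, snp_pos[snp_rows]]
    np.add.at(ca, snp_rows[bases == snp_a[snp_rows]], 1)
    np.add.at(cb, snp_rows[bases == snp_b[snp_rows]], 1)
    other = (bases != snp_a[snp_rows]) & (bases != snp_b[snp_rows])
    np.add.at(cother, snp_rows[other], 1)
    return ca, cb, cother


def build_genotype_matrix(codes: np.ndarray, marker_ids, individuals,
                          snps=None, mmd: float = 0.25,
                          min_allele_individuals: int = 30):
    """Apply the marker-level presence filters; return (matrix, tally).

    A marker is dropped when its missing fraction exceeds ``mmd``
    (maximum missing data) or when either parental allele is present in
    fewer than ``min_allele_individuals`` individuals (heterozygotes
    count for both alleles).  The tally conserves: markers in =
    retained + dropped_mmd + dropped_minor_allele.
    """
    codes = np.asarray(codes, dtype=np.int8)
    n_markers, n_ind = codes.shape
    missing = (codes == GEN_MISSING).sum(axis=1)
    n_a = (codes == GEN_A).sum(axis=1) + (codes == GEN_H).sum(axis=1)
    n_b = (codes == GEN_B).sum(axis=1) + (codes == GEN_H).sum(axis=1)

    drop_mmd = missing > mmd * n_ind
    drop_minor = (~drop_mmd) & ((n_a < min_allele_individuals)
                                | (n_b < min_allele_individuals))
    keep = ~(drop_mmd | drop_minor)
    tally = {"markers_in": n_markers,
             "retained": int(keep.sum()),
             "dropped_mmd": int(drop_mmd.sum()),
             "dropped_minor_allele": int(drop_minor.sum())}
    matrix = GenotypeMatrix(
        marker_ids=[m for m, k in zip(marker_ids, keep) if k],
        individuals=list(individuals),
        codes=codes[keep],
        snps=[s for s, k in zip(snps, keep) if k] if snps is not None else [])
    return matrix, tally


def drop_high_het_markers(codes: np.ndarray, threshold: float = 0.1):
    """Strict heterozygote policy: mask whole loci with het excess.

    Returns a boolean keep-mask over markers; loci where the fraction of
    non-missing calls that are heterozygous exceeds ``threshold`` are
    flagged for removal.  Exposed as an alternative to per-call masking.
    """
    codes = np.asarray(codes)
    non_missing = (codes != GEN_MISSING).sum(axis=1)
    hets = (codes == GEN_H).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # 0/0 -> nan -> keep
        frac = hets / non_missing
    return ~(frac > threshold)
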