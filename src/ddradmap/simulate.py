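"""Synthetic biparental RIL cross and multiplexed ddRAD read sets.

The generator emulates the study design behind a reference-free ddRAD
linkage map in an allotetraploid selfer: two fully homozygous parents
that differ at biallelic SNPs on shared SacI/MseI restriction fragments,
an F9 recombinant-inbred population produced by eight selfing
generations, and ~90 bp paired-end reads carrying 5-8 bp inline barcodes
in 12-plex pools.  Homoeologous (diverged duplicate) tags and a
high-copy repeat family are injected to exercise the uniqueness filters
downstream.  Every simulated object is recorded in a :class:`TruthSet`
so each pipeline stage can be scored against ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .enzymes import EnzymeSpec, MSEI, SACI, revcomp

BASES = "ACGT"
_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)
# byte value -> 0..3 code
_CODE_LUT = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_LUT[_b] = _i

# genotype codes used throughout
GEN_A, GEN_H, GEN_B, GEN_MISSING = 0, 1, 2, -1
GENOTYPE_CHARS = {GEN_A: "a", GEN_H: "h", GEN_B: "b", GEN_MISSING: "-"}

#: 12 default inline barcodes (MIDs), lengths 5-8 bp.  Their first five
#: bases are pairwise distinct, which makes the set prefix-free.
DEFAULT_BARCODES = (
    "ACACA", "CGTAT", "GATCG", "TTAGC",
    "AGGTAC", "CTCAGT", "GGATTC", "TACGGA",
    "ACTGTCA", "CATACGT", "GTGCATC", "TGAGTAC",
)


def _check_prefix_free(barcodes) -> None:
    bcs = list(barcodes)
    if len(set(bcs)) != len(bcs):
        raise ValueError("barcodes must be pairwise distinct")
    for i, a in enumerate(bcs):
        for j, b in enumerate(bcs):
            if i != j and b.startswith(a):
                raise ValueError(f"barcode {a} is a prefix of {b}")


@dataclass
class SimConfig:
    """Parameters of the synthetic cross and library.

    Defaults follow the study design: 166 F9 lines from eight selfing
    generations, ~90 bp reads, 12 individuals per pool with 5-8 bp
    barcodes, SacI/MseI digestion with a 300-500 bp total size window
    (insert plus ``adaptor_length`` of adaptors and indices), eight-fold
    mean coverage per tag per individual.
    """

    n_chromosomes: int = 20
    chrom_length_cM: float = 72.0
    n_tags: int = 2000
    snp_rate: float = 0.005
    paralog_fraction: float = 0.10
    repeat_copies: int = 60
    n_individuals: int = 166
    selfing_generations: int = 8
    read_length: int = 90
    mean_depth: float = 8.0
    parent_mean_depth: float = 16.0
    error_rate: float = 0.001
    barcode_set: tuple = DEFAULT_BARCODES
    pool_size: int = 12
    insert_window: tuple = (300, 500)
    adaptor_length: int = 76
    enzyme_a: EnzymeSpec = SACI
    enzyme_b: EnzymeSpec = MSEI
    min_snps_per_tag: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "n_tags", "n_individuals",
                     "selfing_generations", "read_length", "pool_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("snp_rate", "paralog_fraction", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.repeat_copies < 0:
            raise ValueError("repeat_copies must be >= 0")
        lo, hi = self.insert_window
        if lo > hi:
            raise ValueError("insert_window min must be <= max")
        if lo - self.adaptor_length < self.read_length:
            raise ValueError(
                "insert_window minus adaptor_length must leave fragments "
                "at least one read long"
            )
        _check_prefix_free(self.barcode_set)
        for bc in self.barcode_set:
            if not 5 <= len(bc) <= 8:
                raise ValueError("barcodes must be 5-8 bp")
        if self.pool_size > len(self.barcode_set):
            raise ValueError("pool_size exceeds available barcodes")

    @property
    def fragment_window(self) -> tuple[int, int]:
        """Bare-insert size window after removing adaptors/indices."""
        lo, hi = self.insert_window
        return lo - self.adaptor_length, hi - self.adaptor_length

    @property
    def max_barcode_length(self) -> int:
        return max(len(b) for b in self.barcode_set)

    @property
    def effective_read_length(self) -> int:
        """Genomic bases common to all reads once barcodes are trimmed."""
        return self.read_length - self.max_barcode_length


@dataclass
class TrueSNP:
    tag: int
    position: int  # 0-based on the tag, read1 orientation
    allele1: str   # parent 1 base
    allele2: str   # parent 2 base


@dataclass
class TruthSet:
    """Ground truth against which every pipeline stage is scored."""

    config: SimConfig
    parent1_tags: list = field(default_factory=list)
    parent2_tags: list = field(default_factory=list)
    tag_kind: list = field(default_factory=list)      # core | paralog | repeat
    paralog_source: dict = field(default_factory=dict)
    true_snps: list = field(default_factory=list)
    # per chromosome: list of (tag index, cM position), positions increasing
    true_map: list = field(default_factory=list)
    chrom_of_tag: dict = field(default_factory=dict)
    cm_of_tag: dict = field(default_factory=dict)
    # individuals x core loci, codes GEN_A/GEN_H/GEN_B; filled by
    # simulate_ril_population.  Columns follow mapped_tags order.
    true_genotypes: np.ndarray | None = None
    mapped_tags: list = field(default_factory=list)
    sample_names: list = field(default_factory=list)

    @property
    def n_tags(self) -> int:
        return len(self.parent1_tags)

    def snps_of_tag(self, tag: int) -> list:
        return [s for s in self.true_snps if s.tag == tag]

    def window_sequences(self, length: int, parent: int = 1):
        """Per tag, the (read1-window, read2-window) sequences of a parent.

        Read 1 covers the first ``length`` bases of the fragment, read 2
        the reverse complement of its last ``length`` bases; together
        they are what the sequencer can observe of each tag.
        """
        tags = self.parent1_tags if parent == 1 else self.parent2_tags
        return [(t[:length], revcomp(t)[:length]) for t in tags]

    def observable_snps(self, length: int) -> set:
        """True SNPs visible in at least one read window.

        Returned as tuples ``(tag, fragment position, allele1, allele2)``
        in fragment (read1) orientation, deduplicated across windows.
        """
        out = set()
        for s in self.true_snps:
            tag_len = len(self.parent1_tags[s.tag])
            if s.position < length or s.position >= tag_len - length:
                out.add((s.tag, s.position, s.allele1, s.allele2))
        return out


def parse_read_id(read_id: str):
    """Recover (sample, tag index, haplotype parent, serial) from a read id.

    Provenance is encoded in the id itself so it survives demultiplexing
    and pooling without side tables.
    """
    sample, tag, hap, serial = read_id.split("|")
    return sample, int(tag), int(hap), int(serial)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _sanitize_sites(seq: str, config: SimConfig, core_start: int,
                    core_end: int, rng: np.random.Generator) -> str:
    """Mutate core bases until the tag contains no internal cut site.

    A retained ddRAD fragment cannot contain an uncut recognition site,
    so any occurrence created by the random core is broken by flipping
    one base inside it (within the mutable core region).
    """
    sites = [config.enzyme_a.site, config.enzyme_b.site]
    s = list(seq)
    for _ in range(200):
        dirty = False
        text = "".join(s)
        for site in sites:
            i = text.find(site)
            while i >= 0:
                pos = [p for p in range(i, i + len(site))
                       if core_start <= p < core_end]
                if pos:
                    p = pos[len(pos) // 2]
                    s[p] = BASES[(BASES.index(s[p]) + 1 + rng.integers(0, 3)) % 4]
                    dirty = True
                i = text.find(site, i + 1)
        if not dirty:
            return "".join(s)
    raise RuntimeError("could not sanitize tag sequence")  # pragma: no cover


def _site_free(seq: list, p: int, sites) -> bool:
    """True if no recognition site overlaps position ``p``."""
    for site in sites:
        k = len(site)
        lo = max(0, p - k + 1)
        window = "".join(seq[lo:p + k])
        if site in window:
            return False
    return True


def _mutate_safe(seq: list, p: int, rng: np.random.Generator, sites):
    """A base != seq[p] at p that creates no cut site, or None.

    Substituting a single base can only create a site overlapping it,
    so the check is local.  Candidate order is randomised.
    """
    cur = seq[p]
    start = int(rng.integers(0, 3))
    for k in range(3):
        cand = BASES[(BASES.index(cur) + 1 + (start + k) % 3) % 4]
        seq[p] = cand
        if _site_free(seq, p, sites):
            seq[p] = cur
            return cand
    seq[p] = cur
    return None


def simulate_founders(config: SimConfig,
                      rng: np.random.Generator | None = None) -> TruthSet:
    """Draw the two homozygous parents' tag sequences and true SNPs.

    Each tag models one size-selected SacI-MseI fragment in read1
    orientation: SacI remnant + core + reverse-complemented MseI
    remnant.  Parent 2 differs from parent 1 at Bernoulli(``snp_rate``)
    core positions.  ``paralog_fraction`` of core tags get a homoeolog
    copy diverged at two read-visible positions (identical in both
    parents); one repeat family of ``repeat_copies`` near-identical
    tags is injected.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    truth = TruthSet(config=config)

    rem_a = config.enzyme_a.remnant
    rem_b_rc = revcomp(config.enzyme_b.remnant)
    lo, hi = config.fragment_window
    eff = config.effective_read_length

    sites = (config.enzyme_a.site, config.enzyme_b.site)
    for t in range(config.n_tags):
        length = int(rng.integers(lo, hi + 1))
        core_len = length - len(rem_a) - len(rem_b_rc)
        core = _random_seq(rng, core_len)
        tag1 = _sanitize_sites(rem_a + core + rem_b_rc, config,
                               len(rem_a), length - len(rem_b_rc), rng)
        tag2 = list(tag1)
        snp_mask = rng.random(core_len) < config.snp_rate
        snp_pos = [len(rem_a) + i for i in np.flatnonzero(snp_mask)]
        if config.min_snps_per_tag and len(snp_pos) < config.min_snps_per_tag:
            extra = rng.choice(core_len, size=config.min_snps_per_tag,
                               replace=False)
            snp_pos = sorted(set(snp_pos) | {len(rem_a) + int(i)
                                             for i in extra})
        for p in snp_pos:
            # the alternate allele must not recreate a cut site; a SNP
            # with no site-free alternate (rare) is dropped
            a2 = _mutate_safe(tag2, p, rng, sites)
            if a2 is None:
                continue
            truth.true_snps.append(TrueSNP(t, p, tag1[p], a2))
            tag2[p] = a2
        truth.parent1_tags.append(tag1)
        truth.parent2_tags.append("".join(tag2))
        truth.tag_kind.append("core")

    _inject_paralogs(truth, config, rng, eff)
    _inject_repeats(truth, config, rng, eff)

    # genetic map over core tags: round-robin chromosome assignment,
    # uniform positions, strictly increasing within a chromosome
    core = [i for i, k in enumerate(truth.tag_kind) if k == "core"]
    truth.true_map = [[] for _ in range(config.n_chromosomes)]
    for j, t in enumerate(core):
        truth.true_map[j % config.n_chromosomes].append(t)
    for c, tags in enumerate(truth.true_map):
        pos = np.sort(rng.uniform(0.0, config.chrom_length_cM, size=len(tags)))
        # resolve (measure-zero) ties so positions are strictly increasing
        for k in range(1, len(pos)):
            if pos[k] <= pos[k - 1]:
                pos[k] = np.nextafter(pos[k - 1], np.inf)
        truth.true_map[c] = list(zip(tags, pos.tolist()))
        for t, p in truth.true_map[c]:
            truth.chrom_of_tag[t] = c
            truth.cm_of_tag[t] = p
    truth.mapped_tags = [t for group in truth.true_map for t, _ in group]
    return truth


def _inject_paralogs(truth, config, rng, eff) -> None:
    n_par = int(round(config.paralog_fraction * config.n_tags))
    if n_par == 0:
        return
    sources = rng.choice(config.n_tags, size=n_par, replace=False)
    rem_a_len = len(config.enzyme_a.remnant)
    sites = (config.enzyme_a.site, config.enzyme_b.site)
    for src in sources:
        src = int(src)
        tag = list(truth.parent1_tags[src])
        L = len(tag)
        snp_positions = {s.position for s in truth.snps_of_tag(src)}
        # one divergent base in each read window so merged clusters show
        # the homoeolog as within-parent heterozygosity at read scale
        for wlo, whi in ((rem_a_len, eff), (max(L - eff, rem_a_len), L - 3)):
            for _ in range(50):
                p = int(rng.integers(wlo, whi))
                if p in snp_positions:
                    continue
                base = _mutate_safe(tag, p, rng, sites)
                if base is not None:
                    tag[p] = base
                    break
        seq = "".join(tag)
        truth.parent1_tags.append(seq)
        truth.parent2_tags.append(seq)  # homoeolog: fixed in both parents
        truth.tag_kind.append("paralog")
        truth.paralog_source[len(truth.parent1_tags) - 1] = src


def _inject_repeats(truth, config, rng, eff) -> None:
    if config.repeat_copies <= 0:
        return
    rem_a = config.enzyme_a.remnant
    rem_b_rc = revcomp(config.enzyme_b.remnant)
    lo, hi = config.fragment_window
    # prefer a fragment long enough that the two read windows are
    # disjoint, so each copy's divergence is one base per window
    L = min(max(lo, 2 * eff), hi)
    core = _random_seq(rng, L - len(rem_a) - len(rem_b_rc))
    ancestor = _sanitize_sites(rem_a + core + rem_b_rc, config,
                               len(rem_a), L - len(rem_b_rc), rng)
    w1 = list(range(len(rem_a), min(eff, L - eff)))
    w2 = list(range(max(L - eff, eff), L - len(rem_b_rc)))
    rng.shuffle(w1)
    rng.shuffle(w2)
    sites = (config.enzyme_a.site, config.enzyme_b.site)
    for i in range(config.repeat_copies):
        tag = list(ancestor)
        # each copy diverges at one distinct position per read window
        for window in (w1, w2):
            for attempt in range(len(window)):
                p = window[(i + attempt) % len(window)]
                base = _mutate_safe(tag, p, rng, sites)
                if base is not None:
                    tag[p] = base
                    break
        seq = "".join(tag)
        truth.parent1_tags.append(seq)
        truth.parent2_tags.append(seq)
        truth.tag_kind.append("repeat")


def _meiosis(hap1: np.ndarray, hap2: np.ndarray, pos_morgan: np.ndarray,
             length_morgan: float, rng: np.random.Generator) -> np.ndarray:
    """One gamete under the Haldane (no-interference) crossover model.

    Crossover count is Poisson(map length in Morgans) with uniform
    positions; the starting chromatid is chosen at random.
    """
    n_cx = rng.poisson(length_morgan)
    start = int(rng.integers(0, 2))
    if n_cx == 0:
        return (hap1 if start == 0 else hap2).copy()
    cx = np.sort(rng.uniform(0.0, length_morgan, size=n_cx))
    phase = (start + np.searchsorted(cx, pos_morgan)) % 2
    return np.where(phase == 0, hap1, hap2)


def simulate_ril_population(truth: TruthSet, config: SimConfig,
                            rng: np.random.Generator | None = None) -> TruthSet:
    """Self an F1 for ``selfing_generations`` rounds; record genotypes.

    The F1 is uniformly heterozygous.  Each selfing generation draws two
    independent gametes from the current plant.  Genotypes at the mapped
    tag loci are coded GEN_A / GEN_H / GEN_B (parent-1 homozygote,
    heterozygote, parent-2 homozygote).
    """
    if config.n_chromosomes <= 0 or not truth.true_map:
        raise ValueError("true_map must be present (zero chromosomes?)")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)

    chrom_pos = [np.array([p for _, p in group]) / 100.0
                 for group in truth.true_map]
    length_m = config.chrom_length_cM / 100.0
    n_loci = sum(len(g) for g in truth.true_map)
    geno = np.empty((config.n_individuals, n_loci), dtype=np.int8)

    for ind in range(config.n_individuals):
        col = 0
        for pos in chrom_pos:
            h1 = np.zeros(len(pos), dtype=np.int8)   # F1: parent1 / parent2
            h2 = np.ones(len(pos), dtype=np.int8)
            for _ in range(config.selfing_generations):
                g1 = _meiosis(h1, h2, pos, length_m, rng)
                g2 = _meiosis(h1, h2, pos, length_m, rng)
                h1, h2 = g1, g2
            geno[ind, col:col + len(pos)] = h1 + h2
            col += len(pos)
    truth.true_genotypes = geno
    return truth


def _assign_samples(config: SimConfig):
    """Sample names, barcodes and pools: parents first, then RILs 12-plex."""
    width = max(3, len(str(config.n_individuals)))
    names = ["P1", "P2"] + [f"RIL{i + 1:0{width}d}"
                            for i in range(config.n_individuals)]
    roles = ["parent1", "parent2"] + ["ril"] * config.n_individuals
    rows = []
    for i, (name, role) in enumerate(zip(names, roles)):
        pool = f"pool{i // config.pool_size:02d}"
        barcode = config.barcode_set[i % config.pool_size]
        rows.append({"sample": name, "barcode": barcode,
                     "pool": pool, "role": role})
    return rows


def _apply_errors(seqs: np.ndarray, rng: np.random.Generator,
                  error_rate: float, protect: int = 0):
    """Substitute bases at ``error_rate`` and return (seqs, qualities).

    Correct bases get Q40 ('I'); erroneous ones Q7 ('('), a two-level
    model sufficient to exercise quality trimming.  The first
    ``protect`` columns (inline barcode) are left error-free so that
    assignment failures are not confounded with sequencing error.
    """
    qual = np.full(seqs.shape, ord("I"), dtype=np.uint8)
    if error_rate > 0:
        mask = rng.random(seqs.shape) < error_rate
        if protect:
            mask[:, :protect] = False
        if mask.any():
            codes = _CODE_LUT[seqs[mask]]
            shift = rng.integers(1, 4, size=codes.shape).astype(np.uint8)
            seqs[mask] = _BASE_ARR[(codes + shift) % 4]
            qual[mask] = ord("(")
    return seqs, qual


def _rows_to_strings(arr: np.ndarray) -> list[str]:
    data = arr.tobytes()
    w = arr.shape[1]
    return [data[i:i + w].decode() for i in range(0, len(data), w)]


def simulate_read_set(truth: TruthSet, config: SimConfig, outdir,
                      rng: np.random.Generator | None = None) -> dict:
    """Write multiplexed paired FASTQ pools plus sample sheet and truth TSVs.

    Per individual per tag the read-pair count is Poisson(``mean_depth``)
    (``parent_mean_depth`` for the parents).  Read 1 is barcode + SacI
    remnant + fragment prefix; read 2 starts at the MseI end (reverse
    complement).  Returns a manifest of written paths and per-sample
    pair counts.
    """
    if truth.true_genotypes is None:
        raise ValueError("true_genotypes must be filled before read simulation")
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    samples = _assign_samples(config)
    col_of_tag = {t: j for j, t in enumerate(truth.mapped_tags)}
    rl = config.read_length

    handles = {}
    paths = {}
    for row in samples:
        pool = row["pool"]
        if pool not in handles:
            p1 = outdir / f"{pool}_R1.fastq"
            p2 = outdir / f"{pool}_R2.fastq"
            handles[pool] = (open(p1, "w"), open(p2, "w"))
            paths[pool] = (p1, p2)

    pair_counts = {row["sample"]: 0 for row in samples}
    serial = 0
    for t in range(truth.n_tags):
        tag1, tag2 = truth.parent1_tags[t], truth.parent2_tags[t]
        rc1, rc2 = revcomp(tag1), revcomp(tag2)
        col = col_of_tag.get(t)
        r1_parts, r2_parts, metas = [], [], []
        for s_idx, row in enumerate(samples):
            depth = (config.parent_mean_depth if row["role"] != "ril"
                     else config.mean_depth)
            n = int(rng.poisson(depth))
            if n == 0:
                continue
            if row["role"] == "parent1":
                haps = np.zeros(n, dtype=np.int8)
            elif row["role"] == "parent2":
                haps = np.ones(n, dtype=np.int8)
            else:
                g = (truth.true_genotypes[s_idx - 2, col]
                     if col is not None else GEN_A)
                if g == GEN_A:
                    haps = np.zeros(n, dtype=np.int8)
                elif g == GEN_B:
                    haps = np.ones(n, dtype=np.int8)
                else:  # heterozygote: each read pair samples a haplotype
                    haps = rng.integers(0, 2, size=n).astype(np.int8)
            bc = row["barcode"]
            glen = rl - len(bc)
            for h in haps:
                src, rcsrc = (tag1, rc1) if h == 0 else (tag2, rc2)
                r1_parts.append(bc + src[:glen])
                r2_parts.append(rcsrc[:rl])
                metas.append((row, f"{row['sample']}|{t}|{int(h) + 1}|{serial}",
                              len(bc)))
                serial += 1
        if not metas:
            continue
        a1 = np.frombuffer("".join(r1_parts).encode(), dtype=np.uint8
                           ).reshape(len(metas), rl).copy()
        a2 = np.frombuffer("".join(r2_parts).encode(), dtype=np.uint8
                           ).reshape(len(metas), rl).copy()
        a1, q1 = _apply_errors(a1, rng, config.error_rate,
                               protect=max(len(m[0]["barcode"]) for m in metas))
        a2, q2 = _apply_errors(a2, rng, config.error_rate)
        s1, s2 = _rows_to_strings(a1), _rows_to_strings(a2)
        t1, t2 = _rows_to_strings(q1), _rows_to_strings(q2)
        for k, (row, rid, _) in enumerate(metas):
            f1, f2 = handles[row["pool"]]
            f1.write(f"@{rid}/1\n{s1[k]}\n+\n{t1[k]}\n")
            f2.write(f"@{rid}/2\n{s2[k]}\n+\n{t2[k]}\n")
            pair_counts[row["sample"]] += 1

    for f1, f2 in handles.values():
        f1.close()
        f2.close()

    sheet_path = outdir / "samples.tsv"
    with open(sheet_path, "w") as fh:
        fh.write("sample\tbarcode\tpool\trole\n")
        for row in samples:
            fh.write(f"{row['sample']}\t{row['barcode']}\t{row['pool']}\t"
                     f"{row['role']}\n")
    write_truth_files(truth, outdir)

    truth.sample_names = [row["sample"] for row in samples]
    return {
        "pools": {pool: (str(p1), str(p2)) for pool, (p1, p2) in paths.items()},
        "sample_sheet": str(sheet_path),
        "pair_counts": pair_counts,
    }


def write_truth_files(truth: TruthSet, outdir) -> None:
    """Persist true SNPs, genotypes and map as plain TSV."""
    outdir = Path(outdir)
    with open(outdir / "true_snps.tsv", "w") as fh:
        fh.write("tag\tposition\tallele1\tallele2\n")
        for s in truth.true_snps:
            fh.write(f"{s.tag}\t{s.position}\t{s.allele1}\t{s.allele2}\n")
    with open(outdir / "true_map.tsv", "w") as fh:
        fh.write("chromosome\ttag\tposition_cM\n")
        for c, group in enumerate(truth.true_map):
            for t, p in group:
                fh.write(f"{c}\t{t}\t{p:.6f}\n")
    if truth.true_genotypes is not None:
        n_ind = truth.true_genotypes.shape[0]
        with open(outdir / "true_genotypes.tsv", "w") as fh:
            fh.write("tag\t" + "\t".join(
                f"ind{i + 1}" for i in range(n_ind)) + "\n")
            for j, t in enumerate(truth.mapped_tags):
                codes = "\t".join(GENOTYPE_CHARS[int(g)]
                                  for g in truth.true_genotypes[:, j])
                fh.write(f"{t}\t{codes}\n")


def simulate_dataset(config: SimConfig, outdir) -> tuple[TruthSet, dict]:
    """Founders -> RIL population -> read set, end to end."""
    rng = np.random.default_rng(config.seed)
    truth = simulate_founders(config, rng)
    simulate_ril_population(truth, config, rng)
    manifest = simulate_read_set(truth, config, outdir, rng)
    return truth, manifest


def config_to_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["enzyme_a"] = dataclasses.asdict(config.enzyme_a)
    d["enzyme_b"] = dataclasses.asdict(config.enzyme_b)
    return d
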