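"""Demultiplexing by exact inline barcode + restriction remnant, and QC.

A read pair is assigned to an individual iff read 1 starts with exactly
one sample-sheet barcode immediately followed by the expected bases left
by the rare-cutter site (the remnant).  Barcodes are exact-match only;
the prefix-free sample sheet guarantees at most one barcode can match.
Quality control trims low-quality 3' tails and drops short pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .enzymes import EnzymeSpec, MSEI, SACI


@dataclass(frozen=True)
class SampleSheetRow:
    sample: str
    barcode: str
    pool: str
    role: str = "ril"


@dataclass
class SampleSheet:
    rows: list

    def __post_init__(self) -> None:
        samples = [r.sample for r in self.rows]
        if len(set(samples)) != len(samples):
            raise ValueError("sample ids must be unique")
        pools = {}
        for r in self.rows:
            pools.setdefault(r.pool, []).append(r.barcode)
        for pool, bcs in pools.items():
            if len(set(bcs)) != len(bcs):
                raise ValueError(f"pool {pool}: duplicate barcodes")
            for i, a in enumerate(bcs):
                for j, b in enumerate(bcs):
                    if i != j and b.startswith(a):
                        raise ValueError(
                            f"pool {pool}: barcode {a} is a prefix of {b}")

    @classmethod
    def from_tsv(cls, path) -> "SampleSheet":
        rows = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {name: i for i, name in enumerate(header)}
            for line in fh:
                f = line.rstrip("\n").split("\t")
                rows.append(SampleSheetRow(
                    sample=f[idx["sample"]], barcode=f[idx["barcode"]],
                    pool=f[idx["pool"]],
                    role=f[idx["role"]] if "role" in idx else "ril"))
        return cls(rows)

    def pool_rows(self, pool: str) -> list:
        return [r for r in self.rows if r.pool == pool]

    @property
    def pools(self) -> list:
        seen = []
        for r in self.rows:
            if r.pool not in seen:
                seen.append(r.pool)
        return seen


@dataclass
class ReadPair:
    id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str


@dataclass
class DemuxStats:
    total_pairs: int = 0
    assigned_pairs: dict = field(default_factory=dict)

    @property
    def n_assigned(self) -> int:
        return sum(self.assigned_pairs.values())

    @property
    def n_unassigned(self) -> int:
        return self.total_pairs - self.n_assigned


def read_fastq_pairs(path1, path2):
    """Iterate paired FASTQ records as ReadPair objects.

    Raises a ValueError naming the record offset on malformed or
    desynchronised input.
    """
    with open(path1) as f1, open(path2) as f2:
        it1, it2 = FastqGeneralIterator(f1), FastqGeneralIterator(f2)
        n = 0
        while True:
            r1 = next(it1, None)
            r2 = next(it2, None)
            if r1 is None and r2 is None:
                return
            if r1 is None or r2 is None:
                raise ValueError(f"FASTQ pair desynchronised at record {n}")
            (id1, s1, q1), (id2, s2, q2) = r1, r2
            if len(s1) != len(q1) or len(s2) != len(q2):
                raise ValueError(f"malformed FASTQ record at offset {n}")
            name = id1.split()[0]
            if name.endswith("/1") or name.endswith("/2"):
                name = name[:-2]
            yield ReadPair(name, s1, q1, s2, q2)
            n += 1


def demultiplex(pairs, sheet_rows, enz_a: EnzymeSpec = SACI,
                enz_b: EnzymeSpec = MSEI, trim_remnant: bool = False,
                check_read2_remnant: bool = False):
    """Assign read pairs to samples; return (per-sample pairs, stats).

    Assignment requires read 1 to start with exactly one barcode
    followed by the ``enz_a`` remnant.  The barcode is trimmed from the
    retained read; the remnant is genuine locus sequence shared by all
    reads of a tag and is retained unless ``trim_remnant``.  Optionally
    read 2 is required to start with the ``enz_b`` remnant.  Unassigned
    pairs are counted and discarded.
    """
    rem_a, rem_b = enz_a.remnant, enz_b.remnant
    lut = {r.barcode + rem_a: r.sample for r in sheet_rows}
    lengths = sorted({len(r.barcode) for r in sheet_rows})
    per_sample: dict[str, list] = {r.sample: [] for r in sheet_rows}
    stats = DemuxStats(assigned_pairs={r.sample: 0 for r in sheet_rows})
    bc_len = {r.barcode + rem_a: len(r.barcode) for r in sheet_rows}
    for pair in pairs:
        stats.total_pairs += 1
        sample = None
        for L in lengths:
            key = pair.seq1[:L + len(rem_a)]
            if key in lut:
                sample = lut[key]
                trim = bc_len[key] + (len(rem_a) if trim_remnant else 0)
                break
        if sample is None:
            continue
        if check_read2_remnant and not pair.seq2.startswith(rem_b):
            continue
        per_sample[sample].append(ReadPair(
            pair.id, pair.seq1[trim:], pair.qual1[trim:],
            pair.seq2, pair.qual2))
        stats.assigned_pairs[sample] += 1
    return per_sample, stats


def _trim_3prime(seq: str, qual: str, q_threshold: int) -> int:
    """Length kept after trimming 3' bases below ``q_threshold``."""
    keep = len(seq)
    while keep > 0 and ord(qual[keep - 1]) - 33 < q_threshold:
        keep -= 1
    return keep


def quality_filter(pairs, q_threshold: int = 20, min_length: int = 50):
    """3'-trim low-quality tails; drop pairs with a short mate.

    Returns (retained pairs, stats) where stats reports the Q20 ratio —
    the fraction of retained bases with Phred quality >= 20 — mirroring
    the per-run quality summary of read-cleaning tools.
    """
    kept = []
    bases = 0
    q20 = 0
    for pair in pairs:
        k1 = _trim_3prime(pair.seq1, pair.qual1, q_threshold)
        k2 = _trim_3prime(pair.seq2, pair.qual2, q_threshold)
        if k1 < min_length or k2 < min_length:
            continue
        p = ReadPair(pair.id, pair.seq1[:k1], pair.qual1[:k1],
                     pair.seq2[:k2], pair.qual2[:k2])
        kept.append(p)
        for q in (p.qual1, p.qual2):
            bases += len(q)
            q20 += sum(1 for ch in q if ord(ch) - 33 >= 20)
    stats = {
        "pairs_in": None,  # filled by callers that know the input size
        "pairs_kept": len(kept),
        "q20_ratio": (q20 / bases) if bases else float("nan"),
    }
    return kept, stats


def write_sample_fastq(per_sample: dict, outdir) -> dict:
    """Write per-sample paired FASTQ; returns sample -> (R1, R2) paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for sample, pairs in per_sample.items():
        p1 = outdir / f"{sample}_R1.fastq"
        p2 = outdir / f"{sample}_R2.fastq"
        with open(p1, "w") as f1, open(p2, "w") as f2:
            for pr in pairs:
                f1.write(f"@{pr.id}/1\n{pr.seq1}\n+\n{pr.qual1}\n")
                f2.write(f"@{pr.id}/2\n{pr.seq2}\n+\n{pr.qual2}\n")
        paths[sample] = (str(p1), str(p2))
    return paths


def write_demux_report(stats: DemuxStats, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tassigned_pairs\tfraction\n")
        total = stats.total_pairs or 1
        for sample, n in stats.assigned_pairs.items():
            fh.write(f"{sample}\t{n}\t{n / total:.6f}\n")
        fh.write(f"__unassigned__\t{stats.n_unassigned}\t"
                 f"{stats.n_unassigned / total:.6f}\n")
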