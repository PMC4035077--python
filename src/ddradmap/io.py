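"""File formats: FASTA tags, VCF, genotype TSV, JoinMap loc, map tables.

Everything written here is re-readable by this module (round-trip), so
the pipeline's persisted artifacts are the single source of truth for
every summary statistic.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .reference import ConsensusTag
from .variants import (CHAR_CODES, GEN_A, GEN_B, GEN_H, GEN_MISSING,
                       GenotypeMatrix, ParentalSNP)


def write_tags_fasta(tags, path) -> None:
    records = [SeqRecord(Seq(t.sequence), id=t.id,
                         description=f"depth={t.depth}") for t in tags]
    SeqIO.write(records, str(path), "fasta")


def read_tags_fasta(path):
    tags = []
    for rec in SeqIO.parse(str(path), "fasta"):
        depth = 0
        for token in rec.description.split():
            if token.startswith("depth="):
                depth = int(token[6:])
        tags.append(ConsensusTag(id=rec.id, sequence=str(rec.seq),
                                 depth=depth))
    return tags


def write_hits_tsv(result, path) -> None:
    """Minimal SAM-like TSV of unique-class hits (read, tag, offset,
    strand, NM) plus a per-read class column for the rest."""
    with open(path, "w") as fh:
        fh.write("read\ttag\toffset\tstrand\tNM\tclass\n")
        for h in result.hits:
            fh.write(f"{h.read_id}\t{h.tag_id}\t{h.offset}\t{h.strand}\t"
                     f"{h.mismatches}\t{h.hit_class}\n")


_GT = {GEN_A: "0/0", GEN_H: "0/1", GEN_B: "1/1", GEN_MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path, reference_name="consensus_tags",
              extra_snps=None) -> None:
    """VCF with tags as CHROM, 1-based POS, parent alleles as REF/ALT.

    Records are sorted by (tag, position).  Genotypes: parent-1
    homozygote 0/0, parent-2 homozygote 1/1, heterozygote 0/1,
    missing ./.
    """
    order = sorted(range(matrix.n_markers),
                   key=lambda i: (matrix.snps[i].tag_id,
                                  matrix.snps[i].position))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##reference={reference_name}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.individuals) + "\n")
        for i in order:
            snp = matrix.snps[i]
            gts = "\t".join(_GT[int(c)] for c in matrix.codes[i])
            fh.write(f"{snp.tag_id}\t{snp.position + 1}\t"
                     f"{matrix.marker_ids[i]}\t{snp.allele_p1}\t"
                     f"{snp.allele_p2}\t.\tPASS\t.\tGT\t{gts}\n")


def write_genotype_tsv(matrix: GenotypeMatrix, path) -> None:
    chars = matrix.to_chars()
    with open(path, "w") as fh:
        fh.write("marker\t" + "\t".join(matrix.individuals) + "\n")
        for mid, row in zip(matrix.marker_ids, chars):
            fh.write(mid + "\t" + "\t".join(row) + "\n")


def read_genotype_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    codes = np.full(df.shape, GEN_MISSING, dtype=np.int8)
    for ch, code in CHAR_CODES.items():
        codes[(df.values == ch)] = code
    return GenotypeMatrix(marker_ids=list(df.index),
                          individuals=list(df.columns), codes=codes)


def write_loc(matrix: GenotypeMatrix, path, name="ddradmap",
              population_type="RI8") -> None:
    """JoinMap-style .loc export (codes a/b/h, '-' for missing)."""
    chars = matrix.to_chars()
    with open(path, "w") as fh:
        fh.write(f"name = {name}\n")
        fh.write(f"popt = {population_type}\n")
        fh.write(f"nloc = {matrix.n_markers}\n")
        fh.write(f"nind = {len(matrix.individuals)}\n\n")
        for mid, row in zip(matrix.marker_ids, chars):
            fh.write(mid + "  " + " ".join(row) + "\n")
        fh.write("\nindividual names:\n")
        for ind in matrix.individuals:
            fh.write(ind + "\n")


def read_loc(path) -> GenotypeMatrix:
    marker_ids, rows, individuals = [], [], []
    n_loc = n_ind = None
    in_names = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("individual names"):
                in_names = True
                continue
            if in_names:
                individuals.append(line)
                continue
            if "=" in line:
                key, _, val = line.partition("=")
                key = key.strip()
                if key == "nloc":
                    n_loc = int(val)
                elif key == "nind":
                    n_ind = int(val)
                continue
            fields = line.split()
            marker_ids.append(fields[0])
            rows.append([CHAR_CODES[ch] for ch in fields[1:]])
    if n_loc is not None and len(marker_ids) != n_loc:
        raise ValueError("loc file: nloc does not match marker rows")
    if n_ind is not None and individuals and len(individuals) != n_ind:
        raise ValueError("loc file: nind does not match individual names")
    if not individuals:
        individuals = [f"ind{i + 1}" for i in range(len(rows[0]))]
    return GenotypeMatrix(marker_ids=marker_ids, individuals=individuals,
                          codes=np.array(rows, dtype=np.int8))


def flank_string(snp: ParentalSNP) -> str:
    """Tag sequence with the variant position bracketed [allele1/allele2]."""
    s = snp.flank
    return (s[:snp.position] + f"[{snp.allele_p1}/{snp.allele_p2}]"
            + s[snp.position + 1:])


def write_snp_flanks(snps, marker_ids, path) -> None:
    with open(path, "w") as fh:
        fh.write("marker\ttag\tposition\tflanking_sequence\n")
        for mid, snp in zip(marker_ids, snps):
            fh.write(f"{mid}\t{snp.tag_id}\t{snp.position}\t"
                     f"{flank_string(snp)}\n")


def write_map_tsv(genetic_map, path) -> None:
    """Full per-marker map table: group, position, bin, distortion, SDR."""
    with open(path, "w") as fh:
        fh.write("marker\tgroup\tposition_cM\tbin\tchi2\tp_value\t"
                 "distorted\tsdr\n")
        for g in genetic_map.groups:
            bin_of = {}
            for b_i, markers in enumerate(g.bins):
                for m in markers:
                    bin_of[m] = b_i
            sdr_of = {}
            for s_i, sdr in enumerate(g.sdrs):
                for k in range(sdr.start, sdr.end + 1):
                    sdr_of[k] = f"{g.id}.sdr{s_i + 1}"
            for k, (mid, pos) in enumerate(zip(g.marker_ids, g.positions)):
                t = g.distortion[k] if g.distortion else None
                chi2 = f"{t.chi2:.4f}" if t and t.testable else ""
                p = f"{t.p_value:.6g}" if t and t.testable else ""
                dist = str(bool(t.distorted)).lower() if t else ""
                fh.write(f"{mid}\t{g.id}\t{pos:.4f}\t{g.id}.bin"
                         f"{bin_of.get(mid, -1) + 1}\t{chi2}\t{p}\t{dist}\t"
                         f"{sdr_of.get(k, '')}\n")
        for mid in genetic_map.unlinked_markers:
            fh.write(f"{mid}\tunlinked\t\t\t\t\t\t\n")


def write_mapchart(genetic_map, path) -> None:
    """MapChart-compatible text export: 'group' blocks of marker/position."""
    with open(path, "w") as fh:
        for g in genetic_map.groups:
            fh.write(f"group {g.id}\n")
            for mid, pos in zip(g.marker_ids, g.positions):
                fh.write(f"{mid} {pos:.3f}\n")
            fh.write("\n")


def write_statistics_tsv(stats_df: pd.DataFrame, path) -> None:
    stats_df.to_csv(path, sep="\t", float_format="%.4f")
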