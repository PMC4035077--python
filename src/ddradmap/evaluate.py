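"""Score pipeline outputs against a simulation's ground truth.

The simulator knows, for every consensus tag the pipeline builds, which
fragment and which fragment end it came from; mapping tags back to truth
lets each stage be scored: SNP-call sensitivity/FDR, genotype accuracy,
grouping agreement with the true chromosomes and ordering agreement with
the true cM positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .enzymes import revcomp
from .simulate import GEN_A, GEN_B, GEN_H, TruthSet
from .variants import GEN_MISSING, GenotypeMatrix
from .variants import GEN_A as M_GEN_A, GEN_B as M_GEN_B, GEN_H as M_GEN_H


@dataclass(frozen=True)
class TagOrigin:
    fragment: int        # index into truth tags
    end: int             # 1 = read1 (SacI) window, 2 = read2 (MseI) window
    mismatches: int


def map_tags_to_truth(tags, truth: TruthSet, length: int) -> dict:
    """Best-matching (fragment, end) for each consensus tag sequence.

    Each fragment contributes four candidate window sequences (two ends
    x two parents); a consensus tag is assigned to the fragment/end of
    its minimum-Hamming candidate.  Returns {tag id: TagOrigin}.
    """
    index: dict[str, tuple] = {}
    for parent in (1, 2):
        for frag, (w1, w2) in enumerate(
                truth.window_sequences(length, parent)):
            index.setdefault(w1, (frag, 1))
            index.setdefault(w2, (frag, 2))
    candidates = list(index.items())
    cand_arr = np.frombuffer("".join(s for s, _ in candidates).encode(),
                             dtype=np.uint8).reshape(len(candidates), length)

    origins = {}
    for tag in tags:
        exact = index.get(tag.sequence)
        if exact is not None:
            origins[tag.id] = TagOrigin(exact[0], exact[1], 0)
            continue
        q = np.frombuffer(tag.sequence.encode(), dtype=np.uint8)
        dists = (cand_arr != q).sum(axis=1)
        best = int(np.argmin(dists))
        frag, end = candidates[best][1]
        origins[tag.id] = TagOrigin(frag, end, int(dists[best]))
    return origins


def called_snp_in_fragment_coords(snp, origin: TagOrigin, truth: TruthSet):
    """Translate a called SNP to (fragment, fragment position, alleles).

    Read2-window tags are reverse complements of the fragment's 3' end,
    so the position is mirrored and the alleles complemented.  Alleles
    stay (parent1, parent2)-ordered, which the mirror preserves.
    """
    frag_len = len(truth.parent1_tags[origin.fragment])
    if origin.end == 1:
        return (origin.fragment, snp.position, snp.allele_p1, snp.allele_p2)
    pos = frag_len - 1 - snp.position
    return (origin.fragment, pos, revcomp(snp.allele_p1),
            revcomp(snp.allele_p2))


def recoverable_snps(truth: TruthSet, length: int, radius: int = 2) -> set:
    """Observable SNPs that clustering at ``radius`` can recover.

    A read window where the parents diverge at more than ``radius``
    positions splits into parent-private clusters, so each parent covers
    only its own tag and no between-parent comparison exists there —
    the de novo analogue of excluding regions of complex polymorphism.
    A SNP is recoverable iff at least one window containing it has
    total parental divergence <= ``radius``.
    """
    # divergent positions per fragment (SNPs are the only divergence)
    by_frag: dict[int, list] = {}
    for s in truth.true_snps:
        by_frag.setdefault(s.tag, []).append(s)
    out = set()
    for frag, snps in by_frag.items():
        frag_len = len(truth.parent1_tags[frag])
        w1 = [s for s in snps if s.position < length]
        w2 = [s for s in snps if s.position >= frag_len - length]
        for window in (w1, w2):
            if 0 < len(window) <= radius:
                out.update((s.tag, s.position, s.allele1, s.allele2)
                           for s in window)
    return out


def score_snp_calls(snps, origins: dict, truth: TruthSet, length: int,
                    radius: int | None = None):
    """Sensitivity and FDR of called SNPs vs observable truth.

    Called SNPs on read1- and read2-end tags of the same fragment
    deduplicate to one fragment-coordinate record.  The truth side is
    restricted to SNPs visible in at least one read window and, when
    ``radius`` is given, to those recoverable at that cluster radius.
    """
    called = {called_snp_in_fragment_coords(s, origins[s.tag_id], truth)
              for s in snps}
    expected = truth.observable_snps(length)
    if radius is not None:
        expected &= recoverable_snps(truth, length, radius)
    tp = called & expected
    return {
        "n_called": len(called),
        "n_expected": len(expected),
        "n_true_positive": len(tp),
        "sensitivity": len(tp) / len(expected) if expected else float("nan"),
        "fdr": (len(called) - len(tp)) / len(called) if called
        else float("nan"),
        "false_positives": called - expected,
        "false_negatives": expected - called,
    }


def genotype_accuracy(matrix: GenotypeMatrix, origins: dict,
                      truth: TruthSet):
    """Compare called genotypes with the simulated truth.

    Markers map to fragments through their tag's origin; the truth
    genotype of a RIL at that fragment locus is the comparator.  The
    a/b polarity of a call is parent-anchored on both sides, so no
    orientation fix-up is needed.  Returns per-category counts over
    non-missing calls, split by whether the true genotype is homozygous
    (fully decidable) or heterozygous (depth-limited).
    """
    col_of_tag = {t: j for j, t in enumerate(truth.mapped_tags)}
    to_truth = {M_GEN_A: GEN_A, M_GEN_B: GEN_B, M_GEN_H: GEN_H}
    counts = {"hom_match": 0, "hom_mismatch": 0, "het_called_hom": 0,
              "het_called_het": 0, "missing": 0, "unmapped_marker": 0}
    mismatches = []
    for i, snp in enumerate(matrix.snps):
        origin = origins.get(snp.tag_id)
        col = col_of_tag.get(origin.fragment) if origin else None
        if col is None:
            counts["unmapped_marker"] += 1
            continue
        true_row = truth.true_genotypes[:, col]
        for k, _ind in enumerate(matrix.individuals):
            code = int(matrix.codes[i, k])
            if code == GEN_MISSING:
                counts["missing"] += 1
                continue
            t = int(true_row[k])
            if t == GEN_H:
                key = ("het_called_het" if to_truth.get(code) == GEN_H
                       else "het_called_hom")
                counts[key] += 1
            elif to_truth.get(code) == t:
                counts["hom_match"] += 1
            else:
                counts["hom_mismatch"] += 1
                mismatches.append((matrix.marker_ids[i], k, code, t))
    total_hom = counts["hom_match"] + counts["hom_mismatch"]
    return {
        **counts,
        "hom_accuracy": counts["hom_match"] / total_hom if total_hom
        else float("nan"),
        "mismatch_examples": mismatches[:20],
    }


def grouping_vs_truth(genetic_map, matrix: GenotypeMatrix, origins: dict,
                      truth: TruthSet):
    """Label pairs (true chromosome, assigned group) for each mapped marker.

    Feed the two label vectors to an external agreement index (e.g.
    adjusted Rand) to score grouping.
    """
    marker_group = {}
    for g in genetic_map.groups:
        for mid in g.marker_ids:
            marker_group[mid] = g.id
    true_labels, called_labels = [], []
    for i, mid in enumerate(matrix.marker_ids):
        if mid not in marker_group:
            continue
        origin = origins.get(matrix.snps[i].tag_id)
        if origin is None or origin.fragment not in truth.chrom_of_tag:
            continue
        true_labels.append(truth.chrom_of_tag[origin.fragment])
        called_labels.append(marker_group[mid])
    return true_labels, called_labels


def order_agreement(genetic_map, matrix: GenotypeMatrix, origins: dict,
                    truth: TruthSet):
    """Per-group (called position, true cM) pairs for rank correlation."""
    snp_of_marker = {mid: s for mid, s in zip(matrix.marker_ids,
                                              matrix.snps)}
    out = {}
    for g in genetic_map.groups:
        called, true = [], []
        for mid, pos in zip(g.marker_ids, g.positions):
            snp = snp_of_marker.get(mid)
            if snp is None:
                continue
            origin = origins.get(snp.tag_id)
            if origin is None or origin.fragment not in truth.cm_of_tag:
                continue
            called.append(pos)
            true.append(truth.cm_of_tag[origin.fragment])
        out[g.id] = (called, true)
    return out
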