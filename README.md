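# ddradmap

Reference-free SNP discovery from double-digest RAD sequencing
(ddRADseq) and genetic linkage-map construction for recombinant inbred
line (RIL) populations — built for crops like allotetraploid peanut,
where no reference genome is assumed, polymorphism is scarce, and
homoeologous loci confound short-read genotyping.

ddRADseq samples a reproducible subset of the genome: fragments flanked
by a rare cutter (SacI, GAGCTC) and a frequent cutter (MseI, TTAA)
within a gel-selected size window, sequenced as barcoded, multiplexed
paired-end reads.  `ddradmap` takes such reads (or simulates them) and
produces a genetic map:

1. **demux/QC** — pairs are assigned to individuals by exact inline
   barcode followed by the expected restriction-site remnant; 3' tails
   below Q20 are trimmed.
2. **de novo reference** — parental reads are clustered at Hamming
   radius 2 (greedy star, abundance-ordered, deterministic) and each
   cluster's majority consensus becomes a locus ("tag").
3. **parental SNPs** — reads align back gaplessly with <= 2 mismatches;
   only uniquely aligned reads count; a SNP requires each parent fixed
   (100% one base) with >= 4 reads per allele.  Reads hitting more than
   50 tags are discarded as repetitive contamination.
4. **RIL genotyping** — on the SNP-bearing ("reduced") tags, each
   individual's genotype is the maximum-posterior class under
   L(aa) = (1-e)^na e^nb, L(ab) = 2^-(na+nb), L(bb) = e^na (1-e)^nb,
   with the >= 4-read depth rule for homozygotes and residual
   heterozygotes masked.  Markers need <= 25% missing data and each
   allele in >= 30 individuals.
5. **linkage map** — two-point recombinant fractions are corrected for
   repeated selfing (r = R/(2(1-R))), markers group by single linkage at
   r <= 0.45 and LOD >= 2.0, co-segregating markers collapse into bins,
   bins are ordered by greedy insertion with a window-3 polish, and
   distances come from the Kosambi function d = 25 ln((1+2r)/(1-2r)) cM.
   Markers are chi-square tested against 1:1 segregation; runs of >= 3
   same-direction distorted markers form segregation distortion regions.

A first-class synthetic-data module simulates the whole design — two
homozygous parents, SacI/MseI digestion and size selection, an F9
population from eight selfing generations with Haldane crossovers,
barcoded 12-plex pools, per-base sequencing error, homoeologous
duplicates and a high-copy repeat family — with complete ground truth
(true SNPs, genotypes and map), so every stage is verifiable without
any download.  See `docs/methods.md` for the model and its assumptions.

## Worked example

Simulate a 3-chromosome cross (150 SNP tags, 100 RILs, depth 10, error
rate 0.002) and build its map:

```python
from ddradmap.config import config_from_dict
from ddradmap.pipeline import run_pipeline
from ddradmap.linkage import map_statistics

cfg = config_from_dict({
    "mode": "simulate", "outdir": "runs/demo", "seed": 1,
    "sim": {"n_chromosomes": 3, "chrom_length_cM": 60.0, "n_tags": 150,
            "snp_rate": 0.005, "n_individuals": 100, "mean_depth": 10,
            "parent_mean_depth": 20, "error_rate": 0.002,
            "insert_window": (200, 240), "min_snps_per_tag": 1},
    "variants": {"min_allele_individuals": 20},
    "linkage": {"min_lod": "auto"},
})
res = run_pipeline(cfg)
print(map_statistics(res.genetic_map).round(3).to_string())
```

which prints (seed 1):

```
       length_cM  n_loci  n_bins  density_cM_per_locus  largest_gap_cM  gap_le_5_fraction  n_distorted  n_sdrs
group
LG1       53.709    55.0    24.0                 0.995           6.941              0.944          0.0     0.0
LG2       63.951    52.0    29.0                 1.254           8.095              0.941          0.0     0.0
LG3       64.588    50.0    34.0                 1.318           8.311              0.959          0.0     0.0
Total    182.248   157.0    87.0                 1.183           8.311              0.948          0.0     0.0
```

Three linkage groups are recovered, one per simulated chromosome,
jointly spanning 182 cM against 3 x 60 = 180 cM simulated.  157 markers
(232,004 of 233,758 read pairs assigned; 393 consensus tags; 157
parental SNPs after 1,827 heterozygous-in-parent, 89 multi-allelic and
7 low-depth rejections) collapse into 87 bins; no marker deviates from
1:1 segregation at P < 0.05, as expected for a neutral simulation.
Density is cM per locus interval; "gap <= 5" is the share of adjacent
gaps at most 5 cM.  The run directory holds the per-stage artifacts:
pool FASTQs and truth tables, `tags.fasta`, `genotypes.vcf`,
`genotypes.tsv`, a JoinMap-style `genotypes.loc`, `snp_flanks.tsv`
(variant bracketed as `[A/G]` in its tag context), `map.tsv`,
`map_statistics.tsv` and `summary.json`.

The same pipeline runs from the shell:

```sh
ddradmap run --config demo.yaml          # full pipeline
ddradmap simulate --out sim/ --seed 7    # reads + truth only
ddradmap demux --r1 pool00_R1.fastq --r2 pool00_R2.fastq \
         --sheet samples.tsv --out demux/
```

`mode: fastq` in the config ingests existing pool FASTQs and a sample
sheet (`sample  barcode  pool  role`) instead of simulating; the two
parents are marked by `role` parent1/parent2.

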