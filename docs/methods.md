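# Methods

`ddradmap` implements reference-free SNP discovery from double-digest
RAD sequencing (ddRADseq) and two-point linkage-map construction for a
selfed recombinant-inbred (RIL) population, together with a synthetic
data generator that emulates the full study design so every stage can be
scored against ground truth.  The intended organism profile is an
allotetraploid selfer with low polymorphism and substantial
homoeologous sequence similarity (peanut-like); the defaults throughout
follow that design: SacI (GAGCTC) x MseI (TTAA) digestion, 300-500 bp
total size selection, ~90 bp paired reads with 5-8 bp inline barcodes in
12-plex pools, 166 F9 individuals from eight selfing generations, and
eight-fold mean coverage per locus and individual.

## The generative model (`ddradmap.simulate`)

**Fragments and tags.** The simulator does not build whole chromosomes;
it draws each selectable restriction fragment ("tag") directly, in read-1
orientation: SacI remnant + random core + reverse-complemented MseI
remnant, with total length uniform over the size window minus
`adaptor_length` (default 76 bp, converting the 300-500 bp "with indices
and adaptors" window to a bare-insert window).  Cores are rejected-
sampled so no uncut recognition site survives inside a fragment.  The
*remnant* of an enzyme is the part of its site a read crosses at a
ligated cut: `site[min(c, len-c):]` for top-strand cut offset `c`, i.e.
`AGCTC` for SacI (3' overhang AGCT) and `TAA` for MseI (5' overhang TA).
`digest_and_size_select` is also provided as a standalone operation on
arbitrary sequence, cutting the top strand at each site's offset and
keeping fragments with one end per enzyme inside the window.

**Polymorphism.** Parent 1 and parent 2 are fully homozygous; parent 2
differs at Bernoulli(`snp_rate`) core positions (default 0.005), with
the alternate base constrained never to create a cut site (a biological
constraint: such a variant would abolish the fragment, i.e. be a
dominant absence marker, which is out of scope).  `min_snps_per_tag`
optionally guarantees every tag is informative, used by the recovery
benchmarks where each tag must be a marker.

**Confounders.** `paralog_fraction` of tags receive a homoeolog copy —
identical in both parents, diverged from its source at one base per read
window — to exercise paralog interference.  One repeat family of
`repeat_copies` near-identical tags (one divergent base per read window
per copy, on a fragment long enough that the two read windows are
disjoint) exercises the repetitive-read filter.

**Meiosis.** The F1 is uniformly heterozygous; each selfing generation
draws two independent gametes with crossover counts Poisson(map length
in Morgans) and uniform crossover positions — the Haldane,
no-interference model.  Kosambi is used only on the estimation side, as
in the study being emulated; the simulator and estimator are therefore
*not* paired by construction, and map-length recovery is an honest test
of the two-point procedure, not a round trip.  After g = 8 selfings the
residual heterozygosity per locus is (1/2)^8 ~ 0.39%, which the
calibration tests verify.

**Reads.** Per individual and tag, the read-pair count is
Poisson(`mean_depth`); heterozygous individuals sample a haplotype per
pair.  Read 1 is barcode + fragment prefix (total 90 bp), read 2 the
reverse complement from the MseI end.  Substitution errors occur at
`error_rate` per base; qualities are two-level (Q40 for correct bases,
Q7 for errors), sufficient to exercise 3'-end quality trimming but not a
model of real Illumina quality profiles.  Inline barcodes are protected
from simulated error so that demultiplexing losses measure remnant
damage only.  Read provenance (individual, tag, haplotype) is encoded in
the read id, so truth survives pooling without side tables.

What the generator does *not* model: PCR duplicates, indels, chimeras,
adapter read-through, polysomic inheritance (tetraploidy is represented
as disomic subgenomes plus homoeolog similarity), depth correlation
between loci, and quality-dependent error profiles.  Passing tests on
this generator demonstrate the pipeline's logic and statistics, not
robustness to every artifact of real libraries.

## Preprocessing (`ddradmap.demux`)

A pair is assigned iff read 1 begins with exactly one sample-sheet
barcode immediately followed by the SacI remnant; barcodes are
exact-match (the sample sheet must be prefix-free, which makes the match
unique) and the barcode is trimmed while the remnant is kept — it is
genuine locus sequence shared by every read of a tag, and keeping it
preserves uniform read lengths for the gapless alignment downstream.
Read-2 remnant checking is available behind a flag (off by default; the
check on one mate is already a strong structural filter).  Quality
control trims 3' bases below Q20 and drops pairs with a mate shorter
than 50 bp; both knobs are configurable since no canonical values exist
for this step.

**Uniform working length.** Barcodes of different lengths leave read 1
at 82-85 genomic bases while read 2 keeps 90.  All retained reads are
truncated to L = read length − longest barcode (82 bp by default)
before clustering and alignment: reads are anchored at the cut site, so
the first L bases carry all comparable information, and uniform length
makes Hamming comparison exact.  Reads trimmed below L are dropped from
reference building and alignment and counted.

## De novo reference (`ddradmap.reference`)

**Clustering** is greedy star clustering: unique read sequences are
visited by decreasing abundance (ties lexicographic); each joins the
first existing centroid within Hamming distance `cluster_radius`
(default 2) or founds a new cluster.  Clusters below `min_cluster_depth`
(default 4) are discarded.  The visiting order makes the procedure a
pure function of the input multiset — shuffling reads cannot change the
result.  The default radius equals the alignment mismatch allowance so
that a parental SNP plus one sequencing error still co-clusters.

**Consensus** is the abundance-weighted per-position majority, ties to
the lexicographically smallest base.

**Alignment** is gapless (reads and tags arise from the same fragment
ends, so no indel model is needed; the variant caller handles SNPs
only).  Equal-length reads and tags go through a pigeonhole seed index:
`max_mismatches + 1` disjoint k-mer blocks, so any hit with at most
`max_mismatches` mismatches has at least one exact block and cannot be
missed; candidates are verified by vectorised Hamming distance on both
strands.  Reads are classed by distinct-tag hit count: unaligned (0),
unique (1), multi (2-50) and repetitive (more than `repeat_hit_limit` =
50 locations); only unique reads feed the caller.  Mixed-length inputs
fall back to an exhaustive offset scan.

A consequence of clustering at radius = mismatch allowance is that
homoeologs diverged *within* the radius merge into one consensus tag
rather than forming separate tags.  Their reads then align uniquely to
the merged tag, and suppression happens one stage later: within each
parent the homoeolog divergence positions show two bases, failing the
100%-within-parent criterion, so no SNP is ever emitted from merged
homoeolog clusters.  Homoeologs diverged *beyond* the radius form
separate tags whose cross-mapping reads are multi-class and excluded.
Both routes end in suppression; the tests assert the outcome for both.

## Variant calling (`ddradmap.variants`)

A position is a parental SNP iff (1) reads aligned with at most two
mismatches, (2) only uniquely aligned reads were used, (3) each parent
shows a single base at 100% frequency, and (4) both alleles have depth
of at least `min_allele_depth` = 4 reads.  Rejections are tallied as
heterozygous-in-parent, low-depth, or multi-allelic.  Tags carrying at
least one SNP form the reduced reference for population genotyping.

Genotypes are called per individual and locus from biallelic counts
(n_a, n_b) by maximum posterior over {aa, ab, bb} with likelihoods
L(aa) = (1−e)^na e^nb, L(bb) = e^na (1−e)^nb, L(ab) = (1/2)^(na+nb)
(the shared binomial coefficient cancels); e defaults to 0.01
independently of the simulator's error rate.  Homozygous calls require
the supporting allele depth >= 4, else missing.  Third-allele reads are
discarded before counting; loci where a third base exceeds 20% of any
individual's depth are flagged.  The prior is uniform by default; a
selfing-informed prior (het mass 2^-g) is available and shifts the
het/hom boundary at weakly unbalanced counts.

**Heterozygote policy.** At F9 true heterozygotes are ~0.4% of entries,
so the default masks individual `ab` calls to missing rather than
discarding whole loci; a strict mode drops loci whose het fraction
exceeds 10%.  Note an information-theoretic limit: a true heterozygote
sampled at depth d shows one haplotype with probability 2^(1−d) and is
then indistinguishable from a homozygote — exact genotype recovery is
defined over homozygous truth.

**Marker filters.** A marker is dropped when its missing fraction
exceeds the maximum-missing-data threshold (MMD, default 25%) or when
either allele is present in fewer than `min_allele_individuals`
(default 30, i.e. each allele in >= 30 of 166 individuals and present in
>= 75% of them through the MMD bound).  Both boundaries are inclusive
exactly as stated and are pinned by boundary tests (42/166 missing
drops, 41 keeps; 29 carriers drop, 30 keep).

## Linkage mapping (`ddradmap.linkage`)

Heterozygote codes are masked first; two-point linkage in a selfed RIL
uses homozygous calls only.  For each marker pair, recombinants are
counted over individuals non-missing at both; the observed fraction R
converts to the meiotic r by the Haldane-Waddington F-infinity
correction r = R/(2(1−R)) (clamped to [0, 0.5]), and the linkage LOD is
n_nr log10(2(1−R)) + n_r log10(2R) with 0 log 0 = 0.  Pairs with fewer
than `min_informative` = 20 shared individuals are unusable.

**Grouping** is single-linkage transitive closure over pairs with
r <= 0.45 and LOD >= 2.0, both inclusive (the published thresholds).
Those defaults are kept verbatim, but at large marker counts a fixed
LOD 2 cannot control false linkage: under independence 2 ln10 x LOD is
asymptotically chi-square(1), so with m markers the expected number of
false edges is ~C(m,2) x P(LOD >= 2) — hundreds at m ~ 450 and n = 166 —
and a single false edge chains two chromosomes.  `min_lod="auto"`
therefore substitutes the Bonferroni threshold chi2_isf(alpha/C(m,2), 1)
/ (2 ln10) (~5.5 at 450 markers), the package's own calibration of the
"raise the grouping LOD until groups stabilise" practice; the recovery
benchmarks use it.

**Bins** collect markers with no observed recombination (identical on
all shared non-missing individuals, >= `min_shared` = 20 shared),
closed transitively; the representative is the member with fewest
missing entries.  **Ordering** seeds with the bin pair of smallest r,
grows the chain by cheapest insertion (minimum increase of the sum of
adjacent r), and polishes with sliding window-3 permutations to
convergence — deterministic, with documented tie-breaks.  Positions are
cumulative Kosambi distances d = 25 ln((1+2r)/(1−2r)) cM over adjacent
bins; distances are two-point only (no multipoint/EM re-estimation),
trading a little efficiency for exact reproducibility.

**Distortion and SDRs.** Each marker is tested against 1:1 by a 1-df
chi-square on non-missing a/b counts; markers with P < 0.05 are
distorted, with the over-represented allele as direction.  A segregation
distortion region is a maximal run of at least 3 consecutive
same-direction distorted markers (a common convention; no canonical
definition exists).  Per-group statistics follow the standard map-table
definitions: length = last position, density = length/(n_loci − 1)
(blank for singleton groups), largest gap, and the share of adjacent
gaps <= 5 cM (inclusive by default; a strict comparator is available).

## Numerical and degenerate-input choices

- All coordinates are 0-based half-open internally; 1-based only in VCF.
- r is clamped to 0.4999 before the Kosambi transform so unlinked-
  looking pairs map to a large finite distance.
- The genotype caller clamps e away from 0 and 1 so likelihoods stay
  finite at e = 0.
- Empty FASTQ input demultiplexes to empty output with zero counts; a
  malformed or desynchronised record raises naming the record offset.
- No SNPs after filtering aborts the pipeline with a stage-named
  diagnostic (an empty reduced reference cannot be genotyped).
- Markers with fewer than 2 informative individuals are excluded from
  pairwise linkage with a warning.

## Problem sizes used by the tests and the acceptance script

The verification suite simulates at desk scale: the clean-recovery
benchmark uses 2 chromosomes x 60 cM, 100 tags, 50 individuals at depth
16 with no sequencing error; the noisy benchmark uses 5 chromosomes x
60 cM, 400 SNP-bearing tags, 166 individuals at depth 10 and error rate
0.002 (~660k read pairs).  Both use a 200-240 bp size window so the
~82 bp effective paired reads tile each fragment completely — with the
default 300-500 bp window, fragment middles are unsequenced and SNPs
there are invisible to any read-based caller; the evaluator restricts
truth to read-visible (and, for set-identity checks, cluster-recoverable)
SNPs.  Statistical calibrations use 2000 replicate markers at n = 166
and 2000-individual RIL populations.

## Known limitations

- Map length from two-point adjacent estimates is mildly biased: bins
  absorb sub-resolution gaps (downward, ~(1−R)^n per gap) while residual
  ordering noise adds length (upward); at the benchmark scale the net
  error stays within a few percent but varies by seed.
- SNPs in read windows where parents diverge beyond the cluster radius
  are structurally uncallable (complex-polymorphism exclusion); the
  caller neither sees nor reports them.
- Repetitive-read classification presumes repeat copies survive
  clustering as distinct tags; at the default radius, near-identical
  copies merge and are handled (harmlessly) as one locus instead.
- The chi-square distortion test is asymptotic; at very high missingness
  its discreteness makes the nominal 5% level approximate.
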