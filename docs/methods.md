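# Methods

This note documents the models, estimators and design choices behind
`poolscan`, and what the synthetic data do and do not establish about
behaviour on real sequencing data.

## Pooled site counts and window statistics

A pool of ~40 mosquitoes sequenced together yields, at each variant site,
read counts per nucleotide rather than genotypes. The workflow follows the
standard Pool-seq recipe:

1. **Depth filter.** Sites with depth < 20 or above the pool's 95th depth
   centile are removed (low depth gives unstable frequencies; excess depth
   marks collapsed repeats and misaligned paralogs). The centile is
   computed per pool over all covered sites in the table, not per contig.
2. **Uniform subsampling.** Counts are resampled *with replacement* to a
   uniform depth n (default 20; configurable for lower-coverage pools).
   The n reads are then treated as n sampled chromosomes.
3. **Windowed statistics.** π, θ_W and Tajima's D in 50 kb windows moving
   in 25 kb steps (scan mode), or 10 kb/5 kb for fine locus views. D is
   undefined (NaN) when a window has no polymorphic subsampled site.
4. **Outliers.** Sweep candidates are windows in the lowest 0.1% (or 1%)
   of the empirical D distribution. Ties at the threshold are not flagged,
   so a degenerate constant statistic flags nothing; windows with missing
   D are excluded from the quantile; the X chromosome can be excluded via
   `exclude_contigs` and analysed separately.

**Known bias.** Subsampling to depth n and treating reads as chromosomes
drops rare alleles — P(a 1/20 allele absent from 20 resampled reads) ≈
0.36 — which deflates S more than π and biases D upward by roughly +0.4
under neutrality at n = 20, θ = 10, 40× coverage. This bias is a property
of the estimator, not of this implementation. Consequently the package's
neutrality calibration tests evaluate D on chromosome-resolution counts
(each sampled chromosome counted once), where E[D] ≈ 0 holds and the
Monte-Carlo mean over 500 windows lands within ±0.15 of zero; the pooled
observation model (Poisson depth, binomial allele sampling, base-flip
errors) is exercised by the detection-oriented checks, which compare
windows to each other rather than to an absolute zero.

F_ST uses the classical (H_T − H_S)/H_T with H = 2p(1−p) computed from the
combined-major-allele frequency in each pool, and windows aggregate as a
ratio of sums (sum of numerators over sum of H_T), which weights sites by
their information content instead of averaging unstable per-site ratios.
The estimator is uncorrected for finite depth, giving a small positive
null bias (~1/(2·depth)); between two pools drawn from the same haplotype
set at 50× it stays below 0.02 per 50 kb window. Allele-frequency
differences are tested per site with Fisher's exact test on the 2×2
major/other table. Kernel smoothing of positional tracks uses a Gaussian
kernel with bandwidth equal to the window size, ignoring missing values.

## Coalescent window simulator

Neutral windows follow the standard n-coalescent (waiting times
exponential with rate k(k−1)/2, time in units of 2N generations) with
infinite-sites mutations Poisson-distributed on branches at rate θ/2 per
unit length, so E[π] = θ and E[S] = θa₁. A window is composed of
`n_chunks` independent genealogies each carrying θ/n_chunks (default 1;
the calibration and scan tests use 4). This models intra-window
recombination at the 50 kb scale: real windows span many partially
independent genealogies, which lightens the tails of window statistics,
whereas a sweep remains coherently extreme across the whole window. With
single-genealogy windows the neutral lower tail over 1000 windows
(min ≈ −2.3, checked against msprime) overlaps the sweep distribution and
outlier flagging is unreliable; with 4 chunks the two separate completely
(sweep max −1.7 vs neutral min −1.69 in a 1000-window calibration run).

Sweeps are emulated by a star genealogy with branch length f·E[TMRCA]
(f = `sweep_scaling`, default 0.05 in sweep tests): the minimal model of a
just-swept sample, in which every variant is a recent private mutation, so
windows show few, rare variants and strongly negative D (≈ −2.2 at n = 20,
θ = 10). Temporal pairs share one genealogy between time points (and the
per-site ancestral/derived base identities); the post-sweep pool draws
from frequencies (1−f)·h_j + f·(uniform), where h_j is one haplotype's
indicator vector — a near-fixed sweep with residual diversity f.

Pooled counts then sample depth ~ Poisson(λ), derived copies ~
Binomial(depth, freq), and flip each base to a uniformly chosen other base
with probability e (substitution errors only; the error rate is bounded
below 1%).

## Read simulator and alignment emulation

Fragments are drawn Normal(350, 50) bp (truncated to [read length,
haplotype length]) with 2×125 bp reads, matching a standard short-insert
paired-end library. Instead of running an aligner, the simulator emits the
record a local aligner would produce, derived from the haplotype's
coordinate map: reads inside unedited segments align full length; a read
crossing an edit junction is anchored on its longest reference-consistent
end and soft-clipped (clipped bases retained); a deletion of ≤ 20 bp
inside a read becomes a CIGAR `D` operation, as aligners emit for small
indels; reads mostly within a TE payload align to the TE-library contig.
Pairs spanning a deletion acquire enlarged apparent inserts, pairs
straddling a head-to-tail duplication junction acquire the everted
orientation, and TE-flanking pairs become one-end-anchored — all emergent
from the coordinate map rather than scripted. Errors are substitutions
applied after alignment coordinates are fixed (emulating an error-tolerant
aligner); quality modelling, PCR duplicates and indel errors are out of
scope. What passing tests show is therefore that the *evidence model* and
callers are correct given idealised local alignments; mapping ambiguity in
repeats, indel-containing reads and quality-dependent errors in real data
are not exercised.

Breakpoint coordinates throughout: 1-based labels `contig:left–right` with
`left` the last unaffected base and `right` the last affected base, so the
affected slice is `[left, right)` in 0-based half-open coordinates, the
span is right − left, and the reported length ⌊(right−left)/100⌋/10 kb.
This is the unique convention consistent with the duplication-junction
construction (junction = end of copy + start of copy) and with span
lengths printed to 0.1 kb.

## Structural-variant calling

Three evidence lines are computed from mapq-filtered (≥ 10), deduplicated
records (duplicate key includes the CIGAR so distinct clipped reads at a
breakpoint never collapse):

1. **Depth**: per-position aligned-base depth relative to the genome-wide
   median over covered sites, Gaussian-smoothed (bandwidth 250 bp); runs
   ≥ 500 bp beyond 1.4 (gain) or below 0.6 (loss) become candidate
   regions. The 1.4 threshold admits a 2-copy duplication at 50%
   frequency (expected relative depth 1.5).
2. **Read pairs**: deletion-type (correct orientation, insert > mean +
   4 sd), tandem-type (everted orientation), interchromosomal (mate on
   another contig; fed to the TE scan).
3. **Chimeric reads**: soft-clip boundaries clustered within ±2 bp with
   ≥ 3 supporting reads, majority-vote consensus anchored at the junction,
   matched against the reference at ≥ 90% identity over ≥ 15 bp. Match
   geometry fixes both breakpoints exactly and implies the kind: a clipped
   suffix matching downstream sequence is a deletion; matching upstream is
   a head-to-tail tandem junction.

A record is called when at least two lines agree; chimeric breakpoints are
exact, depth-edge breakpoints approximate (flagged). A deletion whose span
lies inside a called duplication is marked nested — the
duplication-with-internal-deletion configuration, which shows no depth
loss (2 copies − 1 = the genomic median) and is recoverable only from its
junction evidence. Conflicting kinds at one locus are both reported with a
conflict flag.

**Frequency.** Each junction-crossing read is clipped at exactly one of
the two breakpoints (whichever end anchors longer), while read-through
flux is counted at both; the estimator is therefore C/(C + T/2) with C
junction reads and T read-through reads summed over both breakpoints,
which is unbiased for the deletion-carrier frequency (verified on 80:20
simulations). For tandem duplications the junction fraction equals
q(c−1)/(q(c−1)+1) for carrier frequency q and copy number c, which cannot
separate q from c (e.g. one extra copy in everyone and two extra copies in
half the pool give identical junction fractions *and* identical relative
depth); the reported frequency inverts under a 2-copy assumption
(q = f/(1−f), capped at 1). Copy number is estimated as
(rel − (1−q))/q from the relative depth over the span, reported as a
single integer when within 0.25 of one, else as the bracketing range
(relative depth 3.5 at q = 1 reads as 3–4 copies). Deletions at
intermediate estimated frequency (0.05–0.95) are re-labelled segregating
insertion/deletion polymorphisms — except nested deletions, whose
read-through comes from the intact copy on the same haplotype, making the
junction fraction a copy-configuration measure rather than an allele
frequency.

## Transposon-insertion calling

Because the target site is duplicated, reads approaching from the left
align through the TSD before being clipped and reads from the right begin
aligning at the TSD start: the right-approaching clip boundary sits to the
*left* of the left-approaching one, and the TSD is the reference substring
between them (inclusive; up to 20 bp, covering mariner-class 2–10 bp
sites; boundaries further apart mean no TSD). Calls require clip clusters
on both sides with TSD-compatible geometry; one-end-anchored pairs facing
the site from both directions corroborate, as does the depth micro-peak
over the doubly-sequenced TSD. TIRs are found as the longest
junction-proximal prefix of the left clipped consensus whose reverse
complement matches the right consensus at ≥ 90% identity (minimum 10 bp);
identical direct repeats do not qualify. Because identity is thresholded
rather than exact, the reported TIR can extend a few bases past the true
repeat by chance. TE identity is the best approximate match of the clipped
consensus (either orientation) to the supplied TE library — an internal
substitute for a BLAST search against known elements, adequate because the
simulator's elements are drawn from the same library. Junction-read
frequency uses the same C/(C + T/2) correction as SV frequencies (here C
additionally loses the junction reads that anchor on the TE contig, which
the two-junction sum restores in expectation).

## Gene-conversion analysis

Input is an aligned, labelled paralog sequence set (`name|paralog|population`
headers). Trimming retains the first 1464 coding columns (upstream and
intron columns removed via annotations); distances use pairwise (not
listwise) deletion of gapped columns, preserving 3'-truncated sequences.
Uncorrected p-distances feed classical (Torgerson double-centering) MDS;
K2P distances feed Neighbour-Joining (Saitou–Nei Q-criterion, negative
branch lengths clamped to zero — exact on additive matrices), with
column-resampling bootstrap support computed by reweighting a cached
one-hot encoding (distance matrices per replicate are four matrix products,
keeping 200 replicates on 400×1464 data around a minute).

Each paralog's clade is the bipartition side at ≥ 90% purity for that
label that maximises (own-label count − contaminant count), with size
breaking ties. Pure maximal-size selection is deliberately not used: the
complement of a deep subclade of the *other* label can sit exactly at the
purity threshold and absorb dozens of foreign sequences. A sequence whose
label differs from its placement clade is converted; sequences in neither
clade are unplaced (reported, not converted). An MDS-embedding route
(nearest label centroid with a margin rule) is available when no tree is
wanted. The read-level corroboration is the windowed depth ratio across
the paralog pair: conversion re-assigns reads from the converted paralog
to its template, so the ratio rises (expected (1+q)/(1−q) at conversion
frequency q) over a sustained span while total a+b depth stays constant —
a rising ratio with rising total is amplification, not conversion, and is
not flagged. Defaults: 100 bp windows, ratio ≥ 1.5 over ≥ 200 bp, total
within 35% of its mean.

The paralog simulator draws two ancestors separated by `divergence`
substitutions/site (default 0.10) with within-paralog diversity 0.005 —
the ≥ 10× separation regime in which whole-gene conversion is
unambiguous; converted sequences are b-labelled draws from the a ancestor.
Partial-tract conversion, recombinant intermediates and alignment error
are not modelled, so perfect classification on these simulations bounds,
rather than predicts, performance on real paralog sets.

## Marker-level calls

Codon allele frequencies count reads whose aligned bases fully span the
codon (reads interrupted by clips or indels are excluded; third codons are
tabulated separately); coverage below 10 spanning reads sets a
low-confidence flag. Indels near an annotated feature are read directly
from within-read CIGAR `I`/`D` operations within a radius (default
100 bp), with frequency = carriers / (carriers + spanning non-carriers).

## Orchestration and problem sizes

`run_pipeline` executes synthio → poolstats → svscan → tescan →
paralogconv from a YAML config; every output file, stage parameter and
seed lands in `manifest.json`, and a stage failure still writes the
partial manifest. All randomness flows through explicit integer seeds, so
identical configs reproduce identical outputs. Plots (depth tracks, D/FST
tracks) are optional presentation output behind a matplotlib import and
never load-bearing.

The shipped checks run at desk scale by design: 120 kb references at
30–60× for SV/TE recovery, 500–1000 coalescent windows for scan
calibration, 40 windows for the temporal contrast, and 200 bootstrap
replicates (rather than a publication-grade 1000) for the 400-sequence
conversion analysis; the full test suite completes in a few minutes on one
CPU, and `scripts/acceptance.py` in about two.

## Known limitations

* The simulator's idealised alignments sidestep mapping ambiguity; callers
  inherit no robustness guarantees for repeat-rich regions.
* Duplication carrier frequency and copy number are jointly unidentifiable
  from depth + junction data (2-copy convention documented above).
* Tajima's D on uniformly resampled pooled counts is upward-biased under
  neutrality; scans rely on relative ranking, not absolute values.
* Inversions are not called; same-strand pair classes are ignored.
* The F_ST estimator carries the classical finite-sample positive bias;
  no unbiased (e.g. Karlsson) variant is implemented, though the
  windowing is structured to accept one.
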