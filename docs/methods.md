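# Methods

This package reimplements, as a tested library, the downstream computational
procedures used to compare nasal and bronchial airway basal-cell cultures:
the ATAC-seq consensus-peak / differential-accessibility arm and the
organoid swelling / morphometry arm. All stages run on synthetic data with
recorded ground truth; nothing here performs read alignment or peak calling,
which are upstream of this pipeline.

## ATAC-seq arm

### Coordinates and filtering

All coordinates are 0-based half-open (BED convention) internally. Before
any analysis, peaks and fragments on excluded chromosomes (default chrY and
chrM, matching the removal of Y-linked and mitochondrial reads) are dropped
by exact name match. The exclusion set is configuration, since treatment of
unplaced contigs is a per-study choice.

### TSS-enrichment QC

Each fragment is replaced by a fixed-length 64-bp interval anchored at its
5' start — a single representative fragment-length estimate applied to all
samples — and piled up around every annotated TSS in 40-bp bins spanning
±5 kb (250 bins). Minus-strand windows are mirrored so positive offsets are
always downstream of transcription; a fragment contributes
(overlap bp / 40 bp) to every bin it overlaps. The enrichment ratio is the
mean signal over the four bins covering [−80, +80) divided by the mean of
the two outermost bins ([−5000, −4960) and [+4960, +5000)). The 40-bp grid
divides 80 evenly, so no partial bins arise. A zero background with positive
TSS signal reports +inf and is flagged; 0/0 reports NaN, flagged. The ratio
is advisory: no sample is auto-excluded, because the quality cutoff used to
drop a failing sample is a judgement call we leave to the analyst.

### Consensus, reproducible and universal peaks

Replicate peak calls are pooled and merged transitively: any ≥1 bp overlap
chains peaks into a union region (abutting half-open intervals do not
merge), so a consensus region can exceed any single replicate peak. Each
region records which samples contributed at least one peak. A region is
*reproducible* in a group when ≥ `min_support` of that group's replicates
contributed (default 3, i.e. the 3-of-4 and 3-of-5 rules of the emulated
design); the downstream analysis universe is the union of both groups'
reproducible regions. A region is *universal* when reproducible in both
groups; a stricter mode additionally requiring support from literally every
sample is available behind a flag. Merging was validated against an O(n²)
pairwise-overlap union-find oracle.

### Counting and anchored normalization

Counts are fragments-per-peak with midpoint assignment: a fragment is
counted in the unique peak containing its midpoint (half-open, so a midpoint
at a peak's start counts and one at its end does not). Midpoint assignment
guarantees each fragment is counted at most once even for adjacent peaks.

Size factors follow the median-of-ratios recipe, restricted to the universal
peak set: per universal peak, the geometric mean of counts across samples is
computed over peaks with no zero count in any sample (zero-containing anchor
peaks are dropped and logged); each sample's factor is the median ratio of
its counts to those geometric means, re-centred to geometric mean 1. The
factors are then applied to *all* peaks. The rationale is the anchoring
property: accessibility genuinely differs between the two tissues at many
regions, and a factor computed on all peaks absorbs part of that group
effect into the depth correction, while factors computed only on regions
open in both groups do not. The acceptance suite quantifies this: with true
depths (1, 1.5, 2, 0.8, 1.2) and a one-sided 4-fold effect in 30% of
non-anchor peaks, anchored factors recover truth within 5% relative error
while all-peak median-of-ratios shows a larger maximum error. Re-centring to
geometric mean 1 is this package's choice; only the anchor-set restriction
is fixed by the emulated procedure.

### Differential accessibility

Per peak, counts follow a negative-binomial GLM with log link:
mean = s_j · exp(b0 + b1 x_j), where s_j is the anchored size factor
(entering as an offset) and x_j indicates the alphabetically second group.
Dispersion α (variance = μ + αμ²) is estimated per peak by method of
moments from within-group variability of normalized counts — the pooled
Bessel-corrected excess of Var(y/s) over its Poisson part μ·E[1/s] divided
by μ², floored at 1e-8 — with an optional common mode (20%-trimmed mean
across peaks). There is no empirical-Bayes shrinkage of dispersions or fold
changes; this is a deliberate simplification, and the test suite validates
the procedure by simulation rather than by equivalence to any particular
tool.

b1 is fitted by IRLS (Fisher scoring with weights μ/(1+αμ)), vectorized
across peaks as closed-form 2×2 solves; tolerance 1e-8, at most 100
iterations, no randomness. The per-peak fits were cross-checked against
independent per-peak NB-GLM fits (statsmodels) to ~1e-7. The Wald statistic
b1/SE is referred to a Student t with n_samples − 2 degrees of freedom
rather than the normal limit: with a handful of replicates the plug-in
method-of-moments dispersion is noisy, and the normal reference is visibly
anticonservative (raw-p type-I error ≈ 0.10 at nominal 0.05 in our null
simulations at n = 5 + 4), while the t reference restores ≈ 0.05. log2FC is
b1/ln 2. All-zero peaks are untestable (p = NaN) and are excluded from the
Benjamini–Hochberg correction's m; no other independent filtering is done.
Significance uses the strict thresholds |log2FC| > 1 and BH-adjusted
p < 0.1, and significant peaks are partitioned by direction into
nasal- and bronchial-specific sets.

The design is group-only; a donor covariate is not implemented (the emulated
ATAC analysis used none).

### Peak–gene assignment (basal plus extension)

Each gene owns a strand-aware basal domain: 5 kb upstream to 1 kb downstream
of its TSS, clipped to the chromosome. The extended domain pushes each basal
edge outward to the nearer of 1,000 kb from that edge or the nearest
flanking gene's basal-domain boundary; basal domains are never truncated by
neighbours, so when a neighbour's basal domain overlaps a gene's own, the
extension on that side is simply zero. A peak is assigned to every gene
whose extended domain it overlaps by ≥1 bp; peaks overlapping no domain stay
unassigned (no nearest-gene fallback). Curated regulatory domains are not
modelled — only the geometric rule. Construction was validated against an
O(n²) restatement of the rule on random gene layouts.

### Known-motif enrichment

This stage is deliberately a simplified known-motif test, not a motif-finder
reimplementation: no de novo discovery, no ZOOPS scoring. Each peak is
represented by the central 200 bp of its region; masked (lowercase) bases
are treated as N by default. PWMs are scanned on both strands with log2-odds
scores against the PWM background (pseudocount 1e-3; windows containing N
score −inf), and a peak is a hit when ≥1 window scores at or above 80% of
the motif's maximum score (common practice; configurable). Per motif, the
number of hit-containing peaks in the foreground (group-specific
differential peaks) is compared with the background (all reproducible peaks
minus the foreground, by default) by a one-sided hypergeometric tail, with
BH correction across the motif library.

## Organoid arm

Forskolin-induced swelling series (total organoid area per well, imaged
every 15 min for 2 h) are normalized to t = 0 with the baseline at 100%.
The summary AUC integrates percent_area − 100 over [0, 120] min by the
trapezoid rule on the observed grid (exact for linear curves; missing
timepoints are an error, never interpolated). Integrating the *excess* over
baseline — rather than the raw percent curve, which differs only by the
constant 100·t_end — makes a non-swelling control integrate to exactly 0
and is the convention documented here. Shrinkage below baseline yields
negative AUC.

Organoid size from detector bounding boxes assumes a disk shape: the
inscribed ellipse π·w·h/4 (equal to a disk for square boxes). An alternative
convention π·((w+h)/4)² is available behind a configuration switch. Per
well, the arithmetic mean over all detected organoids is reported.
Immunofluorescence staining is quantified as the fraction of pixels strictly
above a fixed threshold, with the same threshold applied to every image of a
comparison.

## Synthetic data

The generators emit every input the pipeline consumes, plus a ground-truth
JSON. Defaults mirror the emulated study design: 5 nasal vs 4 bronchial
replicates (one bronchial sample of five having been dropped for quality),
min_support 3 in both groups, fragment length 64, NB dispersion 0.1, 10% of
peaks carrying a true |log2FC| = 2 accessibility shift (balanced in
direction), per-sample depth factors log-uniform within ±0.4 natural-log
units re-centred to geometric mean 1, per-peak baseline means log-uniform
within 2-fold of 120 fragments, peak-call reproducibility 0.85 per
replicate with ±20 bp boundary jitter and 15 replicate-private noise peaks,
and an 8-fold TSS enrichment. The synthetic genome is two autosomes (1 Mb
and 0.8 Mb) of i.i.d. uniform nucleotides plus chrY/chrM decoys carrying
peaks that must be filtered out. These sizes are desk-scale stand-ins chosen
so every stage runs in seconds while keeping per-peak counts, replicate
structure and effect sizes at realistic magnitudes.

The TSS-enrichment generator plants fragment starts uniformly over
[tss − 80 − L, tss + 80), which yields exactly flat excess coverage across
the central ±80 bp window, so the expected enrichment ratio equals the
configured fold and recovery can be asserted within Monte-Carlo error.
Swelling uses linear kinetics area(t) = A₀(1 + rt)(1 + ε_t) with
multiplicative Gaussian noise (σ = 0.03) in quadruplicate wells: linear
kinetics give the closed form AUC = 720000·r %·min (7200 at r = 0.01),
which anchors the assay tests. An exponential-plateau profile would be more
biologically faithful at late times but has no closed form; linearity is the
tested path. Motif planting embeds a sharp 8-bp consensus at carrier-peak
centers among 9 random decoy PWMs.

What the generators do **not** emulate: Tn5 sequence bias, duplicate reads,
fragment-length periodicity, repeat structure or GC content of real
genomes, donor pairing, or saturating swelling kinetics. Passing tests
therefore demonstrate correctness of the computational procedures under the
stated model, not robustness to every artefact of real ATAC-seq or imaging
data.

All generators are driven by a single seeded numpy Generator per stage;
identical configurations produce byte-identical output files.

## Numerical choices and degenerate inputs

- IRLS: tolerance 1e-8 on coefficients, 100 iterations max, linear
  predictor clipped to ±30 to keep separated groups finite; non-converged
  peaks are flagged and reported with p = NaN.
- Dispersion floor 1e-8; constant counts hit the floor.
- Median-of-ratios drops zero-containing anchor rows; a sample with
  all-zero anchor counts is a hard error naming the sample.
- BH is computed over non-NaN p values only; NaN propagates.
- Ties in motif ranking are broken by (padj, p, motif_id) for determinism.
- Empty wells are excluded from morphometry with a warning; an area of 0 at
  t = 0 is an error.

## Problem sizes used by the test and acceptance runs

Unit tests run on instances of tens to hundreds of peaks/fragments; the
calibration simulations use 2,000 peaks × 9 samples × 20 seeds; the TSS
recovery runs at 10⁵ fragments; the end-to-end determinism check runs the
full default design (300 peaks, ~60k fragments/sample) twice. These sizes
were chosen to give stable Monte-Carlo estimates at interactive runtimes.

## Known limitations

- No dispersion or fold-change shrinkage: rankings for very-low-count peaks
  are noisier than shrinkage-based tools would give.
- Group-only design; no paired-donor correction.
- The motif stage tests enrichment of *known* PWMs only and its
  hypergeometric model treats peaks as exchangeable, ignoring sequence
  composition differences between foreground and background.
- GREAT-style curated domains and nearest-gene fallback are not modelled.
- The t-reference calibration was tuned to small-replicate designs; for
  large n it converges to the normal reference.
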