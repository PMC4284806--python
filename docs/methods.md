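# Methods

## Data model and conventions

All coordinates are 0-based, half-open (BED convention). A CpG dyad is one
record, keyed by the plus-strand C position, with read counts from both
strands summed — combining the strands' calls into a single per-dyad count
is the convention adopted here; averaging instead of summing would halve the
effective depth without changing levels. Chromosome names match by exact
string equality. Sites with zero depth are *missing*, never zero: they are
excluded from every mean and from both sides of the calibration scan.

A `SampleSeries` registers the biological roles: one somatic baseline, an
ordered set of time-course intermediates, the F-class samples (the
alternative stable pluripotent state) and the ESC-like samples. All deltas
and hyper/hypo annotations are relative to the baseline.

## Methylcytosine calling

The error rate *p* is the fraction of cytosine base calls that remained
cytosine in an unmethylated spike-in genome (nonconversion plus sequencing
error); the conversion rate is *cr = 1 − p*. At a CpG with depth *n* and
*k* methylated reads the evidence against the no-methylation null is the
binomial upper tail *P(X ≥ k)*, *X ~ B(n, p)* (`scipy.stats.binom.sf`).

The tail cutoff *M* is chosen by an empirical scan over the observed tails:
each distinct tail *u* is the infimum cutoff whose call set is
{tail ≤ *u*}; the largest *u* with

    u · N_uncalled(u) < fdr · N_called(u)        (fdr = 0.01)

is selected, and the operational threshold is stored as `nextafter(u)` so
the strict `tail < M` rule keeps ties at the selected tail. Numerical
choices worth noting:

- Cutoff candidates are restricted to tails strictly below 1. The tail of a
  zero-methylated-read site is exactly 1; admitting it would make the
  inequality vacuous (nothing remains uncalled) and call every covered
  site. Equivalently, *k* = 0 is never callable.
- `N_uncalled` counts uncalled *tested* sites (depth > 0). The alternative
  base — all tested sites — is exposed as `uncalled_base="tested"`.
- The guard "no calls when *p* ≥ fdr" is global (the error rate is a
  sample-wide quantity), flagged on the threshold table.
- On a genuinely unmethylated genome no cutoff satisfies the inequality and
  the caller returns zero calls — the correct degenerate behaviour.

The cutoff is folded into a per-depth minimum count *k*<sub>min</sub>(*n*)
(non-decreasing in *n*); depths not seen during calibration are derived on
demand. Adjusted levels use the standard nonconversion correction
*(m/n − (1 − cr))/cr* clamped to [0, 1], which is the identity at
*cr* = 1; the raw fraction remains available. The correction's exact
rendering is a documented convention of this package.

## DMR detection

Windows of `window_size` = 30 consecutive CpGs advance one CpG per step,
subject to: genomic span < 6 kb (span measured to the end of the last
dyad), and in *every* sample depth > 5 (strict, "more than 5×") at ≥ 15 of
the 30 CpGs. The per-sample window level is the unweighted mean over
covered (depth > 0) CpGs — not depth-weighted, since the coverage gate has
already been applied.

Candidate screening: max between-sample difference ≥ 0.30 and max/min fold
≥ 4, with the minimum floored at 0.01 to avoid division by zero (the floor
is a documented choice; the screen is a pure effect-size gate). The test is
a one-way ANOVA with samples as groups and per-CpG levels as observations —
the only viable reading when time points have no biological replicates.
The genome-wide scan computes the F statistic from sliding sums
(cumulative sums of levels and squared levels per sample), verified in the
test suite to agree window-by-window with `scipy.stats.f_oneway`; windows
with zero within-group variance get *p* = 0 when group means differ and
*p* = 1 otherwise. BH correction (`statsmodels`) is applied over **all**
tested windows as one family; a window is differential iff it passed the
effect screen *and* *q* < 0.01.

Joining: pass 1 merges windows overlapping by ≥ 1 bp (single-linkage sweep;
abutting intervals do not merge under the half-open convention). Pass 2,
iterated to a fixpoint, additionally merges consecutive regions whose gap
is smaller than (1 − 0.6) × the smaller region's length — i.e. the smaller
region, extended across the gap, would still cover more than 60% of itself
inside the union. Two properties drove this choice among the readings the
join clause admits: it is *local* (a hull-based "combined length over joint
span" rule is runaway — once a merged region grows, it swallows every
neighbour and ultimately the chromosome), and it is *idempotent* (joining
the output changes nothing, since the condition depends only on the final
intervals). The variant using the progressing (left) region as the
yardstick is available via `rule="progressing"`.

DMR levels are unweighted means over all common-universe CpGs in the DMR
interval. Status per sample is hyper when level − baseline > 0.20, hypo
when baseline − level > 0.20, strict inequalities. Trajectory clustering
mean-centres and variance-scales each DMR's level vector and applies
average-linkage agglomerative clustering on correlation distance
(`scipy.cluster.hierarchy`), cut into `n_groups` (default 6). Cluster mean
trajectories are then mapped to archetype labels (1a gain-early, 1b
gain-late, 2a F-class-low, 2b F-class-high/ESC-low, 3 ESC-only-low) by
best correlation against idealized templates; the raw cluster id is always
retained, the label is a heuristic layer. Constant rows are excluded from
clustering and labelled by nearest template in level space.

## Enrichment and TF selection

Fold enrichment is the printed density ratio: (features overlapping the
examined regions / merged region bp) / (reference count / reference bp). A
feature counts once per region set when it overlaps ≥ 1 bp; the examined
bp is the merged union. Containment is the fraction of regions holding
≥ 1 feature and is invariant under splitting a feature into abutting
pieces. The stratified mark association tabulates DMR–sample pairs with
level < 0.30 (low) and ≥ 0.70 (high) against overlap with H3K4me3/H3K27me3
cluster sets. The TF rule selects a factor iff fold enrichment of its sites
in the ESC-only-demethylated group relative to all DMRs exceeds 1.2 *and*
more than 10% of those regions contain a site; the base-pair-fraction
reading of "overlap" is available via `overlap_basis="bp"`.

## TFBS profiles and histone scores

Sites are anchored at the interval midpoint and treated as unoriented.
Neighborhood profiles lay 400 bins of 200 bp (± 40 kb) and average per-CpG
level deltas vs baseline across all sites of a factor, with
pairwise-complete deletion of missing CpGs; bins past a chromosome end
simply receive no CpGs, and contributing-site counts are tracked per bin.
The histone enrichment score of a 30-bp window is the fraction of the
window covered by a merged peak — peak files carry no comparable score
semantics across callers, so coverage fraction is this package's declared
score; deltas aggregate exactly like the methylation profiles. Dip widths
are summarized as the half-width at half depth (bins at least half as deep
as the apex), so a Gaussian kernel of sd σ yields ≈ 1.18 σ.

## Peak clusters and integration

For each mark, peaks from all samples form clusters as connected components
under ≥ 1 bp overlap; a sample's score in a cluster is the total bp of its
(per-sample merged) peaks inside it, so per-sample peak bp is conserved
across clusters. Scores normalize per cluster or per gene with the maximum
mapped to 1 (all-zero vectors stay zero). H3K4me3/H3K27me3 clusters attach
to genes via promoter overlap, H3K36me3 via gene-body overlap.

Promoters are 5 kb upstream to 1 kb downstream of the TSS, strand-aware and
clipped at chromosome bounds. The expression-class cascade uses an FPKM
on-threshold of 1.0 and an "early" boundary at the second intermediate
sample — both configuration keys, as the class definitions are
rule-parameterized in this package — and reuses the 0.30/0.70 methylation
strata. Classes are checked in the order 1a, 1b, 1c, 2a, 2b, 3a, 3b; a rule
needing a missing promoter methylation value leaves the gene unclassified
with the failure recorded in its rule trace. Mark-transition rates restrict
to genes lacking the mark at baseline and compare acquisition in the
ESC-like state between low- and high-methylation strata with a two-sided
Fisher exact test.

## Synthetic data

The generator lays non-overlapping elements along one chromosome — CpG
islands (dense, stably unmethylated), DMR archetype regions (35 CpGs at
~35 bp spacing, levels following the archetype templates scaled to
0.10–0.80), gene promoter clusters (the full strand-aware promoter shares
the gene's methylation trajectory), and 200-bp TF sites — separated by
background CpGs at stable high methylation (0.80). Counts are binomial:
depth ~ Poisson(30); the methylated-read probability is
level + (1 − level) · 0.005, i.e. nonconversion folded into the success
probability, matching the caller's model; per-site Gaussian jitter
(sd 0.03) models biological variability, and a single parameter switches on
beta-binomial overdispersion (default off). Spike-ins are binomial draws at
the nonconversion rate.

Demethylation kernels at TF sites subtract a Gaussian (depth 0.70; sd 1 kb
in non-baseline course samples for early-activated factors, 10 kb in
ESC-like samples; ESC-only factors act only there) from background and
site CpGs — other planted elements keep their own trajectories, so kernels
never corrupt planted DMRs. Overlapping kernels resolve by the minimum
(deepest demethylation wins). Histone tracks are rule-generated and
anti-correlated with methylation: H3K4me3 over islands, demethylated
promoters of expressed genes and demethylated TF sites; H3K27me3 over
low-methylation promoters of silent genes; both marks jointly over
low-methylation DMR regions with probability 0.95; H3K36me3 over expressed
gene bodies. Expression is the class on/off template × lognormal noise
(σ = 0.10) when on and uniform below threshold when off.

Default scale: one 10-Mb chromosome, ~50,000 CpGs, 12 samples (baseline,
five course intermediates, two F-class, four ESC-like), 60 regions per
archetype, 40 genes per expression class, 12 sites per factor. Element
spacing (≈ 9 kb mean gaps, minimum above the 6-kb window span) guarantees
that no test window can bridge two planted elements, so each called DMR
corresponds to one planted locus. Two deliberate departures from real data:
background CpG spacing (~300 bp) is sparser than a mammalian genome, so
most pure-background windows fail the span gate and the tested windows
concentrate on dense elements (the null-calibration configuration plants
250 large islands to supply dense null windows instead); and kernels,
peaks and expression are rule-generated with known coupling rather than
mechanistically linked. Passing tests therefore demonstrate correctness of
the statistics and the end-to-end plumbing under the model's own
assumptions — binomial counts, coherent region-level trajectories — not
robustness to alignment artefacts, copy-number variation or non-CpG
context, which real data would add.

Ground truth includes, besides the planted DMR regions, every other truly
changing locus: late-demethylating (Expr-1c) and early-gaining (Expr-2b)
promoters and kernel footprints (the radius where depletion ≥ 0.1), so
precision is measured against all genuinely differential sequence.

## Evaluation experiments and problem sizes

`methylseries.evaluation` packages the standard experiments: the
false-positive control on a fully unmethylated 10⁵-CpG methylome (three
seeds; the reported value is the calibration-permitted false-positive
percentage among calls, zero when nothing is called); null calibration of
the window scan at 50,000 CpGs × 12 samples; planted-region recovery and
trajectory ARI at 60 regions per archetype; the kernel half-width ratio;
and the expression-class round trip. These sizes keep each experiment in
the seconds-to-a-minute range on one CPU while leaving every rate estimate
with comfortable Monte-Carlo margins.

## Known limitations

- Non-CpG methylation, per-read QC, alignment and peak calling are out of
  scope; counts, peaks and site sets are inputs.
- The adjusted-level formula and the histone enrichment score are declared
  conventions of this package (see above), configurable where alternatives
  are plausible.
- The expression-class rule constants (on-threshold, early boundary) are
  parameters; other rule settings will classify different gene sets.
- The archetype labels on DMR clusters are a template-matching heuristic on
  top of the clustering; inspect cluster means before trusting labels on
  unusual designs.
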