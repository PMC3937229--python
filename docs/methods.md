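# Methods

## Scope and data model

The pipeline starts from mapped retroviral insertion sites: one record
per provirus–host junction with chromosome, 1-based position, strand
relative to the reference plus strand, tumour identity, optional
genotype label, and a supporting read count. Cohorts are pandas
DataFrames with that schema; BED6 I/O converts between BED's 0-based
half-open coordinates and the internal convention (1-based points,
0-based half-open intervals) only at the file boundary. Unknown
chromosomes are an error by default (silently dropping records would
bias every genome-wide null) with an explicit `ignore_unplaced` escape.

## Read-start merging

Reads from the same tumour whose start positions lie within `max_gap`
(default 3) nucleotides are one integration event. Merging is
single-linkage within (sample, chromosome, strand): a chain 100, 103,
106 merges even though its end points are 6 apart, because the rule is
pairwise proximity. The merged site takes the position of the member
with the most reads (ties: smallest coordinate — the deepest pile-up
best estimates the true junction) and the summed read count, so total
read mass is conserved and merging is idempotent and order-independent.
Strand-blind merging is available (`ignore_strand=True`) for datasets
where junction reads from both provirus ends were pooled; the default
keeps strands separate since opposite-strand junctions are distinct
provirus ends.

## CIS detection by multi-scale Gaussian kernel convolution

Each unique site contributes an unnormalised Gaussian bump, f_σ(x) =
Σ_i exp(−(x−x_i)²/(2σ²)), with unit weight regardless of read count:
recurrence of independent integration events, not clone size, is the
evidence of selection (read weighting is available as a config option).
The default scale ladder is 2, 5, 10, 15, 30, 60, 120, 250, 500 kb —
geometric, covering tight intragenic clusters through long-range
enhancer-mode targets, and including the 15 kb and 30 kb scales that
anchor the saturation pseudo-kernels and the bin-enrichment analysis.

**Evaluation.** f_σ is evaluated exactly (windowed summation with a 6σ
kernel cutoff, error ≲ 1.5e-8 per site) on a grid of step 0.25σ
restricted to the union of ±4σ neighbourhoods of the sites, plus every
site position itself. Outside those windows the density cannot reach
any useful threshold; using the same evaluation scheme for observed
cohorts and null draws keeps the comparison exact even where the grid
slightly undersamples a peak.

**Null calibration.** Per scale, the calling threshold is the (1−α)
empirical quantile (α = 0.05) of the genome-wide maximum of f_σ over
`n_null` (default 100) cohorts of the same size placed uniformly over
the genome, chromosomes weighted by length. This is a family-wise
max-statistic control: a uniformly integrating cohort produces a
significant cluster at a given scale in only ~α of runs, which is what
makes "0–3 CISs expected under random integration" the operating point
at screen scale. Thresholds depend only on (cohort size, genome,
scale, α, n_null, seed), so a threshold table computed once at the
nominal cohort size (12,485) is reused across replicate cohorts of
near-identical size in the evaluation functions; the ~1% size
differences shift thresholds negligibly and conservatively.

**Candidate extraction and consolidation.** Contiguous above-threshold
stretches become candidates; members are the sites within the stretch;
candidates with fewer than 2 members are dropped (a cross-sample
minimum is available but off by default, since within-tumour recurrence
is also informative). Candidates overlapping by ≥ 1 nt across scales
form components, and each component is reported at its *matched* scale
— the scale whose candidate maximises peak height relative to that
scale's own threshold. This is the matched-filter choice: the ratio
peaks when the kernel width fits the cluster width. Two alternatives
were rejected after measurement: reporting the union of members across
all significant scales inflates extents to the widest scale's region
(median ~830 kb against the ~30 kb cluster scale actually detected) and
dilutes orientation statistics with passer-by background sites, while
reporting the smallest significant scale fragments broad clusters into
sub-peaks. The component's full envelope, its set of significant scales
and the union of members remain recorded on each CIS
(`envelope`, `supporting_scales`, `all_member_index`). Extents span the
reported members' min/max coordinates; the peak is the density argmax,
clamped into the extent (ties: smallest coordinate).

**Fixed-window rule.** For near-baseline vector datasets the package
also provides the historical cluster definition: a greedy left-to-right
scan emitting disjoint clusters of ≥ 3 sites whose spanned width
(max − min + 1 nt) is at most 12,587 nt. The width bound is inclusive.

## Orientation bias

Per CIS, members are split by strand and tested against the strand
counts of all remaining sites with a one-tailed Fisher exact test in
the direction of the CIS's majority orientation; a tie is defined as
p = 1. Benjamini–Hochberg step-up adjustment runs over the whole CIS
battery and q < 0.05 (strict) defines the biased set. Two properties
of this construction matter for interpretation: choosing the tested
tail from the data makes null p-values anti-conservative by up to a
factor of two (P(p ≤ t) ≈ 2t), and BH's adaptivity means that in a
battery with many genuinely biased CISs the expected share of false
flags among discoveries approaches α. Both effects are inherited from
the screen literature's procedure and are visible in the calibration
suite: the per-null-driver false-flag probability on the default
synthetic design sits at ≈ 0.05, and evaluation uses 40 replicate
cohorts so the Monte-Carlo error of that estimate stays well below the
quantity itself. For batteries of thousands of small clusters (the
near-baseline emulation) a vectorised hypergeometric-tail
implementation is used; it is tested for exact agreement with the
per-CIS route.

## TSS distances, overlap, enrichment, genotype tests

Signed TSS distance is ris.pos − tss_pos flipped for minus-strand
genes, so negative is always upstream of the gene; nearest is by
absolute distance with lexicographic gene-id tie-break, and sites on
chromosomes without annotation are flagged rather than dropped. CIS-set
overlap uses ≥ 1 shared nucleotide between 1-based inclusive extents.
Bin enrichment tiles each chromosome into ⌈L/30 kb⌉ bins, marks bins
intersecting any target region, assigns each CIS to the bin holding its
peak (extent-overlap assignment available), and applies a one-sided
Fisher test; the same routine accepts printed counts directly.
Genotype comparisons are two-sided: Fisher on per-tumour presence of an
expanded insertion (≥ 100 reads) at a locus, either focal-vs-one or
focal-vs-rest since the original contingency construction is ambiguous;
Mann–Whitney U on per-tumour mean reads/RIS at the locus, exact for
tie-free groups of ≤ 8, normal approximation with tie correction
otherwise, with tumours lacking the insertion either excluded (default)
or included as zeros. Gene-set enrichment is a one-sided hypergeometric
test run over a grid of top-k target removals to profile robustness of
enrichment to the strongest hits.

## Saturation analysis

Each sample's sites are widened to half-open pseudo-kernels
[pos − 7,500, pos + 7,500) clipped to the chromosome — exactly 15 kb
for interior sites, matching the 15 kb GKC anchor scale — and merged
within the sample. For each subset size n, union coverage is evaluated
over all n-sample combinations when there are at most `max_combos`
(default 1,000), else over that many distinct seeded random
combinations, and summarised by median and quartiles. Full enumeration
of 2^28 subsets is pointless — quartiles converge long before — and
exactness is retained automatically for small cohorts. The control
re-draws each sample's site count uniformly over the genome. The
saturation signature is quantified as the ratio of real to control
marginal median gain at a given n; on a design whose drivers are
exhausted by the first 15 tumours the ratio at n = 20 is ~0.02.

## Synthetic cohorts

The generator realises the two-stage picture the analysis assumes:
integration preference first, oncogenic selection second.

*Background* (preference): each of `background_sites_per_sample` sites
is TSS-directed with probability `tss_weight`, landing at a uniformly
chosen TSS plus a signed Laplace offset of scale `tss_decay` (Laplace,
not Gaussian — empirical TSS-distance profiles have heavy shoulders),
otherwise uniform; strands are fair coins; reads are geometric, capped
at 99. Defaults: weight 0.2, decay 5 kb against 20,000 synthetic genes
— giving ~17% of sites within 5 kb of a TSS, a realistic γ-retroviral
preference — chosen once as study conditions, not fitted.

*Drivers* (selection): the default design plants 50 driver loci ≥ 5 Mb
apart (CIS targets are genome-scattered; separation keeps called
clusters attributable), 30 enhancer-mode with forward-orientation
probability 0.9 and 20 orientation-neutral, windows 2–20 kb, each
carried by a tumour with probability 0.8. A carried driver contributes
one insertion uniform in its window; its clone's read count is
100 + round(lognormal(μ=5.5, σ=1.2)) — a shifted log-normal floor-100
law reproducing heavy-tailed rank-read curves — and the clone also
receives Poisson(1) passenger insertions at uniform positions carrying
*exactly* the clone's read count (co-amplification). Background reads
never reach 100 and clone reads never fall below it, so the expansion
threshold separates planted clones exactly; with 28 samples the
expected cohort size is ≈ 12,485.

Everything is deterministic given the config seed (genome annotation,
driver placement and cohort draws use separate child seeds). The truth
table labels every insertion driver/passenger/background with clone
identity, and `score_recovery` computes driver sensitivity (locus
inside a called extent, over drivers with ≥ 2 planted insertions),
false-CIS rate (called CISs with no driver member) and biased-set
recall/false-flag against the planted orientation probabilities.

What the generator does *not* model: sequence-level artefacts (PCR,
restriction-site bias, primer drift), chromatin-state integration
hotspots beyond the generic TSS mechanism, subclonal phylogenies, or
copy-number co-amplification noise (a passenger read-noise multiplier
exists but defaults off). Passing recovery tests therefore demonstrate
calibration of the statistics under the stated preference/selection
model, not robustness to library-preparation artefacts of real data.

## Evaluation problem sizes and numerical choices

The reference evaluations run at screen scale: mouse-genome-size
chromosomes (UCSC mm9 lengths), 12,485-site cohorts, 100 Monte-Carlo
null draws per calibration, 10 uniform null cohorts, 100 strand
randomisations over a 1,345-cluster near-baseline battery (32,592
sites), 40 replicate recovery cohorts, and 1,000-combination
saturation curves — sizes at which every reported rate has Monte-Carlo
error comfortably below the margins being tested while a full run
stays in the minutes range on one CPU. Ties are broken
deterministically throughout (smallest coordinate, lexicographic ids);
empty inputs return empty outputs except where a statistic is
undefined, which raises. Known limitations: thresholds assume a
uniform integration null (a TSS-preferential null would be stricter
near promoters — the package measures this as residual false CISs on
synthetic cohorts, ~1%); the per-scale α is not corrected across the
nine scales (the matched-filter consolidation keeps the realised
per-cohort false-call count well under one); and the data-driven
orientation tail is anti-conservative by construction, as documented
above.
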