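# Methods

This note documents the models and procedures implemented in `startshift`,
their assumptions, the parameters that matter, and the design choices made
where the design was genuinely open. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Coordinate conventions

All internal coordinates are 0-based half-open; BED/bedGraph I/O uses the
same convention, so no shifting happens at the boundary. Analysis windows
are expressed as strand-relative nucleotide *offsets* from an anchor
(usually a TSS): offset 0 is the anchor base, positive offsets run
downstream in the direction of transcription, and quoted inclusive ranges
such as −900..+100 are realized as inclusive offset ranges. On the minus
strand, offset +k is genomic position `anchor − k`.

## Observed TSS calling

Per transcript, raw (un-normalized, replicate-summed) control 5′-end counts
are scanned over offsets −1000..+1000:

1. Candidate A is the argmax base; candidate B is the argmax base inside
   the 200-nt window with the greatest summed density (step 1 nt). The
   candidate closer to the annotation wins; this "nearest-to-annotation"
   reading is the conservative resolution of a proximity rule that is
   otherwise underdetermined.
2. Pol II check: if the summed Pol II coverage in the 501-nt window at the
   selected base is strictly below 2/3 of the same window at the annotated
   TSS, the call is re-anchored to the best base within ±250 nt. We use
   coverage sums (not read counts) for the comparison.
3. Below 5 reads at the selected base, the annotation is retained.

Ties at equal counts break toward the annotation, then upstream; window
ties break toward the window whose center is nearest the annotation. These
rules make the caller fully deterministic. Calls at an identical base keep
the shortest annotated→observed distance; same-strand calls within 200 nt
are clustered by single linkage, low-confidence annotations (RIKEN-style
`…Rik` and predicted `Gm####` names) and low-read fallbacks are dropped
unless they are all a cluster has, and the shortest-distance member
represents the cluster. Single linkage was chosen over pairwise grouping
because it is order-independent.

A promoter is classified NF-Y-bound when a ChIP peak interval intersects
the observed TSS −900..+100 window (inclusive at both ends).

## Spike-in normalization

Two estimators are computed from the spike count matrix (spikes × samples):

* **Regression factor** (track scaling): after per-10-million depth
  normalization, the least-squares slope *through the origin* of each
  sample's spike counts against the reference sample — the one with the
  lowest total spike count, whose factor is 1 by construction. No intercept
  is fit: spike input is proportional by construction, and an intercept
  would absorb depth artifacts. Signal tracks are **divided** by the
  factor.
* **Size factors** (for the count test): the median-of-ratios estimator on
  the spike matrix alone — per sample, the median over spikes of
  count / geometric-mean, where spikes with a zero in any sample are
  excluded from the geometric-mean reference set.

The two estimators are kept separate and both reported; they are not forced
to agree numerically. Note the scale-equivariance caveat: scaling one
sample by c scales its regression factor by c exactly, but median-of-ratios
factors rescale their pseudo-reference too, so only factor *ratios* scale
by c.

## Ectopic TSS detection

Counts are taken per sample in 10-nt bins tiling offsets −995..+995 around
each observed TSS. The region length (1991 nt) is not divisible by 10;
bins start at −995 + 10k for k = 0..198, so offsets −995..+994 are covered
and the single farthest downstream base is dropped — the least-consequence
tiling. A bin is excluded when (a) its offset range intersects the core
−25..+24, or (b) its midpoint lies closer to another same-strand observed
TSS than to its own (midpoint rule; same-strand only — antisense initiation
is a separate phenomenon and its TSSs do not compete for sense-strand
bins).

Retained bins are tested for a knockdown increase with an original
negative-binomial exact test:

* Counts are divided by the spike-derived size factors. The per-bin
  dispersion is `max(α_mom, α_trend(μ))` with a floor of 1e-8, where
  α_mom = (v − μ)/μ² uses the grand mean μ and the within-condition
  residual variance v pooled across conditions (so a genuine condition
  difference does not inflate the dispersion), and the trend
  α(μ) = a₀ + a₁/μ is fit by ordinary least squares over all retained bins
  with μ > 0. Taking the max guards against under-estimated per-bin
  dispersions at the cost of mild conservatism.
* The p-value conditions on the grand total N = K_ctrl + K_kd: each
  condition total is modelled as a moment-matched negative binomial with
  pooled rate q₀ = N / (S_ctrl + S_kd) (S = summed size factors; the
  moment match accounts for Σs² within the condition), and the two-sided
  p-value is the probability mass of all splits (a, N − a) no more likely
  than the observed one. Empirically this test is slightly conservative
  (type-I ≈ 0.031–0.037 at nominal 0.05 under the matched null), which the
  calibration experiment quantifies.
* Benjamini–Hochberg correction runs jointly over every retained
  (gene, bin) pair, mirroring a single genome-wide test table.

Per gene, among bins with positive log₂ fold change and padj < 0.1, the
lowest-padj bin wins (ties: lowest p, then nearest the TSS); the ectopic
TSS is the base with the highest summed knockdown 5′-end count inside it
(count ties: nearest the observed TSS, then upstream). Reported log₂ fold
changes use size-factor-normalized condition means with a 0.5 pseudocount
on each mean; the pseudocount affects reporting only, since selection
requires a positive difference. Because core bins are excluded before
testing, no call can ever lie within ±25 nt of the observed TSS — an
invariant the test suite asserts over 100 random simulations.

Interpretation note: the selection rule "the position with the total
knockdown read count" is read as "the highest total" (an apparent elision
in its source).

## Nucleosome encroachment

MNase fragments are filtered to lengths 120–180 inclusive (values outside
the quoted "shorter than 120 / larger than 180" bounds are dropped),
deduplicated on (chrom, start, end) without consulting mate strands, and
reduced to one count at the midpoint `(start + end) // 2` — exact for odd
lengths, rounded toward the 3′ half for even ones, a deterministic and
strand-independent convention. Center tracks are normalized per ten million
retained fragments after merging replicates per condition (normalizing
after the merge; the alternative per-replicate order is logged as a flagged
choice).

Occupancy change per promoter is the pseudocounted ratio
(KD + 1)/(control + 1) of normalized center counts summed over a TSS
window, encroached at ≥ 1.5. The window defaults to the core −25..+24 —
the region whose occlusion defines encroachment — but is a configuration
knob (`mnase_tss_window`) because the exact window behind the published
fold-change statistic is not pinned down. The pseudocount of one
normalized unit avoids division by zero at silent promoters without
materially shifting ratios at occupied ones.

ATAC insertion tracks (for accessibility visualization) cover the first
9 bp of both mates; smoothing extends each 9-bp core symmetrically by
21 nt to 51 bp.

## Ribosome profiling

P-sites are placed a fixed 12 nt downstream of each footprint's 5′ end in
the direction of transcription, for all fragment lengths (no
length-stratified offset calibration). Phasing at a start codon counts
P-sites over 60 codons from the A of the ATG, splits them by offset mod 3,
and tests against the uniform (⅓, ⅓, ⅓) expectation with a χ²
goodness-of-fit; RNA-Seq-like uniform coverage gives frame fractions near
⅓ and serves as the negative control. Candidate upstream ATGs in a
shifted region (ectopic TSS to 25 nt upstream of the canonical TSS,
strandwise, sense strand only) are scored by summed P-site coverage over
offsets 0..59 downstream of the A; ties go to the ATG nearest the ectopic
end. Genes whose shifted region holds strictly more than 5% of the library
are dropped from phasing. Shifted-region expression is RPKM; genes without
a promoter-proximal peak use the fixed surrogate region −115..−25 (the
median-shift-distance convention). Per-gene control-vs-knockdown
significance, where needed, reuses the NB machinery above, since the
underlying comparison does not name a test.

## Sequence features

CCAAT boxes are counted on both strands (ATTGG is the reverse-strand
occurrence) with overlapping matches allowed — NF-Y binds the box in
either orientation, and `count_ccaat(s) == count_ccaat(revcomp(s))` is a
tested invariant. The initiator context of a TSS is the sense-strand
dinucleotide at offsets (−1, 0); YR means pyrimidine then purine.
Conservation profiles aggregate an externally supplied per-base score
track (loaded with NaN fill); unscored bases are excluded from every mean.
Conservation scores and predicted nucleosome occupancies are consumed,
never computed.

## Synthetic data generator

The generator emulates the assays at desk scale: by default 200 genes in
6-kb loci on two chromosomes (alternating strands, TSS mid-locus), three
replicates per condition, and per-sample true scale factors
(1.0, 1.15, 0.9 | 1.05, 0.8, 1.2) representing capture-efficiency
differences at equal nominal depth — the reported totals table is a
constant nominal depth, so depth normalization is neutral and the spike
estimators must recover the planted factors from the spike counts alone
(15 spikes, Poisson, geometric abundance ladder around 300 reads).

Start-Seq 5′-end counts are negative binomial (dispersion 0.05) with a
background of 0.5 reads/nt/sample over ±1 kb of each TSS, a canonical peak
of mean 100 at the TSS, and — in knockdown samples only — an ectopic peak
of mean 50 at the planted offset, i.e. 10× the 10-nt-bin background mean.
The background level was chosen to match the count regime the binned test
is specified for (per-bin means of order tens); at substantially sparser
counts the per-bin dispersion estimate is noise-dominated and the test
loses power by design of its max rule. Planted offsets are uniform on
−300..−40 (sample median shift ≈ 170 nt upstream), always outside the
core; a configuration placing shifts inside the core is rejected.

MNase fragments come from −1/+1 nucleosomes (dyads at −200/+120, centers
Normal(dyad, 20), lengths uniform 120–180), a uniform background of
0.6 fragments/nt over ±500 nt, and — knockdown only, at shifted genes — a
planted TSS nucleosome whose 60 fragments roughly double the fragment
density over the TSS window. Ribo-Seq emits frame-0-enriched P-sites from
a canonical ORF starting +200 nt downstream of each TSS (purity 0.9) and,
for ~70% of shifted genes, from a planted 60-nt uORF whose ATG sits 5 nt
downstream of the ectopic TSS (knockdown only, purity 0.85, 150 P-sites).
Every canonical and ectopic TSS gets a planted CA initiator and every
promoter one CCAAT at −80.

What the generator does *not* model: mappability, GC and sequence bias,
MNase digestion preferences, splicing, divergent/convergent transcription,
and annotation idiosyncrasies. Passing recovery tests therefore
demonstrates correctness of the algorithms under the stated noise model,
not robustness to every artifact of real libraries; absolute published
gene counts that depend on a specific genome annotation and deposited
libraries are out of reach at this scale and are not targeted.

## Numerical and structural choices

* Exact-test summation works in log space with a max-shift; observed-mass
  comparison uses a 1 + 1e-8 relative tolerance to absorb rounding.
* Degenerate inputs: empty tracks give zero windows; all-zero bins give
  p = 1; silent promoters are guarded by pseudocounts; an empty gene set
  yields an empty but well-formed report.
* All tie-breaks are total orders (documented above), so every stage is
  deterministic given its inputs; the pipeline writes no timestamps, and
  two runs from the same seed are byte-identical.
* Problem sizes in the validation experiments (200 genes for recovery,
  10,000 bins for calibration, 100 × 12-gene simulations for the core
  invariant) were chosen so the full validation harness completes in about
  a minute on one CPU while keeping the binomial counting statistics of
  each rate estimate comfortably tight.
* The command-line layer is deliberately thin (`simulate`, `run`); all
  other capabilities are the importable API, demonstrated one per script
  under `examples/`.
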