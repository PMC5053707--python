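# Methods

## The statistical model behind each stage

**Per-CpG methylation.** A CpG observation is a pair (m, t): methylated
reads over total coverage at that base. Its beta-value is β = m/t. Region
methylation is the *unweighted* mean of the beta-values of the CpGs inside
the region (1-based inclusive bounds): the per-CpG values are averaged, not
the pooled counts, so a deeply covered CpG does not dominate a region.
Regions with fewer than `min_cpgs` (default 3) covered CpGs are reported
missing rather than zero.

**Window test.** For each 1000-bp tile the per-sample counts are aggregated
to (mᵢ, tᵢ) and a binomial GLM with logit link regresses the methylated
proportion on an intercept plus group indicator; each observation enters as
a (success, failure) binomial outcome and is therefore weighted by its
coverage. Significance is the likelihood-ratio chi-square with 1 df against
the intercept-only fit. Because the group indicator is the only covariate,
the MLE depends on the counts only through the per-group pooled sums, so
the LRT coincides with the G-test on the pooled 2×2 table — the test suite
pins this equivalence against a hand-written G-test to 1e-6. The effect
size is the pooled percent difference, group1 − group2. Windows with zero
coverage in either group are skipped and logged, not assigned p = 1;
windows whose pooled counts sit at a boundary (all 0 or all t) get p = 1
because the group model cannot improve on the null.

**q-values.** Default `slim_pi0`: the null proportion π₀ is estimated from
the upper tail of the p-value distribution — π₀(λ) = #{p > λ}/(n(1−λ)) on a
λ grid 0.1…0.9, taking the mean from the plateau (smallest finite-difference
slope) onward, clipped to (0, 1] — and q = π₀ × BH. This is a deliberately
simple stand-in for sliding-linear-model q-value estimation; the exact SLIM
spline machinery is not reproduced, and plain BH is always available
(`qmethod="bh"`). π₀ ≤ 1 guarantees q_slim ≤ q_BH, which the suite asserts.

**DME selection.** A two-tailed two-sample t-test (Welch by default;
pooled-variance Student available since the original analysis ran in a
spreadsheet whose test variant is unknown) on per-sample whole-enhancer
methylation, selecting at raw p < 0.05 with no multiplicity correction.
This mirrors the original 24-candidate screen faithfully; it is a
reproduction choice, not a statistical endorsement. Groups that are exactly
constant are handled by convention: equal constants give p = 1, unequal
constants p = 0.

**Correlation screen.** Candidates are all (selected DME, passing DMR)
pairs on the same chromosome, excluding DMRs contained in the tested
enhancer (their CpGs would correlate trivially with the enhancer mean).
Sample Pearson r uses pairwise-complete samples (n recorded; n < 3 pairs
skipped); p = two-tailed tail of t = r·√(n−2)/√(1−r²) on n−2 df. BH runs
within each enhancer's candidate family by default because each enhancer's
screen is reported separately; `fdr_family="pooled"` adjusts jointly. The
published threshold statement "−0.85 ≥ r ≥ 0.85" is unsatisfiable as
written and is implemented as |r| ≥ 0.85. Strength labels follow the
conventional scale: |r| ≥ 0.5 "good to excellent", otherwise "moderate to
nil".

**Annotation.** Priority promoter > gene body > intergenic. The promoter is
the 1500 bp immediately upstream of the TSS in gene orientation (TSS =
tx_start on +, tx_end on −), clipped at position 1. Exons and introns are
numbered in transcription order (exon 1 nearest the TSS), which is what
reproduces "intron 3, exon 4, intron 4" for a minus-strand gene. Published
enhancer-to-TSS distance columns mix anchors (region start in some rows,
region end in others), so `tss_distance` takes an explicit anchor
(`region_start`, `region_end`, `nearest_edge`) and the pipeline reports all
three rather than guessing a single convention. Intergenic gaps use
1-based inclusive arithmetic (an adjacent region is 1 bp away); nearest-gene
ties break on the smaller accession string.

**Capture validation.** Enrichment cohorts measure methylation as read
density, not base-level beta-values, so regions are quantified as rpkm =
(reads overlapping by ≥ 1 bp) / (region kb × mapped reads in millions),
with the library size taken as the sample's full read count. Nominated
pairs are re-tested by Pearson correlation of rpkm vectors; no |r|
threshold is applied at validation — r, p and the strength label are
reported.

## Coordinate conventions

All in-memory coordinates are 1-based inclusive (browser-style); BED is
converted at the I/O boundary ((start+1, end) inward, (start−1, end)
outward) and the round-trip is tested as an identity. CpG calls from
opposite strands are kept as separate observations; no strand merging rule
is applied. Coverage filtering defaults to ≥ 10 reads per CpG.

## What the synthetic cohorts emulate

`SimConfig` defaults encode the study conditions: 6 vs 5 samples, one
2-Mb chromosome, 20,000 CpGs, mean coverage 30 (negative binomial, size 8,
truncated ≥ 1), beta-binomial methylation noise with precision 50, 50
planted DMR windows at group-mean difference 0.6 (0.8 vs 0.2), 20 enhancers
of 1–4 kb, and 10 coupled enhancer–partner pairs with latent-factor slopes
a = b = 0.12. Background CpG methylation is bimodal and identical across
groups: low (0.1) inside CpG-dense segments (8% of 1-kb cells, 5× CpG
density), high (0.8) elsewhere.

Planted DMRs sit exactly on the 1000-bp tiling grid so window-level
recovery is unambiguous. Each coupled enhancer is group-differential over
its whole span and contains one grid-aligned "anchor" DMR window, so the
containment stage can nominate it; its distal partner window is itself a
planted DMR whose group direction is the enhancer's direction times the
coupling sign. Per sample, the enhancer's regional mean moves by a·u_s and
the partner's by sign·b·u_s, where u is a per-sample standard-normal latent
factor **centered within each group** before use — coupling therefore adds
within-group covariation without perturbing the planted between-group
difference, which must stay above the 50% pooled-difference filter for the
windows to remain callable. Means are clamped to [0.02, 0.98] to keep Beta
parameters valid and Pearson r defined. The capture cohort draws a fresh
latent factor for its 24 samples and places fixed-length 36-bp reads with
intensity proportional to regional methylation, so coupled pairs show
correlated rpkm; library composition is ~30% background scatter.

What the generator deliberately does **not** model: read sequences,
bisulfite conversion errors, mappability bias, PCR duplicates, copy-number
variation, or heterogeneous per-sample effect penetrance. Passing tests
demonstrate that the pipeline's logic recovers planted structure under
realistic count noise; they do not demonstrate performance on real tumor
methylomes, whose within-group heterogeneity is far larger.

## Calibration and the specificity of the screen

Two calibration facts are documented because they are properties of the
method, not bugs:

* The aggregated-count window LRT ignores the beta-binomial overdispersion
  it is run on (as the upstream windowed approach does). At the default
  noise settings (precision 50, coverage 30) the variance inflation is
  ≈ 1 + (coverage−1)/(precision+1) ≈ 1.6, and the empirical p < 0.05 rate
  on a null cohort is ≈ 0.12 rather than 0.05. The joint effect-size +
  q-value filter is what restores stringency: the null pass rate at
  |diff| > 50 and q < 0.01 is ≤ 0.001 (measured 0 over ~2,000 windows).
  In the near-binomial regime (precision 5000) the test is calibrated to
  within [0.5α, 2α], which the suite asserts.

* In a clean two-cluster simulation the correlation screen is sensitive but
  unspecific: *any* two group-differential regions measured on the same
  6-vs-5 cohort share the group axis and correlate at ρ ≈ 0.9, so most
  (DME, DMR) candidate pairs pass |r| ≥ 0.85 — the screen's pair-level
  precision at defaults is only a few percent, and the acceptance script
  reports it as a diagnostic. Raising within-group variability enough to
  suppress this would destroy the > 50% pooled-difference recall of the
  planted windows, so the two goals cannot be met simultaneously in this
  design. Recovery is therefore asserted as: all planted coupled pairs
  pass with the planted sign, called windows lie in planted differential
  territory (window-level precision ≥ 90%), and the capture cohort — whose
  only cross-sample structure is the latent factor — reproduces the sign of
  every recovered planted pair while uncoupled regions decorrelate.

## Numerical and design choices

* Window test: likelihood-ratio rather than Wald, for stability at extreme
  proportions; IRLS failures at perfect separation fall back to the exact
  pooled-table deviance.
* Reads and calls are not de-duplicated anywhere in the pipeline.
* Containment ("completely within"), not 1-bp overlap, pairs DMRs with
  enhancers; an `--overlap-mode any` escape hatch exists. One DMR inside
  several overlapping enhancers yields all pairs.
* Exactly-constant vectors are detected by peak-to-peak range, not by a
  floating-point standard deviation.
* Group 1 is the first group label encountered in the sample sheet; all
  signed differences are group1 − group2.
* Problem sizes in the test and acceptance runs (one 2-Mb chromosome,
  20,000 CpGs, ~2,000 windows, 24 capture samples at 50,000 reads) were
  chosen as the smallest sizes at which every stage's statistics are
  well-resolved; all simulations are seeded and reproducible.

## Known limitations

The SLIM approximation shares only the π₀-reweighting idea with the
original method. The DME stage's uncorrected p < 0.05 over candidates is
reproduced from the original workflow and is anti-conservative. The screen
and validation assume a shared sample ordering and pairwise-complete
vectors; no imputation is attempted. Multi-isoform genes are annotated per
transcript model, without isoform reconciliation.
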