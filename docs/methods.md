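# Methods

This note records the models behind `mitodrift`, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical conventions a user should know before trusting a result.

## Coordinates and reference model

All coordinates are 1-based inclusive, matching how positions in animal
mitogenomes are conventionally printed. BED input (0-based half-open) is
converted on read; GFF3 is used as-is. The mitogenome is circular:
homopolymer runs may wrap the origin (handled by scanning modulo the genome
length, capped at one full genome), but gene features may not — in the
standard rotation of the C. elegans mitogenome no gene spans the origin, so
origin-spanning gene features are rejected rather than silently rotated. The
AT-rich control-region mask may wrap, supplied as two intervals. `N` is
allowed in references but breaks homopolymer runs and cannot be translated.

An indel is anchored at the reference position of the affected base: a
deletion's allele is the deleted sequence, an insertion's the inserted one.
Its frequency denominator is the reads informative at the anchor
(reference-supporting plus indel-supporting); partially informative
alignments are not modelled. On VCF output, indels are left-anchored with
the preceding base, per VCF 4.2.

## Copy-number estimation

Relative copy number is the line's mean per-site mitochondrial coverage
divided by the unweighted mean of three single-copy nuclear gene mean
coverages. The unweighted (not length-weighted) mean is deliberate: in the
bundled worked example the printed "single-copy" column equals the
unweighted mean of the three per-gene columns for every line, which pins
down the convention. Sample SD (n−1) is used throughout; the AT-rich mask
applies to the mitochondrial mean/SD only, never to nuclear genes. Fold
change is the mean of MA-line values over the progenitor's value, with the
per-line range reported alongside.

Two lines of the bundled worked example do not recompute from their own
printed inputs (the N2 progenitor, 8.9 recomputed vs 9.4 printed, and N2
MA574, 49.9 vs 50.1, under a one-unit-in-the-last-digit comparison). These
are inconsistencies internal to the source tables; the package reports the
recomputed values and flags the disagreement rather than forcing either
number. Similarly, the per-generation growth translation of the observed
fold changes is ambiguous — a 5.2-fold rise over 250 generations is 1.7%
per generation under a linear model but 0.66% under a geometric one — so
`per_generation_rate` computes both and leaves interpretation to the user.

## The heteroplasmy filter

The filter is calibrated per line, not per cohort:

* **Count rule** (≥ 6 variant reads, inclusive) suppresses frequency
  estimates resting on a handful of reads.
* **Coverage window** (site coverage within 1 SD of the line's per-site
  mean, two-sided and inclusive) excludes sites whose coverage is atypical
  for the line — in practice, repeat- or homopolymer-driven mapping
  artifacts. "Within one SD" is read as |Δ| ≤ 1·SD; the source phrasing
  does not specify inclusivity and the inclusive reading keeps the
  boundary site.
* **Frequency floor** (frequency strictly greater than the line mean
  background frequency + 2 SD). The background statistics are computed over
  **all** unmasked covered sites, zero-variant sites included, which makes
  the floor an empirical estimate of the line's per-base error rate. The
  alternative (variant-bearing sites only) would inflate the floor with the
  very signals being tested; the choice is configurable.
* **Baseline exclusion**: an allele at ≥ 0.95 frequency in any baseline
  (progenitor / lab-strain) profile is a strain-level difference from the
  reference, not a de novo heteroplasmy. The 0.95 cutoff is a default, not
  a sourced value.

Each alternate allele at each site is evaluated independently; non-passing
candidates are retained with per-rule flags, because fate matrices print
sub-threshold frequencies. Filter monotonicity (tightening any threshold
never enlarges the PASS set) is enforced by property test.

## Synthetic cohorts

The generator emulates the study design the package targets: a progenitor
plus `n_lines` MA lines, each line `generations` single-individual
bottlenecks from the progenitor, sequenced as pileups.

**Transmission** is neutral Wright–Fisher resampling of `bottleneck_N`
mtDNA segregating units: f(t+1) = Binomial(N, f(t))/N, absorbing at 0
and 1. One transmission event per MA generation; within-life copy-number
expansion and selection are not modelled (the MA design minimizes
selection). The germline segregating-unit number in C. elegans is unknown;
`bottleneck_N` defaults to 10 on the phenomenological ground that a ~5%
founder heteroplasmy must be able to reach both fixation and loss within
the ≤ 43–50 generations of the emulated experiment, which requires
near-complete absorption on that timescale (at N=10, ≈ 99.7% of replicates
are absorbed by generation 43; at N=20, ~3% still segregate). It is a free
parameter, not a biological claim.

**Coverage** at ordinary sites is negative-binomial with variance
mean + dispersion·mean² (dispersion 0 = Poisson; default 0.003, i.e.
near-Poisson at a few hundred reads). A fraction `artifact_fraction`
(default 0.03) of sites is additionally marked artifact and has its mean
multiplied by a log-uniform **dip** (0.05–0.5×) or **spike** (2–5×),
equiprobably. This two-component model reflects where overdispersion in
real mitogenome coverage actually lives: most of the molecule is
well-behaved, while localized regions (repeat collapse/pile-up, homopolymer
margins, control-region edges) deviate strongly. The defaults give a
site-to-site coverage CV ≈ 0.3, inside the 0.13–0.39 range of per-line
mitochondrial coverage CVs in the bundled worked example. The split matters
for the coverage-window rule: with a single i.i.d. light-tailed coverage
law, a site falls within one SD of the mean only ~68% of the time — no
threshold choice can fix that — whereas under the dip/spike model the SD is
carried by the artifact minority and the rule does what it is meant to do,
discard anomalous sites while keeping ordinary ones. Planted-variant
positions are never chosen as artifact sites, because an artifact site's
allele counts would be mapping-corrupted in a way the generator does not
model; planted biology is placed at clean positions.

**Errors**: each read miscalls with probability `error_rate` (default
1e-3), uniformly over the three non-reference bases. Sites inside
homopolymer runs of ≥ `homopolymer_min_run` (default 5) bases additionally
acquire single-base deletion errors at `homopolymer_indel_error` (default
3e-3), emulating polymerase slippage at indel hotspots. Base-quality
ladders, strand bias and read-level simulation are out of scope.

**Sanger traces** are FASTQ records with Gaussian quality noise around
`flank_quality`; a segregating site's quality is depressed by ≥ 20 Phred
(default drop 25), the signature of overlapping electropherogram peaks. The
classifier flags a site segregating when its score is more than `delta`
(default 15) below the 50 bp flanking mean — the margin between the
simulated ≥ 20 drop and the 15 threshold, against ~1.5-Phred flank noise,
is what makes the closed loop reliable. The trace screen classifies
(absent/segregating/fixed) only; peak heights are not quantified, so no
frequency is estimated from traces.

All generators are pure functions of (config, seed); reruns are
byte-identical, and the pipeline's report bundle is compared file-by-file
in tests.

What passing on synthetic cohorts does **not** show: robustness to
mapping bias around true indels, strand artifacts, index hopping,
contamination, or nuclear insertions of mitochondrial sequence (numts) —
real-data failure modes the generator does not contain.

## Fate classification

Relative to the progenitor, a variant in a line is **lost** (below the 0.01
detection floor, or failing the line's filters), **fixed** (≥ 0.99), or
**segregating**; a variant absent from the progenitor is **gained** where
detected. The floors are configurable defaults: sources print "0.000" and
"1.000" without defining cutoffs, and lines reported as "lost or
dramatically reduced" are collapsed into *lost* here. Summary counts are
emitted under both conventions used in the field: per-record (each PASS
cell counts) and unique-event (a progenitor-shared variant counts once;
parallel de novo events count once per line).

## Statistics

Levene's test uses classic mean centering; Kruskal–Wallis is tie-corrected
with a χ² reference on k−1 df (both via scipy, checked in tests against
direct-formula and brute-force-rank oracles). The post-hoc procedure is
Dunn's z test on the pooled midranks with the standard tie correction
Σ(t³−t)/(12(N−1)), adjusted by Benjamini–Hochberg by default (Bonferroni
available) — the generic "multiple comparison test after Kruskal–Wallis"
in the nonparametric literature. Degenerate inputs (all values identical)
return the conventional (statistic 0, p 1) rather than an error.

Null calibration of Levene's test is done with 3 groups × 50 normal
values × 1,000 replicates. The group size matters: Levene-with-mean is
intrinsically liberal in small samples (measured type-I ≈ 0.065 at n=10,
≈ 0.057 at n=20), so the nominal-level check is run at a size where the
test is honest (≈ 0.05 at n=50). The per-region copy-number groups fed to
these tests in the pipeline are the annotated genes' normalized mean
coverages (equal-width windows when no annotation is supplied).

## Problem sizes

Default test/calibration sizes: filter specificity on 1,000 simulated
200-site lines; sensitivity on 200 lines of 2,000 sites (a planted 10%
variant at 300× with 1e-3 error; sensitivity is genome-size-aware because
the line SD must be estimated from enough sites for the coverage window to
stabilize); 10,000 Wright–Fisher replicates; 100 Sanger seeds per state.
The full-length default genome (13,794 bp, the C. elegans mitogenome
length) is used where per-site resolution matters but not in the
calibration loops.

## Known limitations

* The filter assumes one dominant alternate allele per site; tri-allelic
  sites are evaluated allele-by-allele without joint modelling.
* Indel frequencies ignore alignment left/right-shift ambiguity within a
  homopolymer run (counts are taken at the anchor as given).
* The coverage window rule is calibrated per line from the same pileups it
  filters; on very short genomes (≲ 500 sites) the SD estimate is noisy
  and the rule's behaviour degrades — use longer references or widen the
  window.
* Baseline exclusion needs the baseline sequenced at comparable depth; a
  shallow baseline cannot certify "not fixed in the lab strain".
* Real electropherogram artifacts (dye blobs, mobility shifts) can depress
  Phred scores without heteroplasmy; the trace screen treats any localized
  depression as segregating.
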