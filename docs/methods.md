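# Methods

## Scope and model

`msipeaks` calls microsatellite instability (MSI) status for a single
tumor sample sequenced on a capture panel, without a matched normal.
The statistic is per-locus: the number of distinct repeat-tract lengths
whose depth-corrected supporting-read count exceeds a threshold (the
*peak*). A random forest over the peak values of selected marker loci
produces an MSI-H probability; the call is MSI-H when the score is
≥ 0.6 (inclusive), MSS otherwise.

The model's assumptions: (i) repeat-tract length can be read off a
spanning alignment's indels; (ii) read support per length scales
linearly with coverage, so dividing by the sample/panel-of-normals
depth ratio makes samples comparable; (iii) mismatch-repair deficiency
broadens the tract-length distribution at susceptible loci, which the
peak count captures without modelling the stutter process itself.

## Locus discovery

The scanner reports every maximal tandem-repeat run in the reference
with unit length 1–6. A run is represented once, at its **canonical
unit**: the shortest period, phased at the leftmost position of the
periodic region; whole unit copies only (a trailing partial copy
neither counts nor breaks maximality). `N` or any non-ACGT base breaks
a run; soft-masked lowercase is uppercased first, since capture panels
routinely target repeat-masked loci. Homopolymers are kept at tract
length ≥ 10; multi-base units at copy number strictly > 3. The > 3-copy
rule is applied only to multi-base units — for homopolymers the
10-base minimum already implies 10 copies. Panel restriction keeps loci
overlapping a capture interval by ≥ 1 base (half-open coordinates
throughout, BED-compatible).

## Peak features

A read measures a locus only when it is primary, mapped, not a
duplicate, and aligned with unclipped M/=/X bases at every position of
both `flank` windows (default 5 bp each side). Anchored flanks prevent
misreading tract length at clipped or partially aligned tract edges;
there is no mapping- or base-quality filter by default (both are
configurable). Observed tract length = reference tract length +
inserted − deleted bases within the tract, from the CIGAR. An insertion
whose breakpoint falls exactly on a tract boundary belongs to the
flank, one strictly inside the tract to the tract — a deterministic
tie rule.

The correction ratio uses the locus's own spanning depth, not a
genome-wide sample depth: coverage on capture panels varies strongly
between loci, and a sample-wide ratio would leak that variation into
every locus's support counts. Corrected counts are kept as reals — no
rounding — and the validity test is strict (`support > 3`). Ratios ≤ 1
leave the histogram unchanged: scaling *up* an under-covered sample
would manufacture support where none was observed. A locus with zero
baseline depth is flagged uncorrectable and passed through raw with a
warning.

Downsampling to a maximum per-locus read count (for depth-robustness
experiments) draws a uniform subset with a seeded generator and leaves
loci at or below the cap untouched.

## Marker selection

Candidate screening (mean spanning depth > 30, mean peak > 1.5, both
strict) averages over the labelled training tumors; a flag switches
the depth screen to the normal samples instead, since either cohort is
a defensible source for capture-efficiency estimates. The group
comparison is a two-sided Wilcoxon rank-sum test via the tie-corrected
normal approximation with 0.5 continuity correction
(`scipy.stats.mannwhitneyu`, asymptotic): at cohort sizes around 20 per
group the asymptotic p is accurate where it matters. Known property:
against exact permutation enumeration at very small samples (4 + 4) the
approximation deviates by up to ~0.03 at mid-range p-values
(0.2 < p < 0.7), while agreeing to well under 0.01 in the small-p
region that drives selection at α = 0.01. Selection uses raw p < 0.01,
strict, with no multiple-testing adjustment by default (a Bonferroni
flag exists); all candidate loci are reported with their statistics,
sorted by p-value, and an empty selection is a hard error since the
classifier would have no features.

Note the consequence of the continuity-corrected two-sided test: with
fewer than about 6 samples per group the p-value cannot fall below
0.01, so tiny cohorts select nothing at the default α.

## Classifier

scikit-learn `RandomForestClassifier`; defaults: 500 trees, unlimited
depth, sqrt-of-features per split, seed 42 — enough trees for stable
probability estimates at panel-scale (tens of) features, all exposed
as flags. The score is the forest's MSI-H class probability; the
threshold 0.6 is a fixed operating point, not re-tuned. A sample
missing a marker (no coverage) is imputed as peak 0 with a warning —
an uncovered locus is indistinguishable from an uninformative one,
which is a documented limitation — and a sample missing more than half
the markers is refused. Model bundles serialize the forest, ordered
marker list, threshold and metadata (format version, library versions,
seed) via joblib; loading verifies the format version.

## Synthetic data

The simulator emulates panel-captured, aligned reads over
microsatellite loci — the data the pipeline consumes after upstream
alignment, which is out of scope.

* **Reference**: run-suppressed random background (homopolymers capped
  at 6 bases, multi-base repeats below 4 copies) with planted maximal
  repeat runs, scrubbed until the scanner's output equals the planted
  list exactly; the planted loci are therefore the complete truth set.
* **Defaults** (the simulated study conditions): 50 loci on two 12 kb
  contigs; reference tracts 10–34 bases (mostly A/T homopolymers, 10%
  TG dinucleotides, mirroring real marker panels); 100 bp reads at
  100× mean spanning depth (Poisson per locus); per-read stutter
  probability 0.02 with geometric (p = 0.7) ±1-unit-dominated step
  sizes, the classic PCR stutter ladder; MSI-H samples carry 3–5
  alleles at 20% of loci, spread over up to 8 repeat units below the
  reference length (deletion-biased instability, as observed in dMMR
  tumors); MSS and normal samples carry the reference allele only.
* Reads are emitted pre-aligned with the tract-length change encoded
  as a single insertion just inside the tract or a deletion at its
  right end; every read's emitted tract length is recorded in the
  ground truth, so extraction can be verified read-for-read.

What the simulator does **not** model: sequencing substitution errors,
GC and fragment-length bias, alignment ambiguity or reference bias at
repeats, interrupted/compound repeats, contamination, and tumor purity
below 100%. Passing tests therefore demonstrate the pipeline's
correctness and statistical behaviour under idealized alignments, not
clinical performance on real tumors.

## Problem sizes used in the test suite

End-to-end checks train on simulated cohorts of 50 loci (10 unstable),
20 + 20 training and 10 + 10 held-out tumors with 5 baseline normals at
100× depth, repeated over 5 seeds; held-out sensitivity and specificity
are both ≥ 0.95 on average and marker selection ranks the 10 planted
unstable loci first. Depth-robustness replays cap each locus at 100
spanning reads and require ≤ 5% of held-out calls to change. Scanner
correctness is checked against an independent brute-force enumeration
oracle on repeat-rich 5 kb sequences, and rank-sum calibration on 500
null loci at 19 vs 25 samples per group.

## Numerical and degenerate-input choices

* Strict inequalities everywhere a threshold is stated (> 30, > 1.5,
  < 0.01, > 3); the decision threshold is the single inclusive one
  (score ≥ 0.6 → MSI-H).
* Zero spanning reads → empty histogram, peak 0 (valid, not an error);
  missing chromosome in a tumor BAM → hard input error; in a normal →
  that sample contributes depth 0 to the baseline with a warning.
* Identical rank-sum groups return p = 1.0 exactly (continuity
  correction at the null center clips to 1).
* Metric ratios with zero denominators are NaN, never 0.
* All randomness (simulator, downsampling, forest) flows from explicit
  integer seeds; reruns are bit-reproducible.

## Limitations

Tumor-only calling inherits the panel-of-normals assumption that
normals share the capture chemistry and depth profile of the tumors.
The peak statistic discards allele identity — it counts lengths, so a
locus with two well-supported germline alleles contributes peak 2 in
every sample and is usually removed by marker selection rather than
modelled. Fractional corrected support near the threshold (e.g. a
count of exactly 3.0) is invalid by the strict rule; whether the
original formulation rounded before thresholding is unknown, and no
rounding is applied here.
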