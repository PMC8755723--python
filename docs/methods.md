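# Methods

This note documents the models behind each module, the parameters that
matter, what the synthetic generators do and do not emulate, and the
numerical choices made where the design was open. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Replication index from the ori→ter coverage trend

**Model.** A bacterial population in which a fraction *f* of cells carries one
active replication fork has, in expectation, coverage proportional to
PTR^(1 − 2d/L) at circular distance *d* from the replication origin, where
PTR = 1 + *f* is the origin/terminus coverage ratio and L the genome length.
The estimator does not need *ori*/*ter* positions: window means are sorted
ascending, and because the windows' origin distances are uniform on the
circle, the sorted log₂ means are linear in the rank fraction with slope
log₂ PTR. The index is 2^slope of the OLS fit.

**Numerical choices.**

* Windows: 5,000 bp, non-overlapping; scaffolds of a genome bin are windowed
  separately (linearly, dropping partial tails) and pooled before sorting;
  scaffolds shorter than one window are skipped. A single profile is treated
  as a closed circle (the last window wraps).
* Rank fraction: the midpoint plotting position (i + 0.5)/n, the expected
  uniform quantile of the i-th of n order statistics. Regressing on i/(n − 1)
  instead compresses the slope by (n − 1)/n — a 1.5% downward bias on the
  index at 50 windows, visible against the noise-free generator.
* Trimming: 5% of windows from each tail, *after* assigning rank fractions,
  so trimming shortens the fitted range without changing the expected slope.
  Zero-coverage windows are excluded before the log transform and count
  against retention.
* QC: r² ≥ 0.90 and retained-window fraction ≥ 0.75; failing estimates carry
  `qc_pass=False` and are excluded from cross-sample averaging. An all-zero
  profile returns an explicit "no-coverage" status, never an index of 1.
* A perfectly flat profile has zero slope and an undefined r²; it is reported
  as index 1.0 with r² = 1.0 by convention (the fit is exact).
* Minimum 20 usable windows after trimming (≈ 110 kb of sequence at the
  default window), below which the fit is refused.
* The 2% read-mismatch tolerance applied upstream during mapping is recorded
  as provenance metadata (`mismatch_tolerance`); this package starts from the
  coverage profile.
* Archaeal genomes are refused unless forced: archaea can replicate from
  multiple origins, which invalidates the single-gradient model and makes the
  index non-comparable.

Defaults (window, trim, QC floors) are conventional values for
coverage-trend estimators, exposed in the API and CLI; they are not claimed
to be any published tool's fitted settings.

## Minimal generation time from codon-usage bias

Ribosomal genes of fast-growing prokaryotes are codon-optimized relative to
the genomic background. The 59 informative codons (61 sense codons minus the
single-codon families Met and Trp) are pooled per gene set; frequencies are
per amino-acid family. The bias statistic is the mean over families — with at
least two synonyms, observed in both sets — of half the L1 distance between
the family frequency vectors: 0 for identical usage, 1 for disjoint usage. It
is symmetric and invariant to gene order and to duplicating the gene set.

The calibration ln d(hours) = a − b·bias uses a = ln 40 and b = ln 100, so
bias 0 ↦ 40 h and bias 1 ↦ 0.4 h, spanning the observed range from inert
subsurface organisms to the fastest laboratory growers. The reported sd is
the delta-method transform of a fixed residual scale (0.25) on the ln axis.
These constants are this package's choices — the relationship is calibrated
for monotone comparative use, not absolute agreement with any external
predictor; accordingly the tests assert monotone recovery of injected bias,
not hours. Growth temperature is accepted and recorded but has no numerical
effect (a temperature correction would need externally fitted coefficients).

## Scaffold taxonomy by strict majority

Rank by rank from superkingdom to species, a label is assigned iff strictly
more than 50% of the scaffold's proteins carry it at that rank; the vote
stops at the first rank without a strict majority (exactly 50% never wins).
Unannotated proteins count toward the denominator by default — the
conservative reading — with `count_unannotated=False` to vote over annotated
proteins only. Lineages are the seven canonical ranks with a no-gap
invariant. By construction, a label winning rank r+1 is carried by >50% of
proteins, which also pins the winning parent at rank r.

## Pathway abundance

Per sample, scaffold coverage is normalized by library size as coverage per
Gbp sequenced (the unit is readable and cancels in the Z-scaled view). When a
pathway has several diagnostic key enzymes, the enzyme with the most distinct
scaffold hits in that sample represents it (ties broken lexicographically for
determinism; a coverage-weighted mode is available). The normalized
abundances of the selected enzyme's scaffolds are summed per pathway;
`sum_mode="all"` instead sums every enzyme of the pathway, covering the
alternative reading of the procedure. Rows (pathways) are Z-scaled with the
sample standard deviation (n − 1); zero-variance rows are zeroed and flagged.
Hits are assumed pre-filtered against per-enzyme score thresholds upstream;
the score column is pass-through metadata. Community diversity is the
Shannon–Wiener index H = −Σ p ln p over rpS3-scaffold relative abundances.

## Gene-sharing networks

Hits (BLAST tabular) are scored with similarity = alignment length ×
identity / query length, capped at 1 — a coverage-weighted identity.
"Identity" is the alignment's fractional percent identity; this is the only
reading that keeps the score in [0, 1]. An undirected edge joins two genes
when the larger of the two directed scores reaches the threshold (a stricter
min-mode is available); hits above the E-value cutoff (10⁻⁵) and self-hits
are ignored. Gene families are connected components; raising the threshold
can only remove edges, so family counts are monotone. Families spanning at
most two genomes are exported as gene-loss/HGT candidates; downstream
phylogenetic screening is out of scope.

## Biogeography

Geodesic distances are computed on the WGS84 ellipsoid with Vincenty's
inverse formulae (sub-metre accuracy away from the antipodal singularity; a
spherical great-circle fallback covers non-convergent near-antipodal pairs).
The implementation is validated against reference distances from an
independent Karney-type solver, frozen in the tests.

Fragment ANI chops the query genome into non-overlapping 1 kb fragments,
aligns each to its best gap-tolerant infix match in the subject (edlib, HW
mode; identity = 1 − edit distance / fragment length), keeps fragments with
identity ≥ 70%, and averages the reciprocal A→B and B→A means. The floors
follow common whole-genome ANI conventions. Unrelated sequences leave no
passing fragments and return an explicit "no-alignment" status. Distance
decay is the Pearson correlation of pairwise ANI against pairwise km over all
unordered pairs, with the two-sided p from the t transform.

## Carbon budget

Annual erupted inorganic carbon: volume per eruption × eruptions per year ×
(CO₂ × 12.011/44.009 + HCO₃⁻ × 12.011/61.016), with mg/L ≡ g/m³. Cell-bound
carbon: cells/ml × 10⁶ ml/m³ × volume × eruptions × 14 fg C per cell
(the standard subsurface estimate) × 10⁻¹⁵ g/fg. The fixed fraction is their
ratio in percent. Eruption count (default: ~210-day season × 12 eruptions/day,
one roughly every two hours) and concentrations are free inputs — the
published totals depend on supplementary measurements, so the headline
fraction is reproduced from the printed totals as inputs rather than from
guessed concentrations.

## Statistics

All tests are two-sided; the t-test default is Welch. Depth trends are
Pearson correlations either over every genome value or over per-ecosystem
medians, with an optional exclusion mask (e.g. CO₂-impacted sites). No
multiple-testing correction is applied by default; Benjamini–Hochberg is
available.

TOST equivalence uses symmetric bounds ±d\* where d\* is the Cohen's-d effect
a reference design had 33% power to detect under the two-sided two-sample
t-test (noncentral-t power, bisection; the implementation is cross-checked
against an independent power-curve grid). The bounds are converted to raw
units with the pooled sd and tested with two one-sided tests at α = 0.05.
One structural property deserves note: the 33%-power noncentrality (≈ 1.53)
lies below the one-sided critical value (≈ 1.645) for every sample size, so
when the bound is derived from the tested groups themselves equivalence can
never be declared — the bound must come from a smaller reference design
(`bound_n_a`/`bound_n_b`), e.g. a previously characterized CO₂-poor group.

The genome quality gate keeps bins with completeness ≥ 70% and contamination
≤ 10%, boundaries inclusive.

## Synthetic data: what it emulates, and what it does not

* **Coverage** is generated exactly under the replication-fork model
  (piecewise exponential in origin distance, origin at position 0, terminus
  at L/2) with optional Poisson counting noise, and rescaled so the profile
  mean equals the requested depth exactly. Real coverage additionally shows
  GC bias, mappability gaps, strain mixtures and non-Poisson overdispersion —
  none are simulated, so passing recovery tests demonstrates estimator
  correctness under the model, not robustness to mapping artifacts. Poisson
  noise itself is an assumption; real per-base depth noise is not published
  for these data.
* **Codon bias** is injected by sampling ribosomal-gene codons from
  (1 − s) × background + s × optimized, where the background is a seeded
  Dirichlet draw per family and the optimized table prefers one fixed codon
  per amino acid (major codons of fast-growing bacteria; any fixed one-hot
  table serves). The generator exposes both tables, so tests compare the
  empirical statistic against its closed-form expectation.
* **Site panels** (defaults: 12 sites evenly spanning 0–3000 m, 4 genomes of
  120 kb per site at 50× Poisson depth, base index 1.5 at the surface, depth
  slope −1.3 × 10⁻⁴ per m, per-genome noise sd 0.1, floored at 1.0, and 2
  CO₂-impacted sites with a +0.3 offset) emulate a cross-ecosystem survey in
  which replication activity declines with depth except at degassing-impacted
  sites. The depth effect and its magnitude mirror the comparative claim the
  statistics layer must detect. Note the CO₂ offset is a site-level cluster
  effect: a slope-0 panel including such sites is not a null for the
  per-value Pearson test (which assumes independent observations), so the
  null-calibration test generates panels without them.
* **Biogeo panels** descend n genomes from one ancestor by substituting a
  per-genome fraction p_i of sites independently (substituted base uniform
  over the three alternatives), giving expected pairwise divergence
  p_i + p_j − (4/3) p_i p_j. The loads are fitted by bounded least squares to
  the target identity 100 − decay·km, clamped at 75%. A star tree cannot
  reproduce an arbitrary distance matrix exactly, so the generator returns
  both the linear-law ground truth and the realizable expectation; for a
  single pair the fit is exact. No indels, rearrangements or recombination
  are simulated, which is why fragment ANI recovers the expectation to within
  binomial error.

## Problem sizes used by the test suite

Consistency tests use 250 kb genomes (50 windows); recovery panels use the
generator defaults above; the depth-trend criterion runs 100 seeded panels
per arm; statistical calibration uses 5,000 null replicates for the Welch
type-I rate and 500 for p-value uniformity. These sizes keep the full suite
at roughly two minutes on one CPU while leaving every Monte-Carlo band at
least five estimated standard errors wide.

## Known limitations

* The replication estimator assumes one origin per replicon and unordered but
  unbiased coverage; it is not a growth *rate* (that is the codon-bias
  module's role, and the two are complementary, not interchangeable).
* The growth calibration's absolute hours are package constants; only
  ordering and ratios are meaningful across genomes analyzed with the same
  calibration.
* Fragment ANI is alignment-based on colinear genomes; heavily rearranged or
  repeat-rich genomes would need the fragment matches deduplicated.
* The TOST bound search targets the two-sample pooled-df power function; for
  severely unbalanced designs with unequal variances the Welch df would
  differ slightly from the bound's df.
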