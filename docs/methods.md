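# Methods

## Data model and coordinates

An *editing call* is one candidate edited site observed in one sample:
chromosome, 0-based position (half-open single-base interval),
substitution `REF>ALT`, strand, supporting reads and total coverage.
Call files carry no sample metadata; the manifest TSV is the single
authority for group (tumor/adjacent), subtype (ER+/TNBC) and mapped-read
depth, which prevents call files and design tables from disagreeing.

All internal coordinates are 0-based half-open (BED-native); VCF input is
converted on read (POS − 1) and human-readable reports are rendered
1-based inclusive. This removes the ±1 ambiguity between BED and VCF
sources: a report position converts back to exactly the internal one.
Chromosome names are compared verbatim — silent `chr`-prefix
harmonization would mask annotation mismatches.

## Filter chain

Stages run per sample, in a fixed order, each reporting
input/retained/excluded counts (counts are conserved and the chain is a
monotone, idempotent subset operation):

1. **Editing type.** A-to-I editing reads as A>G; on a minus-strand
   feature the genomic signature is T>C. The strict rule retains exactly
   (A>G, `+`) and (T>C, `−`). The orientation-discordant pairs
   (A>G, `−`) and (T>C, `+`) are excluded by default; `lenient` mode
   accepts any A>G/T>C because some callers emit calls on the read
   strand rather than the annotated feature strand.
2. **Alu overlap.** Only calls inside Alu repeat intervals are retained
   (strand-agnostic — repeat orientation is irrelevant to a single-base
   overlap). Overlap is half-open: an interval [s, e) contains position
   p iff s ≤ p < e.
3. **SNP exclusion.** A call is removed when its position carries a
   known SNP whose allele pair is A>G or T>C — a genomic polymorphism
   indistinguishable from an editing signature. Other SNP alleles at the
   position do not trigger removal by default; a position-only mode is
   provided because annotation pipelines differ on this point.

Interval queries use per-chromosome interval trees; the tests compare
them against an all-pairs scan on random fixtures.

## Burden comparison

Per sample, the burden is the number of *distinct* retained sites.
Because detection is depth-limited, the comparable quantity is sites per
million mapped reads, with depth taken from the manifest. This is the
simplest depth proxy expressible in the data model; the normalizer is a
single column and alternative normalizations can be applied upstream.

Groups are compared within one subtype only (never pooled) with a
two-sided Mann–Whitney U test. For tie-free data with n₁+n₂ ≤ 16 the
exact permutation null is used. Above that, or with ties, a normal
approximation with continuity correction applies; for tie-free data it
includes an Edgeworth fourth-cumulant term using the exact excess
kurtosis of the U null,

γ₂ = −(6/5) · (n₁² + n₂² + n₁n₂ + n₁ + n₂) / (n₁ n₂ (n₁+n₂+1)),

verified against full enumeration for nine (n₁, n₂) shapes. The plain
continuity-corrected normal deviates from the exact two-sided p by up to
0.011 at n₁ = n₂ = 8 (computed over every achievable U); the correction
brings the worst case below 0.004, so the approximation hands over
smoothly at the exact/approximate boundary. With ties the tie-corrected
normal approximation (scipy) is used without the Edgeworth term, whose
tie-free cumulant would not apply.

## Prevalence-ratio prioritization

Detection is binary per (site, sample): the site either appears in the
sample's filtered call file or not, with no minimum supporting-read
threshold beyond the upstream filters. This matches the screening
question — how *consistently* is a site edited across samples — rather
than how strongly it is edited within a sample.

For each site, with detection counts k_t of n_t (tumor) and k_a of n_a
(adjacent): prevalences k/n, a 40 %-in-either-group retention filter
(boundary inclusive), and the tumor/adjacent prevalence ratio. Division
by zero is handled Haldane-style: in the default pipeline both
prevalences are shrunk to (k + 0.5)/(n + 1) unconditionally, which
stabilizes small counts; the plain estimator with a 0.5/n replacement
only for zero counts is also provided (and is what the textbook chain
uses). The guard applies to the numerator as well — a site can pass the
40 % filter through the adjacent group alone with k_t = 0, and the log
ratio must stay finite.

Ratios are standardized across sites and candidates must pass
|Z| > 1.96 (strict) **and** overlap a NAT interval. NAT overlap is
positional and strand-agnostic by default — a natural antisense
transcript is by construction antisense to the edited transcript, so
its annotated strand adds no information for a single-base overlap; a
strand-aware mode would require the NAT strand opposite the call
strand. No multiple-testing correction is applied: the fixed Z cutoff
is a screening rule, not an FDR procedure, and is recorded as such in
the run summary.

### Why the default Z is robust, raw-ratio, full-roster

The textbook standardization z = (v − mean)/sd over the post-filter
record set is exposed (`z_method="classical"`), but it is a poor
screening statistic here, for two reasons quantified in simulation:

- **Self-contamination.** The candidates being sought are by definition
  the outliers of v; with tens of genuinely differential sites among a
  few hundred, they inflate the mean/sd scale estimate and push their
  own |Z| back under the cutoff. On cohorts with 20 sites planted at
  prevalence 0.8 vs 0.1 among 1,000 (Beta(2, 8) shared background,
  20/15 samples), classical Z recovers only ~59 % of planted sites.
- **Selection bias.** The 40 % filter preselects sites whose *empirical*
  prevalence is extreme, so standardizing over the post-filter set
  measures spread on a noise-enriched sample.

The pipeline default therefore uses the robust location/scale pair
(median, 1.4826·MAD), estimated over the **full** detected-site roster,
applied to the **raw** prevalence ratio with Haldane shrinkage. On the
same simulations this recovers ≥ 95 % of planted sites with a mean
false-discovery proportion around 0.14. The raw scale outperforms log2
here because planted ratios (≈ 4–24) separate much further from the
background's MAD than their logs do; its known cost — a compressed
depletion side, since ratios are bounded below by zero — is acceptable
for a screen focused on tumor-enriched editing, and log2 mode remains
one flag away. Even a perfectly calibrated 5 % rule retains Poisson
false-positive noise at these cohort sizes, so the false-discovery
proportion of a single simulated cohort fluctuates by a few candidates
around its mean.

Prevalence, ratio and Z are computed per subtype independently; the
cross-subtype step is a plain set intersection on (chromosome,
position).

## Kinetics

2^−ΔΔCt: technical replicates are averaged on the Ct scale, ΔCt is
formed against the reference gene per (sample, condition, timepoint),
ΔΔCt against the calibrator condition's mean ΔCt (per sample where
available), and fold change is 2^−ΔΔCt. The double normalization used
for fractionation experiments (to a reference gene and to the total
fraction) is this same operation with the total fraction as calibrator.

Decay: first-order kinetics N(t) = N₀·e^(−λt) are fitted by ordinary
least squares of ln(expression) on time — deterministic, closed-form,
and adequate for the 7-point design (0, 0.5, 1, 2, 4, 6, 8 h); a
nonlinear refinement would add iteration without changing the estimate
materially at these noise levels. λ is floored at 0; a flat series
reports t½ = ∞ ("not reached"). Each biological replicate is fitted
separately so that a Welch t-test on replicate half-lives gives a
defined p-value when comparing conditions; pooled-curve fits would
discard the replicate-level variance that the test needs.

## Synthetic data

The cohort simulator emulates the statistical structure the analysis
consumes, not the sequencing process:

- **Detection is binary** per (site, sample) with the site's group
  prevalence — the prioritization statistic uses presence/absence, so
  this is the quantity that must be faithful. Read counts (negative
  binomial coverage, mean 30, dispersion 5; Beta(2, 5) editing fraction;
  supporting ≥ 1) exist so parsers and filters see realistic rows.
- **Background sites** share one Beta(2, 8) prevalence between groups
  (mean 0.2 — most sites detected in a minority of samples, a long
  right tail reaching the 40 % filter); **planted sites** carry the
  configured prevalence gap (defaults 0.8 vs 0.1).
- **Depth** is lognormal in mapped reads (median 3×10⁷, sd_log 0.4 —
  the scale and spread of bulk RNA-seq runs). Optionally, detections
  are thinned toward an expected burden-per-million target, making
  depth-dependent site counts (and hence the normalization) testable;
  by default thinning is off so per-site detection frequency converges
  exactly to the configured prevalence.
- **Annotations**: sites sit on a jittered grid (spacing 150) on one
  pseudo-chromosome; Alu (±20) and NAT (±40) intervals are emitted
  per-site with widths below half the spacing, so the truth table and
  the interval files are exactly consistent and checkable
  exhaustively. 85 % of background sites are Alu-resident, 3 % coincide
  with an A>G/T>C SNP decoy, 25 % are NAT-overlapped (antisense
  transcription covers a minority of expressed loci); planted sites are
  always Alu, never SNP, and NAT-overlapped by default.
- **Seeding**: one global integer seed drives a named child generator
  per artifact (sites, depths, detections, reads, ...), so adding a
  stream never shifts existing ones; identical config + seed is
  byte-identical on disk.

A separate direct generator (`simulate_normalized_burden`) draws
normalized burdens lognormally around group means for power and
calibration studies of the burden test (defaults: 20/15 samples,
sd_log 0.4, 2× shift), bypassing site-level machinery — the burden
test consumes only the per-sample rates, so replicating full cohorts
would add runtime without adding fidelity.

What the simulator does **not** model: read-level artifacts (mapping
bias, hyper-editing clusters), correlated detection between neighboring
sites within one Alu, sample-level covariates (purity, ADAR expression),
and inter-site prevalence correlation. Passing recovery benchmarks on
these cohorts therefore demonstrates correctness of the statistics
under the stated generative model, not performance on real tumors.

## Problem sizes and numerical choices

- Exact Mann–Whitney enumeration is verified exhaustively for all rank
  splits with n₁+n₂ ≤ 10; the approximation is audited at 8+8.
- Recovery benchmarks use the defaults above (1,000 sites, 20 planted,
  20/15 samples); power and calibration use 100 seeded replicates.
- Z-scores require ≥ 3 reference records; an all-equal ratio vector
  yields Z = 0 everywhere with a warning rather than an error.
- Candidate ordering is |Z| descending with (chromosome, position) as
  the tie-break, making output order deterministic.
- The run summary contains versions, seed, parameters and stage counts,
  and no timestamps, so reruns are byte-comparable.

## Known limitations

- The editing-call dialect is a fixed 7-column BED-like table; other
  caller dialects are accommodated via a column map, not sniffed.
- Burden normalization is linear in mapped reads; saturation of site
  discovery at high depth is not modelled.
- The raw-ratio robust screen is asymmetric by construction (weak on
  tumor-depleted events); use `ratio_scale="log2"` when depletion
  matters symmetrically.
- Welch comparison of half-lives treats replicate fits as independent
  estimates and ignores their within-fit standard errors.
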