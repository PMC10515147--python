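# Methods

This note documents the statistical models, default parameters and design
choices behind each stage of the package, and what the validation on
synthetic data does and does not demonstrate.

## Calling model

A candidate observation is a biallelic (ref, alt) pair with mutant-read
depth `alt_depth ≥ 1` and wild-type depth `wt_depth ≥ 0`; third-allele
reads and deletion alleles are assumed discarded upstream. Zygosity is
provisionally heterozygous whenever at least one wild-type read is
present — the caller's behaviour this layer post-processes — and
homozygous otherwise. Acceptance at stringency level (HetMC, HomMC)
requires `alt_depth ≥ HetMC` for provisional heterozygotes and
`alt_depth ≥ HomMC` for homozygotes. Because the canonical ladder
(3,2) → (4,3) → (5,3) → (6,4) is non-decreasing in both components, the
accepted sets are nested; the implementation stores a single `max_tier`
per call and the ladder is validated for monotonicity on entry.

After acceptance, a heterozygous call is reclassified as homozygous when
the wild-type fraction `wt/(wt+alt)` is strictly below 0.15. In a
polyploid, a handful of wild-type reads at a truly homozygous site are
usually homeolog reads mis-mapped across subgenomes, not allelic
evidence. The threshold is configuration (default 0.15), the comparison
is strict, and the reclassification does not revisit tier acceptance:
acceptance used the heterozygous minimum because that is what the
upstream caller applied.

## Per-library EMS98% selection

The fraction of EMS-type calls (%-EMS) is a direct purity readout:
EMS produces essentially only G>A/C>T, so everything else is error or
residual polymorphism. Rather than fixing one stringency level for all
libraries, each library is assigned the *lowest* ladder level at which
its %-EMS reaches the threshold (default 98.0, inclusive). Libraries
that fail at every level are eliminated. A level at which a library has
zero surviving calls cannot qualify (the statistic is undefined on an
empty set). This keeps maximal call yield from clean libraries while
forcing noisy ones through harsher filters, and decouples the final
catalog quality from library-to-library variation.

Error estimation: false G>A/C>T calls are invisible among real EMS
mutations, but random errors generate A>G/T>C at about the same rate, so
the percentage of these reciprocal transitions among total calls
(computed after RH masking, before non-EMS removal) estimates the
residual false-EMS rate. One subtlety the simulation exposes: applied
*after* EMS98% selection, this estimator is slightly conservative,
because the cascade preferentially pushes libraries with many detectable
non-EMS errors to higher stringency and thereby removes proportionally
more of the detectable class than of its invisible G>A/C>T counterpart.
The unbiasedness check in the test suite therefore runs at a fixed
ladder level; the selected-call estimate should be read as a lower
bound within a factor of order one.

Zygosity QC: detected mutations in a selfed M₂ are expected 2/3
heterozygous (the homozygous wild-type quarter is undetectable). Lines
above the excess-heterozygosity cutoff (default 90%, strict) are flagged
as likely fusions of two independently mutagenized gametes. The
`shared_fraction` screen (|A∩B| / |A|, asymmetric on the focal line, with
sites keyed by contig/position/alt) distinguishes such lines from true
siblings, which share roughly half their mutations; a symmetric Jaccard
variant is exposed as well.

## Residual-heterogeneity index

RH windows are scored on four features per line: SNPs per kb, non-EMS
fraction, homozygous fraction, and the mean number of other lines
carrying the identical (contig, pos, ref, alt) SNP. Windows are 1-based
closed, tiled with configurable width and step (defaults 2 Mb / 1 Mb,
sized for a ~100 Mb capture space; analyses of the 2 Mb synthetic genome
use 30 kb / 15 kb so the expected SNPs-per-window is comparable). Each
feature is min-max normalized against the pooled window distribution of
the whole population; a feature constant across windows contributes 0.
The index is the equal-weight mean of the four normalized features and a
window is flagged at index ≥ cutoff (default 0.5). Every call of a line
inside any of that line's flagged windows is masked; survivors are never
modified.

Normalization is deliberately population-wide rather than per line.
The RH signal is population-level — a block descends from one
contaminating haplotype shared by its carriers, so block windows dominate
the pooled feature maxima — whereas normalizing each line against itself
guarantees that even an RH-free line has some window at 1.0 in every
feature, which measurably inflated collateral masking of genuine
mutations (to ~1.5% of true EMS calls) when evaluated on simulation.
With population-wide normalization the default cutoff achieves 100%
sensitivity on injected blocks at ~0.5% collateral loss across seeds.

## Poisson saturation accounting

The two-class simplification treats a fraction of GC sites as
EMS-accessible with a common hit rate and the rest as inert. With M
mutation instances on N accessible sites, per-site line counts are
approximately Poisson(λ = M/N), so the duplicate spectrum has
expectation E_k = (M/λ)·e^(−λ)·λ^k/k!. `fit_lambda` grid-searches
λ ∈ [0.001, 1.0] in steps of 0.001 minimizing
Σ_{k∈{2,3,4}} (n_k − E_k)²/E_k, ties to the smaller λ. Only k = 2..4
enter the objective: higher multiplicities are rare and dominated by
accessibility heterogeneity (the continuous reality behind the two-class
model) rather than Poisson sampling, and k = 1 is fully determined by M
and the multi-hit counts. A spectrum with no doubletons is not fittable
and raises an estimation error.

Derived quantities: accessible sites N = round(M/λ); saturation
1 − e^(−λ), the probability that a new mutation lands on an
already-mutated site; and the empirical duplicate-instance fraction
Σ_{k≥2} k·n_k / M, which equals 1 − e^(−λ) identically on an exact
Poisson spectrum (singleton instances are M·e^(−λ)) and therefore serves
as a model check with no fitted parameter. "Duplicated mutations" are
counted as *instances* at multi-hit sites, not as multi-hit sites: only
the instance-based definition satisfies the closed-form identity. GC
accounting multiplies the mapping space by its GC fraction; densities
are reported per kb of space (population) and per line.

Rounding conventions for reports: densities and percentages to one
decimal, site counts to the nearest integer.

Parameter recovery validated on simulation: for λ ∈ [0.05, 0.4] and
M ≥ 10⁵ the fit recovers the true accessible-site count within 5%
(typically within 1%).

## Context profiling

All EMS calls are oriented into the mutated-G frame (C>T calls are
reverse-complemented) before tallying the ±10 bp flank base frequencies;
position 0 is by construction 100% G. Enrichment divides each frequency
by the genome-wide base composition of the profiled reference itself —
capture spaces differ compositionally from whole genomes, so an external
background would bias the ratios. Calls too close to a contig edge for
the requested flank are skipped and counted. The oxidation profile
applies the same machinery in the damaged-C frame to C>A/G>T calls,
optionally restricted to the N libraries richest in that class (default
60 in the CLI), where the 8-oxoG mechanism predicts the (G/C)CG context:
C at −1 and G at +1 around the damaged base.

## Synthetic population generator

The generator reproduces the statistical structure the estimators
assume, at ~1/15 scale so that the full suite runs in seconds. Defaults
and what they emulate:

| parameter | default | rationale |
|---|---|---|
| `n_lines` | 400 | population of order 10³ lines, scaled down |
| `genome_size` | 2 Mb | capture space, scaled down |
| `gc_fraction` | 0.468 | measured GC content of a wheat capture space |
| `accessible_fraction` | 0.5 | about half of GC sites are EMS-accessible |
| `mean_mutations_per_line` | 250 | gives λ ≈ 0.21, near the fitted 0.15–0.18 range |
| `het_fraction_expected` | 2/3 | M₂ segregation among detectable carriers |
| `depth_mean`, `depth_dispersion` | 25, 5 | overdispersed capture coverage (negative binomial) |
| `contamination_rate` | 0.05 | per-read chance of a mis-mapped homeolog read at homozygous sites |
| `error_rate_per_class` | ems 0.5, A>G/T>C 0.5, oxo 1.6, other 0.8 | ≈1.3% of the mutation load, with C>A/G>T ≈ half of the errors and the EMS-mimicking rate equal to the reciprocal-transition rate |
| `library_quality_sigma` | 1.0 | log-normal library-to-library error intensity, so a tail of libraries fails the lowest tier |
| `oxo_context_bias` | 8 | weight favouring the C_CG context for oxidation artifacts |
| `rh_block_count/length/density` | 2 × 10 kb, 2 SNPs per kb | RH ≈ 1.5% of calls, dense and class-mixed |
| `rh_carrier_fraction` | 0.1 | each block carried by 10% of lines |
| `rh_hom_fraction` | 0.85 | RH blocks are old, mostly fixed polymorphism |
| `rh_class_mix` | 17% EMS / 25% A>G,T>C / 58% transversion | natural polymorphism has no EMS bias |
| `excess_het_line_fraction` | 0.065 | minority of lines formed by two-gamete fusion |
| `excess_het_gamete_mean_factor` | 0.585 | each gamete carries its own load; the union is ~17% larger than an ordinary line |

Mutation placement is uniform over accessible sites (optionally weighted
by `ems_context_bias` toward G-with-downstream-C sites), drawn with
replacement and de-duplicated per line — collisions are negligible at the
default λ. Per-line counts are Poisson; the real dose distribution across
an EMS population is unknown, and Poisson is the overridable default.
Heterozygous sites emit Binomial(depth, 1/2) mutant reads, homozygous
sites lose Binomial(depth, contamination) reads to the wild-type count
and are therefore provisionally mis-called heterozygous, exactly the
situation the 15% rule corrects. Error observations always look
heterozygous with low mutant support (2 + Poisson(1.2) mutant reads), so
stringency suppresses them — mirroring the observation that non-EMS
calls are >99.9% heterozygous in real data. RH carriers emit the block's
SNP list verbatim with their own read noise. A fixed seed yields
byte-identical output.

What the generator does **not** emulate: read-level artifacts beyond the
contamination probability (no FASTQ, no alignment), homeolog sequence
structure (the reference is i.i.d.), linkage between mutations,
continuous accessibility variation (accessibility is the same two-class
simplification the estimator assumes), and chromosome-scale structure
(one contig). Passing tests therefore demonstrate estimator correctness
under the model's own assumptions and calibrated noise — not robustness
to mapping artifacts or reference errors in real captures.

## Numerical and degenerate-input conventions

Statistics on empty call sets raise `UndefinedStatisticError` rather than
returning NaN. The λ grid is inclusive of both ends; ties take the
smaller λ. Min-max normalization of a constant feature yields 0. The
15% and 98% thresholds compare strictly (`<`) and inclusively (`≥`)
respectively, as the conventions they reproduce specify. VCF output is
one record per (line, site) instance with line ID and call annotations
as INFO fields — with thousands of lines each carrying a sparse private
mutation set, a population genotype matrix would be ~99.9% empty.
Coordinates are 1-based in TSV/VCF and 0-based half-open in BED.

## Known limitations

* The RH index weights and cutoff are conventions validated only on
  simulation; real RH blocks with atypical compositions (e.g. from a
  closely related donor with EMS-like divergence) would need re-tuning.
* The λ fit inherits the two-class accessibility simplification; with
  strong continuous accessibility variation, N = M/λ underestimates the
  mutable space and the saturation is correspondingly optimistic.
* The error estimator assumes class-symmetric random errors; any
  mechanism producing A>G/T>C specifically (e.g. certain polymerase
  biases) would inflate it.
* Tier acceptance assumes the upstream caller's het/hom partition; it
  does not re-genotype from raw depths.
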