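# Methods

## Scope and design

`archvar` reimplements, as a tested offline pipeline, a biobank
analysis of archaic single-nucleotide variant (aSNV) carriers: curate a
catalog of positions where archaic hominins carry the ancestral allele
and modern humans a (near-)fixed derived allele; find carriers of the
archaic allele in exome VCF data under explicit genotype QC; assign
ancestry superclusters; prune relatedness; build matched noncarrier
cohorts; summarize carrier phenotypes against the matched
distributions; and quantify what effect sizes the design could have
detected.  The original cohort (UK Biobank exomes, ~452k individuals
after sample QC) is access-controlled, so a synthetic-cohort generator
reproduces the statistical structure the pipeline assumes, and
deterministic fixtures realize the published cohort configurations at
the carrier level.

## Genotype and sample QC

A genotype enters the census only if its site FILTER is PASS and, per
genotype, GQ > 20 and DP > 10 (both strict, matching the stated
inequalities), and — for heterozygotes — the allele balance
AB = alt/(ref+alt) lies strictly inside (0.25, 0.75).  The quality
threshold is applied to the per-genotype GQ; an optional site-level
QUAL check exists but is off by default.  The first failing rule is
recorded in the fixed order site_filter → low_gq → low_dp →
allele_balance.  Genotypes referencing ALT alleles other than the
configured archaic allele are treated as missing for the analysis.
Sample-level QC drops any sample flagged for reported/inferred sex
mismatch, sex-chromosome aneuploidy, heterozygosity outlier, or high
missingness.

On chromosome X, male genotypes are hemizygous whether written haploid
("1") or diploid ("1/1") — both dialects are produced by the generator
and accepted by discovery.  A male chrX heterozygote is flagged
anomalous, excluded from the census, and logged rather than failing the
run: real pipelines tolerate pseudoautosomal artifacts.

## Ancestry superclusters

Self-reported ancestry codes map to EUR/AFR/SAS/EAS; "Mixed", "Other",
and nonresponse codes map to Uncategorized.  Because the original hard
PC cutoffs are unpublished, boxes on PC1–PC4 are fitted per labeled
cluster as the [q, 1−q] empirical quantile interval (default q = 0.01).
A labeled sample keeps its cluster only while inside its own box;
Uncategorized samples inside exactly one box are rescued into it, and
ambiguous (multi-box) membership conservatively stays Uncategorized.  A
sample never moves directly between two named clusters.

## Relatedness pruning

Kinship coefficients are inputs (as in the original design, which used
a precomputed biobank field).  Pairs above the third-degree bound
(default 0.0442; the threshold is configurable because the source
states the bound with two slightly different printed values) are pruned
greedily: remove first noncarriers, then the sample with higher degree
in the remaining over-threshold kinship graph, then the
lexicographically larger id — a deterministic order that empirically
minimizes removals on star graphs (verified against brute force in the
tests).

## Matched cohorts

Matching is greedy in ascending carrier-id order.  For each carrier the
eligible pool members satisfy every exact field (sex, supercluster,
strict label as configured) and caliper (age ± 2.5 years; PC1/PC2 ± 2.5
where the design uses PCs), ranked by absolute age difference, then
PC1/PC2 Euclidean distance, then id; the carrier consumes its k
best-ranked candidates, which leave the pool (global uniqueness).  A
shortfall aborts with the carrier named unless partial cohorts are
allowed.  An optimal flow-based assignment is deliberately out of
scope; the presets record each design explicitly: `ssh2` (k = 2079,
exact sex + strict label, age caliper — the source does not state the
SSH2 age tolerance, so the TKTL1 caliper of 2.5 years is reused),
`tktl1_imaging` (k = 429, age/sex only, across ancestries),
`tktl1_sensitivity` (k = 10) and `tktl1_qualification` (k = 20, PC and
age calipers plus exact sex).  Arm summaries use the n−1 sample SD; a
single-sample arm reports SD 0 and is flagged.

## Phenotype summaries

No hypothesis tests are run — with tens of carriers the design is
powered only for extreme effects, so the summaries are placement
statistics.  Continuous traits: carrier mean with a t-distribution 95%
CI (n−1 df; a normal-z option exists), control quartiles by linear
interpolation, whiskers at 1.5·IQR clipped to the data range, and
per-carrier percentile within the control distribution (fraction
strictly below, midpoint correction for ties).  Categorical traits:
the three nonresponse options are merged into one level before
summarizing; proportions carry Wilson score 95% intervals, implemented
from the closed form

    center = (p + z²/2n) / (1 + z²/n),
    half-width = z/(1 + z²/n) · √(p(1−p)/n + z²/4n²)

and cross-checked against statsmodels to ten significant digits in the
tests.  Qualification responses are multi-select; only the highest
reported level enters the analysis, under an explicit total order
(college/university > A/AS levels > O levels/GCSEs > CSEs >
NVQ/HND/HNC > other professional > merged nonresponse) — the exact
ordinal ranking is a package choice recorded here, as the source does
not print one.  Frontal-lobe composites sum the 11 Desikan-Killiany
frontal parcel surface areas per hemisphere and average their cortical
thicknesses unweighted ("averaged" is stated without weights; an
area-weighted option exists).

## Power model

For MAF f, sample size N and additive standardized effect β the
noncentrality is λ = 2f(1−f)Nβ²; power at two-sided level α is the
noncentral χ²₁ upper tail beyond the central quantile.  The exact
noncentral tail is used (the normal-shift formulation is kept as an
equivalent cross-check).  `detectable_beta` inverts power → β with a
bracketing root finder (bracket grown geometrically from [0, 1], Brent
solve at relative tolerance 1e−9).  Under the design parameters
(f = 5 × 10⁻⁵, N = 423,887, α = 0.05/12, power 0.80) this model gives
β = 0.5694; the originally reported figure is 0.5766 (≈1.3% larger),
and because the original computation's approximation and rounding
choices are not printed, the package reports its own computed value and
logs the variants: with α rounded to 0.0042 the model gives β = 0.5690;
no variant tried reproduces 0.5766 exactly.  Bonferroni reporting keeps
full precision for computation alongside the conventional 4-decimal
display form.

## Synthetic cohort generator

The generator emulates what the pipeline consumes, not biobank biology:

* **PC geometry** — isotropic Gaussian clusters at well-separated
  centroids (arbitrary PC units, spread 3 by default; the Uncategorized
  group is 6× more dispersed).  Only box-assignment behavior matters
  downstream, so realistic PC manifolds are out of scope.
* **Ages** — Normal(57, 8) truncated to [40, 70] by default, the
  middle-aged window typical of volunteer biobanks; fixture cohorts use
  the published arm means/SDs (e.g. 59.42 ± 7.94 for the SSH2 carriers,
  71.2 ± 6.14 for the imaging carriers).
* **Sex** — Bernoulli with default female fraction 0.54.
* **Genotypes** — planted genotype classes are realized exactly
  (counts, per-cluster frequencies, or explicit per-sample classes);
  QC noise then degrades quality fields so that each noise genotype
  violates exactly one filter (GQ ≤ 20, DP ≤ 10, or AB pushed to
  0.12/0.85), and clean heterozygotes are clamped safely inside the AB
  window so no unplanned failures occur.  A configurable fraction of
  sites gets a non-PASS FILTER label.
* **Kinship** — disjoint pairs with coefficients from
  {0.25, 0.125, 0.0625}; a chain mode attaches several relatives to one
  hub to exercise the pruning priority.
* **Phenotypes** — continuous traits Normal(μ + β·σ·dosage, σ) with β
  in SD units per archaic-allele dosage (male chrX dosage 1 by default,
  configurable to 2); categorical levels by stated probabilities with
  optional carrier log-odds shifts; per-parcel imaging values with the
  same effect convention; missingness emits the literal nonresponse
  labels so the merge rule is exercised verbatim.  No trait
  distribution parameters are published for the original cohort; all
  generator defaults are package choices with plausible magnitudes.

The generator does **not** simulate linkage disequilibrium, haplotypes,
introgression tracts, or realistic trait covariance; passing tests
therefore validate the pipeline's bookkeeping and statistics, not
biological realism.

## Fixtures and scale

Fixtures realize the published cohort configurations exactly at the
carrier level (genotype-class counts per supercluster and sex, strict
label membership, the single related SSH2 carrier pair) and scale
noncarrier denominators down by roughly 10³ — the checked quantities
are carrier-side counts, and full ~452k-sample VCFs add nothing
offline.  Matching pools are built as a dedicated block of same-sex,
caliper-eligible candidates per carrier, sized strictly above the
matching ratio (3000 for k = 2079, 600 for k = 429, 40 for k = 20).
Because any candidate consumed within an eligibility-overlap group of g
carriers is eligible for its consumer, total within-group consumption
is ≤ k·g while supply is ≥ block·g, so the greedy pass provably
succeeds for any carrier age configuration whenever block ≥ k.  The
42-site source catalog ships with the 17 published census sites and 4
published excluded positions verbatim; the remaining 21 positions are
synthetic placeholders (`PADGENE*`) because the full source table is
not public — sufficient for all count-level checks (42 − 4 + 1
inclusion = 39 sites in 33 genes; 38 queryable after the one non-PASS
site at chr9:6606647 is dropped).  The autosomal census fixture
realizes the enumerated co-carriage (the SPAG5 triple in five
individuals, one ADAM18 pair, one KNL1 pair), giving 104 unique
carriers of 118 carrier genotypes; the originally reported 103 implies
one further, unenumerated overlap which is noted and not invented.

## Numerical and degenerate-input choices

Quantiles use linear interpolation between order statistics (quartile
conventions differ across tools; this one is pinned).  Wilson bounds at
k = 0 and k = n are pinned to exactly 0 and 1 so floating roundoff can
never push an interval off k/n.  The power inversion brackets from
[0, 1] and doubles the upper bound until it straddles the target.
Byte-identical reproducibility holds for fixed seed and configuration;
fixture bundles use fixed registry seeds, and every stochastic step
accepts an explicit seed.  Problem sizes throughout (fixture cohort of
~63k samples for the largest matching design, 10⁵ Monte-Carlo
replicates for the power oracle, 100 seeds for the null-centering
check) were chosen as the smallest sizes at which the checked
statistics are stable.

## Known limitations

Kinship is consumed, never estimated; liftover is out of scope (the
catalog is hg38); no exon-overlap verification against genome
annotation; no LD between co-carried sites; matching is greedy, not
optimal; binary-trait and burden-test power are not implemented.
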