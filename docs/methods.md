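# Methods

`ssrkit` implements the statistical workflow used to characterize clonally
propagated germplasm collections fingerprinted with SSR (microsatellite)
markers: per-locus diversity and identity statistics, clone and
synonym/homonym detection, polyploid classification, hierarchical and
Bayesian-admixture grouping, F-statistics and AMOVA, likelihood-ratio
parentage analysis, and an allele–trait association screen.  This note
records the models, conventions and numerical choices behind each module,
and what the synthetic-data validation does and does not demonstrate.

## Genotype model

An SSR genotype is the *set* of distinct allele fragment sizes (integer
base pairs) observed per accession and locus, with cardinality 0 (missing)
to 4.  Dosage is deliberately not modelled: fragment analysis reports
presence of a size, not copy number, so a diploid singleton is interpreted
as homozygous and a three-allele call as evidence of polyploidy.  Allele
identity is exact integer size — no binning, which is assumed done upstream
during peak scoring.  Missing data is an empty cell in the tidy CSV dialect
and `-9` in the STRUCTURE-format export.  Declared ploidy travels in a
`#!ploidy` structured comment so that the genotype CSV stays within its
six-column dialect while `read(write(t)) == t` holds exactly.

## Diversity and identity statistics

Allele frequencies weight each individual's distinct alleles by presence:
diploids contribute two observations (singletons twice), an individual
with k ≥ 3 distinct alleles contributes one observation per allele.  This
is a documented convention for mixed-ploidy tables; under unknown dosage
no unbiased weighting exists.

Per locus: Na (allele count), Ne = 1/Σp², RA = 100·#{p < 0.01}/Na,
He = 1 − Σp² (plain Nei gene diversity, no small-sample correction — the
identity formulas below are written in plain pᵢ, and mixing corrected and
uncorrected moments would break the exact relationships the tests verify),
Ho = fraction of typed individuals with ≥ 2 distinct alleles,
F = 1 − Ho/He (reported as NaN for monomorphic loci), and

    PIC     = 1 − Σpᵢ² − (Σpᵢ²)² + Σpᵢ⁴
    P_ID    = Σpᵢ⁴ + Σ_{i<j} (2pᵢpⱼ)²
    P_IDsib = 0.25 + 0.5Σpᵢ² + 0.5(Σpᵢ²)² − 0.25Σpᵢ⁴
    PD      = 1 − P_ID

P_ID is verified in the test suite against a brute-force enumeration of
genotype-pair collision probabilities under Hardy–Weinberg, and P_IDsib
against a full parent-pair/offspring-pair enumeration, both to 1e-12.
Multilocus P_ID values multiply across loci (the panel loci sit on
different linkage groups and are treated as independent).

Hardy–Weinberg equilibrium is tested on the diploid subset only (polyploid
dosage is unknown) with a seeded Monte-Carlo exact test: allele copies are
permuted into genotype pairs and the conditional probability of each
permuted genotype array given the allele counts is compared with the
observed one; `p = (hits + 1)/(n_mc + 1)`.

The null-allele screen is a deliberate simplification of the usual
desktop tooling: the heterozygote-deficit estimator r̂ = (He − Ho)/(1 + He)
with a bootstrap over individuals (default 1000 resamples) and a 95%
percentile interval; a locus is flagged when the interval excludes zero on
the deficit side.  It detects the dominant signature of null alleles but
does not separate them from dropout or stuttering.

## Clone detection, naming, ploidy

Two accessions are clones when their allele sets agree at every locus
non-missing in both and at least `min_compared_loci` (default 15) loci
could be compared; groups are transitive closures, and identical pairs
with fewer compared loci are listed as *potential* matches rather than
merged.  Within a group, same normalized name → duplicate; two known
names → synonym; a UA (unknown) member matching a known one is identified
by it.  Across groups, one name on ≥ 2 distinct profiles is a homonym.
Name normalization (case-fold, strip numeric and collection-code prefixes)
is a convention of this package; curators match names manually in
practice.  Deduplication keeps one representative per group, preferring
known-status members and breaking ties by smallest accession id.

Polyploid calls use the third-allele rule: an accession is called P when
it shows ≥ 3 distinct alleles at ≥ 3 loci (default); isolated third
alleles are treated as artifacts.

## Ward clustering

Clustering operates on the 0/1 allele-presence matrix with Euclidean
distances and Ward's minimum-variance linkage, implemented via the
Lance–Williams update on squared distances with heights reported as
√(merge cost) — the Ward.D2 convention, matching `scipy`'s `linkage`
heights on tie-free data (verified in tests).  The implementation is
in-package because presence/absence data of collections with clones
produce exactly tied merge costs, and the contract requires the member
set at every node to be invariant under input row order: ties are broken
by the lexicographically smallest merged member-id tuple.  Node support
is the recurrence frequency of the exact member set over column-bootstrap
replicates (allele presence characters resampled with replacement).

## Admixture model

The Bayesian clustering model is the standard admixture model: K clusters
with cluster-specific allele frequencies in HWE, per-individual membership
vectors q with a symmetric Dirichlet(α) prior, and latent origins per
allele copy, sampled by Gibbs.  α has a uniform prior on (0, 10] with a
Metropolis random-walk step of 0.05.  The correlated-frequency option
draws cluster frequencies around the sample-wide frequencies with one
drift parameter per cluster (uniform prior, Metropolis step 0.02); the
independent model (Dirichlet(1) prior) is the default for tests because it
mixes faster on well-separated data.

Polyploids are handled presence-only: observed distinct alleles enter as
copies and, for declared triploids with fewer than three distinct alleles
at a locus, the unobserved slot is imputed each sweep from the observed
set proportional to current cluster frequencies.  This is an approximation
of recessive-allele genotype handling, adequate for membership estimation
but not for dosage inference.

Chain-length defaults are desk-scale (burn-in 5 000, total 20 000 sweeps);
production runs of the external reference programs commonly use
300 000/500 000, which remain available through the parameters.  The
replicate experiments in the test-suite and acceptance script use shorter
chains (burn-in 200–300, total 700–1 200) at the problem sizes they
simulate (70–100 individuals, 15–19 loci); at those sizes the posterior
concentrates quickly and the recovery results in the tests are what those
settings demonstrate.

Model choice uses the Evanno statistic ΔK = |L(K+1) − 2L(K) + L(K−1)| /
sd(L(K)) over replicate runs, defined for interior K with positive sd;
a flat or boundary-peaked profile returns no best K rather than guessing.
Assignment uses the argmax membership with an inclusive threshold
q_I ≥ 0.80; below it an individual is labelled admixed.

## F-statistics and AMOVA

F_IS and F_ST are Weir–Cockerham variance-component estimators, computed
per allele, summed within and then across loci; standard errors come from
a delete-one jackknife over loci.  Significance: F_ST by permuting
individuals among groups, F_IS by permuting allele copies among
individuals within groups, `p = (b + 1)/(n_perm + 1)` with a default of
999 permutations.  The estimator assumes diploidy, so calls with ≥ 3
alleles are reduced to two alleles sampled without replacement under the
run seed; AMOVA on the binary encoding is the ploidy-agnostic companion.
AMOVA partitions squared-Euclidean distances among/within groups; negative
variance components are truncated at zero for percentage reporting and
kept signed in the raw output.

## Parentage

Single-parent LOD scores: per locus, the ratio of the Mendelian
single-parent transition probability to the HWE genotype probability,
mixed with the random-genotype likelihood at mistyping rate ε,

    r = [(1 − ε)·T(g_o|g_p) + ε·P(g_o)] / P(g_o),

summed as log10 over mutually typed diploid loci.  With ε = 0 an
incompatible locus is an exclusion (LOD = −∞).  The decision threshold is
calibrated by simulating true parent–offspring and unrelated pairs from
the panel frequencies (default 100 000 each, ε = 0.001) and taking the
equal-error point of the two empirical LOD distributions; when an interval
of scores attains the minimum error gap the midpoint is used, which is
where the two densities cross.  The calibrated value is panel-dependent —
more polymorphic panels separate the distributions further — so the
distribution summaries are exported for users who want a different
operating point.  Parent-pair (trio) likelihoods and pedigree
reconstruction are out of scope.  Polyploid candidates are never mixed
into diploid LOD lists: they are screened by shared-locus fraction
against a simulated unrelated null and flagged.

## Trait association

Every (locus, allele) presence column is correlated with every ordinal
trait by Spearman rank correlation (midranks for ties,
pairwise-complete).  P-values use the t approximation, switching to a
seeded Monte-Carlo permutation test below n = 30.  Screening follows the
raw-p convention at α = 0.001; Benjamini–Hochberg adjustment is available
because a full panel × trait family is large (≈ 280 alleles × 6 traits).
Ordinal scores are treated as numeric ranks, which is what Spearman
consumes.

## Synthetic collections

The generator emulates the structure the analyses assume, with defaults
matching the collection the package is modelled on: 19 loci with 5–26
alleles each, ~20% triploids, and subpopulations differentiated at
F_ST ≈ 0.15.  Ancestral frequencies are symmetric-Dirichlet; subpopulation
frequencies are Balding–Nichols (Dirichlet around the ancestral vector
parameterized directly by F_ST — chosen because the differentiation level
is the quantity the downstream estimators must recover).  Founders are
HWE diploids within subpopulations; triploids arise from an unreduced
two-allele gamete plus a normal gamete (the common cytology of triploid
apples — any three-allele mechanism would serve the tests equally);
clones are exact copies made before error injection; offspring are
Mendelian crosses of named diploid founders; mistyping replaces a random
allele with a random panel allele; missingness blanks whole calls.  Trait
scores are equal-probability bins of a latent standard normal plus
(effect × allele presence), so planted effects move individuals
monotonically across categories with known sign.

What the generator does **not** emulate: linkage between loci, mutation,
genealogical (coalescent) structure within subpopulations, allele-size
homoplasy, and scoring artifacts other than uniform random mistyping.
Passing recovery tests therefore demonstrates correctness of the
estimators under their own assumptions, not robustness to the correlated
errors of real fragment data.

Every random quantity flows from an explicit seed; identical configs give
byte-identical outputs.

## Validation problem sizes

The test suite and `scripts/acceptance.py` run at sizes chosen to make the
Monte-Carlo checks stable: collections of 75–175 accessions, 10–19 loci,
5 replicate chains per K for ΔK over 10 independent experiments, 5
replicate collections for F_ST recovery, 20 offspring for parentage
recovery with a 100 000-pair threshold calibration, and 10 replicate
collections (~5 500 null tests) for the trait-screen size check.  These
reproduce the qualitative and quantitative behaviour of the full-scale
analysis; larger collections sharpen the same estimates.

## Known limitations

- Frequency weighting for polyploids (one observation per distinct
  allele) can bias He slightly relative to dosage-aware estimators.
- The null-allele screen shares the heterozygote-deficit signal with
  inbreeding and population structure; flags on structured collections
  should be read as "deficit", not proof of nulls.
- The Weir–Cockerham route subsamples polyploid calls to two alleles;
  with many polyploids, prefer the AMOVA route.
- The LOD threshold is an equal-error point, not a posterior odds bound;
  users needing a specific false-positive rate should pick the operating
  point from the exported distribution summaries.
- ΔK cannot evaluate K = 1 and inherits the usual sensitivity of the
  statistic to the K-range simulated.
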