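# Methods

`kbagen` quantifies the *distinct genetic diversity* of candidate Key
Biodiversity Areas (KBAs): the share of a species' genetic variation that a
site encompasses, the quantity the IUCN KBA criteria A1b (> 1% of the global
total) and B1 (> 10%) are applied to.  Because "distinct genetic diversity"
mixes two concepts — within-area *diversity* and between-area
*distinctiveness* — the toolkit computes six per-area metrics spanning both,
applies the KBA criteria to each, and quantifies how the metrics agree.

All metrics operate on allele frequencies (not heterozygosity-based
F-statistics), computed from an allele-dosage tensor
(individual × locus × allele).  Dosages represent unphased diploid genotypes
and remain valid after fractional mean imputation.

## Data preparation

Uniform pipeline, in order: (1) drop areas with fewer than 30 individuals
(small samples produce negative or unrealistically low LD-N_e estimates);
(2) drop individuals with strictly more than 20% missing loci (missingness
inflates N_e); (3) replace each remaining missing genotype with the mean
observed allele dosage at that locus **pooled over the whole dataset**, not
per area.  Pooled imputation biases area frequencies slightly toward the
global mean; it is the pipeline's documented convention and the reason the
LD-N_e estimator defaults to the *unimputed* (filtered) genotypes —
fractional imputed dosages attenuate the disequilibrium signal.  Both
thresholds are strict inequalities.  By default the area-size filter is not
re-applied after individual removal (`strict_recheck` enables that; with it
the pipeline is idempotent).

## The six metrics

**Δ+ (average taxonomic distinctness of alleles).**
Δ+ = Σ_{i<j} ω_ij / C(m, 2) over the m alleles *present* (frequency >
`presence_threshold`, default 0) in an area, with pair weight ω from a
two-level hierarchy (allele → locus → genome).  Presence/absence only, so
Δ+ is exactly invariant under sample duplication.  The weight orientation is
a genuine design choice:

- Classic taxonomic orientation (`HierarchyWeights(1, 2)`, the `avtd()`
  default): deeper-level pairs are more distant.  On genotype data this
  makes Δ+ *decrease* as loci gain alleles — every extra allele adds short
  within-locus pairs diluting the fixed cross-locus distance — so Δ+
  anti-tracks allelic richness.
- Allelic orientation (`ALLELIC_WEIGHTS = HierarchyWeights(2, 1)`, the
  pipeline default): two alleles of one locus — a true segregating
  polymorphism — are the most distinct pair, alleles of different loci
  (which co-occur in every genome and represent no variation) the least.
  Under this orientation Δ+ grows with within-locus polymorphism and tracks
  rarefied allelic richness strongly and positively (Kendall τ ≈ +0.9 on
  island-model panels), which is the published behaviour of Δ+ as a KBA
  metric and what makes it capture diversity and distinctiveness at once.

An optional `standardize_to=100` rescales weights as in classic AvTD.  A
presence threshold of 1/(2n) is recommended on imputed data to suppress
trace presences introduced by fractional imputation.

**Allelic overlap.**  Czekanowski (1 − ½ Σ|p_A − p_B|) or Pianka
(Σ p_A p_B / √(Σ p_A² Σ p_B²)) similarity per shared locus, averaged over
loci; per-area score = mean over all partner areas; in [0, 1]; low = distinct.

**Jost's D_est.**  Per locus, with s = 2 areas and ñ the harmonic mean
individual count: H_S,obs = 1 − ½ Σ_j Σ_a p_ja²; H_T,obs = 1 − Σ_a p̄_a²
(unweighted mean frequencies); Ĥ_S = (2ñ/(2ñ−1)) H_S,obs;
Ĥ_T = H_T,obs + Ĥ_S/(2ñs); D = s/(s−1) · (Ĥ_T − Ĥ_S)/(1 − Ĥ_S).
Multi-locus value: arithmetic mean over loci polymorphic in the pooled pair
(Jost's harmonic-mean variant is available).  Negative per-locus estimates
are retained.  Note the estimator is unbiased over *independent* samples
from one population; evaluated at literally identical samples it returns a
small negative O(1/ñ) value, not exactly 0.  Per-area score = mean over
partners; approximately invariant under sample duplication (drift ≲ 0.01
absolute).

**Pairwise AMOVA.**  Individual distance d²(i,j) = ¼ Σ_l Σ_a (c_ia − c_ja)²
on dosages (0 / 0.5 / 2 per locus for shared het / one-allele / disjoint
homozygote differences).  SS_total = (1/N) Σ_{i<j} d², SS_within likewise per
group, SS_among by subtraction (computed via the centroid identity and
verified against the O(N²) distance-matrix form).  σ²_w = MS_within,
σ²_a = (MS_among − MS_within)/n0 with n0 = (N − Σ N_g²/N)/(s−1), and
Φ_ST = σ²_a/(σ²_a + σ²_w).  The per-area statistic (default σ²_a; Φ_ST and
SS_among available) is the mean over pairwise analyses with every other
area.  SS_among scales directly with sample size — duplicating every
individual doubles it while D_est and Δ+ move < 1% — which is why raw AMOVA
output is a poor prioritisation score.

**λ_cor (sample-size-corrected Simpson diversity).**  Per locus, on
integer-rounded counts, λ_unb = Σ n_a(n_a−1)/[N(N−1)]; reported as diversity
1 − λ_unb averaged over loci so it is oriented like N_e (higher = more
diverse).  Its weakness: it saturates toward 1, so the gain per tenfold N_e
increase collapses at high diversity and areas become indistinguishable.

**N_e (LD method).**  For every unordered locus pair and allele pair with
within-area frequencies strictly inside (pcrit, 1 − pcrit) (default
pcrit = 0.02), on the S individuals complete at both loci: Burrows'
composite disequilibrium Δ̂ = cov(x, y)/2 with the S/(S−1) covariance,
r̂² = Δ̂²/[p(1−p)q(1−q)].  The unweighted mean r̂² (the original LDNe
weighting scheme is deliberately not reproduced) minus the sampling
expectation (1/S + 3.19/S² for S ≥ 30; 0.0018 + 0.907/S + 4.44/S² below)
gives r²′, inverted by the random-mating bias-corrected formula
N̂e = [1/3 + √(1/9 − 2.76 r²′)]/(2 r²′) (constants 0.308/2.08 for S < 30).
Conventions: r²′ ≤ 0 → +∞ (no drift signal above sampling noise); when the
discriminant is negative the analytic continuation
[c − √(b r²′ − c²)]/(2 r²′) is returned — continuous at the boundary,
strictly decreasing through zero into negative values — so the pipeline
sees the literal negative estimates this method is known to produce.  The
estimate distribution over replicates is right-skewed.

**Rarefied allelic richness** (comparison covariate):
AR = Σ_a [1 − C(n−n_a, g)/C(n, g)] per locus, averaged; g defaults to the
smallest per-(area, locus) gene-copy total; counts are integer-rounded only
inside the binomial coefficients.

## KBA criteria

Per metric: areas without an estimate (NaN; ±∞ by default, or capped at the
maximum finite value under the alternative policy) receive the median of
the remaining areas; if any value is ≤ 0, the smallest natural number k
making all values strictly positive is added (k is recorded — the shift
distorts ratios, a caveat that matters most for N_e); proportions
p_i = v_i/Σv are tested with strict inequalities against A1b (> 0.01) and
B1 (> 0.10).  Strict thresholds bound the flag counts: at most 9 B1 and 99
A1b flags.  Every adjustment is logged in the assessment for audit.

## Metric comparison

Kendall's τ_b between per-area metric vectors, pairwise-complete (sample
sizes differ per pair when N_e is unavailable for some areas).  P-values:
exact permutation for n ≤ 10 without ties, otherwise a normal approximation
with continuity correction and the Kendall–Gibbons tie-adjusted variance.
Optional per-metric outlier removal beyond 1.5 × IQR Tukey fences with
type-7 (linear interpolation) quartiles.  Comparisons should pool areas only
across datasets of a common design/scale: pooling heterogeneous datasets
mixes per-dataset level shifts and can flip the sign of pooled rank
correlations even when every within-dataset correlation agrees.

On island-model panels whose areas differ in N_e and isolation, the
comparison reproduces the expected sign structure: distinctiveness metrics
(AMOVA, D_est) correlate negatively with diversity (λ_cor) and positively
with each other; Δ+ (allelic orientation) correlates strongly positively
with allelic richness.

## Simulator

Individual-based Wright–Fisher island model: each area holds a gene-copy
matrix (N_e diploids × loci × 2); each generation every offspring draws two
parents (own area with probability 1 − m, otherwise from the migrant pool —
uniform over areas, or weighted by an explicit matrix for stepping-stone /
clustered structure) and one allele per locus from each parent (free
recombination).  Mutation: symmetric flip for SNPs, stepwise ±1 for
microsatellites.  The scheme's expected frequency update is the classic
island-model mixing p′ = (1 − m) p + m p̄, and shared parentage generates
the between-locus association E[r²] ≈ 1/(3N_e) that the LD estimator
measures — a frequency-only resampling scheme would leave unlinked loci
independent and carry no N_e signal, which is why the simulator is
individual-based.  Calibration checks: drift is unbiased in frequency;
heterozygosity decays as H_0(1 − 1/(2N_e))^t; full migration drives
pairwise D_est below 0.02.

What the simulator does not emulate: linkage maps (all loci unlinked),
selection, uneven sampling within areas, genotyping error, null alleles,
and isolation-by-distance beyond what the migration matrix encodes.
Passing tests therefore demonstrate estimator correctness under neutral
random-mating structure, not robustness to real-data artefacts.

Founders: SNP frequencies uniform on (0.1, 0.9) per locus; microsatellites
a Dirichlet-weighted ladder of `n_founder_alleles` (default 6) integer
repeat sizes around 20.  A single integer seed drives all randomness.

The benchmark panel (SNP and microsatellite variants of panmictic /
one-divergent-area / N_e-gradient / two-cluster designs) uses ≥ 30 sampled
individuals per area so it passes the preparation filters, with 100 SNP or
30 microsatellite loci and 60–200 generations — the same order as typical
published datasets, sized for fast simulation.

## Numerical choices and edge cases

- Diploid dosage sums are enforced to 2 within 1e-9; missing genotypes are
  all-zero rows behind a boolean mask.
- Δ+ with fewer than 2 present alleles, and D_est with no shared
  polymorphic locus, return NaN (logged), never silent zeros; downstream
  KBA handling treats NaN as missing.
- Rarefaction requires g ≥ 2 and g ≤ n; binomial coefficients are evaluated
  in log-gamma space.
- LD-N_e uses pairwise-complete genotypes; a locus pair needs S ≥ 2; zero
  eligible comparisons raise an error naming pcrit.
- The λ-vs-Δ+ "plateau" contrast is meaningful only as saturation (the λ
  gain per decade of N_e collapses near 1): absolute spreads of the two
  metrics are not comparable, because a two-level-hierarchy Δ+ is confined
  to an interval of width (weight gap) · O(1/n_loci).
- Relative (percent) sample-size-stability checks for D_est are performed on
  strongly differentiated fixtures; near zero the estimator's O(1/ñ)
  absolute drift dominates any relative comparison.

## Known limitations

Two-level AMOVA only (no region/population nesting); no bootstrap or
jackknife intervals for D_est or N_e; no temporal-method N_e; the LDNe
comparison-weighting scheme is not reproduced; Genepop files do not carry
individual ids (the writer labels rows by area, the common locality-label
layout, and ids are regenerated on read).
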