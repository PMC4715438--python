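# Methods

This note documents the models behind each module, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the numerical decisions a maintainer would want written down.

## Sequence statistics (`seqstats`)

**Site handling.** All statistics default to *complete deletion*: any
alignment column containing a gap or IUPAC ambiguity code is removed before
anything is computed (`gap_policy="pairwise"` keeps columns and masks them
per pair). The retained length is the denominator for π.

**Diversity.** H and haplotype counts come from exact string identity on
retained sites, in first-occurrence order (deterministic). h uses the
unbiased estimator n(1 − Σp̂ᵢ²)/(n − 1); π is the mean pairwise difference
per site over all n(n−1)/2 pairs and is checked against an all-pairs
brute-force oracle in the tests.

**Tajima's D** uses the standard a₁…e₂ constants. Its p-value is obtained
by simulating neutral coalescent genealogies *conditioned on (n, S)*:
S mutations are placed multinomially on branches in proportion to branch
length (Hudson's fixed-S scheme), the statistic is recomputed, and a
two-tailed p is taken as 2·min(P(D* ≤ D), P(D* ≥ D)). A published "1000
permutations" convention for these tests is read as 1000 simulated
replicates, which is what the classic software actually does.

**Fu's Fs** is computed exactly: S′ = P(K ≥ k_obs | θ̂, n) under the Ewens
sampling distribution with θ̂ = mean pairwise differences per locus, using
unsigned Stirling numbers of the first kind accumulated entirely in log
space (numerically safe to n in the hundreds), and Fs = ln(S′/(1 − S′)).
The test suite verifies the tail against two independent routes: the
Chinese-restaurant-process recursion and full set-partition enumeration at
n ≤ 7. The p-value simulates genealogies at θ̂, counts distinct haplotypes
as distinct sets of mutated branches (infinite sites), and reports
P(Fs* ≤ Fs), the conventional lower tail.

**Sudden-expansion fit.** The model for the probability that a random pair
differs at j sites after a stepwise size change θ₀ → θ₁ at τ mutational
units ago has the closed form

    F_j = G_j(θ₁) + e^{−τ/θ₁} Σ_{i≤j} Pois(i; τ)·[G_{j−i}(θ₀) − G_{j−i}(θ₁)]

where G_j(θ) = θʲ/(1+θ)^{j+1} is the geometric equilibrium. This follows
from the exponential-mixture representation of the pairwise coalescent and
needs no numerical integration; `theta1=None` selects the infinite-growth
Poisson limit. Fitting minimises the SSD between observed and model
frequencies over k = 0..k_max by a coarse grid (τ × θ₀ × θ₁) followed by
Nelder–Mead on (τ, θ₀, θ₁−θ₀) with bounds τ ∈ [0, 2·k_max], 0 ≤ θ₀ ≤ θ₁ ≤
10⁴ enforced by projection. Harpending's raggedness is Σ(x_{k+1} − x_k)²
on normalised frequencies.

**Parametric bootstrap.** Replicates simulate a genealogy under the fitted
two-epoch model directly in mutational time (pair coalescence rate 1/θ per
epoch, mutation rate ½ per lineage per unit), rebuild the spectrum, refit,
and compare the replicate SSD (against its own refit) and raggedness with
the observed values; p is the fraction ≥ observed. The production default
is 9000 replicates; test studies use 100–200 and say so.

**Identifiability caveat.** In the mismatch distribution only τ + θ₀ is
strongly identified at realistic sample sizes; when θ₀ is sizeable the
least-squares fit tends to push θ₀ toward 0 and let τ̂ absorb it. The
parameter-recovery study therefore uses a pronounced expansion
(τ = 3, θ₀ = 0.5, θ₁ = 50 — a hundredfold growth, the regime these fits
are used for in practice); with θ₀ ≈ τ/3 or larger, expect τ̂ biased high
by roughly θ₀.

## Haplotype networks (`hapnet`)

The minimum spanning network is the union of all minimum spanning trees,
built from the bottleneck (minimax-path) characterisation: an edge belongs
to some MST iff its weight equals the bottleneck distance between its
endpoints; the ε-relaxed variant admits edges up to bottleneck + ε
(default ε = 0). Median joining iterates: build the ε-MSN over the current
node set; form quasi-medians (per-site majority; three-way ties take the
lexicographically smallest state) for mutually connected triplets; add the
candidate that most reduces the MST cost of the node set, ties broken
lexicographically; prune median vectors of degree ≤ 1; repeat to a fixed
point. The spanning cost is integer and strictly decreases on insertion,
so termination is guaranteed and the output is deterministic — the
order-dependence of the classic desktop program is deliberately not
emulated. Binary (0/1) encodings are accepted alongside nucleotides.

## Demographic conversions (`demography`)

* T = a + s/(1 − s); default age at maturity a = 2 y. (A published verbal
  description of maturity "one year after hatching" conflicts with the
  generation-time range that same source reports, which requires a = 2;
  the package follows the arithmetic.)
* t = B/U with U = u × locus length (per year); Nₑ = q/(c·U·T) with the
  inheritance scalar c defaulting to 4 (the q = 4Nₑμ convention; c = 2
  selectable for strict maternal haploid accounting — the convention is
  configurable precisely because sources rarely state it).
* `rescale_ne` re-expresses sizes across generation-time assumptions as
  N·T_old/T_new, rounding half away from zero to the input's precision.
  Cross-checking a published size table this way reproduces most printed
  integers exactly and all within ±1 — the residual unit is rounding noise
  in the source's own printed columns, not a conversion discrepancy.
* `m_from_M` uses m = M·μ, because M is defined as m/μ; the literal
  "divide by μ" wording found in print would produce m > 1 and is kept
  only behind `paper_literal=True` with a warning. Correlation-based
  comparisons are invariant to the choice.
* The Mantel test correlates off-diagonal cells and permutes row/column
  labels of the second matrix simultaneously — appropriate for asymmetric
  (directional) migration matrices, which is why the symmetric-distance
  implementations in existing libraries are not used. With k = 3 the six
  label permutations are enumerated exactly and flagged; the null is
  near-nominal for larger matrices (verified at 6×6 in the tests).

## Assignment post-processing (`clusterpost`)

ΔK(K) = mean_r |lnP_r(K+1) − 2 lnP_r(K) + lnP_r(K−1)| / sd_r(lnP(K)),
pairing replicates by id; defined only at interior K, with an explicit
error naming any K whose replicate spread is zero. Genotype PCA one-hot
encodes allele counts (one column per locus×allele, values 0/1/2),
mean-centres without scaling, imputes missing genotypes to the column mean
(so they sit at the centroid and cannot drive an axis; per-population mean
imputation is a documented alternative not implemented), and fixes signs
so each component's largest-magnitude loading is positive.

## Niche divergence (`nichetest`)

Variable pruning is a greedy scan in a user-supplied priority order
(mirroring "most temporally inclusive" choices, which are study-specific):
keep a variable iff |r| < 0.7 against everything already kept. Backgrounds
are delimited by convex hulls in plain longitude/latitude (no projection —
adequate at the spatial scales involved), sampled uniformly by rejection,
with climate attached by nearest-record lookup. The niche PCA is fitted on
pooled *background* points (they define available environmental space) with
unit-variance standardisation by default (bioclim units are
incommensurable); occurrences are projected onto those axes.

Per axis, D_occ = |mean occurrence score A − mean B| is compared with the
(α/2, 1 − α/2) empirical quantiles of the background divergence score over
1000 jackknife replicates, each resampling 75% of background points
*without* replacement ("75% replacement" read as subsampling; a
with-replacement bootstrap is available behind a flag). Divergence iff
D_occ exceeds the upper bound, conservatism iff below the lower, else none;
α = 0.05 two-sided.

**Operating regime.** The null describes the *background* score, whose
subsample-mean noise scales as √((1−f)/(f·n_bg)); D_occ carries its own
sampling noise √(2/n_occ). The test holds its nominal level only when
occurrence means are estimated at least as precisely as the subsampled
background means (roughly n_occ ≳ n_bg); with few occurrences against a
large background it over-calls divergence, a known property of the
background-similarity framework. The calibration study in the tests uses
1000 occurrences against 250 background points per group accordingly, and
false conservatism is not controlled by this design at all — only the
divergence call is calibrated.

Elevation differences use scipy's tie-corrected Kruskal–Wallis plus a
hand-rolled Dunn post-hoc (rank-sum z with tie correction, Bonferroni
adjusted) — no installed package provides Dunn's test.

## Colour index (`colourindex`)

The exact published per-character state scores are not reproduced in any
accessible source; the default scheme is constrained by what is known: ten
characters, additive integer scores, endpoints 0 and 24. Four primary
diagnostic characters (rufous patch on secondaries, rufous patch on
primaries, belly colour, tail colour) take four states scored 0–3 and six
auxiliary characters take three states scored 0–2 (4·3 + 6·2 = 24).
Intermediate states get intermediate integers; the scheme is fully
user-overridable, and every consumer takes it as a parameter.

## Synthetic data (`synthdata`)

* **Sequences** come from a built-in continuous-time structured coalescent
  (island model collapsing to one ancestral deme at the split time) with
  per-site Poisson mutations and symmetric base substitution. θ per site is
  the haploid 2Nμ, so panmictic E[π̂] equals it (verified within 20% over
  replicate loci, and the genealogy-length distribution is cross-checked
  against msprime, which serves only as a test oracle). An explicit
  `effective_size` (default 1000) anchors the per-generation inputs.
* **Microsatellites** use the Balding–Nichols construction: cluster allele
  frequencies are Dirichlet draws around a shared ancestral frequency with
  concentration (1 − F)/F, giving Weir–Cockerham F_ST within ±0.05 of the
  target at n ≥ 100 per cluster. The K-allele representation carries allele
  identity only — sufficient for every frequency-based consumer here, but
  it does not emulate a stepwise size ladder. Twelve loci by default;
  whole-locus missingness coded −9, STRUCTURE-style.
* **Landscapes** place groups in disjoint longitude bands with multivariate
  normal climate around per-group centroids (default spacing 1.5 SD on the
  leading axes: partially overlapping niches); occurrences are the same
  distribution displaced by `occupied_offset`, so offset 0 means the
  occupied niche equals the available background by construction. Defaults
  (100 occurrences, 1000 background candidates per group, elevations
  1375 ± 700 / 921 ± 526 / 542 ± 585 m) mirror the field setting the
  package emulates. There are no rasters and no spatial autocorrelation in
  climate — a green niche test establishes calibration of the statistics,
  not robustness to spatial structure.
* **Plumage** longitudes are evenly spaced so both cline endpoints are
  realised; expected per-character scores fall linearly from maximal west
  of the first barrier to zero east of the second, with Gaussian score
  noise rounded and clipped to each character's range.

All generators take explicit seeds, use no global random state, and are
byte-reproducible.

## What the generators do not emulate

Recombination, selection, mutation-rate heterogeneity, allele size
homoplasy, null alleles, georeferencing error, raster-based climate, and
spatial autocorrelation. Green tests therefore establish internal
correctness and statistical calibration of the implementations under their
stated models, not robustness to these real-data complications.

## Pipeline

Stages run in dependency order; pre-flight validation reports every
missing input at once; all seeds are explicit, and the JSON summary
excludes timings so identical configs produce byte-identical output.
Warnings (e.g. the literal M/μ mode) surface in the summary's warning
list and on stderr.
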