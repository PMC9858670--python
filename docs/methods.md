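# Methods

This note documents the statistical models behind `mitodiv`, the choices
made where conventions genuinely diverge, and what the synthetic-data tests
do and do not establish about real museum/modern sequence data.

## Data model and missing-data policies

Input is a multiple alignment of haploid mitochondrial sequences over
`{A, C, G, T, N, -}` plus an id → epoch table. Gaps are treated as missing
data, identically to `N`, everywhere: these are intraspecific mtDNA
alignments in which the indel-rich control region is excluded upstream
rather than modelled, so a residual `-` carries no phylogenetic signal we
trust. Coordinates in reports are 1-based alignment sites.

Museum-grade consensus sequences can be mostly `N` (read coverage in such
studies spans below 1× to above 100×), which forces explicit policy choices:

* **Haplotype collapsing.** `strict` treats `N` as a sixth state (two
  sequences share a haplotype only if byte-identical); `merge_compatible`
  merges sequences identical at all mutually observed sites, taking the
  site-wise consensus as representative. Compatibility is not transitive;
  an ambiguous sequence joins the *first-seen* compatible haplotype in
  input order, a deterministic tie-break recorded via the stable H1..HK
  numbering. `strict` never yields fewer haplotypes than
  `merge_compatible` (property-tested). Neither policy is claimed to
  replicate any particular legacy software's internal counting; published
  haplotype counts under heavy missing data are software-dependent (see
  "Known reproduction caveats").
* **Distances and segregating sites.** Defaults are pairwise deletion for
  distances and an any-two-non-missing rule for S, because complete
  deletion across a sample containing one 60%-missing sequence would
  collapse the usable length toward zero. Complete-deletion variants are
  available for clean data.
* **Completeness filter.** Sequences above a missing-fraction threshold
  (default 0.5 for short-fragment workflows) are excluded with their ids
  logged.

## Estimators

With haplotype counts c₁..c_K, n = Σcᵢ, p̂ᵢ = cᵢ/n:

* **Hd** = n(1 − Σp̂ᵢ²)/(n − 1); SD from Nei's estimator variance
  Var = 2/(n(n−1)) · {2(n−2)[Σp̂ᵢ³ − (Σp̂ᵢ²)²] + Σp̂ᵢ² − (Σp̂ᵢ²)²}.
* **Θ̂π** = mean pairwise difference count (per sequence); SD from
  Tajima's total variance (n+1)/(3(n−1))·θ + 2(n²+n+3)/(9n(n−1))·θ².
  Per-site π = Θ̂π/L_eff, where L_eff is the mean pairwise shared
  non-missing site count under pairwise deletion (matching the distances'
  implicit denominators) or the complete-site count under complete
  deletion.
* **Θ̂S** = S/a₁ with a₁ = Σ₁ⁿ⁻¹ 1/i; SD from
  Var = θ/a₁ + a₂θ²/a₁², a₂ = Σ₁ⁿ⁻¹ 1/i².
* **Θ̂K** solves K = Σᵢ₌₀ⁿ⁻¹ θ/(θ+i), a strictly increasing function of θ,
  by Brent root-finding on [10⁻¹⁰, 10⁶] (bracket expanded upward if
  needed; relative tolerance well below 10⁻⁸). K = 1 gives 0; K = n makes
  the likelihood unbounded and returns an explicit ∞ sentinel (or raises,
  per caller choice) — the CI upper bound is likewise ∞ there.
* **Θ̂K interval.** Equal-tail inversion of the exact distribution of the
  number of haplotypes under the Ewens sampling formula,
  P(K=k | θ, n) = |s(n,k)| θᵏ / (θ(θ+1)⋯(θ+n−1)): the lower bound solves
  P(K ≥ k_obs) = α/2 and the upper solves P(K ≤ k_obs) = α/2. Unsigned
  Stirling numbers |s(n,k)| come from the recurrence
  |s(n,k)| = |s(n−1,k−1)| + (n−1)|s(n−1,k)|, exact integers for small n
  (used in tests, including the generating-function identity
  Σₖ|s(n,k)|tᵏ = t⁽ⁿ⁾ over rationals) and a log-space recurrence for
  numerics, cached per n. Discreteness of K makes the interval
  conservative; measured coverage at n = 100, θ = 5 exceeds 95%.

## Rarefaction

Accumulation curves permute the individual order uniformly (without
replacement — classic interpolation rarefaction; no extrapolated richness)
and average the cumulative distinct-haplotype count. The reported spread is
the SD across permutations, matching the ribbon convention of the usual
accumulation-curve helpers, not SD/√B. The closed form
E[K_g] = Σ_h [1 − C(n−c_h, g)/C(n, g)] is used as an independent oracle;
agreement is asserted within 4 Monte-Carlo standard errors with a
rule-of-three floor of 3/B for cells whose empirical spread collapses to
zero.

## Permutation test

Two-sided test on |Δ| of Hd or per-site π, pooling both samples and
redrawing groups of the original sizes without replacement. Monte-Carlo
p-values use the (b+1)/(B+1) correction (never zero); when
C(n₁+n₂, n₁) ≤ 10⁵ and requested, all splits are enumerated and the exact
proportion reported. For π, the per-pair per-site difference matrix is
computed once on the pooled alignment; permutations only index into it
(O(n²) once, O(B·n²) total). A monomorphic pool degenerates to
Δ = 0, p = 1 with a warning. Calibration: under a shared-population null
(one ESF draw split into two samples — the construction under which group
labels are genuinely exchangeable) the measured type-I error at α = 0.05
is ≈ 0.03–0.05, slightly conservative due to ties in the discrete null.

## Networks

Distances are Hamming counts on sites observed in *all* haplotypes;
haplotypes rendered indistinguishable by that restriction are merged into a
single node (id `a+b`) so every edge weight stays ≥ 1. The
minimum-spanning network is Kruskal with equal-weight closure: at each
distance level, every inter-component pair at that distance is added before
components merge — the union of all MSTs. Median joining (ε = 0) iterates:
build the MSN; for triplets (u,v,w) with u–v an edge and w adjacent to
either, propose the site-wise majority median (ties among three distinct
states resolve to the lexicographically first node's state); add the
single median giving the largest reduction in MST weight (ties broken
lexicographically on sequence); repeat to fixpoint, guarded at 10·K
additions; finally prune unsampled medians of degree < 3 iteratively.
Node and edge ordering are lexicographic throughout, so GraphML/TSV output
is byte-stable. No TCS/statistical-parsimony variant and no ε > 0.

## Synthetic data: what it emulates, what it does not

* `sample_esf_partition` — Hoppe-urn draw of the Ewens sampling formula,
  the exact generative model inverted by Θ̂K (distribution of K verified by
  chi-square against exact probabilities at n = 8).
* `coalescent_infinite_sites` — Kingman genealogy (Exp(k(k−1)/2)
  coalescence times), Poisson(θ/2 × tree length) mutations on branches,
  each at a fresh site: E[S] = θa₁ and E[Θ̂π] = θ, both verified to within
  3 standard errors over thousands of replicates. A guard rejects
  E[S] > L/2, where the finite-L approximation to infinite sites degrades.
* `mask_missing` — per-individual uniform site masking, emulating
  low-coverage consensus calling. Real aDNA missingness is *not* uniform
  (coverage is autocorrelated along the molecule, and damage concentrates
  at fragment ends); the generator stresses the missing-data policies, not
  the spatial structure of degradation.
* `simulate_two_epoch` — one coalescent haplotype pool
  (n_historical + 60 extra lineages holding unsampled diversity), a
  historical sample, Wright–Fisher multinomial drift of the pool
  frequencies for G generations at size N_e, then a modern sample. The
  drift phase adds no new mutations: the inter-epoch interval (decades)
  is negligible on the mutational timescale of mtDNA. Defaults mirror the
  whole-mitogenome study regime: θ = 11.7 (≈ 41 segregating sites at
  n = 19), samples of 19 and 29, L = 15,460, historical missing fractions
  uniform on [0, 0.3], drift at N_e = 350 (the census number of breeding
  females/packs) for 12 generations (≈ 50 years at ~4-year generations).
  A short-fragment configuration (θ = 1.7, L = 425, n = 17/27) is
  provided by `control_region_config`. The simulator is a test harness
  with a plausible parameterization, not a fitted demographic model; no
  heterochronous coalescent, selection, recombination or migration.

One user seed fans out to per-stage child seeds via
`numpy.random.SeedSequence.spawn`, so each stage is independently
reproducible and recorded in outputs.

## Effective size

For a haploid maternally inherited locus, θ = 2N_ef·μ per site, so
N_ef(μ) = (θ/L)/(2μ); μ is per site per generation and the two interval
bounds give the high/low size pair (their ratio equals μ_high/μ_low
exactly before display rounding). Unrounded θ estimates should be piped
in: rounding Θ̂K to two decimals before conversion shifts N_ef by several
individuals. No generation-time modelling or census-to-effective ratios.

## Known reproduction caveats

Reproducing legacy-software output from printed tables exposes several
conventions that are not recoverable:

* A published per-sample Θ̂K of 10.05 at n = 19 is the Ewens MLE for
  K = 11, not for the reported 10 haplotypes (MLE 7.82): the source
  software's internal haplotype count under missing data evidently
  differed from the reported one. Both of this package's policies are
  provided; neither claims to replicate that internal counting.
* Published Θ̂K 95% brackets match none of the standard constructions
  (exact equal-tail on K, normal inversion of E[K] ± 1.96·SD(K), Wald,
  log-scale Wald, likelihood ratio); the equal-tail exact interval is
  implemented and property-tested instead of value-matched.
* Published Θ̂S dispersions run ~10% below the standard estimator-variance
  formula, and one published Hd SD differs from Nei's formula in the last
  digit; the standard formulas are implemented.
* One published Θ̂S value (6 segregating sites at n = 17 → 1.7748) sits at
  a rounding boundary and is printed as 1.78.
* Per-site π for partially missing data depends on the per-site
  normalization length, which legacy software does not document; this
  package defines L_eff explicitly (see Estimators).

## Problem sizes in the test suite

Simulation-backed checks run at sizes chosen to make Monte-Carlo error
small relative to the asserted tolerances while keeping the suite quick:
2000 coalescent replicates (n = 19, L = 500) for the E[S]/E[Θ̂π] checks,
10⁴ urn draws for the ESF goodness-of-fit, 500 null replicates × 199
permutations for test calibration, 200 replicates for drift and
CI-coverage checks. Alignment lengths in simulations are scaled to a few
hundred–thousand sites; every estimator here depends on L only through
per-site scaling, so the regime is set by θ and n.
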