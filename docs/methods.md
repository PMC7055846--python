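# Methods

## Problem setting

A regional species pool of unknown size S is sampled at n sites (traps).
The data are a site-by-species matrix of specimen counts (or, for some
groups, presence/absence only). The goal is a point estimate of S, and an
understanding of when each estimator can be trusted. All estimators here
assume a closed pool over the sampling period and exact species identity by
label; none model detection covariates.

## Estimators

### Chapman mark-recapture

With a pre-inventory checklist of `S_known` species, of which
`S_obs,known` reappear among the `S_obs` species caught,

    S_MR = (S_obs + 1)/(S_obs,known + 1) × (S_known + 1) − 1.

The add-one form is defined even with no prior knowledge and is less biased
than the plain Lincoln–Petersen ratio in small samples. Reported values are
rounded to the nearest integer (ties half-up); the raw point is retained on
the estimate object. The implicit assumption is that previously known
species are caught with the same probability as unknown ones — violated
if, say, taxonomists preferentially described common species, which makes
the estimator conservative.

### Classical non-parametric estimators

Conventions follow the vegan R package, which a cross-check test invokes as
an independent oracle:

* Chao1: `S_obs + F1(F1−1)/(2(F2+1))` (bias-corrected, default) or the
  classic `S_obs + F1²/(2F2)` via `variant="classic"`.
* ACE with rare/abundant cutoff 10 (configurable); when every rare species
  is a singleton the coverage estimate is zero and ACE falls back to Chao1
  with a warning.
* Chao2: `S_obs + ((n−1)/n)·Q1(Q1−1)/(2(Q2+1))`; the classic variant keeps
  the `(n−1)/n` factor with denominator `2Q2`, matching vegan's specpool.
* Jackknife orders 1–2 and the occupancy bootstrap
  `S_obs + Σ(1−pₖ)ⁿ`.

Abundance-based estimators refuse incidence-only input rather than
guessing counts.

### Preston lognormal

Abundances are binned into log2 octaves with upper boundaries 2^k; a
species whose abundance is exactly a power of two is split half-and-half
between the adjacent octaves. A Gaussian `h·exp(−(x−μ)²/2σ²)` is fitted to
octave frequencies by bounded least squares (initialised at the modal
octave); the richness estimate is the Gaussian area `hσ√(2π)`, clamped
below at S_obs. At least three occupied octaves are required; a
non-convergent fit raises an error rather than returning a number.

### Combined non-parametric estimator

The CNE addresses the two failure modes jointly: Chao1 extrapolates only
the fauna of the sampled sites, while Chao2's observed uniques/duplicates
are depressed by undersampling *within* sites. Per site i, with F1ᵢ/F2ᵢ the
within-site singleton/doubleton species counts and S⁽¹⁾ᵢ/S⁽²⁾ᵢ the observed
unique/duplicate species there,

    extraᵢ = F1ᵢ(F1ᵢ−1)/(2(F2ᵢ+1))
    ŝ1ᵢ = S⁽¹⁾ᵢ(1 + extraᵢ/S_obs,ᵢ),  ŝ2ᵢ = S⁽²⁾ᵢ(1 + extraᵢ/S_obs,ᵢ)
    Q̂1 = Σᵢ ŝ1ᵢ,  Q̂2 = ½ Σᵢ ŝ2ᵢ
    S_CNE = S_obs + Q̂1(Q̂1−1)/(2(Q̂2+1)).

The hidden assumption is that undiscovered species at a site are unique or
duplicate in the same proportion as the observed ones. Design choices:

* **Denominator convention.** The default uses the small-sample
  bias-corrected Chao denominator `2(x+1)` at both levels; the literal
  `2x+1` reading is available as `denominator="as_printed"`. Both are
  covered by the oracle tests.
* Sites with no specimens are dropped before the sums (they carry no
  information and would inflate n).
* Q̂1, Q̂2 stay real-valued throughout; nothing is rounded before the final
  step. Since each ŝ1ᵢ ≥ S⁽¹⁾ᵢ, Q̂1 is either 0 or ≥ 1, so the final
  quadratic term is never negative and S_CNE ≥ S_obs always.
* Incidence-only input is refused (F1ᵢ/F2ᵢ need counts); the error message
  points to Chao2/jackknife.
* At least two sites with specimens are required; the across-site
  extrapolation is undefined otherwise.

## Data handling

Samples are pooled to the trap/site level before any estimation (site =
trap); the estimators are indexed by site and the accumulation curves
accumulate sites. Records identified only to genus (taxon label ending in
an unqualified `sp.`) are removed before analysis; `sp. indet.` records are
retained as distinct species. Species identity is the trimmed label string —
no fuzzy matching. Zero-count records are dropped with a warning. A group
containing any countless record is demoted to incidence as a whole. Whether
trap-years should be treated as separate sites is left to the caller (pool
per trap before calling, or pass trap-year row labels).

## Synthetic communities

The simulator emulates the estimation problem, not any particular fauna:

* relative abundances `exp(N(0, σ))` with σ = 1.5 by default — a lognormal
  abundance structure with realistic dominance;
* occupancy: per-species probability drawn uniformly from (0.05, 0.55)
  (mean 0.3), giving a mix of widespread and highly localized species;
  homogeneous-probability and fixed-site-count models are available;
  every pool species occupies at least one site;
* sampling: per-site Poisson counts with rates proportional to abundance
  over the species present, normalised so the expected catch per site
  equals `effort_per_site`. Varying effort sweeps coverage of the pool
  from a few percent to complete.

What the simulator does *not* emulate: phenology and trap-day structure,
spatial autocorrelation between nearby sites, abundance-dependent
occupancy, and taxonomic error. Benchmark results therefore speak to
estimator behaviour under heterogeneous occupancy and undersampling, not to
any specific inventory's biology.

Benchmark problem sizes: the bias-ordering experiments use pools of 200
species at 20 sites (260 replicates at ~25% coverage, 200 at ~90%); the
error-vs-coverage grid uses six effort levels × 40 replicates. These sizes
give Monte-Carlo standard errors on mean log-bias of about 0.02, an order
of magnitude below the effects being measured.

## Evaluation framework

Accuracy is `(ln Ŝ − ln S)²` and bias `ln Ŝ − ln S` (natural logs; a mean
squared log-error of 0.4 corresponds to a typical multiplicative error of
exp(√0.4) ≈ 1.9). True richness is always supplied as data. The benchmark's
inclusion rule (more than 100 specimens from more than 5 sites, both
configurable) mirrors standard practice of excluding barely-sampled groups.
Accumulation curves average distinct-species counts over random site
orderings (default 10,000, seeded); the exact hypergeometric expectation
`E[S(k)] = Σⱼ(1 − C(n−oⱼ,k)/C(n,k))` is provided for validation.

## Permutation tests

Trap-to-group labels are permuted uniformly with group sizes fixed. The
statistic is either the focal-trait proportion difference between the
extreme groups of a stated ordering (default) or the slope of proportion on
group rank; both are exposed because the appropriate trend statistic is a
modelling choice. Sidedness defaults to the direction of the observed
statistic (an anti-conservative convention appropriate for descriptive
use); fixed `greater`/`less`/`two-sided` alternatives are available and are
what the calibration tests use, since direction-picking makes null p-values
non-uniform by construction. Monte-Carlo p-values use the add-one
convention `(1 + hits)/(n_perm + 1)`, so p ≥ 1/(n_perm+1) and exact zeros
are impossible; small designs can be enumerated exactly.

## Known limitations

* No variance or interval estimates: the estimators are point estimators
  here, matching their typical inventory use.
* The sampling-effort-corrected estimator family (corrections fitted to
  external benchmark data) is not implemented; the estimator registry
  (`register_estimator`) is the plug-in point.
* Preston fitting on very sparse data (fewer than three occupied octaves)
  is refused rather than regularised.
* The bootstrap-below-jack1 ordering often quoted for incidence estimators
  is a tendency, not a theorem; communities dominated by low-occupancy but
  non-unique species can reverse it.
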