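# Methods

This note documents the statistical model, the numerical choices, and the
synthetic study conditions behind `sigdriver`, in the spirit of a methods
supplement. It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model and assumptions

The unit of inference is a (hotspot, signature) pair. The response is the
tumor's normalized exposure to the signature — a proportion in [0, 1]
obtained by a non-negative quadratic program against a fixed signature
matrix — and the predictor is hotspot carrier status. The working model is the
linear kernel regression

    exposure ~ beta * Genotype + entity + nvar + sex

where `nvar` is the tumor's filtered sSNV count and entity/sex enter as
one-hot factors (an "unknown" sex level is admitted as its own category;
single-level factors are dropped). Exposures are treated as a continuous
trait; no logistic variant is provided. The null model is ordinary least
squares; inference is a score test, so only the null fit is ever needed.

Assumptions worth keeping in mind:

* Exposure proportions are compositional — raising one signature's exposure
  necessarily lowers the others. Planted positive associations therefore
  induce genuine negative associations of the same site with other
  signatures; the test reports a direction (sign of the weighted burden
  score) for exactly this reason.
* Residuals are not Gaussian (proportions are bounded and skewed). The
  kernel score test is asymptotically valid under moment conditions, and
  its finite-sample behaviour is checked empirically (type-I error on null
  regions) and calibrated by residual-permutation resampling.
* Site weights R × median(carrier load) are taken as specified; note the
  weight *increases* with carrier mutational load. An
  `--inverse-load-weight`-style alternative was considered and rejected to
  keep the published weighting; the weighting only rescales the kernel, and
  the test is invariant to a global weight rescaling (tested).

## Exposure assignment

Counts per context class are multinomial, so their variance scales with
the expected count. The assigner therefore solves a short sequence of
non-negative quadratic programs per tumor: an unweighted NNLS fit first,
then two re-solves with classes weighted by 1/sqrt(max(fitted, 0.5)) —
a Gauss–Newton approximation to the multinomial likelihood that matches
the efficiency of a full multinomial MLE in recovery experiments while
staying a plain quadratic program (the unweighted single solve remains
available via `irls_iterations=0`). No sum-to-one constraint is imposed
during optimization; exposures are normalized to proportions afterwards,
and zero-mutation tumors get all-zero rows.

## Hotspot search

Windows of 2000 bp at 1000 bp steps tile each chromosome from coordinate 1;
a trailing partial window is kept when it still holds the minimum 6
variants. Sub-windows of 30 bp at 15 bp steps are scored with
L_i = Σ_t l_it / log₂(V_t); loads below 2 clamp to 2 (log₂1 = 0 would
divide by zero) with a warning. The three selection conditions use ≥, >, ≥
respectively, with the sample (n−1) standard deviation; a single sub-window
region has undefined sd, treated as 0. Selection is scale-free, which the
suite verifies by property test and by brute-force oracle agreement on
random load vectors.

Recurrence is counted per (chrom, pos, alt): substitution identity matters
because signature association is substitution-specific (C>T vs C>G at one
base are different events). Position-only recurrence can be obtained by
collapsing alleles upstream; it is not the default.

Overlapping scan windows can surface the identical member-site set twice;
the pipeline deduplicates hotspots by their member-site sets and counts the
deduplicated number of tests per signature as the Bonferroni m, which is
recorded in the run manifest.

## Kernel test numerics

Q_ρ = (1−ρ)·Q_SKAT + ρ·Q_burden is evaluated on the ρ grid
{0, 0.01, 0.04, …, 0.81, 1}. Per-ρ null distributions are weighted
chi-square mixtures with weights from the eigenvalues of
R_ρ^{1/2} Z̃ᵀZ̃ R_ρ^{1/2}, Z̃ the covariate-residualized, weight-scaled
genotype matrix. The omnibus p integrates the minimum-p statistic over its
chi-square(1) mixing variable (the Lee et al. construction), with the
integration variable substituted as x = t² to remove the density
singularity at zero and evaluated on 64 Gauss–Legendre nodes; the final p
is clipped to [min-p, 11·min-p], its Bonferroni bracket.

Mixture tails are computed by characteristic-function inversion (Imhof's
integral) on a truncated range, with three pragmatic regimes:

* numerically equal eigenvalues collapse to an exact scaled chi-square
  survival (this includes every single-site test);
* the general case integrates with composite 8-node Gauss–Legendre panels
  sized to the oscillation wavelength 4π/(q + Σλ), truncated where the
  oscillation-damped tail estimate 2/(π q U ρ(U)) drops below 1e-6 — an
  estimate that ignores cancellation and is conservative by roughly two
  orders of magnitude (observed agreement with the exact Ruben series is
  ~1e-7 or better in the unit tests);
* thresholds in the far tails (q < 0.02·Σλ or q > 100·Σλ, i.e. p ≈ 1 or
  p ≈ 0) use Liu–Tang–Zhang moment matching, whose absolute error there is
  far below anything that affects a decision. Moment matching is also the
  fallback whenever the truncation estimate fails its 1e-6 target.

A slow exact Ruben series (positive mixing coefficients, computable
truncation-mass bound) ships in `sigdriver.quadform` purely as an
independent cross-check; tests compare the production path against it on
spread eigenvalue sets.

P-values are floored at 1e-300 to respect the (0, 1] contract when survival
functions underflow.

## Resampling calibration

Residual permutation with B = 999 replicates by default, escalating ×10 up
to 99,999 while p_raw < 10/(B+1), calibrated as
(1 + #{replicate ≤ observed})/(B + 1). The replicate statistic is the
minimum over ρ of the moment-matched per-ρ p — the same functional for the
observed data and every replicate, so moment-matching bias cancels in the
comparison. Because each per-ρ p is monotone in Q_ρ, a replicate beats the
observed statistic iff some Q_ρ exceeds a per-ρ critical value obtained by
inverting once, which removes all distribution-function evaluations from
the permutation loop. All draws flow from the caller's seed.

The null model's residual variance uses RSS/(n−p). A score test with a
plug-in variance differs from the exact permutation null by O(p/n); at
n = 300 and p ≈ 7 this amounts to ~1e-3 absolute near p = 0.01, which is
why the permutation-oracle fixtures in the acceptance suite use n = 1000 —
there the bias sits below the Monte-Carlo resolution of 10⁵ permutations
and the comparison isolates the tail computation itself.

## Enrichment and classification

Permutation enrichment redraws |hotspots| positions uniformly over the
concatenated mappable territory (mappability track rows with score < 0.25
removed) and counts element overlaps; p = (1 + #{overlap ≥ observed}) /
(n_perm + 1), one-sided, 100,000 rounds by default. Draws are
position-uniform; trinucleotide composition is deliberately not matched.
The hypergeometric driver-enrichment test uses a 21,000-gene coding
background by default. Both p families are BH-corrected across the
signature set, and the binary "enriched" gate is q < 0.05 (configurable;
the stricter significance tiers q < 0.01 / q < 0.001 are reporting
conventions, not gates).

ChromHMM annotation counts epigenomes whose state at the top site is a
foreground state (enhancer: EnhG1/EnhG2/EnhA1/EnhA2; TSS: TssA/TssFlnk)
versus a background state (enhancer background: states 1–6, 12–14; TSS
background: states 5–15). The background sets are kept exactly as
published, asymmetries included, and are configurable. A foreground count
with zero background epigenomes counts as a hit (the ratio is unbounded).

The driver-associated-signature rule is a conjunction: q_driver < 0.05 AND
q_elements < 0.05 AND strictly more than 3 Cancer Gene Census overlaps.
The putative-driver rule requires the signature flag plus at least one of:
regulatory location, coding location, an externally supplied expression
effect (differential expression itself is out of scope; absent evidence
means the criterion is unmet), or top-site recurrence ≥ 10.

## Synthetic cohorts — what they emulate and what they do not

The generator produces an i.i.d.-uniform A/C/G/T genome, entities with
fixed proportions, per-tumor exposures from a symmetric Dirichlet(α = 1),
per-tumor loads from log-normal(ln 2000, 1) truncated to [50, 100000] (the
module default, mimicking WGS load spread without claiming fidelity to any
cohort), and background mutations sampled from the exposure-weighted
signature mixture and placed by context-matched lookup with both strands
indexed. Planted hotspots shift carrier exposures by a chosen number of
residual standard deviations (spread after entity-mean centering) before
renormalization and add the recurrent substitution at a position whose
context matches the target signature's modal class. Duplicate
(tumor, pos, alt) draws are collapsed, and per-tumor loads are recomputed
from the final table so the bookkeeping invariants hold exactly.

Real somatic data differ in ways the simulator does not model: chromatin-
and replication-timing-dependent mutation rates, copy-number structure,
subclonality, calling artifacts beyond the panel-of-normals mechanism, and
correlated signature activity across entities. Passing tests on synthetic
cohorts therefore demonstrate the correctness and calibration of the
machinery under the stated generative model, not discovery performance on
any real cohort.

### Desk-scale study conditions

The calibration and power experiments (tests and acceptance script) run on
a fixed desk-scale configuration chosen once: 300 tumors, one 300 kb
chromosome, loads log-normal(ln 300, 0.5) truncated to [50, 3000], 4 sparse
synthetic signatures (Dirichlet concentration 0.1 over the 96 classes,
giving the peaked, near-disjoint profiles real processes show), 3 entities
(40/35/25%). These sizes keep a full genome scan near a few seconds while
preserving ~10⁵ variants per cohort, enough that every scan window clears
the 6-variant filter and eligible background sites arise naturally. The
planted-hotspot power experiment uses a +3 residual-SD shift with 30/300
carriers; the null experiments use the same generative process with effect
sizes forced to zero.

## Known limitations

* The bundled exposure assigner is iteratively reweighted NNLS; it is not
  a re-implementation of constrained convex optimization assigners, and an
  import path for externally computed exposure tables exists for
  comparability.
* No mixed-model/kinship correction, no binary-trait test, no CNV-aware
  load adjustment, no consequence-level (codon) annotation.
* The MAF dialect is the minimal five columns (tumor_id, chrom, pos, ref,
  alt; common MAF headers are aliased); richer MAF semantics are ignored.
* Exact characteristic-function inversion is used for all decision-relevant
  tail evaluations, but the far tails (p ≈ 0 or 1) are moment-matched; a
  tiny (≲1e-4) discontinuity can exist at those regime boundaries.
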