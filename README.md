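# sigdriver

Discovery of somatic-SNV hotspots associated with mutational-signature
exposures, with knowledge-based classification of putative coding and
non-coding cancer drivers.

Most driver-discovery methods model a background mutation rate and look for
regions mutated more often than expected. `sigdriver` takes a different
route: it asks which recurrently mutated sites are *statistically coupled to
a mutational process*. Tumors whose mutations were largely produced by, say,
APOBEC deamination carry a measurable exposure to the corresponding
single-base-substitution (SBS) signature; a genomic site whose carriers
systematically show unusual exposure to one signature is a candidate target
— or driver — of that process. The package is aimed at cancer-genomics
researchers working with somatic SNV call sets from tumor cohorts
(WGS-scale), and everything it does is reproducible on bundled synthetic
cohorts, so no controlled-access data are needed to use or test it.

## Method

For a cohort of T tumors with somatic SNV counts V_t:

1. **Catalogs and exposures.** Each substitution is classified on the
   pyrimidine strand into 96 context classes — classic trinucleotide
   (X[R>A]Y), or the NxSxN penta-reduced context that keeps the bases two
   positions away and marginalises the immediate neighbours, collapsing
   1536 = 6·4·4·4·4 penta classes to 96 while widening the motif footprint.
   Normalized signature exposures e_t are assigned per tumor by a
   non-negative quadratic program against a signature matrix S
   (min ‖c_t − e_tᵀS‖₂ with e_t ≥ 0, iteratively reweighted for the
   multinomial count variance, then row-normalized); externally computed
   exposure tables can be supplied instead.
2. **Hotspot pruning.** The genome is tiled in 2 kb windows at 1 kb steps;
   windows with fewer than 6 sSNVs are discarded. Within a window, variants
   are binned into 30 bp sub-windows at 15 bp steps, weighted per tumor by
   w_t = 1/log₂V_t, giving sub-window loads L_i = Σ_t w_t·l_it. Sub-window
   i is a hotspot iff
   L_i ≥ max(L)/2, L_i > 3·mean(L), and L_i ≥ mean(L) + 3·sd(L).
3. **Association.** Each eligible hotspot (a site recurring in ≥ 6 tumors,
   or ≥ 10 variants with recurrence ≥ 3) is tested under

   exposure ~ β·Genotype + entity + nvar + sex

   with a variance-component/burden kernel score test over the mixing grid
   ρ ∈ {0, 0.01, …, 0.81, 1} (the SKAT-O construction), sites weighted by
   R × median(carrier load). Per-ρ p-values come from exact
   characteristic-function inversion of the weighted chi-square mixture;
   the omnibus p integrates over the minimum-p statistic. Raw p-values are
   calibrated by seeded residual-permutation resampling and
   Bonferroni-corrected per signature; signature series with genomic
   inflation λ > 1.5 are removed. Per-site contributions are resolved by
   leave-one-site-out perturbation ratios P_t/min(P).
4. **Annotation and driver calls.** Hotspot top sites are intersected with
   18-state ChromHMM segmentations across epigenomes (enhancer/TSS flags by
   a > 1:2 foreground:background ratio), a gene model (coding status,
   nearest gene) and known-driver lists. Element enrichment uses 100,000
   permutations over the mappability-filtered genome (score ≥ 0.25);
   known-driver enrichment is an upper-tail hypergeometric test on a
   21,000-gene background, both BH-corrected across the signature set. A
   signature is *driver-associated* when both enrichments reach q < 0.05
   and more than three events overlap Cancer Gene Census genes; its
   significant hotspots become *putative drivers* when they are regulatory,
   coding, expression-altering, or carried by ≥ 10 tumors — otherwise they
   are susceptible targets.

A seeded synthetic-cohort simulator (`sigdriver.simulate`) generates ground
-truthed inputs for every stage: a random reference genome, Dirichlet
exposures, truncated log-normal loads, context-faithful background
mutations and planted hotspots with chosen effect sizes.

## Worked example

```bash
python examples/04_hotspot_scan.py
```

simulates 300 tumors on a 300 kb genome with one planted hotspot (+3
residual-SD exposure shift on SIG-2, 30 carriers), re-estimates exposures
and scans the genome. Output (abridged):

```
            region signature  n_sites    p_raw  p_resampled  p_adjusted direction  top_pos  top_recurrence
chr1:251001-253000     SIG-2       11  8.1e-14      0.00001     0.00002  positive   252439              32
chr1:251001-253000     SIG-1       11  0.00140      0.00150     0.00300  negative   252439              32
...
truth: planted site at 252439 on SIG-2
tests per signature (Bonferroni m): {'SIG-1': 2, 'SIG-2': 2, 'SIG-3': 2, 'SIG-4': 2}
```

The planted site is recovered at single-base resolution with a strongly
positive SIG-2 association (adjusted p = 2×10⁻⁵; the resampled p sits at
the adaptive-resampling floor). The *negative* associations of the same
site with the other signatures are a real compositional effect — exposure
proportions sum to one, so carriers enriched for SIG-2 are depleted for the
rest — the same phenomenon that makes negative hotspot–signature
associations biologically meaningful. Other example scripts cover cohort
simulation, catalog/exposure fitting, the NxSxN reduction, and
annotation/driver classification.

The same pipeline is scriptable from a shell:

```bash
sigdriver simulate --seed 7 --out data/
sigdriver run-all --config run.yaml --seed 7 --out results/
```

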