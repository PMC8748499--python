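"""Build a 96-class mutation catalog and assign signature exposures.

Classifies every simulated variant into its trinucleotide context class
(pyrimidine strand), assembles the tumors x 96 catalog and solves the
non-negative least-squares exposure assignment, then compares the
estimate against the simulation truth.
"""

import numpy as np

from sigdriver import SimulationConfig, build_catalog, fit_exposures, simulate_cohort

result = simulate_cohort(SimulationConfig(seed=3, n_tumors=50, genome_length=100_000))

catalog = build_catalog(result.variants, result.genome,
                        tumors=list(result.profiles["tumor_id"]))
print(f"catalog: {catalog.shape[0]} tumors x {catalog.shape[1]} classes, "
      f"{catalog.values.sum()} classified mutations")

exposures = fit_exposures(catalog, result.signatures)
l1 = np.abs(exposures.values - result.exposures.values).sum(axis=1)
print(exposures.head().round(3))
print(f"\nmean L1 distance to true exposures: {l1.mean():.4f}")
# At a few hundred mutations per tumor the per-tumor exposure proportions
# are typically recovered to within a few percent in L1.
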