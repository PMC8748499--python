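"""Genome scan with hotspot pruning and kernel association tests.

Simulates a planted cohort, re-estimates exposures, scans the genome in
2 kb / 1 kb windows, prunes each window by the weighted-load rules and
tests every eligible hotspot for association with each signature.
"""

import numpy as np

from sigdriver import (
    PlantedHotspot,
    SimulationConfig,
    build_catalog,
    fit_exposures,
    scan_cohort,
    simulate_cohort,
)

config = SimulationConfig(
    seed=11, n_tumors=300, genome_length=300_000, n_signatures=4,
    load_log_mu=float(np.log(300)), load_log_sigma=0.5, load_max=3000,
    hotspots=(PlantedHotspot(signature="SIG-2", effect_size=3.0, carrier_fraction=0.1),),
)
result = simulate_cohort(config)
catalog = build_catalog(result.variants, result.genome,
                        tumors=list(result.profiles["tumor_id"]))
exposures = fit_exposures(catalog, result.signatures)

outcome = scan_cohort(result.variants, result.profiles, exposures,
                      result.chrom_sizes, seed=5)
cols = ["region", "signature", "n_sites", "p_raw", "p_resampled", "p_adjusted",
        "direction", "top_pos", "top_recurrence"]
print(outcome.results[cols].to_string(index=False))
print(f"\ntruth: planted site at {result.truth['causal_sites'][0]['position']} on SIG-2")
print(f"tests per signature (Bonferroni m): {outcome.m_per_signature}")
# The planted site should reach a small adjusted p for SIG-2 with a
# positive direction; other signatures often show a *negative* association
# at the same site because exposure proportions are compositional.
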