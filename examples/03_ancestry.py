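"""Assign super populations by projecting samples into a reference PC space.

Builds a labeled 7-population reference panel, projects freshly drawn study
samples onto its top 10 principal components, and classifies each by a
20-nearest-neighbor inverse-distance vote with a 75% threshold.
"""

from collections import Counter

import pgsdesk as pk
from pgsdesk.simulate import draw_from_population, simulate_admixed

cfg = pk.SimulationConfig(n_populations=7, n_ref_per_pop=50, n_study=2,
                          n_snps=2000, fst=0.08, seed=2)
panel = pk.simulate_panel(cfg)
space = pk.fit_reference_pca(panel.ref_genotypes, panel.ref_labels,
                             snp_keys=panel.snp_keys, n_pcs=10)

pure = draw_from_population(panel, "EUR", 20, seed=3)
coords = pk.project_samples(space, pure, snp_keys=panel.snp_keys)
calls = pk.classify_samples(coords, space, k=20, vote_threshold=0.75)
print("EUR draws classified as:", dict(Counter(c.label for c in calls)))

admixed = simulate_admixed(panel, "AFR", "EAS", 20, seed=4)
coords = pk.project_samples(space, admixed, snp_keys=panel.snp_keys)
calls = pk.classify_samples(coords, space)
print("AFR x EAS F1 crosses:", dict(Counter(c.label for c in calls)))
# Samples whose winning population holds <= 75% of the weighted vote are
# UNCLASSIFIED — typically admixed individuals between reference clusters.
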