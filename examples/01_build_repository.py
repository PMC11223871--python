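"""Merge scoring files into a Tabix-indexed weight repository.

Simulates three small score files, merges them by variant, writes the
bgzipped repository + index, and queries one 20 Mb interval.
"""

import os
import tempfile

import pgsdesk as pk

work = tempfile.mkdtemp()
cfg = pk.SimulationConfig(n_populations=2, n_ref_per_pop=5, n_study=5,
                          n_snps=300, n_scores=3, variants_per_score=40, seed=0)
panel = pk.simulate_panel(cfg)
sim = pk.simulate_scores(cfg, panel, os.path.join(work, "scores"))

definitions = [pk.parse_score_file(p) for p in sim.paths]
repo = pk.merge_scores(definitions)
pk.write_repository(repo, os.path.join(work, "repo"))

indexed = pk.load_repository(os.path.join(work, "repo"))
rows = indexed.query_interval("1", 1, 20_000_000)
print(f"repository: {len(repo.table)} variant rows x {len(repo.score_ids)} scores")
print(f"chr1:1-20,000,000 holds {len(rows)} of those rows")
# Each row carries one weight column per score ('.'/NaN where a score lacks
# the variant); the Tabix index makes the interval fetch O(rows returned).
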