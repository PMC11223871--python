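"""Compute polygenic scores PGS_j = sum_i beta_i * D_ij from an imputed VCF.

Simulates a study cohort with imputed dosages, scores it against a
repository in 20 Mb chunks, and prints per-score coverage and the first
samples' scores.
"""

import os
import tempfile

import pgsdesk as pk

work = tempfile.mkdtemp()
cfg = pk.SimulationConfig(n_populations=3, n_ref_per_pop=10, n_study=8,
                          n_snps=400, n_scores=3, variants_per_score=50,
                          low_r2_rate=0.1, seed=1)
panel = pk.simulate_panel(cfg)
vcf = pk.write_study_vcf(panel, os.path.join(work, "study.vcf.gz"))
sim = pk.simulate_scores(cfg, panel, os.path.join(work, "scores"))
repo = pk.merge_scores([pk.parse_score_file(p) for p in sim.paths])
pk.write_repository(repo, os.path.join(work, "repo"))

result = pk.run_scoring([vcf], pk.load_repository(os.path.join(work, "repo")),
                        min_r2=0.3, chunk_size_mb=20)
print(result.frame().head(3).round(3))
for sid in result.score_ids:
    print(f"{sid}: used {result.n_used[sid]}/{result.n_total[sid]} variants, "
          f"coverage {result.coverage[sid]:.0%} ({result.coverage_class[sid]})")
# Coverage counts variants that survived allele matching, the palindromic
# exclusion, the r2 >= 0.3 imputation-quality filter and the missing-dosage
# rule; scores with low coverage should be interpreted with caution.
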