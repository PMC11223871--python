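"""Per-score summaries with population matching, plus the HTML report.

Scores every sample, estimates ancestries, then summarizes each score over
the samples whose population matches the score's GWAS populations;
mismatched and unclassified samples stay in the score matrix but are
excluded from the summary statistics.
"""

import os
import tempfile

import pgsdesk as pk

work = tempfile.mkdtemp()
cfg = pk.SimulationConfig(n_populations=3, n_ref_per_pop=30, n_study=12,
                          n_snps=800, fst=0.1, n_scores=2,
                          variants_per_score=40, seed=5)
panel = pk.simulate_panel(cfg)
vcf = pk.write_study_vcf(panel, os.path.join(work, "study.vcf.gz"))
# first score restricted to EUR GWAS samples, second unrestricted
sim = pk.simulate_scores(cfg, panel, os.path.join(work, "scores"),
                         populations_per_score=[frozenset({"EUR"}),
                                                frozenset(pk.SUPER_POPULATIONS)])
repo = pk.merge_scores([pk.parse_score_file(p) for p in sim.paths])
pk.write_repository(repo, os.path.join(work, "repo"))
result = pk.run_scoring([vcf], pk.load_repository(os.path.join(work, "repo")))

space = pk.fit_reference_pca(panel.ref_genotypes, panel.ref_labels,
                             snp_keys=panel.snp_keys, n_pcs=5)
coords = pk.project_samples(space, panel.study_dosages, snp_keys=panel.snp_keys)
calls = pk.classify_samples(coords, space, samples=panel.study_samples)

summaries = pk.summarize(result, calls, repo.annotations)
cols = ["score_id", "populations", "n_included", "n_excluded_mismatch",
        "mean", "sd", "coverage_class"]
print(summaries.table[cols].round(3).to_string(index=False))
for w in summaries.warnings:
    print("warning:", w)
pk.render_html(summaries, calls, os.path.join(work, "report.html"))
print("HTML report written to", os.path.join(work, "report.html"))
# The EUR-only score's mean/sd cover only the EUR-classified samples; the
# excluded samples still have scores in result.frame().
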