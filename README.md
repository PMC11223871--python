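# pgsdesk

Desk-scale calculation of polygenic scores from imputed genotypes, with
ancestry-aware reporting.

Polygenic scores summarize an individual's genetic liability for a trait as
a weighted sum over trait-associated variants:

    PGS_j = Σ_i β_i · D_ij

where β_i is the published per-allele weight of variant i and D_ij ∈ [0, 2]
is individual j's imputed dosage of the *effect* allele. Applying thousands
of published scores to an imputed cohort is mostly a data-hygiene problem,
and that is what this package implements:

- **Scoring-file parsing and a unified repository** — PGS Catalog-style
  score files (author-reported or harmonized `hm_*` coordinates) are merged
  into a single variant-grouped, coordinate-sorted table with one weight
  column per score, written as bgzipped TSV with a Tabix index so any
  genomic interval can be extracted efficiently.
- **Exact matching semantics** — effect/other alleles are matched against
  each VCF record's REF/ALT; when the effect allele corresponds to REF the
  dosage is inverted (2 − D). Strand flips are resolved automatically by
  complementing the score alleles, which forces the exclusion of palindromic
  (A/T, G/C) SNVs whose strand cannot be determined. InDels are matched
  exactly and never complemented. Variants with imputation r² below 0.3
  (INFO `R2`/`ER2`) are dropped, and a variant with a missing dosage in
  *any* sample is dropped for *all* samples, so incomplete genotypes cannot
  systematically deflate one sample's scores. Every excluded variant is
  reported with a reason code, and each score gets a coverage fraction
  classified HIGH (> 75%), MEDIUM (25–75%) or LOW (< 25%).
- **Chunked, deterministic execution** — the genome is tiled into 20 Mb
  chunks; each chunk is scored from a Tabix interval query plus a VCF region
  query, and per-chunk partial sums are merged in fixed genomic order, so
  results are bit-identical across worker counts and stable across chunk
  sizes.
- **Ancestry estimation** — a labeled reference panel (e.g. HGDP) defines a
  PC space (genotypes standardized by allele frequency, top 10 components);
  study samples are projected onto the reference loadings and classified
  into one of seven super populations (AFR, EUR, GME, EAS, SAS, AMR, OTH)
  by their 20 nearest reference neighbors voting with weight 1/distance. A
  sample is labeled only when one population takes > 75% of the vote,
  otherwise it is UNCLASSIFIED. Per-score summaries then exclude samples
  whose population is not among the score's GWAS populations — the scores
  themselves are still reported for everyone.
- **Synthetic cohorts** — a Balding–Nichols simulator generates labeled
  reference panels, imputed-dosage study VCFs and score files with known
  ground truth, so the whole pipeline is testable without any downloads.

## Worked example

```python
import os, pgsdesk as pk

cfg = pk.SimulationConfig(n_populations=3, n_ref_per_pop=10, n_study=8,
                          n_snps=400, n_scores=3, variants_per_score=50,
                          low_r2_rate=0.1, seed=1)
panel = pk.simulate_panel(cfg)
vcf = pk.write_study_vcf(panel, "study.vcf.gz")
sim = pk.simulate_scores(cfg, panel, "scores")
repo = pk.merge_scores([pk.parse_score_file(p) for p in sim.paths])
pk.write_repository(repo, "repo")

result = pk.run_scoring([vcf], pk.load_repository("repo"),
                        min_r2=0.3, chunk_size_mb=20)
print(result.frame().head(3).round(3))
for sid in result.score_ids:
    print(f"{sid}: used {result.n_used[sid]}/{result.n_total[sid]} variants, "
          f"coverage {result.coverage[sid]:.0%} ({result.coverage_class[sid]})")
```

prints

```
           SYN000001  SYN000002  SYN000003
sample
study0000      1.150     15.585     15.661
study0001      5.042     13.086     18.148
study0002     -0.196     16.915     18.085
SYN000001: used 37/50 variants, coverage 74% (MEDIUM)
SYN000002: used 37/50 variants, coverage 74% (MEDIUM)
SYN000003: used 40/50 variants, coverage 80% (HIGH)
```

Each matrix cell is one sample's Σβ·D for one score; the coverage lines say
how many of each score's variants survived allele matching, the palindromic
exclusion, the r² filter and the missing-dosage rule — low-coverage scores
should not be compared across cohorts. The `examples/` directory has one
short script per capability (repository building, scoring, ancestry,
reporting, and a shell walkthrough of the `pgs-desk` CLI).

## Command line

```sh
pgs-desk simulate   --out-dir sim --seed 7 ...
pgs-desk build-repo sim/scores/*.txt --out repo
pgs-desk score      --vcf sim/study.vcf.gz --repo repo --out-prefix run \
                    --min-r2 0.3 --chunk-size-mb 20 --strand-mode resolve
pgs-desk ancestry   --vcf sim/study.vcf.gz --ref-vcf sim/reference.vcf.gz \
                    --labels sim/reference.labels.txt --out-prefix anc
pgs-desk report     --scores run.scores.txt --coverage run.coverage.txt \
                    --populations anc.populations.txt --repo repo \
                    --out-prefix rep
```

Exit codes: 0 success, 1 usage error, 2 data error. `--print-config` on
`score`/`ancestry` prints the effective parameters as JSON.

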