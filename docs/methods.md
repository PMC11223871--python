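# Methods

## Scoring model

For sample j the score is PGS_j = Σ_i β_i·D_ij, where D_ij is the imputed
dosage of the effect allele of variant i. The VCF stores ALT dosages (FORMAT
`DS`, falling back to the hard-call ALT count from `GT` when `DS` is
absent), so the engine must first decide how each score variant's
(effect, other) pair maps onto the record's (REF, ALT):

- `(effect, other) == (ALT, REF)` → use D directly (**DIRECT**);
- `(effect, other) == (REF, ALT)` → the weight applies to the reference
  allele, so use 2 − D (**SWAPPED**);
- otherwise, if both score alleles are single bases, retry with the
  complemented pair (**FLIPPED** / **FLIPPED_SWAPPED**) — this resolves
  variants reported on the opposite strand;
- palindromic pairs (A/T, G/C) are excluded *before* any match is
  attempted in resolve mode, because complementation maps the pair onto
  itself and the weight's direction cannot be determined;
- InDels (any allele longer than one base) and score variants that omit the
  other allele are matched exactly and never complemented — complementation
  is ill-defined for them, and an allele-absent match is already ambiguous
  enough that we restrict it to effect==ALT or effect==REF;
- `strict` mode disables complementation entirely and therefore retains
  palindromic SNVs.

Filters applied after matching: variants with imputation quality below
`min_r2` (default **0.3**; INFO key `R2`, `ER2` accepted as alias) are
dropped; records carrying no quality value pass, since genotyped (TYPED)
sites legitimately lack an imputation r². A variant with a missing dosage
in any sample is dropped for all samples — otherwise samples with missing
genotypes would receive systematically smaller |scores|. Each score's
**coverage** is used/total variants, classified HIGH (> 0.75), MEDIUM
([0.25, 0.75]), LOW (< 0.25); the boundary values deliberately read
"above"/"below" as strict and fall in MEDIUM.

Every (variant, score) pair receives exactly one audit reason:
`USED_{DIRECT,SWAPPED,FLIPPED,FLIPPED_SWAPPED}`, `EXCLUDED_PALINDROMIC`,
`EXCLUDED_MISMATCH` (position present, alleles foreign), `EXCLUDED_LOW_R2`,
`EXCLUDED_MISSING_DOSAGE`, or `NOT_FOUND` (position absent from the VCF).
`EXCLUDED_MISMATCH` and `NOT_FOUND` are kept distinct — collapsing them
would hide genome-build or allele-coding problems.

## Repository format

Scores are merged by variant key `(chrom, pos, other, effect)` — both
alleles are part of the key so split multi-allelic sites occupy separate
rows. The merged table (one weight column per score, `.` for absent) is
written coordinate-sorted as bgzipped TSV with a generic Tabix index
(1-based, inclusive), plus one `key=value` annotation sidecar per score
(trait, GWAS populations, sample count, publication, build, variant
count). Chromosome names are normalized (leading `chr` stripped, X/Y/MT
upper-cased) and sorted naturally (1..22, X, Y, MT). Weights are written
with `repr()` and parsed back with `float()`, so interval queries
round-trip bit-identically; a genome-build mismatch between score file and
VCF is surfaced as a warning, not an error, since no liftover is performed.

## Chunked execution

Each chromosome is tiled with ⌈L/S⌉ non-overlapping chunks of S = 20 Mb
(configurable); a variant belongs to the chunk containing its position —
scoring needs no flanking context. Per chunk, repository rows come from a
Tabix interval query and dosages from an indexed VCF region query; partial
sums are accumulated in sorted variant-key order within a chunk and merged
in chunk-ordinal order, which makes the result bit-identical across worker
counts (threads only change who computes a chunk, never the summation
order) and reproducible to ~1e-15 relative across chunk sizes (different
chunk sizes regroup the same additions).

## Ancestry estimation

A labeled reference panel defines the PC space: SNPs with MAF < 0.01 are
dropped, genotypes standardized to (g − 2p)/√(2p(1−p)) with reference
frequencies p, and the top **10** components retained (full SVD; at these
panel sizes speed is irrelevant and determinism is not). Study samples are
projected onto the reference loadings using the *reference*
standardization; missing genotypes become 0 after centering (mean
imputation), so an all-missing sample lands at the origin. Projection
requires ≥ 50% SNP overlap with the panel by default. This direct
projection replaces per-batch PCA with Procrustes alignment: at desk scale
the reference loadings are available, so projecting onto them satisfies the
same contract with far less machinery. It does inherit the usual
high-dimensional projection shrinkage toward the origin, which is common to
all projected samples and does not affect the nearest-neighbor vote in
practice (the parameter-recovery tests quantify this).

Classification: Euclidean distance to every reference sample over the
first 10 PCs; the **k = 20** nearest (ties at the k-th distance broken by
reference input order, so exactly k vote) vote their label with weight
1/(d + ε), ε = 1e-12 — a coincident reference dominates without division
by zero. The winner needs strictly more than **75%** of the total weight;
otherwise the sample is UNCLASSIFIED. Plain (not squared) Euclidean
distance is used; the neighbor ranking is identical either way, only the
weights differ. Per-score summaries then drop samples whose label is not
among the score's GWAS populations, and all UNCLASSIFIED samples; exclusion
affects summaries and plots only, never the score matrix.

## Synthetic data

The generator emulates what the pipeline consumes, not human genetics in
full. Population structure is Balding–Nichols: ancestral frequency
p ~ U(0.05, 0.95) per SNP, population frequency ~ Beta(p(1−F)/F,
(1−p)(1−F)/F) with F the divergence parameter (realized pairwise Hudson
Fst tracks F within a few percent at a few thousand SNPs); genotypes are
Binomial(2, p_pop). Study dosages add truncated-Gaussian noise
(sd 0.05, clipped to [0, 2], rounded to 4 decimals as imputation servers
print them); per-variant r² is U(0.7, 1) except a configurable fraction
pushed below 0.3. Score files deliberately mix orientations (effect allele
written as REF with probability 0.5), strand-flipped entries (default 20%),
palindromic sites (5%), variants absent from the VCF (10%) and, optionally,
allele-mismatched entries, so every audit reason is reachable; weights are
N(0, 1). A construction-truth oracle matrix (naive summation honoring every
exclusion rule) accompanies the score files. One integer seed drives all
draws; equal seeds give byte-identical VCFs.

Defaults (7 populations, 50 references each, 2000 SNPs, F = 0.08) give a
panel whose populations separate cleanly in PC space while remaining in the
Fst range typical of continental human populations. What the model omits —
LD, within-population substructure, relatedness, admixture clines —
matters mainly for ancestry edge cases: real reference clusters are
broader and heavier-tailed relative to an individual's sampling noise than
iid Balding–Nichols clusters. One measurable consequence: exact 50/50 F1
crosses between two simulated populations are flagged UNCLASSIFIED in only
~35–45% of draws (the 20-NN neighborhood becomes winner-take-all once a
cross's genome-sampling asymmetry exceeds about half the cluster spread,
and the geometry is invariant in SNP count and F), whereas broader
real-world clusters push such samples to the unclassified side. Passing
ancestry tests on this generator therefore demonstrates correctness of the
projection and voting machinery, and near-perfect recovery for unadmixed
samples — not a guarantee for every admixed individual in real data.

## Numerical and design choices

- Dosages outside [0, 2] raise an error rather than being clamped: they
  indicate wrong field semantics (e.g. GP parsed as DS), not noise.
- VCF Float fields are parsed back to the decimal literal written in the
  file (htslib stores them as float32; the shortest float32 repr recovers
  the original text for ≤ 7 significant digits).
- Duplicate variant keys within one score file: first kept, rest counted
  and warned — scoring files in the wild contain exact duplicate rows.
- Multiple VCF records matching one score variant at one position (should
  not occur after multi-allelic splitting): first in file order used, with
  a warning count.
- `aggregate` rejects overlapping chunk intervals; determinism would
  otherwise silently break.
- Empty-coverage scores are reported as 0.0 with coverage 0 and an explicit
  warning so a sum over the empty set cannot be mistaken for a real score.
- Test and acceptance problem sizes (hundreds of SNPs, tens of samples for
  scoring; 350 references × 2000 SNPs for ancestry) were chosen as the
  smallest sizes at which every code path and statistical property is
  exercised with comfortable margins; all of them run in seconds.

## Known limitations

- No liftover: score files and VCFs must share a genome build (mismatch is
  only warned).
- No BGEN/PGEN input and no dosage recomputation from genotype
  probabilities.
- Mean-imputation of missing dosages by allele frequency is deliberately
  not offered; the all-sample exclusion rule is the conservative default.
- The ancestry module estimates a single categorical label, not admixture
  proportions.
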