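#!/bin/sh
# End-to-end pgs-desk run on simulated data: fixtures -> repository ->
# scores -> ancestry -> report.  All outputs land in ./pgs-desk-demo.
set -e
OUT=pgs-desk-demo
pgs-desk simulate --out-dir "$OUT/sim" --seed 7 --n-populations 3 \
    --n-ref-per-pop 25 --n-study 12 --n-snps 500 --n-scores 3
pgs-desk build-repo "$OUT"/sim/scores/*.txt --out "$OUT/repo"
pgs-desk score --vcf "$OUT/sim/study.vcf.gz" --repo "$OUT/repo" \
    --out-prefix "$OUT/run" --min-r2 0.3 --chunk-size-mb 20
pgs-desk ancestry --vcf "$OUT/sim/study.vcf.gz" \
    --ref-vcf "$OUT/sim/reference.vcf.gz" \
    --labels "$OUT/sim/reference.labels.txt" --out-prefix "$OUT/anc" --k 10
pgs-desk report --scores "$OUT/run.scores.txt" --coverage "$OUT/run.coverage.txt" \
    --populations "$OUT/anc.populations.txt" --repo "$OUT/repo" \
    --out-prefix "$OUT/rep"
echo "scores:    $OUT/run.scores.txt"
echo "summary:   $OUT/rep.summary.txt"
echo "report:    $OUT/rep.report.html"
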