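"""Scoring engine: accumulation, filters, aggregation, and its invariants."""

import numpy as np
import pandas as pd
import pytest

import pgsdesk as pk
from pgsdesk.errors import DataError

from oracles import naive_scores_from_files


def _rows(entries, score_ids):
    """Repository-row DataFrame from (chrom, pos, other, effect, {sid: w})."""
    recs = []
    for chrom, pos, other, effect, weights in entries:
        row = {"CHROM": chrom, "POS": pos, "OTHER": other, "EFFECT": effect}
        for sid in score_ids:
            row[sid] = weights.get(sid, np.nan)
        recs.append(row)
    return pd.DataFrame(recs)


def _rec(chrom, pos, ref, alt, dosages, quality=0.9):
    return pk.DosageRecord(chrom, pos, ref, alt, np.asarray(dosages, float), quality)


class TestScoreChunk:
    def test_single_variant_contributes_beta_times_dosage(self):
        rows = _rows([("1", 100, "A", "G", {"S": 1.0})], ["S"])
        part = pk.score_chunk([_rec("1", 100, "A", "G", [2.0], 0.9)], rows, ["x"])
        assert part.sums.tolist() == [[2.0]]
        assert part.used.tolist() == [1]
        assert part.audits[0].reason == "USED_DIRECT"

    def test_low_quality_variant_filtered(self):
        rows = _rows([("1", 100, "A", "G", {"S": 1.0})], ["S"])
        part = pk.score_chunk([_rec("1", 100, "A", "G", [2.0], 0.2)], rows, ["x"],
                              min_r2=0.3)
        assert part.sums.tolist() == [[0.0]]
        assert part.used.tolist() == [0]
        assert part.audits[0].reason == "EXCLUDED_LOW_R2"

    def test_quality_absent_passes_filter(self):
        rows = _rows([("1", 100, "A", "G", {"S": 2.0})], ["S"])
        part = pk.score_chunk([_rec("1", 100, "A", "G", [1.0], None)], rows, ["x"],
                              min_r2=0.99)
        assert part.sums.tolist() == [[2.0]]

    def test_missing_dosage_excludes_variant_for_all_samples(self):
        rows = _rows([("1", 100, "A", "G", {"S": 5.0}),
                      ("1", 200, "C", "T", {"S": 1.0})], ["S"])
        recs = [_rec("1", 100, "A", "G", [1.0, np.nan]),
                _rec("1", 200, "C", "T", [1.0, 1.0])]
        part = pk.score_chunk(recs, rows, ["x", "y"])
        # the complete sample loses the missing variant too
        assert part.sums.tolist() == [[1.0, 1.0]]
        reasons = {a.reason for a in part.audits}
        assert "EXCLUDED_MISSING_DOSAGE" in reasons

    def test_unmatched_repo_row_not_found(self):
        rows = _rows([("1", 100, "A", "G", {"S": 1.0})], ["S"])
        part = pk.score_chunk([], rows, ["x"])
        assert part.audits[0].reason == "NOT_FOUND"

    def test_swapped_variant_inverts_dosage(self):
        rows = _rows([("1", 100, "G", "A", {"S": 1.0})], ["S"])  # effect == REF
        part = pk.score_chunk([_rec("1", 100, "A", "G", [0.25])], rows, ["x"])
        assert part.sums.tolist() == [[1.75]]
        assert part.audits[0].reason == "USED_SWAPPED"

    def test_inconsistent_sample_count_rejected(self):
        rows = _rows([("1", 100, "A", "G", {"S": 1.0})], ["S"])
        with pytest.raises(DataError):
            pk.score_chunk([_rec("1", 100, "A", "G", [1.0, 1.0])], rows, ["x"])


class TestAggregate:
    def _partial(self, chunk_id, value, interval):
        return pk.PartialScore(chunk_id, ["S"], ["x"],
                               np.array([[value]]), np.array([1]),
                               interval=interval)

    def test_two_chunks_sum(self):
        ann = {"S": pk.ScoreAnnotation("S", n_variants=4)}
        res = pk.aggregate([self._partial(0, 0.4, ("1", 1, 100)),
                            self._partial(1, -0.1, ("1", 101, 200))], ann)
        assert res.values[0, 0] == pytest.approx(0.3)
        assert res.n_used["S"] == 2
        assert res.coverage["S"] == 0.5
        assert res.coverage_class["S"] == "MEDIUM"

    def test_single_chunk_identity(self):
        ann = {"S": pk.ScoreAnnotation("S", n_variants=1)}
        res = pk.aggregate([self._partial(0, 1.25, ("1", 1, 100))], ann)
        assert res.values[0, 0] == 1.25
        assert res.coverage_class["S"] == "HIGH"

    def test_overlapping_chunks_rejected(self):
        ann = {"S": pk.ScoreAnnotation("S", n_variants=2)}
        with pytest.raises(DataError, match="overlap"):
            pk.aggregate([self._partial(0, 0.4, ("1", 1, 150)),
                          self._partial(1, -0.1, ("1", 101, 200))], ann)


class TestOracleEquivalence:
    def test_engine_matches_naive_oracle(self, small_dataset):
        """Engine scores equal an independent per-variant loop to <=1e-9."""
        sim, panel = small_dataset["sim"], small_dataset["panel"]
        res = pk.run_scoring([small_dataset["vcf"]], small_dataset["indexed"])
        oracle_sums, oracle_used = naive_scores_from_files(sim.paths, panel)
        frame = res.frame()
        for sid in sim.score_ids:
            expect = oracle_sums[sid]
            got = frame[sid].to_numpy()
            assert np.all(np.abs(got - expect) <=
                          1e-9 * np.maximum(np.abs(expect), 1.0))
            assert res.n_used[sid] == oracle_used[sid]

    def test_engine_matches_construction_truth(self, small_dataset):
        sim = small_dataset["sim"]
        res = pk.run_scoring([small_dataset["vcf"]], small_dataset["indexed"])
        got = res.frame()[sim.score_ids].to_numpy()
        expect = sim.oracle_scores.to_numpy()
        assert np.allclose(got, expect, rtol=1e-9, atol=1e-12)
        assert res.n_used == sim.expected_used

    def test_audit_reasons_match_construction_truth(self, small_dataset):
        sim = small_dataset["sim"]
        res = pk.run_scoring([small_dataset["vcf"]], small_dataset["indexed"])
        got = {(a.score_id, a.chrom, a.pos, a.effect_allele, a.other_allele):
               a.reason for a in res.audits}
        truth = sim.variant_truth
        for row in truth.itertuples(index=False):
            key = (row.score_id, row.chrom, row.pos, row.effect,
                   row.other if row.other else ".")
            assert got[key] == row.reason


def _transform_score_file(src, dst, transform):
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    with open(src) as fin, open(dst, "wt") as fout:
        for line in fin:
            if line.startswith("#") or line.startswith("chr_name"):
                fout.write(line)
                continue
            c, p, e, o, w = line.rstrip("\n").split("\t")
            fout.write("\t".join(transform(c, p, e, o, w, comp)) + "\n")


def _score_files(tmp_path, dataset, paths, name):
    defs = [pk.parse_score_file(p) for p in paths]
    repo = pk.merge_scores(defs)
    prefix = str(tmp_path / name)
    pk.write_repository(repo, prefix)
    return pk.run_scoring([dataset["vcf"]], pk.load_repository(prefix))


class TestTransformInvariants:
    def test_strand_flip_invariance(self, small_dataset, tmp_path):
        """Complementing all non-palindromic SNV entries changes nothing."""
        def flip(c, p, e, o, w, comp):
            if len(e) == 1 and len(o) == 1 and {e, o} not in ({"A", "T"}, {"C", "G"}):
                return c, p, comp[e], comp[o], w
            return c, p, e, o, w

        flipped_paths = []
        for src in small_dataset["sim"].paths:
            dst = tmp_path / ("flip_" + src.split("/")[-1])
            _transform_score_file(src, str(dst), flip)
            flipped_paths.append(str(dst))
        base = pk.run_scoring([small_dataset["vcf"]], small_dataset["indexed"])
        flipped = _score_files(tmp_path, small_dataset, flipped_paths, "fliprepo")
        assert np.allclose(base.frame().to_numpy(), flipped.frame().to_numpy(),
                           rtol=1e-12, atol=1e-12)
        assert base.n_used == flipped.n_used

    def test_allele_swap_identity(self, small_dataset, tmp_path):
        """Swapping effect/other with the same beta gives 2*sum(beta) - score."""
        def swap(c, p, e, o, w, comp):
            return c, p, o, e, w

        swapped_paths = []
        for src in small_dataset["sim"].paths:
            dst = tmp_path / ("swap_" + src.split("/")[-1])
            _transform_score_file(src, str(dst), swap)
            swapped_paths.append(str(dst))
        base = pk.run_scoring([small_dataset["vcf"]], small_dataset["indexed"])
        swapped = _score_files(tmp_path, small_dataset, swapped_paths, "swaprepo")
        assert base.n_used == swapped.n_used

        # per score: sum of betas over the variants actually used
        used_beta = {}
        for sid in base.score_ids:
            used_keys = {(a.chrom, a.pos, a.other_allele, a.effect_allele)
                         for a in base.audits
                         if a.score_id == sid and a.reason.startswith("USED")}
            table = small_dataset["repo"].table
            beta = 0.0
            for row in table.itertuples(index=False):
                if (row.CHROM, row.POS, row.OTHER, row.EFFECT) in used_keys:
                    w = getattr(row, sid)
                    if not pd.isna(w):
                        beta += w
            used_beta[sid] = beta
        for j, sid in enumerate(base.score_ids):
            expect = 2.0 * used_beta[sid] - base.values[:, j]
            assert np.allclose(swapped.frame()[sid].to_numpy(), expect,
                               rtol=1e-9, atol=1e-9)

    def test_deleting_variant_equals_missing_dosage(self, tmp_path):
        """One MISSING dosage removes the variant exactly as if deleted."""
        score_ids = ["S"]
        entries = [("1", 100, "A", "G", {"S": 1.5}),
                   ("1", 200, "C", "T", {"S": -2.0}),
                   ("1", 300, "G", "A", {"S": 0.7})]
        rows = _rows(entries, score_ids)
        recs = [_rec("1", 100, "A", "G", [0.5, 1.5]),
                _rec("1", 200, "C", "T", [1.0, 0.1]),
                _rec("1", 300, "G", "A", [2.0, 0.0])]
        full = pk.score_chunk(recs, rows, ["x", "y"])

        recs_missing = [r for r in recs]
        recs_missing[1] = _rec("1", 200, "C", "T", [1.0, np.nan])
        with_missing = pk.score_chunk(recs_missing, rows, ["x", "y"])

        deleted = pk.score_chunk([recs[0], recs[2]],
                                 _rows([entries[0], entries[2]], score_ids),
                                 ["x", "y"])
        assert with_missing.sums.tolist() == deleted.sums.tolist()
        assert with_missing.used.tolist() == deleted.used.tolist()
        assert full.used.tolist() == [3]

    def test_coverage_monotone_in_min_r2(self, small_dataset):
        prev = None
        for r2 in [0.0, 0.3, 0.6, 0.9, 1.0]:
            res = pk.run_scoring([small_dataset["vcf"]], small_dataset["indexed"],
                                 min_r2=r2)
            cov = res.coverage
            if prev is not None:
                for sid in cov:
                    assert cov[sid] <= prev[sid] + 1e-15
            prev = cov
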