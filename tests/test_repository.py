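import numpy as np
import pandas as pd
import pytest

import pgsdesk as pk
from pgsdesk.errors import EmptyScoreError, RepositoryError, ScoreFileError
from pgsdesk.repository import chrom_sort_key, normalize_chrom


def _write_score(path, rows, header=("#pgs_id=PGS999999",),
                 columns="chr_name\tchr_position\teffect_allele\tother_allele\teffect_weight"):
    with open(path, "wt") as fh:
        for h in header:
            fh.write(h + "\n")
        fh.write(columns + "\n")
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")
    return str(path)


class TestParseScoreFile:
    def test_duplicate_variant_collapsed_first_kept(self, tmp_path):
        p = _write_score(tmp_path / "s.txt", [
            ("chr1", 100, "A", "G", 0.5),
            ("2", 200, "C", "T", -0.1),
            ("2", 200, "C", "T", -0.1),
        ])
        sd = pk.parse_score_file(p)
        assert len(sd.variants) == 2
        assert sd.n_duplicates == 1
        assert sd.annotation.n_variants == 2
        assert sd.variants[0] == pk.ScoreVariant("1", 100, "A", "G", 0.5)

    def test_harmonized_columns_take_precedence(self, tmp_path):
        p = _write_score(
            tmp_path / "s.txt",
            [("1", 100, "A", "G", 0.5, "1", 111),
             ("2", 200, "C", "T", -0.1, "2", 222)],
            columns="chr_name\tchr_position\teffect_allele\tother_allele\t"
                    "effect_weight\thm_chr\thm_pos",
        )
        sd = pk.parse_score_file(p)
        assert [v.pos for v in sd.variants] == [111, 222]
        sd_author = pk.parse_score_file(p, dialect="author_reported")
        assert [v.pos for v in sd_author.variants] == [100, 200]

    def test_empty_data_section_raises(self, tmp_path):
        p = _write_score(tmp_path / "s.txt", [])
        with pytest.raises(EmptyScoreError):
            pk.parse_score_file(p)

    def test_missing_required_column_named_in_error(self, tmp_path):
        p = _write_score(tmp_path / "s.txt", [("1", 100, "A", 0.5)],
                         columns="chr_name\tchr_position\teffect_allele\tweight")
        with pytest.raises(ScoreFileError, match="effect_weight"):
            pk.parse_score_file(p)

    def test_rows_without_position_or_allele_dropped(self, tmp_path):
        p = _write_score(tmp_path / "s.txt", [
            ("1", 100, "A", "G", 0.5),
            ("1", "", "C", "T", 0.1),
            ("1", 300, "", "T", 0.1),
        ])
        sd = pk.parse_score_file(p)
        assert len(sd.variants) == 1
        assert sd.n_dropped == 2

    def test_metadata_parsed(self, tmp_path):
        p = _write_score(tmp_path / "s.txt", [("1", 100, "A", "G", 0.5)],
                         header=("### header", "#pgs_id=PGS000027",
                                 "#trait_reported=BMI", "#populations=EUR,EAS",
                                 "#genome_build=GRCh37"))
        ann = pk.parse_score_file(p).annotation
        assert ann.score_id == "PGS000027"
        assert ann.trait == "BMI"
        assert ann.populations == frozenset({"EUR", "EAS"})
        assert ann.genome_build == "GRCh37"

    def test_absent_other_allele_kept(self, tmp_path):
        p = _write_score(tmp_path / "s.txt", [("1", 100, "A", ".", 0.5)])
        sd = pk.parse_score_file(p)
        assert sd.variants[0].other_allele is None


@pytest.mark.parametrize("raw,expected", [
    ("chr1", "1"), ("1", "1"), ("chrX", "X"), ("x", "X"),
    ("chrM", "MT"), ("MT", "MT"), ("22", "22"),
])
def test_chromosome_normalization(raw, expected):
    assert normalize_chrom(raw) == expected


def test_chrom_sort_order():
    names = ["X", "2", "MT", "1", "10", "Y"]
    assert sorted(names, key=chrom_sort_key) == ["1", "2", "10", "X", "Y", "MT"]


def _mk_score(sid, triples):
    variants = [pk.ScoreVariant(c, p, e, o, w) for c, p, e, o, w in triples]
    ann = pk.ScoreAnnotation(score_id=sid, n_variants=len(variants))
    return pk.ScoreDefinition(ann, variants)


class TestMergeScores:
    def test_shared_variant_union_row_count(self):
        a = _mk_score("A", [("1", 1, "A", "G", 1.0), ("1", 2, "C", "T", 2.0),
                            ("2", 5, "G", "A", 3.0)])
        b = _mk_score("B", [("1", 1, "A", "G", -1.0), ("1", 9, "T", "C", 0.5),
                            ("3", 4, "A", "C", 0.25)])
        repo = pk.merge_scores([a, b])
        assert len(repo.table) == 5  # |A ∪ B| = 3 + 3 - 1

    def test_single_score_identity(self):
        a = _mk_score("A", [("1", 1, "A", "G", 1.5), ("2", 2, "C", "T", -2.5)])
        repo = pk.merge_scores([a])
        assert len(repo.table) == 2
        got = {(r.CHROM, r.POS, r.OTHER, r.EFFECT): r.A
               for r in repo.table.itertuples()}
        for v in a.variants:
            assert got[v.key] == v.weight

    def test_duplicate_score_id_rejected(self):
        a = _mk_score("A", [("1", 1, "A", "G", 1.0)])
        with pytest.raises(RepositoryError, match="duplicate"):
            pk.merge_scores([a, a])

    def test_fifty_random_scores_every_cell_matches_source(self):
        rng = np.random.default_rng(11)
        keys = [("1", int(p), "A", "G") for p in rng.choice(10_000, 800, replace=False)]
        scores = []
        for s in range(50):
            picks = rng.choice(len(keys), size=rng.integers(5, 40), replace=False)
            scores.append(_mk_score(
                f"S{s}", [(keys[i][0], keys[i][1], keys[i][3], keys[i][2],
                           float(rng.normal())) for i in picks]))
        repo = pk.merge_scores(scores)
        union = {v.key for s in scores for v in s.variants}
        assert len(repo.table) == len(union)
        lookup = repo.table.set_index(["CHROM", "POS", "OTHER", "EFFECT"])
        for s in scores:
            sid = s.annotation.score_id
            col = lookup[sid]
            # every (variant, score) weight identical to the source
            for v in s.variants:
                assert col.loc[v.key] == v.weight
            # annotation conservation: non-absent cells == n_variants
            assert col.notna().sum() == s.annotation.n_variants


@pytest.fixture(scope="module")
def written(tmp_path_factory):
    rng = np.random.default_rng(5)
    scores = []
    for s in range(6):
        rows = []
        for _ in range(60):
            chrom = str(rng.integers(1, 4))
            pos = int(rng.integers(1, 50_000_000))
            rows.append((chrom, pos, "A", "G", float(rng.normal())))
        scores.append(_mk_score(f"S{s}", rows))
    repo = pk.merge_scores(scores)
    prefix = str(tmp_path_factory.mktemp("repo") / "repo")
    paths = pk.write_repository(repo, prefix)
    return repo, pk.load_repository(prefix), paths


class TestRepositoryRoundTrip:

    def test_files_written(self, written):
        import os
        _, _, paths = written
        assert all(os.path.exists(p) for p in paths.values())
        assert paths["index"].endswith(".tbi")

    def test_interval_queries_match_linear_scan(self, written):
        repo, indexed, _ = written
        rng = np.random.default_rng(17)
        for _ in range(50):
            chrom = str(rng.integers(1, 4))
            a = int(rng.integers(1, 50_000_000))
            b = int(rng.integers(1, 50_000_000))
            start, end = min(a, b), max(a, b)
            mem = repo.query_interval(chrom, start, end)
            disk = indexed.query_interval(chrom, start, end)
            pd.testing.assert_frame_equal(mem, disk, check_exact=True)

    def test_20mb_query_equals_linear_scan(self, written):
        repo, indexed, _ = written
        got = indexed.query_interval("1", 1, 20_000_000)
        t = repo.table
        expect = t[(t.CHROM == "1") & (t.POS <= 20_000_000)].reset_index(drop=True)
        pd.testing.assert_frame_equal(got, expect, check_exact=True)

    def test_empty_and_unknown_chrom_queries(self, written):
        _, indexed, _ = written
        assert len(indexed.query_interval("1", 1, 1)) in (0, 1)
        assert len(indexed.query_interval("99", 1, 10**9)) == 0

    def test_annotations_round_trip(self, written):
        repo, indexed, _ = written
        assert set(indexed.score_ids) == set(repo.score_ids)
        for sid, ann in repo.annotations.items():
            assert indexed.annotations[sid].n_variants == ann.n_variants


def test_unsorted_rows_rejected_on_write(tmp_path):
    a = _mk_score("A", [("1", 10, "A", "G", 1.0), ("1", 5, "C", "T", 1.0)])
    repo = pk.merge_scores([a])
    repo.table = repo.table.iloc[::-1].reset_index(drop=True)
    with pytest.raises(RepositoryError, match="sorted"):
        pk.write_repository(repo, str(tmp_path / "r"))
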