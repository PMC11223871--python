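"""Scoring-file parsing and the unified, indexed multi-score weight repository.

A *scoring file* (PGS Catalog flavour) lists the variants of one published
polygenic score: genomic position, effect allele, optional other (non-effect)
allele and the per-allele weight beta.  Many scores are merged into a single
*unified repository*: one coordinate-sorted table with a row per distinct
variant key ``(chrom, pos, other_allele, effect_allele)`` and one weight
column per score, written as a bgzip-compressed TSV with a Tabix index so
that any genomic interval can be extracted efficiently.
"""

from __future__ import annotations

import io
import logging
import os
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .errors import EmptyScoreError, RepositoryError, ScoreFileError

logger = logging.getLogger(__name__)

#: The seven GWAS Catalog super-population codes.
SUPER_POPULATIONS = ("AFR", "EUR", "GME", "EAS", "SAS", "AMR", "OTH")

#: Placeholder used in repository files for an absent allele or weight.
ABSENT = "."

_CHROM_ORDER = {str(i): i for i in range(1, 23)}
_CHROM_ORDER.update({"X": 23, "Y": 24, "MT": 25})


def normalize_chrom(name: str) -> str:
    """Strip a leading ``chr`` prefix and canonicalize X/Y/MT."""
    s = str(name).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.upper() in ("X", "Y", "MT"):
        return s.upper()
    if s.upper() == "M":
        return "MT"
    return s


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Sort key: 1..22, X, Y, MT, then anything else lexicographically."""
    return (_CHROM_ORDER.get(chrom, 99), chrom)


@dataclass(frozen=True)
class ScoreVariant:
    """One weighted variant of a polygenic score."""

    chrom: str
    pos: int
    effect_allele: str
    other_allele: str | None
    weight: float

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Repository row key ``(chrom, pos, other, effect)``; absent other is '.'."""
        return (self.chrom, self.pos, self.other_allele or ABSENT, self.effect_allele)


@dataclass
class ScoreAnnotation:
    """Per-score metadata carried alongside the weights."""

    score_id: str
    trait: str = ""
    populations: frozenset[str] = frozenset()
    gwas_sample_count: int | None = None
    publication: str = ""
    genome_build: str = ""
    n_variants: int = 0

    def __post_init__(self) -> None:
        bad = set(self.populations) - set(SUPER_POPULATIONS)
        if bad:
            raise ScoreFileError(
                f"{self.score_id}: unknown population code(s) {sorted(bad)}; "
                f"allowed: {SUPER_POPULATIONS}"
            )


@dataclass
class ScoreDefinition:
    """A parsed scoring file: annotation plus ordered variants."""

    annotation: ScoreAnnotation
    variants: list[ScoreVariant]
    n_dropped: int = 0      # rows lacking position/effect allele or with bad values
    n_duplicates: int = 0   # duplicate variant keys collapsed (first kept)


_META_RE = re.compile(r"^#+\s*([A-Za-z0-9_]+)\s*=\s*(.*)$")


def _read_metadata(path: str) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path, "rt") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            m = _META_RE.match(line.rstrip("\n"))
            if m:
                meta[m.group(1).lower()] = m.group(2).strip()
    return meta


def _clean_allele(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip().upper()
    return s if s and s != ABSENT else None


def parse_score_file(path: str, dialect: str = "auto") -> ScoreDefinition:
    """Parse one PGS Catalog-style scoring file.

    Parameters
    ----------
    path:
        Tab-delimited scoring file; ``#``-prefixed ``key=value`` header lines
        carry metadata (``pgs_id``, ``trait_reported``, ...).
    dialect:
        ``auto`` uses harmonized ``hm_chr``/``hm_pos`` coordinates when both
        columns are present, otherwise author-reported ``chr_name``/
        ``chr_position``; ``harmonized`` and ``author_reported`` force one
        dialect and fail if its columns are missing.

    Rows lacking a position or effect allele are dropped and counted; of
    duplicate variant keys the first is kept and the rest counted.
    """
    if dialect not in ("auto", "author_reported", "harmonized"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if not os.path.exists(path):
        raise ScoreFileError(f"scoring file not found: {path}")
    meta = _read_metadata(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptyScoreError(f"{path}: no data section") from None

    cols = set(df.columns)
    has_hm = {"hm_chr", "hm_pos"} <= cols
    has_author = {"chr_name", "chr_position"} <= cols
    if dialect == "harmonized" and not has_hm:
        raise ScoreFileError(f"{path}: missing required column hm_chr/hm_pos")
    use_hm = has_hm if dialect == "auto" else (dialect == "harmonized")
    if not use_hm and not has_author:
        missing = "chr_name" if "chr_name" not in cols else "chr_position"
        raise ScoreFileError(f"{path}: missing required column {missing}")
    for col in ("effect_allele", "effect_weight"):
        if col not in cols:
            raise ScoreFileError(f"{path}: missing required column {col}")

    chrom_col, pos_col = ("hm_chr", "hm_pos") if use_hm else ("chr_name", "chr_position")

    variants: list[ScoreVariant] = []
    seen: set[tuple] = set()
    n_dropped = 0
    n_dup = 0
    for row in df.itertuples(index=False):
        rec = row._asdict()
        chrom_raw = rec.get(chrom_col)
        pos_raw = rec.get(pos_col)
        effect = _clean_allele(rec.get("effect_allele"))
        if chrom_raw is None or pd.isna(chrom_raw) or pd.isna(pos_raw) or effect is None:
            n_dropped += 1
            continue
        try:
            pos = int(float(pos_raw))
            weight = float(rec["effect_weight"])
        except (TypeError, ValueError):
            n_dropped += 1
            continue
        if pos < 1 or not np.isfinite(weight):
            n_dropped += 1
            continue
        other = _clean_allele(rec.get("other_allele"))
        if other == effect:
            n_dropped += 1
            continue
        sv = ScoreVariant(normalize_chrom(chrom_raw), pos, effect, other, weight)
        if sv.key in seen:
            n_dup += 1
            continue
        seen.add(sv.key)
        variants.append(sv)

    if not variants:
        raise EmptyScoreError(f"{path}: zero parseable variants")
    if n_dup:
        logger.warning("%s: dropped %d duplicate variant key(s), first kept", path, n_dup)
    if n_dropped:
        logger.warning("%s: dropped %d unparseable row(s)", path, n_dropped)

    score_id = meta.get("pgs_id") or os.path.basename(path).split(".")[0]
    pops = frozenset(
        p.strip().upper() for p in meta.get("populations", "").split(",") if p.strip()
    )
    gwas_n = None
    for key in ("gwas_sample_count", "n_samples", "samples_variants"):
        if key in meta:
            try:
                gwas_n = int(re.sub(r"[^\d]", "", meta[key]) or 0)
                break
            except ValueError:
                pass
    ann = ScoreAnnotation(
        score_id=score_id,
        trait=meta.get("trait_reported", ""),
        populations=pops,
        gwas_sample_count=gwas_n,
        publication=meta.get("citation", meta.get("publication", "")),
        genome_build=meta.get("genome_build", meta.get("hmpos_build", "")),
        n_variants=len(variants),
    )
    return ScoreDefinition(ann, variants, n_dropped=n_dropped, n_duplicates=n_dup)


_KEY_COLS = ["CHROM", "POS", "OTHER", "EFFECT"]


@dataclass
class UnifiedRepository:
    """Variant-grouped, coordinate-sorted multi-score weight table.

    ``table`` has columns CHROM, POS, OTHER, EFFECT followed by one float
    column per score id (NaN where the score lacks the variant).
    """

    table: pd.DataFrame
    annotations: dict[str, ScoreAnnotation] = field(default_factory=dict)

    @property
    def score_ids(self) -> list[str]:
        return [c for c in self.table.columns if c not in _KEY_COLS]

    def query_interval(self, chrom: str, start: int, end: int) -> pd.DataFrame:
        """Rows on ``chrom`` with ``start <= POS <= end`` (1-based inclusive)."""
        if start > end:
            raise RepositoryError(f"interval start {start} > end {end}")
        chrom = normalize_chrom(chrom)
        t = self.table
        mask = (t["CHROM"] == chrom) & (t["POS"] >= start) & (t["POS"] <= end)
        return t.loc[mask].reset_index(drop=True)

    def contig_extents(self) -> dict[str, int]:
        """Max position per chromosome, for chunking when no length is known."""
        return self.table.groupby("CHROM", sort=False)["POS"].max().to_dict()


def merge_scores(scores: list[ScoreDefinition]) -> UnifiedRepository:
    """Merge score definitions into one repository, grouping weights by variant.

    One row per distinct variant key; cell (row, score) is that score's
    weight or NaN.  Row count equals the size of the union of variant keys.
    """
    if not scores:
        raise RepositoryError("merge_scores requires at least one score")
    ids = [s.annotation.score_id for s in scores]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise RepositoryError(f"duplicate score_id(s): {dup}")

    cells: dict[tuple, dict[str, float]] = {}
    for s in scores:
        sid = s.annotation.score_id
        for v in s.variants:
            cells.setdefault(v.key, {})[sid] = v.weight

    keys = sorted(cells, key=lambda k: (chrom_sort_key(k[0]), k[1], k[2], k[3]))
    data = {
        "CHROM": [k[0] for k in keys],
        "POS": np.array([k[1] for k in keys], dtype=np.int64),
        "OTHER": [k[2] for k in keys],
        "EFFECT": [k[3] for k in keys],
    }
    table = pd.DataFrame(data)
    for sid in ids:
        table[sid] = np.array([cells[k].get(sid, np.nan) for k in keys], dtype=float)
    return UnifiedRepository(table, {s.annotation.score_id: s.annotation for s in scores})


def _annotation_path(out_prefix: str, score_id: str) -> str:
    return f"{out_prefix}.{score_id}.annot.txt"


def write_repository(repo: UnifiedRepository, out_prefix: str) -> dict[str, str]:
    """Write the repository as bgzipped TSV + Tabix index + annotation sidecars.

    Emits ``<prefix>.txt.gz`` (columns ``#CHROM POS OTHER EFFECT`` then one
    column per score, ``.`` for absent weights, coordinate-sorted),
    ``<prefix>.txt.gz.tbi`` and one ``key=value`` sidecar per score.
    Returns the paths of the written files.
    """
    t = repo.table
    coords = [(chrom_sort_key(c), p) for c, p in zip(t["CHROM"], t["POS"])]
    if coords != sorted(coords):
        raise RepositoryError("repository rows are not coordinate-sorted")

    plain = f"{out_prefix}.txt"
    bgz = plain + ".gz"
    with open(plain, "wt") as fh:
        fh.write("#" + "\t".join(_KEY_COLS + repo.score_ids) + "\n")
        buf = io.StringIO()
        out = t.copy()
        for sid in repo.score_ids:
            out[sid] = out[sid].map(lambda w: ABSENT if pd.isna(w) else repr(w))
        out.to_csv(buf, sep="\t", header=False, index=False)
        fh.write(buf.getvalue())
    pysam.tabix_compress(plain, bgz, force=True)
    os.remove(plain)
    pysam.tabix_index(bgz, seq_col=0, start_col=1, end_col=1, meta_char="#", force=True)

    paths = {"repository": bgz, "index": bgz + ".tbi"}
    for sid in repo.score_ids:
        ann = repo.annotations[sid]
        p = _annotation_path(out_prefix, sid)
        with open(p, "wt") as fh:
            fh.write(f"score_id={ann.score_id}\n")
            fh.write(f"trait={ann.trait}\n")
            fh.write(f"populations={','.join(sorted(ann.populations))}\n")
            fh.write(f"gwas_sample_count={ann.gwas_sample_count if ann.gwas_sample_count is not None else ''}\n")
            fh.write(f"publication={ann.publication}\n")
            fh.write(f"genome_build={ann.genome_build}\n")
            fh.write(f"n_variants={ann.n_variants}\n")
        paths[f"annotation:{sid}"] = p
    return paths


def load_repository(prefix: str) -> "IndexedRepository":
    """Open a written repository for Tabix-backed interval queries."""
    return IndexedRepository(prefix)


class IndexedRepository:
    """On-disk repository: bgzipped TSV queried through its Tabix index.

    Presents the same ``query_interval`` / ``score_ids`` / ``annotations``
    surface as :class:`UnifiedRepository`.
    """

    def __init__(self, prefix: str):
        self.path = f"{prefix}.txt.gz"
        if not os.path.exists(self.path):
            raise RepositoryError(f"repository file not found: {self.path}")
        if not os.path.exists(self.path + ".tbi"):
            raise RepositoryError(
                f"missing Tabix index {self.path}.tbi; rebuild with write_repository"
            )
        self._tabix = pysam.TabixFile(self.path)
        header = self._tabix.header[0].lstrip("#").split("\t")
        if header[:4] != _KEY_COLS:
            raise RepositoryError(f"{self.path}: unexpected header {header[:4]}")
        self._columns = header
        self.score_ids: list[str] = header[4:]
        self.annotations: dict[str, ScoreAnnotation] = {}
        for sid in self.score_ids:
            p = _annotation_path(prefix, sid)
            if os.path.exists(p):
                self.annotations[sid] = _read_annotation(p)

    def query_interval(self, chrom: str, start: int, end: int) -> pd.DataFrame:
        if start > end:
            raise RepositoryError(f"interval start {start} > end {end}")
        chrom = normalize_chrom(chrom)
        rows = []
        try:
            it = self._tabix.fetch(chrom, start - 1, end)
        except ValueError:  # unknown chromosome
            it = iter(())
        for line in it:
            rows.append(line.split("\t"))
        df = pd.DataFrame(rows, columns=self._columns) if rows else pd.DataFrame(
            columns=self._columns
        )
        df = df.rename(columns=dict(zip(self._columns[:4], _KEY_COLS)))
        df["POS"] = df["POS"].astype(np.int64) if len(df) else df["POS"].astype(np.int64)
        for sid in self.score_ids:
            if len(df):
                # float() round-trips repr() exactly; pd.to_numeric may be
                # off in the last ulp
                df[sid] = np.array(
                    [np.nan if v == ABSENT else float(v) for v in df[sid]])
            else:
                df[sid] = df[sid].astype(float)
        return df

    def contig_extents(self) -> dict[str, int]:
        extents: dict[str, int] = {}
        for contig in self._tabix.contigs:
            last = 0
            for line in self._tabix.fetch(contig):
                last = max(last, int(line.split("\t", 2)[1]))
            extents[contig] = last
        return extents

    def close(self) -> None:
        self._tabix.close()


def _read_annotation(path: str) -> ScoreAnnotation:
    kv: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if "=" in line:
                k, v = line.rstrip("\n").split("=", 1)
                kv[k] = v
    return ScoreAnnotation(
        score_id=kv.get("score_id", os.path.basename(path)),
        trait=kv.get("trait", ""),
        populations=frozenset(p for p in kv.get("populations", "").split(",") if p),
        gwas_sample_count=int(kv["gwas_sample_count"]) if kv.get("gwas_sample_count") else None,
        publication=kv.get("publication", ""),
        genome_build=kv.get("genome_build", ""),
        n_variants=int(kv.get("n_variants", 0)),
    )
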