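"""The scoring engine: allele matching, filters, and PGS accumulation.

For each individual j, the polygenic score is

    PGS_j = sum_i beta_i * D_ij

where beta_i is the published weight of variant i and D_ij the imputed
dosage of the *effect* allele.  The engine matches each score variant to a
VCF record, resolving strand flips by allele complementation (excluding
palindromic A/T and G/C SNVs, whose strand cannot be determined), inverts
the dosage (2 - D) when the effect allele corresponds to REF, filters on
imputation quality and missing dosages, and accumulates per-chunk partial
sums that are later merged in genomic order for bit-stable results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .dosage import DosageRecord
from .errors import ConfigError, DataError
from .repository import ScoreAnnotation, ScoreVariant, chrom_sort_key

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class MatchStatus(Enum):
    DIRECT = "DIRECT"                        # (effect, other) == (ALT, REF)
    SWAPPED = "SWAPPED"                      # effect allele is REF: dosage -> 2 - D
    FLIPPED = "FLIPPED"                      # direct match after complementing
    FLIPPED_SWAPPED = "FLIPPED_SWAPPED"      # swapped match after complementing
    EXCLUDED_PALINDROMIC = "EXCLUDED_PALINDROMIC"
    EXCLUDED_MISMATCH = "EXCLUDED_MISMATCH"

    @property
    def used(self) -> bool:
        return self in _USED


_USED = {
    MatchStatus.DIRECT,
    MatchStatus.SWAPPED,
    MatchStatus.FLIPPED,
    MatchStatus.FLIPPED_SWAPPED,
}

#: Audit vocabulary: why each score variant did or did not contribute.
REASONS = (
    "USED_DIRECT",
    "USED_SWAPPED",
    "USED_FLIPPED",
    "USED_FLIPPED_SWAPPED",
    "EXCLUDED_PALINDROMIC",
    "EXCLUDED_MISMATCH",
    "EXCLUDED_LOW_R2",
    "EXCLUDED_MISSING_DOSAGE",
    "NOT_FOUND",
)


@dataclass(frozen=True)
class VariantAudit:
    chrom: str
    pos: int
    other_allele: str
    effect_allele: str
    score_id: str
    reason: str


def is_palindromic(a: str, b: str) -> bool:
    """A/T or G/C allele pair: complementation maps it onto itself."""
    return {a, b} in ({"A", "T"}, {"C", "G"})


def _complement(allele: str) -> str | None:
    out = []
    for base in allele:
        c = _COMPLEMENT.get(base)
        if c is None:
            return None
        out.append(c)
    return "".join(out)


def match_alleles(
    sv: ScoreVariant, dr: DosageRecord, strand_mode: str = "resolve"
) -> MatchStatus:
    """Match a score variant's alleles against a biallelic VCF record.

    In ``resolve`` mode (the default), palindromic single-base pairs are
    excluded outright, and non-palindromic SNVs that fail a direct/swapped
    match are retried with complemented score alleles.  ``strict`` mode
    never complements and retains palindromic SNVs.  InDels (any allele
    longer than one base) and variants lacking the other allele are matched
    exactly, never flipped.
    """
    if strand_mode not in ("resolve", "strict"):
        raise ConfigError(f"unknown strand_mode {strand_mode!r}")
    e, o = sv.effect_allele, sv.other_allele
    ref, alt = dr.ref, dr.alt

    if o is None:
        if e == alt:
            return MatchStatus.DIRECT
        if e == ref:
            return MatchStatus.SWAPPED
        return MatchStatus.EXCLUDED_MISMATCH

    snv_pair = len(e) == 1 and len(o) == 1
    if strand_mode == "resolve" and snv_pair and is_palindromic(e, o):
        return MatchStatus.EXCLUDED_PALINDROMIC

    if (e, o) == (alt, ref):
        return MatchStatus.DIRECT
    if (e, o) == (ref, alt):
        return MatchStatus.SWAPPED

    if strand_mode == "resolve" and snv_pair and len(ref) == 1 and len(alt) == 1:
        ce, co = _complement(e), _complement(o)
        if ce is not None and co is not None:
            if (ce, co) == (alt, ref):
                return MatchStatus.FLIPPED
            if (ce, co) == (ref, alt):
                return MatchStatus.FLIPPED_SWAPPED
    return MatchStatus.EXCLUDED_MISMATCH


def effect_dosage(match: MatchStatus, alt_dosage):
    """Effect-allele dosage given the ALT dosage and the match orientation.

    When the effect allele corresponds to REF (SWAPPED variants) the weight
    direction is inverted by taking 2 - D.  Accepts scalars or arrays.
    """
    if match in (MatchStatus.DIRECT, MatchStatus.FLIPPED):
        return alt_dosage
    if match in (MatchStatus.SWAPPED, MatchStatus.FLIPPED_SWAPPED):
        return 2.0 - alt_dosage
    raise DataError(f"effect_dosage called with excluded status {match}")


@dataclass
class PartialScore:
    """Per-chunk running sums of beta * D_effect and usage audit."""

    chunk_id: int
    score_ids: list[str]
    samples: list[str]
    sums: np.ndarray                 # (n_scores, n_samples)
    used: np.ndarray                 # per-score count of contributing variants
    audits: list[VariantAudit] = field(default_factory=list)
    interval: tuple[str, int, int] | None = None
    n_multi_record_warnings: int = 0


@dataclass
class ScoreResult:
    """Final per-sample scores with per-score coverage and audits."""

    samples: list[str]
    score_ids: list[str]
    values: np.ndarray               # (n_samples, n_scores)
    n_total: dict[str, int]
    n_used: dict[str, int]
    coverage: dict[str, float]
    coverage_class: dict[str, str]
    audits: list[VariantAudit]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.samples, name="sample"),
                            columns=self.score_ids)

    def stats_frame(self) -> pd.DataFrame:
        rows = [
            {
                "score_id": s,
                "n_total": self.n_total[s],
                "n_used": self.n_used[s],
                "coverage": self.coverage[s],
                "coverage_class": self.coverage_class[s],
            }
            for s in self.score_ids
        ]
        return pd.DataFrame(rows)


def classify_coverage(coverage: float) -> str:
    """HIGH above 0.75, LOW below 0.25, MEDIUM in between (bounds inclusive)."""
    if not (0.0 <= coverage <= 1.0):
        raise DataError(f"coverage {coverage} outside [0,1]")
    if coverage > 0.75:
        return "HIGH"
    if coverage < 0.25:
        return "LOW"
    return "MEDIUM"


def score_chunk(
    records,
    repo_rows: pd.DataFrame,
    samples: list[str],
    min_r2: float = 0.3,
    strand_mode: str = "resolve",
    chunk_id: int = 0,
    interval: tuple[str, int, int] | None = None,
) -> PartialScore:
    """Score one genomic chunk.

    ``records`` is a stream of :class:`DosageRecord` restricted to the same
    interval as ``repo_rows`` (a repository interval query).  For every
    repository row the first VCF record (in file order) with a usable allele
    match contributes ``beta * D_effect`` to every score holding a weight at
    that row — unless the record's imputation quality is below ``min_r2``
    (quality-less records pass) or any sample's dosage is missing, in which
    case the variant is dropped for *all* samples so that samples with
    missing genotypes do not get systematically lower scores.  Contributions
    are accumulated in sorted variant-key order for determinism.
    """
    if not (0.0 <= min_r2 <= 1.0):
        raise ConfigError(f"min_r2 {min_r2} outside [0,1]")
    score_ids = [c for c in repo_rows.columns if c not in ("CHROM", "POS", "OTHER", "EFFECT")]
    n_scores, n_samples = len(score_ids), len(samples)
    sums = np.zeros((n_scores, n_samples))
    used = np.zeros(n_scores, dtype=np.int64)
    audits: list[VariantAudit] = []
    n_multi = 0

    by_pos: dict[tuple[str, int], list[DosageRecord]] = {}
    for rec in records:
        if rec.n_samples != n_samples:
            raise DataError(
                f"record {rec.chrom}:{rec.pos} has {rec.n_samples} samples, "
                f"expected {n_samples}"
            )
        by_pos.setdefault((rec.chrom, rec.pos), []).append(rec)

    rows = sorted(
        repo_rows.itertuples(index=False),
        key=lambda r: (chrom_sort_key(r.CHROM), r.POS, r.OTHER, r.EFFECT),
    )
    weight_cols = {sid: i for i, sid in enumerate(score_ids)}

    for row in rows:
        other = None if row.OTHER == "." else row.OTHER
        sv = ScoreVariant(row.CHROM, int(row.POS), row.EFFECT, other, 0.0)
        candidates = by_pos.get((row.CHROM, int(row.POS)), [])
        matched: list[tuple[MatchStatus, DosageRecord]] = []
        saw_palindromic = False
        for rec in candidates:
            st = match_alleles(sv, rec, strand_mode)
            if st.used:
                matched.append((st, rec))
            elif st is MatchStatus.EXCLUDED_PALINDROMIC:
                saw_palindromic = True

        if not candidates:
            reason = "NOT_FOUND"
            status_rec = None
        elif not matched:
            reason = "EXCLUDED_PALINDROMIC" if saw_palindromic else "EXCLUDED_MISMATCH"
            status_rec = None
        else:
            if len(matched) > 1:
                n_multi += 1
            status, rec = matched[0]
            if rec.quality is not None and rec.quality < min_r2:
                reason = "EXCLUDED_LOW_R2"
                status_rec = None
            elif np.isnan(rec.dosages).any():
                reason = "EXCLUDED_MISSING_DOSAGE"
                status_rec = None
            else:
                reason = f"USED_{status.value}"
                status_rec = (status, rec)

        row_dict = row._asdict()
        if status_rec is not None:
            status, rec = status_rec
            d_eff = effect_dosage(status, rec.dosages)
            for sid, col in weight_cols.items():
                w = row_dict[sid]
                if not pd.isna(w):
                    sums[col] += float(w) * d_eff
                    used[col] += 1
        for sid in score_ids:
            if not pd.isna(row_dict[sid]):
                audits.append(
                    VariantAudit(row.CHROM, int(row.POS), row.OTHER, row.EFFECT, sid, reason)
                )

    return PartialScore(
        chunk_id=chunk_id, score_ids=score_ids, samples=list(samples),
        sums=sums, used=used, audits=audits, interval=interval,
        n_multi_record_warnings=n_multi,
    )


def aggregate(
    partials: list[PartialScore],
    annotations: dict[str, ScoreAnnotation],
) -> ScoreResult:
    """Merge disjoint per-chunk partial scores into final scores.

    Chunks are summed in chunk-ordinal (genomic) order so the result is
    independent of how many workers produced the partials.  Coverage is
    n_used / n_total per score, classified HIGH / MEDIUM / LOW.
    """
    if not partials:
        raise DataError("aggregate requires at least one partial score")
    first = partials[0]
    for p in partials[1:]:
        if p.score_ids != first.score_ids or p.samples != first.samples:
            raise DataError("partial scores disagree on score ids or samples")
    seen: list[tuple[str, int, int]] = []
    for p in partials:
        if p.interval is None:
            continue
        c, s, e = p.interval
        for (c2, s2, e2) in seen:
            if c == c2 and s <= e2 and s2 <= e:
                raise DataError(f"overlapping chunks: {p.interval} vs {(c2, s2, e2)}")
        seen.append((c, s, e))

    ordered = sorted(partials, key=lambda p: p.chunk_id)
    sums = np.zeros_like(first.sums)
    used = np.zeros_like(first.used)
    audits: list[VariantAudit] = []
    for p in ordered:
        sums += p.sums
        used += p.used
        audits.extend(p.audits)

    n_total, n_used, cov, cls = {}, {}, {}, {}
    for i, sid in enumerate(first.score_ids):
        ann = annotations.get(sid)
        total = ann.n_variants if ann is not None else int(used[i])
        n_total[sid] = total
        n_used[sid] = int(used[i])
        c = (used[i] / total) if total else 0.0
        cov[sid] = float(c)
        cls[sid] = classify_coverage(float(c))
    return ScoreResult(
        samples=first.samples, score_ids=first.score_ids, values=sums.T.copy(),
        n_total=n_total, n_used=n_used, coverage=cov, coverage_class=cls,
        audits=audits,
    )
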