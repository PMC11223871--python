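"""Reading imputed-genotype VCFs into per-site dosage records.

Each biallelic ALT of each VCF record becomes one :class:`DosageRecord`
carrying the per-sample expected ALT-allele count (DS in [0, 2], falling back
to the hard-call count from GT) and the per-variant imputation quality
(INFO R2, with ER2 accepted as alias).  Missing dosages are NaN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pysam

from .errors import VcfError

logger = logging.getLogger(__name__)


@dataclass
class DosageRecord:
    """One biallelic site with per-sample effect(ALT)-allele dosages."""

    chrom: str
    pos: int
    ref: str
    alt: str
    dosages: np.ndarray        # float per sample; NaN = missing
    quality: float | None      # imputation r2 in [0,1], None if absent
    typed: bool = False        # genotyped rather than imputed

    @property
    def n_samples(self) -> int:
        return len(self.dosages)


def vcf_samples(path: str) -> list[str]:
    with pysam.VariantFile(path) as vf:
        return list(vf.header.samples)


def vcf_contigs(path: str) -> dict[str, int | None]:
    """Contig name -> declared length (None when the header omits it)."""
    with pysam.VariantFile(path) as vf:
        return {name: c.length for name, c in vf.header.contigs.items()}


def _f32_text(x) -> float:
    """Recover the decimal a VCF Float field was written as.

    htslib parses Float fields into float32; converting straight to Python
    float would keep the float32 representation error (0.1234 becomes
    0.12340000271...).  The shortest repr of the float32 value is exactly
    the decimal literal in the file whenever it has <= 7 significant digits.
    """
    return float(np.format_float_positional(np.float32(x)))


def _per_allele(value, n_alts: int):
    """Normalize a FORMAT/INFO value to a tuple of length n_alts, or None."""
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        return tuple(value)
    return (value,)


def read_dosages(
    vcf: str,
    region: tuple[str, int, int] | None = None,
    quality_field: str = "R2",
):
    """Stream :class:`DosageRecord` objects from a VCF.

    Parameters
    ----------
    vcf:
        Path to a VCF, optionally bgzipped + Tabix/CSI indexed (an index is
        required for region queries).
    region:
        ``(chrom, start, end)``, 1-based inclusive, or None for the whole file.
    quality_field:
        INFO key holding imputation quality; ``ER2`` is always accepted as an
        alias (imputation servers emit R2 for imputed and ER2 for genotyped
        sites).

    Multi-allelic records are emitted once per ALT when DS is per-allele;
    otherwise they are skipped with a warning.  DS takes precedence over GT
    per sample; a sample with neither carries NaN.  A DS outside [0, 2]
    raises :class:`~pgsdesk.errors.VcfError` (it signals wrong field
    semantics and must not be silently clamped).
    """
    try:
        vf = pysam.VariantFile(vcf)
    except (OSError, ValueError) as exc:
        raise VcfError(f"cannot open VCF {vcf}: {exc}") from exc
    with vf:
        if region is not None:
            chrom, start, end = region
            try:
                it = vf.fetch(chrom, start - 1, end)
            except ValueError as exc:
                raise VcfError(
                    f"{vcf}: region query needs a Tabix/CSI index "
                    f"(bgzip the file and run `tabix -p vcf`): {exc}"
                ) from exc
        else:
            it = vf
        try:
            yield from _records(vcf, it, quality_field)
        except VcfError:
            raise
        except Exception as exc:  # malformed record mid-stream
            raise VcfError(f"{vcf}: malformed VCF record: {exc}") from exc


def _records(path: str, it, quality_field: str):
    for rec in it:
        alts = rec.alts or ()
        n_alts = len(alts)
        if n_alts == 0:
            continue

        quality = None
        for key in (quality_field, "ER2"):
            if key in rec.info:
                raw = rec.info[key]
                if isinstance(raw, (tuple, list)):
                    raw = raw[0]
                quality = _f32_text(raw)
                break
        if quality is not None and not (0.0 <= quality <= 1.0):
            raise VcfError(
                f"{path}:{rec.chrom}:{rec.pos}: quality {quality} outside [0,1]"
            )
        typed = any(k in rec.info for k in ("TYPED", "GENOTYPED", "TYPED_ONLY"))

        n_samples = len(rec.samples)
        ds_rows = []
        ds_ok = True
        for sample in rec.samples.values():
            ds = _per_allele(sample.get("DS"), n_alts)
            if ds is not None and n_alts > 1 and len(ds) != n_alts:
                ds_ok = False
            ds_rows.append(ds)
        if not ds_ok:
            logger.warning(
                "%s:%s:%d multi-allelic record without per-allele DS; skipped",
                path, rec.chrom, rec.pos,
            )
            continue

        for a in range(n_alts):
            dosages = np.full(n_samples, np.nan)
            for j, sample in enumerate(rec.samples.values()):
                ds = ds_rows[j]
                val = None
                if ds is not None and a < len(ds) and ds[a] is not None:
                    val = _f32_text(ds[a])
                else:
                    gt = sample.get("GT")
                    if gt is not None and not all(g is None for g in gt):
                        val = float(sum(1 for g in gt if g == a + 1))
                if val is not None:
                    if not (0.0 <= val <= 2.0):
                        raise VcfError(
                            f"{path}:{rec.chrom}:{rec.pos}: dosage {val} outside "
                            f"[0,2] for sample index {j}"
                        )
                    dosages[j] = val
            yield DosageRecord(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=str(rec.ref).upper(),
                alt=str(alts[a]).upper(),
                dosages=dosages,
                quality=quality,
                typed=typed,
            )
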