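"""Fixed-size genomic chunking and the chunked scoring driver.

The genome is tiled into fixed-size chunks (default 20 Mb); each chunk is
scored independently — repository rows come from a Tabix interval query,
dosages from a VCF region query — and the per-chunk sub-scores are summed
into the final scores.  Workers may run concurrently, but partials are
always merged in chunk-ordinal order, so the result is bit-stable across
worker counts and chunk sizes.
"""

from __future__ import annotations

import threading
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass

from .dosage import read_dosages, vcf_contigs, vcf_samples
from .errors import ConfigError, DataError
from .repository import chrom_sort_key
from .scoring import ScoreResult, aggregate, score_chunk


@dataclass(frozen=True)
class Chunk:
    chrom: str
    start: int          # 1-based inclusive
    end: int            # 1-based inclusive
    ordinal: int


def make_chunks(contigs: dict[str, int], chunk_size_mb: int = 20) -> list[Chunk]:
    """Tile each contig with ceil(L/S) non-overlapping chunks of size S.

    ``contigs`` maps contig name to its length (or the largest observed
    position).  Chunk k of a contig spans [(k-1)*S + 1, k*S], the last one
    truncated at the contig length; chunks are returned in genomic order.
    """
    if not contigs:
        raise DataError("empty contig set")
    if chunk_size_mb < 1:
        raise ConfigError(f"chunk_size_mb must be >= 1, got {chunk_size_mb}")
    size = chunk_size_mb * 10**6
    chunks: list[Chunk] = []
    ordinal = 0
    for name in sorted(contigs, key=chrom_sort_key):
        length = int(contigs[name])
        if length < 1:
            raise DataError(f"contig {name} has non-positive length {length}")
        start = 1
        while start <= length:
            chunks.append(Chunk(name, start, min(start + size - 1, length), ordinal))
            ordinal += 1
            start += size
    return chunks


def run_scoring(
    vcfs: list[str],
    repo,
    min_r2: float = 0.3,
    strand_mode: str = "resolve",
    chunk_size_mb: int = 20,
    threads: int = 1,
    quality_field: str = "R2",
) -> ScoreResult:
    """Score all samples of one or more (per-chromosome) VCFs against a repository.

    ``repo`` is a :class:`~pgsdesk.repository.UnifiedRepository` or
    :class:`~pgsdesk.repository.IndexedRepository`.  Contig lengths come
    from the VCF headers, falling back to the largest position seen in the
    repository for contigs declared without a length.
    """
    if not vcfs:
        raise DataError("no VCF inputs")
    if threads < 1:
        raise ConfigError(f"threads must be >= 1, got {threads}")

    samples = vcf_samples(vcfs[0])
    chrom_to_vcf: dict[str, str] = {}
    lengths: dict[str, int] = {}
    repo_extents = repo.contig_extents()
    for path in vcfs:
        if vcf_samples(path) != samples:
            raise DataError(f"{path}: sample set differs from {vcfs[0]}")
        for name, length in vcf_contigs(path).items():
            chrom_to_vcf.setdefault(name, path)
            if length:
                lengths[name] = max(lengths.get(name, 0), int(length))
            elif name in repo_extents:
                lengths[name] = max(lengths.get(name, 0), int(repo_extents[name]))
    if not lengths:
        raise DataError("no contig lengths available from VCF headers or repository")

    chunks = make_chunks(lengths, chunk_size_mb)

    repo_lock = threading.Lock()  # TabixFile handles are not thread-safe

    def score_one(chunk: Chunk):
        with repo_lock:
            rows = repo.query_interval(chunk.chrom, chunk.start, chunk.end)
        records = read_dosages(
            chrom_to_vcf[chunk.chrom],
            region=(chunk.chrom, chunk.start, chunk.end),
            quality_field=quality_field,
        )
        return score_chunk(
            records, rows, samples, min_r2=min_r2, strand_mode=strand_mode,
            chunk_id=chunk.ordinal, interval=(chunk.chrom, chunk.start, chunk.end),
        )

    if threads == 1:
        partials = [score_one(c) for c in chunks]
    else:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            partials = list(pool.map(score_one, chunks))
    return aggregate(partials, repo.annotations)
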