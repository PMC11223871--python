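"""PCA-based ancestry estimation with inverse-distance-weighted K-NN voting.

A reference panel of genotyped individuals with known super-population
labels (e.g. HGDP) defines a PC space: genotypes are centered by twice the
reference allele frequency and scaled by sqrt(2p(1-p)), and the top
principal components (default 10) are retained.  Study samples are
projected onto the reference loadings with the reference standardization
(missing genotypes mean-imputed to zero after centering), and classified by
their k = 20 nearest reference samples in Euclidean distance, each neighbor
voting its label with weight 1/distance.  A sample is assigned a label only
when that label holds strictly more than 75% of the total weighted vote;
otherwise it is left UNCLASSIFIED (typically admixed individuals sitting
between reference clusters).

The seven super-population codes are AFR, EUR, GME, EAS, SAS, AMR and OTH.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .dosage import read_dosages, vcf_samples
from .errors import ConfigError, DataError
from .repository import SUPER_POPULATIONS

UNCLASSIFIED = "UNCLASSIFIED"

_EPS = 1e-12  # inverse-distance regularizer: zero-distance neighbors dominate


@dataclass
class PcaSpace:
    """Reference PC space: per-SNP standardization, loadings, labeled coords."""

    snps: list[tuple]          # variant keys, e.g. (chrom, pos, ref, alt)
    freqs: np.ndarray          # reference allele frequency p per SNP
    scales: np.ndarray         # sqrt(2 p (1-p)) per SNP
    loadings: np.ndarray       # (n_snps, n_pcs)
    ref_coords: np.ndarray     # (n_ref, n_pcs)
    ref_labels: list[str]
    n_pcs: int


@dataclass
class AncestryCall:
    sample: str
    coords: np.ndarray
    label: str                          # one of the 7 codes or UNCLASSIFIED
    vote_fractions: dict[str, float]    # sums to 1 over codes that received votes


def fit_reference_pca(
    ref_genotypes: np.ndarray,
    ref_labels: list[str],
    snp_keys: list[tuple] | None = None,
    n_pcs: int = 10,
    maf_min: float = 0.01,
) -> PcaSpace:
    """Build the labeled reference PC space from a samples x SNPs dosage matrix.

    SNPs with minor allele frequency below ``maf_min`` are dropped.
    Genotypes are standardized to (g - 2p) / sqrt(2p(1-p)) before the PCA,
    so each SNP contributes on the drift scale rather than proportionally
    to its frequency.
    """
    X = np.asarray(ref_genotypes, dtype=float)
    n, m = X.shape
    if len(ref_labels) != n:
        raise DataError(f"{n} samples but {len(ref_labels)} labels")
    bad = set(ref_labels) - set(SUPER_POPULATIONS)
    if bad:
        raise DataError(f"unknown population label(s): {sorted(bad)}")
    if n <= n_pcs:
        raise DataError(f"need more than n_pcs={n_pcs} samples, got {n}")
    if snp_keys is None:
        snp_keys = [("SNP", i) for i in range(m)]
    if len(snp_keys) != m:
        raise DataError("snp_keys length does not match genotype columns")

    p = X.mean(axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    keep = maf >= maf_min
    if int(keep.sum()) < n_pcs:
        raise DataError(
            f"only {int(keep.sum())} SNPs pass MAF >= {maf_min}; need >= {n_pcs}"
        )
    X = X[:, keep]
    p = p[keep]
    scales = np.sqrt(2.0 * p * (1.0 - p))
    Z = (X - 2.0 * p) / scales

    pca = PCA(n_components=n_pcs, svd_solver="full")
    coords = pca.fit_transform(Z)
    return PcaSpace(
        snps=[k for k, kp in zip(snp_keys, keep) if kp],
        freqs=p,
        scales=scales,
        loadings=pca.components_.T.copy(),
        ref_coords=coords,
        ref_labels=list(ref_labels),
        n_pcs=n_pcs,
    )


def project_samples(
    space: PcaSpace,
    genotypes: np.ndarray,
    snp_keys: list[tuple] | None = None,
    min_overlap: float = 0.5,
) -> np.ndarray:
    """Project study dosages into the reference PC space.

    Study values are standardized with the *reference* frequencies and
    scales; missing values (NaN, or SNPs absent from the study data) are
    set to zero after centering, i.e. mean-imputed.  When ``snp_keys`` is
    given, study columns are aligned to ``space.snps`` by key and the
    overlap must reach ``min_overlap``; otherwise the columns are assumed
    to already match ``space.snps``.
    """
    G = np.asarray(genotypes, dtype=float)
    if G.ndim == 1:
        G = G[None, :]
    m = len(space.snps)
    if snp_keys is not None:
        idx = {k: i for i, k in enumerate(snp_keys)}
        aligned = np.full((G.shape[0], m), np.nan)
        hits = 0
        for j, key in enumerate(space.snps):
            i = idx.get(key)
            if i is not None:
                aligned[:, j] = G[:, i]
                hits += 1
        overlap = hits / m
        if overlap < min_overlap:
            raise DataError(
                f"study data covers only {overlap:.1%} of the reference SNPs "
                f"(minimum {min_overlap:.0%})"
            )
        G = aligned
    elif G.shape[1] != m:
        raise DataError(f"expected {m} SNP columns, got {G.shape[1]}")

    Z = (G - 2.0 * space.freqs) / space.scales
    Z[~np.isfinite(Z)] = 0.0
    return Z @ space.loadings


def classify_knn(
    coords: np.ndarray,
    space: PcaSpace,
    k: int = 20,
    vote_threshold: float = 0.75,
    sample: str = "",
) -> AncestryCall:
    """Assign a super population by inverse-distance-weighted K-NN vote.

    Euclidean distance over the first ``space.n_pcs`` PCs; the k nearest
    reference samples (ties at the k-th distance broken by reference input
    order) vote their label with weight 1/(d + 1e-12).  The winning label
    must hold strictly more than ``vote_threshold`` of the total weight,
    else the sample is UNCLASSIFIED.
    """
    if k <= 0:
        raise ConfigError(f"k must be positive, got {k}")
    if not (0.0 < vote_threshold <= 1.0):
        raise ConfigError(f"vote_threshold must be in (0,1], got {vote_threshold}")
    n_ref = space.ref_coords.shape[0]
    if k > n_ref:
        raise ConfigError(f"k={k} exceeds the {n_ref} reference samples")

    coords = np.asarray(coords, dtype=float).ravel()[: space.n_pcs]
    d = np.sqrt(((space.ref_coords[:, : space.n_pcs] - coords) ** 2).sum(axis=1))
    nearest = np.argsort(d, kind="stable")[:k]
    w = 1.0 / (d[nearest] + _EPS)
    total = w.sum()
    fractions: dict[str, float] = {}
    for i, wi in zip(nearest, w):
        lab = space.ref_labels[i]
        fractions[lab] = fractions.get(lab, 0.0) + wi / total
    best = max(fractions, key=lambda c: fractions[c])
    label = best if fractions[best] > vote_threshold else UNCLASSIFIED
    return AncestryCall(sample=sample, coords=coords, label=label,
                        vote_fractions=fractions)


def classify_samples(
    coords: np.ndarray,
    space: PcaSpace,
    samples: list[str] | None = None,
    k: int = 20,
    vote_threshold: float = 0.75,
) -> list[AncestryCall]:
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if samples is None:
        samples = [f"sample{i}" for i in range(coords.shape[0])]
    return [
        classify_knn(coords[i], space, k=k, vote_threshold=vote_threshold,
                     sample=samples[i])
        for i in range(coords.shape[0])
    ]


def match_population(call: AncestryCall, ann) -> str:
    """Decide whether a sample enters a score's summary statistics.

    Unclassified samples are always excluded; classified samples are
    excluded when their population is not among the populations of the GWAS
    the score was built from.
    """
    if call.label == UNCLASSIFIED:
        return "EXCLUDED_UNCLASSIFIED"
    if call.label not in ann.populations:
        return "EXCLUDED_POP_MISMATCH"
    return "INCLUDED"


# ---------------------------------------------------------------------------
# panel I/O helpers

def dosage_matrix_from_vcf(path: str, region=None):
    """Read a VCF into (samples, snp_keys, matrix) with ALT dosages in [0,2]."""
    samples = vcf_samples(path)
    keys: list[tuple] = []
    rows: list[np.ndarray] = []
    for rec in read_dosages(path, region=region):
        keys.append((rec.chrom, rec.pos, rec.ref, rec.alt))
        rows.append(rec.dosages)
    if not rows:
        raise DataError(f"{path}: no biallelic records")
    return samples, keys, np.column_stack(rows)


def read_labels(path: str) -> dict[str, str]:
    """Two-column sample -> super-population TSV (header optional)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise DataError(f"{path}: expected two tab-separated columns")
    if df.iloc[0, 1] not in SUPER_POPULATIONS:  # header row
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_pcs_tsv(samples: list[str], coords: np.ndarray, path: str) -> None:
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    pd.DataFrame(coords, index=pd.Index(samples, name="sample"), columns=cols).to_csv(
        path, sep="\t"
    )


def write_populations_tsv(calls: list[AncestryCall], path: str) -> None:
    rows = []
    for c in calls:
        row = {"sample": c.sample, "population": c.label}
        for code in SUPER_POPULATIONS:
            row[f"vote_{code}"] = c.vote_fractions.get(code, 0.0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_populations_tsv(path: str) -> list[AncestryCall]:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    calls = []
    for row in df.itertuples(index=False):
        votes = {
            code: float(getattr(row, f"vote_{code}", 0.0))
            for code in SUPER_POPULATIONS
            if getattr(row, f"vote_{code}", 0.0) > 0
        }
        calls.append(AncestryCall(sample=row.sample, coords=np.empty(0),
                                  label=row.population, vote_fractions=votes))
    return calls
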