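"""Synthetic fixtures with known ground truth.

Population structure follows the Balding–Nichols model: each SNP draws an
ancestral frequency p ~ Uniform(0.05, 0.95) and every population draws its
own frequency from Beta(p(1-F)/F, (1-p)(1-F)/F), so the divergence
parameter F plays the role of Fst.  Reference individuals carry hard-call
genotypes Binomial(2, p_pop); study individuals additionally receive
truncated-Gaussian dosage noise (sd 0.05, clipped to [0, 2]) to mimic
imputation uncertainty, a per-variant imputation r2 (high, except a
configurable fraction pushed below the 0.3 filter default), and optional
missing entries.

Score files are drawn from the simulated sites and deliberately include
swapped-orientation entries (effect allele written as REF), strand-flipped
entries (both alleles complemented), palindromic sites and variants absent
from the VCF, so every matching and filtering path is exercised; a naive
summation oracle honoring every exclusion rule is produced alongside.

Everything is driven by a single integer seed; identical seeds give
byte-identical output files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .errors import ConfigError, DataError
from .repository import SUPER_POPULATIONS

_BASES = np.array(["A", "C", "G", "T"])
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}
_NONPAL_PAIRS = [("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
                 ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G")]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults give a small structured panel."""

    n_populations: int = 7
    n_ref_per_pop: int = 50
    n_study: int = 20
    n_snps: int = 2000
    fst: float = 0.08
    n_scores: int = 5
    variants_per_score: int = 100
    missing_rate: float = 0.0
    low_r2_rate: float = 0.05
    frac_absent: float = 0.1        # score variants not present in the VCF
    frac_palindromic: float = 0.05  # score variants at A/T / C/G sites
    frac_complemented: float = 0.2  # score entries written on the other strand
    frac_mismatch: float = 0.0      # score entries with alleles foreign to the site
    seed: int = 0
    n_chroms: int = 3
    chrom_length: int = 60_000_000

    def __post_init__(self):
        for name in ("n_populations", "n_ref_per_pop", "n_study", "n_snps",
                     "n_scores", "variants_per_score", "n_chroms", "chrom_length"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        if self.n_populations > len(SUPER_POPULATIONS):
            raise ConfigError(f"at most {len(SUPER_POPULATIONS)} populations")
        for name in ("missing_rate", "low_r2_rate", "frac_absent",
                     "frac_palindromic", "frac_complemented", "frac_mismatch"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must be in [0,1]")
        if not 0.0 <= self.fst < 1.0:
            raise ConfigError("fst must be in [0,1)")


@dataclass
class Panel:
    """Simulated reference panel + study cohort with full ground truth."""

    cfg: SimulationConfig
    chroms: np.ndarray           # str per SNP, coordinate-sorted
    positions: np.ndarray        # int per SNP
    refs: np.ndarray             # str per SNP
    alts: np.ndarray             # str per SNP
    pop_freqs: np.ndarray        # (n_populations, n_snps)
    ancestral_freqs: np.ndarray  # (n_snps,)
    ref_genotypes: np.ndarray    # (n_ref, n_snps) ints 0/1/2
    ref_labels: list[str]
    ref_samples: list[str]
    study_genotypes: np.ndarray  # (n_study, n_snps) ints
    study_dosages: np.ndarray    # (n_study, n_snps) floats, NaN = missing
    study_labels: list[str]
    study_samples: list[str]
    r2: np.ndarray               # (n_snps,)

    @property
    def populations(self) -> list[str]:
        return list(SUPER_POPULATIONS[: self.cfg.n_populations])

    @property
    def snp_keys(self) -> list[tuple]:
        return [
            (c, int(p), r, a)
            for c, p, r, a in zip(self.chroms, self.positions, self.refs, self.alts)
        ]

    def is_palindromic(self) -> np.ndarray:
        return np.array(
            [{r, a} in ({"A", "T"}, {"C", "G"}) for r, a in zip(self.refs, self.alts)]
        )


def _draw_sites(rng: np.random.Generator, cfg: SimulationConfig):
    """Unique (chrom, pos) pairs, coordinate-sorted, with distinct SNV alleles."""
    seen: set[tuple[int, int]] = set()
    while len(seen) < cfg.n_snps:
        need = cfg.n_snps - len(seen)
        cands = zip(
            rng.integers(0, cfg.n_chroms, size=2 * need + 10),
            rng.integers(1, cfg.chrom_length + 1, size=2 * need + 10),
        )
        for c, p in cands:
            seen.add((int(c), int(p)))
            if len(seen) == cfg.n_snps:
                break
    sites = sorted(seen)
    chroms = np.array([str(c + 1) for c, _ in sites])
    positions = np.array([p for _, p in sites], dtype=np.int64)
    ref_idx = rng.integers(0, 4, size=cfg.n_snps)
    alt_idx = (ref_idx + rng.integers(1, 4, size=cfg.n_snps)) % 4
    return chroms, positions, _BASES[ref_idx], _BASES[alt_idx]


def simulate_panel(cfg: SimulationConfig) -> Panel:
    """Simulate the labeled reference panel and the imputed study cohort."""
    rng = np.random.default_rng(cfg.seed)
    chroms, positions, refs, alts = _draw_sites(rng, cfg)
    m = cfg.n_snps

    p_anc = rng.uniform(0.05, 0.95, size=m)
    if cfg.fst > 0:
        a = p_anc * (1 - cfg.fst) / cfg.fst
        b = (1 - p_anc) * (1 - cfg.fst) / cfg.fst
        pop_freqs = rng.beta(a, b, size=(cfg.n_populations, m))
        # Beta draws of exactly 0/1 would make a population monomorphic with
        # probability 1; nudge them back into the open interval.
        pop_freqs = np.clip(pop_freqs, 1e-4, 1 - 1e-4)
    else:
        pop_freqs = np.tile(p_anc, (cfg.n_populations, 1))

    pops = list(SUPER_POPULATIONS[: cfg.n_populations])
    ref_genotypes = np.vstack([
        rng.binomial(2, pop_freqs[k], size=(cfg.n_ref_per_pop, m))
        for k in range(cfg.n_populations)
    ])
    ref_labels = [pops[k] for k in range(cfg.n_populations)
                  for _ in range(cfg.n_ref_per_pop)]
    ref_samples = [f"ref{i:04d}" for i in range(len(ref_labels))]

    study_pop = np.arange(cfg.n_study) % cfg.n_populations
    study_genotypes = np.vstack([
        rng.binomial(2, pop_freqs[k], size=(1, m)) for k in study_pop
    ])
    study_labels = [pops[k] for k in study_pop]
    study_samples = [f"study{i:04d}" for i in range(cfg.n_study)]

    noise = rng.normal(0.0, 0.05, size=study_genotypes.shape)
    dosages = np.clip(study_genotypes + noise, 0.0, 2.0)
    dosages = np.round(dosages, 4)  # VCFs carry short decimals
    if cfg.missing_rate > 0:
        mask = rng.random(dosages.shape) < cfg.missing_rate
        dosages[mask] = np.nan

    r2 = rng.uniform(0.7, 1.0, size=m)
    low = rng.random(m) < cfg.low_r2_rate
    r2[low] = rng.uniform(0.05, 0.295, size=int(low.sum()))
    r2 = np.round(r2, 4)

    return Panel(
        cfg=cfg, chroms=chroms, positions=positions, refs=refs, alts=alts,
        pop_freqs=pop_freqs, ancestral_freqs=p_anc,
        ref_genotypes=ref_genotypes, ref_labels=ref_labels, ref_samples=ref_samples,
        study_genotypes=study_genotypes, study_dosages=dosages,
        study_labels=study_labels, study_samples=study_samples, r2=r2,
    )


_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def _write_vcf(path, cfg, chroms, positions, refs, alts, samples, gts, dosages, r2):
    plain = path[:-3] if path.endswith(".gz") else path
    with open(plain, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pgsdesk-simulate\n")
        for c in range(cfg.n_chroms):
            fh.write(f"##contig=<ID={c + 1},length={cfg.chrom_length}>\n")
        if r2 is not None:
            fh.write('##INFO=<ID=R2,Number=1,Type=Float,'
                     'Description="Imputation r-squared">\n')
        fh.write('##INFO=<ID=TYPED,Number=0,Type=Flag,Description="Genotyped">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=A,Type=Float,'
                 'Description="Estimated alternate allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for i in range(len(positions)):
            info = f"R2={r2[i]:g}" if r2 is not None else "TYPED"
            cells = []
            for j in range(len(samples)):
                d = dosages[i][j] if dosages is not None else float(gts[i][j])
                if np.isnan(d):
                    cells.append("./.:.")
                else:
                    g = _GT[int(gts[i][j])] if gts is not None else "./."
                    cells.append(f"{g}:{d:g}")
            fh.write(
                f"{chroms[i]}\t{positions[i]}\t.\t{refs[i]}\t{alts[i]}\t.\tPASS\t"
                f"{info}\tGT:DS\t" + "\t".join(cells) + "\n"
            )
    if path.endswith(".gz"):
        pysam.tabix_compress(plain, path, force=True)
        os.remove(plain)
        pysam.tabix_index(path, preset="vcf", force=True)
    return path


def write_study_vcf(panel: Panel, path: str) -> str:
    """Write the study cohort as a bgzipped, indexed VCF with GT:DS and INFO/R2."""
    return _write_vcf(
        path, panel.cfg, panel.chroms, panel.positions, panel.refs, panel.alts,
        panel.study_samples, panel.study_genotypes.T,
        # a missing dosage entry also voids GT so the record truly lacks data
        np.where(np.isnan(panel.study_dosages), np.nan, panel.study_dosages).T,
        panel.r2,
    )


def write_reference_vcf(panel: Panel, path: str) -> str:
    """Reference panel as a VCF of hard-call genotypes (DS = allele count)."""
    return _write_vcf(
        path, panel.cfg, panel.chroms, panel.positions, panel.refs, panel.alts,
        panel.ref_samples, panel.ref_genotypes.T,
        panel.ref_genotypes.astype(float).T, None,
    )


def write_labels_tsv(panel: Panel, path: str, which: str = "reference") -> str:
    if which == "reference":
        samples, labels = panel.ref_samples, panel.ref_labels
    else:
        samples, labels = panel.study_samples, panel.study_labels
    with open(path, "wt") as fh:
        fh.write("sample\tpopulation\n")
        for s, l in zip(samples, labels):
            fh.write(f"{s}\t{l}\n")
    return path


@dataclass
class SimulatedScores:
    """Written score files plus the construction-truth oracle."""

    paths: list[str]
    score_ids: list[str]
    oracle_scores: pd.DataFrame       # study samples x scores, naive summation
    expected_used: dict[str, int]     # usable variants per score at min_r2
    expected_total: dict[str, int]
    variant_truth: pd.DataFrame = field(repr=False, default=None)


def simulate_scores(
    cfg: SimulationConfig,
    panel: Panel,
    out_dir: str,
    min_r2: float = 0.3,
    populations_per_score: list[frozenset] | None = None,
) -> SimulatedScores:
    """Draw score files from the panel and compute the oracle score matrix.

    The oracle applies the same rules as the engine in resolve mode: a
    variant contributes beta * D_effect (D_effect = 2 - D when the effect
    allele is the REF allele) unless it is palindromic, absent from the
    VCF, has r2 < ``min_r2``, or any study sample's dosage is missing.
    """
    rng = np.random.default_rng(cfg.seed + 10_000)
    os.makedirs(out_dir, exist_ok=True)
    n = cfg.variants_per_score
    pal = panel.is_palindromic()
    pal_idx = np.flatnonzero(pal)
    nonpal_idx = np.flatnonzero(~pal)
    n_pal = int(round(cfg.frac_palindromic * n))
    n_abs = int(round(cfg.frac_absent * n))
    n_mis = int(round(cfg.frac_mismatch * n))
    n_main = n - n_pal - n_abs - n_mis
    if n_main < 0:
        raise ConfigError("frac_palindromic + frac_absent + frac_mismatch exceed 1")
    if n_main > len(nonpal_idx) or n_pal > len(pal_idx):
        raise DataError("panel has fewer usable variants than requested per score")

    existing = {(c, int(p)) for c, p in zip(panel.chroms, panel.positions)}
    missing_mask = np.isnan(panel.study_dosages).any(axis=0)

    paths, score_ids = [], []
    oracle = np.zeros((cfg.n_study, cfg.n_scores))
    expected_used: dict[str, int] = {}
    expected_total: dict[str, int] = {}
    truth_rows = []
    for s in range(cfg.n_scores):
        sid = f"SYN{s + 1:06d}"
        score_ids.append(sid)
        idx_main = rng.choice(nonpal_idx, size=n_main, replace=False)
        idx_pal = rng.choice(pal_idx, size=n_pal, replace=False) if n_pal else np.array([], int)
        rows = []
        used = 0
        for i in np.concatenate([idx_main, idx_pal]).astype(int):
            w = float(rng.normal())
            swapped = bool(rng.random() < 0.5)
            effect, other = (panel.refs[i], panel.alts[i]) if swapped else \
                            (panel.alts[i], panel.refs[i])
            complemented = (not pal[i]) and bool(rng.random() < cfg.frac_complemented)
            if complemented:
                effect, other = _COMP[effect], _COMP[other]
            usable = (not pal[i]) and panel.r2[i] >= min_r2 and not missing_mask[i]
            if usable:
                d = panel.study_dosages[:, i]
                oracle[:, s] += w * (2.0 - d if swapped else d)
                used += 1
            if pal[i]:
                reason = "EXCLUDED_PALINDROMIC"
            elif panel.r2[i] < min_r2:
                reason = "EXCLUDED_LOW_R2"
            elif missing_mask[i]:
                reason = "EXCLUDED_MISSING_DOSAGE"
            elif complemented:
                reason = "USED_FLIPPED_SWAPPED" if swapped else "USED_FLIPPED"
            else:
                reason = "USED_SWAPPED" if swapped else "USED_DIRECT"
            rows.append((panel.chroms[i], int(panel.positions[i]), effect, other, w))
            truth_rows.append({"score_id": sid, "chrom": panel.chroms[i],
                               "pos": int(panel.positions[i]), "effect": effect,
                               "other": other, "reason": reason})
        if n_mis:  # entries whose alleles belong to neither strand of the site
            for i in rng.choice(nonpal_idx, size=n_mis, replace=False).astype(int):
                true = {panel.refs[i], panel.alts[i]}
                flipped = {_COMP[panel.refs[i]], _COMP[panel.alts[i]]}
                options = [pr for pr in _NONPAL_PAIRS
                           if set(pr) != true and set(pr) != flipped]
                e, o = options[int(rng.integers(0, len(options)))]
                rows.append((panel.chroms[i], int(panel.positions[i]), e, o,
                             float(rng.normal())))
                truth_rows.append({"score_id": sid, "chrom": panel.chroms[i],
                                   "pos": int(panel.positions[i]), "effect": e,
                                   "other": o, "reason": "EXCLUDED_MISMATCH"})
        for _ in range(n_abs):  # variants the VCF does not contain
            while True:
                c = str(int(rng.integers(0, cfg.n_chroms)) + 1)
                p = int(rng.integers(1, cfg.chrom_length + 1))
                if (c, p) not in existing:
                    break
            existing.add((c, p))
            e, o = _NONPAL_PAIRS[int(rng.integers(0, len(_NONPAL_PAIRS)))]
            rows.append((c, p, e, o, float(rng.normal())))
            truth_rows.append({"score_id": sid, "chrom": c, "pos": p,
                               "effect": e, "other": o, "reason": "NOT_FOUND"})
        order = rng.permutation(len(rows))
        rows = [rows[i] for i in order]
        pops = (populations_per_score[s] if populations_per_score is not None
                else frozenset(SUPER_POPULATIONS))
        path = os.path.join(out_dir, f"{sid}.txt")
        with open(path, "wt") as fh:
            fh.write("### pgsdesk synthetic scoring file\n")
            fh.write(f"#pgs_id={sid}\n")
            fh.write(f"#trait_reported=synthetic trait {s + 1}\n")
            fh.write(f"#populations={','.join(sorted(pops))}\n")
            fh.write("#genome_build=GRCh37\n")
            fh.write("chr_name\tchr_position\teffect_allele\tother_allele\t"
                     "effect_weight\n")
            for c, p, e, o, w in rows:
                fh.write(f"{c}\t{p}\t{e}\t{o}\t{w!r}\n")
        paths.append(path)
        expected_used[sid] = used
        expected_total[sid] = len(rows)

    oracle_df = pd.DataFrame(
        oracle, index=pd.Index(panel.study_samples, name="sample"), columns=score_ids
    )
    return SimulatedScores(
        paths=paths, score_ids=score_ids, oracle_scores=oracle_df,
        expected_used=expected_used, expected_total=expected_total,
        variant_truth=pd.DataFrame(truth_rows),
    )


def hudson_fst(geno_a: np.ndarray, geno_b: np.ndarray) -> float:
    """Hudson's Fst estimator (ratio of averages) between two genotype matrices."""
    pa = geno_a.mean(axis=0) / 2.0
    pb = geno_b.mean(axis=0) / 2.0
    na, nb = geno_a.shape[0] * 2, geno_b.shape[0] * 2
    num = (pa - pb) ** 2 - pa * (1 - pa) / (na - 1) - pb * (1 - pb) / (nb - 1)
    den = pa * (1 - pb) + pb * (1 - pa)
    ok = den > 0
    return float(num[ok].sum() / den[ok].sum())


def mean_pairwise_fst(panel: Panel) -> float:
    """Average Hudson Fst over all population pairs of the reference panel."""
    cfg = panel.cfg
    vals = []
    for i in range(cfg.n_populations):
        for j in range(i + 1, cfg.n_populations):
            gi = panel.ref_genotypes[np.array(panel.ref_labels) == panel.populations[i]]
            gj = panel.ref_genotypes[np.array(panel.ref_labels) == panel.populations[j]]
            vals.append(hudson_fst(gi, gj))
    return float(np.mean(vals))


def simulate_admixed(
    panel: Panel, pop_a: str, pop_b: str, n: int, seed: int = 0
) -> np.ndarray:
    """Genotypes of 50/50 admixed individuals between two panel populations.

    Each individual draws one allele from each parent population's frequency
    at every SNP, the Balding–Nichols analogue of a first-generation cross.
    """
    rng = np.random.default_rng(seed)
    ia = panel.populations.index(pop_a)
    ib = panel.populations.index(pop_b)
    fa, fb = panel.pop_freqs[ia], panel.pop_freqs[ib]
    return (rng.binomial(1, fa, size=(n, panel.cfg.n_snps))
            + rng.binomial(1, fb, size=(n, panel.cfg.n_snps))).astype(float)


def draw_from_population(panel: Panel, pop: str, n: int, seed: int = 0) -> np.ndarray:
    """Fresh hard-call genotypes drawn from one population's frequencies."""
    rng = np.random.default_rng(seed)
    k = panel.populations.index(pop)
    return rng.binomial(2, panel.pop_freqs[k], size=(n, panel.cfg.n_snps)).astype(float)
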