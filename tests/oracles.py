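"""Independent brute-force oracles used by the test suite.

These deliberately re-derive the scoring and classification rules from
first principles — plain loops over the simulation ground truth — and
share no code with the package implementation they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _orientation(effect, other, ref, alt, resolve=True):
    """'ALT' if the effect allele maps to ALT, 'REF' if to REF, else None.

    Palindromic single-base pairs return 'PAL' in resolve mode.
    """
    single = all(len(a) == 1 for a in (effect, other, ref, alt))
    if resolve and len(effect) == 1 and len(other) == 1 and \
            {effect, other} in ({"A", "T"}, {"C", "G"}):
        return "PAL"
    if (effect, other) == (alt, ref):
        return "ALT"
    if (effect, other) == (ref, alt):
        return "REF"
    if resolve and single:
        ce, co = COMP.get(effect), COMP.get(other)
        if (ce, co) == (alt, ref):
            return "ALT"
        if (ce, co) == (ref, alt):
            return "REF"
    return None


def naive_scores_from_files(score_paths, panel, min_r2=0.3, resolve=True):
    """Per-sample sum(beta * D_effect) straight from score files + panel truth.

    Reads the raw scoring files with pandas (not the package parser), looks
    sites up by (chrom, pos) in the simulated panel, and applies the
    exclusion rules — palindromic, allele mismatch, absent site, low r2,
    any-sample-missing — one variant at a time.
    """
    n_study = panel.study_dosages.shape[0]
    site_index = {}
    for i, (c, p) in enumerate(zip(panel.chroms, panel.positions)):
        site_index.setdefault((str(c), int(p)), []).append(i)
    missing_any = np.isnan(panel.study_dosages).any(axis=0)

    sums = {}
    used = {}
    for path in score_paths:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        sid = None
        with open(path) as fh:
            for line in fh:
                if line.startswith("#pgs_id="):
                    sid = line.strip().split("=", 1)[1]
        total = np.zeros(n_study)
        n_used = 0
        for row in df.itertuples(index=False):
            chrom, pos = str(row.chr_name), int(row.chr_position)
            effect, other = row.effect_allele, row.other_allele
            w = float(row.effect_weight)
            hit = None
            for i in site_index.get((chrom, pos), []):
                o = _orientation(effect, other, panel.refs[i], panel.alts[i],
                                 resolve=resolve)
                if o in ("ALT", "REF"):
                    hit = (i, o)
                    break
            if hit is None:
                continue
            i, o = hit
            if panel.r2[i] < min_r2 or missing_any[i]:
                continue
            d = panel.study_dosages[:, i]
            total = total + w * (d if o == "ALT" else 2.0 - d)
            n_used += 1
        sums[sid] = total
        used[sid] = n_used
    return sums, used


def brute_knn_label(x, ref_coords, ref_labels, k, threshold):
    """K-NN inverse-distance vote by explicit sort-and-sum."""
    d = [float(np.sqrt(((r - x) ** 2).sum())) for r in ref_coords]
    order = sorted(range(len(d)), key=lambda i: (d[i], i))[:k]
    weights = [1.0 / (d[i] + 1e-12) for i in order]
    total = sum(weights)
    votes = {}
    for i, w in zip(order, weights):
        votes[ref_labels[i]] = votes.get(ref_labels[i], 0.0) + w / total
    best = max(votes, key=votes.get)
    return best if votes[best] > threshold else "UNCLASSIFIED", votes


def hudson_fst_pairwise(ga, gb):
    """Hudson Fst, ratio of averages, written out longhand."""
    pa = ga.mean(axis=0) / 2.0
    pb = gb.mean(axis=0) / 2.0
    na = 2 * ga.shape[0]
    nb = 2 * gb.shape[0]
    num = (pa - pb) ** 2 - pa * (1 - pa) / (na - 1) - pb * (1 - pb) / (nb - 1)
    den = pa * (1 - pb) + pb * (1 - pa)
    keep = den > 0
    return float(np.sum(num[keep]) / np.sum(den[keep]))
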