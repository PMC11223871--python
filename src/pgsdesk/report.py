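"""Score output: TSV matrix, per-score summaries, and a self-contained HTML report.

Scores are computed and reported for *every* sample; ancestry-based
exclusion (population mismatch with the GWAS populations of a score, or an
unclassified sample) removes a sample only from the summary statistics and
distribution plots, never from the score matrix itself.
"""

from __future__ import annotations

import html
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ancestry import AncestryCall, match_population
from .errors import DataError
from .repository import SUPER_POPULATIONS, ScoreAnnotation
from .scoring import ScoreResult

_CLASS_COLORS = {"HIGH": "#2e7d32", "MEDIUM": "#ef6c00", "LOW": "#c62828"}


def write_scores_tsv(result: ScoreResult, out: str) -> None:
    """Tab-delimited score matrix: `sample` column then one column per score.

    Row order follows the VCF sample order, column order the repository
    score order; values are written at full precision so the file
    round-trips exactly.
    """
    if not result.samples or not result.score_ids:
        raise DataError("score result is empty")
    with open(out, "wt") as fh:
        fh.write("sample\t" + "\t".join(result.score_ids) + "\n")
        for i, sample in enumerate(result.samples):
            vals = "\t".join(repr(float(v)) for v in result.values[i])
            fh.write(f"{sample}\t{vals}\n")


def read_scores_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample",
                       float_precision="round_trip")


def write_audits_tsv(result: ScoreResult, out: str) -> None:
    rows = [
        {
            "chrom": a.chrom, "pos": a.pos, "other_allele": a.other_allele,
            "effect_allele": a.effect_allele, "score_id": a.score_id,
            "reason": a.reason,
        }
        for a in result.audits
    ]
    pd.DataFrame(rows, columns=["chrom", "pos", "other_allele", "effect_allele",
                                "score_id", "reason"]).to_csv(out, sep="\t", index=False)


@dataclass
class ScoreSummaries:
    """Per-score summary statistics over ancestry-included samples only."""

    table: pd.DataFrame                       # one row per score
    included: dict[str, list[str]]            # score_id -> included samples
    histograms: dict[str, tuple[np.ndarray, np.ndarray]]  # (bin_edges, counts)
    warnings: list[str] = field(default_factory=list)


def summarize(
    result: ScoreResult,
    calls: list[AncestryCall],
    annotations: dict[str, ScoreAnnotation],
    n_bins: int = 20,
) -> ScoreSummaries:
    """Per-score summaries after population matching.

    For each score, samples whose estimated population is not among the
    score's GWAS populations — or that are unclassified — are excluded and
    counted by reason; mean/sd/min/max and a histogram are computed over
    the included samples.  A score whose GWAS population set is empty
    places no restriction (all classified samples included).
    """
    call_by_sample = {c.sample: c for c in calls}
    missing = [s for s in result.samples if s not in call_by_sample]
    if missing:
        raise DataError(f"no ancestry call for sample(s): {missing[:5]}")

    frame = result.frame()
    rows = []
    included: dict[str, list[str]] = {}
    histograms: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    warnings: list[str] = []
    for sid in result.score_ids:
        ann = annotations.get(sid, ScoreAnnotation(score_id=sid))
        if ann.populations:
            restrict = ann
        else:  # no population annotation: only unclassified samples excluded
            restrict = ScoreAnnotation(score_id=sid,
                                       populations=frozenset(SUPER_POPULATIONS))
        inc, n_mismatch, n_unclassified = [], 0, 0
        for s in result.samples:
            verdict = match_population(call_by_sample[s], restrict)
            if verdict == "INCLUDED":
                inc.append(s)
            elif verdict == "EXCLUDED_POP_MISMATCH":
                n_mismatch += 1
            else:
                n_unclassified += 1
        included[sid] = inc
        vals = frame.loc[inc, sid].to_numpy() if inc else np.empty(0)
        if len(vals):
            mean = float(np.mean(vals))
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            vmin, vmax = float(np.min(vals)), float(np.max(vals))
            counts, edges = np.histogram(vals, bins=n_bins)
        else:
            mean = sd = vmin = vmax = float("nan")
            counts, edges = np.zeros(n_bins, dtype=int), np.linspace(0, 1, n_bins + 1)
        histograms[sid] = (edges, counts)
        if n_mismatch or n_unclassified:
            warnings.append(
                f"{sid}: {n_mismatch} sample(s) excluded by population mismatch, "
                f"{n_unclassified} unclassified"
            )
        if result.n_used[sid] == 0:
            warnings.append(
                f"{sid}: zero coverage — no score variant passed the filters; "
                f"reported values are 0.0 and not meaningful"
            )
        rows.append({
            "score_id": sid,
            "trait": ann.trait,
            "populations": ",".join(sorted(ann.populations)),
            "n_variants": result.n_total[sid],
            "n_used": result.n_used[sid],
            "coverage": result.coverage[sid],
            "coverage_class": result.coverage_class[sid],
            "n_included": len(inc),
            "n_excluded_mismatch": n_mismatch,
            "n_excluded_unclassified": n_unclassified,
            "mean": mean, "sd": sd, "min": vmin, "max": vmax,
        })
    return ScoreSummaries(pd.DataFrame(rows), included, histograms, warnings)


def write_summary_tsv(summaries: ScoreSummaries, out: str) -> None:
    summaries.table.to_csv(out, sep="\t", index=False)


def _svg_histogram(edges: np.ndarray, counts: np.ndarray, width=320, height=90) -> str:
    if counts.sum() == 0:
        return "<em>no included samples</em>"
    peak = counts.max()
    n = len(counts)
    bw = width / n
    bars = []
    for i, c in enumerate(counts):
        h = (c / peak) * (height - 6)
        bars.append(
            f'<rect x="{i * bw:.1f}" y="{height - h:.1f}" width="{bw - 1:.1f}" '
            f'height="{h:.1f}" fill="#4472a8"><title>[{edges[i]:.4g}, '
            f'{edges[i + 1]:.4g}): {c}</title></rect>'
        )
    return (
        f'<svg width="{width}" height="{height}" data-counts="'
        + ",".join(str(int(c)) for c in counts) + '">' + "".join(bars) + "</svg>"
    )


def render_html(
    summaries: ScoreSummaries,
    calls: list[AncestryCall],
    out: str,
    title: str = "Polygenic score report",
) -> None:
    """Write a single self-contained HTML report.

    Contains the score table colored by coverage class, per-score score
    distributions of the included samples, an ancestry overview and the
    warning list.  All numbers come from :func:`summarize`; nothing is
    recomputed here.
    """
    if summaries.table.empty:
        raise DataError("no score summaries to render")
    t = summaries.table
    esc = html.escape

    pop_counts: dict[str, int] = {}
    for c in calls:
        pop_counts[c.label] = pop_counts.get(c.label, 0) + 1

    rows_html = []
    for row in t.itertuples(index=False):
        color = _CLASS_COLORS.get(row.coverage_class, "#555")
        edges, counts = summaries.histograms[row.score_id]
        rows_html.append(
            "<tr>"
            f"<td>{esc(str(row.score_id))}</td>"
            f"<td>{esc(str(row.trait))}</td>"
            f"<td>{esc(str(row.populations))}</td>"
            f"<td>{row.n_variants}</td><td>{row.n_used}</td>"
            f"<td>{row.coverage:.1%}</td>"
            f'<td><span class="badge" style="background:{color}">'
            f"{esc(row.coverage_class)}</span></td>"
            f"<td>{row.n_included}</td>"
            f"<td>{'' if row.n_included == 0 else format(row.mean, '.6g')}</td>"
            f"<td>{'' if row.n_included == 0 else format(row.sd, '.6g')}</td>"
            f"<td>{_svg_histogram(edges, counts)}</td>"
            "</tr>"
        )
    ancestry_rows = "".join(
        f"<tr><td>{esc(label)}</td><td>{n}</td></tr>"
        for label, n in sorted(pop_counts.items())
    )
    warning_items = "".join(f"<li>{esc(w)}</li>" for w in summaries.warnings) or \
        "<li>none</li>"

    doc = f"""<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>{esc(title)}</title>
<style>
body {{ font-family: sans-serif; margin: 2em; }}
table {{ border-collapse: collapse; }}
td, th {{ border: 1px solid #ccc; padding: 4px 8px; font-size: 13px; }}
.badge {{ color: white; padding: 2px 6px; border-radius: 3px; }}
</style></head><body>
<h1>{esc(title)}</h1>
<h2>Scores</h2>
<table id="scores"><thead><tr>
<th>score</th><th>trait</th><th>GWAS populations</th><th>variants</th>
<th>used</th><th>coverage</th><th>class</th><th>n included</th>
<th>mean</th><th>sd</th><th>distribution (included samples)</th>
</tr></thead><tbody>
{''.join(rows_html)}
</tbody></table>
<h2>Ancestry overview</h2>
<table id="ancestry"><thead><tr><th>population</th><th>samples</th></tr></thead>
<tbody>{ancestry_rows}</tbody></table>
<h2>Warnings</h2>
<ul id="warnings">{warning_items}</ul>
</body></html>
"""
    with open(out, "wt") as fh:
        fh.write(doc)
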