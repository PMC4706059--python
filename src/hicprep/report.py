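"""Per-stage QC aggregation and report rendering.

Every pipeline stage persists its tallies as a small key/value TSV inside
the run directory; :func:`summarize` re-reads those files into a
:class:`StageSummary`, and :func:`render_report` turns one or more
summaries into a combined one-row-per-sample TSV plus a self-contained
static HTML page (optionally with embedded plots). The report is a pure
function of the stage TSVs — percentages are always recomputed from the
stored counts and denominators, and re-rendering the same inputs is
byte-identical.

Denominators (printed in the report footer):
truncated / unique-map / multi-map — of reads per mate; paired — of read
pairs in; category rows — of paired di-tags; unique — of valid di-tags;
trans — of unique di-tags.
"""

from __future__ import annotations

import base64
import io
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .align import MappingStats
from .dedup import DedupStats, cis_trans_ratio, trans_percentage
from .filtering import Category, FilterStats
from .truncate import TruncationStats

logger = logging.getLogger(__name__)

STAGE_FILES = {
    "truncate": "truncation.tsv",
    "map": "mapping.tsv",
    "filter": "filter.tsv",
    "dedup": "dedup.tsv",
}


class IncompleteRunError(FileNotFoundError):
    pass


@dataclass
class StageSummary:
    """All per-stage tallies for one sample."""

    sample: str
    truncation: dict[int, TruncationStats]  # per mate
    mapping: MappingStats
    filtering: FilterStats
    dedup: DedupStats

    def check_conservation(self) -> None:
        """Pipeline-wide count conservation.

        Paired di-tags = valid + every artifact class; valid di-tags =
        unique + duplicates removed."""
        total_categories = sum(self.filtering.counts.values())
        if total_categories != self.filtering.ditags_in:
            raise ValueError(
                f"{self.sample}: category counts sum to "
                f"{total_categories}, expected {self.filtering.ditags_in}")
        if self.filtering.ditags_in != self.mapping.pairs_formed:
            raise ValueError(
                f"{self.sample}: filtered {self.filtering.ditags_in} "
                f"di-tags but {self.mapping.pairs_formed} pairs formed")
        if self.dedup.ditags_in != self.filtering.valid:
            raise ValueError(
                f"{self.sample}: dedup saw {self.dedup.ditags_in} "
                f"di-tags but {self.filtering.valid} were valid")


def _pct(count: int, denom: int) -> float:
    """Percentage with an explicit zero-denominator marker (NaN)."""
    if denom == 0:
        return float("nan")
    return 100.0 * count / denom


def _fmt(value: float) -> str:
    if isinstance(value, float) and math.isnan(value):
        return "0 (n/a)"
    return f"{value:.2f}"


def summary_row(summary: StageSummary) -> dict[str, object]:
    """One flat row of counts and recomputed percentages."""
    row: dict[str, object] = {"sample": summary.sample}
    for mate in (1, 2):
        t = summary.truncation[mate]
        row[f"reads_r{mate}"] = t.reads_total
        row[f"truncated_r{mate}"] = t.reads_truncated
        row[f"truncated_r{mate}_pct"] = _pct(t.reads_truncated,
                                             t.reads_total)
        m = summary.mapping.per_mate[mate]
        denom = sum(m.values())
        for status in ("unique", "multi", "unmapped"):
            row[f"{status}_r{mate}"] = m[status]
            row[f"{status}_r{mate}_pct"] = _pct(m[status], denom)
    pairs_in = summary.mapping.reads_in // 2
    row["pairs_in"] = pairs_in
    row["paired"] = summary.mapping.pairs_formed
    row["paired_pct"] = _pct(summary.mapping.pairs_formed, pairs_in)
    ditags = summary.filtering.ditags_in
    row["ditags_paired"] = ditags
    for cat in Category:
        row[cat.value] = summary.filtering.counts[cat]
        row[f"{cat.value}_pct"] = _pct(summary.filtering.counts[cat],
                                       ditags)
    row["valid_cis"] = summary.filtering.valid_cis
    row["valid_trans"] = summary.filtering.valid_trans
    d = summary.dedup
    row["unique_ditags"] = d.ditags_unique
    row["unique_pct"] = _pct(d.ditags_unique, d.ditags_in)
    row["cis"] = d.cis_count
    row["trans"] = d.trans_count
    row["trans_pct"] = trans_percentage(d)
    row["cis_trans_ratio"] = cis_trans_ratio(d)
    return row


def summary_frame(summaries: Sequence[StageSummary]) -> pd.DataFrame:
    """Combined table, one row per sample, stable column order."""
    rows = [summary_row(s) for s in summaries]
    return pd.DataFrame(rows, columns=list(rows[0]))


# ---------------------------------------------------------------------------
# stage-TSV persistence (single source of truth for the report)

def _write_kv(path: Path, pairs: list[tuple[str, object]]) -> None:
    with open(path, "w") as fh:
        fh.write("key\tvalue\n")
        for k, v in pairs:
            fh.write(f"{k}\t{v}\n")


def _read_kv(path: Path) -> dict[str, str]:
    with open(path) as fh:
        header = fh.readline()
        if header.rstrip("\n") != "key\tvalue":
            raise ValueError(f"{path}: not a stage stats TSV")
        return dict(line.rstrip("\n").split("\t", 1) for line in fh)


def write_stage_stats(run_dir: str | Path, summary: StageSummary) -> None:
    run_dir = Path(run_dir)
    pairs = []
    for mate in (1, 2):
        t = summary.truncation[mate]
        pairs += [(f"reads_total_r{mate}", t.reads_total),
                  (f"reads_truncated_r{mate}", t.reads_truncated),
                  (f"too_short_r{mate}", t.too_short),
                  (f"truncated_length_sum_r{mate}",
                   t.truncated_length_sum)]
    _write_kv(run_dir / STAGE_FILES["truncate"], pairs)
    m = summary.mapping
    pairs = [("reads_in", m.reads_in), ("pairs_formed", m.pairs_formed)]
    for mate in (1, 2):
        for status in ("unique", "multi", "unmapped"):
            pairs.append((f"{status}_r{mate}", m.per_mate[mate][status]))
    _write_kv(run_dir / STAGE_FILES["map"], pairs)
    f = summary.filtering
    pairs = [("ditags_in", f.ditags_in),
             ("valid_cis", f.valid_cis), ("valid_trans", f.valid_trans)]
    pairs += [(cat.value, f.counts[cat]) for cat in Category]
    _write_kv(run_dir / STAGE_FILES["filter"], pairs)
    d = summary.dedup
    _write_kv(run_dir / STAGE_FILES["dedup"],
              [("ditags_in", d.ditags_in),
               ("ditags_unique", d.ditags_unique),
               ("cis_count", d.cis_count),
               ("trans_count", d.trans_count)])


def summarize(run_dir: str | Path, sample: str = "sample") -> StageSummary:
    """Rebuild a :class:`StageSummary` from the persisted stage TSVs."""
    run_dir = Path(run_dir)
    missing = [stage for stage, name in STAGE_FILES.items()
               if not (run_dir / name).exists()]
    if missing:
        raise IncompleteRunError(
            f"run in {run_dir} is missing stage output for: "
            f"{', '.join(missing)}")
    kv = _read_kv(run_dir / STAGE_FILES["truncate"])
    truncation = {}
    for mate in (1, 2):
        truncation[mate] = TruncationStats(
            reads_total=int(kv[f"reads_total_r{mate}"]),
            reads_truncated=int(kv[f"reads_truncated_r{mate}"]),
            truncated_length_sum=int(kv[f"truncated_length_sum_r{mate}"]),
            too_short=int(kv[f"too_short_r{mate}"]))
    kv = _read_kv(run_dir / STAGE_FILES["map"])
    mapping = MappingStats(
        reads_in=int(kv["reads_in"]),
        pairs_formed=int(kv["pairs_formed"]),
        per_mate={mate: {status: int(kv[f"{status}_r{mate}"])
                         for status in ("unique", "multi", "unmapped")}
                  for mate in (1, 2)})
    mapping.unique_mapped = sum(mapping.per_mate[m]["unique"]
                                for m in (1, 2))
    mapping.multi_mapped = sum(mapping.per_mate[m]["multi"]
                               for m in (1, 2))
    mapping.unmapped = sum(mapping.per_mate[m]["unmapped"] for m in (1, 2))
    kv = _read_kv(run_dir / STAGE_FILES["filter"])
    filtering = FilterStats(
        ditags_in=int(kv["ditags_in"]),
        counts={cat: int(kv[cat.value]) for cat in Category},
        valid_cis=int(kv["valid_cis"]),
        valid_trans=int(kv["valid_trans"]))
    kv = _read_kv(run_dir / STAGE_FILES["dedup"])
    dedup = DedupStats(
        ditags_in=int(kv["ditags_in"]),
        ditags_unique=int(kv["ditags_unique"]),
        cis_count=int(kv["cis_count"]),
        trans_count=int(kv["trans_count"]))
    return StageSummary(sample=sample, truncation=truncation,
                        mapping=mapping, filtering=filtering, dedup=dedup)


# ---------------------------------------------------------------------------
# rendering

_FOOTER = (
    "Denominators: truncated / unique-map / multi-map — reads per mate; "
    "paired — read pairs in; category rows — paired di-tags; "
    "unique — valid di-tags; trans — unique di-tags.")

_CATEGORY_ROWS = [
    ("Valid pairs", Category.VALID),
    ("Circularised", Category.SAME_CIRCULARISED),
    ("Dangling ends", Category.SAME_DANGLING),
    ("Same internal", Category.SAME_INTERNAL),
    ("Re-ligation", Category.RELIGATION),
    ("Contiguous", Category.CONTIGUOUS),
    ("Wrong size", Category.WRONG_SIZE),
    ("Not at cut site", Category.NOT_AT_CUT_SITE),
    ("Wrong enzyme end", Category.WRONG_ENZYME),
]


def _category_plot_png(summaries: Sequence[StageSummary]) -> str:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3.2))
    labels = [label for label, _ in _CATEGORY_ROWS]
    width = 0.8 / max(len(summaries), 1)
    for i, s in enumerate(summaries):
        denom = max(s.filtering.ditags_in, 1)
        vals = [100.0 * s.filtering.counts[cat] / denom
                for _, cat in _CATEGORY_ROWS]
        ax.bar([j + i * width for j in range(len(labels))], vals,
               width=width, label=s.sample)
    ax.set_xticks([j + 0.4 - width / 2 for j in range(len(labels))])
    ax.set_xticklabels(labels, rotation=30, ha="right", fontsize=8)
    ax.set_ylabel("% of paired di-tags")
    ax.legend(fontsize=8)
    fig.tight_layout()
    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=100)
    plt.close(fig)
    return base64.b64encode(buf.getvalue()).decode()


def _html_table(df: pd.DataFrame) -> str:
    head = "".join(f"<th>{c}</th>" for c in df.columns)
    body = []
    for _, row in df.iterrows():
        cells = "".join(
            f"<td>{_fmt(v) if isinstance(v, float) else v}</td>"
            for v in row)
        body.append(f"<tr>{cells}</tr>")
    return (f"<table><thead><tr>{head}</tr></thead>"
            f"<tbody>{''.join(body)}</tbody></table>")


def render_report(summaries: Sequence[StageSummary],
                  out_dir: str | Path,
                  plots: bool = False) -> tuple[Path, Path]:
    """Write ``summary.tsv`` and a self-contained ``report.html``.

    Returns the two paths. With ``plots=True`` a category bar chart is
    embedded as base64 PNG (no network assets either way)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for s in summaries:
        s.check_conservation()
    df = summary_frame(summaries)
    tsv_path = out_dir / "summary.tsv"
    df.to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")
    per_sample_tables = []
    for s in summaries:
        denom = s.filtering.ditags_in
        cat_rows = "".join(
            f"<tr><td>{label}</td><td>{s.filtering.counts[cat]}</td>"
            f"<td>{_fmt(_pct(s.filtering.counts[cat], max(denom, 0)))}"
            f"</td></tr>"
            for label, cat in _CATEGORY_ROWS)
        per_sample_tables.append(
            f"<h2>{s.sample}: di-tag categories</h2>"
            f"<table><thead><tr><th>Category</th><th>Count</th>"
            f"<th>% of paired di-tags</th></tr></thead>"
            f"<tbody>{cat_rows}</tbody></table>")
    plot_html = ""
    if plots:
        plot_html = (f'<h2>Category overview</h2><img alt="categories" '
                     f'src="data:image/png;base64,'
                     f'{_category_plot_png(summaries)}"/>')
    html = f"""<!DOCTYPE html>
<html><head><meta charset="utf-8"/>
<title>Hi-C processing QC report</title>
<style>
body {{ font-family: sans-serif; margin: 2em; }}
table {{ border-collapse: collapse; margin-bottom: 1.5em; }}
th, td {{ border: 1px solid #999; padding: 3px 8px; font-size: 12px; }}
th {{ background: #eee; }}
footer {{ color: #555; font-size: 11px; margin-top: 2em; }}
</style></head><body>
<h1>Hi-C processing QC report</h1>
<h2>Per-sample summary</h2>
{_html_table(df)}
{''.join(per_sample_tables)}
{plot_html}
<footer>{_FOOTER}</footer>
</body></html>
"""
    html_path = out_dir / "report.html"
    html_path.write_text(html)
    logger.info("wrote %s and %s", tsv_path, html_path)
    return html_path, tsv_path
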