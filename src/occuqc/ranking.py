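"""Five-scale color-rank classification of the metric panel, the overall
quality score, and the TSV + HTML report.

Each metric is flagged Excellent / Good / Average / Below-average / Poor
with numeric scores 2 / 1 / 0 / −1 / −2; the overall quality Q is the mean
score of the ranked, non-missing metrics and is itself flagged on the same
scale. Thresholds follow ENCODE-derived recommendations; every boundary is
inclusive toward the better band.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

from .model import OccuqcError


@dataclass(frozen=True)
class RankLevel:
    label: str
    score: int
    color: str

    def __str__(self) -> str:
        return self.label


EXCELLENT = RankLevel("Excellent", 2, "#1a9850")
GOOD = RankLevel("Good", 1, "#91cf60")
AVERAGE = RankLevel("Average", 0, "#fee08b")
BELOW_AVERAGE = RankLevel("Below-average", -1, "#fc8d59")
POOR = RankLevel("Poor", -2, "#d73027")

RANK_LEVELS = (EXCELLENT, GOOD, AVERAGE, BELOW_AVERAGE, POOR)

# Thresholds per metric, tested top-down with inclusive >= at each
# boundary; values below every boundary fall to Poor.
_THRESHOLDS: dict[str, list[tuple[float, RankLevel]]] = {
    "A": [(80, EXCELLENT), (70, GOOD), (60, AVERAGE), (50, BELOW_AVERAGE)],
    "F": [(0.05, EXCELLENT), (0.02, GOOD), (0.01, AVERAGE),
          (0.0075, BELOW_AVERAGE)],
    "L": [(10_000, EXCELLENT), (5_000, GOOD), (2_000, AVERAGE),
          (1_000, BELOW_AVERAGE)],
    "NRF": [(0.8, EXCELLENT), (0.7, GOOD), (0.6, AVERAGE),
            (0.5, BELOW_AVERAGE)],
    "N": [(10_000, EXCELLENT), (5_000, GOOD), (2_000, AVERAGE),
          (1_000, BELOW_AVERAGE)],
    "NSC": [(1.045, EXCELLENT)],
    "C": [(0.9, EXCELLENT), (0.75, GOOD), (0.66, AVERAGE),
          (0.5, BELOW_AVERAGE)],
    "P": [(10_000, EXCELLENT), (5_000, GOOD), (2_000, AVERAGE),
          (1_000, BELOW_AVERAGE)],
    "R": [(30_000_000, EXCELLENT), (25_000_000, GOOD), (20_000_000, AVERAGE),
          (15_000_000, BELOW_AVERAGE)],
    "RSC": [(1.0, EXCELLENT), (0.75, GOOD)],
    "S": [(0.2, EXCELLENT), (0.1, GOOD), (0.05, AVERAGE),
          (0.02, BELOW_AVERAGE)],
    "Q": [(2, EXCELLENT), (1, GOOD), (0, AVERAGE), (-1, BELOW_AVERAGE)],
}

_FLAG_METRICS = {"B", "D"}
_FLAG_MAP = {"pass": EXCELLENT, "warn": AVERAGE, "fail": POOR}

# E: |delta| under 10 bp between predicted tag length and read length
E_TOLERANCE = 10

UNRANKED_METRICS = {"fragment_width", "read_length", "SE"}

KNOWN_METRICS = (set(_THRESHOLDS) | _FLAG_METRICS | UNRANKED_METRICS | {"E"})


def rank_metric(name: str, value: Union[float, str, None]
                ) -> Optional[RankLevel]:
    """Rank one metric value; None for unranked metrics or missing values.

    Raises on unknown metric names. pass/warn/fail metrics map to
    Excellent/Average/Poor; E is Excellent when |E| < 10 bp, else Poor.
    """
    if name not in KNOWN_METRICS:
        raise OccuqcError(f"unknown metric {name!r}")
    if value is None:
        return None
    if name in UNRANKED_METRICS:
        return None
    if name in _FLAG_METRICS:
        try:
            return _FLAG_MAP[value]
        except KeyError:
            raise OccuqcError(
                f"metric {name}: expected pass/warn/fail, got {value!r}"
            ) from None
    if name == "E":
        return EXCELLENT if abs(float(value)) < E_TOLERANCE else POOR
    v = float(value)
    for bound, level in _THRESHOLDS[name]:
        if v >= bound:
            return level
    return POOR


@dataclass
class MetricEntry:
    key: str
    display: str
    value: Union[float, str, None]
    rank: Optional[RankLevel]

    @property
    def score(self) -> Optional[int]:
        return None if self.rank is None else self.rank.score


@dataclass
class MetricPanel:
    entries: list[MetricEntry]
    overall_q: Optional[float] = None
    overall_rank: Optional[RankLevel] = None


# (key, display name, format kind) in dashboard order
PANEL_LAYOUT: list[tuple[str, str, str]] = [
    ("A", "Aligned percent (A)", "percent"),
    ("B", "Base quality (B)", "flag"),
    ("fragment_width", "Estimated fragment width", "count"),
    ("E", "Estimated tag length (E)", "bp"),
    ("F", "FRiP (F)", "ratio"),
    ("L", "Linear stitched peaks (L)", "count"),
    ("NRF", "Non-redundant fraction (NRF)", "ratio"),
    ("N", "Normalized peaks (N)", "count"),
    ("NSC", "NSC", "ratio"),
    ("D", "Sequence diversity (D)", "flag"),
    ("C", "PCR bottleneck coefficient (C)", "ratio"),
    ("P", "Peaks (P)", "count"),
    ("R", "Raw reads (R)", "count"),
    ("read_length", "Read length", "bp"),
    ("RSC", "RSC", "ratio"),
    ("SE", "SE-like enriched regions", "count"),
    ("S", "Super stitched ratio (S)", "ratio"),
]

_FORMAT_KIND = {k: kind for k, _, kind in PANEL_LAYOUT}


def overall_quality(panel: MetricPanel) -> tuple[float, RankLevel]:
    """Q = mean score over ranked, non-missing metrics, flagged on the
    Q thresholds. Raises when no metric is ranked."""
    scores = [e.score for e in panel.entries if e.score is not None]
    if not scores:
        raise OccuqcError("overall quality undefined: no ranked metrics")
    q = sum(scores) / len(scores)
    rank = rank_metric("Q", q)
    panel.overall_q = q
    panel.overall_rank = rank
    return q, rank


def build_panel(values: dict[str, Union[float, str, None]]) -> MetricPanel:
    """Assemble the full dashboard panel from a metric-value mapping.

    Keys absent from ``values`` are reported as missing and excluded from
    the overall quality.
    """
    entries = [
        MetricEntry(key, display, values.get(key),
                    rank_metric(key, values.get(key)))
        for key, display, _ in PANEL_LAYOUT
    ]
    panel = MetricPanel(entries)
    overall_quality(panel)
    return panel


# ---------------------------------------------------------------------------
# rendering

MISSING_VALUE = "NA"
MISSING_RANK = "–"  # en dash


def format_value(key: str, value: Union[float, str, None]) -> str:
    if value is None:
        return MISSING_VALUE
    if isinstance(value, str):
        return value
    kind = _FORMAT_KIND.get(key, "ratio")
    if key == "Q":
        kind = "ratio"
    if kind == "ratio":
        return f"{float(value):.4f}"
    if kind == "percent":
        return f"{float(value):.1f}"
    if kind == "bp":
        v = float(value)
        return f"{v:.1f}" if v != int(v) else f"{int(v):,}"
    # counts
    return f"{int(round(float(value))):,}"


def panel_rows(panel: MetricPanel) -> list[tuple[str, str, str, str]]:
    """(metric, value, rank, score) string rows including Overall quality."""
    rows = []
    for e in panel.entries:
        rows.append((
            e.display,
            format_value(e.key, e.value),
            MISSING_RANK if e.rank is None else e.rank.label,
            "" if e.score is None else str(e.score),
        ))
    rows.append((
        "Overall quality (Q)",
        format_value("Q", panel.overall_q),
        MISSING_RANK if panel.overall_rank is None else panel.overall_rank.label,
        "" if panel.overall_rank is None else str(panel.overall_rank.score),
    ))
    return rows


def render_tsv(panel: MetricPanel, path: Union[str, Path]) -> None:
    lines = ["metric\tvalue\trank\tscore"]
    lines += ["\t".join(row) for row in panel_rows(panel)]
    Path(path).write_text("\n".join(lines) + "\n")


_HTML_HEAD = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>Occupancy QC report</title>
<style>
body { font-family: Helvetica, Arial, sans-serif; margin: 2em; }
table { border-collapse: collapse; }
th, td { border: 1px solid #999; padding: 4px 10px; text-align: left; }
th { background: #eee; }
td.rank { font-weight: bold; }
</style></head><body>
<h1>Chromatin occupancy QC report</h1>
<table>
<tr><th>Metric</th><th>Value</th><th>Rank</th><th>Score</th></tr>
"""

_HTML_FOOT = """</table>
<p>Rank scale: Excellent (2) &gt; Good (1) &gt; Average (0) &gt;
Below-average (&minus;1) &gt; Poor (&minus;2). Missing metrics are excluded
from the overall quality.</p>
</body></html>
"""


def render_html(panel: MetricPanel, path: Union[str, Path]) -> None:
    by_label = {lvl.label: lvl for lvl in RANK_LEVELS}
    parts = [_HTML_HEAD]
    for metric, value, rank, score in panel_rows(panel):
        level = by_label.get(rank)
        if level is None:
            cell = f'<td class="rank">{rank}</td>'
        else:
            fg = "#ffffff" if level.label != "Average" else "#000000"
            cell = (f'<td class="rank" style="background:{level.color};'
                    f'color:{fg}">{rank}</td>')
        parts.append(
            f"<tr><td>{metric}</td><td>{value}</td>{cell}"
            f"<td>{score}</td></tr>\n"
        )
    parts.append(_HTML_FOOT)
    Path(path).write_text("".join(parts))


def render_report(panel: MetricPanel, out_dir: Union[str, Path],
                  prefix: str = "occuqc") -> tuple[Path, Path]:
    """Write <prefix>-stats.tsv and <prefix>-stats.html into out_dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv = out_dir / f"{prefix}-stats.tsv"
    html = out_dir / f"{prefix}-stats.html"
    render_tsv(panel, tsv)
    render_html(panel, html)
    return tsv, html
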