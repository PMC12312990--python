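"""Pie and forest renderers for disproportionality reports.

The forest plot follows pharmacovigilance convention: diamonds at the
log2-transformed ROR, whiskers spanning the log2-transformed 95% CI, a
reference line at 0 (ROR = 1), and a star for rows whose CI lower bound
is above the reference.  Rendering is deterministic for fixed input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt


@dataclass(frozen=True)
class ForestRow:
    """One plotted row: a label and a log2 ROR with its log2 CI."""

    label: str
    log2_ror: float
    log2_ci_low: float
    log2_ci_high: float
    display: str = ""  # free-text counts column
    significant: bool = False

    def __post_init__(self):
        finite = all(
            math.isfinite(v) for v in (self.log2_ror, self.log2_ci_low, self.log2_ci_high)
        )
        if not finite:
            raise ValueError(f"non-finite forest values for row {self.label!r}")
        if not (self.log2_ci_low <= self.log2_ror <= self.log2_ci_high):
            raise ValueError(f"CI does not bracket the estimate for row {self.label!r}")


def forest_row(
    label: str,
    ror: float,
    ci_low: float,
    ci_high: float,
    display: str = "",
    significant: Optional[bool] = None,
) -> ForestRow:
    """Build a :class:`ForestRow` from natural-scale ROR and CI bounds."""
    if min(ror, ci_low, ci_high) <= 0:
        raise ValueError(f"ROR and CI bounds must be positive for row {label!r}")
    lo = math.log2(ci_low)
    if significant is None:
        significant = lo > 0.0
    return ForestRow(
        label=label,
        log2_ror=math.log2(ror),
        log2_ci_low=lo,
        log2_ci_high=math.log2(ci_high),
        display=display,
        significant=significant,
    )


def forest_rows_from_report(report) -> List[ForestRow]:
    """Estimable rows of an :class:`~faerskit.analysis.AnalysisReport`."""
    rows = []
    for r in report.rows:
        if r.result is None:
            continue
        label = r.pt if r.stratum is None else f"{r.pt} [{r.stratum}]"
        display = f"{r.table.a}/{r.table.n_exposed}"
        rows.append(
            forest_row(
                label,
                r.result.ror,
                r.result.ci_low,
                r.result.ci_high,
                display=display,
                significant=r.result.significant,
            )
        )
    return rows


def render_pie(
    freqs: Sequence[Tuple[str, int]],
    out: Optional[Union[str, Path]] = None,
):
    """Pie chart of reaction frequencies; wedge angle proportional to count.

    Wedges appear in the given order starting at 12 o'clock, clockwise;
    labels carry the PT and its count.  Returns the matplotlib Figure
    (saved to *out* when given).
    """
    freqs = list(freqs)
    if not freqs:
        raise ValueError("cannot render a pie chart of zero reactions")
    if any(n <= 0 for _, n in freqs):
        raise ValueError("all counts must be positive")
    labels = [f"{pt} ({n})" for pt, n in freqs]
    counts = [n for _, n in freqs]
    fig, ax = plt.subplots(figsize=(8, 8))
    ax.pie(
        counts,
        labels=labels,
        startangle=90,
        counterclock=False,
        textprops={"fontsize": 8},
    )
    ax.set_aspect("equal")
    if out is not None:
        fig.savefig(out, bbox_inches="tight")
        plt.close(fig)
    return fig


def render_forest(
    rows: Sequence[ForestRow],
    out: Optional[Union[str, Path]] = None,
    title: str = "",
):
    """Forest plot on the log2 scale, one row per entry, in given order.

    Diamond at ``log2_ror``, whisker spanning the log2 CI, dashed
    reference line at 0; a star marks rows whose CI lower bound exceeds
    the reference.  Returns the matplotlib Figure (saved to *out* when
    given).
    """
    rows = list(rows)
    if not rows:
        raise ValueError("cannot render an empty forest plot")
    n = len(rows)
    ys = list(range(n, 0, -1))  # first row on top
    fig, ax = plt.subplots(figsize=(8, 1.5 + 0.45 * n))
    for y, row in zip(ys, rows):
        ax.plot(
            [row.log2_ci_low, row.log2_ci_high], [y, y],
            color="green", linewidth=1.8, solid_capstyle="butt", zorder=2,
        )
        ax.plot([row.log2_ror], [y], marker="D", color="black", markersize=6, zorder=3)
        if row.significant:
            ax.annotate(
                "*", (row.log2_ci_high, y), textcoords="offset points",
                xytext=(6, -3), fontsize=11, color="black",
            )
    ax.axvline(0.0, color="grey", linestyle="--", linewidth=1, zorder=1)
    ax.set_yticks(ys)
    labels = [r.label if not r.display else f"{r.label}  ({r.display})" for r in rows]
    ax.set_yticklabels(labels, fontsize=8)
    ax.set_ylim(0.3, n + 0.7)
    ax.set_xlabel("log2(ROR) with 95% CI")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, bbox_inches="tight")
        plt.close(fig)
    return fig
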