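"""Bit-stable tabular report rendering.

Reports are plain tab-separated text with a fixed column order and
documented rounding: populations and transition percentages to whole
percent, distances to two decimals, all rounded half-away-from-zero.
Internal computation is never rounded — rounding happens only here.
Each report embeds the thresholds used so it is self-describing.
"""

from __future__ import annotations

import math

import numpy as np

from .patterns import ALL_PATTERNS, FoldingSummary, PatternTable
from .transitions import FoldingPathway, TransitionMap

__all__ = [
    "round_half_away",
    "render_pattern_table",
    "render_transition_map",
    "render_pathway",
    "render_summary",
]

NA = "NA"


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (3.5 -> 4, -3.5 -> -4)."""
    scale = 10**ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5) / scale, x)


def _fmt_pct(x: float) -> str:
    return NA if x is None or (isinstance(x, float) and math.isnan(x)) else f"{round_half_away(x):.0f}"


def _fmt_dist(x: float) -> str:
    return NA if x is None or (isinstance(x, float) and math.isnan(x)) else f"{round_half_away(x, 2):.2f}"


def _criteria_header(criteria, folded_threshold: float | None = None) -> str:
    parts = [
        f"distance_cutoff_A={criteria.distance_cutoff:g}",
        f"angle_min_deg={criteria.angle_min:g}",
    ]
    if folded_threshold is not None:
        parts.append(f"folded_threshold_A={folded_threshold:g}")
    return "# criteria: " + " ".join(parts) + "\n"


def render_pattern_table(table: PatternTable, scope: str = "top") -> str:
    """Render the per-pattern population/distance table.

    ``scope='top'`` keeps patterns whose rounded population is >= 1%
    (ordered by descending population); ``scope='full'`` prints all 16
    patterns in binary order, empty ones with population 0 and NA distance
    cells.
    """
    if scope not in ("top", "full"):
        raise ValueError(f"unknown scope {scope!r}")
    df = table.table
    if scope == "top":
        df = df[df["significant"]].sort_values("population", ascending=False, kind="stable")
    lines = [_criteria_header(table.criteria, table.folded_threshold)]
    cols = ["pattern", "%"] + table.bond_labels + ["Average", "Folded"]
    lines.append("\t".join(cols) + "\n")
    for pattern, row in df.iterrows():
        if row["n_frames"] == 0:
            folded_s = NA
        else:
            folded_s = "f" if bool(row["folded"]) else "u"
        cells = [str(pattern), _fmt_pct(row["population"])]
        cells += [_fmt_dist(row[f"mean_{b}"]) for b in table.bond_labels]
        cells += [_fmt_dist(row["overall_mean"]), folded_s]
        lines.append("\t".join(cells) + "\n")
    return "".join(lines)


def render_transition_map(tmap: TransitionMap, criteria=None) -> str:
    """Render a population change map: rows = origin, columns = destination."""
    lines = []
    if criteria is not None:
        lines.append(_criteria_header(criteria))
    lines.append("\t".join(["from\\to"] + list(tmap.states)) + "\n")
    pct = tmap.percentages
    for i, s in enumerate(tmap.states):
        if pct is None or np.all(np.isnan(pct[i])):
            cells = [NA] * tmap.n_states
        else:
            cells = [_fmt_pct(pct[i, j]) for j in range(tmap.n_states)]
        lines.append("\t".join([s] + cells) + "\n")
    return "".join(lines)


def render_pathway(pathway: FoldingPathway) -> str:
    """Render a pathway as a ``state -> state (p%)`` chain plus branches."""
    if not pathway.steps:
        return pathway.start + "\n"
    chain = pathway.states[0]
    branch_lines = []
    for step in pathway.steps:
        chain += f" -> {step.destination} ({_fmt_pct(step.percent)}%)"
        if step.alt_destination is not None:
            branch_lines.append(
                f"# branch at {step.source}: {step.alt_destination} "
                f"({_fmt_pct(step.alt_percent)}%)\n"
            )
    return chain + "\n" + "".join(branch_lines)


def render_summary(summary: FoldingSummary, folded_threshold: float) -> str:
    lines = [
        f"# folded_threshold_A={folded_threshold:g} mode={summary.mode}\n",
        f"folded_fraction_percent\t{round_half_away(summary.folded_fraction, 1):.1f}\n",
        f"pattern_level_percent\t{round_half_away(summary.pattern_level, 1):.1f}\n",
    ]
    if summary.frame_level is not None:
        lines.append(f"frame_level_percent\t{round_half_away(summary.frame_level, 1):.1f}\n")
    return "".join(lines)
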