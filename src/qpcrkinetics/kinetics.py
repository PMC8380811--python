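"""Trajectory classification, first-onset location and timing summaries.

A gene x cell type trajectory is classified from its Tukey-adjusted
baseline contrasts: UP when every significant change is upward, DOWN when
all are downward, MIXED when both directions occur, STABLE when nothing is
significant.  The first onset is the earliest significant pellet time point
(the monolayer condition is reported separately and never counts as an
onset).  Timing summaries give, per functional annotation group and cell
type, the percentage of the group's genes whose first onset falls at each
post-baseline time point; a gene carrying several annotations is counted
once in each of its groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import pandas as pd

from .design import SamplingDesign, time_to_hours
from .io_qpcr import ANNOTATION_GROUPS, parse_groups
from .stats import SCOPE_MONOLAYER, SCOPE_TIME, ContrastResult

TRAJECTORY_CLASSES = ("UP", "DOWN", "MIXED", "STABLE")


@dataclass(frozen=True)
class OnsetProfile:
    """Classified trajectory of one gene in one cell type."""

    gene: str
    cell_type: str
    trajectory_class: str
    first_onset_h: str | None = None
    first_direction: str | None = None


def classify_trajectory(contrasts: Sequence[ContrastResult]) -> OnsetProfile:
    """Classify one gene x cell type trajectory from its baseline contrasts.

    Only TIME_VS_BASELINE contrasts participate; monolayer contrasts, if
    present in the input, are ignored.
    """
    time_contrasts = [c for c in contrasts if c.scope == SCOPE_TIME]
    if not time_contrasts:
        raise ValueError("no time-vs-baseline contrasts to classify")
    gene = time_contrasts[0].gene
    cell_type = time_contrasts[0].cell_type
    significant = sorted(
        (c for c in time_contrasts if c.significant),
        key=lambda c: time_to_hours(c.level_a),
    )
    if not significant:
        return OnsetProfile(gene, cell_type, "STABLE")
    directions = {c.direction for c in significant}
    if directions == {"UP"}:
        cls = "UP"
    elif directions == {"DOWN"}:
        cls = "DOWN"
    else:
        cls = "MIXED"
    first = significant[0]
    return OnsetProfile(gene, cell_type, cls, first.level_a, first.direction)


def profiles_to_frame(profiles: Sequence[OnsetProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": p.gene,
                "cell_type": p.cell_type,
                "trajectory_class": p.trajectory_class,
                "first_onset_h": p.first_onset_h or "",
                "first_direction": p.first_direction or "",
            }
            for p in profiles
        ]
    )


def tabulate_trajectory_classes(profiles: pd.DataFrame) -> dict[str, int]:
    """Count gene x cell type combinations per trajectory class."""
    if profiles.duplicated(subset=["gene", "cell_type"]).any():
        dup = profiles.loc[
            profiles.duplicated(subset=["gene", "cell_type"]), ["gene", "cell_type"]
        ].iloc[0]
        raise ValueError(f"duplicate profile for {tuple(dup)}")
    counts = profiles["trajectory_class"].value_counts()
    return {cls: int(counts.get(cls, 0)) for cls in TRAJECTORY_CLASSES}


def _round1(value: float) -> float:
    return float(Decimal(repr(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize_onset_by_annotation(
    profiles: pd.DataFrame,
    panel: pd.DataFrame,
    design: SamplingDesign,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """First-onset timing distribution per annotation group and cell type.

    For each (annotation group, cell type) the percentage of the group's
    genes whose first onset falls at each post-baseline time point is
    100 * count / group size, rounded half-up to one decimal.  Genes with no
    annotation are excluded; multi-annotated genes count in each group.
    Also returns the distribution pooled across cell types (denominator =
    group size x number of cell types), the histogram view.
    """
    groups_of = {
        row.gene_symbol: parse_groups(row.annotation_groups) for row in panel.itertuples()
    }
    profiled_genes = sorted(profiles["gene"].unique())
    members = {
        g: sorted(x for x in profiled_genes if g in groups_of.get(x, frozenset()))
        for g in ANNOTATION_GROUPS
    }
    times = design.post_baseline_labels
    onset = {
        (row.gene, row.cell_type): row.first_onset_h
        for row in profiles.itertuples()
    }
    cell_types = list(design.cell_types)

    rows, pooled_rows = [], []
    for group in ANNOTATION_GROUPS:
        genes = members[group]
        if not genes:
            continue
        for cell_type in cell_types:
            row = {"annotation_group": group, "cell_type": cell_type, "group_size": len(genes)}
            for t in times:
                n = sum(1 for g in genes if onset.get((g, cell_type)) == t)
                row[f"pct_{t}h"] = _round1(100.0 * n / len(genes))
            rows.append(row)
        denom = len(genes) * len(cell_types)
        pooled = {"annotation_group": group, "n_combinations": denom}
        for t in times:
            n = sum(
                1 for g in genes for ct in cell_types if onset.get((g, ct)) == t
            )
            pooled[f"pct_{t}h"] = _round1(100.0 * n / denom)
        pooled_rows.append(pooled)
    return pd.DataFrame(rows), pd.DataFrame(pooled_rows)


def monolayer_effect(contrasts: Sequence[ContrastResult]) -> pd.DataFrame:
    """Gene x cell type combinations with a significant monolayer-vs-0 h shift."""
    rows = [
        {"gene": c.gene, "cell_type": c.cell_type, "direction": c.direction}
        for c in contrasts
        if c.scope == SCOPE_MONOLAYER and c.significant
    ]
    return pd.DataFrame(rows, columns=["gene", "cell_type", "direction"])
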