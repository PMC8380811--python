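"""Four-pattern cell-type divergence before and after chondrogenic induction.

For each gene and each pair of cell types, two flags are read off the
Tukey-adjusted pairwise contrasts: whether the pair differed at the 0 h
baseline, and whether it differed at one or more post-baseline time points.
The flags map onto four categories:

    baseline  post   category
      yes     yes    RETAINED   (difference survived induction)
      yes     no     LOST       (initial difference disappeared)
      no      yes    BECAME     (difference emerged under induction)
      no      no     SIMILAR    (never different)

Cross-pair summaries then report, per category, the genes common to every
cell-type pair and those specific to a single pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .design import MONOLAYER, time_to_hours
from .stats import SCOPE_CELLTYPE, ContrastResult

DIVERGENCE_CATEGORIES = ("RETAINED", "LOST", "BECAME", "SIMILAR")


@dataclass(frozen=True)
class DivergencePattern:
    gene: str
    pair: str
    baseline_different: bool
    post_different: bool
    category: str


def pair_label(cell_a: str, cell_b: str) -> str:
    return f"{cell_a}-{cell_b}"


def category_from_flags(baseline_different: bool, post_different: bool) -> str:
    if baseline_different:
        return "RETAINED" if post_different else "LOST"
    return "BECAME" if post_different else "SIMILAR"


def categorize_divergence(
    contrasts: Sequence[ContrastResult],
    baseline: str = "0",
) -> DivergencePattern:
    """Divergence category for one gene x cell-type pair.

    ``contrasts`` are that pair's CELLTYPE_PAIR contrasts across time points;
    the baseline (0 h) contrast must be present and at least one
    post-baseline time point is required.  Monolayer contrasts are ignored.
    Direction is deliberately not consulted — the categories are about the
    presence of a difference, not its sign.
    """
    relevant = [
        c
        for c in contrasts
        if c.scope == SCOPE_CELLTYPE and c.time_point != MONOLAYER
    ]
    if not relevant:
        raise ValueError("no cell-type contrasts supplied")
    gene = relevant[0].gene
    pair = pair_label(relevant[0].level_a, relevant[0].level_b)
    at_baseline = [c for c in relevant if c.time_point == baseline]
    if not at_baseline:
        raise ValueError(f"{gene} ({pair}): baseline ({baseline} h) contrast missing")
    post = [c for c in relevant if time_to_hours(c.time_point) > time_to_hours(baseline)]
    if not post:
        raise ValueError(f"{gene} ({pair}): no post-baseline contrast available")
    baseline_different = any(c.significant for c in at_baseline)
    post_different = any(c.significant for c in post)
    return DivergencePattern(
        gene=gene,
        pair=pair,
        baseline_different=baseline_different,
        post_different=post_different,
        category=category_from_flags(baseline_different, post_different),
    )


def patterns_to_frame(patterns: Sequence[DivergencePattern]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": p.gene,
                "pair": p.pair,
                "baseline_different": p.baseline_different,
                "post_different": p.post_different,
                "category": p.category,
            }
            for p in patterns
        ]
    )


def summarize_divergence(
    patterns: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, dict[str, list[str]]]]:
    """Per-pair category counts and cross-pair gene sets.

    Counts sum to the analyzed-gene total within each pair.  For every
    category, ``gene_sets[category]["common"]`` holds the genes assigned that
    category in all pairs, and ``gene_sets[category][pair]`` those specific
    to a single pair (that category in this pair and no other).  Genes
    without a pattern in every pair are excluded from the cross-pair sets
    with a warning.
    """
    pairs = sorted(patterns["pair"].unique())
    counts = (
        patterns.groupby(["pair", "category"]).size().rename("n_genes").reset_index()
    )
    full = pd.DataFrame(
        [
            {
                "pair": pair,
                "category": cat,
                "n_genes": int(
                    counts.loc[
                        (counts["pair"] == pair) & (counts["category"] == cat), "n_genes"
                    ].sum()
                ),
            }
            for pair in pairs
            for cat in DIVERGENCE_CATEGORIES
        ]
    )

    coverage = patterns.groupby("gene")["pair"].nunique()
    incomplete = sorted(coverage.index[coverage < len(pairs)])
    if incomplete:
        warnings.warn(
            f"{len(incomplete)} gene(s) lack patterns for every pair and are "
            f"excluded from cross-pair sets, e.g. {incomplete[:3]}",
            stacklevel=2,
        )
    covered = patterns[~patterns["gene"].isin(incomplete)]
    cat_of = {(r.gene, r.pair): r.category for r in covered.itertuples()}
    genes = sorted(covered["gene"].unique())

    gene_sets: dict[str, dict[str, list[str]]] = {}
    for cat in DIVERGENCE_CATEGORIES:
        in_cat = {pair: {g for g in genes if cat_of[(g, pair)] == cat} for pair in pairs}
        common = set.intersection(*in_cat.values()) if pairs else set()
        sets = {"common": sorted(common)}
        for pair in pairs:
            others = set().union(*(in_cat[p] for p in pairs if p != pair))
            sets[pair] = sorted(in_cat[pair] - others)
        gene_sets[cat] = sets
    return full, gene_sets
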