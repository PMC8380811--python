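"""Per-gene significance machinery: one-way ANOVA with Tukey HSD contrasts.

Each gene is tested separately on the log2(RQ) scale.  Within a cell type the
factor is the culture condition (monolayer + the ten pellet time points, one
Tukey family of 55 pairs from which the baseline contrasts are reported);
across cell types the factor is cell type at a fixed time point.  Tukey
adjustment uses the studentized range distribution with the Tukey-Kramer
standard error for unequal group sizes, so the reported p-values control the
familywise error rate over all pairs of the family even though only the
contrasts of interest are returned.  Significance is strict: p_adj < alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import studentized_range

from .design import MONOLAYER, time_sort_key

SCOPE_TIME = "TIME_VS_BASELINE"
SCOPE_MONOLAYER = "MONOLAYER_VS_BASELINE"
SCOPE_CELLTYPE = "CELLTYPE_PAIR"


@dataclass(frozen=True)
class AnovaFit:
    """One-way ANOVA decomposition over labelled groups."""

    labels: tuple[str, ...]
    means: tuple[float, ...]
    ns: tuple[int, ...]
    f_stat: float
    p_value: float
    mse: float
    df_resid: int
    ss_between: float
    ss_within: float

    @property
    def k(self) -> int:
        return len(self.labels)

    def mean(self, label: str) -> float:
        return self.means[self.labels.index(label)]

    def n(self, label: str) -> int:
        return self.ns[self.labels.index(label)]


@dataclass(frozen=True)
class ContrastResult:
    """One Tukey-adjusted pairwise comparison on the log2-RQ scale."""

    level_a: str
    level_b: str
    estimate: float
    p_adj: float
    significant: bool
    direction: str
    scope: str = ""
    gene: str = ""
    cell_type: str = ""
    time_point: str = ""


def log_transform(rq: pd.DataFrame) -> pd.DataFrame:
    """Append a ``log2_rq`` column (= -ddCt); nonpositive RQ is an error."""
    if (rq["rq"] <= 0).any():
        bad = rq.loc[rq["rq"] <= 0].iloc[0]
        raise ValueError(f"nonpositive RQ for gene {bad['gene']!r}, sample {bad['sample_id']!r}")
    out = rq.copy()
    out["log2_rq"] = np.log2(out["rq"].to_numpy(float))
    return out


def prepare_expression(rq: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Join log2-RQ values with sample metadata, dropping the calibrator."""
    log = log_transform(rq)
    meta = samples.loc[
        ~samples["is_calibrator"], ["sample_id", "cell_type", "time_point", "replicate"]
    ]
    return log.merge(meta, on="sample_id", how="inner")


def anova_oneway(groups: Mapping[str, Sequence[float]]) -> AnovaFit:
    """Classical one-way ANOVA over labelled groups.

    Every group needs at least two values; with zero residual variance the
    fit is degenerate: p = 0 when the group means differ (the F statistic is
    unbounded), p = 1 when all values are identical, with a warning either
    way.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    labels = tuple(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    for g, a in zip(labels, arrays):
        if a.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    ns = tuple(int(a.size) for a in arrays)
    means = tuple(float(a.mean()) for a in arrays)
    n_total = sum(ns)
    grand = sum(a.sum() for a in arrays) / n_total
    ss_between = float(sum(n * (m - grand) ** 2 for n, m in zip(ns, means)))
    ss_within = float(sum(((a - m) ** 2).sum() for a, m in zip(arrays, means)))
    df_between = len(labels) - 1
    df_resid = n_total - len(labels)
    mse = ss_within / df_resid
    if mse == 0.0:
        warnings.warn("zero residual variance: degenerate ANOVA", stacklevel=2)
        f_stat, p = (np.inf, 0.0) if ss_between > 0 else (0.0, 1.0)
    else:
        f_stat = (ss_between / df_between) / mse
        p = float(f_dist.sf(f_stat, df_between, df_resid))
    return AnovaFit(
        labels=labels,
        means=means,
        ns=ns,
        f_stat=float(f_stat),
        p_value=float(p),
        mse=float(mse),
        df_resid=df_resid,
        ss_between=ss_between,
        ss_within=ss_within,
    )


def tukey_contrasts(
    fit: AnovaFit,
    alpha: float = 0.05,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> list[ContrastResult]:
    """Tukey(-Kramer) HSD contrasts from a fitted one-way ANOVA.

    For a pair (a, b): q = |mean_a - mean_b| / sqrt(mse/2 * (1/n_a + 1/n_b))
    and p_adj is the upper tail of the studentized range distribution with
    the family's k groups and residual df — the adjustment always spans the
    whole family even when only a subset of pairs is requested.  The
    reported estimate is mean_a - mean_b, direction its sign, and a pair is
    significant when p_adj is strictly below alpha.
    """
    if fit.df_resid < 1:
        raise ValueError("residual degrees of freedom must be >= 1")
    if pairs is None:
        pairs = list(combinations(fit.labels, 2))
    estimates = np.array([fit.mean(a) - fit.mean(b) for a, b in pairs])
    if fit.mse > 0:
        ses = np.array(
            [np.sqrt(fit.mse / 2.0 * (1.0 / fit.n(a) + 1.0 / fit.n(b))) for a, b in pairs]
        )
        q_obs = np.abs(estimates) / ses
        p_adj = studentized_range.sf(q_obs, fit.k, fit.df_resid)
        p_adj = np.clip(np.nan_to_num(p_adj, nan=1.0), 0.0, 1.0)
    else:
        p_adj = np.where(estimates == 0.0, 1.0, 0.0)
    out = []
    for (a, b), est, p in zip(pairs, estimates, p_adj):
        out.append(
            ContrastResult(
                level_a=a,
                level_b=b,
                estimate=float(est),
                p_adj=float(p),
                significant=bool(p < alpha),
                direction="UP" if est > 0 else ("DOWN" if est < 0 else ""),
            )
        )
    return out


def _groups_from_frame(
    data: pd.DataFrame, by: str, value: str = "log2_rq", min_n: int = 2
) -> dict[str, np.ndarray]:
    groups = {}
    for label, grp in data.groupby(by, sort=False):
        values = grp[value].to_numpy(float)
        if values.size < min_n:
            warnings.warn(f"level {label!r} has <{min_n} values; dropped", stacklevel=3)
            continue
        groups[str(label)] = values
    return groups


def timecourse_contrasts(
    expr: pd.DataFrame,
    gene: str,
    cell_type: str,
    alpha: float = 0.05,
    baseline: str = "0",
) -> list[ContrastResult]:
    """Baseline contrasts of one gene's time course within one cell type.

    A single one-way ANOVA over all culture conditions (monolayer + pellet
    time points) with Tukey adjustment over every pair; the returned
    contrasts are each post-baseline time point vs the 0 h baseline
    (scope TIME_VS_BASELINE) plus monolayer vs 0 h
    (scope MONOLAYER_VS_BASELINE), oriented so the estimate is
    level - baseline.
    """
    data = expr[(expr["gene"] == gene) & (expr["cell_type"] == cell_type)]
    if data.empty:
        raise ValueError(f"no data for gene {gene!r} in cell type {cell_type!r}")
    groups = _groups_from_frame(data, "time_point")
    if baseline not in groups:
        raise ValueError(f"baseline level {baseline!r} missing for {gene}/{cell_type}")
    ordered = sorted(groups, key=time_sort_key)
    fit = anova_oneway({t: groups[t] for t in ordered})
    pairs = [(t, baseline) for t in ordered if t != baseline]
    results = tukey_contrasts(fit, alpha=alpha, pairs=pairs)
    return [
        replace(
            r,
            scope=SCOPE_MONOLAYER if r.level_a == MONOLAYER else SCOPE_TIME,
            gene=gene,
            cell_type=cell_type,
        )
        for r in results
    ]


def celltype_contrasts(
    expr: pd.DataFrame,
    gene: str,
    time_point: str,
    alpha: float = 0.05,
) -> list[ContrastResult]:
    """Pairwise cell-type contrasts of one gene at one fixed time point."""
    data = expr[(expr["gene"] == gene) & (expr["time_point"] == time_point)]
    groups = _groups_from_frame(data, "cell_type")
    expected = sorted(data["cell_type"].unique())
    if len(groups) < len(expected):
        warnings.warn(
            f"{gene} @ {time_point}: cell type(s) missing; their pairs omitted", stacklevel=2
        )
    if len(groups) < 2:
        return []
    fit = anova_oneway(groups)
    results = tukey_contrasts(fit, alpha=alpha)
    return [
        replace(r, scope=SCOPE_CELLTYPE, gene=gene, time_point=time_point) for r in results
    ]


def contrasts_to_frame(contrasts: Sequence[ContrastResult]) -> pd.DataFrame:
    """Flatten contrast results into the on-disk table layout."""
    return pd.DataFrame(
        [
            {
                "gene": c.gene,
                "scope": c.scope,
                "cell_type": c.cell_type,
                "time_point": c.time_point,
                "level_a": c.level_a,
                "level_b": c.level_b,
                "estimate": c.estimate,
                "p_adj": c.p_adj,
                "significant": c.significant,
                "direction": c.direction,
            }
            for c in contrasts
        ]
    )
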