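"""Endogenous-control selection, delta-delta-Ct quantification and QC filters.

The quantification chain is the classical dual-reference comparative-Ct
method: within each sample, dCt = Ct(gene) - mean Ct of the selected
endogenous controls; ddCt = dCt - dCt of the same gene in the calibrator
sample (a pooled positive control); RQ = 2**(-ddCt).  Because both controls
are measured in the same reaction chamber set as the gene, per-chip Ct
offsets cancel in dCt, so no explicit inter-plate correction is applied; the
dilution series is used only to estimate amplification efficiency and to
report cross-chip agreement.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

NONDETECT_POLICIES = ("drop", "censor")


def rank_control_stability(
    ct: pd.DataFrame,
    panel: pd.DataFrame,
    samples: pd.DataFrame | None = None,
    candidates: Sequence[str] | None = None,
    top_k: int = 2,
) -> tuple[pd.DataFrame, list[str]]:
    """Rank endogenous-control candidates by raw Ct stability.

    The stability score is the standard deviation of detected Ct across all
    experimental samples (the calibrator is excluded); candidates are ordered
    ascending, ties broken alphabetically, and the best ``top_k`` become the
    selected controls.  Candidates with fewer than 3 detected measurements
    are excluded from the ranking with a warning.

    Returns the ranking table (gene, stability score, n detected, selected
    flag) and the selected control list.
    """
    gene_of = dict(zip(panel["assay_id"], panel["gene_symbol"]))
    if candidates is None:
        candidates = list(panel.loc[panel["is_control_candidate"], "gene_symbol"])
    if len(candidates) < 2:
        warnings.warn(
            "fewer than 2 control candidates: dual-reference averaging is degenerate",
            stacklevel=2,
        )
    data = ct.copy()
    data["gene"] = data["assay_id"].map(gene_of)
    if samples is not None:
        experimental = set(samples.loc[~samples["is_calibrator"], "sample_id"])
        data = data[data["sample_id"].isin(experimental)]

    rows = []
    for gene in candidates:
        values = data.loc[data["gene"] == gene, "ct"].dropna()
        if len(values) < 3:
            warnings.warn(f"control candidate {gene!r} has <3 detected values; excluded from ranking", stacklevel=2)
            continue
        rows.append({"gene": gene, "stability_ct_sd": float(values.std(ddof=1)), "n_detected": len(values)})
    if not rows:
        raise ValueError("no control candidate has enough detected measurements")
    ranking = (
        pd.DataFrame(rows)
        .sort_values(["stability_ct_sd", "gene"], kind="mergesort")
        .reset_index(drop=True)
    )
    ranking["selected"] = ranking.index < top_k
    return ranking, list(ranking.loc[ranking["selected"], "gene"])


def compute_relative_quantity(
    ct: pd.DataFrame,
    panel: pd.DataFrame,
    samples: pd.DataFrame,
    controls: Sequence[str],
    nondetect_policy: str = "drop",
    nondetect_ct_limit: float = 28.0,
) -> pd.DataFrame:
    """Dual-reference ddCt relative quantification against the calibrator.

    Per sample, dCt = Ct(gene) - mean(Ct of the selected controls in that
    sample); ddCt subtracts the calibrator's dCt for the same gene and
    RQ = 2**(-ddCt).  Samples in which any selected control is a non-detect
    are dropped for all genes with a warning.  A gene that is a non-detect in
    a sample yields a missing RQ under the default ``drop`` policy, or is
    censored at ``nondetect_ct_limit`` cycles under ``censor``; a gene
    undetected in the calibrator has no RQ at all unless censoring is active.

    Returns a long table (gene, sample_id, d_ct, dd_ct, rq) covering every
    usable sample including the calibrator itself (where RQ is identically 1).
    """
    if nondetect_policy not in NONDETECT_POLICIES:
        raise ValueError(f"nondetect_policy must be one of {NONDETECT_POLICIES}")
    gene_of = dict(zip(panel["assay_id"], panel["gene_symbol"]))
    cal_ids = samples.loc[samples["is_calibrator"], "sample_id"]
    if len(cal_ids) != 1:
        raise ValueError("exactly one calibrator sample is required")
    calibrator = cal_ids.iloc[0]

    data = ct.copy()
    data["gene"] = data["assay_id"].map(gene_of)
    wide = data.pivot(index="gene", columns="sample_id", values="ct")
    missing_controls = [c for c in controls if c not in wide.index]
    if missing_controls:
        raise ValueError(f"controls not present in data: {missing_controls}")

    ctrl = wide.loc[list(controls)]
    usable = ctrl.notna().all(axis=0)
    dropped = sorted(usable.index[~usable])
    if dropped:
        warnings.warn(
            f"{len(dropped)} sample(s) dropped: control non-detect, e.g. {dropped[:3]}",
            stacklevel=2,
        )
    if calibrator not in usable.index or not usable[calibrator]:
        raise ValueError("a selected control is undetected in the calibrator sample")

    target = wide.drop(index=list(controls)).loc[:, usable[usable].index]
    if nondetect_policy == "censor":
        target = target.fillna(nondetect_ct_limit)
    d_ct = target.sub(ctrl.loc[:, usable[usable].index].mean(axis=0), axis=1)

    cal_dct = d_ct[calibrator]
    uncalibrated = sorted(cal_dct.index[cal_dct.isna()])
    if uncalibrated:
        warnings.warn(
            f"gene(s) undetected in calibrator, RQ not computed: {uncalibrated}",
            stacklevel=2,
        )
    dd_ct = d_ct.sub(cal_dct, axis=0)
    rq = np.exp2(-dd_ct)

    long = (
        pd.concat(
            {"d_ct": d_ct, "dd_ct": dd_ct, "rq": rq},
            names=["quantity"],
        )
        .stack(future_stack=True)
        .unstack("quantity")
        .reset_index()
    )
    long = long.dropna(subset=["rq"])
    return long[["gene", "sample_id", "d_ct", "dd_ct", "rq"]].reset_index(drop=True)


def estimate_efficiency(dilutions: pd.DataFrame, min_points: int = 3) -> pd.DataFrame:
    """Per-assay amplification efficiency from the dilution standard curve.

    Ordinary least squares of Ct on log10(concentration); the efficiency is
    E = 10**(-1/slope) - 1 and R-squared measures curve quality.  Assays with
    a non-negative or too-shallow slope (|slope| < 1) or fewer than
    ``min_points`` detected dilution points are flagged as having no valid
    standard curve (efficiency left missing).
    """
    rows = []
    for assay_id, grp in dilutions.groupby("assay_id", sort=True):
        detected = grp.dropna(subset=["ct"])
        row = {"assay_id": assay_id, "n_points": len(detected), "slope": np.nan,
               "efficiency": np.nan, "r_squared": np.nan, "valid": False}
        if len(detected) >= min_points:
            x = np.log10(detected["concentration_ng_ul"].to_numpy(float))
            y = detected["ct"].to_numpy(float)
            slope, intercept = np.polyfit(x, y, 1)
            resid = y - (slope * x + intercept)
            ss_tot = float(np.sum((y - y.mean()) ** 2))
            row["slope"] = float(slope)
            row["r_squared"] = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan
            if slope < 0 and abs(slope) >= 1:
                row["efficiency"] = 10.0 ** (-1.0 / slope) - 1.0
                row["valid"] = True
            else:
                warnings.warn(f"assay {assay_id!r}: no valid standard curve (slope {slope:.3g})", stacklevel=2)
        rows.append(row)
    return pd.DataFrame(rows)


def interplate_deviation(dilutions: pd.DataFrame) -> tuple[float, pd.DataFrame]:
    """Cross-chip Ct agreement of the dilution series.

    For every (assay, concentration) measured on more than one chip, the Ct
    range (max - min) across chips is computed; the maximum range is the
    headline inter-plate deviation.  Purely diagnostic — no correction is
    applied.
    """
    detected = dilutions.dropna(subset=["ct"])
    per = (
        detected.groupby(["assay_id", "concentration_ng_ul"])["ct"]
        .agg(lambda v: v.max() - v.min())
        .rename("ct_range")
        .reset_index()
    )
    return float(per["ct_range"].max()), per


def flag_low_expression(
    rq: pd.DataFrame,
    samples: pd.DataFrame,
    threshold: float = 0.02,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Flag minimally expressed genes.

    A gene is flagged MINIMAL_EXPRESSION when the maximum over all
    (cell type, time point) group-mean RQs across experimental samples is
    below ``threshold`` — i.e. the gene never rises to a meaningful fraction
    of its calibrator level in any condition.  A gene with no computable RQ
    in any experimental sample (listed via ``genes`` but absent from the RQ
    table) is likewise flagged.
    """
    meta = samples.loc[~samples["is_calibrator"], ["sample_id", "cell_type", "time_point"]]
    data = rq.merge(meta, on="sample_id", how="inner")
    group_means = (
        data.groupby(["gene", "cell_type", "time_point"])["rq"].mean().rename("mean_rq").reset_index()
    )
    max_mean = group_means.groupby("gene")["mean_rq"].max()
    all_genes = sorted(set(rq["gene"].unique()) | set(genes or ()))
    rows = []
    for gene in all_genes:
        peak = max_mean.get(gene, np.nan)
        flagged = bool(np.isnan(peak) or peak < threshold)
        rows.append({"gene": gene, "max_group_mean_rq": peak, "minimal_expression": flagged})
    return pd.DataFrame(rows)


def validate_assays(pc_ct: pd.DataFrame, detection_ceiling: float = 35.0) -> pd.DataFrame:
    """Check amplification of every assay in the positive-control run.

    An assay amplified if it was detected at or below the detection ceiling.
    Non-amplifying assays are flagged NO_AMPLIFICATION but retained with a
    warning — absence from the positive-control pool does not preclude
    expression in the experimental samples.
    """
    rows = []
    for row in pc_ct.sort_values("assay_id").itertuples():
        amplified = bool(not np.isnan(row.ct) and row.ct <= detection_ceiling)
        rows.append(
            {
                "assay_id": row.assay_id,
                "amplified_in_positive_control": amplified,
                "pc_ct": row.ct,
                "flag": "" if amplified else "NO_AMPLIFICATION",
            }
        )
    out = pd.DataFrame(rows)
    n_failed = int((~out["amplified_in_positive_control"]).sum())
    if n_failed:
        warnings.warn(f"{n_failed} assay(s) did not amplify in the positive control; retained", stacklevel=2)
    return out
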