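"""End-to-end orchestration: simulate/load -> normalize -> analyze -> report.

:func:`run_pipeline` drives the full analysis on either a simulated dataset
or CSV inputs, writes every stage's tables to the output directory together
with a JSON run manifest (seed, parameters, per-stage counts), and cleans up
partial output on failure.  Outputs are deterministic for a given
configuration and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .design import MONOLAYER, SamplingDesign
from .divergence import categorize_divergence, patterns_to_frame, summarize_divergence
from .io_qpcr import Dataset, read_ct_long, write_table
from .kinetics import (
    classify_trajectory,
    monolayer_effect,
    profiles_to_frame,
    summarize_onset_by_annotation,
    tabulate_trajectory_classes,
)
from .normalize import (
    compute_relative_quantity,
    estimate_efficiency,
    flag_low_expression,
    interplate_deviation,
    rank_control_stability,
    validate_assays,
)
from .simulate import SimulatedDataset, SimulationSpec, generate_dataset
from .stats import (
    SCOPE_MONOLAYER,
    celltype_contrasts,
    contrasts_to_frame,
    prepare_expression,
    timecourse_contrasts,
)

logger = logging.getLogger("qpcrkinetics")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs; every field appears in the manifest."""

    out_dir: Path
    input_dir: Path | None = None
    simulation: SimulationSpec | None = None
    alpha: float = 0.05
    low_rq_threshold: float = 0.02
    nondetect_policy: str = "drop"
    controls: str | tuple[str, ...] = "auto"
    low_signal_genes: tuple[str, ...] = ()
    seed: int = 0
    design: SamplingDesign | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if (self.input_dir is None) == (self.simulation is None):
            raise ValueError("exactly one of input_dir or simulation must be given")


def _canonical_pair_order(contrast, cell_order: Sequence[str]):
    """Orient a cell-type contrast so level_a precedes level_b in design order."""
    order = {c: i for i, c in enumerate(cell_order)}
    if order.get(contrast.level_a, 99) <= order.get(contrast.level_b, 99):
        return contrast
    return replace(
        contrast,
        level_a=contrast.level_b,
        level_b=contrast.level_a,
        estimate=-contrast.estimate,
        direction={"UP": "DOWN", "DOWN": "UP"}.get(contrast.direction, ""),
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run(config, out, written)
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise


def _write(df: pd.DataFrame, out: Path, name: str, written: list[Path], seed: int) -> None:
    """write_table plus the run-provenance comment header."""
    path = out / name
    with open(path, "w") as fh:
        fh.write(f"# qpcrkinetics {__version__} seed={seed}\n")
    key_cols = [c for c in df.columns if df[c].dtype.kind not in "fc"]
    ordered = df.sort_values(key_cols, kind="mergesort") if key_cols else df
    ordered.to_csv(path, index=False, float_format="%.6g", na_rep="", lineterminator="\n", mode="a")
    written.append(path)


def _run(config: PipelineConfig, out: Path, written: list[Path]) -> dict:
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "alpha": config.alpha,
        "low_rq_threshold": config.low_rq_threshold,
        "nondetect_policy": config.nondetect_policy,
        "counts": {},
    }
    counts = manifest["counts"]
    low_signal = set(config.low_signal_genes)

    # ---- inputs -----------------------------------------------------------
    dilutions = pc_ct = truth = None
    if config.simulation is not None:
        spec = config.simulation
        logger.info("simulating dataset (seed=%d)", spec.seed)
        sim: SimulatedDataset = generate_dataset(spec)
        ct, samples, panel = sim.ct, sim.samples, sim.panel
        truth, pc_ct, dilutions = sim.truth, sim.pc_assessment, sim.dilutions
        design = spec.design
        low_signal |= set(spec.low_signal_genes)
        nondetect_limit = spec.nondetect_ct_limit
        for name, df in [
            ("ct_long.csv", ct), ("samples.csv", samples), ("panel.csv", panel),
            ("truth.csv", truth), ("pc_assessment.csv", pc_ct), ("dilutions.csv", dilutions),
        ]:
            _write(df, out, name, written, config.seed)
    else:
        indir = Path(config.input_dir)
        for required in ("ct_long.csv", "samples.csv", "panel.csv"):
            if not (indir / required).exists():
                raise FileNotFoundError(f"required input file missing: {indir / required}")
        design = config.design or SamplingDesign()
        dataset: Dataset = read_ct_long(
            indir / "ct_long.csv", indir / "samples.csv", indir / "panel.csv", design=design
        )
        ct, samples, panel = dataset
        nondetect_limit = 28.0
        if (indir / "dilutions.csv").exists():
            dilutions = pd.read_csv(indir / "dilutions.csv", comment="#")
        if (indir / "pc_assessment.csv").exists():
            pc_ct = pd.read_csv(indir / "pc_assessment.csv", comment="#")

    counts["experimental_samples"] = int((~samples["is_calibrator"]).sum())
    counts["assays"] = len(panel)

    # ---- assay validation and efficiency ---------------------------------
    if pc_ct is not None:
        assay_qc = validate_assays(pc_ct)
        counts["assays_amplified_in_pc"] = int(assay_qc["amplified_in_positive_control"].sum())
    else:
        assay_qc = pd.DataFrame(
            {"assay_id": panel["assay_id"], "amplified_in_positive_control": True, "pc_ct": np.nan, "flag": ""}
        )
    if dilutions is not None:
        efficiency = estimate_efficiency(dilutions)
        max_dev, _ = interplate_deviation(dilutions)
        manifest["max_interplate_ct_deviation"] = round(float(max_dev), 4)
        _write(efficiency, out, "efficiency.csv", written, config.seed)

    # ---- normalization ----------------------------------------------------
    ranking, auto_controls = rank_control_stability(ct, panel, samples)
    controls = list(config.controls) if config.controls != "auto" else auto_controls
    manifest["controls"] = controls
    _write(ranking, out, "control_ranking.csv", written, config.seed)

    rq = compute_relative_quantity(
        ct, panel, samples, controls,
        nondetect_policy=config.nondetect_policy,
        nondetect_ct_limit=nondetect_limit,
    )
    _write(rq, out, "rq_long.csv", written, config.seed)

    target_genes = sorted(
        set(panel.loc[~panel["is_control_candidate"], "gene_symbol"]) - set(controls)
    )
    low_expr = flag_low_expression(
        rq, samples, threshold=config.low_rq_threshold, genes=target_genes
    )
    minimal = set(low_expr.loc[low_expr["minimal_expression"], "gene"])
    counts["minimal_expression_genes"] = len(minimal)
    counts["low_signal_genes"] = len(low_signal & set(target_genes))

    qc = panel[["assay_id", "gene_symbol"]].merge(assay_qc, on="assay_id", how="left")
    qc["excluded_reason"] = "NONE"
    qc.loc[~qc["amplified_in_positive_control"].fillna(True).astype(bool), "excluded_reason"] = "NONE"
    qc.loc[qc["gene_symbol"].isin(low_signal), "excluded_reason"] = "LOW_SIGNAL_QUALITY"
    qc.loc[qc["gene_symbol"].isin(minimal), "excluded_reason"] = "MINIMAL_EXPRESSION"
    _write(qc, out, "assay_qc.csv", written, config.seed)

    analyzed = [g for g in target_genes if g not in minimal and g not in low_signal]
    analyzed = [g for g in analyzed if g in set(rq["gene"])]
    counts["genes_analyzed"] = len(analyzed)

    # ---- per-gene statistics ----------------------------------------------
    expr = prepare_expression(rq[rq["gene"].isin(analyzed)], samples)
    time_results = []
    onset_profiles = []
    for gene in analyzed:
        for cell_type in design.cell_types:
            contrasts = timecourse_contrasts(expr, gene, cell_type, alpha=config.alpha)
            time_results.extend(contrasts)
            onset_profiles.append(classify_trajectory(contrasts))
    counts["combinations_analyzed"] = len(onset_profiles)
    time_frame = contrasts_to_frame(time_results)
    _write(time_frame, out, "contrasts_timecourse.csv", written, config.seed)

    ct_results = []
    pellet_times = ["0"] + list(design.post_baseline_labels)
    for gene in analyzed:
        for t in pellet_times:
            for c in celltype_contrasts(expr, gene, t, alpha=config.alpha):
                ct_results.append(_canonical_pair_order(c, design.cell_types))
    ct_frame = contrasts_to_frame(ct_results)
    _write(ct_frame, out, "contrasts_celltype.csv", written, config.seed)

    # ---- kinetics reports --------------------------------------------------
    profiles = profiles_to_frame(onset_profiles)
    _write(profiles, out, "onsets.csv", written, config.seed)
    class_counts = tabulate_trajectory_classes(profiles)
    counts["trajectory_classes"] = class_counts
    _write(
        pd.DataFrame([{"trajectory_class": k, "n_combinations": v} for k, v in class_counts.items()]),
        out, "trajectory_counts.csv", written, config.seed,
    )
    summary, pooled = summarize_onset_by_annotation(profiles, panel, design)
    if not summary.empty:
        _write(summary, out, "onset_summary.csv", written, config.seed)
        _write(pooled, out, "onset_summary_pooled.csv", written, config.seed)
    mono = monolayer_effect(time_results)
    counts["monolayer_affected_combinations"] = len(mono)
    counts["monolayer_affected_genes"] = int(mono["gene"].nunique()) if len(mono) else 0
    if len(mono):
        _write(mono, out, "monolayer_effects.csv", written, config.seed)

    # ---- divergence ---------------------------------------------------------
    by_pair: dict[tuple[str, str, str], list] = {}
    for c in ct_results:
        by_pair.setdefault((c.gene, c.level_a, c.level_b), []).append(c)
    patterns = [categorize_divergence(group) for group in by_pair.values()]
    pattern_frame = patterns_to_frame(patterns)
    _write(pattern_frame, out, "divergence_patterns.csv", written, config.seed)
    div_summary, gene_sets = summarize_divergence(pattern_frame)
    _write(div_summary, out, "divergence_summary.csv", written, config.seed)
    counts["divergence"] = {
        f"{row.pair}:{row.category}": int(row.n_genes) for row in div_summary.itertuples()
    }

    sets_path = out / "gene_sets.txt"
    with open(sets_path, "w") as fh:
        fh.write(f"# qpcrkinetics {__version__} seed={config.seed}\n")
        for category, sets in gene_sets.items():
            for scope, members in sets.items():
                fh.write(f"{category}\t{scope}\t{','.join(members)}\n")
    written.append(sets_path)

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(manifest_path)
    logger.info("pipeline complete: %d genes, %d combinations", counts["genes_analyzed"], counts["combinations_analyzed"])
    return manifest
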