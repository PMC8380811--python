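"""Calibration experiments: type-I error, onset recovery, efficiency recovery.

These run the full simulate -> normalize -> test chain on purpose-built
synthetic datasets and summarize how well the pipeline recovers known truth.
They back both the package's validation suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from .design import SamplingDesign, format_time
from .kinetics import classify_trajectory
from .normalize import compute_relative_quantity, estimate_efficiency
from .simulate import KineticProfile, SimulationSpec, generate_dataset, make_dilution_series
from .stats import SCOPE_TIME, prepare_expression, timecourse_contrasts

_CONTROLS = {"CTRLA": 19.0, "CTRLB": 21.0}
_CONTROL_SDS = {"CTRLA": 0.1, "CTRLB": 0.1}


def _single_celltype_spec(
    profiles: list[KineticProfile],
    noise_sd: float,
    n_replicates: int,
    seed: int,
) -> SimulationSpec:
    design = SamplingDesign(cell_types=("IZ",), n_replicates=n_replicates)
    return SimulationSpec(
        design=design,
        profiles=tuple(profiles),
        control_ct_means=_CONTROLS,
        control_ct_sds=_CONTROL_SDS,
        noise_sd=noise_sd,
        chip_offset_sd=0.2,
        seed=seed,
    )


def _run_families(spec: SimulationSpec, alpha: float = 0.05):
    """Simulate, normalize and return per-gene baseline contrasts."""
    sim = generate_dataset(spec)
    rq = compute_relative_quantity(
        sim.ct, sim.panel, sim.samples, controls=sorted(_CONTROLS)
    )
    expr = prepare_expression(rq, sim.samples)
    for gene in spec.genes:
        yield gene, timecourse_contrasts(expr, gene, "IZ", alpha=alpha)


def null_type_i_experiment(
    n_genes: int = 1000,
    noise_sd: float = 0.3,
    n_replicates: int = 7,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Familywise false-positive rate on genes with no true response.

    Simulates ``n_genes`` flat trajectories and reports the fraction of
    gene families with at least one significant time-vs-baseline contrast.
    With Tukey adjustment over the whole condition family this should not
    exceed alpha by more than simulation noise.
    """
    profiles = [
        KineticProfile(gene=f"NULL{i:04d}", cell_type="IZ", baseline_dct=3.0)
        for i in range(n_genes)
    ]
    spec = _single_celltype_spec(profiles, noise_sd, n_replicates, seed)
    n_positive = 0
    for _, contrasts in _run_families(spec, alpha):
        if any(c.significant for c in contrasts if c.scope == SCOPE_TIME):
            n_positive += 1
    return {"value": n_positive / n_genes, "n": n_genes}


def onset_recovery_experiment(
    n_genes: int = 200,
    magnitude_dct: float = 2.0,
    noise_sd: float = 0.3,
    n_replicates: int = 7,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Exact recovery of step-response onsets and trajectory classes.

    ``n_genes`` step genes (alternating up/down) with onsets cycling over
    the full post-baseline grid; reports the fraction whose classified
    trajectory class AND first onset both match the truth.
    """
    design = SamplingDesign(cell_types=("IZ",), n_replicates=n_replicates)
    grid = design.post_baseline_labels
    profiles = []
    for i in range(n_genes):
        onset = float(grid[i % len(grid)])
        profiles.append(
            KineticProfile(
                gene=f"STEP{i:04d}",
                cell_type="IZ",
                baseline_dct=3.0,
                response_type="STEP_UP" if i % 2 == 0 else "STEP_DOWN",
                onset_h=onset,
                magnitude_dct=magnitude_dct,
            )
        )
    truth = {
        p.gene: ("UP" if p.response_type == "STEP_UP" else "DOWN", format_time(p.onset_h))
        for p in profiles
    }
    spec = _single_celltype_spec(profiles, noise_sd, n_replicates, seed)
    n_exact = 0
    for gene, contrasts in _run_families(spec, alpha):
        profile = classify_trajectory(contrasts)
        cls, onset = truth[gene]
        if profile.trajectory_class == cls and profile.first_onset_h == onset:
            n_exact += 1
    return {"value": n_exact / n_genes, "n": n_genes}


def efficiency_recovery_experiment(
    true_efficiencies: tuple[float, ...] = (0.85, 0.95, 1.0),
    noise_sd: float = 0.15,
    seed: int = 0,
) -> dict:
    """Absolute error of standard-curve efficiency estimates.

    One assay per true efficiency, a 7-point 3-fold dilution series with
    ``noise_sd`` cycles of measurement noise on each chip; reports the
    estimated efficiency and |error| per assay.
    """
    design = SamplingDesign(cell_types=("IZ",), n_replicates=2)
    profiles = [
        KineticProfile(gene=f"EFF{i}", cell_type="IZ", baseline_dct=2.0)
        for i in range(len(true_efficiencies))
    ]
    spec = SimulationSpec(
        design=design,
        profiles=tuple(profiles),
        control_ct_means=_CONTROLS,
        control_ct_sds=_CONTROL_SDS,
        noise_sd=noise_sd,
        chip_offset_sd=0.0,
        n_chips=3,
        seed=seed,
    )
    efficiencies = {f"EFF{i}": e for i, e in enumerate(true_efficiencies)}
    dilutions = make_dilution_series(spec, efficiencies, rng=np.random.default_rng(seed))
    est = estimate_efficiency(dilutions)
    panel_gene = {f"A{i + 1:03d}": g for i, g in enumerate(sorted(_CONTROLS) + [p.gene for p in profiles])}
    out = {}
    for row in est.itertuples():
        gene = panel_gene[row.assay_id]
        if gene in efficiencies:
            out[gene] = {
                "true": efficiencies[gene],
                "estimated": float(row.efficiency),
                "abs_error": abs(float(row.efficiency) - efficiencies[gene]),
            }
    return out
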