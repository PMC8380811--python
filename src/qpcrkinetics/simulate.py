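"""Synthetic microfluidic qPCR datasets with known ground-truth kinetics.

The generative model works on the cycle-threshold (Ct) scale, after
pre-amplification (pre-amplification chemistry itself is not modeled):

    Ct(gene, sample) = chip_offset(chip) + control_level + baseline_dct
                       - effect(t; profile) + eps,   eps ~ N(0, noise_sd)

where ``control_level`` is the mean of the endogenous-control candidate Ct
means, ``baseline_dct`` positions the gene relative to the controls in a
given cell type, and ``effect`` is the expression response in cycles
(positive = more transcript = lower Ct).  Step responses are 0 before the
onset time and +/- ``magnitude_dct`` from the onset onward; a MIXED profile
flips sign at a second onset; a ramp option reaches the full magnitude
linearly over ``ramp_duration_h``.  Measurements whose Ct exceeds
``nondetect_ct_limit`` are emitted as non-detects.  The calibrator sample
(the pooled positive control) is generated noise-free at its own per-gene
expression level, which is distinct from the cell-type baselines, as a
multi-tissue RNA pool would be.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from .design import MONOLAYER, SamplingDesign, format_time

RESPONSE_TYPES = ("NONE", "STEP_UP", "STEP_DOWN", "MIXED")

#: The 3-fold positive-control dilution series loaded on each chip, ng/ul.
DEFAULT_DILUTION_CONCENTRATIONS = (125.0, 41.67, 13.89, 4.63, 1.54, 0.51, 0.17)


@dataclass(frozen=True)
class KineticProfile:
    """Ground-truth expression trajectory of one gene in one cell type.

    ``baseline_dct`` is the gene's Ct distance above the endogenous-control
    level before induction; ``magnitude_dct`` the response size in cycles.
    For a MIXED profile the first step runs opposite to ``second_direction``
    and the effect flips sign at ``second_onset_h``.
    ``monolayer_effect_dct`` is the expression difference of the pre-pellet
    monolayer relative to the 0 h pellet (negative = lower in monolayer).
    """

    gene: str
    cell_type: str
    baseline_dct: float
    response_type: str = "NONE"
    onset_h: float | None = None
    magnitude_dct: float | None = None
    second_onset_h: float | None = None
    second_direction: str | None = None
    monolayer_effect_dct: float = 0.0
    response_shape: str = "step"
    ramp_duration_h: float = 0.0

    def __post_init__(self) -> None:
        if self.response_type not in RESPONSE_TYPES:
            raise ValueError(f"unknown response type {self.response_type!r}")
        if self.response_type == "NONE":
            if self.onset_h is not None:
                raise ValueError(f"{self.gene}/{self.cell_type}: NONE profile cannot have an onset")
        else:
            if self.onset_h is None or self.magnitude_dct is None:
                raise ValueError(f"{self.gene}/{self.cell_type}: responsive profile needs onset and magnitude")
            if self.onset_h <= 0:
                raise ValueError(f"{self.gene}/{self.cell_type}: onset must be after the 0 h baseline")
            if self.magnitude_dct <= 0:
                raise ValueError(f"{self.gene}/{self.cell_type}: magnitude must be positive")
        if self.response_type == "MIXED":
            if self.second_onset_h is None or self.second_direction not in ("UP", "DOWN"):
                raise ValueError(f"{self.gene}/{self.cell_type}: MIXED needs second_onset_h and second_direction")
            if self.second_onset_h <= (self.onset_h or 0):
                raise ValueError(f"{self.gene}/{self.cell_type}: second onset must follow the first")
        if self.response_shape not in ("step", "ramp"):
            raise ValueError(f"unknown response shape {self.response_shape!r}")

    @property
    def first_direction(self) -> str | None:
        """Direction of the first expression change (None for NONE)."""
        if self.response_type == "NONE":
            return None
        if self.response_type == "STEP_UP":
            return "UP"
        if self.response_type == "STEP_DOWN":
            return "DOWN"
        return "DOWN" if self.second_direction == "UP" else "UP"

    def effect_dct(self, t_hours: float) -> float:
        """Expression effect in cycles at pellet time ``t_hours``."""
        if self.response_type == "NONE" or t_hours < self.onset_h:
            return 0.0
        scale = 1.0
        if self.response_shape == "ramp" and self.ramp_duration_h > 0:
            scale = min(1.0, (t_hours - self.onset_h) / self.ramp_duration_h)
        sign = 1.0 if self.first_direction == "UP" else -1.0
        if self.response_type == "MIXED" and t_hours >= self.second_onset_h:
            sign = -sign
            scale = 1.0
        return sign * self.magnitude_dct * scale


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of one synthetic chip experiment."""

    design: SamplingDesign
    profiles: tuple[KineticProfile, ...]
    control_ct_means: Mapping[str, float]
    control_ct_sds: Mapping[str, float]
    calibrator_dct: Mapping[str, float] | None = None
    annotation_groups: Mapping[str, frozenset[str]] = field(default_factory=dict)
    noise_sd: float = 0.3
    chip_offset_sd: float = 0.2
    nondetect_ct_limit: float = 28.0
    n_chips: int = 3
    dilution_efficiencies: Mapping[str, float] | float = 1.0
    dilution_concentrations: tuple[float, ...] = DEFAULT_DILUTION_CONCENTRATIONS
    pc_nondetect_genes: tuple[str, ...] = ()
    low_signal_genes: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "profiles", tuple(self.profiles))
        if self.noise_sd < 0 or self.chip_offset_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if len(self.control_ct_means) < 2:
            raise ValueError("at least 2 endogenous-control candidates are required")
        if set(self.control_ct_means) != set(self.control_ct_sds):
            raise ValueError("control means and sds must cover the same candidates")
        seen: set[tuple[str, str]] = set()
        for p in self.profiles:
            if p.cell_type not in self.design.cell_types:
                raise ValueError(f"profile references unknown cell type {p.cell_type!r}")
            if p.gene in self.control_ct_means:
                raise ValueError(f"profile references control candidate {p.gene!r}")
            if p.onset_h is not None and p.onset_h not in self.design.time_points_h:
                raise ValueError(f"{p.gene}/{p.cell_type}: onset {p.onset_h} not on the sampling grid")
            key = (p.gene, p.cell_type)
            if key in seen:
                raise ValueError(f"duplicate profile for {key}")
            seen.add(key)
        genes = self.genes
        for g in genes:
            cts = {ct for (gg, ct) in seen if gg == g}
            if cts != set(self.design.cell_types):
                raise ValueError(f"gene {g!r} needs exactly one profile per cell type")

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(sorted({p.gene for p in self.profiles}))

    @property
    def control_level(self) -> float:
        return float(np.mean(list(self.control_ct_means.values())))

    def calibrator_level(self, gene: str) -> float:
        """Per-gene delta-Ct of the pooled calibrator (defaults to the mean
        of the gene's cell-type baselines)."""
        if self.calibrator_dct is not None and gene in self.calibrator_dct:
            return float(self.calibrator_dct[gene])
        baselines = [p.baseline_dct for p in self.profiles if p.gene == gene]
        return float(np.mean(baselines))


class SimulatedDataset(NamedTuple):
    ct: pd.DataFrame
    samples: pd.DataFrame
    panel: pd.DataFrame
    truth: pd.DataFrame
    pc_assessment: pd.DataFrame
    dilutions: pd.DataFrame


CALIBRATOR_ID = "CAL"
CALIBRATOR_CELL_TYPE = "positive_control"


def _sample_id(cell_type: str, time_label: str, replicate: int) -> str:
    t = "ML" if time_label == MONOLAYER else time_label
    return f"{cell_type}_t{t}_r{replicate}"


def build_panel(spec: SimulationSpec) -> pd.DataFrame:
    """Gene panel implied by a simulation spec (controls first)."""
    rows = []
    names = sorted(spec.control_ct_means) + list(spec.genes)
    for i, gene in enumerate(names, start=1):
        rows.append(
            {
                "assay_id": f"A{i:03d}",
                "gene_symbol": gene,
                "is_control_candidate": gene in spec.control_ct_means,
                "annotation_groups": ";".join(sorted(spec.annotation_groups.get(gene, ()))),
            }
        )
    return pd.DataFrame(rows)


def generate_dataset(spec: SimulationSpec) -> SimulatedDataset:
    """Draw one complete synthetic dataset, fully reproducible from the seed.

    Returns the experimental Ct table (including the calibrator sample), the
    sample metadata, the gene panel, the ground-truth profile table, a
    positive-control assessment run (one Ct per assay, used for assay
    validation) and the on-chip dilution series.
    """
    rng = np.random.default_rng(spec.seed)
    design = spec.design
    panel = build_panel(spec)
    gene_of_assay = dict(zip(panel["assay_id"], panel["gene_symbol"]))
    base = spec.control_level

    chips = [f"chip{i + 1}" for i in range(spec.n_chips)]
    chip_offsets = dict(zip(chips, rng.normal(0.0, spec.chip_offset_sd, spec.n_chips)))

    sample_rows = []
    cells = design.expected_cells()
    block = math.ceil(len(cells) / spec.n_chips)
    chip_of_sample: dict[str, str] = {}
    for i, (ct_label, t_label, rep) in enumerate(cells):
        sid = _sample_id(ct_label, t_label, rep)
        chip_of_sample[sid] = chips[min(i // block, spec.n_chips - 1)]
        sample_rows.append(
            {
                "sample_id": sid,
                "cell_type": ct_label,
                "time_point": t_label,
                "replicate": rep,
                "is_calibrator": False,
                "qc_flags": "",
            }
        )
    sample_rows.append(
        {
            "sample_id": CALIBRATOR_ID,
            "cell_type": CALIBRATOR_CELL_TYPE,
            "time_point": "0",
            "replicate": 1,
            "is_calibrator": True,
            "qc_flags": "",
        }
    )
    chip_of_sample[CALIBRATOR_ID] = chips[0]
    samples = pd.DataFrame(sample_rows)

    profile_map = {(p.gene, p.cell_type): p for p in spec.profiles}
    ct_rows = []
    for assay_id, gene in gene_of_assay.items():
        is_control = gene in spec.control_ct_means
        for row in sample_rows:
            sid = row["sample_id"]
            offset = chip_offsets[chip_of_sample[sid]]
            if row["is_calibrator"]:
                level = spec.control_ct_means[gene] if is_control else base + spec.calibrator_level(gene)
                ct = offset + level  # noise-free by construction
            elif is_control:
                ct = offset + spec.control_ct_means[gene] + rng.normal(0.0, spec.control_ct_sds[gene])
            else:
                p = profile_map[(gene, row["cell_type"])]
                if row["time_point"] == MONOLAYER:
                    expr = p.monolayer_effect_dct
                else:
                    expr = p.effect_dct(float(row["time_point"]))
                ct = offset + base + p.baseline_dct - expr + rng.normal(0.0, spec.noise_sd)
            ct_rows.append(
                {
                    "assay_id": assay_id,
                    "sample_id": sid,
                    "ct": np.nan if ct > spec.nondetect_ct_limit else ct,
                    "chip_id": chip_of_sample[sid],
                }
            )
    ct_table = pd.DataFrame(ct_rows)

    truth = pd.DataFrame(
        [
            {
                "gene": p.gene,
                "cell_type": p.cell_type,
                "baseline_dct": p.baseline_dct,
                "response_type": p.response_type,
                "onset_h": p.onset_h,
                "magnitude_dct": p.magnitude_dct,
                "second_onset_h": p.second_onset_h,
                "second_direction": p.second_direction or "",
                "monolayer_effect_dct": p.monolayer_effect_dct,
            }
            for p in spec.profiles
        ]
    )

    pc_rows = []
    for assay_id, gene in gene_of_assay.items():
        if gene in spec.pc_nondetect_genes:
            ct = np.nan
        elif gene in spec.control_ct_means:
            ct = spec.control_ct_means[gene]
        else:
            ct = base + spec.calibrator_level(gene)
        pc_rows.append({"assay_id": assay_id, "sample_id": "PC_ASSESSMENT", "ct": ct, "chip_id": "pc_run"})
    pc_assessment = pd.DataFrame(pc_rows)

    dilutions = make_dilution_series(spec, spec.dilution_efficiencies, rng=rng)
    return SimulatedDataset(ct_table, samples, panel, truth, pc_assessment, dilutions)


def make_dilution_series(
    spec: SimulationSpec,
    efficiencies: Mapping[str, float] | float = 1.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate the positive-control dilution series.

    Ct falls log-linearly with log10 concentration with slope
    ``-1 / log10(1 + E)`` per decade, anchored at the most concentrated
    point, plus ``noise_sd`` measurement noise.  One series is emitted per
    chip (the inter-plate control layout).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    concs = np.asarray(spec.dilution_concentrations, dtype=float)
    if np.any(concs <= 0):
        raise ValueError("dilution concentrations must be positive")
    panel = build_panel(spec)
    rows = []
    for assay_id, gene in zip(panel["assay_id"], panel["gene_symbol"]):
        e = efficiencies if isinstance(efficiencies, (int, float)) else efficiencies.get(gene, 1.0)
        if not 0 < e:
            raise ValueError(f"efficiency for {gene!r} must be positive")
        slope = -1.0 / math.log10(1.0 + e)
        if gene in spec.control_ct_means:
            top_ct = spec.control_ct_means[gene] - 6.0
        else:
            top_ct = 12.0 + spec.calibrator_level(gene)
        for chip_i in range(spec.n_chips):
            chip = f"chip{chip_i + 1}"
            for conc in concs:
                ct = top_ct + slope * (math.log10(conc) - math.log10(concs.max()))
                ct += rng.normal(0.0, spec.noise_sd)
                rows.append(
                    {
                        "assay_id": assay_id,
                        "sample_id": f"DIL_{chip}_{conc:g}",
                        "ct": ct,
                        "chip_id": chip,
                        "concentration_ng_ul": conc,
                    }
                )
    return pd.DataFrame(rows)


def true_onsets(truth: pd.DataFrame) -> pd.DataFrame:
    """Ground-truth trajectory class and first onset per gene x cell type.

    The oracle for recovery tests: STEP_UP -> UP, STEP_DOWN -> DOWN,
    MIXED -> MIXED at its first onset, NONE -> STABLE with no onset.
    """
    rows = []
    for row in truth.itertuples():
        rtype = row.response_type
        if rtype == "NONE":
            cls, onset, direction = "STABLE", None, ""
        elif rtype == "STEP_UP":
            cls, onset, direction = "UP", row.onset_h, "UP"
        elif rtype == "STEP_DOWN":
            cls, onset, direction = "DOWN", row.onset_h, "DOWN"
        elif rtype == "MIXED":
            cls = "MIXED"
            onset = row.onset_h
            direction = "DOWN" if row.second_direction == "UP" else "UP"
        else:
            raise ValueError(f"unknown response type {rtype!r}")
        rows.append(
            {
                "gene": row.gene,
                "cell_type": row.cell_type,
                "trajectory_class": cls,
                "first_onset_h": "" if onset is None else format_time(onset),
                "first_direction": direction,
            }
        )
    return pd.DataFrame(rows)
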