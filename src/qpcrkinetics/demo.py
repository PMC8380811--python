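"""Default synthetic study: a full-size chondrogenesis chip experiment.

:func:`default_study_spec` builds a fixed, fully synthetic ground truth that
mirrors the structure of a 96.96 microfluidic chip run on three cell types
(interzone IZ, anlagen ANL, dermal fibroblast FB): 3 endogenous-control
candidates of differing stability, 93 target assays — of which 5 are
minimally expressed, 1 carries a low-fluorescence quality flag and 1 fails
to amplify in the (pre-amplification-free) positive-control assessment — and
7 biological replicates at 11 conditions (monolayer + 10 pellet time
points), i.e. 231 experimental samples plus calibrator and dilution series.

The 87 analyzable genes carry engineered kinetic profiles:

* the interzone-vs-anlagen divergence structure is exact by construction —
  11 genes differ at baseline and retain the difference, 3 differ at
  baseline and converge from the first post-induction time point (LOST),
  47 share a baseline but respond differently (BECAME), 26 behave
  identically (SIMILAR);
* first-onset times are drawn from annotation-group-specific distributions:
  transcription-regulation genes respond early (1.5-24 h), signaling genes
  across the whole course, ECM genes never before 3 h — with fibroblast
  responses delayed relative to the chondrogenic cell types;
* one gene responds in no cell type, four signaling genes are expressed at
  lower levels in monolayers than in 0 h pellets.

The ground-truth layout is frozen (an internal construction seed), so the
same study is simulated for every run seed; the run seed drives only the
measurement noise and chip offsets.
"""

from __future__ import annotations

import numpy as np

from .design import SamplingDesign
from .simulate import KineticProfile, SimulationSpec

CELL_TYPES = ("IZ", "ANL", "FB")

#: Endogenous-control candidates: two tight, one drifting.
CONTROL_CT_MEANS = {"B2M": 20.5, "GUSB": 21.4, "RPLP0": 18.2}
CONTROL_CT_SDS = {"B2M": 0.55, "GUSB": 0.12, "RPLP0": 0.10}

_CONSTRUCTION_SEED = 7  # freezes the ground-truth layout, not the noise

#: Onset-time sampling weights per annotation group (hours -> weight).
_ONSET_POOLS = {
    "TRANSCRIPTION": {1.5: 0.10, 3: 0.35, 6: 0.18, 12: 0.25, 24: 0.12},
    "SIGNALING": {1.5: 0.05, 3: 0.20, 6: 0.22, 12: 0.12, 24: 0.10, 48: 0.12, 96: 0.10, 168: 0.04, 336: 0.05},
    "ECM": {3: 0.20, 6: 0.12, 12: 0.25, 24: 0.12, 48: 0.10, 96: 0.10, 168: 0.06, 336: 0.05},
    "": {1.5: 0.05, 3: 0.15, 6: 0.2, 12: 0.15, 24: 0.15, 48: 0.1, 96: 0.1, 168: 0.05, 336: 0.05},
}

_TIME_GRID = (1.5, 3, 6, 12, 24, 48, 96, 168, 336)

MINIMAL_GENES = tuple(f"MN{i:02d}" for i in range(1, 6))
LOW_SIGNAL_GENE = "LS01"
PC_NONDETECT_GENE = "EC22"  # amplifies only after pre-amplification
NULL_RESPONDER_GENE = "UN02"  # responds in no cell type
MONOLAYER_GENES = ("SG01", "SG02", "SG03", "SG04")


def _gene_table() -> list[tuple[str, frozenset[str]]]:
    """The 93 target genes and their annotation-group memberships."""
    genes: list[tuple[str, frozenset[str]]] = []
    genes += [(f"TX{i:02d}", frozenset({"TRANSCRIPTION"})) for i in range(1, 13)]
    genes += [(f"TS{i:02d}", frozenset({"TRANSCRIPTION", "SIGNALING"})) for i in range(1, 4)]
    genes += [(f"SG{i:02d}", frozenset({"SIGNALING"})) for i in range(1, 48)]
    genes += [("SE01", frozenset({"SIGNALING", "ECM"}))]
    genes += [(f"EC{i:02d}", frozenset({"ECM"})) for i in range(1, 23)]
    genes += [("UN01", frozenset()), (NULL_RESPONDER_GENE, frozenset())]
    genes += [(g, frozenset()) for g in MINIMAL_GENES]
    genes += [(LOW_SIGNAL_GENE, frozenset())]
    return genes


def _primary_group(groups: frozenset[str]) -> str:
    for g in ("TRANSCRIPTION", "SIGNALING", "ECM"):
        if g in groups:
            return g
    return ""


def _draw_onset(rng: np.random.Generator, group: str, delayed: bool = False) -> float:
    pool = _ONSET_POOLS[group]
    times = np.array(list(pool))
    weights = np.array(list(pool.values()))
    onset = float(rng.choice(times, p=weights / weights.sum()))
    if delayed:
        i = _TIME_GRID.index(onset)
        onset = _TIME_GRID[min(i + int(rng.integers(1, 3)), len(_TIME_GRID) - 1)]
    return onset


def _response(
    rng: np.random.Generator,
    gene: str,
    cell_type: str,
    baseline: float,
    group: str,
    delayed: bool = False,
    force_direction: str | None = None,
) -> KineticProfile:
    """Draw a responsive profile, keeping DOWN responses above the detection
    floor (baseline + magnitude capped at 7 cycles over the control level)."""
    onset = _draw_onset(rng, group, delayed=delayed)
    magnitude = float(rng.uniform(2.0, 3.2))
    direction = force_direction or ("UP" if rng.random() < 0.5 else "DOWN")
    if direction == "DOWN" and baseline + magnitude > 7.0:
        direction = "UP"
    if direction != "MIXED" and force_direction is None and rng.random() < 0.12:
        direction = "MIXED"
    if direction == "MIXED":
        i = _TIME_GRID.index(onset)
        if i >= len(_TIME_GRID) - 1:
            onset = 12.0
            i = _TIME_GRID.index(onset)
        second = float(_TIME_GRID[int(rng.integers(i + 1, len(_TIME_GRID)))])
        first_dir = "UP" if (baseline + magnitude > 7.0 or rng.random() < 0.6) else "DOWN"
        return KineticProfile(
            gene=gene,
            cell_type=cell_type,
            baseline_dct=baseline,
            response_type="MIXED",
            onset_h=onset,
            magnitude_dct=magnitude,
            second_onset_h=second,
            second_direction="DOWN" if first_dir == "UP" else "UP",
        )
    return KineticProfile(
        gene=gene,
        cell_type=cell_type,
        baseline_dct=baseline,
        response_type="STEP_UP" if direction == "UP" else "STEP_DOWN",
        onset_h=onset,
        magnitude_dct=magnitude,
    )


def _stable(gene: str, cell_type: str, baseline: float) -> KineticProfile:
    return KineticProfile(gene=gene, cell_type=cell_type, baseline_dct=baseline)


def default_study_spec(
    seed: int = 0,
    noise_sd: float = 0.3,
    chip_offset_sd: float = 0.2,
    n_replicates: int = 7,
) -> SimulationSpec:
    """The package's default full-size synthetic study (see module docstring)."""
    rng = np.random.default_rng(_CONSTRUCTION_SEED)
    design = SamplingDesign(cell_types=CELL_TYPES, n_replicates=n_replicates)
    genes = _gene_table()
    analyzed = [
        (g, grp)
        for g, grp in genes
        if g not in MINIMAL_GENES and g != LOW_SIGNAL_GENE
    ]

    # Interzone-vs-anlagen divergence roles, spread across annotation groups.
    # Transcription-regulation genes are kept out of any role that leaves an
    # IZ/ANL trajectory flat: in the emulated study every gene in that group
    # responded in both chondrogenic cell types.
    groups_of = dict(genes)
    is_tx = lambda g: "TRANSCRIPTION" in groups_of[g]
    ordered = [g for g, _ in analyzed if g != NULL_RESPONDER_GENE]
    retained = ordered[0::8][:11]
    rest = [g for g in ordered if g not in retained]
    lost = [g for g in rest if not is_tx(g)][0::18][:3]
    rest = [g for g in rest if g not in lost]
    became = rest[0::3] + rest[1::3]
    became = became[:47]
    similar = [g for g in ordered if g not in retained and g not in lost and g not in became]
    similar.append(NULL_RESPONDER_GENE)

    profiles: list[KineticProfile] = []
    calibrator_dct: dict[str, float] = {}
    annotation: dict[str, frozenset[str]] = {g: grp for g, grp in genes}
    # Only one gene is allowed to be flat in every cell type; all other
    # stable trajectories are scattered over single cell types so that 86 of
    # the 87 analyzable genes respond somewhere.
    similar_stable = {NULL_RESPONDER_GENE}

    for gene, groups in analyzed:
        group = _primary_group(groups)
        b = float(rng.uniform(1.5, 4.0))
        mono = -2.0 if gene in MONOLAYER_GENES else 0.0

        def with_mono(p: KineticProfile, ct: str) -> KineticProfile:
            if mono and ct in ("IZ", "ANL"):
                return KineticProfile(
                    gene=p.gene, cell_type=p.cell_type, baseline_dct=p.baseline_dct,
                    response_type=p.response_type, onset_h=p.onset_h,
                    magnitude_dct=p.magnitude_dct, second_onset_h=p.second_onset_h,
                    second_direction=p.second_direction, monolayer_effect_dct=mono,
                )
            return p

        if gene in retained:
            # Baselines differ by 2.5 cycles; both cell types share the same
            # upward response, so the difference persists at every time point.
            iz_b, anl_b = b, b + 2.5
            shared = _response(rng, gene, "IZ", iz_b, group, force_direction="UP")
            iz = shared
            anl = KineticProfile(
                gene=gene, cell_type="ANL", baseline_dct=anl_b,
                response_type=shared.response_type, onset_h=shared.onset_h,
                magnitude_dct=shared.magnitude_dct,
            )
            if gene in retained[:3]:
                # different at baseline against fibroblasts too
                fb = KineticProfile(
                    gene=gene, cell_type="FB", baseline_dct=b - 2.5,
                    response_type=shared.response_type,
                    onset_h=_draw_onset(rng, group, delayed=True),
                    magnitude_dct=shared.magnitude_dct,
                )
            else:
                fb = _response(rng, gene, "FB", iz_b, group, delayed=True, force_direction="UP")
        elif gene in lost:
            # ANL starts 2.5 cycles below IZ and converges at the very first
            # post-induction time point; FB shares the IZ baseline but
            # responds late.
            iz = _stable(gene, "IZ", b)
            anl = KineticProfile(
                gene=gene, cell_type="ANL", baseline_dct=b + 2.5,
                response_type="STEP_UP", onset_h=1.5, magnitude_dct=2.5,
            )
            fb = KineticProfile(
                gene=gene, cell_type="FB", baseline_dct=b,
                response_type="STEP_UP", onset_h=float(rng.choice((96, 168))),
                magnitude_dct=2.5,
            )
        elif gene in became:
            # Same baseline, divergent responses; transcription genes always
            # respond in both chondrogenic cell types.
            if not is_tx(gene) and rng.random() < 0.45:
                iz = _response(rng, gene, "IZ", b, group)
                anl = _stable(gene, "ANL", b)
                if rng.random() < 0.5:
                    iz, anl = (
                        _stable(gene, "IZ", b),
                        _response(rng, gene, "ANL", b, group),
                    )
            else:
                iz = _response(rng, gene, "IZ", b, group, force_direction="UP")
                anl = _response(rng, gene, "ANL", b, group, force_direction="DOWN")
                if rng.random() < 0.45:
                    iz, anl = (
                        _response(rng, gene, "IZ", b, group, force_direction="DOWN"),
                        _response(rng, gene, "ANL", b, group, force_direction="UP"),
                    )
            fb = (
                _stable(gene, "FB", b)
                if rng.random() < 0.3
                else _response(rng, gene, "FB", b, group, delayed=True)
            )
        else:  # SIMILAR: identical trajectories in IZ and ANL
            if gene in similar_stable:
                iz, anl, fb = _stable(gene, "IZ", b), _stable(gene, "ANL", b), _stable(gene, "FB", b)
            else:
                iz = _response(rng, gene, "IZ", b, group)
                anl = KineticProfile(
                    gene=gene, cell_type="ANL", baseline_dct=b,
                    response_type=iz.response_type, onset_h=iz.onset_h,
                    magnitude_dct=iz.magnitude_dct, second_onset_h=iz.second_onset_h,
                    second_direction=iz.second_direction,
                )
                fb = (
                    _stable(gene, "FB", b)
                    if rng.random() < 0.3
                    else _response(rng, gene, "FB", b, group, delayed=True)
                )
        profiles += [with_mono(iz, "IZ"), with_mono(anl, "ANL"), with_mono(fb, "FB")]
        calibrator_dct[gene] = float(rng.uniform(1.0, 5.0))

    # Minimally expressed targets: far above the detection limit in every
    # experimental sample, but well expressed in the pooled calibrator.
    for gene in MINIMAL_GENES:
        for ct in CELL_TYPES:
            profiles.append(_stable(gene, ct, 9.3))
        calibrator_dct[gene] = 2.0
    # Low-fluorescence assay: unremarkable Ct values; excluded via its
    # instrument quality flag, not via the Ct model.
    for ct in CELL_TYPES:
        profiles.append(_stable(LOW_SIGNAL_GENE, ct, 3.0))
    calibrator_dct[LOW_SIGNAL_GENE] = 3.0

    return SimulationSpec(
        design=design,
        profiles=tuple(profiles),
        control_ct_means=CONTROL_CT_MEANS,
        control_ct_sds=CONTROL_CT_SDS,
        calibrator_dct=calibrator_dct,
        annotation_groups=annotation,
        noise_sd=noise_sd,
        chip_offset_sd=chip_offset_sd,
        pc_nondetect_genes=(PC_NONDETECT_GENE,),
        low_signal_genes=(LOW_SIGNAL_GENE,),
        seed=seed,
    )
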