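import warnings
from pathlib import Path

import pytest

from qpcrkinetics.design import SamplingDesign
from qpcrkinetics.simulate import KineticProfile, SimulationSpec, generate_dataset

TINY_CONTROL_MEANS = {"CTRLA": 19.0, "CTRLB": 21.0}
TINY_CONTROL_SDS = {"CTRLA": 0.1, "CTRLB": 0.1}


def make_spec(profiles, design=None, **kwargs):
    """SimulationSpec with small-footprint defaults for unit tests."""
    design = design or SamplingDesign(
        cell_types=("IZ", "ANL"), time_points_h=(0, 1.5, 3, 6), n_replicates=3
    )
    defaults = dict(
        control_ct_means=TINY_CONTROL_MEANS,
        control_ct_sds=TINY_CONTROL_SDS,
        noise_sd=0.1,
        chip_offset_sd=0.1,
        seed=7,
    )
    defaults.update(kwargs)
    return SimulationSpec(design=design, profiles=tuple(profiles), **defaults)


@pytest.fixture
def tiny_design():
    return SamplingDesign(
        cell_types=("IZ", "ANL"), time_points_h=(0, 1.5, 3, 6), n_replicates=3
    )


@pytest.fixture
def tiny_dataset(tiny_design):
    """Three genes: an up-step in IZ only, a flat gene, a down-step in both."""
    profiles = []
    for ct in tiny_design.cell_types:
        profiles += [
            KineticProfile(
                gene="GUP", cell_type=ct, baseline_dct=3.0,
                response_type="STEP_UP" if ct == "IZ" else "NONE",
                onset_h=3.0 if ct == "IZ" else None,
                magnitude_dct=2.5 if ct == "IZ" else None,
            ),
            KineticProfile(gene="GFLAT", cell_type=ct, baseline_dct=2.0),
            KineticProfile(
                gene="GDOWN", cell_type=ct, baseline_dct=1.5,
                response_type="STEP_DOWN", onset_h=1.5, magnitude_dct=2.0,
            ),
        ]
    spec = make_spec(profiles, design=tiny_design)
    return spec, generate_dataset(spec)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full-size default-study pipeline run, shared across tests."""
    from qpcrkinetics.demo import default_study_spec
    from qpcrkinetics.pipeline import PipelineConfig, run_pipeline

    out = tmp_path_factory.mktemp("demo_run")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        config = PipelineConfig(
            out_dir=out, simulation=default_study_spec(seed=1), seed=1
        )
        manifest = run_pipeline(config)
    return out, manifest
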