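import numpy as np
import pandas as pd
import pytest

from qpcrkinetics.normalize import (
    compute_relative_quantity,
    estimate_efficiency,
    flag_low_expression,
    interplate_deviation,
    rank_control_stability,
    validate_assays,
)
from qpcrkinetics.simulate import KineticProfile, generate_dataset
from tests.conftest import make_spec


def _tables(ct_by_gene, calibrator="CAL", control_genes=("R1", "R2")):
    """Build ct/panel/samples frames from {gene: {sample: ct}}."""
    genes = list(ct_by_gene)
    panel = pd.DataFrame(
        {
            "assay_id": [f"A{i}" for i in range(len(genes))],
            "gene_symbol": genes,
            "is_control_candidate": [g in control_genes for g in genes],
            "annotation_groups": "",
        }
    )
    assay_of = dict(zip(genes, panel["assay_id"]))
    rows = []
    sample_ids = sorted({s for v in ct_by_gene.values() for s in v})
    for g, by_sample in ct_by_gene.items():
        for s in sample_ids:
            rows.append(
                {"assay_id": assay_of[g], "sample_id": s, "ct": by_sample.get(s, np.nan), "chip_id": "c1"}
            )
    ct = pd.DataFrame(rows)
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "cell_type": "IZ",
            "time_point": [str(float(i)) for i in range(len(sample_ids))],
            "replicate": 1,
            "is_calibrator": [s == calibrator for s in sample_ids],
            "qc_flags": "",
        }
    )
    return ct, panel, samples


class TestControlRanking:
    def test_orders_by_sd_with_alphabetical_ties(self):
        rng = np.random.default_rng(0)
        n = 40
        ct_by_gene = {
            "A": {f"S{i}": 20 + 0.10 * z for i, z in enumerate(rng.normal(size=n))},
            "B": {f"S{i}": 20 + 0.40 * z for i, z in enumerate(rng.normal(size=n))},
            "C": {f"S{i}": 20 + 0.12 * z for i, z in enumerate(rng.normal(size=n))},
        }
        ct, panel, _ = _tables(ct_by_gene, control_genes=("A", "B", "C"))
        ranking, selected = rank_control_stability(ct, panel)
        assert list(ranking["gene"]) == ["A", "C", "B"]
        assert selected == ["A", "C"]

    def test_single_candidate_warns_and_is_selected(self):
        ct, panel, _ = _tables({"A": {f"S{i}": 20.0 + 0.01 * i for i in range(5)}}, control_genes=("A",))
        with pytest.warns(UserWarning, match="degenerate"):
            _, selected = rank_control_stability(ct, panel)
        assert selected == ["A"]

    def test_recovers_tight_controls_from_simulation(self, tiny_design):
        profiles = [
            KineticProfile(gene="G1", cell_type=ct, baseline_dct=2.0)
            for ct in tiny_design.cell_types
        ]
        spec = make_spec(
            profiles,
            design=tiny_design,
            control_ct_means={"CTRLA": 19.0, "CTRLB": 21.0, "DRIFT": 20.0},
            control_ct_sds={"CTRLA": 0.1, "CTRLB": 0.1, "DRIFT": 0.5},
            seed=11,
        )
        ds = generate_dataset(spec)
        _, selected = rank_control_stability(ds.ct, ds.panel, ds.samples)
        assert set(selected) == {"CTRLA", "CTRLB"}


class TestRelativeQuantity:
    def test_worked_example(self):
        # gene Ct 25 with controls at 21/19 -> dCt 5; calibrator dCt 3 -> ddCt 2, RQ 0.25
        ct, panel, samples = _tables(
            {
                "R1": {"CAL": 21.0, "S1": 21.0},
                "R2": {"CAL": 19.0, "S1": 19.0},
                "G": {"CAL": 23.0, "S1": 25.0},
            }
        )
        rq = compute_relative_quantity(ct, panel, samples, ["R1", "R2"]).set_index("sample_id")
        assert rq.loc["S1", "d_ct"] == pytest.approx(5.0)
        assert rq.loc["S1", "dd_ct"] == pytest.approx(2.0)
        assert rq.loc["S1", "rq"] == pytest.approx(0.25)
        assert rq.loc["CAL", "rq"] == pytest.approx(1.0)

    @pytest.mark.parametrize("dd_ct, expected", [(0.0, 1.0), (-3.0, 8.0)])
    def test_fold_change_identities(self, dd_ct, expected):
        ct, panel, samples = _tables(
            {
                "R1": {"CAL": 20.0, "S1": 20.0},
                "R2": {"CAL": 20.0, "S1": 20.0},
                "G": {"CAL": 22.0, "S1": 22.0 + dd_ct},
            }
        )
        rq = compute_relative_quantity(ct, panel, samples, ["R1", "R2"]).set_index("sample_id")
        assert rq.loc["S1", "rq"] == pytest.approx(expected)

    def test_control_nondetect_drops_whole_sample(self):
        ct, panel, samples = _tables(
            {
                "R1": {"CAL": 20.0, "S1": 20.0, "S2": np.nan},
                "R2": {"CAL": 20.0, "S1": 20.0, "S2": 20.0},
                "G": {"CAL": 22.0, "S1": 23.0, "S2": 23.0},
            }
        )
        with pytest.warns(UserWarning, match="control non-detect"):
            rq = compute_relative_quantity(ct, panel, samples, ["R1", "R2"])
        assert "S2" not in set(rq["sample_id"])

    def test_gene_nondetect_policy(self):
        tables = _tables(
            {
                "R1": {"CAL": 20.0, "S1": 20.0},
                "R2": {"CAL": 20.0, "S1": 20.0},
                "G": {"CAL": 22.0, "S1": np.nan},
            }
        )
        dropped = compute_relative_quantity(*tables[:3], ["R1", "R2"], nondetect_policy="drop")
        assert set(dropped.loc[dropped["gene"] == "G", "sample_id"]) == {"CAL"}
        censored = compute_relative_quantity(
            *tables[:3], ["R1", "R2"], nondetect_policy="censor", nondetect_ct_limit=28.0
        ).set_index("sample_id")
        assert censored.loc["S1", "d_ct"] == pytest.approx(8.0)

    def test_gene_undetected_in_calibrator_warns(self):
        ct, panel, samples = _tables(
            {
                "R1": {"CAL": 20.0, "S1": 20.0},
                "R2": {"CAL": 20.0, "S1": 20.0},
                "G": {"CAL": np.nan, "S1": 23.0},
            }
        )
        with pytest.warns(UserWarning, match="undetected in calibrator"):
            rq = compute_relative_quantity(ct, panel, samples, ["R1", "R2"])
        assert "G" not in set(rq["gene"])


class TestEfficiency:
    def _dilutions(self, slope, intercept=20.0, concs=(125.0, 41.67, 13.89, 4.63, 1.54, 0.51, 0.17)):
        return pd.DataFrame(
            {
                "assay_id": "A1",
                "sample_id": [f"D{i}" for i in range(len(concs))],
                "ct": [intercept + slope * np.log10(c) for c in concs],
                "chip_id": "c1",
                "concentration_ng_ul": concs,
            }
        )

    def test_perfect_doubling_gives_full_efficiency(self):
        est = estimate_efficiency(self._dilutions(slope=-1 / np.log10(2)))
        assert est.iloc[0]["efficiency"] == pytest.approx(1.0, abs=1e-9)
        assert est.iloc[0]["r_squared"] == pytest.approx(1.0)

    def test_formula_for_known_slope(self):
        est = estimate_efficiency(self._dilutions(slope=-3.6))
        assert est.iloc[0]["efficiency"] == pytest.approx(10 ** (1 / 3.6) - 1, abs=1e-9)

    def test_flat_curve_flagged(self):
        with pytest.warns(UserWarning, match="no valid standard curve"):
            est = estimate_efficiency(self._dilutions(slope=0.0))
        assert not est.iloc[0]["valid"]
        assert np.isnan(est.iloc[0]["efficiency"])

    def test_interplate_deviation_reports_range(self):
        a = self._dilutions(slope=-3.3)
        b = a.copy()
        b["chip_id"] = "c2"
        b["ct"] += 0.25
        dev, per = interplate_deviation(pd.concat([a, b]))
        assert dev == pytest.approx(0.25)


class TestExpressionFilters:
    def test_low_and_high_expression_flags(self):
        rq = pd.DataFrame(
            {
                "gene": ["L"] * 4 + ["H"] * 4,
                "sample_id": ["S1", "S2", "S3", "S4"] * 2,
                "d_ct": 0.0,
                "dd_ct": 0.0,
                "rq": [0.01, 0.011, 0.009, 0.012, 0.5, 0.6, 0.01, 0.01],
            }
        )
        samples = pd.DataFrame(
            {
                "sample_id": ["S1", "S2", "S3", "S4"],
                "cell_type": ["IZ", "IZ", "ANL", "ANL"],
                "time_point": ["0", "3", "0", "3"],
                "replicate": [1, 1, 1, 1],
                "is_calibrator": False,
                "qc_flags": "",
            }
        )
        flags = flag_low_expression(rq, samples).set_index("gene")
        assert flags.loc["L", "minimal_expression"]
        assert not flags.loc["H", "minimal_expression"]

    def test_gene_with_no_rq_is_flagged(self):
        rq = pd.DataFrame(
            {"gene": ["H"], "sample_id": ["S1"], "d_ct": [0.0], "dd_ct": [0.0], "rq": [1.0]}
        )
        samples = pd.DataFrame(
            {
                "sample_id": ["S1"], "cell_type": ["IZ"], "time_point": ["0"],
                "replicate": [1], "is_calibrator": [False], "qc_flags": [""],
            }
        )
        flags = flag_low_expression(rq, samples, genes=["H", "MISSING"]).set_index("gene")
        assert flags.loc["MISSING", "minimal_expression"]


class TestAssayValidation:
    def test_one_nondetect_among_96(self):
        pc = pd.DataFrame(
            {
                "assay_id": [f"A{i:03d}" for i in range(96)],
                "sample_id": "PC",
                "ct": [20.0] * 95 + [np.nan],
                "chip_id": "pc",
            }
        )
        with pytest.warns(UserWarning, match="did not amplify"):
            qc = validate_assays(pc)
        assert int(qc["amplified_in_positive_control"].sum()) == 95
        assert (qc.loc[~qc["amplified_in_positive_control"], "flag"] == "NO_AMPLIFICATION").all()

    def test_detection_ceiling(self):
        pc = pd.DataFrame(
            {"assay_id": ["A1", "A2"], "sample_id": "PC", "ct": [20.0, 39.0], "chip_id": "pc"}
        )
        with pytest.warns(UserWarning):
            qc = validate_assays(pc, detection_ceiling=35.0).set_index("assay_id")
        assert qc.loc["A1", "amplified_in_positive_control"]
        assert not qc.loc["A2", "amplified_in_positive_control"]
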