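import warnings

import numpy as np
import pandas as pd
import pytest

from calscreen import (
    PlateLayout,
    SelectionConfig,
    WellAssignment,
    call_activity,
    log2_effect_matrix,
    normalize_to_controls,
    run_cascade,
    zscore_per_plate,
)
from calscreen.errors import DataError, ParameterError
from calscreen.profiling import PARAM_COLUMNS
from calscreen.synthetic import generate_screen


def _params_table(n_controls=10, n_compounds=20, compound_p2=None, plate="P1"):
    rows = []
    for i in range(n_controls):
        rows.append({"plate": plate, "well": f"A{i+1}", "role": "agonist_control",
                     "compound_id": "", **{c: v for c, v in zip(PARAM_COLUMNS, [100, 400, 3.5, 500, -1.0, -0.5, 60000])}})
    for i in range(n_compounds):
        p2 = 400.0 if compound_p2 is None else compound_p2[i]
        rows.append({"plate": plate, "well": f"B{i+1}", "role": "compound",
                     "compound_id": f"C{i+1}", **{c: v for c, v in zip(PARAM_COLUMNS, [100, p2, 3.5, 100 + p2, -1.0, -0.5, 60000])}})
    return pd.DataFrame(rows)


def _layout_for(df, agonist="CRP"):
    wells = {}
    for _, r in df.iterrows():
        wells[r["well"]] = WellAssignment(
            role=r["role"],
            compound_id=r["compound_id"],
            concentration_um=10.0 if r["role"] == "compound" else None,
        )
    return PlateLayout(str(df["plate"].iloc[0]), "well1536", agonist, "A", 60.0, wells)


class TestNormalization:
    def test_percent_arithmetic(self):
        df = _params_table(compound_p2=[100.0] + [400.0] * 19)
        norm = normalize_to_controls(df, _layout_for(df))
        assert norm.loc[norm["compound_id"] == "C1", "p2_pct"].iloc[0] == pytest.approx(25.0)

    def test_controls_average_to_hundred(self):
        df = _params_table()
        norm = normalize_to_controls(df, _layout_for(df))
        controls = norm[norm["role"] == "agonist_control"]
        for col in PARAM_COLUMNS:
            assert controls[f"{col}_pct"].mean() == pytest.approx(100.0)

    def test_zero_control_mean_becomes_missing(self):
        df = _params_table()
        df.loc[df["role"] == "agonist_control", "p5"] = 0.0
        with pytest.warns(UserWarning, match="p5"):
            norm = normalize_to_controls(df, _layout_for(df))
        assert norm["p5_pct"].isna().all()

    def test_too_few_controls_rejects_plate(self):
        df = _params_table(n_controls=4)
        with pytest.raises(DataError, match="rejected"):
            normalize_to_controls(df, _layout_for(df))


class TestZScore:
    def test_classic_z_matches_independent_mean_sd(self):
        values = [95.0, 105.0] * 12 + [55.0]
        df = _params_table(n_compounds=25, compound_p2=values)
        norm = normalize_to_controls(df, _layout_for(df))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            z = zscore_per_plate(norm, SelectionConfig(robust_z=False))
        comp = z[z["role"] == "compound"]
        pct = comp["p2_pct"].to_numpy()
        expected = (pct - pct.mean()) / pct.std(ddof=1)
        np.testing.assert_allclose(comp["p2_z"].to_numpy(), expected, atol=1e-12)
        # the outlying well sits more than 4 SD below the plate mean
        assert comp.loc[comp["compound_id"] == "C25", "p2_z"].iloc[0] < -4.0

    def test_value_at_plate_mean_has_zero_z(self):
        values = [90.0, 110.0] * 10 + [100.0]  # plate mean is exactly 100
        df = _params_table(n_compounds=21, compound_p2=values)
        norm = normalize_to_controls(df, _layout_for(df))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            z = zscore_per_plate(norm, SelectionConfig(robust_z=False))
        comp = z[z["role"] == "compound"]
        assert comp.loc[comp["compound_id"] == "C21", "p2_z"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_constant_column_warns_and_zeroes(self):
        df = _params_table(n_compounds=20)
        norm = normalize_to_controls(df, _layout_for(df))
        with pytest.warns(UserWarning, match="zero spread"):
            z = zscore_per_plate(norm, SelectionConfig(robust_z=True))
        assert (z["p2_z"] == 0.0).all()

    def test_too_few_compound_wells_rejected(self):
        df = _params_table(n_compounds=10)
        norm = normalize_to_controls(df, _layout_for(df))
        with pytest.raises(DataError, match="compound wells"):
            zscore_per_plate(norm)


class TestCallActivity:
    def test_single_negative_direction_param(self):
        active, direction = call_activity({"p2_z": -5.0, "p3_z": 1.0, "p7_z": -0.5})
        assert active and direction == "inhibitor"

    def test_positive_direction_is_potentiator(self):
        active, direction = call_activity({"p2_z": 6.0})
        assert active and direction == "potentiator"

    def test_all_below_threshold_inactive(self):
        active, direction = call_activity({f"{p}_z": 3.9 for p in ("p2", "p3", "p7")})
        assert not active and direction == "none"

    def test_conflicting_directions_mixed(self):
        active, direction = call_activity({"p2_z": -5.0, "p7_z": 5.0})
        assert active and direction == "mixed"

    def test_direction_params_must_be_subset(self):
        with pytest.raises(ParameterError):
            SelectionConfig(active_parameters=("p2",), direction_parameters=("p2", "p7"))


@pytest.fixture(scope="module")
def screen():
    dataset, truth = generate_screen(n_compounds=80, seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        verdicts, report = run_cascade(dataset)
    return dataset, truth, verdicts, report


class TestCascade:
    def test_stage_counts_non_increasing(self, screen):
        _, _, _, report = screen
        for agonist, stages in report.stages.items():
            counts = [s["count"] for s in stages]
            assert counts == sorted(counts, reverse=True)

    def test_stages_are_nested_subsets(self, screen):
        _, _, _, report = screen
        for agonist, stages in report.stages.items():
            for prev, cur in zip(stages, stages[1:]):
                assert set(cur["ids"]) <= set(prev["ids"])

    def test_planted_specific_inhibitors_recovered(self, screen):
        _, truth, _, report = screen
        for agonist, sel in (("CRP", "CRP_only"), ("thrombin", "thrombin_only")):
            planted = set(truth.ids_with("inhibitor", sel))
            hits = set(report.stages[agonist][-1]["ids"])
            assert planted <= hits

    def test_dual_agonist_inhibitors_removed_at_specificity(self, screen):
        _, truth, _, report = screen
        dual = set(truth.ids_with("inhibitor", "both"))
        assert dual
        for agonist in ("CRP", "thrombin"):
            active = set(report.retained(agonist, "active"))
            specific = set(report.retained(agonist, "agonist_specific"))
            assert dual <= active
            assert not (dual & specific)

    def test_quenchers_removed_at_artifact_stage(self, screen):
        _, truth, _, report = screen
        quench = set(truth.ids_with("quencher"))
        assert quench
        assert quench <= set(report.rejected_at("CRP", "artifact_free"))

    def test_plate_order_invariance(self, screen):
        dataset, _, _, report = screen
        reordered = type(dataset)(
            plate_pairs=list(reversed(dataset.plate_pairs)),
            annotations=dataset.annotations,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, report2 = run_cascade(reordered)
        assert report.stages == report2.stages

    def test_admet_flag_rejects_hits(self, screen):
        dataset, truth, _, report = screen
        hits = report.stages["CRP"][-1]["ids"]
        assert hits
        annotations = pd.DataFrame(
            {"compound_id": [hits[0]], "library": ["test"], "admet_fail": [True]}
        )
        flagged = type(dataset)(plate_pairs=dataset.plate_pairs, annotations=annotations)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, report2 = run_cascade(flagged)
        assert hits[0] not in report2.stages["CRP"][-1]["ids"]
        assert set(report2.stages["CRP"][-1]["ids"]) == set(hits) - {hits[0]}


class TestLog2Matrix:
    def test_log2_of_full_effect_is_zero(self):
        df = pd.DataFrame({"compound_id": ["A"], **{f"{p}_pct": [100.0] for p in PARAM_COLUMNS}})
        mat = log2_effect_matrix(df)
        assert (mat.loc["A"] == 0.0).all()

    def test_half_effect_is_minus_one(self):
        df = pd.DataFrame({"compound_id": ["A"], **{f"{p}_pct": [50.0] for p in PARAM_COLUMNS}})
        assert (log2_effect_matrix(df).loc["A"] == -1.0).all()

    def test_non_positive_percent_missing(self):
        df = pd.DataFrame({"compound_id": ["A"], **{f"{p}_pct": [-5.0] for p in PARAM_COLUMNS}})
        assert log2_effect_matrix(df).loc["A"].isna().all()
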