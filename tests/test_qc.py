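import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from lipidharmony.nomenclature import parse_shorthand
from lipidharmony.qc import QCThresholds, apply_qc, cov, linearity_r2
from lipidharmony.quantify import InternalStandardMap
from lipidharmony.simulate import (
    SimulationConfig, build_is_map, generate, plant_qc_failures,
)

from .conftest import make_table


class TestCov:
    def test_constant_vector_is_zero(self):
        assert cov([5, 5, 5, 5]) == 0.0

    def test_hand_value(self):
        assert cov([1, 2, 3]) == pytest.approx(0.5)

    @given(st.floats(min_value=0.1, max_value=100.0))
    def test_scale_invariance(self, k):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        assert cov(k * x) == pytest.approx(cov(x), rel=1e-9)

    @pytest.mark.parametrize("values", [[1.0], [], [0.0, 0.0]])
    def test_undefined_cases_are_nan(self, values):
        assert np.isnan(cov(values))


class TestLinearityR2:
    def test_proportional_series(self):
        f = [0.5, 0.75, 1.0, 1.5, 2.0]
        assert linearity_r2(f, [2 * x for x in f]) == pytest.approx(1.0)

    def test_flat_response_is_zero(self):
        assert linearity_r2([0.5, 1.0, 1.5, 2.0], [3, 3, 3, 3]) == 0.0

    def test_matches_normal_equations_oracle(self):
        f = np.array([0.5, 0.75, 1.0, 1.5, 2.0])
        y = np.array([1.0, 1.4, 2.1, 3.0, 4.1])
        # closed-form least squares with intercept
        X = np.column_stack([np.ones_like(f), f])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        r2 = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        assert linearity_r2(f, y) == pytest.approx(r2, abs=1e-12)

    def test_out_of_range_points_excluded(self):
        # in-range points are a perfect line; 10% and 25% points saturate
        f = [0.10, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0]
        y = [5.0, 5.0] + [2 * x for x in f[2:]]
        assert linearity_r2(f, y) == pytest.approx(1.0)

    def test_too_few_in_range_points_is_nan(self):
        assert np.isnan(linearity_r2([0.5, 1.0], [1.0, 2.0]))


def _qc_fixture():
    """Three lipids, each tripping exactly one rule, plus one clean one."""
    inj = {}
    roles = {}
    for i in range(1, 5):
        roles[f"q{i}"] = "qc_ltr"
    for i in range(1, 3):
        roles[f"b{i}"] = "blank"
    dil = {}
    for k, f in enumerate((0.5, 0.75, 1.0, 1.5, 2.0), start=1):
        roles[f"d{k}"] = "dilution"
        dil[f"d{k}"] = f

    def rows(qc, blank, dilution):
        return dict(
            zip(["q1", "q2", "q3", "q4"], qc)
        ) | dict(zip(["b1", "b2"], blank)) | dict(
            zip(["d1", "d2", "d3", "d4", "d5"], dilution)
        )

    line = [1000 * f for f in (0.5, 0.75, 1.0, 1.5, 2.0)]
    flat = [1000.0] * 5
    data = {
        # A: noisy (CoV 25%), clean blank, linear
        "PC 34:1": rows([700, 1300, 800, 1200], [0, 0], line),
        # B: reproducible, contaminated blank (15% of QC), linear
        "PC 34:2": rows([1000, 1010, 990, 1000], [150, 150], line),
        # C: clean everywhere
        "PC 34:3": rows([1000, 1010, 990, 1000], [0, 0], line),
        # D: reproducible, clean blank, flat dilution response
        "PC 34:4": rows([1000, 1010, 990, 1000], [0, 0], flat),
        "IS PC": rows([1000] * 4, [1000, 1000], [1000.0] * 5),
    }
    table = make_table(data, roles=roles, dilution=dil)
    index = {n: parse_shorthand(n) for n in data if not n.startswith("IS")}
    is_map = InternalStandardMap(class_map={"PC": ("IS PC", 100.0)})
    return table, index, is_map


class TestApplyQC:
    def test_each_rule_trips_once(self):
        table, index, is_map = _qc_fixture()
        report = apply_qc(table, index, is_map)
        t = report.table
        assert not t.loc["PC 34:1", "pass_cov"]
        assert not t.loc["PC 34:2", "pass_blank"]
        assert not t.loc["PC 34:4", "pass_r2"]
        assert report.survivors == ["PC 34:3"]

    def test_cov_boundary_is_strict(self):
        """CoV exactly at the threshold fails (the cut is CoV < 20%)."""
        table, index, is_map = _qc_fixture()
        report = apply_qc(table, index, is_map)
        observed = report.table.loc["PC 34:1", "cov"]
        boundary = QCThresholds(cov_max=float(observed))
        again = apply_qc(table, index, is_map, boundary)
        assert not again.table.loc["PC 34:1", "pass_cov"]

    def test_r2_boundary_is_strict(self):
        table, index, is_map = _qc_fixture()
        report = apply_qc(table, index, is_map)
        r2 = float(report.table.loc["PC 34:3", "r2"])
        boundary = QCThresholds(r2_min=r2)  # R² must strictly exceed
        again = apply_qc(table, index, is_map, boundary)
        assert not again.table.loc["PC 34:3", "pass_r2"]

    def test_relaxing_thresholds_never_shrinks_survivors(self):
        table, index, is_map = _qc_fixture()
        strict = set(apply_qc(table, index, is_map, QCThresholds()).survivors)
        relaxed = set(
            apply_qc(
                table, index, is_map,
                QCThresholds(cov_max=0.5, blank_ratio_max=0.5, r2_min=0.5),
            ).survivors
        )
        assert strict <= relaxed

    def test_verdicts_recompute_from_reported_statistics(self):
        table, index, is_map = _qc_fixture()
        report = apply_qc(table, index, is_map)
        t, th = report.table, report.thresholds
        recomputed = (
            (t["cov"] < th.cov_max)
            & (t["blank_ratio"] < th.blank_ratio_max)
            & (t["r2"] > th.r2_min)
        )
        pd.testing.assert_series_equal(
            recomputed, t["pass_overall"], check_names=False
        )

    def test_missing_role_fails_by_default_but_can_skip(self):
        table, index, is_map = _qc_fixture()
        from lipidharmony.tables import MeasurementTable

        no_blank = MeasurementTable(
            table.intensities.drop(columns=["b1", "b2"]),
            table.injections.drop(index=["b1", "b2"]),
        )
        failing = apply_qc(no_blank, index, is_map)
        assert failing.survivors == []
        skipping = apply_qc(
            no_blank, index, is_map, QCThresholds(missing_role_policy="skip")
        )
        assert "PC 34:3" in skipping.survivors


class TestPlantedFailures:
    def test_survivor_set_equals_planted_pass_set(self):
        """Noise-free planting: QC excludes exactly the planted failures."""
        cfg = SimulationConfig(
            classes=("PC", "LPC", "PE", "SM", "TG"), lipids_per_class=10,
            methods=("RP",), technical_cov=0.0, seed=11,
        )
        cfg = plant_qc_failures(cfg, n_contamination=5, n_high_cov=4, n_nonlinear=3)
        tables, truth = generate(cfg)
        report = apply_qc(tables["RP"], truth.species_index, build_is_map(cfg))
        assert set(report.survivors) == set(truth.planted_pass)
        assert len(truth.planted_fail) == 12

    def test_450_detected_to_142_quantifiable(self):
        """450 detected features, 308 planted failures → exactly 142 survive."""
        cfg = SimulationConfig(
            classes=("PC", "LPC", "PE", "LPE", "PI", "PS", "SM", "Cer", "TG"),
            lipids_per_class=50, methods=("DI",), technical_cov=0.0, seed=4,
        )
        cfg = plant_qc_failures(cfg, n_contamination=120, n_high_cov=100, n_nonlinear=88)
        tables, truth = generate(cfg)
        assert len(truth.species_index) == 450
        report = apply_qc(tables["DI"], truth.species_index, build_is_map(cfg))
        assert len(report.survivors) == 142
        assert set(report.survivors) == set(truth.planted_pass)
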