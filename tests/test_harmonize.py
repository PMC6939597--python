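import numpy as np
import pandas as pd
import pytest

from lipidharmony.harmonize import (
    ConsensusValues,
    median_fold_align,
    reference_normalize,
    summarize_reference,
)
from lipidharmony.tables import ConcentrationTable


def conc_table(values: dict, roles: dict, method="m1", state="raw"):
    df = pd.DataFrame(values).T.astype(float)
    meta = pd.DataFrame(index=list(df.columns))
    meta["sample"] = "s"
    meta["role"] = [roles[c] for c in df.columns]
    meta["method"] = method
    meta["batch"] = 0
    meta["replicate"] = range(len(df.columns))
    meta["dilution_fraction"] = np.nan
    return ConcentrationTable(df, meta, method=method, state=state)


class TestSummarizeReference:
    def test_mean_policy(self):
        t = conc_table({"PC 34:1": {"r1": 4, "r2": 5, "r3": 6}},
                       {"r1": "reference", "r2": "reference", "r3": "reference"})
        assert summarize_reference(t, "mean").values["PC 34:1"] == 5.0

    def test_single_replicate_same_under_both_policies(self):
        t = conc_table({"PC 34:1": {"r1": 7}}, {"r1": "reference"})
        assert summarize_reference(t, "mean").values["PC 34:1"] == 7.0
        assert summarize_reference(t, "median").values["PC 34:1"] == 7.0

    def test_policies_differ_on_skewed_replicates(self):
        t = conc_table({"PC 34:1": {"r1": 1, "r2": 1, "r3": 10}},
                       {"r1": "reference", "r2": "reference", "r3": "reference"})
        assert summarize_reference(t, "mean").values["PC 34:1"] == 4.0
        assert summarize_reference(t, "median").values["PC 34:1"] == 1.0

    def test_no_reference_columns_is_hard_error(self):
        t = conc_table({"PC 34:1": {"s1": 1}}, {"s1": "study"})
        with pytest.raises(ValueError, match="reference"):
            summarize_reference(t)


class TestReferenceNormalize:
    def test_sample_equal_to_reference_maps_to_consensus(self):
        t = conc_table(
            {"PC 34:1": {"s1": 3.0, "r1": 3.0}}, {"s1": "study", "r1": "reference"}
        )
        consensus = ConsensusValues({"PC 34:1": 2.5})
        out, dropped = reference_normalize(t, summarize_reference(t), consensus)
        assert out.values.loc["PC 34:1", "s1"] == pytest.approx(2.5)
        assert out.state == "consensus-scaled"
        assert dropped == []

    def test_without_consensus_output_is_ratio(self):
        t = conc_table(
            {"PC 34:1": {"s1": 6.0, "r1": 3.0}}, {"s1": "study", "r1": "reference"}
        )
        out, _ = reference_normalize(t, summarize_reference(t))
        assert out.values.loc["PC 34:1", "s1"] == pytest.approx(2.0)
        assert out.state == "reference-normalized"

    def test_per_lipid_multiplicative_bias_cancels(self):
        """The core theorem: method B = per-lipid bias × method A normalizes
        to an identical table."""
        rng = np.random.default_rng(0)
        lipids = [f"PC 34:{d}" for d in range(5)]
        base = {
            lip: {"s1": rng.uniform(1, 10), "s2": rng.uniform(1, 10),
                  "r1": rng.uniform(1, 10), "r2": rng.uniform(1, 10)}
            for lip in lipids
        }
        roles = {"s1": "study", "s2": "study", "r1": "reference", "r2": "reference"}
        a = conc_table(base, roles, method="A")
        bias = pd.Series(np.exp(rng.normal(0, 0.5, len(lipids))), index=lipids)
        b = ConcentrationTable(
            a.values.mul(bias, axis=0), a.injections, method="B"
        )
        out_a, _ = reference_normalize(a, summarize_reference(a))
        out_b, _ = reference_normalize(b, summarize_reference(b))
        np.testing.assert_allclose(
            out_a.values.to_numpy(), out_b.values.to_numpy(), rtol=1e-12
        )

    def test_idempotent_against_unit_reference(self):
        t = conc_table(
            {"PC 34:1": {"s1": 6.0, "r1": 3.0}}, {"s1": "study", "r1": "reference"}
        )
        once, _ = reference_normalize(t, summarize_reference(t))
        twice, _ = reference_normalize(once, summarize_reference(once))
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_own_reference_as_consensus_restores_reference_columns(self):
        t = conc_table(
            {"PC 34:1": {"s1": 6.0, "r1": 3.0, "r2": 5.0}},
            {"s1": "study", "r1": "reference", "r2": "reference"},
        )
        summary = summarize_reference(t)
        consensus = ConsensusValues(dict(summary.values))
        out, _ = reference_normalize(t, summary, consensus)
        # the mean of the normalized reference columns is the consensus value
        assert out.values.loc["PC 34:1", ["r1", "r2"]].mean() == pytest.approx(4.0)
        np.testing.assert_allclose(
            out.values.loc["PC 34:1"], t.values.loc["PC 34:1"], rtol=1e-12
        )

    def test_lipid_without_reference_is_dropped_and_reported(self):
        t = conc_table(
            {"PC 34:1": {"s1": 6.0, "r1": 3.0}, "PC 36:1": {"s1": 2.0, "r1": 0.0}},
            {"s1": "study", "r1": "reference"},
        )
        with pytest.warns(UserWarning, match="dropped"):
            out, dropped = reference_normalize(t, summarize_reference(t))
        assert dropped == ["PC 36:1"]
        assert "PC 36:1" not in out.lipids

    def test_method_mismatch_is_hard_error(self):
        t = conc_table({"PC 34:1": {"s1": 1, "r1": 1}},
                       {"s1": "study", "r1": "reference"}, method="A")
        other = conc_table({"PC 34:1": {"s1": 1, "r1": 1}},
                           {"s1": "study", "r1": "reference"}, method="B")
        with pytest.raises(ValueError, match="method"):
            reference_normalize(t, summarize_reference(other))


class TestMedianFoldAlign:
    def _site(self, factor=1.0, method="s1"):
        values = {
            "PC 34:1": {"a": 2.0 * factor, "b": 4.0 * factor, "r1": 3.0 * factor},
            "PC 34:2": {"a": 1.0 * factor, "b": 5.0 * factor, "r1": 2.0 * factor},
        }
        roles = {"a": "study", "b": "study", "r1": "reference"}
        return conc_table(values, roles, method=method)

    def test_identical_sites_align_to_equal_tables(self):
        aligned = median_fold_align(
            {"s1": self._site(method="s1"), "s2": self._site(method="s2")}
        )
        np.testing.assert_allclose(
            aligned["s1"].values.to_numpy(), aligned["s2"].values.to_numpy()
        )

    def test_global_fold_between_sites_cancels(self):
        aligned = median_fold_align(
            {"s1": self._site(1.0, "s1"), "s2": self._site(2.0, "s2")}
        )
        np.testing.assert_allclose(
            aligned["s1"].values.to_numpy(), aligned["s2"].values.to_numpy(),
            rtol=1e-12,
        )

    def test_per_lipid_lognormal_bias_cancels_exactly(self):
        """Noise-free per-lipid per-site bias → post-alignment ratio 1."""
        rng = np.random.default_rng(3)
        lipids = [f"PC 34:{d}" for d in range(10)]
        truth = pd.Series(rng.uniform(1, 100, 10), index=lipids)
        ref_truth = pd.Series(rng.uniform(1, 100, 10), index=lipids)
        sites = {}
        for site in ("s1", "s2"):
            bias = pd.Series(np.exp(rng.normal(0, 0.5, 10)), index=lipids)
            values = {
                lip: {"a": truth[lip] * bias[lip], "r1": ref_truth[lip] * bias[lip],
                      "r2": ref_truth[lip] * bias[lip]}
                for lip in lipids
            }
            sites[site] = conc_table(
                values, {"a": "study", "r1": "reference", "r2": "reference"},
                method=site,
            )
        aligned = median_fold_align(sites, rescale="grand-median")
        ratio = aligned["s1"].values["a"] / aligned["s2"].values["a"]
        np.testing.assert_allclose(ratio, 1.0, rtol=1e-12)

    def test_lipid_missing_reference_at_one_site_excluded(self):
        s1 = self._site(method="s1")
        s2_values = s1.values.copy()
        s2_values.loc["PC 34:2", "r1"] = 0.0
        s2 = ConcentrationTable(s2_values, s1.injections, method="s2")
        aligned = median_fold_align({"s1": s1, "s2": s2})
        assert "PC 34:2" not in aligned["s1"].lipids
        assert "PC 34:2" not in aligned["s2"].lipids
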