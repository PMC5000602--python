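import numpy as np
import pandas as pd
import pytest

from tcskit.errors import ValidationError
from tcskit.expression import CtTable, delta_delta_ct, hclust_order, log2_matrix
from tcskit.synthetic import simulate_ct_table


def table_from_ct(ct_map, reference="UBI", control="control"):
    """ct_map: {(gene, sample): ct or [ct, ...]}"""
    rows = []
    for (gene, sample), cts in ct_map.items():
        for i, ct in enumerate(np.atleast_1d(cts), 1):
            rows.append({"gene": gene, "sample": sample, "replicate": i, "ct": float(ct)})
    return CtTable(pd.DataFrame(rows), reference, control)


class TestDeltaDeltaCt:
    def test_unchanged_ct_pattern_gives_fold_one(self):
        t = table_from_ct({
            ("g", "control"): 25, ("g", "treat"): 25,
            ("UBI", "control"): 20, ("UBI", "treat"): 20,
        })
        m = delta_delta_ct(t)
        assert m.values.loc["g", "treat"] == pytest.approx(1.0)

    def test_one_cycle_earlier_doubles_expression(self):
        t = table_from_ct({
            ("g", "control"): 25, ("g", "treat"): 24,
            ("UBI", "control"): 20, ("UBI", "treat"): 20,
        })
        assert delta_delta_ct(t).values.loc["g", "treat"] == pytest.approx(2.0)

    def test_control_column_exactly_one(self):
        t = table_from_ct({
            ("g", "control"): [25.3, 25.1], ("g", "treat"): 24,
            ("UBI", "control"): [20.2, 19.9], ("UBI", "treat"): 20,
        })
        assert (delta_delta_ct(t).values["control"] == 1.0).all()

    def test_replicates_averaged_before_subtraction(self):
        t = table_from_ct({
            ("g", "control"): [25, 27], ("g", "treat"): [24, 26],  # mean -1
            ("UBI", "control"): 20, ("UBI", "treat"): 20,
        })
        assert delta_delta_ct(t).values.loc["g", "treat"] == pytest.approx(2.0)

    def test_per_sample_ct_shift_cancels(self):
        base = {
            ("g", "control"): 25, ("g", "treat"): 23.5,
            ("UBI", "control"): 20, ("UBI", "treat"): 20,
        }
        shifted = dict(base)
        shifted[("g", "treat")] = 23.5 + 3.0
        shifted[("UBI", "treat")] = 20 + 3.0
        a = delta_delta_ct(table_from_ct(base)).values
        b = delta_delta_ct(table_from_ct(shifted)).values
        assert np.allclose(a, b)

    def test_missing_reference_ct_names_sample(self):
        t = table_from_ct({
            ("g", "control"): 25, ("g", "treat"): 24,
            ("UBI", "control"): 20,
        })
        with pytest.raises(ValidationError, match="treat"):
            delta_delta_ct(t)

    def test_missing_control_sample_rejected(self):
        t = table_from_ct({("g", "treat"): 24, ("UBI", "treat"): 20})
        with pytest.raises(ValidationError, match="control"):
            delta_delta_ct(t)


class TestLog2:
    def _mat(self):
        t = table_from_ct({
            ("g", "control"): 25, ("g", "treat"): 24,
            ("h", "control"): 25, ("h", "treat"): 25,
            ("UBI", "control"): 20, ("UBI", "treat"): 20,
        })
        return delta_delta_ct(t)

    def test_fold_two_maps_to_one(self):
        lm = log2_matrix(self._mat())
        assert lm.values.loc["g", "treat"] == pytest.approx(1.0)
        assert lm.values.loc["h", "treat"] == pytest.approx(0.0)
        assert (lm.values["control"] == 0.0).all()

    def test_round_trip(self):
        m = self._mat()
        lm = log2_matrix(m)
        assert np.allclose(np.power(2.0, lm.values), m.values)

    def test_nonpositive_entry_rejected(self):
        m = self._mat()
        m.values.loc["g", "treat"] = 0.0
        with pytest.raises(ValidationError):
            log2_matrix(m)


class TestHclustOrder:
    def test_identical_rows_merge_first(self):
        m = self._planted(sep=0.0)
        order, link = hclust_order(m)
        # first merge joins the two zero-distance rows
        assert link[0, 2] == pytest.approx(0.0)

    def _planted(self, sep=10.0):
        from tcskit.expression import ExpressionMatrix

        rows = {
            "a1": [0, 0, 0], "a2": [0, 0, 0],
            "b1": [sep, sep, 0], "b2": [sep, sep, 0.1],
        }
        return ExpressionMatrix(pd.DataFrame(rows).T, "log2", "control")

    def test_planted_clusters_contiguous(self):
        order, _ = hclust_order(self._planted())
        pos = {g: i for i, g in enumerate(order)}
        assert abs(pos["a1"] - pos["a2"]) == 1
        assert abs(pos["b1"] - pos["b2"]) == 1

    def test_row_permutation_same_partition(self):
        m = self._planted()
        perm = m.values.iloc[[2, 0, 3, 1]]
        from tcskit.expression import ExpressionMatrix

        order2, _ = hclust_order(ExpressionMatrix(perm, "log2", "control"))
        order1, _ = hclust_order(m)
        first = {frozenset(order1[:2]), frozenset(order1[2:])}
        second = {frozenset(order2[:2]), frozenset(order2[2:])}
        assert first == second

    def test_constant_row_under_correlation_named(self):
        with pytest.raises(ValidationError, match="a1"):
            hclust_order(self._planted(), metric="correlation")


class TestGeneratorRecovery:
    PLAN = {"g1": {"treat": 2.0, "salt": 0.5}, "g2": {"treat": 8.0, "salt": 1.0}}

    def test_noiseless_recovery_is_exact(self):
        table, truth = simulate_ct_table(self.PLAN, ct_noise_sd=0.0, seed=1)
        m = delta_delta_ct(table)
        for g, samples in truth.fold_plan.items():
            for s, fold in samples.items():
                assert m.values.loc[g, s] == pytest.approx(fold, abs=1e-12)
        assert (m.values["control"] == 1.0).all()

    def test_noisy_recovery_within_15_percent(self):
        # sd 0.15 per replicate propagates to ~13% (1 sigma) on a single
        # fold estimate; the 15% bound therefore applies to the mean
        # relative error over the plan
        table, truth = simulate_ct_table(self.PLAN, ct_noise_sd=0.15, seed=4, n_replicates=3)
        m = delta_delta_ct(table)
        errors = [
            abs(m.values.loc[g, s] - fold) / fold
            for g, samples in truth.fold_plan.items()
            for s, fold in samples.items()
        ]
        assert np.mean(errors) < 0.15

    def test_reference_ct_constant_across_samples(self):
        table, _ = simulate_ct_table(self.PLAN, ct_noise_sd=0.0, seed=1)
        ref = table.data[table.data.gene == "UBI"]
        assert ref.ct.nunique() == 1
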