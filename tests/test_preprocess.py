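"""Relative abundances, reference choice, filters, and dataset assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from taxadyn.data_io import CountTable, ResourceSeries
from taxadyn.preprocess import (
    build_regression_dataset,
    classify_abundance,
    combine_replicates,
    presence_filter,
    relative_abundances,
    select_reference_taxon,
)


def _table(counts, days, reps, taxa=None):
    counts = np.asarray(counts)
    taxa = taxa or [f"t{i}" for i in range(counts.shape[0])]
    sids = [f"s{i}" for i in range(counts.shape[1])]
    meta = pd.DataFrame(
        {
            "sample_id": sids,
            "replicate_id": reps,
            "day": days,
            "group": ["g"] * len(sids),
        }
    ).set_index("sample_id")
    return CountTable(taxon_ids=taxa, sample_ids=sids, counts=counts, metadata=meta)


class TestRelativeAbundances:
    def test_fractions(self):
        table = _table([[2], [3], [5]], [0.0], ["R1"])
        abund = relative_abundances(table)
        days, X = abund.replicates["R1"]
        np.testing.assert_allclose(X[:, 0], [0.2, 0.3, 0.5])

    def test_single_taxon_all_ones(self):
        table = _table([[7, 9]], [0.0, 5.0], ["R1", "R1"])
        abund = relative_abundances(table)
        np.testing.assert_allclose(abund.replicates["R1"][1], 1.0)

    def test_zero_total_sample_rejected(self):
        table = _table([[0, 1], [0, 1]], [0.0, 5.0], ["R1", "R1"])
        with pytest.raises(ValueError, match="s0"):
            relative_abundances(table)


class TestReferenceSelection:
    def test_occupancy_then_abundance(self):
        # A: 10/10 samples, mean 0.30; B: 10/10, mean 0.25 -> A
        counts = np.vstack([np.full(10, 30), np.full(10, 25), np.full(10, 45)])
        table = _table(counts, list(range(10)), ["R1"] * 10, ["A", "B", "C"])
        abund = relative_abundances(table)
        assert select_reference_taxon(abund) == "C"  # C has mean 0.45

    def test_occupancy_beats_abundance(self):
        # A absent once with mean 0.5 when present; B always present, mean 0.1
        a = np.array([50, 50, 50, 50, 50, 50, 50, 50, 50, 0])
        b = np.full(10, 10)
        c = 100 - a - b
        table = _table(np.vstack([a, b, c]), list(range(10)), ["R1"] * 10, ["A", "B", "C"])
        abund = relative_abundances(table)
        assert select_reference_taxon(abund) in ("B", "C")

    def test_no_full_occupancy_is_an_error(self):
        counts = np.array([[1, 0], [0, 1]])
        table = _table(counts, [0.0, 5.0], ["R1", "R1"])
        abund = relative_abundances(table)
        with pytest.raises(ValueError, match="reference"):
            select_reference_taxon(abund)


class TestClassifyAbundance:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (5e-5, "rare"),
            (5e-4, "moderate"),
            (2e-3, "abundant"),
            (1e-4, "moderate"),  # boundary 0.01% belongs to moderate
            (1e-3, "moderate"),  # boundary 0.1% belongs to moderate
            (0.0, "rare"),
            (1.0, "abundant"),
        ],
    )
    def test_classes(self, value, expected):
        assert classify_abundance(value) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_abundance(1.5)

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
    def test_partition_is_total(self, value):
        assert classify_abundance(value) in {"rare", "moderate", "abundant"}


class TestPresenceFilter:
    def test_threshold(self):
        n = 53
        a = np.zeros(n, dtype=int)
        a[:6] = 1  # present 6 times -> kept
        b = np.zeros(n, dtype=int)
        b[:5] = 1  # present 5 times -> dropped
        c = np.full(n, 100)
        table = _table(np.vstack([a, b, c]), list(range(n)), ["R1"] * n, ["A", "B", "C"])
        abund = relative_abundances(table)
        kept = presence_filter(abund, min_points=6)
        assert "A" in kept and "B" not in kept

    def test_min_points_two(self):
        a = np.array([1, 1, 0, 0])
        c = np.array([9, 9, 10, 10])
        table = _table(np.vstack([a, c]), [0, 1, 2, 3], ["R1"] * 4, ["A", "C"])
        kept = presence_filter(relative_abundances(table), min_points=2)
        assert "A" in kept

    def test_min_points_below_two_rejected(self):
        table = _table([[1, 1]], [0, 1], ["R1", "R1"])
        with pytest.raises(ValueError):
            presence_filter(relative_abundances(table), min_points=1)


class TestBuildRegressionDataset:
    def test_direct_substitution_example(self):
        # days (0, 2), X_i (0.1, 0.2), X_r (0.5, 0.5)
        counts = np.array([[10, 20], [50, 50], [40, 30]])
        table = _table(counts, [0.0, 2.0], ["R1", "R1"], ["i", "r", "z"])
        abund = relative_abundances(table)
        rs = ResourceSeries("R1", ["VS"], np.array([0.0, 2.0]), np.array([[1.0], [1.0]]))
        ds = build_regression_dataset(abund, rs, "i", "r")
        assert ds.n_obs == 1
        np.testing.assert_allclose(ds.response[0], np.log(2) / 2)
        np.testing.assert_allclose(ds.weights[0], 2 / 24)
        np.testing.assert_allclose(ds.inv_x[0], 10.0)
        np.testing.assert_allclose(ds.inv_xr[0], 2.0)

    def test_interval_with_absent_taxon_dropped(self):
        counts = np.array([[0, 20, 20], [50, 50, 50], [50, 30, 30]])
        table = _table(counts, [0.0, 2.0, 4.0], ["R1"] * 3, ["i", "r", "z"])
        abund = relative_abundances(table)
        rs = ResourceSeries("R1", ["VS"], np.array([0.0, 4.0]), np.array([[1.0], [1.0]]))
        ds = build_regression_dataset(abund, rs, "i", "r")
        assert ds.n_obs == 1  # only the (2, 4) interval survives

    def test_equal_abundances_give_zero_response(self):
        counts = np.array([[10, 20, 30], [10, 20, 30], [80, 60, 40]])
        table = _table(counts, [0.0, 1.0, 2.0], ["R1"] * 3, ["i", "r", "z"])
        abund = relative_abundances(table)
        rs = ResourceSeries("R1", ["VS"], np.array([0.0, 2.0]), np.array([[1.0], [1.0]]))
        ds = build_regression_dataset(abund, rs, "i", "r")
        np.testing.assert_allclose(ds.response, 0.0, atol=1e-14)

    def test_no_interval_crosses_replicates(self):
        counts = np.array([[10, 20, 10, 20], [90, 80, 90, 80]])
        table = _table(counts, [0.0, 10.0, 0.0, 10.0], ["R1", "R1", "R2", "R2"], ["i", "r"])
        abund = relative_abundances(table)
        rs = [
            ResourceSeries(rep, ["VS"], np.array([0.0, 10.0]), np.array([[1.0], [1.0]]))
            for rep in ("R1", "R2")
        ]
        ds = build_regression_dataset(abund, rs, "i", "r")
        # two replicates with two samples each: exactly one interval per replicate
        assert ds.n_obs == 2
        assert set(ds.replicate_ids) == {"R1", "R2"}

    def test_weights_recomputable(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 100, size=(3, 8))
        table = _table(counts, list(range(8)), ["R1"] * 8)
        abund = relative_abundances(table)
        rs = ResourceSeries("R1", ["VS"], np.array([0.0, 7.0]), np.array([[1.0], [2.0]]))
        ds = build_regression_dataset(abund, rs, "t0", "t2")
        np.testing.assert_allclose(
            ds.weights, ds.dt / (2 * ds.inv_x + 2 * ds.inv_xr), rtol=1e-12
        )
        assert (ds.weights > 0).all()


class TestCombineReplicates:
    def _ds(self, n, taxon="i", ref="r"):
        rng = np.random.default_rng(n)
        counts = rng.integers(1, 100, size=(3, n + 1))
        table = _table(counts, list(range(n + 1)), ["R1"] * (n + 1), [taxon, ref, "zz"])
        abund = relative_abundances(table)
        rs = ResourceSeries(
            "R1", ["VS"], np.array([0.0, float(n)]), np.array([[1.0], [2.0]])
        )
        return build_regression_dataset(abund, rs, taxon, ref)

    def test_concatenation_counts(self):
        parts = [self._ds(10), self._ds(10), self._ds(10)]
        combined = combine_replicates(parts)
        assert combined.n_obs == sum(p.n_obs for p in parts)

    def test_single_dataset_identity(self):
        ds = self._ds(5)
        out = combine_replicates([ds])
        np.testing.assert_array_equal(out.response, ds.response)

    def test_mismatched_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            combine_replicates([self._ds(5, ref="r"), self._ds(5, ref="z")])
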