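import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from methcohort import (
    cluster_samples,
    cluster_table,
    drop_residual,
    filter_missing,
    impute_linear,
    root_split,
)
from methcohort.errors import DataError, NothingToClusterError
from methcohort.simulate import CohortSpec, simulate_cohort_table
from conftest import make_table


def column_table(columns: dict, positions=None):
    names = list(columns)
    values = np.array([columns[n] for n in names], float).T
    positions = positions or list(range(1, values.shape[0] + 1))
    return make_table(positions, names, values)


class TestFilterMissing:
    def test_forty_percent_boundary_is_inclusive(self):
        t = column_table({
            "at40": [np.nan] * 4 + [0.5] * 6,
            "at30": [np.nan] * 3 + [0.5] * 7,
        })
        kept, removed = filter_missing(t)
        assert removed == ["at40"] and kept.samples == ["at30"]

    def test_threshold_sweep(self):
        cols = {}
        for pct in range(0, 100, 10):
            vals = [0.5] * 10
            vals[: pct // 10] = [np.nan] * (pct // 10)
            cols[f"m{pct:02d}"] = vals
        kept, removed = filter_missing(column_table(cols))
        assert sorted(removed) == [f"m{p:02d}" for p in range(40, 100, 10)]
        assert len(removed) == 6

    def test_all_removed_is_an_error(self):
        t = column_table({"a": [np.nan, 0.5], "b": [0.5, np.nan]})
        with pytest.raises(NothingToClusterError):
            filter_missing(t, max_missing=0.5)


class TestImputeLinear:
    def test_midpoint_and_position_weighting(self):
        t = make_table([100, 200, 300], ["A"], [[0.2], [np.nan], [0.6]])
        assert impute_linear(t).data["A"].tolist() == [0.2, 0.4, 0.6]
        t = make_table([100, 200, 400], ["B"], [[0.0], [np.nan], [0.9]])
        # 1/3 of the genomic way, not 1/2 of the row rank
        assert impute_linear(t).data["B"].iloc[1] == pytest.approx(0.3)

    def test_edges_stay_missing_and_observed_untouched(self):
        t = make_table(
            [10, 20, 30, 40],
            ["A"],
            [[np.nan], [0.5], [np.nan], [np.nan]],
        )
        out = impute_linear(t).data["A"]
        assert math.isnan(out.iloc[0]) and math.isnan(out.iloc[2])
        assert math.isnan(out.iloc[3]) and out.iloc[1] == 0.5

    def test_does_not_interpolate_across_chromosomes(self):
        import pandas as pd

        idx = pd.MultiIndex.from_tuples(
            [("chr1", 100), ("chr1", 200), ("chr2", 100), ("chr2", 200)],
            names=["chrom", "position"],
        )
        from methcohort import FrequencyTable

        t = FrequencyTable(
            pd.DataFrame({"A": [0.0, np.nan, np.nan, 1.0]}, index=idx)
        )
        out = impute_linear(t).data["A"]
        assert math.isnan(out.iloc[1]) and math.isnan(out.iloc[2])

    @given(st.integers(0, 2**31 - 1))
    def test_affine_columns_recovered_to_machine_precision(self, seed):
        rng = np.random.default_rng(seed)
        positions = np.sort(rng.choice(10_000, size=30, replace=False) + 1)
        slope = rng.uniform(-1, 1) * 0.3 / 10_000
        intercept = rng.uniform(0.35, 0.65)
        truth = intercept + slope * positions
        masked = truth.copy()
        interior = rng.choice(np.arange(1, 29), size=10, replace=False)
        masked[interior] = np.nan
        t = make_table([int(p) for p in positions], ["A"], masked[:, None])
        out = impute_linear(t).data["A"].to_numpy()
        assert np.nanmax(np.abs(out - truth)) <= 1e-12

    def test_idempotent_and_bounded_by_neighbors(self):
        rng = np.random.default_rng(12)
        vals = rng.random(40)
        vals[rng.choice(38, 10, replace=False) + 1] = np.nan
        t = make_table(list(range(10, 410, 10)), ["A"], vals[:, None])
        once = impute_linear(t)
        assert once == impute_linear(once)
        filled = once.data["A"].to_numpy()
        assert np.nanmin(filled) >= np.nanmin(vals) - 1e-12
        assert np.nanmax(filled) <= np.nanmax(vals) + 1e-12


class TestDropResidual:
    def test_edge_gap_column_removed(self):
        t = column_table({"edge": [np.nan, 0.5, 0.5], "full": [0.1, 0.2, 0.3]})
        kept, removed = drop_residual(impute_linear(t))
        assert removed == ["edge"] and kept.samples == ["full"]

    def test_output_never_contains_missing(self):
        rng = np.random.default_rng(2)
        vals = rng.random((30, 8))
        vals[rng.random((30, 8)) < 0.2] = np.nan
        t = make_table(list(range(1, 31)), [f"s{i}" for i in range(8)], vals)
        kept, _ = drop_residual(impute_linear(t))
        assert not kept.data.isna().any().any()


class TestClusterSamples:
    def test_identical_columns_merge_at_height_zero(self):
        t = column_table({"a": [0.1, 0.2], "b": [0.1, 0.2], "c": [0.9, 0.9]})
        result = cluster_samples(t)
        assert result.merge_tree[0][2] == 0.0

    def test_hand_computed_complete_linkage(self):
        # d(A,B)=0.1, d(A,C)=d(B,C)=1.0: merge (A,B) at 0.1, then +C at 1.0.
        c_y = math.sqrt(1.0 - 0.05**2)
        t = column_table({"A": [0.0, 0.0], "B": [0.1, 0.0], "C": [0.05, c_y]})
        result = cluster_samples(t)
        (a, b, h1), (_, _, h2) = result.merge_tree
        assert {a, b} == {0, 1} and h1 == pytest.approx(0.1)
        assert h2 == pytest.approx(1.0)
        assert result.kept_samples == ["A", "B", "C"]

    def test_heights_monotone_and_order_invariance(self):
        rng = np.random.default_rng(3)
        cols = {f"s{i}": rng.random(20) for i in range(7)}
        t = column_table(cols)
        shuffled = column_table({k: cols[k] for k in reversed(list(cols))})
        r1, r2 = cluster_samples(t), cluster_samples(shuffled)
        heights = [h for _, _, h in r1.merge_tree]
        assert heights == sorted(heights)
        assert r1.kept_samples == r2.kept_samples

    def test_fewer_than_two_columns_errors(self):
        with pytest.raises(NothingToClusterError):
            cluster_samples(column_table({"only": [0.1, 0.2]}))

    def test_missing_cells_rejected(self):
        with pytest.raises(DataError):
            cluster_samples(column_table({"a": [np.nan, 0.2], "b": [0.1, 0.2]}))


class TestPipeline:
    def test_imprinted_cohort_root_split_separates_haplotypes(self):
        spec = CohortSpec(n_individuals=20, seed=42, missing_rate=0.05)
        table, labels = simulate_cohort_table(spec)
        result = cluster_table(table)
        side_a, side_b = root_split(result)
        assert {labels[s] for s in side_a} in ({"H1"}, {"H2"})
        assert {labels[s] for s in side_b} in ({"H1"}, {"H2"})
        assert {labels[s] for s in side_a} != {labels[s] for s in side_b}

    def test_partition_of_input_columns(self):
        rng = np.random.default_rng(5)
        vals = rng.random((20, 6))
        vals[:, 0] = np.nan  # removed pre-filter
        vals[0, 1] = np.nan  # edge gap -> removed post-imputation
        t = make_table(list(range(10, 210, 10)),
                       [f"s{i}" for i in range(6)], vals)
        result = cluster_table(t)
        assert result.removed_pre == ["s0"]
        assert result.removed_post == ["s1"]
        all_cols = set(result.kept_samples) | set(result.removed_pre) | set(
            result.removed_post
        )
        assert all_cols == set(t.samples)
        assert not result.imputed.data.isna().any().any()
        assert len(result.merge_tree) == len(result.kept_samples) - 1
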