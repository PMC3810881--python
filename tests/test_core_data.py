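import numpy as np
import pandas as pd
import pytest

from ecoregion_beta import (DistanceMatrix, OccurrenceMatrix,
                            filter_high_elevation, merge_ecoregions,
                            read_distance_matrix, read_occurrence_matrix,
                            split_by_endemism, summarize_pool,
                            write_distance_matrix, write_occurrence_matrix)
from ecoregion_beta.core_data import ValidationError, validate_ecoregion_info

from conftest import random_occurrence


def make_info(ids, in_hotspot=None, in_baetic=None, areas=None):
    n = len(ids)
    return validate_ecoregion_info(pd.DataFrame({
        "name": ids,
        "region": ["r"] * n,
        "in_hotspot": in_hotspot if in_hotspot is not None else [True] * n,
        "in_baetic": in_baetic if in_baetic is not None else [False] * n,
        "area_km2": areas if areas is not None else [100.0] * n,
    }, index=pd.Index(ids, name="id")))


class TestOccurrenceIO:
    def test_round_trip_identity(self, tiny_occ, tmp_path):
        path = tmp_path / "occ.tsv"
        write_occurrence_matrix(tiny_occ, path)
        back = read_occurrence_matrix(path)
        pd.testing.assert_frame_equal(back.incidence, tiny_occ.incidence,
                                      check_names=False)
        pd.testing.assert_series_equal(back.range_flag, tiny_occ.range_flag,
                                       check_names=False, check_index=False)

    def test_shape_preserved_from_file(self, tmp_path):
        path = tmp_path / "occ.tsv"
        path.write_text("taxon\tA\tB\trange_flag\n"
                        "t1\t1\t0\tnonendemic\n"
                        "t2\t0\t1\tnonendemic\n"
                        "t3\t1\t1\tendemic\n")
        occ = read_occurrence_matrix(path)
        assert occ.incidence.shape == (3, 2)
        assert occ.taxa == ["t1", "t2", "t3"]

    def test_duplicate_taxon_named_in_error(self, tmp_path):
        path = tmp_path / "occ.tsv"
        path.write_text("taxon\tA\trange_flag\n"
                        "t1\t1\tnonendemic\n"
                        "t1\t0\tnonendemic\n")
        with pytest.raises(ValidationError, match="t1"):
            read_occurrence_matrix(path)

    def test_non_binary_cell_positions_in_error(self, tmp_path):
        path = tmp_path / "occ.tsv"
        path.write_text("taxon\tA\tB\trange_flag\n"
                        "t1\t1\t2\tnonendemic\n")
        with pytest.raises(ValidationError, match="t1.*B"):
            read_occurrence_matrix(path)

    def test_excluded_rows_are_dropped(self, tmp_path):
        path = tmp_path / "occ.tsv"
        path.write_text("taxon\tA\trange_flag\texcluded\n"
                        "t1\t1\tnonendemic\t0\n"
                        "hybrid\t1\tnonendemic\t1\n")
        assert read_occurrence_matrix(path).taxa == ["t1"]

    def test_endemic_without_range_class_rejected(self):
        inc = pd.DataFrame([[True]], index=["t1"], columns=["A"])
        with pytest.raises(ValidationError, match="t1"):
            OccurrenceMatrix(inc, pd.Series({"t1": "endemic"}),
                             pd.Series({"t1": None}))


class TestMerge:
    def test_or_semantics_and_area_additivity(self, tiny_occ):
        info = make_info(["A", "B", "C"], areas=[100.0, 250.0, 50.0])
        grid = pd.DataFrame({"x_km": [0.5, 1.5, 2.5], "y_km": [0.5] * 3,
                             "ecoregion": ["A", "B", "C"],
                             "elev_m": [10.0, 20.0, 30.0]})
        occ, info2, grid2 = merge_ecoregions(tiny_occ, ["A", "B"], "AB",
                                             info=info, grid=grid)
        # t1 in A and B, t2 in A only, t3 in B only -> all present in AB
        assert occ.incidence["AB"].tolist() == [True, True, True]
        assert info2.loc["AB", "area_km2"] == 350.0
        assert set(grid2["ecoregion"]) == {"AB", "C"}

    def test_absent_from_both_stays_absent(self):
        inc = pd.DataFrame([[False, False, True]], index=["t"],
                           columns=["A", "B", "C"])
        occ = OccurrenceMatrix(inc, pd.Series({"t": "nonendemic"}))
        merged = merge_ecoregions(occ, ["A", "B"], "AB")
        assert not merged.incidence.loc["t", "AB"]

    def test_single_id_merge_is_rename(self, tiny_occ):
        renamed = merge_ecoregions(tiny_occ, ["A"], "A2")
        assert "A2" in renamed.ecoregions and "A" not in renamed.ecoregions
        assert renamed.incidence["A2"].equals(tiny_occ.incidence["A"])

    def test_unknown_id_rejected(self, tiny_occ):
        with pytest.raises(ValidationError, match="nope"):
            merge_ecoregions(tiny_occ, ["nope"], "X")

    def test_merge_and_split_commute(self):
        rng = np.random.default_rng(5)
        occ = random_occurrence(rng)
        e_then_m = [merge_ecoregions(part, ["e0", "e1"], "m")
                    for part in split_by_endemism(occ)]
        m_then_e = split_by_endemism(merge_ecoregions(occ, ["e0", "e1"], "m"))
        for a, b in zip(m_then_e, e_then_m):
            pd.testing.assert_frame_equal(a.incidence, b.incidence)


class TestSplit:
    def test_partition_is_exhaustive_and_disjoint(self):
        rng = np.random.default_rng(1)
        occ = random_occurrence(rng)
        end, non = split_by_endemism(occ)
        assert end.n_taxa + non.n_taxa == occ.n_taxa
        assert not set(end.taxa) & set(non.taxa)
        assert end.ecoregions == non.ecoregions == occ.ecoregions

    def test_all_endemic_gives_empty_nonendemic(self, tiny_occ):
        occ = OccurrenceMatrix(tiny_occ.incidence,
                               pd.Series("endemic", index=tiny_occ.incidence.index),
                               pd.Series("both", index=tiny_occ.incidence.index))
        end, non = split_by_endemism(occ)
        assert end.n_taxa == 3 and non.n_taxa == 0


class TestHighElevationFilter:
    def grid_for(self, elevs_by_eco):
        rows = []
        for eco, elevs in elevs_by_eco.items():
            for i, e in enumerate(elevs):
                rows.append({"x_km": i + 0.5, "y_km": 0.5,
                             "ecoregion": eco, "elev_m": float(e)})
        return pd.DataFrame(rows)

    def test_mountain_retained_lowland_removed(self):
        grid = self.grid_for({"high": [2000] * 10, "low": [100] * 10})
        assert filter_high_elevation(grid) == ["high"]

    def test_marginal_ecoregion_removed_under_defaults(self):
        # 4% above 1500 m (< 5% required) and 40% below 500 m
        elevs = [2000] * 4 + [100] * 40 + [800] * 56
        grid = self.grid_for({"mixed": elevs})
        assert filter_high_elevation(grid) == []

    def test_idempotent(self):
        grid = self.grid_for({"a": [2000] * 10, "b": [1600] * 5 + [100] * 95,
                              "c": [900] * 20})
        kept = filter_high_elevation(grid)
        sub = grid[grid["ecoregion"].isin(kept)]
        assert filter_high_elevation(sub) == kept

    def test_missing_ecoregion_errors(self):
        grid = self.grid_for({"a": [2000]})
        with pytest.raises(ValidationError, match="ghost"):
            filter_high_elevation(grid, ecoregions=["a", "ghost"])


class TestPoolSummary:
    def test_percentages_recompute_from_counts(self):
        rng = np.random.default_rng(9)
        occ = random_occurrence(rng, n_taxa=50)
        info = make_info(occ.ecoregions,
                         in_hotspot=[True] * 6 + [False] * 2)
        s = summarize_pool(occ, info)
        assert s.hotspot_percent == round(100 * s.hotspot_taxa / s.total_taxa)
        assert s.endemic_percent == round(100 * s.endemic_taxa / s.hotspot_taxa, 1)
        assert s.endemic_taxa + s.nonendemic_taxa == s.hotspot_taxa
        assert sum(s.range_class_counts.values()) == s.endemic_taxa


class TestDistanceMatrix:
    def test_invariants_enforced(self):
        with pytest.raises(ValidationError):
            DistanceMatrix([[0, 1], [2, 0]], ["a", "b"])      # asymmetric
        with pytest.raises(ValidationError):
            DistanceMatrix([[1, 0], [0, 0]], ["a", "b"])      # diag nonzero
        with pytest.raises(ValidationError):
            DistanceMatrix([[0, 1], [1, 0]], ["a"])           # label mismatch
        with pytest.raises(ValidationError):
            DistanceMatrix([[0, np.nan], [np.nan, 0]], ["a", "b"])

    def test_tsv_round_trip(self, tmp_path):
        dm = DistanceMatrix([[0, 1.5, 2], [1.5, 0, 3], [2, 3, 0]],
                            ["x", "y", "z"])
        path = tmp_path / "d.tsv"
        write_distance_matrix(dm, path)
        back = read_distance_matrix(path)
        assert back.labels == dm.labels
        np.testing.assert_allclose(back.values, dm.values)

    def test_subset_reorders_consistently(self):
        dm = DistanceMatrix([[0, 1.0, 2], [1, 0, 3], [2, 3, 0]],
                            ["x", "y", "z"])
        sub = dm.subset(["z", "x"])
        assert sub.labels == ["z", "x"]
        assert sub.values[0, 1] == 2.0

    def test_condensed_matches_upper_triangle(self):
        vals = np.array([[0, 1.0, 2], [1, 0, 3], [2, 3, 0]])
        dm = DistanceMatrix(vals, list("xyz"))
        np.testing.assert_allclose(dm.condensed(), [1, 2, 3])
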