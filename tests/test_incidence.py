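"""Incidence data model, CSV I/O, and the frequency/richness accounting."""

import numpy as np
import pandas as pd
import pytest

from emscape.incidence import (
    IncidenceMatrix,
    SpeciesRecord,
    count_exclusive_species,
    frequency_table,
    merge_age_classes,
    read_incidence_csv,
    richness_summary,
    round_half_up,
    taxon_counts,
    write_incidence_csv,
)

from .conftest import matrix_from_rows


class TestReadWrite:
    def test_basic_parse(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("species,s1,s2\nspA,1,0\nspB,0,1\n")
        m = read_incidence_csv(p, "adult")
        assert m.species_ids == ["spA", "spB"]
        assert m.site_ids == ["s1", "s2"]
        assert m.occupancy.tolist() == [[True, False], [False, True]]
        assert m.age_class == "adult"

    def test_empty_species_row_retained(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("species,s1,s2\nspA,1,1\nspB,0,0\n")
        m = read_incidence_csv(p)
        assert m.n_species == 2
        assert not m.occupancy[1].any()

    def test_non_binary_cell_rejected(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("species,s1\nspA,2\n")
        with pytest.raises(ValueError, match=r"non-binary.*spA.*s1"):
            read_incidence_csv(p)

    def test_duplicate_species_rejected(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("species,s1\nspA,1\nspA,0\n")
        with pytest.raises(ValueError, match="duplicate species"):
            read_incidence_csv(p)

    def test_round_trip_preserves_order_and_cells(self, tmp_path, rng):
        occ = rng.random((7, 5)) < 0.4
        m = matrix_from_rows(occ)
        p = tmp_path / "rt.csv"
        write_incidence_csv(m, p)
        back = read_incidence_csv(p)
        assert back.species_ids == m.species_ids
        assert back.site_ids == m.site_ids
        np.testing.assert_array_equal(back.occupancy, m.occupancy)


class TestMerge:
    def test_union_of_layers(self):
        a = IncidenceMatrix([[1, 0]], ["spA"], ["s1", "s2"], "adult")
        j = IncidenceMatrix([[0, 1]], ["spA"], ["s1", "s2"], "juvenile")
        t = merge_age_classes(a, j)
        assert t.age_class == "total"
        assert t.occupancy.tolist() == [[True, True]]

    def test_juvenile_only_species_appended(self):
        a = IncidenceMatrix([[1, 0]], ["spA"], ["s1", "s2"], "adult")
        j = IncidenceMatrix([[1, 1]], ["spB"], ["s1", "s2"], "juvenile")
        t = merge_age_classes(a, j)
        assert t.species_ids == ["spA", "spB"]
        assert t.occupancy.tolist() == [[True, False], [True, True]]

    def test_site_mismatch_rejected(self):
        a = IncidenceMatrix([[1]], ["spA"], ["s1"], "adult")
        j = IncidenceMatrix([[1]], ["spA"], ["s2"], "juvenile")
        with pytest.raises(ValueError, match="site set"):
            merge_age_classes(a, j)

    def test_total_af_at_least_each_layer(self, rng):
        a = matrix_from_rows(rng.random((10, 8)) < 0.3, "adult")
        j = matrix_from_rows(rng.random((10, 8)) < 0.3, "juvenile")
        t = merge_age_classes(a, j)
        af_t = t.species_frequencies()
        assert (af_t >= a.species_frequencies()).all()
        assert (af_t >= j.species_frequencies()).all()


class TestFrequencyTable:
    @pytest.mark.parametrize(
        "af, n, rf",
        [(31, 32, 97), (30, 32, 94), (29, 32, 91), (1, 32, 3), (16, 32, 50)],
    )
    def test_rounded_rf(self, af, n, rf):
        occ = np.zeros((1, n), dtype=bool)
        occ[0, :af] = True
        m = IncidenceMatrix(occ, ["spA"], [f"s{i}" for i in range(n)])
        ft = frequency_table(m)
        assert ft.RF.iloc[0] == rf

    def test_unrounded_rf_kept(self):
        m = IncidenceMatrix([[1] + [0] * 31], ["spA"], [f"s{i}" for i in range(32)])
        ft = frequency_table(m)
        assert ft.RF_unrounded.iloc[0] == pytest.approx(3.125)

    def test_sorted_by_af_descending_ties_stable(self):
        m = matrix_from_rows([(1, 0, 0), (1, 1, 0), (1, 0, 0)])
        ft = frequency_table(m)
        assert ft.species.tolist() == ["sp2", "sp1", "sp3"]

    def test_crf_is_prefix_sum_of_rf(self, rng):
        from .conftest import random_matrix

        m = random_matrix(rng, 12, 9)
        ft = frequency_table(m)
        np.testing.assert_allclose(ft.CRF, np.cumsum(ft.RF_unrounded))
        assert (np.diff(ft.CRF) >= 0).all()
        assert ft.CRF.iloc[-1] == pytest.approx(ft.RF_unrounded.sum())


class TestExclusiveSpecies:
    def test_adult_only(self):
        a = IncidenceMatrix([[1]], ["spA"], ["s1"], "adult")
        j = IncidenceMatrix([[0]], ["spA"], ["s1"], "juvenile")
        c = count_exclusive_species(a, j)
        assert c["adult_only"] == 1 and c["juvenile_only"] == 0
        assert c["single_site_adult"] == 1

    def test_single_site_both(self):
        a = IncidenceMatrix([[1, 0]], ["spA"], ["s1", "s2"], "adult")
        j = IncidenceMatrix([[1, 0]], ["spA"], ["s1", "s2"], "juvenile")
        assert count_exclusive_species(a, j)["single_site_both"] == 1

    def test_partition_of_species(self, rng):
        """adult_only + juvenile_only + both-layer species = total species."""
        a = matrix_from_rows(rng.random((15, 6)) < 0.3, "adult")
        j = matrix_from_rows(rng.random((15, 6)) < 0.3, "juvenile")
        c = count_exclusive_species(a, j)
        both = sum(
            1
            for ra, rj in zip(a.occupancy, j.occupancy)
            if ra.any() and rj.any()
        )
        total_present = sum(
            1 for ra, rj in zip(a.occupancy, j.occupancy) if ra.any() or rj.any()
        )
        assert c["adult_only"] + c["juvenile_only"] + both == total_present


class TestTaxonCounts:
    def test_counts_and_native_pct(self):
        recs = [
            SpeciesRecord("Acacia caven", "Fabaceae"),
            SpeciesRecord("Acacia bonariensis", "Fabaceae"),
            SpeciesRecord("Morus alba", "Moraceae", origin="exotic"),
        ]
        out = taxon_counts(recs)
        assert out["species"] == 3
        assert out["genera"] == 2
        assert out["families"] == 2
        assert out["pct_native"] == 67

    def test_single_record(self):
        out = taxon_counts([SpeciesRecord("Celtis tala", "Cannabaceae")])
        assert (out["species"], out["genera"], out["families"]) == (1, 1, 1)
        assert out["pct_native"] == 100


class TestRichnessSummary:
    def test_hand_arithmetic(self):
        m = matrix_from_rows(
            [(1, 1, 1), (1, 1, 1), (0, 1, 1), (0, 1, 1), (0, 0, 1), (0, 0, 1)]
        )
        out = richness_summary(m)
        row = out.iloc[0]
        assert (row["min"], row["max"], row["mean"]) == (2, 6, 4)
        assert row["sd"] == pytest.approx(2.0)

    def test_single_site_group_sd_is_nan(self):
        m = matrix_from_rows([(1, 0), (1, 1)])
        out = richness_summary(m, {"s1": "a", "s2": "b"}).set_index("group")
        assert np.isnan(out.loc["a", "sd"])

    def test_groups_independent(self, rng):
        from .conftest import random_matrix

        m = random_matrix(rng, 8, 6)
        groups = {s: ("x" if i < 3 else "y") for i, s in enumerate(m.site_ids)}
        both = richness_summary(m, groups).set_index("group")
        sub = m.reorder(range(m.n_species), range(3))
        alone = richness_summary(sub, {s: "x" for s in sub.site_ids}).set_index("group")
        pd.testing.assert_series_equal(both.loc["x"], alone.loc["x"], check_names=False)

    def test_unlabeled_site_rejected(self):
        m = matrix_from_rows([(1, 1)])
        with pytest.raises(ValueError, match="without group label"):
            richness_summary(m, {"s1": "a"})


def test_round_half_up_midpoints():
    assert [round_half_up(x) for x in (0.5, 1.5, 2.4, 2.5, 96.875)] == [1, 2, 2, 3, 97]
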