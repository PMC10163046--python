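import numpy as np
import pandas as pd
import pytest

from ncplink import (RelationshipValue, SpeciesRecord, apply_synonym_map,
                     count_relationships, filter_species, ncp_summary,
                     percent, read_relationship_table, species_score_summary,
                     top_scored_species, validate_table,
                     write_relationship_table)
from ncplink.catalog import CATEGORIES, applicability_mask
from ncplink.errors import (CellValueError, MergeConflictError,
                            TableValidationError, UnknownSpeciesError)
from ncplink.synth import TableGeneratorSpec, generate_table
from ncplink.table import filter_species_frame, score_frame

from conftest import build_table


def random_table(catalog, seed, n_trach=10, n_vert=5):
    spec = TableGeneratorSpec(
        n_tracheophytes=n_trach, n_vertebrates=n_vert,
        p_positive=0.35,
        p_negative={n.ncp_id: (0.15 if n.negative_allowed else 0.0)
                    for n in catalog},
        p_na=0.15, seed=seed)
    table, _ = generate_table(spec, catalog)
    return table


# ---------------------------------------------------------------- reading

class TestReadWrite:
    def test_two_species_has_25_applicable_cells(self, salix_wolf_table,
                                                 tmp_path):
        path = tmp_path / "t.csv"
        write_relationship_table(salix_wolf_table, path)
        table = read_relationship_table(path, salix_wolf_table.catalog)
        assert table.applicable_matrix().to_numpy().sum() == 16 + 9

    def test_round_trip_preserves_cells(self, catalog, tmp_path):
        table = random_table(catalog, seed=7)
        path = tmp_path / "t.csv"
        write_relationship_table(table, path)
        back = read_relationship_table(path, catalog)
        pd.testing.assert_frame_equal(
            back.cells, table.cells, check_names=False)

    def test_negative_under_non_material_rejected(self, salix_wolf_table,
                                                  tmp_path):
        path = tmp_path / "t.csv"
        write_relationship_table(salix_wolf_table, path)
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        df.loc[0, "iconic_species"] = "-1"
        df.to_csv(path, index=False)
        with pytest.raises(TableValidationError, match="negative"):
            read_relationship_table(path, salix_wolf_table.catalog)

    def test_unknown_ncp_column_rejected(self, salix_wolf_table, tmp_path):
        path = tmp_path / "t.csv"
        write_relationship_table(salix_wolf_table, path)
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        df["not_an_ncp"] = "1"
        df.to_csv(path, index=False)
        with pytest.raises(TableValidationError, match="not_an_ncp"):
            read_relationship_table(path, salix_wolf_table.catalog)

    def test_garbage_cell_value_names_row_and_column(self, salix_wolf_table,
                                                     tmp_path):
        path = tmp_path / "t.csv"
        write_relationship_table(salix_wolf_table, path)
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        df.loc[1, "wild_food"] = "2"
        df.to_csv(path, index=False)
        with pytest.raises(CellValueError) as exc:
            read_relationship_table(path, salix_wolf_table.catalog)
        assert exc.value.species_id == "canis_lupus"
        assert exc.value.column == "wild_food"

    def test_empty_cells_become_na_no_info(self, catalog, tmp_path):
        table = build_table(catalog, {
            "t1": ({"lineage": "tracheophyte", "subgroup": "angiosperm"}, {}),
        })
        path = tmp_path / "t.csv"
        write_relationship_table(table, path)
        back = read_relationship_table(path, catalog)
        assert back.value_at("t1", "wild_food") is RelationshipValue.NA_NO_INFO
        assert (back.value_at("t1", "reduce_species_damage")
                is RelationshipValue.NA_NOT_APPLICABLE)


# ------------------------------------------------------------- validation

class TestValidate:
    def test_valid_synthetic_table_empty_report(self, catalog):
        assert validate_table(random_table(catalog, seed=1)).empty

    def test_minus_one_under_solid_wood_is_one_violation(self, catalog):
        table = build_table(catalog, {
            "t1": ({"lineage": "tracheophyte", "subgroup": "angiosperm"},
                   {"solid_wood": -1}),
        })
        report = validate_table(table)
        assert len(report) == 1
        assert report.violations[0].rule == "negative_not_allowed"
        assert report.violations[0].ncp_id == "solid_wood"

    def test_vertebrate_with_potential_crop_cell_is_violation(self, catalog):
        table = build_table(catalog, {
            "v1": ({"lineage": "vertebrate", "subgroup": "bird"},
                   {"potential_crop": 1}),
        })
        report = validate_table(table)
        assert len(report) == 1
        assert report.violations[0].rule == "value_at_inapplicable_cell"

    def test_subgroup_lineage_mismatch_flagged(self, catalog):
        table = build_table(catalog, {
            "v1": ({"lineage": "vertebrate", "subgroup": "angiosperm"}, {}),
        })
        rules = {v.rule for v in validate_table(table)}
        assert "subgroup_lineage_mismatch" in rules

    def test_report_frame_has_expected_columns(self, catalog):
        table = build_table(catalog, {
            "t1": ({"lineage": "tracheophyte", "subgroup": "angiosperm"},
                   {"solid_wood": -1}),
        })
        frame = validate_table(table).to_frame()
        assert list(frame.columns) == ["rule", "species_id", "ncp_id", "message"]


# ----------------------------------------------------------- score summary

class TestScoreSummary:
    def test_salix_alba_worked_row(self, salix_wolf_table):
        s = species_score_summary(salix_wolf_table, "salix_alba")
        assert s.totals == {"material": 6, "non_material": 2, "regulating": 4}
        assert (s.grand_total, s.grand_positive, s.grand_negative) == (12, 12, 0)

    def test_canis_lupus_worked_row(self, salix_wolf_table):
        s = species_score_summary(salix_wolf_table, "canis_lupus")
        assert (s.grand_total, s.grand_positive, s.grand_negative) == (3, 4, -1)
        assert s.negatives["regulating"] == -1

    def test_total_is_positive_plus_negative_per_category(self, salix_wolf_table):
        for sid in salix_wolf_table.species_ids:
            s = species_score_summary(salix_wolf_table, sid)
            for cat in CATEGORIES:
                assert s.totals[cat] == s.positives[cat] + s.negatives[cat]
            assert s.grand_total == sum(s.totals.values())

    def test_all_na_species(self, catalog):
        table = build_table(catalog, {
            "v1": ({"lineage": "vertebrate", "subgroup": "bird"}, {}),
        })
        s = species_score_summary(table, "v1")
        assert s.grand_total == s.grand_positive == s.grand_negative == 0
        assert sum(s.n_na.values()) == 9  # all applicable cells NA_no_info

    def test_unknown_species_raises(self, salix_wolf_table):
        with pytest.raises(UnknownSpeciesError):
            species_score_summary(salix_wolf_table, "nope")

    def test_matches_naive_recount(self, catalog):
        # oracle: recount every cell with plain Python loops
        table = random_table(catalog, seed=11, n_trach=30, n_vert=20)
        for sid in table.species_ids[::7]:
            lineage = table.lineage_of(sid)
            mask = applicability_mask(catalog, lineage)
            s = species_score_summary(table, sid)
            for cat in CATEGORIES:
                ids = [n for n in catalog.category_ids(cat) if n in mask]
                vals = [table.cells.at[sid, n] for n in ids]
                assert s.positives[cat] == sum(1 for v in vals if v == 1)
                assert s.negatives[cat] == -sum(1 for v in vals if v == -1)
                assert s.n_na[cat] == sum(1 for v in vals if np.isnan(v))

    def test_score_frame_agrees_with_per_species(self, catalog):
        table = random_table(catalog, seed=3)
        frame = score_frame(table)
        for sid in table.species_ids:
            s = species_score_summary(table, sid)
            assert frame.loc[sid, "grand_total"] == s.grand_total
            assert frame.loc[sid, "grand_positive"] == s.grand_positive
            for cat in CATEGORIES:
                assert frame.loc[sid, f"n_na_{cat}"] == s.n_na[cat]


# ------------------------------------------------------------ ncp summary

class TestNCPSummary:
    def test_known_value_mix(self, catalog):
        vals = [1, 1, -1, 0, np.nan]
        rows = {f"t{i}": ({"lineage": "tracheophyte", "subgroup": "angiosperm"},
                          {"wild_food": v} if not np.isnan(v) else {})
                for i, v in enumerate(vals)}
        table = build_table(catalog, rows)
        (s,) = ncp_summary(table, "wild_food", group_by="lineage")
        assert (s.n_positive, s.n_negative, s.n_neutral, s.n_na) == (2, 1, 1, 1)

    def test_inapplicable_group_is_empty(self, catalog):
        table = build_table(catalog, {
            "t1": ({"lineage": "tracheophyte", "subgroup": "angiosperm"}, {}),
        })
        (s,) = ncp_summary(table, "reduce_species_damage", group_by="lineage")
        assert s.n_applicable == 0
        assert (s.n_positive, s.n_negative, s.n_neutral, s.n_na) == (0, 0, 0, 0)

    def test_counts_partition_applicable_species(self, catalog):
        table = random_table(catalog, seed=5, n_trach=20, n_vert=10)
        for ncp_id in catalog.ncp_ids:
            for s in ncp_summary(table, ncp_id, group_by="subgroup"):
                assert (s.n_positive + s.n_negative + s.n_neutral + s.n_na
                        == s.n_applicable)

    def test_conservation_over_ncps(self, catalog):
        # sum of all counts per lineage = |species| x |mask(lineage)|
        table = random_table(catalog, seed=6, n_trach=12, n_vert=8)
        for lineage, n_sp in (("tracheophyte", 12), ("vertebrate", 8)):
            total = 0
            for ncp_id in catalog.ncp_ids:
                for s in ncp_summary(table, ncp_id, group_by="lineage"):
                    if s.group == lineage:
                        total += (s.n_positive + s.n_negative
                                  + s.n_neutral + s.n_na)
            assert total == n_sp * len(applicability_mask(catalog, lineage))

    def test_matches_naive_recount(self, catalog):
        table = random_table(catalog, seed=8, n_trach=25, n_vert=15)
        groups = dict(zip(table.species["species_id"], table.species["subgroup"]))
        for ncp_id in ["wild_food", "potential_crop", "reduce_species_damage"]:
            ncp = catalog.get(ncp_id)
            for s in ncp_summary(table, ncp_id, group_by="subgroup"):
                members = [sid for sid, g in groups.items() if g == s.group]
                if not ncp.applies_to(table.lineage_of(members[0])):
                    continue
                vals = [table.cells.at[sid, ncp_id] for sid in members]
                assert s.n_positive == sum(1 for v in vals if v == 1)
                assert s.n_negative == sum(1 for v in vals if v == -1)
                assert s.n_neutral == sum(1 for v in vals if v == 0)
                assert s.n_na == sum(1 for v in vals if np.isnan(v))


# --------------------------------------------------------- count + filter

class TestCountRelationships:
    def test_small_table_with_one_na(self, catalog):
        rows = {}
        for i in range(3):
            cells = {"wild_food": 1, "keystone_species": 0}
            if i == 0:
                cells.pop("keystone_species")  # one NA_no_info cell
            rows[f"x{i}"] = ({"lineage": "vertebrate", "subgroup": "bird"},
                             cells)
        table = build_table(catalog, rows)
        # restrict to a 3 species x 2 NCP view by checking the deltas
        n_reported, n_possible = count_relationships(table)
        assert n_possible == 3 * 9
        assert n_possible - n_reported == 3 * 9 - 5  # 5 filled cells

    def test_zero_na_means_reported_equals_possible(self, catalog):
        spec = TableGeneratorSpec(4, 4, 0.5, 0.0, 0.0, seed=0)
        table, _ = generate_table(spec, catalog)
        n_reported, n_possible = count_relationships(table)
        assert n_reported == n_possible

    def test_reported_plus_na_equals_possible(self, catalog):
        for seed in range(5):
            table = random_table(catalog, seed=seed)
            n_reported, n_possible = count_relationships(table)
            app = table.applicable_matrix().to_numpy()
            n_na = int((np.isnan(table.cells.to_numpy()) & app).sum())
            assert n_reported + n_na == n_possible

    def test_printed_study_shape(self, catalog):
        t_mask = len(applicability_mask(catalog, "tracheophyte"))
        v_mask = len(applicability_mask(catalog, "vertebrate"))
        assert 1816 * t_mask + 250 * v_mask == 31306


class TestFilterSpecies:
    def test_boundary_inclusive_at_min(self):
        records = [SpeciesRecord(f"s{i}", n_occurrences=n)
                   for i, n in enumerate([9, 10, 11])]
        kept = filter_species(records, min_occurrences=10, exclude_alien=True)
        assert [r.species_id for r in kept] == ["s1", "s2"]

    def test_alien_dropped_despite_many_occurrences(self):
        records = [SpeciesRecord("a", n_occurrences=1000, alien=True)]
        assert filter_species(records, 10, exclude_alien=True) == []
        assert filter_species(records, 10, exclude_alien=False) == records

    def test_identity_when_unconstrained(self):
        records = [SpeciesRecord(f"s{i}", n_occurrences=i, alien=(i % 2 == 0))
                   for i in range(5)]
        assert filter_species(records, 0, exclude_alien=False) == records

    def test_idempotent(self):
        records = [SpeciesRecord(f"s{i}", n_occurrences=i * 3,
                                 alien=(i == 2)) for i in range(8)]
        once = filter_species(records, 10, True)
        assert filter_species(once, 10, True) == once

    def test_frame_variant_preserves_order(self, catalog):
        table = random_table(catalog, seed=2)
        out = filter_species_frame(table.species, min_occurrences=0,
                                   exclude_alien=False)
        assert list(out["species_id"]) == table.species_ids

    def test_table_filter_returns_consistent_table(self, catalog):
        table = random_table(catalog, seed=4)
        table.species.loc[0, "n_occurrences"] = 3
        filtered = table.filter_species(min_occurrences=10)
        assert filtered.n_species == table.n_species - 1
        assert validate_table(filtered).empty

    def test_negative_min_rejected(self):
        with pytest.raises(ValueError):
            filter_species([], min_occurrences=-1)


# ------------------------------------------------------------ synonym map

class TestSynonymMap:
    def test_identical_rows_merge_to_one(self, catalog):
        cells = {"wild_food": 1, "iconic_species": 0}
        table = build_table(catalog, {
            "a": ({"lineage": "vertebrate", "subgroup": "bird"}, cells),
            "b": ({"lineage": "vertebrate", "subgroup": "bird"}, cells),
        })
        merged = apply_synonym_map(table, {"b": "a"})
        assert merged.species_ids == ["a"]
        assert merged.value_at("a", "wild_food") is RelationshipValue.POSITIVE

    def test_non_na_beats_na(self, catalog):
        table = build_table(catalog, {
            "a": ({"lineage": "vertebrate", "subgroup": "bird"},
                  {"wild_food": 1}),
            "b": ({"lineage": "vertebrate", "subgroup": "bird"}, {}),
        })
        merged = apply_synonym_map(table, {"b": "a"})
        assert merged.value_at("a", "wild_food") is RelationshipValue.POSITIVE

    def test_conflicting_values_raise_naming_cell(self, catalog):
        table = build_table(catalog, {
            "a": ({"lineage": "vertebrate", "subgroup": "bird"},
                  {"wild_food": 1}),
            "b": ({"lineage": "vertebrate", "subgroup": "bird"},
                  {"wild_food": -1}),
        })
        with pytest.raises(MergeConflictError, match="wild_food"):
            apply_synonym_map(table, {"b": "a"}, policy="strict")
        with pytest.raises(MergeConflictError):
            apply_synonym_map(table, {"b": "a"})

    def test_occurrences_summed(self, catalog):
        table = build_table(catalog, {
            "a": ({"lineage": "vertebrate", "subgroup": "bird",
                   "n_occurrences": 30}, {}),
            "b": ({"lineage": "vertebrate", "subgroup": "bird",
                   "n_occurrences": 12}, {}),
        })
        merged = apply_synonym_map(table, {"b": "a"})
        assert merged.species.loc[0, "n_occurrences"] == 42

    def test_unknown_policy(self, salix_wolf_table):
        with pytest.raises(ValueError):
            apply_synonym_map(salix_wolf_table, {}, policy="vote")


# ----------------------------------------------------------------- ranking

class TestTopScored:
    def _three_species(self, catalog, positives):
        rows = {}
        ncp_pool = [n for n in catalog.ncp_ids
                    if catalog.get(n).applies_to("tracheophyte")]
        for i, k in enumerate(positives):
            cells = {ncp_pool[j]: 1 for j in range(k)}
            rows[f"s{i}"] = ({"lineage": "tracheophyte",
                              "subgroup": "angiosperm"}, cells)
        return build_table(catalog, rows)

    def test_ranked_by_positive_count(self, catalog):
        table = self._three_species(catalog, [5, 2, 4])
        top = top_scored_species(table, "tracheophyte", n=2)
        assert [s.species_id for s in top] == ["s0", "s2"]
        assert [s.grand_positive for s in top] == [5, 4]

    def test_all_equal_breaks_ties_lexicographically(self, catalog):
        table = self._three_species(catalog, [3, 3, 3])
        top = top_scored_species(table, "tracheophyte", n=3)
        assert [s.species_id for s in top] == ["s0", "s1", "s2"]

    def test_n_larger_than_table_returns_all(self, catalog):
        table = self._three_species(catalog, [1, 2, 3])
        assert len(top_scored_species(table, "tracheophyte", n=50)) == 3

    def test_grand_total_breaks_positive_ties(self, catalog):
        table = build_table(catalog, {
            "a": ({"lineage": "vertebrate", "subgroup": "bird"},
                  {"wild_food": 1, "reduce_species_damage": -1}),
            "b": ({"lineage": "vertebrate", "subgroup": "bird"},
                  {"wild_food": 1}),
        })
        top = top_scored_species(table, "vertebrate", n=2)
        assert [s.species_id for s in top] == ["b", "a"]


# -------------------------------------------------------------- reporting

class TestPercent:
    @pytest.mark.parametrize("count,total,expected", [
        (1139, 1816, 62.7),
        (235, 1816, 12.9),
        (458, 1816, 25.2),
        (454, 1816, 25.0),
        (69, 250, 27.6),
        (34, 250, 13.6),
        (29, 250, 11.6),
        (22, 250, 8.8),
        (10, 11, 90.9),
    ])
    def test_printed_percentages(self, count, total, expected):
        assert percent(count, total) == expected

    def test_half_up_rounding(self):
        assert percent(1, 8) == 12.5
        assert percent(5, 1000) == 0.5
        assert percent(25, 10000) == 0.3  # 0.25 rounds up, not to even

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            percent(1, 0)
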