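"""Consultation building, cohort filtering, and summary shares."""

from __future__ import annotations

import pandas as pd
import pytest

from vetamu.consultations import (
    apply_cohort_filter,
    build_consultations,
    hpcia_share,
    summarize_human_drugs,
    summarize_substance_classes,
    summarize_treatment_share,
)
from vetamu.io import _norm_name
from vetamu.model import CohortFilter


def _entries(rows):
    base = {
        "practice_id": "PR0",
        "patient_id": "P1",
        "species": "dog",
        "breed": "Beagle",
        "sex": "m",
        "birth_date": "2015-01-01",
        "death_date": "",
        "anamnesis_text": "",
        "diagnosis_text": "",
        "item_kind": "examination",
        "item_name": "Untersuchung",
    }
    frame = pd.DataFrame([base | r for r in rows])
    for col in ("birth_date", "death_date", "entry_date"):
        frame[col] = pd.to_datetime(frame[col].replace("", pd.NA))
    return frame


def brute_force_grouping(entries: pd.DataFrame) -> dict[tuple, dict]:
    """Quadratic oracle: nested loops over rows, no pandas grouping."""
    groups: dict[tuple, dict] = {}
    for _, row in entries.iterrows():
        key = (row["patient_id"], row["entry_date"])
        groups.setdefault(key, {"n": 0, "names": []})
        groups[key]["n"] += 1
        groups[key]["names"].append(row["item_name"])
    return groups


class TestBuildConsultations:
    def test_same_substance_twice_counts_once(self, drug_dict):
        entries = _entries(
            [
                {"entry_date": "2019-03-01"},
                {"entry_date": "2019-03-01", "item_kind": "drug",
                 "item_name": "Duphamox LA"},
                {"entry_date": "2019-03-01", "item_kind": "drug",
                 "item_name": "Amoxi-Tabs 250 mg"},
            ]
        )
        data = build_consultations(entries, drug_dict)
        assert len(data.consultations) == 1
        row = data.consultations.iloc[0]
        assert row["n_substances"] == 1
        assert row["substances"] == "amoxicillin"
        assert row["treated"]
        assert len(data.applications) == 2  # applications keep both rows

    def test_two_patients_one_date_two_consultations(self, drug_dict):
        entries = _entries(
            [
                {"entry_date": "2019-03-01"},
                {"entry_date": "2019-03-01", "patient_id": "P2"},
            ]
        )
        data = build_consultations(entries, drug_dict)
        assert len(data.consultations) == 2

    def test_amoxicillin_and_clavulanate_are_two_substances(self, drug_dict):
        entries = _entries(
            [
                {"entry_date": "2019-03-01", "item_kind": "drug",
                 "item_name": "amoxicillin"},
                {"entry_date": "2019-03-01", "item_kind": "drug",
                 "item_name": "Synulox RTU"},
            ]
        )
        data = build_consultations(entries, drug_dict)
        assert data.consultations.iloc[0]["n_substances"] == 2

    def test_partition_property_and_oracle_equivalence(self, small_dataset, drug_dict):
        _, table, _ = small_dataset
        subset = table.head(200)
        data = build_consultations(subset, drug_dict)
        # partition: every input entry lands in exactly one consultation
        assert data.consultations["n_entries"].sum() == len(subset)
        oracle = brute_force_grouping(subset)
        assert len(data.consultations) == len(oracle)
        for _, row in data.consultations.iterrows():
            key = (row["patient_id"], row["date"])
            assert oracle[key]["n"] == row["n_entries"]

    def test_row_order_invariance(self, small_dataset, drug_dict, breed_table, lexicon):
        _, table, _ = small_dataset
        subset = table.head(400)
        shuffled = subset.sample(frac=1, random_state=7).reset_index(drop=True)
        a = build_consultations(subset, drug_dict, breed_table, lexicon)
        b = build_consultations(shuffled, drug_dict, breed_table, lexicon)
        pd.testing.assert_frame_equal(a.consultations, b.consultations)

    def test_unresolved_drug_rows_counted(self, drug_dict):
        entries = _entries(
            [{"entry_date": "2019-03-01", "item_kind": "drug",
              "item_name": "Mystery Tonic"}]
        )
        data = build_consultations(entries, drug_dict)
        assert data.n_unresolved_drug_rows == 1
        assert not data.consultations.iloc[0]["treated"]


class TestCohortFilter:
    def _cohort(self, n_patients, practice="PRx", year=2019):
        return _entries(
            [
                {"patient_id": f"P{i}", "practice_id": practice,
                 "entry_date": f"{year}-05-0{1 + i % 9}"}
                for i in range(n_patients)
            ]
        )

    def test_practice_below_minimum_excluded(self, drug_dict):
        data = build_consultations(self._cohort(99), drug_dict)
        filtered, report = apply_cohort_filter(
            data, CohortFilter(min_patients_per_practice=100)
        )
        assert len(filtered.consultations) == 0
        assert report.practices_excluded == 1

    def test_practice_at_exactly_minimum_retained(self, drug_dict):
        data = build_consultations(self._cohort(100), drug_dict)
        filtered, report = apply_cohort_filter(
            data, CohortFilter(min_patients_per_practice=100)
        )
        assert len(filtered.consultations) == 100
        assert report.practices_excluded == 0

    def test_out_of_range_year_excluded(self, drug_dict):
        entries = pd.concat(
            [self._cohort(5, year=2023), self._cohort(5, year=2020)]
        ).reset_index(drop=True)
        data = build_consultations(entries, drug_dict)
        filtered, report = apply_cohort_filter(
            data, CohortFilter(min_patients_per_practice=1)
        )
        assert report.excluded_year == 5
        years = filtered.consultations["date"].dt.year.unique()
        assert list(years) == [2020]

    def test_species_whitelist(self, drug_dict):
        entries = _entries(
            [
                {"entry_date": "2019-05-01"},
                {"entry_date": "2019-05-01", "patient_id": "P2", "species": "other"},
            ]
        )
        data = build_consultations(entries, drug_dict)
        filtered, report = apply_cohort_filter(
            data, CohortFilter(min_patients_per_practice=1)
        )
        assert report.excluded_species == 1
        assert set(filtered.consultations["species"]) == {"dog"}

    def test_empty_result_warns_not_raises(self, drug_dict):
        data = build_consultations(self._cohort(3, year=2005), drug_dict)
        filtered, report = apply_cohort_filter(data, CohortFilter())
        assert len(filtered.consultations) == 0
        assert report.warnings


class TestTreatmentShare:
    def test_all_untreated_is_zero_percent(self, drug_dict):
        entries = _entries([{"entry_date": "2019-03-01"},
                            {"entry_date": "2019-04-01", "patient_id": "P2"}])
        data = build_consultations(entries, drug_dict)
        share = summarize_treatment_share(data.consultations)
        assert (share["percent"] == 0).all()

    def test_all_treated_is_hundred_percent(self, drug_dict):
        entries = _entries(
            [{"entry_date": "2019-03-01", "item_kind": "drug",
              "item_name": "amoxicillin"}]
        )
        data = build_consultations(entries, drug_dict)
        share = summarize_treatment_share(data.consultations)
        assert (share["percent"] == 100).all()

    def test_unknown_stratifier_raises(self, small_cohort):
        data, _ = small_cohort
        with pytest.raises(ValueError, match="stratifier"):
            summarize_treatment_share(data.consultations, by=("practice_name",))

    def test_share_matches_ground_truth_exactly(self, small_cohort):
        data, truth = small_cohort
        share = summarize_treatment_share(data.consultations)
        by_species = dict(zip(share["species"], share["percent"]))
        for species in ("dog", "cat"):
            assert by_species[species] == pytest.approx(
                100 * truth.treatment_share[species]
            )

    def test_stratified_by_year_covers_study_span(self, small_cohort):
        data, _ = small_cohort
        share = summarize_treatment_share(data.consultations, by=("species", "year"))
        assert set(share["year"]) == set(range(2018, 2023))


class TestSubstanceClassShares:
    def test_single_fluoroquinolone_is_all_hpcia(self, drug_dict):
        entries = _entries(
            [{"entry_date": "2019-03-01", "item_kind": "drug",
              "item_name": "Baytril 50 mg Tabletten"}]
        )
        data = build_consultations(entries, drug_dict)
        shares = summarize_substance_classes(data.applications)
        assert len(shares) == 1
        assert shares.iloc[0]["substance_class"] == "fluoroquinolone"
        assert shares.iloc[0]["percent"] == 100.0
        assert hpcia_share(data.applications) == 100.0

    def test_empty_treated_set_is_empty_table(self, drug_dict):
        entries = _entries([{"entry_date": "2019-03-01"}])
        data = build_consultations(entries, drug_dict)
        assert len(summarize_substance_classes(data.applications)) == 0

    def test_class_shares_match_ground_truth(self, small_cohort):
        data, truth = small_cohort
        shares = summarize_substance_classes(data.applications)
        got = dict(zip(shares["substance_class"], shares["percent"]))
        for cls, expected in truth.substance_class_shares.items():
            assert got[cls] == pytest.approx(100 * expected, abs=1e-9)


class TestHumanDrugs:
    def test_no_human_products_is_zero(self, drug_dict):
        entries = _entries(
            [{"entry_date": "2019-03-01", "item_kind": "drug",
              "item_name": "amoxicillin"}]
        )
        data = build_consultations(entries, drug_dict)
        summary = summarize_human_drugs(data.consultations, data.applications)
        assert summary.share_percent == 0.0

    def test_all_local_human_products(self, drug_dict):
        entries = _entries(
            [{"entry_date": "2019-03-01", "item_kind": "drug",
              "item_name": "gentamicin eye drops"}]
        )
        data = build_consultations(entries, drug_dict)
        summary = summarize_human_drugs(data.consultations, data.applications)
        assert summary.share_percent == 100.0
        assert summary.route_breakdown_percent == {"local": 100.0}

    def test_share_matches_ground_truth(self, small_cohort):
        data, truth = small_cohort
        summary = summarize_human_drugs(data.consultations, data.applications)
        assert summary.share_percent == pytest.approx(
            100 * truth.human_product_share, abs=1e-9
        )
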