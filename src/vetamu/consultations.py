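"""Aggregate invoice entries into consultations and summarize treatment.

A consultation is the set of all invoice entries of one animal on one
calendar date. A consultation is *treated* when at least one entry resolves
to an antibiotic product; the same substance applied and dispensed on one
date counts once in the substance set, while per-class usage shares count
every application/delivery row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import indications as ind
from .io import _norm_name, breed_flags
from .model import (
    UNASSIGNED,
    BreedProfile,
    CohortFilter,
    DrugRecord,
    Species,
    impute_weight,
)

#: Stratifiers accepted by :func:`summarize_treatment_share`.
STRATIFIERS = ("species", "practice", "year", "indication", "age_band")

AGE_BAND_EDGES = (0, 2, 4, 6, 8, 10, 12, 14, 16, 30)


@dataclass
class ConsultationData:
    """Built consultations plus the per-application tidy table."""

    consultations: pd.DataFrame
    applications: pd.DataFrame
    n_unresolved_drug_rows: int = 0


@dataclass
class ExclusionReport:
    """Counts per exclusion reason from the cohort filter."""

    consultations_in: int = 0
    excluded_species: int = 0
    excluded_year: int = 0
    excluded_small_practice: int = 0
    practices_excluded: int = 0
    consultations_out: int = 0
    warnings: list[str] = field(default_factory=list)


def _consult_id(patient: pd.Series, date: pd.Series) -> pd.Series:
    return patient.astype(str) + "@" + date.dt.strftime("%Y-%m-%d")


def build_consultations(
    entries: pd.DataFrame,
    drug_dictionary: dict[str, DrugRecord],
    breed_table: dict[str, BreedProfile] | None = None,
    lexicon: dict[str, str] | None = None,
) -> ConsultationData:
    """Group validated invoice entries into one consultation per
    (patient, date), resolving drugs, breed flags, imputed weight, and —
    when a lexicon is given — the indication category.
    """
    df = entries.copy()
    if len(df) == 0:
        return ConsultationData(
            consultations=pd.DataFrame(), applications=pd.DataFrame(), n_unresolved_drug_rows=0
        )
    df["consult_id"] = _consult_id(df["patient_id"], df["entry_date"])

    # resolve drug-kind rows through the dictionary (vectorized over names)
    drug_rows = df[df["item_kind"] == "drug"].copy()
    records = {
        name: drug_dictionary.get(_norm_name(name))
        for name in drug_rows["item_name"].unique()
    }
    resolved = drug_rows["item_name"].map(records)
    n_unresolved = int(resolved.isna().sum())
    is_ab = resolved.map(lambda r: r is not None and r.is_antibiotic).astype(bool)
    if is_ab.any():
        ab_rows = drug_rows[is_ab].copy()
        ab_records = resolved[is_ab]
    else:
        ab_rows = drug_rows.iloc[0:0].copy()
        ab_records = resolved.iloc[0:0]
    applications = pd.DataFrame(
        {
            "consult_id": ab_rows["consult_id"].to_numpy(),
            "practice_id": ab_rows["practice_id"].to_numpy(),
            "patient_id": ab_rows["patient_id"].to_numpy(),
            "species": ab_rows["species"].to_numpy(),
            "date": ab_rows["entry_date"].to_numpy(),
            "item_name": ab_rows["item_name"].to_numpy(),
            "substance": [";".join(r.substances) for r in ab_records],
            "substance_class": [r.substance_class.value for r in ab_records],
            "hpcia": [r.hpcia for r in ab_records],
            "route": [r.route.value for r in ab_records],
            "registration": [r.registration.value for r in ab_records],
        }
    )

    def _join_unique(texts: pd.Series) -> str:
        seen, out = set(), []
        for t in texts:
            t = str(t).strip()
            if t and t not in seen:
                seen.add(t)
                out.append(t)
        return " ".join(out)

    grouped = df.groupby("consult_id", sort=True)
    consults = grouped.agg(
        practice_id=("practice_id", "first"),
        patient_id=("patient_id", "first"),
        species=("species", "first"),
        breed=("breed", "first"),
        sex=("sex", "first"),
        date=("entry_date", "first"),
        birth_date=("birth_date", "first"),
        death_date=("death_date", "first"),
        n_entries=("item_name", "size"),
        anamnesis_text=("anamnesis_text", _join_unique),
        diagnosis_text=("diagnosis_text", _join_unique),
    ).reset_index()

    # substance set per consultation (deduplicated), plus route/registration flags
    if len(applications):
        per_consult = applications.groupby("consult_id").agg(
            substances=("substance", lambda s: ";".join(sorted(set(s)))),
            n_substances=("substance", lambda s: len(set(s))),
            hpcia_any=("hpcia", "any"),
            human_drug_any=("registration", lambda r: bool((r == "human").any())),
            local_only=("route", lambda r: bool((r == "local").all())),
        )
        consults = consults.merge(per_consult.reset_index(), on="consult_id", how="left")
    else:
        consults["substances"] = None
        consults["n_substances"] = np.nan
        consults["hpcia_any"] = False
        consults["human_drug_any"] = False
        consults["local_only"] = False
    consults["substances"] = consults["substances"].fillna("")
    consults["n_substances"] = consults["n_substances"].fillna(0).astype(int)
    consults["treated"] = consults["n_substances"] >= 1
    for col in ("hpcia_any", "human_drug_any", "local_only"):
        consults[col] = consults[col].astype("boolean").fillna(False).astype(bool)

    consults["age_years"] = (
        (consults["date"] - consults["birth_date"]).dt.days / 365.25
    )

    # breed flags + imputed weight
    if breed_table is None:
        breed_table = {}
    profiles = {b: breed_flags(b, breed_table) for b in consults["breed"].unique()}
    for flag in ("short_nose", "skin_predisposed", "entropion_predisposed", "crossbreed"):
        consults[flag] = consults["breed"].map(
            {b: getattr(p, flag) for b, p in profiles.items()}
        )
    weights = []
    for sp, breed in zip(consults["species"], consults["breed"]):
        if sp in (Species.DOG.value, Species.CAT.value):
            weights.append(impute_weight(sp, profiles[breed]))
        else:
            weights.append(np.nan)
    consults["weight_kg"] = weights

    if lexicon is not None:
        assigned = ind.assign_indications(
            consults["anamnesis_text"], consults["diagnosis_text"], lexicon
        )
        consults["indication"] = assigned["category"]
        consults["matched_keywords"] = assigned["matched_keywords"]
    else:
        consults["indication"] = UNASSIGNED
        consults["matched_keywords"] = ""

    consults = consults.sort_values(["patient_id", "date"], kind="mergesort").reset_index(
        drop=True
    )
    return ConsultationData(
        consultations=consults,
        applications=applications,
        n_unresolved_drug_rows=n_unresolved,
    )


def apply_cohort_filter(
    data: ConsultationData, cohort_filter: CohortFilter
) -> tuple[ConsultationData, ExclusionReport]:
    """Apply species / year / practice-size eligibility.

    Practices contributing fewer than ``min_patients_per_practice`` distinct
    eligible patients are removed entirely; a practice with exactly the
    minimum is retained. An empty result is a warning, not an error.
    """
    consults = data.consultations
    report = ExclusionReport(consultations_in=len(consults))
    if len(consults) == 0:
        report.warnings.append("empty input")
        return data, report

    species_ok = consults["species"].isin(cohort_filter.species_whitelist)
    report.excluded_species = int((~species_ok).sum())
    kept = consults[species_ok]

    y0, y1 = cohort_filter.year_range
    year = kept["date"].dt.year
    year_ok = (year >= y0) & (year <= y1)
    report.excluded_year = int((~year_ok).sum())

    counting_pool = kept[year_ok] if cohort_filter.count_patients_within_years else kept
    patients_per_practice = counting_pool.groupby("practice_id")["patient_id"].nunique()
    big_enough = patients_per_practice[
        patients_per_practice >= cohort_filter.min_patients_per_practice
    ].index
    all_practices = consults["practice_id"].unique()
    report.practices_excluded = len(set(all_practices)) - len(set(big_enough))

    kept = kept[year_ok]
    practice_ok = kept["practice_id"].isin(big_enough)
    report.excluded_small_practice = int((~practice_ok).sum())
    kept = kept[practice_ok].reset_index(drop=True)
    report.consultations_out = len(kept)
    if len(kept) == 0:
        report.warnings.append("all consultations excluded by the cohort filter")

    apps = data.applications
    if len(apps):
        apps = apps[apps["consult_id"].isin(set(kept["consult_id"]))].reset_index(
            drop=True
        )
    return (
        ConsultationData(kept, apps, data.n_unresolved_drug_rows),
        report,
    )


def _stratum_columns(consults: pd.DataFrame, by: tuple[str, ...]) -> pd.DataFrame:
    frame = pd.DataFrame(index=consults.index)
    for strat in by:
        if strat == "species":
            frame["species"] = consults["species"]
        elif strat == "practice":
            frame["practice"] = consults["practice_id"]
        elif strat == "year":
            frame["year"] = consults["date"].dt.year
        elif strat == "indication":
            frame["indication"] = consults["indication"]
        elif strat == "age_band":
            frame["age_band"] = pd.cut(
                consults["age_years"],
                bins=AGE_BAND_EDGES,
                right=False,
                labels=[
                    f"{lo}-{hi}" for lo, hi in zip(AGE_BAND_EDGES[:-1], AGE_BAND_EDGES[1:])
                ],
            )
        else:
            raise ValueError(
                f"unknown stratifier {strat!r}; expected one of {STRATIFIERS}"
            )
    return frame


def summarize_treatment_share(
    consults: pd.DataFrame, by: tuple[str, ...] = ("species",)
) -> pd.DataFrame:
    """Treatment share per stratum: (stratum, n_consultations, n_treated, percent).

    Strata with zero consultations are omitted.
    """
    strata = _stratum_columns(consults, tuple(by))
    work = strata.assign(treated=consults["treated"].to_numpy())
    grouped = work.groupby(list(by), observed=True)["treated"].agg(["size", "sum"])
    out = grouped.reset_index().rename(
        columns={"size": "n_consultations", "sum": "n_treated"}
    )
    out["n_treated"] = out["n_treated"].astype(int)
    out["percent"] = 100.0 * out["n_treated"] / out["n_consultations"]
    return out


def summarize_substance_classes(applications: pd.DataFrame) -> pd.DataFrame:
    """Per-class application counts and shares over all applications."""
    if len(applications) == 0:
        return pd.DataFrame(
            columns=["substance_class", "n_applications", "percent", "hpcia"]
        )
    grouped = (
        applications.groupby("substance_class")
        .agg(n_applications=("substance", "size"), hpcia=("hpcia", "first"))
        .reset_index()
        .sort_values("n_applications", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )
    grouped["percent"] = 100.0 * grouped["n_applications"] / grouped["n_applications"].sum()
    return grouped[["substance_class", "n_applications", "percent", "hpcia"]]


def hpcia_share(applications: pd.DataFrame) -> float:
    """Percent of applications/deliveries in HPCIA classes."""
    if len(applications) == 0:
        return float("nan")
    return 100.0 * float(applications["hpcia"].mean())


@dataclass
class HumanDrugSummary:
    """Use of human-registered products among treated consultations."""

    share_percent: float
    n_treated_consultations: int
    n_with_human_product: int
    route_breakdown_percent: dict[str, float]
    top_substances: dict[str, int]


def summarize_human_drugs(
    consults: pd.DataFrame, applications: pd.DataFrame, top_n: int = 5
) -> HumanDrugSummary:
    """Share of treated consultations using a human-registered product,
    with the route breakdown and the most frequent substances among those
    applications."""
    treated = consults[consults["treated"]]
    n_treated = len(treated)
    human_apps = (
        applications[applications["registration"] == "human"]
        if len(applications)
        else applications
    )
    n_with = int(human_apps["consult_id"].nunique()) if len(human_apps) else 0
    share = 100.0 * n_with / n_treated if n_treated else float("nan")
    if len(human_apps):
        routes = (100.0 * human_apps["route"].value_counts(normalize=True)).to_dict()
        top = human_apps["substance"].value_counts().head(top_n).to_dict()
        top = {k: int(v) for k, v in top.items()}
    else:
        routes, top = {}, {}
    return HumanDrugSummary(
        share_percent=share,
        n_treated_consultations=n_treated,
        n_with_human_product=n_with,
        route_breakdown_percent=routes,
        top_substances=top,
    )
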