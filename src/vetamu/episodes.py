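"""Treatment-episode construction from per-patient consultation histories.

A treated consultation is an *initial* treatment when the same animal had
no antibiotic treatment in the preceding 30 days, and a *follow-up*
treatment when it falls 1-7 days after another treatment. Gaps of 8-30
days are neither. A *substance change* is a follow-up whose single
substance differs from the single substance of the preceding treatment;
consultations with more than one substance are excluded from change
eligibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: Day-offset windows (inclusive): follow-up at offsets 1..7,
#: washout blocking initial status at offsets 1..30.
FOLLOWUP_WINDOW_DAYS = 7
WASHOUT_DAYS = 30


def label_episodes(
    consultations: pd.DataFrame,
    washout: int = WASHOUT_DAYS,
    followup_window: int = FOLLOWUP_WINDOW_DAYS,
) -> pd.DataFrame:
    """Label every treated consultation as initial / follow-up / neither.

    Returns one row per treated consultation with day offsets to the
    previous and next treatment, the chain's initial consultation, and the
    substance-change flag (defined only for single-substance follow-up
    pairs). Input order is irrelevant; output is sorted per patient by
    date.
    """
    treated = consultations[consultations["treated"]].copy()
    cols = [
        "consult_id", "patient_id", "species", "date", "substances", "n_substances",
    ]
    treated = treated[[c for c in cols if c in treated.columns]]
    treated = treated.sort_values(["patient_id", "date"], kind="mergesort").reset_index(
        drop=True
    )
    dup = treated.duplicated(subset=["patient_id", "date"])
    assert not dup.any(), "duplicate (patient, date) among consultations"

    records = []
    for patient_id, group in treated.groupby("patient_id", sort=True):
        dates = group["date"].tolist()
        n_subs = group["n_substances"].tolist()
        subs = group["substances"].tolist()
        chain_initial = [None] * len(group)
        for i in range(len(group)):
            prev_gap = (dates[i] - dates[i - 1]).days if i > 0 else None
            next_gap = (
                (dates[i + 1] - dates[i]).days if i + 1 < len(group) else None
            )
            is_initial = prev_gap is None or prev_gap > washout
            is_followup = prev_gap is not None and 1 <= prev_gap <= followup_window
            if is_followup:
                chain_initial[i] = chain_initial[i - 1]
            else:
                chain_initial[i] = i
            days_since_initial = (
                (dates[i] - dates[chain_initial[i]]).days if is_followup else None
            )
            changed: bool | None = None
            prev_substance = None
            if is_followup and n_subs[i] == 1 and n_subs[i - 1] == 1:
                prev_substance = subs[i - 1]
                changed = subs[i] != subs[i - 1]
            records.append(
                {
                    "consult_id": group["consult_id"].iloc[i],
                    "patient_id": patient_id,
                    "species": group["species"].iloc[i],
                    "date": dates[i],
                    "is_initial": is_initial,
                    "is_followup": is_followup,
                    "days_since_prev_treatment": prev_gap,
                    "days_since_initial": days_since_initial,
                    "days_to_next_treatment": next_gap,
                    "n_substances": n_subs[i],
                    "substances": subs[i],
                    "prev_substances": prev_substance,
                    "substance_changed": changed,
                }
            )
    labels = pd.DataFrame.from_records(
        records,
        columns=[
            "consult_id", "patient_id", "species", "date", "is_initial",
            "is_followup", "days_since_prev_treatment", "days_since_initial",
            "days_to_next_treatment", "n_substances", "substances",
            "prev_substances", "substance_changed",
        ],
    )
    return labels


def initial_share(labels: pd.DataFrame) -> pd.DataFrame:
    """Percent of treatments that are initial, per species."""
    grouped = labels.groupby("species")["is_initial"].agg(["size", "sum"]).reset_index()
    grouped.columns = ["species", "n_treatments", "n_initial"]
    grouped["n_initial"] = grouped["n_initial"].astype(int)
    grouped["percent"] = 100.0 * grouped["n_initial"] / grouped["n_treatments"]
    return grouped


def followup_within(
    labels: pd.DataFrame, window: int = FOLLOWUP_WINDOW_DAYS
) -> pd.DataFrame:
    """Percent of initial treatments followed by another treatment within
    ``window`` days (inclusive), per species."""
    initials = labels[labels["is_initial"]].copy()
    gap = initials["days_to_next_treatment"]
    initials["followed"] = gap.notna() & (gap >= 1) & (gap <= window)
    grouped = initials.groupby("species")["followed"].agg(["size", "sum"]).reset_index()
    grouped.columns = ["species", "n_initial", "n_followed"]
    grouped["n_followed"] = grouped["n_followed"].astype(int)
    grouped["percent"] = 100.0 * grouped["n_followed"] / grouped["n_initial"]
    return grouped


def repeat_treatment_share(
    consultations: pd.DataFrame,
    window_days: int = 365,
    mode: str = "sliding",
) -> pd.DataFrame:
    """Percent of patients with at least two treatments within one year.

    ``mode="sliding"``: any two treated consultations <= ``window_days``
    apart (for sorted dates it suffices to check adjacent gaps).
    ``mode="calendar"``: at least two treated consultations within one
    calendar year. Denominator: all patients of the species.
    """
    if mode not in ("sliding", "calendar"):
        raise ValueError("mode must be 'sliding' or 'calendar'")
    out = []
    for species, group in consultations.groupby("species"):
        patients = group["patient_id"].nunique()
        treated = group[group["treated"]].sort_values(
            ["patient_id", "date"], kind="mergesort"
        )
        if mode == "sliding":
            gaps = treated.groupby("patient_id")["date"].diff().dt.days
            hit = treated.loc[gaps.notna() & (gaps <= window_days), "patient_id"]
            n_repeat = hit.nunique()
        else:
            per_year = treated.groupby(
                ["patient_id", treated["date"].dt.year]
            ).size()
            n_repeat = (
                per_year[per_year >= 2].reset_index()["patient_id"].nunique()
            )
        out.append(
            {
                "species": species,
                "n_patients": patients,
                "n_repeat_patients": int(n_repeat),
                "percent": 100.0 * n_repeat / patients if patients else float("nan"),
            }
        )
    return pd.DataFrame(out)


def time_to_return_histogram(
    consultations: pd.DataFrame, max_offset: int = 30
) -> pd.DataFrame:
    """Counts of day offsets to each patient's next consultation (of any
    kind), split by whether the index consultation was treated."""
    work = consultations.sort_values(["patient_id", "date"], kind="mergesort")
    offset = (
        work.groupby("patient_id")["date"].shift(-1) - work["date"]
    ).dt.days
    frame = pd.DataFrame(
        {"index_treated": work["treated"].to_numpy(), "offset": offset.to_numpy()}
    ).dropna()
    frame = frame[(frame["offset"] >= 1) & (frame["offset"] <= max_offset)]
    if len(frame) == 0:
        return pd.DataFrame(columns=["index_treated", "offset", "n"])
    hist = (
        frame.astype({"offset": int})
        .groupby(["index_treated", "offset"])
        .size()
        .reset_index(name="n")
    )
    return hist


@dataclass
class SubstanceChangeResult:
    """Substance-change events among single-substance follow-up pairs.

    ``change_share`` uses eligible follow-up pairs as the denominator;
    ``change_share_per_initial`` divides by single-substance initial
    treatments instead — both denominators are defensible readings of
    "share of cases" and are therefore both reported.
    """

    transitions: pd.DataFrame
    n_eligible_pairs: int
    n_changes: int
    change_share: float
    n_single_substance_initial: int
    change_share_per_initial: float

    @property
    def offset_distribution(self) -> pd.DataFrame:
        if len(self.transitions) == 0:
            return pd.DataFrame(columns=["days_since_initial", "n"])
        return (
            self.transitions.groupby("days_since_initial")
            .size()
            .reset_index(name="n")
        )


def detect_substance_change(labels: pd.DataFrame) -> SubstanceChangeResult:
    """Collect substance-change events from episode labels.

    A change event is a follow-up (offset 1-7) whose single substance
    differs from the preceding treatment's single substance. Emits the
    transition table (from, to, day offsets) and both change shares.
    """
    eligible = labels[labels["substance_changed"].notna()]
    changes = eligible[eligible["substance_changed"].astype(bool)]
    transitions = pd.DataFrame(
        {
            "from_substance": changes["prev_substances"].to_numpy(),
            "to_substance": changes["substances"].to_numpy(),
            "days_since_prev": changes["days_since_prev_treatment"].to_numpy(),
            "days_since_initial": changes["days_since_initial"].to_numpy(),
        }
    )
    n_eligible = len(eligible)
    n_changes = len(changes)
    initials_single = labels[labels["is_initial"] & (labels["n_substances"] == 1)]
    n_init = len(initials_single)
    return SubstanceChangeResult(
        transitions=transitions.reset_index(drop=True),
        n_eligible_pairs=n_eligible,
        n_changes=n_changes,
        change_share=n_changes / n_eligible if n_eligible else float("nan"),
        n_single_substance_initial=n_init,
        change_share_per_initial=n_changes / n_init if n_init else float("nan"),
    )
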