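"""End-to-end pipeline orchestration with an auditable report bundle.

A single run config (YAML) names the input invoice table, the three
reference dictionaries, and every filter/window/model option; the run
produces intermediate CSVs (consultations, applications, episode labels,
summary tables) plus a machine-readable ``report.json`` (schema-validated)
and a human-readable ``report.md``. All defaults follow the study
conventions: minimum 100 patients per practice, years 2018-2022, a 7-day
follow-up window, a 30-day washout, and spline df = 4.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel

from . import consultations as cons
from . import episodes as epi
from . import indications as ind
from . import io as vio
from . import stats
from .model import CohortFilter, SplineModelSpec

#: The three predisposition/indication pairings analyzed in dogs.
PREDISPOSITION_PAIRS = (
    ("short_nose", "respiratory system"),
    ("skin_predisposed", "dermatology"),
    ("entropion_predisposed", "ophthalmology"),
)

_BOOL_COLS = (
    "treated", "hpcia_any", "human_drug_any", "local_only",
    "short_nose", "skin_predisposed", "entropion_predisposed", "crossbreed",
)


@dataclass
class RunConfig:
    """Configuration of one end-to-end pipeline run."""

    invoices: str
    out_dir: str
    drugs: str | None = None
    breeds: str | None = None
    lexicon: str | None = None
    min_patients_per_practice: int = 100
    year_range: tuple[int, int] = (2018, 2022)
    followup_window: int = 7
    washout: int = 30
    spline_df: int = 4
    repeat_mode: str = "sliding"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.followup_window < 1 or self.washout < 1:
            raise ValueError("episode windows must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "year_range" in raw and raw["year_range"] is not None:
            raw["year_range"] = tuple(raw["year_range"])
        return cls(**raw)


class ORRow(BaseModel):
    a: int
    b: int
    c: int
    d: int
    or_point: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    p_value: float | None = None
    error: str | None = None


class PredispositionSection(BaseModel):
    flag: str
    category: str
    indication_occurrence: ORRow | None = None
    treatment: ORRow | None = None
    treatment_within_indication: ORRow | None = None
    error: str | None = None


class Report(BaseModel):
    """Schema of the machine-readable pipeline report."""

    n_practices: int
    n_patients: dict[str, int]
    n_consultations: dict[str, int]
    n_treated: dict[str, int]
    exclusions: dict[str, int]
    n_rejected_rows: int
    n_unresolved_drug_rows: int
    treatment_share_percent: dict[str, float]
    substance_class_percent: dict[str, float]
    hpcia_share_percent: float
    multi_substance_percent: float
    human_product_percent: float
    human_route_percent: dict[str, float]
    initial_share_percent: dict[str, float]
    followup_within_window_percent: dict[str, float]
    repeat_within_year_percent: dict[str, float]
    substance_change_percent: float
    substance_change_per_initial_percent: float
    indication_coverage_percent: float
    indication_distribution_percent: dict[str, float]
    predispositions: list[PredispositionSection]
    crossbreed: ORRow | None = None
    crossbreed_percent: dict[str, float] = {}
    ci_null_coverage: float | None = None

    model_config = {"extra": "forbid"}


def write_consultations_csv(consults: pd.DataFrame, path: str | Path) -> None:
    out = consults.copy()
    for col in ("date", "birth_date", "death_date"):
        if col in out and pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d").fillna("")
    out.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")


def read_consultations_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    for col in ("date", "birth_date", "death_date"):
        if col in df:
            df[col] = pd.to_datetime(df[col].replace("", pd.NA))
    for col in _BOOL_COLS:
        if col in df:
            df[col] = df[col].map({"True": True, "False": False, "": False})
    for col in ("age_years", "weight_kg"):
        if col in df:
            df[col] = pd.to_numeric(df[col].replace("", pd.NA), errors="coerce")
    if "n_substances" in df:
        df["n_substances"] = pd.to_numeric(df["n_substances"]).astype(int)
    if "n_entries" in df:
        df["n_entries"] = pd.to_numeric(df["n_entries"]).astype(int)
    return df


def _or_row(table) -> ORRow:
    row = ORRow(a=table.a, b=table.b, c=table.c, d=table.d)
    try:
        result = stats.odds_ratio(table)
        row.or_point = result.or_point
        row.ci_low = result.ci_low
        row.ci_high = result.ci_high
        row.p_value = result.p_value
    except ValueError as err:
        row.error = str(err)
    return row


def _share_map(frame: pd.DataFrame, key: str = "species") -> dict[str, float]:
    return {str(r[key]): float(r["percent"]) for _, r in frame.iterrows()}


def run_pipeline(config: RunConfig) -> Report:
    """Run the full pipeline and write the report bundle to ``out_dir``.

    Deterministic for identical inputs and seed. Any stage failure aborts
    with the stage name; files written so far are removed.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write_csv(frame: pd.DataFrame, name: str) -> None:
        path = out_dir / name
        frame.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")
        written.append(path)

    stage = "load"
    try:
        drugs = vio.load_drug_dictionary(config.drugs)
        breeds = vio.load_breed_table(config.breeds)
        lexicon = vio.load_lexicon(config.lexicon)
        invoices, rejects = vio.load_invoices(config.invoices)

        stage = "build"
        data = cons.build_consultations(invoices, drugs, breeds, lexicon)
        cohort_filter = CohortFilter(
            min_patients_per_practice=config.min_patients_per_practice,
            year_range=config.year_range,
        )
        data, exclusions = cons.apply_cohort_filter(data, cohort_filter)
        consults, apps = data.consultations, data.applications
        path = out_dir / "consultations.csv"
        write_consultations_csv(consults, path)
        written.append(path)
        _write_csv(apps, "applications.csv")

        stage = "episodes"
        labels = epi.label_episodes(
            consults, washout=config.washout, followup_window=config.followup_window
        )
        _write_csv(labels, "episodes.csv")
        change = epi.detect_substance_change(labels)
        _write_csv(change.transitions, "substance_changes.csv")
        _write_csv(epi.time_to_return_histogram(consults), "time_to_return.csv")

        stage = "statistics"
        share = cons.summarize_treatment_share(consults, by=("species",))
        class_shares = cons.summarize_substance_classes(apps)
        _write_csv(class_shares, "substance_class_shares.csv")
        human = cons.summarize_human_drugs(consults, apps)
        init = epi.initial_share(labels)
        follow = epi.followup_within(labels, window=config.followup_window)
        repeat = epi.repeat_treatment_share(consults, mode=config.repeat_mode)
        coverage = ind.assignment_coverage(consults["indication"])
        ind_counts = (
            consults.groupby("indication").size().reset_index(name="n_consultations")
        )
        ind_counts["percent"] = (
            100.0 * ind_counts["n_consultations"] / len(consults)
            if len(consults)
            else float("nan")
        )
        _write_csv(ind_counts, "indication_counts.csv")

        dogs = consults[consults["species"] == "dog"]
        predispositions = []
        for flag, category in PREDISPOSITION_PAIRS:
            section = PredispositionSection(flag=flag, category=category)
            try:
                section.indication_occurrence = _or_row(
                    stats.indication_occurrence_table(dogs, flag, category)
                )
                section.treatment = _or_row(stats.treatment_table(dogs, flag))
                section.treatment_within_indication = _or_row(
                    stats.treatment_within_indication_table(dogs, flag, category)
                )
            except ValueError as err:
                section.error = str(err)
            predispositions.append(section)

        crossbreed_row = None
        crossbreed_pct: dict[str, float] = {}
        try:
            cb = stats.crossbreed_comparison(consults)
            crossbreed_row = _or_row(cb.table)
            crossbreed_pct = {
                "crossbreed": cb.crossbreed_percent,
                "purebreed": cb.purebreed_percent,
            }
        except (ValueError, KeyError):
            pass

        # spline prevalence curves over weight (dogs) and age (both species)
        for predictor, frame in (("weight_kg", dogs), ("age_years", consults)):
            try:
                curve = stats.fit_spline_prevalence(
                    frame, SplineModelSpec(predictor=predictor, degrees_of_freedom=config.spline_df)
                )
                _write_csv(curve.curve, f"prevalence_{predictor}.csv")
            except (stats.SplineFitError, KeyError):
                pass

        coverage_null = stats.simulate_null_coverage(
            n_replicates=200, seed=config.seed
        )

        treated_total = int(consults["treated"].sum())
        multi_pct = (
            100.0 * float((consults["n_substances"] >= 2).sum()) / treated_total
            if treated_total
            else float("nan")
        )
        report = Report(
            n_practices=int(consults["practice_id"].nunique()),
            n_patients={
                sp: int(g["patient_id"].nunique())
                for sp, g in consults.groupby("species")
            },
            n_consultations={
                sp: int(len(g)) for sp, g in consults.groupby("species")
            },
            n_treated={
                sp: int(g["treated"].sum()) for sp, g in consults.groupby("species")
            },
            exclusions={
                "excluded_species": exclusions.excluded_species,
                "excluded_year": exclusions.excluded_year,
                "excluded_small_practice": exclusions.excluded_small_practice,
                "practices_excluded": exclusions.practices_excluded,
            },
            n_rejected_rows=rejects.n,
            n_unresolved_drug_rows=data.n_unresolved_drug_rows,
            treatment_share_percent=_share_map(share),
            substance_class_percent={
                str(r["substance_class"]): float(r["percent"])
                for _, r in class_shares.iterrows()
            },
            hpcia_share_percent=cons.hpcia_share(apps),
            multi_substance_percent=multi_pct,
            human_product_percent=human.share_percent,
            human_route_percent=human.route_breakdown_percent,
            initial_share_percent=_share_map(init),
            followup_within_window_percent=_share_map(follow),
            repeat_within_year_percent=_share_map(repeat),
            substance_change_percent=100.0 * change.change_share,
            substance_change_per_initial_percent=100.0 * change.change_share_per_initial,
            indication_coverage_percent=coverage,
            indication_distribution_percent={
                str(r["indication"]): float(r["percent"])
                for _, r in ind_counts.iterrows()
            },
            predispositions=predispositions,
            crossbreed=crossbreed_row,
            crossbreed_percent=crossbreed_pct,
            ci_null_coverage=coverage_null,
        )

        stage = "write-report"
        report_path = out_dir / "report.json"
        with open(report_path, "w", encoding="utf-8") as fh:
            json.dump(report.model_dump(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(report_path)
        md_path = out_dir / "report.md"
        md_path.write_text(_render_markdown(report), encoding="utf-8")
        written.append(md_path)
        return report
    except Exception as err:
        for path in written:
            path.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err


def _render_markdown(report: Report) -> str:
    lines = ["# Antimicrobial-usage report", ""]
    lines.append(
        f"Cohort: {report.n_practices} practices; "
        + "; ".join(
            f"{sp}: {report.n_patients.get(sp, 0)} patients, "
            f"{report.n_consultations.get(sp, 0)} consultations, "
            f"{report.n_treated.get(sp, 0)} treated"
            for sp in sorted(report.n_consultations)
        )
    )
    lines.append("")
    lines.append("## Treatment shares")
    for sp, pct in sorted(report.treatment_share_percent.items()):
        lines.append(f"- {sp}: {pct:.1f}% of consultations treated")
    lines.append(f"- HPCIA share of applications: {report.hpcia_share_percent:.1f}%")
    lines.append(f"- multi-substance consultations: {report.multi_substance_percent:.1f}%")
    lines.append(f"- human-registered products: {report.human_product_percent:.1f}%")
    lines.append("")
    lines.append("## Episodes")
    for sp in sorted(report.initial_share_percent):
        lines.append(
            f"- {sp}: {report.initial_share_percent[sp]:.1f}% initial; "
            f"{report.followup_within_window_percent.get(sp, float('nan')):.1f}% of initials "
            f"followed up; {report.repeat_within_year_percent.get(sp, float('nan')):.1f}% of "
            "patients treated twice within a year"
        )
    lines.append(
        f"- substance changed in {report.substance_change_percent:.1f}% of eligible "
        f"follow-up pairs ({report.substance_change_per_initial_percent:.1f}% per "
        "single-substance initial treatment)"
    )
    lines.append("")
    lines.append("## Indications")
    lines.append(f"- coverage: {report.indication_coverage_percent:.1f}% assigned")
    lines.append("")
    lines.append("## Breed predispositions (dogs)")
    for section in report.predispositions:
        if section.error or section.treatment is None:
            lines.append(f"- {section.flag}: not computable ({section.error})")
            continue
        t = section.treatment
        lines.append(
            f"- {section.flag} x {section.category}: treatment OR "
            f"{t.or_point:.2f} ({t.ci_low:.2f}-{t.ci_high:.2f})"
            if t.or_point is not None
            else f"- {section.flag}: {t.error}"
        )
    return "\n".join(lines) + "\n"
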