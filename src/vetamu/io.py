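"""Reading, validation, and reference-table lookups for invoice data.

Invoice tables travel as UTF-8 CSV (RFC-4180 quoting); the drug dictionary,
breed dictionary, and indication lexicon are tab-separated text. Small
versions of all three reference tables ship with the package.
"""

from __future__ import annotations

import re
from importlib import resources
from pathlib import Path

import pandas as pd

from .model import (
    INVOICE_COLUMNS,
    BreedProfile,
    DrugRecord,
    ItemKind,
    Registration,
    RejectReport,
    Route,
    Species,
    SubstanceClass,
)


class SchemaError(ValueError):
    """Raised when an input table does not match the declared schema."""


def packaged_data_path(name: str) -> Path:
    """Path to a data file shipped inside the package."""
    return Path(str(resources.files("vetamu").joinpath("data", name)))


def _norm_name(text: str) -> str:
    """Case/whitespace normalization used for dictionary keys."""
    return re.sub(r"\s+", " ", str(text).strip().lower())


# ---------------------------------------------------------------------------
# reference tables


def load_drug_dictionary(path: str | Path | None = None) -> dict[str, DrugRecord]:
    """Load the drug dictionary keyed by normalized product name.

    Bare substance names (e.g. "amoxicillin") appear as their own entries,
    resolving to substance-only records with unknown route/concentration —
    real invoices frequently record just the substance.
    """
    if path is None:
        path = packaged_data_path("drugs.tsv")
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False).fillna("")
    records: dict[str, DrugRecord] = {}
    for _, row in raw.iterrows():
        substances = tuple(
            s.strip() for s in str(row["substances"]).split(";") if s.strip()
        )
        rec = DrugRecord(
            product_name=row["product_name"].strip(),
            substances=substances,
            substance_class=SubstanceClass(row["substance_class"].strip()),
            route=Route(row.get("route", "unknown").strip() or "unknown"),
            registration=Registration(
                row.get("registration", "unknown").strip() or "unknown"
            ),
            concentration=str(row.get("concentration", "")).strip(),
            package_amount=str(row.get("package_amount", "")).strip(),
        )
        records[_norm_name(rec.product_name)] = rec
    return records


def resolve_drug(
    item_name: str, dictionary: dict[str, DrugRecord]
) -> DrugRecord | None:
    """Resolve a billed item name to a drug record, or None.

    Matching is case-insensitive on the whitespace-normalized name;
    an unresolvable name is a value (None), not an error.
    """
    if not item_name or not str(item_name).strip():
        return None
    return dictionary.get(_norm_name(item_name))


def load_breed_table(path: str | Path | None = None) -> dict[str, BreedProfile]:
    """Load the breed dictionary keyed by normalized breed name."""
    if path is None:
        path = packaged_data_path("breeds.tsv")
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    table: dict[str, BreedProfile] = {}
    for _, row in raw.iterrows():
        profile = BreedProfile(
            breed_name=row["breed_name"].strip(),
            mean_weight_kg=float(row["mean_weight_kg"]),
            short_nose=row["short_nose"].strip() == "1",
            skin_predisposed=row["skin_predisposed"].strip() == "1",
            entropion_predisposed=row["entropion_predisposed"].strip() == "1",
        )
        table[_norm_name(profile.breed_name)] = profile
    return table


def breed_flags(breed_text: str, breed_table: dict[str, BreedProfile]) -> BreedProfile:
    """Profile for a recorded breed string, with the crossbreed rule applied.

    Any breed text containing "Mischling" (case-insensitive substring) is a
    crossbreed. Other strings are looked up in the dictionary; an unknown
    pure breed yields a profile with all flags False and no mean weight.
    """
    text = str(breed_text or "").strip()
    if "mischling" in text.lower():
        return BreedProfile(
            breed_name=text, mean_weight_kg=None, crossbreed=True, known=False
        )
    profile = breed_table.get(_norm_name(text))
    if profile is None:
        return BreedProfile(breed_name=text, mean_weight_kg=None, known=False)
    return profile


def load_lexicon(path: str | Path | None = None) -> dict[str, str]:
    """Load the indication keyword lexicon as {keyword -> category}.

    Keywords are stored pre-normalized (lower case, whitespace-trimmed,
    umlauts folded); normalization is re-applied defensively on load.
    """
    if path is None:
        path = packaged_data_path("lexicon.tsv")
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(raw.columns) != ["keyword", "category"]:
        raise SchemaError(
            f"lexicon must have columns ['keyword', 'category'], got {list(raw.columns)}"
        )
    from .indications import normalize_text  # late import avoids a cycle

    lex: dict[str, str] = {}
    for _, row in raw.iterrows():
        kw = normalize_text(row["keyword"])
        if kw:
            lex[kw] = row["category"].strip()
    return lex


# ---------------------------------------------------------------------------
# invoice tables

_DATE_COLS = ("birth_date", "death_date", "entry_date")


def _parse_dates(series: pd.Series, date_format: str | None) -> pd.Series:
    return pd.to_datetime(series.replace("", pd.NA), format=date_format, errors="coerce")


def load_invoices(
    path: str | Path,
    date_format: str | None = None,
    max_reject_fraction: float = 0.5,
) -> tuple[pd.DataFrame, RejectReport]:
    """Read and validate an invoice CSV.

    Returns the rows passing all row-level invariants plus a reject report
    naming, for each rejected row, the violated rule. A reject fraction
    above ``max_reject_fraction`` aborts with :class:`SchemaError` (suspect
    schema drift rather than scattered bad rows).

    Dates are ISO-8601 by default; ``date_format`` accepts a strftime
    pattern for other exports.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in INVOICE_COLUMNS if c not in df.columns]
    extra = [c for c in df.columns if c not in INVOICE_COLUMNS]
    if missing or extra:
        raise SchemaError(
            f"invoice schema mismatch: missing columns {missing}, extra columns {extra}"
        )
    df = df[list(INVOICE_COLUMNS)].copy()
    for col in _DATE_COLS:
        parsed = _parse_dates(df[col], date_format)
        df[col + "_parsed"] = parsed

    report = RejectReport()
    valid_species = {s.value for s in Species}
    valid_kinds = {k.value for k in ItemKind}
    keep = []
    for idx, row in df.iterrows():
        rule = _validate_row(row, valid_species, valid_kinds)
        if rule is None:
            keep.append(idx)
        else:
            report.add(int(idx), rule[0], rule[1])

    if len(df) > 0 and report.n / len(df) > max_reject_fraction:
        raise SchemaError(
            f"{report.n}/{len(df)} rows rejected (> {max_reject_fraction:.0%}); "
            "suspect schema drift — check column mapping and date format"
        )
    out = df.loc[keep].copy()
    for col in _DATE_COLS:
        out[col] = out.pop(col + "_parsed")
    out = out[list(INVOICE_COLUMNS)].reset_index(drop=True)
    return out, report


def _validate_row(row, valid_species, valid_kinds) -> tuple[str, str] | None:
    if row["species"] not in valid_species:
        return ("invalid_species", row["species"])
    if row["item_kind"] not in valid_kinds:
        return ("invalid_item_kind", row["item_kind"])
    entry = row["entry_date_parsed"]
    if pd.isna(entry):
        return ("missing_or_unparseable_entry_date", row["entry_date"])
    birth = row["birth_date_parsed"]
    if pd.notna(birth) and entry < birth:
        return ("entry_before_birth", f"{entry.date()} < {birth.date()}")
    death = row["death_date_parsed"]
    if pd.notna(death) and entry > death:
        return ("entry_after_death", f"{entry.date()} > {death.date()}")
    if row["item_kind"] == ItemKind.DRUG.value and not str(row["item_name"]).strip():
        return ("drug_without_item_name", "")
    return None


def write_fixture(table: pd.DataFrame, path: str | Path) -> None:
    """Write an invoice table as UTF-8 CSV with RFC-4180 quoting."""
    missing = [c for c in INVOICE_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"table missing invoice columns: {missing}")
    out = table[list(INVOICE_COLUMNS)].copy()
    for col in _DATE_COLS:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d").fillna("")
    out.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")


def read_fixture(path: str | Path) -> pd.DataFrame:
    """Read back a fixture written by :func:`write_fixture` (no validation).

    Round-trips free text exactly, including delimiters and non-ASCII
    characters; dates come back as datetimes.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in INVOICE_COLUMNS if c not in df.columns]
    extra = [c for c in df.columns if c not in INVOICE_COLUMNS]
    if missing or extra:
        raise SchemaError(
            f"invoice schema mismatch: missing columns {missing}, extra columns {extra}"
        )
    for col in _DATE_COLS:
        df[col] = _parse_dates(df[col], None)
    return df[list(INVOICE_COLUMNS)]
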