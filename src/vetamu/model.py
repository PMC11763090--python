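"""Core domain model for companion-animal antimicrobial-usage analysis.

The raw unit of data is an *invoice entry*: one billed item (drug,
consumable, or examination) for one animal on one date, carrying the
patient's basic attributes and free-text anamnesis/diagnosis. All entries
of one animal on one calendar date form a *consultation*, the analysis
unit. Reference data are a drug dictionary (product name -> substances,
class, route, registration), a breed dictionary (mean weight and
predisposition flags), and an indication keyword lexicon.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class Species(str, enum.Enum):
    DOG = "dog"
    CAT = "cat"
    OTHER = "other"


class ItemKind(str, enum.Enum):
    DRUG = "drug"
    CONSUMABLE = "consumable"
    EXAMINATION = "examination"


class SubstanceClass(str, enum.Enum):
    """Antibiotic substance classes used for reporting and HPCIA flagging."""

    AMINOPENICILLIN = "aminopenicillin"
    AMINOPENICILLIN_INHIBITOR = "aminopenicillin+inhibitor"
    FLUOROQUINOLONE = "fluoroquinolone"
    CEPHALOSPORIN_1_2 = "cephalosporin-1/2-gen"
    CEPHALOSPORIN_3_4 = "cephalosporin-3/4-gen"
    MACROLIDE = "macrolide"
    POLYMYXIN = "polymyxin"
    AMINOGLYCOSIDE = "aminoglycoside"
    TETRACYCLINE = "tetracycline"
    NITROIMIDAZOLE = "nitroimidazole"
    OTHER = "other"
    NON_ANTIBIOTIC = "non-antibiotic"


#: Highest-priority critically important antimicrobials (WHO list):
#: 3rd/4th-generation cephalosporins, fluoroquinolones, macrolides, polymyxins.
HPCIA_CLASSES: frozenset[SubstanceClass] = frozenset(
    {
        SubstanceClass.CEPHALOSPORIN_3_4,
        SubstanceClass.FLUOROQUINOLONE,
        SubstanceClass.MACROLIDE,
        SubstanceClass.POLYMYXIN,
    }
)


def is_hpcia(substance_class: SubstanceClass | str) -> bool:
    """Whether a substance class belongs to the WHO HPCIA group.

    Total over the class enum; an unknown class raises ``ValueError``.
    """
    cls = SubstanceClass(substance_class)
    return cls in HPCIA_CLASSES


class Route(str, enum.Enum):
    LOCAL = "local"
    ORAL = "oral"
    PARENTERAL = "parenteral"
    UNKNOWN = "unknown"


class Registration(str, enum.Enum):
    VETERINARY = "veterinary"
    HUMAN = "human"
    UNKNOWN = "unknown"


#: The twenty coarse clinical indication categories assigned from free text.
#: Fifteen labels follow the published grouping (diagnostics/therapy covers
#: vaccination, castration, euthanasia, examination ...; "routine" covers
#: parasite treatment, drug delivery, chipping; "systemic" covers weakness,
#: anorexia, fever; non-specific terms fall to "unclear"); the remaining five
#: are package-defined placeholders completing the twenty-label set.
INDICATION_CATEGORIES: tuple[str, ...] = (
    "diagnostics/therapy",
    "dermatology",
    "orthopedics",
    "digestive system",
    "respiratory system",
    "otology",
    "ophthalmology",
    "urogenital tract",
    "emergency",
    "trauma",
    "intoxication",
    "endocrinology",
    "routine",
    "systemic",
    "unclear",
    "cardiology",
    "neurology",
    "dentistry",
    "oncology",
    "infectious disease",
)

#: Sentinel for consultations whose free text matched no lexicon keyword.
UNASSIGNED = "unassigned"

#: Columns of the invoice-entry table, in canonical order.
INVOICE_COLUMNS: tuple[str, ...] = (
    "practice_id",
    "patient_id",
    "species",
    "breed",
    "sex",
    "birth_date",
    "death_date",
    "entry_date",
    "anamnesis_text",
    "diagnosis_text",
    "item_name",
    "item_kind",
)


@dataclass(frozen=True)
class DrugRecord:
    """One product (or bare substance) in the drug dictionary."""

    product_name: str
    substances: tuple[str, ...]
    substance_class: SubstanceClass
    route: Route = Route.UNKNOWN
    registration: Registration = Registration.UNKNOWN
    concentration: str = ""
    package_amount: str = ""

    def __post_init__(self) -> None:
        has_substances = len(self.substances) > 0
        is_antibiotic = self.substance_class is not SubstanceClass.NON_ANTIBIOTIC
        if has_substances != is_antibiotic:
            raise ValueError(
                f"drug {self.product_name!r}: substances must be non-empty "
                f"iff the class is antibiotic (class={self.substance_class.value})"
            )

    @property
    def is_antibiotic(self) -> bool:
        return self.substance_class is not SubstanceClass.NON_ANTIBIOTIC

    @property
    def hpcia(self) -> bool:
        return self.substance_class in HPCIA_CLASSES


@dataclass(frozen=True)
class BreedProfile:
    """Per-breed mean weight and predisposition flags for dogs.

    ``crossbreed`` is derived from the recorded breed text, not from the
    dictionary: any breed string containing "Mischling" is a crossbreed.
    """

    breed_name: str
    mean_weight_kg: float | None
    short_nose: bool = False
    skin_predisposed: bool = False
    entropion_predisposed: bool = False
    crossbreed: bool = False
    known: bool = True

    def __post_init__(self) -> None:
        if self.mean_weight_kg is not None and not self.mean_weight_kg > 0:
            raise ValueError(
                f"breed {self.breed_name!r}: mean_weight_kg must be positive"
            )


#: Default weights when breed information cannot supply one.
DEFAULT_DOG_WEIGHT_KG = 20.0
CAT_WEIGHT_KG = 5.0


def impute_weight(species: Species | str, breed_profile: BreedProfile | None) -> float:
    """Impute the animal weight in kg.

    Cats get a flat 5 kg. Dogs get their breed's mean weight, falling back
    to 20 kg when the breed is missing, unknown, or a crossbreed without a
    recorded mean. Other species are excluded upstream and raise here.
    """
    sp = Species(species)
    if sp is Species.CAT:
        return CAT_WEIGHT_KG
    if sp is Species.DOG:
        if breed_profile is not None and breed_profile.mean_weight_kg is not None:
            return float(breed_profile.mean_weight_kg)
        return DEFAULT_DOG_WEIGHT_KG
    raise ValueError("weight imputation is defined for dogs and cats only")


@dataclass(frozen=True)
class CohortFilter:
    """Eligibility filter applied to built consultations.

    Practices contributing fewer than ``min_patients_per_practice`` distinct
    dog/cat patients are dropped entirely ("less than 100" keeps exactly
    100); consultations outside ``year_range`` (inclusive) or whose species
    is not whitelisted are dropped row-wise.
    """

    min_patients_per_practice: int = 100
    year_range: tuple[int, int] = (2018, 2022)
    species_whitelist: frozenset[str] = frozenset({"dog", "cat"})
    count_patients_within_years: bool = True

    def __post_init__(self) -> None:
        if self.min_patients_per_practice < 1:
            raise ValueError("min_patients_per_practice must be >= 1")
        lo, hi = self.year_range
        if hi < lo:
            raise ValueError("year_range must be non-empty (lo <= hi)")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for a 2x2 exposure x outcome table.

    a = exposed & outcome+, b = exposed & outcome-,
    c = unexposed & outcome+, d = unexposed & outcome-.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            if getattr(self, name) < 0:
                raise ValueError(f"cell {name} must be non-negative")

    @property
    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0

    def swapped_exposure(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(self.c, self.d, self.a, self.b)

    def percent_outcome_exposed(self) -> float:
        return 100.0 * self.a / (self.a + self.b)

    def percent_outcome_unexposed(self) -> float:
        return 100.0 * self.c / (self.c + self.d)


@dataclass(frozen=True)
class ORResult:
    """Odds ratio with Woolf (logit) confidence interval and Wald p-value."""

    or_point: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str = "woolf-logit"

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.or_point <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")


@dataclass(frozen=True)
class SplineModelSpec:
    """Natural-cubic-spline logistic model for treatment prevalence."""

    predictor: str = "weight_kg"
    degrees_of_freedom: int = 4
    outcome: str = "treated"
    spline_basis: str = "natural-cubic"

    def __post_init__(self) -> None:
        if self.degrees_of_freedom < 1:
            raise ValueError("degrees_of_freedom must be >= 1")


@dataclass
class RejectReport:
    """Validation rejects from invoice ingestion: row index, rule, detail."""

    rejects: list[tuple[int, str, str]] = field(default_factory=list)

    def add(self, row: int, rule: str, detail: str = "") -> None:
        self.rejects.append((row, rule, detail))

    @property
    def n(self) -> int:
        return len(self.rejects)

    def rules(self) -> set[str]:
        return {rule for _, rule, _ in self.rejects}
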