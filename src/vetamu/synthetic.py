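"""Synthetic multi-practice invoice-record generator with known ground truth.

Emulates the structure of companion-animal practice-management exports: one
row per billed item (examination, drug, consumable) for one animal on one
date, with free-text anamnesis/diagnosis, across several practices and
calendar years. All clinically meaningful rates are configurable, so every
downstream stage (consultation building, episode labelling, indication
mapping, statistics) can be tested against configured parameters.

The visit process per patient: index consultations at a Poisson rate; each
index consultation is treated with a per-species probability (with a
between-practice random effect); each treated consultation may spawn one
treated follow-up visit 1-7 days later (early offsets dominating), possibly
with a different substance; untreated consultations may spawn an untreated
return visit at a later offset. The index treatment probability is solved
so that the share of *all* consultations that are treated equals the
configured per-species prevalence in expectation.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as vio
from .io import _norm_name as _norm
from .model import INDICATION_CATEGORIES, INVOICE_COLUMNS, Route, SubstanceClass


class ConfigurationError(ValueError):
    """Invalid generator configuration; the message names the field."""


#: Default substance mix over normalized substance names. Aminopenicillins
#: dominate (amoxicillin with and without clavulanic acid are distinct
#: substances); fluoroquinolone + 3rd/4th-gen cephalosporin + macrolide +
#: polymyxin mass is 0.125, the HPCIA share.
DEFAULT_SUBSTANCE_MIX: dict[str, float] = {
    "amoxicillin": 0.373,
    "amoxicillin/clavulanic acid": 0.278,
    "enrofloxacin": 0.050,
    "marbofloxacin": 0.022,
    "pradofloxacin": 0.008,
    "cefovecin": 0.025,
    "tylosin": 0.005,
    "polymyxin b": 0.015,
    "ampicillin": 0.030,
    "benzylpenicillin": 0.020,
    "cefalexin": 0.040,
    "gentamicin": 0.045,
    "neomycin": 0.012,
    "oxytetracycline": 0.008,
    "doxycycline": 0.035,
    "metronidazole": 0.028,
    "clindamycin": 0.006,
}

#: Substance mix for the occasional human-registered product; the local
#: eye/ear preparations carry 95% of the mass.
HUMAN_PRODUCT_MIX: dict[str, float] = {
    "gentamicin": 0.65,
    "ofloxacin": 0.20,
    "oxytetracycline": 0.10,
    "erythromycin": 0.03,
    "cefazolin": 0.02,
}

DEFAULT_INDICATION_MIX: dict[str, float] = {
    "diagnostics/therapy": 0.20,
    "dermatology": 0.13,
    "orthopedics": 0.10,
    "digestive system": 0.12,
    "respiratory system": 0.08,
    "otology": 0.06,
    "ophthalmology": 0.05,
    "urogenital tract": 0.06,
    "emergency": 0.02,
    "trauma": 0.03,
    "intoxication": 0.01,
    "endocrinology": 0.03,
    "routine": 0.04,
    "systemic": 0.03,
    "unclear": 0.02,
    "cardiology": 0.005,
    "neurology": 0.005,
    "dentistry": 0.005,
    "oncology": 0.004,
    "infectious disease": 0.001,
}

#: Filler tokens that never match the packaged lexicon.
NOISE_TOKENS = (
    "patient", "heute", "seit", "tagen", "zeigt", "links", "rechts",
    "besitzer", "allgemeinzustand", "gut", "maessig", "vorstellung",
    "wieder", "leicht", "deutlich", "etwas", "beim", "nach", "ohne",
    "unauffaellig",
)

CAT_BREEDS = ("Europaeisch Kurzhaar", "Maine Coon", "Britisch Kurzhaar", "", "Mischling")

_FOLLOWUP_OFFSETS = np.arange(1, 8)
#: Early returns dominate: decreasing geometric weight over day offsets 1-7.
_FOLLOWUP_WEIGHTS = 0.65 ** (_FOLLOWUP_OFFSETS - 1)
_FOLLOWUP_WEIGHTS = _FOLLOWUP_WEIGHTS / _FOLLOWUP_WEIGHTS.sum()

_UNTREATED_OFFSETS = np.arange(1, 15)
#: Untreated returns skew later than treated follow-ups.
_UNTREATED_WEIGHTS = np.minimum(_UNTREATED_OFFSETS, 7).astype(float)
_UNTREATED_WEIGHTS = _UNTREATED_WEIGHTS / _UNTREATED_WEIGHTS.sum()

_MULTI_SIZES = np.array([2, 3, 4])
_MULTI_SIZE_WEIGHTS = np.array([0.945, 0.052, 0.003])


def _per_species(value, name: str) -> dict[str, float]:
    if isinstance(value, dict):
        out = {"dog": float(value["dog"]), "cat": float(value["cat"])}
    else:
        out = {"dog": float(value), "cat": float(value)}
    for sp, p in out.items():
        if not 0.0 <= p <= 1.0:
            raise ConfigurationError(f"{name}[{sp}] must be in [0, 1], got {p}")
    return out


def _check_prob_vector(vec: dict[str, float], name: str) -> None:
    if not vec:
        raise ConfigurationError(f"{name} must be a non-empty probability vector")
    for k, p in vec.items():
        if not 0.0 <= p <= 1.0:
            raise ConfigurationError(f"{name}[{k!r}] must be in [0, 1], got {p}")
    total = sum(vec.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError(f"{name} must sum to 1 (got {total!r})")


def _check_prob(p: float, name: str) -> None:
    if not 0.0 <= p <= 1.0:
        raise ConfigurationError(f"{name} must be in [0, 1], got {p}")


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic invoice generator.

    Defaults emulate the study conditions the pipeline is meant to
    reproduce: 2018-2022, a dog-majority caseload, per-species treatment
    prevalence of 12.9% (dogs) / 22.5% (cats), an 11.5% multi-substance
    share, per-species follow-up rates of 23.1% / 38.7%, a 13% substance-
    change rate, a 43.3% keyword-bearing text share, and 4.4% of treated
    consultations using a human-registered product.
    """

    n_practices: int = 12
    patients_per_practice: tuple[int, int] = (150, 400)
    species_mix: float = 0.58  # probability a patient is a dog
    years: tuple[int, int] = (2018, 2022)
    consult_rate: float = 1.1  # index consultations per patient-year
    p_treat: dict[str, float] | float = field(
        default_factory=lambda: {"dog": 0.129, "cat": 0.225}
    )
    substance_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBSTANCE_MIX)
    )
    p_multi_substance: float = 0.115
    p_followup: dict[str, float] | float = field(
        default_factory=lambda: {"dog": 0.231, "cat": 0.387}
    )
    p_change: float = 0.13
    indication_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INDICATION_MIX)
    )
    p_indication_text: float = 0.433
    p_human_product: float = 0.044
    p_return_untreated: float = 0.18
    practice_dispersion: float = 0.35  # CV of the practice-level effect
    p_death: float = 0.02
    p_crossbreed: float = 0.24
    p_missing_breed: float = 0.17
    predisposition_effects: dict[str, dict] | None = None
    breed_table_ref: str = "breeds.tsv"
    seed: int = 0

    def validate(self) -> None:
        if self.n_practices < 1:
            raise ConfigurationError("n_practices must be >= 1")
        lo, hi = self.patients_per_practice
        if not (1 <= lo <= hi):
            raise ConfigurationError("patients_per_practice must be 1 <= lo <= hi")
        y0, y1 = self.years
        if y1 < y0:
            raise ConfigurationError("years must be a non-empty inclusive span")
        if not self.consult_rate > 0:
            raise ConfigurationError("consult_rate must be > 0")
        _check_prob(self.species_mix, "species_mix")
        _per_species(self.p_treat, "p_treat")
        _per_species(self.p_followup, "p_followup")
        _check_prob_vector(self.substance_mix, "substance_mix")
        _check_prob_vector(self.indication_mix, "indication_mix")
        unknown = set(self.indication_mix) - set(INDICATION_CATEGORIES)
        if unknown:
            raise ConfigurationError(f"indication_mix has unknown categories: {sorted(unknown)}")
        for name in (
            "p_multi_substance", "p_change", "p_indication_text",
            "p_human_product", "p_return_untreated", "p_death",
            "p_crossbreed", "p_missing_breed",
        ):
            _check_prob(getattr(self, name), name)
        if self.practice_dispersion < 0:
            raise ConfigurationError("practice_dispersion must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("patients_per_practice", "years"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def demo_scenario(**overrides) -> GeneratorConfig:
    """The packaged demo scenario (documentation / CI cohort)."""
    cfg = GeneratorConfig.from_yaml(vio.packaged_data_path("demo_scenario.yaml"))
    for key, value in overrides.items():
        setattr(cfg, key, value)
    cfg.validate()
    return cfg


@dataclass
class GroundTruth:
    """Realized rates of a generated dataset, tallied during generation."""

    n_consultations: int = 0
    n_consultations_by_species: dict[str, int] = field(default_factory=dict)
    treatment_share: dict[str, float] = field(default_factory=dict)
    substance_class_shares: dict[str, float] = field(default_factory=dict)
    hpcia_share: float = float("nan")
    followup_rate: dict[str, float] = field(default_factory=dict)
    change_rate: float = float("nan")
    multi_substance_share: float = float("nan")
    indication_coverage: float = float("nan")
    human_product_share: float = float("nan")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


class _Tally:
    def __init__(self):
        self.consults = {"dog": 0, "cat": 0}
        self.treated = {"dog": 0, "cat": 0}
        self.treated_index = {"dog": 0, "cat": 0}
        self.followups = {"dog": 0, "cat": 0}
        self.eligible_pairs = 0
        self.changes = 0
        self.multi = 0
        self.class_apps: dict[str, int] = {}
        self.human_consults = 0
        self.keyword_texts = 0


def _adjust_probability(p: float, odds_ratio: float) -> float:
    """Apply a multiplicative odds effect to a probability."""
    return odds_ratio * p / (1.0 - p + odds_ratio * p)


class _Generator:
    def __init__(self, config: GeneratorConfig):
        config.validate()
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.drugs = vio.load_drug_dictionary()
        breed_path = None
        if config.breed_table_ref and config.breed_table_ref != "breeds.tsv":
            breed_path = config.breed_table_ref
        self.breeds = vio.load_breed_table(breed_path)
        self.breed_names = sorted(p.breed_name for p in self.breeds.values())
        self.lexicon = vio.load_lexicon()
        self.cat_keywords: dict[str, list[str]] = {}
        for kw, cat in self.lexicon.items():
            self.cat_keywords.setdefault(cat, []).append(kw)
        for kws in self.cat_keywords.values():
            kws.sort()
        self.subst_names = list(config.substance_mix)
        self.subst_probs = np.array([config.substance_mix[s] for s in self.subst_names])
        self.ind_names = list(config.indication_mix)
        self.ind_probs = np.array([config.indication_mix[c] for c in self.ind_names])
        self.human_names = list(HUMAN_PRODUCT_MIX)
        self.human_probs = np.array(list(HUMAN_PRODUCT_MIX.values()))
        self.p_treat = _per_species(config.p_treat, "p_treat")
        self.p_followup = _per_species(config.p_followup, "p_followup")
        self._product_pools()
        missing = [s for s in self.subst_names if s not in self.vet_products]
        if missing:
            raise ConfigurationError(
                f"substance_mix names not in the drug dictionary: {missing}"
            )

    def _product_pools(self) -> None:
        self.vet_products: dict[str, list[str]] = {}
        self.human_local: dict[str, list[str]] = {}
        self.human_other: dict[str, list[str]] = {}
        for rec in self.drugs.values():
            if not rec.is_antibiotic or len(rec.substances) != 1:
                continue
            substance = rec.substances[0]
            if rec.registration.value == "human":
                pool = (
                    self.human_local
                    if rec.route is Route.LOCAL
                    else self.human_other
                )
                pool.setdefault(substance, []).append(rec.product_name)
            else:
                self.vet_products.setdefault(substance, []).append(rec.product_name)
        for pools in (self.vet_products, self.human_local, self.human_other):
            for names in pools.values():
                names.sort()

    # -- sampling helpers ---------------------------------------------------

    def _sample_applications(self) -> list[tuple[str, bool]]:
        """Application rows of one treated consultation as (substance, is_human).

        The number of *distinct* substances is 1, or 2-4 with probability
        p_multi_substance. Every application row is an independent draw
        from the substance mix, so the per-application class distribution
        equals the configured mix; repeated draws of the same substance
        stay as extra rows (the same substance injected during the visit
        and dispensed to the owner). With probability p_human_product the
        first substance is swapped for one from the human-product mix.
        """
        rng = self.rng
        if rng.random() < self.cfg.p_multi_substance:
            k = int(rng.choice(_MULTI_SIZES, p=_MULTI_SIZE_WEIGHTS))
            k = min(k, len(self.subst_names))
        else:
            k = 1
        draws: list[str] = []
        seen: set[str] = set()
        for _ in range(60):
            s = self.subst_names[int(rng.choice(len(self.subst_names), p=self.subst_probs))]
            draws.append(s)
            seen.add(s)
            if len(seen) == k:
                break
        apps = [(s, False) for s in draws]
        if rng.random() < self.cfg.p_human_product:
            human_sub = self.human_names[
                int(rng.choice(len(self.human_names), p=self.human_probs))
            ]
            first = draws[0]
            apps = [(human_sub if s == first else s, s == first) for s in draws]
        return apps

    def _sample_single_substance(self, exclude: str | None = None) -> str:
        while True:
            i = int(self.rng.choice(len(self.subst_names), p=self.subst_probs))
            name = self.subst_names[i]
            if name != exclude:
                return name

    def _sample_category(self, flags: dict[str, bool]) -> str:
        probs = self.ind_probs
        effects = self.cfg.predisposition_effects or {}
        for flag, effect in effects.items():
            if not flags.get(flag):
                continue
            target = effect.get("category")
            orr = float(effect.get("or_indication", 1.0))
            if target in self.ind_names and orr != 1.0:
                probs = probs.copy()
                i = self.ind_names.index(target)
                p_new = _adjust_probability(probs[i], orr)
                scale = (1.0 - p_new) / (1.0 - probs[i])
                probs = probs * scale
                probs[i] = p_new
        i = int(self.rng.choice(len(self.ind_names), p=probs / probs.sum()))
        return self.ind_names[i]

    def _treatment_or(self, flags: dict[str, bool]) -> float:
        orr = 1.0
        for flag, effect in (self.cfg.predisposition_effects or {}).items():
            if flags.get(flag):
                orr *= float(effect.get("or_treatment", 1.0))
        return orr

    def _make_text(self, category: str, tally: _Tally) -> tuple[str, str]:
        rng = self.rng
        if rng.random() < self.cfg.p_indication_text:
            pool = self.cat_keywords.get(category)
            if pool:
                n_kw = int(rng.integers(1, 4))
                kws = [pool[int(i)] for i in rng.integers(0, len(pool), size=n_kw)]
                noise = [
                    NOISE_TOKENS[int(i)]
                    for i in rng.integers(0, len(NOISE_TOKENS), size=int(rng.integers(2, 6)))
                ]
                tokens = noise[:2] + kws + noise[2:]
                anamnesis = " ".join(tokens)
                diagnosis = kws[0] if rng.random() < 0.3 else ""
                tally.keyword_texts += 1
                return anamnesis, diagnosis
        if self.rng.random() < 0.7:
            noise = [
                NOISE_TOKENS[int(i)]
                for i in self.rng.integers(0, len(NOISE_TOKENS), size=int(self.rng.integers(2, 6)))
            ]
            return " ".join(noise), ""
        return "", ""

    def _pick_product(self, substance: str, human: bool) -> tuple[str, bool]:
        """Product name for an application row; returns (name, is_human)."""
        rng = self.rng
        if human:
            local = self.human_local.get(substance, [])
            other = self.human_other.get(substance, [])
            if local and (rng.random() < 0.95 or not other):
                pool = local
            elif other:
                pool = other
            else:
                pool, human = self.vet_products.get(substance, [substance]), False
            return pool[int(rng.integers(0, len(pool)))], human
        pool = self.vet_products.get(substance)
        if not pool:
            return substance, False
        return pool[int(rng.integers(0, len(pool)))], False

    # -- main loop ----------------------------------------------------------

    def run(self) -> tuple[pd.DataFrame, GroundTruth]:
        cfg = self.cfg
        rng = self.rng
        y0, y1 = cfg.years
        start = dt.date(y0, 1, 1)
        end = dt.date(y1, 12, 31)
        n_days = (end - start).days + 1
        n_years = y1 - y0 + 1
        g = cfg.p_return_untreated
        tally = _Tally()
        rows: list[dict] = []

        disp = cfg.practice_dispersion
        shape = 1.0 / disp**2 if disp > 0 else None

        for pr in range(cfg.n_practices):
            practice_id = f"PR{pr:03d}"
            effect = float(rng.gamma(shape, 1.0 / shape)) if shape else 1.0
            lo, hi = cfg.patients_per_practice
            n_patients = int(rng.integers(lo, hi + 1))
            for pt in range(n_patients):
                patient_id = f"{practice_id}-P{pt:05d}"
                species = "dog" if rng.random() < cfg.species_mix else "cat"
                breed = self._sample_breed(species)
                profile = vio.breed_flags(breed, self.breeds)
                flags = {
                    "short_nose": profile.short_nose,
                    "skin_predisposed": profile.skin_predisposed,
                    "entropion_predisposed": profile.entropion_predisposed,
                    "crossbreed": profile.crossbreed,
                }
                sex = ("m", "w", "mk", "wk")[int(rng.integers(0, 4))]
                birth = start - dt.timedelta(days=float(rng.uniform(60, 14 * 365.25)))
                death_day: int | None = None
                if rng.random() < cfg.p_death:
                    death_day = int(rng.integers(0, n_days))

                p_tr = self.p_treat[species] * effect
                p_tr = _adjust_probability(
                    min(p_tr, 0.95), self._treatment_or(flags)
                )
                p_tr = min(p_tr, 0.95)
                f = self.p_followup[species]
                p_star = p_tr * (1 + g) / ((1 + f) * (1 - p_tr) + p_tr * (1 + g))

                n_index = max(1, int(rng.poisson(cfg.consult_rate * n_years)))
                n_index = min(n_index, n_days // 3)
                index_days = sorted(
                    int(d) for d in rng.choice(n_days, size=n_index, replace=False)
                )
                used = set(index_days)
                visits: list[tuple[int, bool, list, str]] = []
                for day in index_days:
                    treated = rng.random() < p_star
                    category = self._sample_category(flags)
                    if treated:
                        apps = self._sample_applications()
                        visits.append((day, True, apps, category))
                        tally.treated_index[species] += 1
                        if rng.random() < f:
                            offset = int(
                                rng.choice(_FOLLOWUP_OFFSETS, p=_FOLLOWUP_WEIGHTS)
                            )
                            fday = day + offset
                            if fday not in used and fday < n_days:
                                used.add(fday)
                                f_apps = self._followup_applications(apps, tally)
                                visits.append((fday, True, f_apps, category))
                                tally.followups[species] += 1
                    else:
                        visits.append((day, False, [], category))
                        if rng.random() < g:
                            offset = int(
                                rng.choice(_UNTREATED_OFFSETS, p=_UNTREATED_WEIGHTS)
                            )
                            rday = day + offset
                            if rday not in used and rday < n_days:
                                used.add(rday)
                                visits.append((rday, False, [], category))

                visits.sort(key=lambda v: v[0])
                if death_day is not None:
                    alive = [v for v in visits if v[0] <= death_day]
                    if alive:
                        visits = alive
                    else:
                        death_day = None
                death_date = (
                    start + dt.timedelta(days=death_day) if death_day is not None else None
                )

                for day, treated, apps, category in visits:
                    self._emit_consultation(
                        rows, tally, practice_id, patient_id, species, breed,
                        sex, birth, death_date, start + dt.timedelta(days=day),
                        treated, apps, category,
                    )

        table = pd.DataFrame(rows, columns=list(INVOICE_COLUMNS))
        for col in ("birth_date", "death_date", "entry_date"):
            table[col] = pd.to_datetime(table[col])
        return table, self._ground_truth(tally)

    def _sample_breed(self, species: str) -> str:
        rng = self.rng
        if species == "cat":
            return CAT_BREEDS[int(rng.integers(0, len(CAT_BREEDS)))]
        r = rng.random()
        if r < self.cfg.p_crossbreed:
            base = self.breed_names[int(rng.integers(0, len(self.breed_names)))]
            return "Mischling" if rng.random() < 0.6 else f"{base}-Mischling"
        if r < self.cfg.p_crossbreed + self.cfg.p_missing_breed:
            return ""
        return self.breed_names[int(rng.integers(0, len(self.breed_names)))]

    def _followup_applications(
        self, index_apps: list[tuple[str, bool]], tally: _Tally
    ) -> list[tuple[str, bool]]:
        """Applications of a spawned follow-up visit.

        Single-substance pairs are the eligible set for the substance-change
        statistic: the follow-up keeps the substance or, with probability
        p_change, switches to a different one.
        """
        apps = self._sample_applications()
        index_distinct = {s for s, _ in index_apps}
        if len(index_distinct) == 1 and len({s for s, _ in apps}) == 1:
            tally.eligible_pairs += 1
            if self.rng.random() < self.cfg.p_change:
                tally.changes += 1
                new = self._sample_single_substance(exclude=next(iter(index_distinct)))
                return [(new, False)]
            return [index_apps[0]]
        return apps

    def _emit_consultation(
        self, rows, tally, practice_id, patient_id, species, breed, sex,
        birth, death_date, date, treated, apps, category,
    ) -> None:
        rng = self.rng
        anamnesis, diagnosis = self._make_text(category, tally)
        base = {
            "practice_id": practice_id,
            "patient_id": patient_id,
            "species": species,
            "breed": breed,
            "sex": sex,
            "birth_date": birth.isoformat(),
            "death_date": death_date.isoformat() if death_date else "",
            "entry_date": date.isoformat(),
            "anamnesis_text": anamnesis,
            "diagnosis_text": diagnosis,
        }
        rows.append(
            base | {"item_name": "Allgemeine Untersuchung", "item_kind": "examination"}
        )
        tally.consults[species] += 1
        if not treated:
            if rng.random() < 0.15:
                rows.append(base | {"item_name": "Verbandsmaterial", "item_kind": "consumable"})
            return

        tally.treated[species] += 1
        if len({s for s, _ in apps}) > 1:
            tally.multi += 1
        if any(h for _, h in apps):
            tally.human_consults += 1
        for substance, is_human in apps:
            product, _ = self._pick_product(substance, human=is_human)
            rec = self.drugs[_norm(product)]
            cls = rec.substance_class.value
            tally.class_apps[cls] = tally.class_apps.get(cls, 0) + 1
            rows.append(base | {"item_name": product, "item_kind": "drug"})

    def _ground_truth(self, tally: _Tally) -> GroundTruth:
        total_consults = sum(tally.consults.values())
        total_treated = sum(tally.treated.values())
        total_apps = sum(tally.class_apps.values())
        hpcia_classes = {
            SubstanceClass.CEPHALOSPORIN_3_4.value,
            SubstanceClass.FLUOROQUINOLONE.value,
            SubstanceClass.MACROLIDE.value,
            SubstanceClass.POLYMYXIN.value,
        }
        gt = GroundTruth(
            n_consultations=total_consults,
            n_consultations_by_species=dict(tally.consults),
            treatment_share={
                sp: tally.treated[sp] / n if n else float("nan")
                for sp, n in tally.consults.items()
            },
            substance_class_shares={
                cls: n / total_apps for cls, n in sorted(tally.class_apps.items())
            }
            if total_apps
            else {},
            hpcia_share=(
                sum(n for c, n in tally.class_apps.items() if c in hpcia_classes)
                / total_apps
                if total_apps
                else float("nan")
            ),
            followup_rate={
                sp: tally.followups[sp] / n if n else float("nan")
                for sp, n in tally.treated_index.items()
            },
            change_rate=(
                tally.changes / tally.eligible_pairs
                if tally.eligible_pairs
                else float("nan")
            ),
            multi_substance_share=(
                tally.multi / total_treated if total_treated else float("nan")
            ),
            indication_coverage=(
                tally.keyword_texts / total_consults if total_consults else float("nan")
            ),
            human_product_share=(
                tally.human_consults / total_treated if total_treated else float("nan")
            ),
        )
        return gt


def generate_invoices(config: GeneratorConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate an invoice table plus the realized ground truth.

    Deterministic: identical config + seed yields a byte-identical table.
    """
    return _Generator(config).run()


def write_dataset(
    table: pd.DataFrame, ground_truth: GroundTruth, csv_path: str | Path
) -> Path:
    """Write the invoice CSV with a ``.truth.json`` ground-truth sidecar."""
    csv_path = Path(csv_path)
    vio.write_fixture(table, csv_path)
    ground_truth.to_json(csv_path.with_suffix(".truth.json"))
    return csv_path


def prevalence_cohort(
    n: int,
    truth,
    predictor: str = "weight_kg",
    value_range: tuple[float, float] = (2.0, 75.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Minimal consultation-like cohort for prevalence-curve testing.

    Draws the predictor uniformly over ``value_range`` and the treated flag
    as Bernoulli(truth(x)); ``truth`` maps predictor values to
    probabilities (vectorized).
    """
    rng = np.random.default_rng(seed)
    x = rng.uniform(value_range[0], value_range[1], size=n)
    p = np.asarray(truth(x), dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("truth() must return probabilities in [0, 1]")
    treated = rng.random(n) < p
    return pd.DataFrame({predictor: x, "treated": treated})


__all__ = [
    "ConfigurationError",
    "GeneratorConfig",
    "GroundTruth",
    "demo_scenario",
    "generate_invoices",
    "prevalence_cohort",
    "write_dataset",
    "DEFAULT_SUBSTANCE_MIX",
    "DEFAULT_INDICATION_MIX",
]
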