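"""Keyword-based indication classification of consultation free text.

Anamnesis and diagnosis text are concatenated, normalized (lower case,
German umlauts folded, punctuation stripped), and scanned for lexicon
keywords; multi-word keywords match as phrases. The category with the most
hits wins; ties fall to a fixed priority order that prefers specific
clinical categories over generic ones. Text with no hit stays unassigned.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .model import INDICATION_CATEGORIES, UNASSIGNED

#: Tie-break order: specific organ-system categories first, generic last.
CATEGORY_PRIORITY: tuple[str, ...] = (
    "respiratory system",
    "otology",
    "ophthalmology",
    "urogenital tract",
    "dermatology",
    "orthopedics",
    "digestive system",
    "cardiology",
    "neurology",
    "dentistry",
    "oncology",
    "endocrinology",
    "infectious disease",
    "emergency",
    "trauma",
    "intoxication",
    "systemic",
    "diagnostics/therapy",
    "routine",
    "unclear",
)

assert set(CATEGORY_PRIORITY) == set(INDICATION_CATEGORIES)

_UMLAUTS = str.maketrans({"ä": "ae", "ö": "oe", "ü": "ue", "ß": "ss"})
_PUNCT = re.compile(r"[^\w\s]", re.UNICODE)
_WS = re.compile(r"\s+")


def normalize_text(text: str) -> str:
    """Lower-case, fold umlauts/ß, strip punctuation, collapse whitespace."""
    t = str(text or "").lower().translate(_UMLAUTS)
    t = _PUNCT.sub(" ", t)
    return _WS.sub(" ", t).strip()


@dataclass(frozen=True)
class CategoryAssignment:
    """Resolved indication for one consultation's free text."""

    category: str
    matched_keywords: tuple[str, ...]
    n_candidate_categories: int


class KeywordMatcher:
    """Compiled matcher over an indication lexicon.

    A single alternation regex with word boundaries scans each text once;
    alternatives are ordered longest-first so multi-word phrases win over
    their component words at the same position.
    """

    def __init__(self, lexicon: dict[str, str]):
        unknown = sorted(set(lexicon.values()) - set(INDICATION_CATEGORIES))
        if unknown:
            raise ValueError(f"lexicon maps to unknown categories: {unknown}")
        self.lexicon = {normalize_text(k): v for k, v in lexicon.items() if k.strip()}
        if self.lexicon:
            alternatives = sorted(self.lexicon, key=len, reverse=True)
            pattern = r"\b(?:" + "|".join(re.escape(k) for k in alternatives) + r")\b"
            self._regex: re.Pattern | None = re.compile(pattern)
        else:
            self._regex = None

    def match(self, *texts: str) -> tuple[Counter, tuple[str, ...]]:
        """Per-category hit counts and matched keywords for concatenated text."""
        if self._regex is None:
            return Counter(), ()
        normalized = " ".join(normalize_text(t) for t in texts if t)
        hits = self._regex.findall(normalized)
        counts = Counter(self.lexicon[h] for h in hits)
        return counts, tuple(hits)

    def assign(self, *texts: str) -> CategoryAssignment:
        counts, hits = self.match(*texts)
        return resolve_category(counts, matched_keywords=hits)


def resolve_category(
    candidates: Counter | dict[str, int],
    matched_keywords: tuple[str, ...] = (),
) -> CategoryAssignment:
    """Pick one category from per-category hit counts.

    Highest count wins; ties break by :data:`CATEGORY_PRIORITY`; no hits
    means unassigned. Deterministic for identical input.
    """
    counts = {c: n for c, n in dict(candidates).items() if n > 0}
    if not counts:
        return CategoryAssignment(UNASSIGNED, tuple(matched_keywords), 0)
    best = max(counts.values())
    tied = [c for c, n in counts.items() if n == best]
    winner = min(tied, key=CATEGORY_PRIORITY.index)
    return CategoryAssignment(winner, tuple(matched_keywords), len(counts))


def assign_indications(
    anamnesis: pd.Series, diagnosis: pd.Series, lexicon: dict[str, str]
) -> pd.DataFrame:
    """Assign a category per row over paired anamnesis/diagnosis text.

    Returns a DataFrame (same index) with columns ``category``,
    ``matched_keywords`` (semicolon-joined), ``n_candidate_categories``.
    """
    matcher = KeywordMatcher(lexicon)
    cats, kws, ncand = [], [], []
    for a, d in zip(anamnesis.fillna(""), diagnosis.fillna("")):
        assignment = matcher.assign(a, d)
        cats.append(assignment.category)
        kws.append(";".join(assignment.matched_keywords))
        ncand.append(assignment.n_candidate_categories)
    return pd.DataFrame(
        {"category": cats, "matched_keywords": kws, "n_candidate_categories": ncand},
        index=anamnesis.index,
    )


def assignment_coverage(categories: pd.Series) -> float:
    """Percent of consultations assigned to any category (not unassigned)."""
    if len(categories) == 0:
        return float("nan")
    return 100.0 * float((categories != UNASSIGNED).mean())
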