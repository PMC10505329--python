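"""Seed food-word dictionary with energy-density classification.

Food terms are normalized multi-word strings (tokens joined by ``_``) carrying
an energy density in kcal/g. Energy density is bucketed two ways:

* the British Nutrition Foundation (BNF) four-level scheme
  (very low < 0.6; low 0.6-1.5; medium 1.5-4; high > 4 kcal/g), and
* a binary collapse at 1.5 kcal/g into low-energy-density (L-ED) and
  high-energy-density (H-ED) classes, the target variable for the
  downstream classifiers.

Seed lexicons are built from food-composition tables (one row per food item
with an energy value) intersected with the vocabulary of a word-embedding
space, since only in-vocabulary terms can participate in clustering and
expansion.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "BNF_VERY_LOW_MAX",
    "BNF_LOW_MAX",
    "BNF_MEDIUM_MAX",
    "KCAL_PER_KJ",
    "UnusableTermError",
    "FoodTerm",
    "Lexicon",
    "normalize_term",
    "classify_bnf",
    "classify_ed",
    "aggregate_synonyms",
    "build_seed_lexicon",
]

logger = logging.getLogger(__name__)

# BNF energy-density cut points, kcal/g.
BNF_VERY_LOW_MAX = 0.6
BNF_LOW_MAX = 1.5
BNF_MEDIUM_MAX = 4.0

#: 1 kcal = 4.184 kJ (thermochemical calorie).
KCAL_PER_KJ = 1.0 / 4.184

BNF_CLASSES = ("very_low", "low", "medium", "high")
ED_CLASSES = ("L_ED", "H_ED")
SOURCES = ("usda", "off", "expanded")

#: Energy units accepted in composition tables.
ENERGY_UNITS = ("kcal_per_100g", "kcal_per_g", "kJ_per_100g")

_SURFACE_RE = re.compile(r"^[a-z0-9]+(?:_[a-z0-9]+)*$")
_NON_WORD_RE = re.compile(r"[^a-z0-9]+")


class UnusableTermError(ValueError):
    """Raised when a raw item name normalizes to the empty string."""


def normalize_term(raw: str) -> str:
    """Normalize a free-text item name to a lexicon surface string.

    Lowercases, folds diacritics to ASCII, strips punctuation and other
    non-word characters, and joins the remaining tokens with ``_``
    (the word2vec phrase convention, e.g. ``sweet_potato_fries``).

    Raises
    ------
    UnusableTermError
        If nothing survives cleaning (the caller should drop the item).
    """
    if not raw or not raw.strip():
        raise UnusableTermError("empty item name")
    folded = unicodedata.normalize("NFKD", raw).encode("ascii", "ignore").decode()
    tokens = [t for t in _NON_WORD_RE.split(folded.lower()) if t]
    if not tokens:
        raise UnusableTermError(f"item name {raw!r} is empty after cleaning")
    return "_".join(tokens)


def _check_ed(ed: float) -> None:
    if ed < 0:
        raise ValueError(f"energy density must be nonnegative, got {ed}")


def classify_bnf(ed: float) -> str:
    """Four-level BNF class for an energy density in kcal/g.

    very_low: ED < 0.6; low: 0.6 <= ED < 1.5; medium: 1.5 <= ED <= 4;
    high: ED > 4.
    """
    _check_ed(ed)
    if ed < BNF_VERY_LOW_MAX:
        return "very_low"
    if ed < BNF_LOW_MAX:
        return "low"
    if ed <= BNF_MEDIUM_MAX:
        return "medium"
    return "high"


def classify_ed(ed: float) -> str:
    """Binary energy-density class: L_ED below 1.5 kcal/g, H_ED at or above."""
    _check_ed(ed)
    return "L_ED" if ed < BNF_LOW_MAX else "H_ED"


@dataclass(frozen=True)
class FoodTerm:
    """A normalized (possibly multi-word) food term with class labels.

    ``surface`` must be lowercase tokens joined by single underscores;
    ``n_words`` is derived and validated against it. When an energy density
    is present both class labels are derived from it and validated.
    """

    surface: str
    n_words: int = 0
    ed_kcal_per_g: float | None = None
    bnf_class: str | None = None
    ed_class: str | None = None
    source: str = "usda"

    def __post_init__(self) -> None:
        if not _SURFACE_RE.match(self.surface):
            raise ValueError(f"malformed surface {self.surface!r}")
        parts = self.surface.count("_") + 1
        if self.n_words == 0:
            object.__setattr__(self, "n_words", parts)
        elif self.n_words != parts:
            raise ValueError(
                f"n_words={self.n_words} but surface {self.surface!r} has {parts} parts"
            )
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if self.ed_kcal_per_g is not None:
            _check_ed(self.ed_kcal_per_g)
            bnf = classify_bnf(self.ed_kcal_per_g)
            ed2 = classify_ed(self.ed_kcal_per_g)
            if self.bnf_class is None:
                object.__setattr__(self, "bnf_class", bnf)
            elif self.bnf_class != bnf:
                raise ValueError(
                    f"bnf_class {self.bnf_class!r} inconsistent with ED "
                    f"{self.ed_kcal_per_g} (expected {bnf!r})"
                )
            if self.ed_class is None:
                object.__setattr__(self, "ed_class", ed2)
            elif self.ed_class != ed2:
                raise ValueError(
                    f"ed_class {self.ed_class!r} inconsistent with ED "
                    f"{self.ed_kcal_per_g} (expected {ed2!r})"
                )


@dataclass
class Lexicon:
    """Mapping of unique surfaces to :class:`FoodTerm` entries."""

    terms: dict[str, FoodTerm] = field(default_factory=dict)

    def add(self, term: FoodTerm) -> None:
        if term.surface in self.terms:
            raise ValueError(f"duplicate surface {term.surface!r}")
        self.terms[term.surface] = term

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, surface: str) -> bool:
        return surface in self.terms

    def __getitem__(self, surface: str) -> FoodTerm:
        return self.terms[surface]

    def __iter__(self):
        return iter(self.terms.values())

    @property
    def surfaces(self) -> set[str]:
        return set(self.terms)

    def counts_by_n_words(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for t in self.terms.values():
            out[t.n_words] = out.get(t.n_words, 0) + 1
        return out

    def counts_by_source(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for t in self.terms.values():
            out[t.source] = out.get(t.source, 0) + 1
        return out

    def max_n_words(self) -> int:
        return max((t.n_words for t in self.terms.values()), default=0)

    def merged_with(self, other: "Lexicon") -> "Lexicon":
        """Union of two lexicons; entries of ``self`` win on collision."""
        out = Lexicon(dict(self.terms))
        for t in other:
            if t.surface not in out:
                out.add(t)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "surface": t.surface,
                "n_words": t.n_words,
                "ed_kcal_per_g": t.ed_kcal_per_g,
                "bnf_class": t.bnf_class,
                "ed_class": t.ed_class,
                "source": t.source,
            }
            for t in sorted(self.terms.values(), key=lambda t: t.surface)
        ]
        return pd.DataFrame(
            rows,
            columns=["surface", "n_words", "ed_kcal_per_g", "bnf_class", "ed_class", "source"],
        )

    def to_tsv(self, path: str | Path) -> None:
        # %.17g keeps the ED values round-trip exact
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Lexicon":
        lex = cls()
        for row in df.itertuples(index=False):
            ed = None if pd.isna(row.ed_kcal_per_g) else float(row.ed_kcal_per_g)
            lex.add(
                FoodTerm(
                    surface=row.surface,
                    ed_kcal_per_g=ed,
                    source=row.source,
                )
            )
        return lex

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Lexicon":
        # round_trip parsing keeps rebuild-from-output bit-identical
        return cls.from_frame(
            pd.read_csv(path, sep="\t", float_precision="round_trip")
        )


def aggregate_synonyms(
    items: Sequence[tuple[str, float]], representative: str
) -> FoodTerm:
    """Collapse synonymous items into one term with the mean energy density.

    Mirrors how composition databases list many near-duplicates (all beer
    brands become one ``beer`` entry); class labels are derived from the
    mean ED, not from any single item.
    """
    if not items:
        raise ValueError("cannot aggregate an empty item list")
    eds = [ed for _, ed in items]
    for ed in eds:
        _check_ed(ed)
    mean_ed = sum(eds) / len(eds)
    return FoodTerm(surface=representative, ed_kcal_per_g=mean_ed)


def _to_kcal_per_g(energy: float, unit: str) -> float:
    if unit == "kcal_per_g":
        return energy
    if unit == "kcal_per_100g":
        return energy / 100.0
    if unit == "kJ_per_100g":
        return energy * KCAL_PER_KJ / 100.0
    raise ValueError(f"unknown energy unit {unit!r}; expected one of {ENERGY_UNITS}")


def build_seed_lexicon(
    composition_rows: pd.DataFrame,
    vocab: Iterable[str] | Mapping[str, object],
    source: str = "usda",
) -> Lexicon:
    """Build a seed lexicon from a composition table and an embedding vocabulary.

    The table needs columns ``name``, ``energy`` and ``unit`` (one of
    ``kcal_per_100g``, ``kcal_per_g``, ``kJ_per_100g``). Rows without an
    energy value are dropped, names are normalized, duplicate surfaces are
    merged via :func:`aggregate_synonyms`, and surfaces absent from ``vocab``
    are discarded — only in-vocabulary terms can be clustered later.
    """
    vocab = set(vocab)
    groups: dict[str, list[tuple[str, float]]] = {}
    n_dropped_ed = n_dropped_name = 0
    for row in composition_rows.itertuples(index=False):
        if pd.isna(row.energy):
            n_dropped_ed += 1
            continue
        try:
            surface = normalize_term(str(row.name))
        except UnusableTermError:
            n_dropped_name += 1
            continue
        ed = _to_kcal_per_g(float(row.energy), str(row.unit))
        groups.setdefault(surface, []).append((str(row.name), ed))
    if n_dropped_ed or n_dropped_name:
        logger.info(
            "dropped %d rows without energy and %d unusable names",
            n_dropped_ed,
            n_dropped_name,
        )
    lex = Lexicon()
    n_oov = 0
    for surface, items in groups.items():
        if surface not in vocab:
            n_oov += 1
            continue
        term = aggregate_synonyms(items, surface)
        lex.add(
            FoodTerm(
                surface=term.surface, ed_kcal_per_g=term.ed_kcal_per_g, source=source
            )
        )
    if n_oov:
        logger.info("dropped %d surfaces absent from the embedding vocabulary", n_oov)
    if not lex:
        logger.warning("seed lexicon is empty after filtering")
    return lex
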