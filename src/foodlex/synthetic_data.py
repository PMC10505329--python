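"""Synthetic embedding spaces, seed lexicons and review corpora with ground truth.

The generator stands in for the ingredients that cannot be redistributed —
a pretrained news-corpus embedding, curated food-composition seeds, and a
review corpus — while preserving the geometry the pipeline exploits:

* food words form isotropic Gaussian clusters whose centers sit on a shell
  around the origin, so cluster members have high cosine similarity to their
  centroid;
* background (non-food) vocabulary lies far beyond the shell in random
  directions, so it is separable both by cosine similarity and by
  Mahalanobis distance;
* each cluster carries one energy-density class, and seed ED values are
  drawn from class-consistent ranges, so planted labels always agree with
  the threshold rules;
* reviews contain planted lexicon-term occurrences embedded in filler text,
  with the exact planted counts returned for oracle comparison.

Word strings are opaque letter-only identifiers ("w" + base-26 letters): no
string feature can leak cluster or class labels into matching or
classification, and every identifier survives the expansion module's
clean-word candidate filter.

What it does not emulate: Zipfian word frequencies, polysemy, anisotropic
cluster shapes, or any real lexical semantics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus_analysis import ReviewRecord
from .embedding import EmbeddingSpace
from .lexicon import FoodTerm, Lexicon, classify_ed

__all__ = [
    "SyntheticSpec",
    "generate_embedding_space",
    "generate_seed_lexicon",
    "generate_review_corpus",
]

logger = logging.getLogger(__name__)

#: ED ranges (kcal/g) that always classify to the intended binary class.
L_ED_RANGE = (0.05, 1.45)
H_ED_RANGE = (1.55, 6.0)


def _word_id(i: int, prefix: str = "w", width: int = 5) -> str:
    """Opaque letter-only identifier: base-26 in a..z, fixed width."""
    chars = []
    for _ in range(width):
        i, r = divmod(i, 26)
        chars.append(chr(ord("a") + r))
    return prefix + "".join(reversed(chars))


@dataclass(frozen=True)
class SyntheticSpec:
    """Geometry and labelling of a planted embedding space.

    Distances are in units of the within-cluster standard deviation σ.
    Cluster centers sit on a shell of radius ``center_radius``·σ with pairwise
    separation at least ``min_separation``·σ; background words lie at radii
    beyond ``background_offset``·σ. The defaults give 8σ-separated food
    clusters with background 20σ+ away — comfortably separable, mirroring
    the regime in which the harvest thresholds were chosen — at a dimension
    (25) where full-covariance mixtures are still cheap to fit.
    """

    n_food_clusters: int = 10
    words_per_cluster: int = 40
    n_background_words: int = 400
    d: int = 25
    center_radius: float = 10.0
    sigma: float = 1.0
    min_separation: float = 8.0
    background_offset: float = 30.0
    ed_classes: "tuple[str, ...]" = ()
    seed: int = 0

    def resolved_ed_classes(self) -> tuple[str, ...]:
        """Per-cluster class labels; default alternates starting from H_ED.

        The alternation keeps both classes well represented so the binary
        classification benchmark is non-degenerate.
        """
        if self.ed_classes:
            if len(self.ed_classes) != self.n_food_clusters:
                raise ValueError("ed_classes length must equal n_food_clusters")
            return tuple(self.ed_classes)
        return tuple(
            "H_ED" if k % 2 == 0 else "L_ED" for k in range(self.n_food_clusters)
        )

    def validate(self) -> None:
        if self.n_food_clusters < 1 or self.words_per_cluster < 1:
            raise ValueError("need at least one cluster with at least one word")
        if self.background_offset <= self.center_radius + 4.0 * self.sigma:
            raise ValueError(
                "background offset must exceed center radius + 4 sigma "
                f"({self.background_offset} <= {self.center_radius + 4 * self.sigma})"
            )
        for c in self.resolved_ed_classes():
            if c not in ("L_ED", "H_ED"):
                raise ValueError(f"unknown ed class {c!r}")


def _place_centers(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Quasi-uniform centers on the shell, rejection-sampled for separation."""
    centers = np.empty((spec.n_food_clusters, spec.d))
    min_sep = spec.min_separation * spec.sigma
    placed = 0
    for _ in range(10_000):
        if placed == spec.n_food_clusters:
            break
        v = rng.standard_normal(spec.d)
        v *= spec.center_radius * spec.sigma / np.linalg.norm(v)
        if placed == 0 or np.min(
            np.linalg.norm(centers[:placed] - v, axis=1)
        ) >= min_sep:
            centers[placed] = v
            placed += 1
    if placed < spec.n_food_clusters:
        raise ValueError(
            "could not place cluster centers at the requested separation; "
            "lower min_separation or raise center_radius/d"
        )
    return centers


def generate_embedding_space(
    spec: SyntheticSpec,
) -> tuple[EmbeddingSpace, dict[str, "int | str"], dict[str, str]]:
    """Planted space plus the ground truth behind it.

    Returns ``(space, cluster_truth, ed_truth)`` where ``cluster_truth`` maps
    each word to its cluster index or ``"background"`` and ``ed_truth`` maps
    each food word to its planted class. Deterministic given the spec.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    centers = _place_centers(spec, rng)
    ed_classes = spec.resolved_ed_classes()

    words: list[str] = []
    vectors: list[np.ndarray] = []
    cluster_truth: dict[str, int | str] = {}
    ed_truth: dict[str, str] = {}
    idx = 0
    for k in range(spec.n_food_clusters):
        for _ in range(spec.words_per_cluster):
            w = _word_id(idx)
            idx += 1
            words.append(w)
            vectors.append(centers[k] + spec.sigma * rng.standard_normal(spec.d))
            cluster_truth[w] = k
            ed_truth[w] = ed_classes[k]
    for _ in range(spec.n_background_words):
        w = _word_id(idx)
        idx += 1
        direction = rng.standard_normal(spec.d)
        direction /= np.linalg.norm(direction)
        radius = spec.sigma * rng.uniform(spec.background_offset, 1.5 * spec.background_offset)
        words.append(w)
        vectors.append(radius * direction + spec.sigma * rng.standard_normal(spec.d))
        cluster_truth[w] = "background"

    space = EmbeddingSpace(words, np.array(vectors))
    return space, cluster_truth, ed_truth


def generate_seed_lexicon(
    cluster_truth: dict[str, "int | str"],
    ed_truth: dict[str, str],
    fraction: float = 0.5,
    seed: int = 0,
) -> tuple[Lexicon, list[str]]:
    """Promote a seeded random fraction of each food cluster to seed terms.

    Seed ED values are drawn uniformly from the class-consistent range
    (L-ED: 0.05–1.45; H-ED: 1.55–6.0 kcal/g) so derived labels always match
    the planted class. The complement of the seeds — the rest of every food
    cluster — is returned as the held-out expansion target.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    by_cluster: dict[int, list[str]] = {}
    for w, c in cluster_truth.items():
        if c != "background":
            by_cluster.setdefault(int(c), []).append(w)
    lex = Lexicon()
    held_out: list[str] = []
    for c in sorted(by_cluster):
        members = sorted(by_cluster[c])
        n_seed = int(round(fraction * len(members)))
        if n_seed == 0:
            logger.warning("fraction %.3f leaves cluster %d without seeds", fraction, c)
        chosen = rng.choice(len(members), size=n_seed, replace=False)
        chosen_set = {members[i] for i in chosen}
        for w in members:
            if w in chosen_set:
                lo, hi = L_ED_RANGE if ed_truth[w] == "L_ED" else H_ED_RANGE
                ed = float(rng.uniform(lo, hi))
                assert classify_ed(ed) == ed_truth[w]
                lex.add(FoodTerm(surface=w, ed_kcal_per_g=ed, source="usda"))
            else:
                held_out.append(w)
    return lex, held_out


def generate_review_corpus(
    lexicon: Lexicon,
    n_outlets: int,
    districts: Sequence[str],
    mean_terms_per_review: float,
    filler_vocab: Sequence[str],
    seed: int = 0,
    reviews_per_outlet: int = 1,
) -> tuple[list[ReviewRecord], pd.DataFrame]:
    """Reviews with planted term occurrences, plus the exact planted counts.

    Each review draws a Poisson(``mean_terms_per_review``) number of term
    occurrences uniformly from the lexicon; multi-word surfaces are spelled
    out as their space-separated tokens. At least one filler word separates
    consecutive planted terms, and filler words sharing a token with any
    lexicon surface are discarded, so greedy matching recovers the planted
    counts exactly. The count table has one row per (outlet, surface).
    """
    if not districts:
        raise ValueError("need at least one district")
    if mean_terms_per_review < 0:
        raise ValueError("mean terms per review must be >= 0")
    lex_tokens = {tok for s in lexicon.surfaces for tok in s.split("_")}
    filler = [w for w in filler_vocab if w not in lex_tokens]
    if not filler:
        raise ValueError("filler vocabulary is empty after removing lexicon tokens")
    surfaces = sorted(lexicon.surfaces)
    rng = np.random.default_rng(seed)
    records: list[ReviewRecord] = []
    counts: dict[tuple[str, str], int] = {}
    for o in range(n_outlets):
        outlet = f"outlet_{o:04d}"
        district = districts[o % len(districts)]
        for _ in range(reviews_per_outlet):
            n_terms = int(rng.poisson(mean_terms_per_review)) if surfaces else 0
            tokens: list[str] = [str(rng.choice(filler))]
            for _ in range(n_terms):
                surface = surfaces[int(rng.integers(len(surfaces)))]
                tokens.extend(surface.split("_"))
                tokens.append(str(rng.choice(filler)))
                counts[(outlet, surface)] = counts.get((outlet, surface), 0) + 1
            records.append(
                ReviewRecord(outlet_id=outlet, district=district, text=" ".join(tokens))
            )
    planted = pd.DataFrame(
        [
            {"outlet_id": o, "surface": s, "count": c}
            for (o, s), c in sorted(counts.items())
        ],
        columns=["outlet_id", "surface", "count"],
    )
    return records, planted
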