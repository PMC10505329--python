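"""Harvest new candidate food words around fitted mixture centroids.

For each component centroid, vocabulary words within a cosine similarity
level ``s`` are retrieved (the cheap pre-filter), then tested for membership
in the component hyperellipses at probability level ``p``. Words passing both
thresholds for at least one component — and not already in the seed
lexicon — form the expansion. Raising either threshold can only shrink the
harvest: fewer words, but more likely to be genuine food terms.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import GaussianMixtureModel, membership_matrix
from .embedding import EmbeddingSpace, cosine_similarity, neighbors_within
from .lexicon import Lexicon

__all__ = ["ExpansionConfig", "ExpansionResult", "expand", "sweep", "evaluate_precision"]

logger = logging.getLogger(__name__)

#: Candidate words must look like clean (multi-)word phrases; pretrained news
#: vocabularies are full of tokens with digits and symbols that are never
#: food terms.
_CLEAN_WORD_RE = re.compile(r"^[A-Za-z]+(?:_[A-Za-z]+)*$")


@dataclass(frozen=True)
class ExpansionConfig:
    """One (similarity level, probability level) harvest setting."""

    similarity_level: float
    probability_level: float
    mode: str = "posterior"
    candidate_cap: int = 100_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.similarity_level <= 1.0:
            raise ValueError(f"similarity level must be in [0,1], got {self.similarity_level}")
        if not 0.0 < self.probability_level < 1.0:
            raise ValueError(
                f"probability level must be in (0,1), got {self.probability_level}"
            )
        if self.mode not in ("posterior", "quantile"):
            raise ValueError(f"unknown membership mode {self.mode!r}")
        if self.candidate_cap < 1:
            raise ValueError("candidate cap must be positive")


@dataclass
class ExpansionResult:
    """Discovered words with provenance.

    ``discovered`` has one row per unique new word: word, component (the
    highest-similarity accepting centroid), similarity to that centroid, and
    the membership value governing acceptance (responsibility in posterior
    mode, squared Mahalanobis distance in quantile mode).
    """

    discovered: pd.DataFrame
    config: ExpansionConfig
    n_candidates: int = 0
    n_seeds_excluded: int = 0

    @property
    def words(self) -> list[str]:
        return list(self.discovered["word"])

    def __len__(self) -> int:
        return len(self.discovered)


def expand(
    lexicon: Lexicon,
    space: EmbeddingSpace,
    model: GaussianMixtureModel,
    config: ExpansionConfig,
) -> ExpansionResult:
    """Discover new candidate food words under one harvest configuration."""
    if model.d != space.d:
        raise ValueError(f"model dimension {model.d} != space dimension {space.d}")
    if len(lexicon) == 0:
        raise ValueError("seed lexicon is empty")
    seeds_lower = {s.lower() for s in lexicon.surfaces}

    # Per-centroid cosine retrieval, keeping the best similarity per word.
    best_sim: dict[str, tuple[float, int]] = {}
    for k in range(model.K):
        hits = neighbors_within(space, model.means[k], config.similarity_level)
        if len(hits) > config.candidate_cap:
            hits = hits[: config.candidate_cap]
        for word, sim in hits:
            if not _CLEAN_WORD_RE.match(word):
                continue
            if word not in best_sim or sim > best_sim[word][0]:
                best_sim[word] = (sim, k)
    n_candidates = len(best_sim)

    candidates = [w for w in best_sim if w.lower() not in seeds_lower]
    n_excluded = n_candidates - len(candidates)

    rows = []
    if candidates:
        X = np.array([space.vector(w) for w in candidates])
        accepted, values = membership_matrix(
            model, X, config.probability_level, config.mode
        )
        for i, word in enumerate(candidates):
            if not accepted[i].any():
                continue
            sim, comp = best_sim[word]
            # report under the highest-similarity accepting component
            if not accepted[i, comp]:
                acc_ks = np.flatnonzero(accepted[i])
                comp = int(
                    max(acc_ks, key=lambda k: cosine_similarity(X[i], model.means[k]))
                )
                sim = cosine_similarity(X[i], model.means[comp])
            rows.append(
                {
                    "word": word,
                    "component": comp,
                    "similarity": sim,
                    "membership": float(values[i, comp]),
                }
            )
    discovered = pd.DataFrame(rows, columns=["word", "component", "similarity", "membership"])
    discovered = discovered.sort_values(
        ["similarity", "word"], ascending=[False, True]
    ).reset_index(drop=True)
    return ExpansionResult(
        discovered=discovered,
        config=config,
        n_candidates=n_candidates,
        n_seeds_excluded=n_excluded,
    )


def sweep(
    lexicon: Lexicon,
    space: EmbeddingSpace,
    model: GaussianMixtureModel,
    configs: "list[ExpansionConfig]",
    truth: "dict[str, bool] | None" = None,
    classifier=None,
) -> pd.DataFrame:
    """Run :func:`expand` per config and tabulate the harvests.

    With ``truth`` (word → is-food) a precision column is added; with a
    fitted binary energy-density ``classifier`` the L-ED/H-ED percentage
    split of each harvest is added.
    """
    if not configs:
        raise ValueError("no configurations to sweep")
    rows = []
    for cfg in configs:
        res = expand(lexicon, space, model, cfg)
        row: dict = {
            "similarity_level": cfg.similarity_level,
            "probability_level": cfg.probability_level,
            "mode": cfg.mode,
            "n_discovered": len(res),
        }
        if truth is not None:
            row["precision"] = evaluate_precision(res, truth=truth)[0]
        if classifier is not None and len(res):
            from .ed_classifier import predict_ed

            labels = predict_ed(classifier, res.words, space)
            vals = np.array(list(labels.values()))
            row["pct_l_ed"] = 100.0 * float(np.mean(vals == 1))
            row["pct_h_ed"] = 100.0 * float(np.mean(vals == 2))
        rows.append(row)
    return pd.DataFrame(rows)


def evaluate_precision(
    result: ExpansionResult,
    truth: "dict[str, bool] | None" = None,
    sample_size: "int | None" = None,
    seed: "int | None" = None,
) -> tuple["float | None", list[str]]:
    """Precision of a harvest, exact or via a seeded annotation sample.

    With ``truth`` the exact fraction of discovered words that are food is
    returned (sampled first if ``sample_size`` is given). Without truth, a
    seeded uniform sample of ``sample_size`` words is returned for human
    annotation and the precision slot is None.
    """
    words = result.words
    if not words:
        raise ValueError("cannot evaluate precision of an empty expansion")
    if sample_size is not None:
        if sample_size > len(words):
            raise ValueError(
                f"sample size {sample_size} exceeds {len(words)} discovered words"
            )
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(words), size=sample_size, replace=False)
        sample = [words[i] for i in sorted(idx)]
    else:
        sample = list(words)
    if truth is None:
        logger.info("exported %d words for annotation", len(sample))
        return None, sample
    precision = float(np.mean([bool(truth.get(w, False)) for w in sample]))
    return precision, sample
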