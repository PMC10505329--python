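"""Match lexicon terms in review text and compare dictionaries per district.

Reviews are tokenized with the same character rules as lexicon normalization
so that a lexicon surface like ``sweet_potato_fries`` matches the token
window ``sweet potato fries``. Matching is greedy longest-first and
non-overlapping: at each position the longest window (up to 4 tokens) that is
a lexicon surface is emitted and the scan jumps past it, so sub-terms of a
dish name are not double-counted. Occurrences (tokens), not distinct types,
are counted.

Two dictionaries (original seeds vs. expanded) are compared per district by

* the percent-increase statistic 100·(E − O)/(O + E) — the difference over
  the combined total, the form under which the reference district and
  word-length figures reproduce (the conventional 100·(E − O)/O is also
  provided), and
* Welch's unequal-variance two-sample t-test on per-outlet match counts,
  with Welch–Satterthwaite fractional degrees of freedom.
"""

from __future__ import annotations

import json
import logging
import re
import unicodedata
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .lexicon import Lexicon

__all__ = [
    "ReviewRecord",
    "TTestResult",
    "tokenize",
    "match_terms",
    "count_matches",
    "percent_increase",
    "percent_increase_conventional",
    "welch_t_test",
    "district_report",
    "n_words_report",
    "load_reviews",
]

logger = logging.getLogger(__name__)

_TOKEN_SPLIT_RE = re.compile(r"[^a-z0-9]+")


@dataclass(frozen=True)
class ReviewRecord:
    """One review of one food outlet."""

    outlet_id: str
    district: str
    text: str
    lon: float | None = None
    lat: float | None = None

    def __post_init__(self) -> None:
        if not self.outlet_id:
            raise ValueError("outlet_id must be non-empty")


@dataclass(frozen=True)
class TTestResult:
    """Welch two-sample t statistic with fractional df and two-sided p."""

    df: float
    t: float
    p: float


def tokenize(text: str) -> list[str]:
    """Lowercase tokens with diacritics folded and punctuation stripped.

    Applies the same character rules as lexicon normalization (hyphens split
    tokens apart) so surfaces and token windows line up.
    """
    folded = unicodedata.normalize("NFKD", text).encode("ascii", "ignore").decode()
    return [t for t in _TOKEN_SPLIT_RE.split(folded.lower()) if t]


def match_terms(
    tokens: list[str],
    lexicon: Lexicon,
    max_n: int = 4,
    *,
    overlapping: bool = False,
) -> list[tuple[str, int]]:
    """Lexicon surfaces found in a token sequence, with start positions.

    Greedy longest-match-first, left-to-right, non-overlapping by default.
    With ``overlapping=True`` every window of every length is counted (a
    sensitivity mode; sub-terms of matched dish names then count too).
    """
    if max_n < 1:
        raise ValueError("max_n must be >= 1")
    surfaces = lexicon.surfaces
    out: list[tuple[str, int]] = []
    n = len(tokens)
    if overlapping:
        for i in range(n):
            for width in range(1, max_n + 1):
                if i + width > n:
                    break
                cand = "_".join(tokens[i : i + width])
                if cand in surfaces:
                    out.append((cand, i))
        return out
    i = 0
    while i < n:
        for width in range(min(max_n, n - i), 0, -1):
            cand = "_".join(tokens[i : i + width])
            if cand in surfaces:
                out.append((cand, i))
                i += width
                break
        else:
            i += 1
    return out


def count_matches(
    reviews: "list[ReviewRecord]",
    lexicon: Lexicon,
    max_n: int = 4,
    *,
    overlapping: bool = False,
) -> pd.DataFrame:
    """Per-outlet match counts: total, by term length, by ED class.

    Returns one row per outlet with its district, ``total`` matches, columns
    ``n{1..max_n}_words`` and ``l_ed``/``h_ed``/``unlabelled`` splits.
    """
    per_outlet: dict[str, dict] = {}
    for rev in reviews:
        row = per_outlet.setdefault(
            rev.outlet_id,
            {
                "outlet_id": rev.outlet_id,
                "district": rev.district,
                "total": 0,
                **{f"n{i}_words": 0 for i in range(1, max_n + 1)},
                "l_ed": 0,
                "h_ed": 0,
                "unlabelled": 0,
            },
        )
        for surface, _pos in match_terms(
            tokenize(rev.text), lexicon, max_n, overlapping=overlapping
        ):
            term = lexicon[surface]
            row["total"] += 1
            row[f"n{term.n_words}_words"] += 1
            if term.ed_class == "L_ED":
                row["l_ed"] += 1
            elif term.ed_class == "H_ED":
                row["h_ed"] += 1
            else:
                row["unlabelled"] += 1
    return pd.DataFrame(per_outlet.values()).reset_index(drop=True)


def percent_increase(original: float, expanded: float) -> float:
    """Percent increase as the difference over the combined total.

    100·(E − O)/(O + E); undefined when both counts are zero.
    """
    if original + expanded == 0:
        raise ValueError("percent increase undefined when both counts are zero")
    return 100.0 * (expanded - original) / (original + expanded)


def percent_increase_conventional(original: float, expanded: float) -> float:
    """Conventional percent change 100·(E − O)/O (undefined at O = 0)."""
    if original == 0:
        raise ValueError("conventional percent change undefined at original = 0")
    return 100.0 * (expanded - original) / original


def welch_t_test(a, b) -> TTestResult:
    """Welch's unequal-variance two-sample t-test (two-sided).

    The fractional degrees of freedom follow Welch–Satterthwaite.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            # identical constant samples: no difference by construction
            return TTestResult(df=float(len(a) + len(b) - 2), t=0.0, p=1.0)
        raise ValueError("both samples have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return TTestResult(df=float(res.df), t=float(res.statistic), p=float(res.pvalue))


def district_report(
    reviews: "list[ReviewRecord]",
    lexicon_old: Lexicon,
    lexicon_new: Lexicon,
    max_n: int = 4,
) -> pd.DataFrame:
    """Per-district comparison of the two dictionaries.

    One row per district: outlet count, total matches under each lexicon,
    both percent-increase statistics, and the Welch test on per-outlet
    counts (omitted with a note for districts with fewer than 2 outlets).
    """
    old = count_matches(reviews, lexicon_old, max_n).set_index("outlet_id")
    new = count_matches(reviews, lexicon_new, max_n).set_index("outlet_id")
    rows = []
    for district in sorted(old["district"].unique()):
        o = old[old["district"] == district]["total"]
        e = new[new["district"] == district]["total"]
        row: dict = {
            "district": district,
            "n_outlets": len(o),
            "original_total": int(o.sum()),
            "expanded_total": int(e.sum()),
        }
        both = int(o.sum() + e.sum())
        row["pct_increase"] = (
            percent_increase(o.sum(), e.sum()) if both else np.nan
        )
        row["pct_increase_conventional"] = (
            percent_increase_conventional(o.sum(), e.sum()) if o.sum() else np.nan
        )
        if len(o) >= 2:
            try:
                tt = welch_t_test(o.to_numpy(), e.to_numpy())
                row.update({"t": tt.t, "df": tt.df, "p": tt.p, "note": ""})
            except ValueError as exc:
                row.update({"t": np.nan, "df": np.nan, "p": np.nan, "note": str(exc)})
        else:
            row.update(
                {"t": np.nan, "df": np.nan, "p": np.nan, "note": "fewer than 2 outlets"}
            )
        rows.append(row)
    return pd.DataFrame(rows)


def n_words_report(
    reviews: "list[ReviewRecord]",
    lexicon_old: Lexicon,
    lexicon_new: Lexicon,
    max_n: int = 4,
) -> pd.DataFrame:
    """Corpus-wide comparison by term length (1..max_n words).

    One row per length: totals under each lexicon, percent increases, and
    the Welch test on per-outlet counts of that length.
    """
    old = count_matches(reviews, lexicon_old, max_n).set_index("outlet_id").sort_index()
    new = count_matches(reviews, lexicon_new, max_n).set_index("outlet_id").sort_index()
    rows = []
    for width in range(1, max_n + 1):
        col = f"n{width}_words"
        o, e = old[col], new[col]
        total = int(o.sum() + e.sum())
        row = {
            "n_words": width,
            "original_total": int(o.sum()),
            "expanded_total": int(e.sum()),
            "pct_increase": percent_increase(o.sum(), e.sum()) if total else np.nan,
        }
        try:
            tt = welch_t_test(o.to_numpy(), e.to_numpy())
            row.update({"t": tt.t, "df": tt.df, "p": tt.p})
        except ValueError:
            row.update({"t": np.nan, "df": np.nan, "p": np.nan})
        rows.append(row)
    return pd.DataFrame(rows)


def load_reviews(path: str | Path) -> list[ReviewRecord]:
    """Read reviews from CSV or JSONL (fields outlet_id, district, text[, lon, lat])."""
    path = Path(path)
    records: list[ReviewRecord] = []
    if path.suffix.lower() == ".jsonl":
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                obj = json.loads(line)
                records.append(
                    ReviewRecord(
                        outlet_id=str(obj["outlet_id"]),
                        district=str(obj["district"]),
                        text=str(obj.get("text", "")),
                        lon=obj.get("lon"),
                        lat=obj.get("lat"),
                    )
                )
    else:
        df = pd.read_csv(path)
        for row in df.itertuples(index=False):
            records.append(
                ReviewRecord(
                    outlet_id=str(row.outlet_id),
                    district=str(row.district),
                    text="" if pd.isna(row.text) else str(row.text),
                    lon=getattr(row, "lon", None),
                    lat=getattr(row, "lat", None),
                )
            )
    return records
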