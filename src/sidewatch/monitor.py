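"""Twelve-month surveillance analytics over classified post streams.

Aggregate-level analyses only: daily per-class time series, first-name
gender inference and pattern-based age extraction for coarse demographic
profiles, category summary tables, and Spearman rank correlation between
the daily rate of suicidal-ideation posts and a daily mortality series.
No per-account flagging or alerting is implemented, by design.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from datetime import date, datetime, timedelta, timezone
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import CLASS_LABELS, ClassLabel, Post

NameLexicon = Mapping[str, str]  # name -> {male, female, unisex}


@dataclass
class ClassTimeSeries:
    """Per-day per-class counts over a contiguous date range."""

    frame: pd.DataFrame  # index: dates, columns: class codes, values: counts
    n_excluded: int = 0

    @property
    def start(self) -> date:
        return self.frame.index[0].date()

    def day_counts(self, class_code: str) -> pd.Series:
        return self.frame[class_code]

    def to_tidy_csv(self, path) -> None:
        tidy = self.frame.reset_index(names="date").melt(
            id_vars="date", var_name="class", value_name="count"
        )
        tidy.to_csv(path, index=False)


def build_time_series(
    classified: Sequence[Tuple[Post, "ClassLabel | str"]],
    start: date,
    end: date,
) -> ClassTimeSeries:
    """Count classified posts per UTC day and class, zero-filling empty days.

    Posts outside ``[start, end]`` (or without timestamps) are excluded and
    counted in ``n_excluded``.
    """
    if start > end:
        raise ValueError("start must be on or before end")
    index = pd.date_range(start, end, freq="D")
    codes = [l.code for l in CLASS_LABELS]
    frame = pd.DataFrame(0, index=index, columns=codes)
    excluded = 0
    for post, label in classified:
        code = label.code if isinstance(label, ClassLabel) else str(label)
        ts = post.timestamp
        if ts is None:
            excluded += 1
            continue
        day = ts.astimezone(timezone.utc).date()
        if day < start or day > end:
            excluded += 1
            continue
        frame.loc[pd.Timestamp(day), code] += 1
    return ClassTimeSeries(frame, n_excluded=excluded)


def infer_gender(profile_name: Optional[str], lexicon: NameLexicon) -> str:
    """Infer a coarse gender category from a profile's first name token.

    The first whitespace-delimited token is matched by containment against
    the name lexicon (the token must be a substring of a lexicon name); the
    gender category with the greatest count among matches wins, ties map to
    ``"unisex"``.  Tokens shorter than 3 characters over-match wildly under
    containment and are sent to ``"unknown"``, as are empty or unmatched
    tokens.
    """
    if not profile_name or not profile_name.strip():
        return "unknown"
    token = profile_name.strip().split()[0].lower()
    token = re.sub(r"[^a-z'\-]", "", token)
    if len(token) < 3:
        return "unknown"
    tally = {"male": 0, "female": 0, "unisex": 0}
    for name, gender in lexicon.items():
        if token in name:
            tally[gender] += 1
    if not any(tally.values()):
        return "unknown"
    best = max(tally.values())
    winners = [g for g, c in tally.items() if c == best]
    return winners[0] if len(winners) == 1 else "unisex"


_AGE_PATTERNS = (
    # 1. "I am/I'm X years old"
    re.compile(r"\bi\s*(?:am|'m|m)\s+(\d{2})\s+years?\s+old\b", re.IGNORECASE),
    # 2. "born in X" with X a year or a date
    re.compile(
        r"\bborn\s+(?:in|on)\s+(?:(?P<day>\d{1,2})[/\-\. ])?(?:(?P<month>\d{1,2})[/\-\. ])?(?P<year>(?:19|20)\d{2})\b",
        re.IGNORECASE,
    ),
    # 3. bare "X years old"
    re.compile(r"\b(\d{2})\s+years?\s+old\b", re.IGNORECASE),
)


def extract_age(
    text: str,
    reference_date: date,
    filters: Optional[Sequence[str]] = None,
) -> Optional[int]:
    """Extract a stated age from free text, if any.

    Applies three patterns in order — "I am X years old", "born in X", and
    bare "X years old" — with X either a two-digit number or a year/date
    from which the age is computed against ``reference_date``.  A candidate
    match is discarded when a false-positive filter pattern (e.g. "years
    ago", "felt ... years old") matches a window around it; the first
    surviving match wins.  Ages must lie in [0, 99].
    """
    if filters is None:
        from .resources import default_age_filters

        filters = default_age_filters()
    filter_res = [re.compile(p, re.IGNORECASE) for p in filters]

    def filtered(match: "re.Match[str]") -> bool:
        window = text[max(0, match.start() - 25): match.end() + 25]
        return any(fr.search(window) for fr in filter_res)

    for i, pattern in enumerate(_AGE_PATTERNS):
        for match in pattern.finditer(text):
            if filtered(match):
                continue
            if i == 1:
                year = int(match.group("year"))
                age = reference_date.year - year
                month = match.group("month")
                day = match.group("day")
                if month is not None:
                    m = int(month)
                    d = int(day) if day is not None else 1
                    if 1 <= m <= 12 and 1 <= d <= 31:
                        if (reference_date.month, reference_date.day) < (m, d):
                            age -= 1
            else:
                age = int(match.group(1))
            if 0 <= age < 100:
                return age
    return None


AGE_BANDS = ("13-20", "21-30", "31-40", "41-50", "51-60", "60+")


def age_band(age: int) -> Optional[str]:
    """Band an age per the reporting scheme; under-13 reported separately."""
    if age < 13:
        return "under-13"
    for lo, hi, name in (
        (13, 20, "13-20"), (21, 30, "21-30"), (31, 40, "31-40"),
        (41, 50, "41-50"), (51, 60, "51-60"),
    ):
        if lo <= age <= hi:
            return name
    return "60+"


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    ok: bool = True
    reason: str = ""


def correlate_mortality(
    tweets: pd.Series,
    deaths: pd.Series,
    window: str = "24h",
    lag_days: Optional[int] = None,
) -> CorrelationResult:
    """Spearman rank correlation between daily post and death counts.

    ``"24h"`` pairs deaths(d) with tweets(d); ``"48h"`` pairs deaths(d)
    with tweets(d) + tweets(d+1), i.e. the posts in the 48 hours following
    the start of day d.  ``lag_days`` (signed) shifts the tweet series as
    an alternative alignment.  Uses mid-rank ties and a two-sided p-value.
    Constant input yields an undefined coefficient, flagged via ``ok``.
    """
    tweets = pd.Series(tweets).astype(float)
    deaths = pd.Series(deaths).astype(float)
    tweets.index = pd.to_datetime(tweets.index)
    deaths.index = pd.to_datetime(deaths.index)
    if window == "24h":
        paired = tweets
    elif window == "48h":
        paired = tweets + tweets.shift(-1)
    else:
        raise ValueError(f"unknown window: {window!r}")
    if lag_days:
        paired = paired.shift(lag_days)
    joined = pd.concat({"tweets": paired, "deaths": deaths}, axis=1).dropna()
    if len(joined) < 5:
        raise ValueError("overlapping date range must cover at least 5 days")
    if joined["tweets"].nunique() < 2 or joined["deaths"].nunique() < 2:
        return CorrelationResult(float("nan"), float("nan"), len(joined), ok=False,
                                 reason="constant series: rho undefined")
    rho, p = stats.spearmanr(joined["tweets"], joined["deaths"])
    return CorrelationResult(float(rho), float(p), len(joined))


@dataclass
class CategorySummaryRow:
    class_code: str
    description: str
    count: int
    percent: float
    mean_daily_rate: int
    std_daily: float


def summarise_from_counts(
    counts: Mapping[str, int],
    n_days: int = 365,
    daily_std: Optional[Mapping[str, float]] = None,
) -> List[CategorySummaryRow]:
    """Category summary table from per-class totals.

    percent is 100 x count/total; the mean daily rate is count/n_days
    rounded to the nearest integer.  Standard deviations over the daily
    series are filled in when a daily breakdown is available.
    """
    if n_days <= 0:
        raise ValueError("n_days must be positive")
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("no classified posts")
    rows = []
    for label in CLASS_LABELS:
        c = int(counts.get(label.code, 0))
        rows.append(
            CategorySummaryRow(
                class_code=label.code,
                description=label.description,
                count=c,
                percent=100.0 * c / total,
                mean_daily_rate=int(round(c / n_days)),
                std_daily=float(daily_std.get(label.code, float("nan"))) if daily_std else float("nan"),
            )
        )
    return rows


def summarise_categories(
    classified: Sequence[Tuple[Post, "ClassLabel | str"]],
    n_days: int = 365,
    start: Optional[date] = None,
) -> List[CategorySummaryRow]:
    """Category summary (count, percent, mean daily rate, sd) from posts."""
    if n_days <= 0:
        raise ValueError("n_days must be positive")
    counts: Dict[str, int] = {}
    for _, label in classified:
        code = label.code if isinstance(label, ClassLabel) else str(label)
        counts[code] = counts.get(code, 0) + 1
    daily_std: Dict[str, float] = {}
    timestamps = [p.timestamp for p, _ in classified if p.timestamp is not None]
    if timestamps:
        first = start or min(ts.date() for ts in timestamps)
        series = build_time_series(
            [(p, l) for p, l in classified if p.timestamp is not None],
            first,
            first + timedelta(days=n_days - 1),
        )
        for code in series.frame.columns:
            daily_std[code] = float(series.frame[code].std(ddof=0))
    return summarise_from_counts(counts, n_days=n_days, daily_std=daily_std or None)
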