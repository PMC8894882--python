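"""Cohort ETL: raw patient/episode tables -> diagnosis event stream.

Implements the cleaning rules of the analysis: ICD-10 codes are rounded
to their 3-character category, non-disease chapters (XV-XXII: obstetric,
perinatal, congenital, symptoms, injury, external causes, administrative)
are dropped, and each patient's diagnoses are split into pre- and
post-index (SMI) condition sets with the new-condition ratio

    |N2 \\ N1| / |N1 U N2|

where N1 are conditions seen strictly before the first SMI date and N2
those seen on or after it.  Events dated exactly on the first SMI date
count as post-index (the index diagnosis itself occurs that day).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_EXCLUDED_CHAPTERS",
    "ConditionSplit",
    "normalize_code",
    "chapter_of",
    "build_event_stream",
    "resolve_first_smi",
    "split_conditions",
    "split_cohort",
    "new_per_year",
    "splits_to_frame",
]

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25

_CODE3_RE = re.compile(r"^[A-Z][0-9][0-9]$")

# (first code, last code, chapter) — gapless over valid letters
_CHAPTER_RANGES: list[tuple[str, str, str]] = [
    ("A00", "B99", "I"),
    ("C00", "D48", "II"),
    ("D49", "D89", "III"),
    ("E00", "E99", "IV"),
    ("F00", "F99", "V"),
    ("G00", "G99", "VI"),
    ("H00", "H59", "VII"),
    ("H60", "H99", "VIII"),
    ("I00", "I99", "IX"),
    ("J00", "J99", "X"),
    ("K00", "K99", "XI"),
    ("L00", "L99", "XII"),
    ("M00", "M99", "XIII"),
    ("N00", "N99", "XIV"),
    ("O00", "O99", "XV"),
    ("P00", "P99", "XVI"),
    ("Q00", "Q99", "XVII"),
    ("R00", "R99", "XVIII"),
    ("S00", "T99", "XIX"),
    ("V00", "Y99", "XX"),
    ("Z00", "Z99", "XXI"),
    ("U00", "U99", "XXII"),
]

#: non-disease chapters excluded from network construction
DEFAULT_EXCLUDED_CHAPTERS = frozenset(
    {"XV", "XVI", "XVII", "XVIII", "XIX", "XX", "XXI", "XXII"}
)


def normalize_code(raw: str) -> str | None:
    """Round an ICD-10 code to its 3-character category.

    Returns the uppercase 3-character category, or None when the first
    three characters do not match letter-digit-digit (rejection is a
    value, not an error; callers log the rejects).
    """
    if not isinstance(raw, str):
        return None
    code3 = raw.strip().upper().replace(".", "")[:3]
    return code3 if _CODE3_RE.match(code3) else None


def chapter_of(code3: str) -> str:
    """Map a 3-character category to its ICD-10 chapter label (I..XXII)."""
    if not (isinstance(code3, str) and _CODE3_RE.match(code3)):
        raise ValueError(f"invalid 3-character ICD-10 category: {code3!r}")
    for lo, hi, chapter in _CHAPTER_RANGES:
        if lo <= code3 <= hi:
            return chapter
    raise ValueError(f"no chapter covers {code3!r}")  # pragma: no cover


def build_event_stream(
    episodes: pd.DataFrame,
    patients: pd.DataFrame,
    exclude_chapters: frozenset[str] = DEFAULT_EXCLUDED_CHAPTERS,
    exclude_mental: bool = False,
    window_years: float | None = None,
    delimiter: str = ";",
) -> pd.DataFrame:
    """Explode episodes into one row per (episode, retained diagnosis).

    Each event carries the admission date as its timestamp, the position
    of the code in the episode's ordered diagnosis list, and the signed
    offset in years from the patient's first SMI date.  Codes failing
    3-character normalization are dropped (logged); duplicate codes
    within one episode collapse to the smallest rank; optional filters
    drop excluded chapters, all F-prefixed (mental) codes, or events
    outside +-window_years of the index date.
    """
    known = set(patients["patient_id"])
    orphans = sorted(set(episodes["patient_id"]) - known)
    if orphans:
        raise ValueError(f"episodes reference unknown patient_ids: {orphans[:10]}")

    smi_date = patients.set_index("patient_id")["first_smi_date"]

    columns = ["patient_id", "code3", "timestamp", "episode_id",
               "within_episode_rank", "years_to_smi", "chapter"]
    if episodes.empty:
        return pd.DataFrame(columns=columns)

    codes = episodes["diagnoses"].fillna("").str.split(delimiter)
    long = episodes.loc[
        episodes.index.repeat(codes.str.len()),
        ["episode_id", "patient_id", "admission_date"],
    ].copy()
    long["raw"] = np.concatenate([np.asarray(c, dtype=object) for c in codes])
    long["within_episode_rank"] = np.concatenate(
        [np.arange(len(c)) for c in codes]
    )
    long["code3"] = long["raw"].map(normalize_code)
    n_rejected = long["code3"].isna().sum()
    if n_rejected:
        logger.info("rejected %d diagnosis codes failing the 3-character pattern",
                    n_rejected)
    long = long.dropna(subset=["code3"])

    long["chapter"] = long["code3"].map(chapter_of)
    if exclude_chapters:
        long = long[~long["chapter"].isin(exclude_chapters)]
    if exclude_mental:
        long = long[~long["code3"].str.startswith("F")]

    # within-episode duplicates collapse to the smallest rank
    long = long.sort_values("within_episode_rank", kind="stable")
    long = long.drop_duplicates(subset=["episode_id", "code3"], keep="first")

    long = long.rename(columns={"admission_date": "timestamp"})
    long["years_to_smi"] = (
        long["timestamp"] - long["patient_id"].map(smi_date)
    ).dt.days / DAYS_PER_YEAR
    if window_years is not None:
        long = long[long["years_to_smi"].abs() <= window_years]

    long = long.sort_values(
        ["timestamp", "episode_id", "within_episode_rank"], kind="stable"
    ).reset_index(drop=True)
    return long[columns]


def resolve_first_smi(
    mentions: list[tuple[str, "pd.Timestamp | str", str]],
) -> tuple[str, pd.Timestamp]:
    """Resolve a patient's index diagnosis across record sources.

    ``mentions`` holds (code, date, source) triples with code in
    {F20, F31} and source "MH" (mental-health register) or "HOSP"
    (hospital admissions).  The earliest date wins; date ties prefer the
    mental-health source, then the lexicographically smaller code.
    """
    valid = [
        (pd.Timestamp(d), 0 if src == "MH" else 1, c)
        for c, d, src in mentions
        if c in ("F20", "F31")
    ]
    if not valid:
        raise ValueError("no SMI mention (F20/F31): patient not in cohort")
    date, _, code = min(valid)
    return code, date


@dataclass
class ConditionSplit:
    """Per-patient pre/post-index condition sets and the new-condition ratio."""

    patient_id: str
    pre_existing: set[str]
    post_set: set[str]
    new_conditions: set[str] = field(init=False)
    re_occurring: set[str] = field(init=False)
    new_ratio: float = field(init=False)
    first_appearance_years: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.new_conditions = self.post_set - self.pre_existing
        self.re_occurring = self.pre_existing & self.post_set
        union = self.pre_existing | self.post_set
        self.new_ratio = len(self.new_conditions) / len(union) if union else math.nan


def split_conditions(
    events: pd.DataFrame, first_smi_code: str, first_smi_date: pd.Timestamp
) -> ConditionSplit:
    """Split one patient's events into pre/post condition sets.

    Events strictly before the index date feed N1, on/after feed N2; all
    events carrying the patient's own index code are excluded from both.
    A patient with no remaining conditions gets new_ratio = NaN and is
    later dropped from network construction.
    """
    if events.empty:
        return ConditionSplit(patient_id="", pre_existing=set(), post_set=set())
    pid = events["patient_id"].iloc[0]
    ev = events[events["code3"] != first_smi_code]
    pre_mask = ev["timestamp"] < first_smi_date
    n1 = set(ev.loc[pre_mask, "code3"])
    post = ev[~pre_mask]
    n2 = set(post["code3"])
    split = ConditionSplit(patient_id=pid, pre_existing=n1, post_set=n2)
    for code in split.new_conditions:
        first = post.loc[post["code3"] == code, "timestamp"].min()
        split.first_appearance_years[code] = (
            first - first_smi_date
        ).days / DAYS_PER_YEAR
    return split


def split_cohort(events: pd.DataFrame, patients: pd.DataFrame) -> list[ConditionSplit]:
    """split_conditions for every patient with >=1 retained event."""
    meta = patients.set_index("patient_id")[["first_smi_code", "first_smi_date"]]
    out = []
    for pid, group in events.groupby("patient_id", sort=True):
        code, date = meta.loc[pid, "first_smi_code"], meta.loc[pid, "first_smi_date"]
        out.append(split_conditions(group, code, date))
    return out


def new_per_year(
    split: ConditionSplit,
    first_smi_date: pd.Timestamp,
    death_date: "pd.Timestamp | None",
    censor_date: pd.Timestamp,
) -> dict[str, float]:
    """Average number of new conditions per post-index year.

    The denominator runs from the index date to death if the patient
    died, otherwise to the censor date; mental = F-prefixed new
    conditions, physical = the rest.
    """
    if pd.Timestamp(censor_date) <= pd.Timestamp(first_smi_date):
        raise ValueError("censor_date must be after first_smi_date")
    end = death_date if death_date is not None and pd.notna(death_date) else censor_date
    end = pd.Timestamp(end)
    if end < pd.Timestamp(first_smi_date):
        raise ValueError("death_date precedes first_smi_date")
    years = (end - pd.Timestamp(first_smi_date)).days / DAYS_PER_YEAR
    mental = {c for c in split.new_conditions if c.startswith("F")}
    return {
        "overall": len(split.new_conditions) / years,
        "mental": len(mental) / years,
        "physical": (len(split.new_conditions) - len(mental)) / years,
    }


def splits_to_frame(splits: list[ConditionSplit]) -> pd.DataFrame:
    """Tidy per-patient table of split sizes and the new-condition ratio."""
    return pd.DataFrame(
        {
            "patient_id": [s.patient_id for s in splits],
            "n_pre_existing": [len(s.pre_existing) for s in splits],
            "n_post": [len(s.post_set) for s in splits],
            "n_new": [len(s.new_conditions) for s in splits],
            "n_re_occurring": [len(s.re_occurring) for s in splits],
            "new_ratio": [s.new_ratio for s in splits],
        }
    )
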