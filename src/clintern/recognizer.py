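"""Rule/dictionary recognition of temporal phrases as fine-grained entities.

The recognizer is the front end of the pipeline: it scans note text with a
set of rule families and emits :class:`ScateEntity` records — explicit
dates/times, 2-place dates (``01/10``), quantity+unit periods (``2 days
ago``), bare calendar intervals (``a week``), clinical frequency
abbreviations (``b.i.d.``), worded frequencies (``daily``, ``x4``) and
temporal adverbs.  Entities are non-overlapping; longest match wins, ties
broken by earliest start then rule priority.

Relative cue words ("ago", "prior", "past", "next", "later") adjacent to a
quantity+unit core are folded into the entity span so that lenient-overlap
evaluation and downstream disambiguation both see them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path

__all__ = [
    "EntityKind", "Unit", "ScateEntity", "AbbreviationLexicon",
    "RecognizerConfig", "recognize", "match_two_place_date",
    "match_abbreviations", "filter_adverbs",
    "MONTH_NAMES", "WEEKDAY_NAMES", "default_config",
]


class EntityKind(str, Enum):
    ExplicitDate = "ExplicitDate"
    ExplicitTime = "ExplicitTime"
    TwoPlaceDate = "TwoPlaceDate"
    Period = "Period"
    CalendarInterval = "CalendarInterval"
    Frequency = "Frequency"
    TemporalAdverb = "TemporalAdverb"


class Unit(str, Enum):
    minute = "minute"
    hour = "hour"
    day = "day"
    week = "week"
    month = "month"
    year = "year"


# rule priority for overlap ties (higher wins)
_PRIORITY = {
    EntityKind.ExplicitDate: 6,
    EntityKind.ExplicitTime: 5,
    EntityKind.TwoPlaceDate: 4,
    EntityKind.Period: 3,
    EntityKind.CalendarInterval: 3,
    EntityKind.Frequency: 2,
    EntityKind.TemporalAdverb: 1,
}


@dataclass(frozen=True)
class ScateEntity:
    start: int
    end: int
    text: str
    kind: EntityKind
    quantity: float | None = None
    unit: Unit | None = None
    approx_word: str | None = None
    expansion: str | None = None
    norm_value: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"entity span ({self.start},{self.end}) is empty")
        if self.quantity is not None and self.quantity <= 0:
            raise ValueError(f"entity quantity {self.quantity} must be > 0")
        if self.kind in (EntityKind.Period, EntityKind.CalendarInterval) and self.unit is None:
            raise ValueError(f"{self.kind.value} entity must carry a unit")

    def overlaps(self, other: "ScateEntity") -> bool:
        return self.start < other.end and other.start < self.end


# ---------------------------------------------------------------------------
# Lexicons

def _normalize_key(surface: str) -> str:
    """Case/period-insensitive abbreviation key ('B.I.D.' and 'bid' collide)."""
    return surface.lower().replace(".", "").strip(",;:!?")


@dataclass
class AbbreviationLexicon:
    """Map normalized abbreviation → (kind, expansion, normalized value)."""

    entries: dict[str, tuple[EntityKind, str, str]] = field(default_factory=dict)

    def add(self, surface: str, kind: EntityKind, expansion: str, value: str = "") -> None:
        key = _normalize_key(surface)
        if key in self.entries:
            raise ValueError(f"duplicate abbreviation key {key!r}")
        self.entries[key] = (kind, expansion, value)

    def lookup(self, surface: str):
        return self.entries.get(_normalize_key(surface))

    @classmethod
    def from_file(cls, path: str | Path) -> "AbbreviationLexicon":
        lex = cls()
        for line in Path(path).read_text().splitlines():
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            surface, kind = parts[0], EntityKind(parts[1])
            expansion = parts[2] if len(parts) > 2 else ""
            value = parts[3] if len(parts) > 3 else ""
            lex.add(surface, kind, expansion, value)
        return lex


def _load_lines(name: str) -> list[str]:
    data = resources.files("clintern").joinpath("data", name).read_text()
    return [ln.strip() for ln in data.splitlines() if ln.strip() and not ln.startswith("#")]


def default_abbreviations() -> AbbreviationLexicon:
    lex = AbbreviationLexicon()
    data = resources.files("clintern").joinpath("data", "abbreviations.tsv").read_text()
    for line in data.splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        lex.add(parts[0], EntityKind(parts[1]),
                parts[2] if len(parts) > 2 else "",
                parts[3] if len(parts) > 3 else "")
    return lex


def default_adverbs() -> frozenset[str]:
    return frozenset(w.lower() for w in _load_lines("adverbs.txt"))


@dataclass
class RecognizerConfig:
    abbreviations: AbbreviationLexicon = field(default_factory=default_abbreviations)
    adverbs: frozenset[str] = field(default_factory=default_adverbs)
    drop_adverbs: bool = False


def default_config() -> RecognizerConfig:
    return RecognizerConfig()


# ---------------------------------------------------------------------------
# Vocabulary

MONTH_NAMES = [
    "january", "february", "march", "april", "may", "june", "july",
    "august", "september", "october", "november", "december",
]
WEEKDAY_NAMES = [
    "monday", "tuesday", "wednesday", "thursday", "friday", "saturday", "sunday",
]

WORDED_NUMBERS = {
    "one": 1, "two": 2, "three": 3, "four": 4, "five": 5,
    "six": 6, "seven": 7, "eight": 8, "nine": 9, "ten": 10,
}
APPROX_WORDS = ("couple", "few", "several", "many")

_UNIT_WORDS = {
    "minute": Unit.minute, "minutes": Unit.minute, "min": Unit.minute,
    "hour": Unit.hour, "hours": Unit.hour, "hr": Unit.hour, "hrs": Unit.hour,
    "day": Unit.day, "days": Unit.day, "d": Unit.day,
    "week": Unit.week, "weeks": Unit.week, "wk": Unit.week, "wks": Unit.week,
    "month": Unit.month, "months": Unit.month, "mo": Unit.month, "mos": Unit.month,
    "year": Unit.year, "years": Unit.year, "yr": Unit.year, "yrs": Unit.year,
}

_MONTH_ALT = "|".join(m[:3] + r"(?:" + m[3:] + r")?" if len(m) > 3 else m
                      for m in MONTH_NAMES)
_WEEKDAY_ALT = "|".join(WEEKDAY_NAMES)
_UNIT_ALT = "|".join(sorted(_UNIT_WORDS, key=len, reverse=True))
_NUM_ALT = "|".join(WORDED_NUMBERS)
_APPROX_ALT = "|".join(APPROX_WORDS)

# Explicit dates: ISO, slash-with-year, "Month D, YYYY", "Month D", bare
# month/weekday names (explicit per the relative-filter criteria).
_RE_ISO_DATE = re.compile(r"\b\d{4}-\d{2}-\d{2}\b")
_RE_SLASH_DATE = re.compile(r"\b\d{1,2}/\d{1,2}/\d{2,4}\b")
_RE_MONTH_DATE = re.compile(
    rf"\b(?:{_MONTH_ALT})\.?\s+\d{{1,2}}(?:st|nd|rd|th)?(?:,?\s+\d{{4}})?\b"
    rf"|\b(?:{_MONTH_ALT})\.?,?\s+\d{{4}}\b"
    rf"|\b(?:{_MONTH_ALT})\b"
    rf"|\b(?:{_WEEKDAY_ALT})\b",
    re.IGNORECASE,
)
_RE_TWO_PLACE = re.compile(r"\b\d{1,2}/\d{1,2}\b")
_RE_TIME = re.compile(
    r"\b\d{1,2}:\d{2}(?::\d{2})?(?:\s?[ap]\.?m\.?)?"
    r"|\b\d{1,2}\s?[ap]\.?m\.?",
    re.IGNORECASE,
)

_CUE_BEFORE = r"(?:over\s+the\s+|in\s+the\s+|the\s+|within\s+the\s+)?(?:past|last|next|previous|first)\s+"
_CUE_AFTER = r"\s+(?:ago|later|prior|earlier|before|after)"
_RE_PERIOD = re.compile(
    rf"\b(?:{_CUE_BEFORE})?"
    rf"(\d+|{_NUM_ALT}|a\s+couple(?:\s+of)?|couple(?:\s+of)?|{_APPROX_ALT}|an?|the)"
    rf"\s+({_UNIT_ALT})\b"
    rf"(?:{_CUE_AFTER})?",
    re.IGNORECASE,
)

# postoperative / hospital / life day counters — Period-like with unit=day
_RE_COUNTED_DAY = re.compile(
    rf"\b(?:pod\s?#?\s?(\d+)"
    rf"|(?:post-?op(?:erative)?\s+day|hospital\s+day|day\s+of\s+life)\s?#?\s?(\d+|{_NUM_ALT}))\b",
    re.IGNORECASE,
)

_RE_FREQ = re.compile(
    rf"\b(?:daily|nightly|weekly|monthly|hourly"
    rf"|(?:once|twice|(?:\d+|{_NUM_ALT})\s+times)\s+(?:a|per|each)\s+(?:{_UNIT_ALT})"
    rf"|q\s?\d+\s?h)\b"
    r"|[x×]\s?\d+\b"
    r"|\b\d+\s?[x×](?=\s|$|[.,;])",
    re.IGNORECASE,
)

_FREQ_WORD_VALUES = {
    "daily": "RP1D", "nightly": "RP1D", "weekly": "RP1W",
    "monthly": "RP1M", "hourly": "RPT1H",
}


# ---------------------------------------------------------------------------
# Token-level matchers

def match_two_place_date(token: str) -> tuple[int, int] | None:
    """``d{1,2}/d{1,2}`` with calendar bounds → (month, day), else None."""
    m = re.fullmatch(r"(\d{1,2})/(\d{1,2})", token.strip(",.;:!?"))
    if not m:
        return None
    month, day = int(m.group(1)), int(m.group(2))
    if 1 <= month <= 12 and 1 <= day <= 31:
        return month, day
    return None


def match_abbreviations(
    tokens: list[tuple[int, int, str]],
    lexicon: AbbreviationLexicon,
) -> list[ScateEntity]:
    """Match whitespace tokens against the abbreviation lexicon.

    Matching is case-insensitive and tolerant of period variants ("bid",
    "b.i.d.") and trailing punctuation.  ``POD#n`` tokens yield Period
    entities with quantity ``n`` and unit day.
    """
    out: list[ScateEntity] = []
    for start, end, surface in tokens:
        trimmed = surface.rstrip(",;:!?")
        pod = re.fullmatch(r"(?i)pod#?(\d+)", trimmed)
        if pod:
            out.append(ScateEntity(
                start=start, end=start + len(trimmed), text=trimmed,
                kind=EntityKind.Period, quantity=int(pod.group(1)),
                unit=Unit.day, expansion=f"postoperative day {pod.group(1)}",
            ))
            continue
        hit = lexicon.lookup(trimmed)
        if hit is None:
            # a lexicon entry like "b.i.d." may keep its final period while
            # the sentence tokenizer leaves it attached; retry without it
            if trimmed.endswith("."):
                hit = lexicon.lookup(trimmed[:-1])
            if hit is None:
                continue
        kind, expansion, value = hit
        out.append(ScateEntity(
            start=start, end=start + len(trimmed), text=trimmed,
            kind=kind, expansion=expansion or None, norm_value=value or None,
        ))
    return out


def filter_adverbs(
    entities: list[ScateEntity],
    adverb_lexicon: frozenset[str],
    drop: bool,
) -> list[ScateEntity]:
    """Drop TemporalAdverb entities whose text is in the lexicon (if drop)."""
    if not drop:
        return list(entities)
    return [
        e for e in entities
        if not (e.kind is EntityKind.TemporalAdverb
                and e.text.lower().strip(",.;:!?") in adverb_lexicon)
    ]


# ---------------------------------------------------------------------------
# Full-text recognition

def _quantity_from(word: str) -> tuple[float | None, str | None]:
    """(quantity, approx_word) for a matched quantity word."""
    w = word.lower()
    if w.isdigit():
        return float(int(w)), None
    if w in WORDED_NUMBERS:
        return float(WORDED_NUMBERS[w]), None
    if w.startswith("a couple") or w.startswith("couple"):
        return None, "couple"
    if w in APPROX_WORDS:
        return None, w
    if w in ("a", "an", "the"):
        return 1.0, None
    return None, None


def _period_candidates(text: str) -> list[ScateEntity]:
    out = []
    for m in _RE_PERIOD.finditer(text):
        quantity, approx = _quantity_from(m.group(1))
        unit = _UNIT_WORDS[m.group(2).lower()]
        bare_article = m.group(1).lower() in ("a", "an", "the")
        kind = EntityKind.CalendarInterval if bare_article else EntityKind.Period
        out.append(ScateEntity(
            start=m.start(), end=m.end(), text=m.group(0), kind=kind,
            quantity=quantity, unit=unit, approx_word=approx,
        ))
    for m in _RE_COUNTED_DAY.finditer(text):
        raw = m.group(1) or m.group(2)
        qty = float(int(raw)) if raw.isdigit() else float(WORDED_NUMBERS[raw.lower()])
        out.append(ScateEntity(
            start=m.start(), end=m.end(), text=m.group(0),
            kind=EntityKind.Period, quantity=qty, unit=Unit.day,
            expansion=m.group(0),
        ))
    return out


def _freq_candidates(text: str, lexicon: AbbreviationLexicon) -> list[ScateEntity]:
    out = []
    for m in _RE_FREQ.finditer(text):
        surface = m.group(0)
        low = surface.lower()
        value = _FREQ_WORD_VALUES.get(low)
        qh = re.fullmatch(r"q\s?(\d+)\s?h", low)
        if qh:
            value = f"RPT{qh.group(1)}H"
        out.append(ScateEntity(
            start=m.start(), end=m.end(), text=surface,
            kind=EntityKind.Frequency, norm_value=value,
        ))
    # lexicon abbreviations over whitespace tokens
    tokens = [(t.start(), t.end(), t.group(0)) for t in re.finditer(r"\S+", text)]
    out.extend(match_abbreviations(tokens, lexicon))
    return out


def _adverb_candidates(text: str, adverbs: frozenset[str]) -> list[ScateEntity]:
    out = []
    for m in re.finditer(r"[A-Za-z]+", text):
        if m.group(0).lower() in adverbs:
            out.append(ScateEntity(
                start=m.start(), end=m.end(), text=m.group(0),
                kind=EntityKind.TemporalAdverb,
            ))
    return out


def _resolve_overlaps(candidates: list[ScateEntity]) -> list[ScateEntity]:
    """Longest match wins; ties by earliest start, then rule priority."""
    ranked = sorted(
        candidates,
        key=lambda e: (-(e.end - e.start), e.start, -_PRIORITY[e.kind]),
    )
    kept: list[ScateEntity] = []
    for cand in ranked:
        if not any(cand.overlaps(k) for k in kept):
            kept.append(cand)
    return sorted(kept, key=lambda e: e.start)


def recognize(text: str, config: RecognizerConfig | None = None) -> list[ScateEntity]:
    """Recognize temporal phrases in raw text as non-overlapping entities."""
    cfg = config or default_config()
    candidates: list[ScateEntity] = []

    for regex, kind in (
        (_RE_ISO_DATE, EntityKind.ExplicitDate),
        (_RE_SLASH_DATE, EntityKind.ExplicitDate),
        (_RE_MONTH_DATE, EntityKind.ExplicitDate),
        (_RE_TIME, EntityKind.ExplicitTime),
    ):
        for m in regex.finditer(text):
            candidates.append(ScateEntity(
                start=m.start(), end=m.end(), text=m.group(0), kind=kind,
            ))
    for m in _RE_TWO_PLACE.finditer(text):
        if match_two_place_date(m.group(0)):
            candidates.append(ScateEntity(
                start=m.start(), end=m.end(), text=m.group(0),
                kind=EntityKind.TwoPlaceDate,
            ))
    candidates.extend(_period_candidates(text))
    candidates.extend(_freq_candidates(text, cfg.abbreviations))
    candidates.extend(_adverb_candidates(text, cfg.adverbs))

    entities = _resolve_overlaps(candidates)
    entities = filter_adverbs(entities, cfg.adverbs, cfg.drop_adverbs)
    # span/text consistency is structural; assert it cheaply here
    for e in entities:
        assert text[e.start:e.end] == e.text
    return entities
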