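"""Conversion of fine-grained entities to TimeML TIMEX3 annotations.

Explicit dates/times are normalized to ISO-8601 with ``dateutil``;
quantity+unit periods become ISO-8601 durations (``P2D`` for "2 days");
approximate quantity words ("several days") resolve through a configurable
quantity table and carry an APPROX modifier.  Period and Calendar-Interval
entities are the ambiguous class: without a disambiguation model attached
they fall to the naive rule (always DURATION); with a model attached the
predicted type wins, and relative DATE outputs keep an empty value because
anchoring a relative date on the calendar is outside this toolkit's scope.
"""

from __future__ import annotations

import datetime as _dt
import logging
import re
from dataclasses import dataclass, field
from typing import Protocol

from dateutil import parser as _dateparser

from clintern.corpus_io import Document, TimexAnnotation, TimexType
from clintern.recognizer import EntityKind, ScateEntity, Unit

__all__ = [
    "ApproxTable", "ConversionConfig", "NormalizationError",
    "iso_duration", "approximate_quantity", "normalize_explicit_date",
    "scate_to_timeml", "convert_entities",
]

log = logging.getLogger(__name__)


class NormalizationError(ValueError):
    pass


class TypePredictor(Protocol):
    """Anything that maps a phrase feature vector to 'DATE' or 'DURATION'."""

    def predict_label(self, feature) -> str: ...


DEFAULT_APPROX = {"couple": 2, "few": 3, "several": 3, "many": 7}


@dataclass
class ApproxTable:
    """Word → integer quantity for approximate temporal phrases."""

    table: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_APPROX))

    def __post_init__(self) -> None:
        self.table = {k.lower(): v for k, v in self.table.items()}
        if any(v < 1 for v in self.table.values()):
            raise ValueError("approximate quantities must be >= 1")

    def __contains__(self, word: str) -> bool:
        return word.lower() in self.table

    def __getitem__(self, word: str) -> int:
        return self.table[word.lower()]


@dataclass
class ConversionConfig:
    approx_table: ApproxTable = field(default_factory=ApproxTable)
    ttd_model: TypePredictor | None = None
    day_first: bool = False          # slash dates read month-first by default
    year_fill_window_days: int = 183  # ±6 months around admission


# ---------------------------------------------------------------------------

_UNIT_ISO = {
    Unit.year: ("P", "Y"), Unit.month: ("P", "M"), Unit.week: ("P", "W"),
    Unit.day: ("P", "D"), Unit.hour: ("PT", "H"), Unit.minute: ("PT", "M"),
}


def iso_duration(quantity: float, unit: Unit) -> str:
    """ISO-8601 duration: P-prefix for date units, PT for time units."""
    if quantity <= 0:
        raise NormalizationError(f"duration quantity must be > 0, got {quantity}")
    prefix, letter = _UNIT_ISO[Unit(unit)]
    n = int(quantity) if float(quantity).is_integer() else quantity
    return f"{prefix}{n}{letter}"


def approximate_quantity(word: str, table: ApproxTable) -> tuple[int, str]:
    """Resolve an approximate quantity word; returns (quantity, 'APPROX')."""
    if word not in table:
        raise NormalizationError(f"no approximate quantity for {word!r}")
    return table[word], "APPROX"


def _fill_two_place_year(month: int, day: int, doc: Document,
                         window_days: int) -> int | None:
    """Pick a year for a month/day pair from the document reference dates.

    Admission year wins when the resulting date falls within the window of
    admission; otherwise the candidate year (admission/discharge, ±1) whose
    date lies nearest either reference is chosen.
    """
    adm, dis = doc.admission_date, doc.discharge_date
    if adm is None and dis is None:
        return None
    anchor = adm or dis

    def mk(year: int) -> _dt.date | None:
        try:
            return _dt.date(year, month, day)
        except ValueError:
            return None

    if adm is not None:
        cand = mk(adm.year)
        if cand is not None and abs((cand - adm).days) <= window_days:
            return adm.year

    years = set()
    for ref in (adm, dis):
        if ref is not None:
            years.update({ref.year - 1, ref.year, ref.year + 1})

    def distance(year: int) -> int:
        cand = mk(year)
        if cand is None:
            return 10**9
        ds = [abs((cand - ref).days) for ref in (adm, dis) if ref is not None]
        return min(ds)

    best = min(sorted(years), key=distance)
    return best if mk(best) is not None else anchor.year


def normalize_explicit_date(entity: ScateEntity, doc: Document,
                            cfg: ConversionConfig | None = None) -> str:
    """ISO-8601 normalization of explicit date/time and 2-place-date phrases.

    2-place dates have no year; it is filled from the document reference
    dates.  Raises :class:`NormalizationError` when the phrase cannot be
    parsed (callers emit the annotation with an empty value).
    """
    cfg = cfg or ConversionConfig()
    text = entity.text.strip()

    if entity.kind is EntityKind.TwoPlaceDate:
        m = re.fullmatch(r"(\d{1,2})/(\d{1,2})", text)
        if not m:
            raise NormalizationError(f"not a 2-place date: {text!r}")
        month, day = int(m.group(1)), int(m.group(2))
        if cfg.day_first:
            month, day = day, month
        year = _fill_two_place_year(month, day, doc, cfg.year_fill_window_days)
        if year is None:
            raise NormalizationError(
                f"no reference date to fill the year of {text!r}")
        return f"{year:04d}-{month:02d}-{day:02d}"

    if entity.kind is EntityKind.ExplicitTime:
        default = _dt.datetime.combine(
            doc.admission_date or _dt.date(1900, 1, 1), _dt.time(0, 0))
        try:
            parsed = _dateparser.parse(text, dayfirst=cfg.day_first, default=default)
        except (ValueError, OverflowError) as exc:
            raise NormalizationError(f"unparseable time {text!r}") from exc
        if doc.admission_date is None:
            raise NormalizationError(
                f"no reference date to anchor the time {text!r}")
        return parsed.strftime("%Y-%m-%dT%H:%M")

    try:
        parsed = _dateparser.parse(
            text, dayfirst=cfg.day_first,
            default=_dt.datetime(1900, 1, 1),
        )
    except (ValueError, OverflowError) as exc:
        raise NormalizationError(f"unparseable date {text!r}") from exc
    # a bare month/weekday name has no resolvable calendar position here
    if not re.search(r"\d", text):
        raise NormalizationError(f"date phrase {text!r} has no numeric anchor")
    if re.search(r"\b\d{4}\b", text) or parsed.year != 1900:
        if not re.search(r"[/\-]\d{1,2}[/\-]|,?\s+\d{4}|\d{4}-", text):
            # "January 3" style without a year: fill like 2-place dates
            year = _fill_two_place_year(parsed.month, parsed.day, doc,
                                        cfg.year_fill_window_days)
            if year is None:
                raise NormalizationError(
                    f"no reference date to fill the year of {text!r}")
            return f"{year:04d}-{parsed.month:02d}-{parsed.day:02d}"
        return parsed.strftime("%Y-%m-%d")
    year = _fill_two_place_year(parsed.month, parsed.day, doc,
                                cfg.year_fill_window_days)
    if year is None:
        raise NormalizationError(f"no reference date for {text!r}")
    return f"{year:04d}-{parsed.month:02d}-{parsed.day:02d}"


# ---------------------------------------------------------------------------

def _duration_value(entity: ScateEntity, cfg: ConversionConfig) -> tuple[str, str]:
    """(ISO value, modifier) for a DURATION-typed output."""
    if entity.quantity is not None and entity.unit is not None:
        return iso_duration(entity.quantity, entity.unit), "NA"
    if entity.approx_word is not None and entity.unit is not None:
        qty, mod = approximate_quantity(entity.approx_word, cfg.approx_table)
        return iso_duration(qty, entity.unit), mod
    return "", "NA"


def scate_to_timeml(
    entity: ScateEntity,
    doc: Document,
    cfg: ConversionConfig | None = None,
    feature=None,
    ann_id: str = "t0",
) -> TimexAnnotation:
    """Convert one entity to a TIMEX3 annotation.

    Period/Calendar-Interval entities are routed through the disambiguation
    model when one is attached (the caller supplies the phrase feature);
    otherwise the naive rule types them DURATION.
    """
    cfg = cfg or ConversionConfig()
    kind = entity.kind
    value, modifier = "", "NA"

    if kind in (EntityKind.ExplicitDate, EntityKind.TwoPlaceDate):
        ttype = TimexType.DATE
        try:
            value = normalize_explicit_date(entity, doc, cfg)
        except NormalizationError as exc:
            log.debug("normalization failed for %r: %s", entity.text, exc)
    elif kind is EntityKind.ExplicitTime:
        ttype = TimexType.TIME
        try:
            value = normalize_explicit_date(entity, doc, cfg)
        except NormalizationError as exc:
            log.debug("normalization failed for %r: %s", entity.text, exc)
    elif kind is EntityKind.Frequency:
        ttype = TimexType.FREQUENCY
        value = entity.norm_value or ""
    elif kind in (EntityKind.Period, EntityKind.CalendarInterval):
        if cfg.ttd_model is not None:
            if feature is None:
                raise ValueError(
                    "a phrase feature is required to route "
                    f"{kind.value} entities through the attached model")
            predicted = cfg.ttd_model.predict_label(feature)
            ttype = TimexType(predicted)
        else:
            ttype = TimexType.DURATION  # naive rule
        if ttype is TimexType.DURATION:
            value, modifier = _duration_value(entity, cfg)
        # relative DATE: value stays empty (anchor resolution out of scope)
    else:  # TemporalAdverb — typed DATE with no value when not dropped
        ttype = TimexType.DATE

    ann = TimexAnnotation(
        ann_id=ann_id, start=entity.start, end=entity.end, text=entity.text,
        ttype=ttype, value=value, modifier=modifier,
    )
    log.debug("converted %s %r -> %s %r", kind.value, entity.text,
              ann.ttype.value, ann.value)
    return ann


def convert_entities(
    entities: list[ScateEntity],
    doc: Document,
    cfg: ConversionConfig | None = None,
    features: dict[int, object] | None = None,
) -> list[TimexAnnotation]:
    """Convert a recognizer output list; conversion is total per entity.

    ``features`` maps entity index → PhraseFeature for the ambiguous
    entities when a disambiguation model is attached.
    """
    cfg = cfg or ConversionConfig()
    out: list[TimexAnnotation] = []
    for i, ent in enumerate(entities):
        feat = (features or {}).get(i)
        try:
            out.append(scate_to_timeml(ent, doc, cfg, feature=feat,
                                       ann_id=f"t{i}"))
        except (NormalizationError, ValueError) as exc:
            log.warning("entity %r dropped: %s", ent.text, exc)
    return out
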