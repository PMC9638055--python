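"""Corpus filtering for the disambiguation study.

Two gold-standard filters and one system-output restriction:

* DD filter — keep only DATE and DURATION annotations (drop TIME and
  FREQUENCY); this is the training corpus for the disambiguator.
* RelIV filter — from a DD-filtered corpus, remove every explicit or
  incomplete expression: digit-bearing date forms (full or partial, e.g.
  ``2/4/2013``, ``5/6``), clock times (``9 a.m.``), proper month or weekday
  names, and holiday names.  What remains is the relative/implicit/vague
  evaluation set.
* gold-overlap restriction — keep only system annotations that overlap a
  RelIV gold span, so systems that split a gold phrase into several
  annotations are still compared fairly (all fragments are retained).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from clintern.corpus_io import Document, TimexAnnotation, TimexType
from clintern.recognizer import MONTH_NAMES, WEEKDAY_NAMES, _load_lines

__all__ = ["RelIVLexicons", "filter_dd", "is_explicit", "filter_reliv",
           "restrict_to_gold_overlap"]


def _default_holidays() -> tuple[str, ...]:
    return tuple(_load_lines("holidays.txt"))


@dataclass(frozen=True)
class RelIVLexicons:
    months: tuple[str, ...] = tuple(MONTH_NAMES)
    weekdays: tuple[str, ...] = tuple(WEEKDAY_NAMES)
    holidays: tuple[str, ...] = field(default_factory=_default_holidays)

    def __post_init__(self) -> None:
        if not (self.months and self.weekdays and self.holidays):
            raise ValueError("RelIV lexicons must be non-empty")


# Digit-bearing date forms: digits around a date separator (slash or dash),
# with or without a year.  A phrase like "2 weeks prior" has digits attached
# to a unit word, not a date separator, so it is NOT explicit.
_RE_DIGIT_DATE = re.compile(r"\d{1,4}[/\-]\d{1,2}([/\-]\d{1,4})?")
_RE_CLOCK = re.compile(r"\b\d{1,2}:\d{2}\b|\b\d{1,2}\s?[ap]\.?m\.?", re.IGNORECASE)


def is_explicit(annotation: TimexAnnotation,
                lexicons: RelIVLexicons | None = None) -> bool:
    """True iff the phrase is an explicit/incomplete expression to remove."""
    lex = lexicons or RelIVLexicons()
    text = annotation.text.lower()
    if _RE_DIGIT_DATE.search(text) or _RE_CLOCK.search(text):
        return True
    words = set(re.findall(r"[a-z']+", text))
    if words & set(lex.months) or words & set(lex.weekdays):
        return True
    return any(h in text for h in lex.holidays)


def filter_dd(corpus: list[Document]) -> list[Document]:
    """Keep DATE and DURATION annotations only; documents are retained."""
    keep = (TimexType.DATE, TimexType.DURATION)
    return [
        doc.replace_annotations([a for a in doc.annotations if a.ttype in keep])
        for doc in corpus
    ]


def filter_reliv(dd_corpus: list[Document],
                 lexicons: RelIVLexicons | None = None) -> list[Document]:
    """Remove explicit/incomplete annotations from a DD-filtered corpus."""
    lex = lexicons or RelIVLexicons()
    return [
        doc.replace_annotations(
            [a for a in doc.annotations if not is_explicit(a, lex)])
        for doc in dd_corpus
    ]


def restrict_to_gold_overlap(
    system_annotations: list[TimexAnnotation],
    reliv_gold: list[TimexAnnotation],
) -> list[TimexAnnotation]:
    """System annotations overlapping >=1 RelIV gold span (splits retained)."""
    return [
        s for s in system_annotations
        if any(s.start < g.end and g.start < s.end for g in reliv_gold)
    ]
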