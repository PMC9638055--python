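"""Deterministic generator of synthetic discharge summaries with gold TIMEX3.

Real clinical temporal corpora are distribution-restricted, so every test
in this package runs on synthetic sectioned notes that emulate their
structure: a header with admission/discharge dates, HISTORY / HOSPITAL
COURSE / DISCHARGE sections, and a configurable mixture of explicit dates,
relative DATE phrases ("2 weeks prior to admission", "POD#2"), DURATION
phrases ("several days", "the past 2 weeks"), clock times, and frequency
expressions ("b.i.d.", "daily", "x 10").  Default mixture weights follow
the type proportions of annotated discharge summaries (roughly two thirds
DATE, a fifth DURATION, the rest TIME and FREQUENCY, with about a third of
DATEs being relative).

The generator returns full bookkeeping — which annotations are explicit vs
relative — providing ground truth for filter and evaluation tests.  A
companion perturbation routine fabricates system-style output from gold
with known error composition (dropped, added, mislabeled, wrong-value).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np

from clintern.corpus_io import Document, TimexAnnotation, TimexType

__all__ = ["GeneratorConfig", "generate_corpus", "generate_system_run"]

_WORDED = {2: "two", 3: "three", 4: "four", 5: "five", 6: "six", 7: "seven"}
_MONTHS = ["January", "February", "March", "April", "May", "June", "July",
           "August", "September", "October", "November", "December"]
_WEEKDAYS = ["Monday", "Tuesday", "Wednesday", "Thursday", "Friday"]

DEFAULT_MIXTURE = {
    "date_explicit": 0.44,
    "date_relative": 0.24,
    "duration": 0.19,
    "time": 0.03,
    "frequency": 0.10,
}

DEFAULT_SECTIONS = (
    "HISTORY OF PRESENT ILLNESS",
    "HOSPITAL COURSE",
    "DISCHARGE INSTRUCTIONS",
)


@dataclass
class GeneratorConfig:
    n_documents: int = 50
    seed: int = 0
    mixture: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MIXTURE))
    phrases_per_doc: tuple[int, int] = (10, 16)   # inclusive range
    sections: tuple[str, ...] = DEFAULT_SECTIONS

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.mixture.values()):
            raise ValueError("mixture weights must be >= 0")
        if sum(self.mixture.values()) <= 0:
            raise ValueError("mixture weights must sum to > 0")


# ---------------------------------------------------------------------------
# Phrase factories: each returns (phrase text, ttype, value, modifier, explicit)

def _date_explicit(rng, adm: _dt.date, dis: _dt.date):
    day = adm + _dt.timedelta(days=int(rng.integers(-60, 5)))
    style = int(rng.integers(0, 6))
    if style == 0:
        return (f"{day.month}/{day.day}/{day.year}", TimexType.DATE,
                day.isoformat(), "NA", True)
    if style == 1:
        return (day.isoformat(), TimexType.DATE, day.isoformat(), "NA", True)
    if style == 2:
        return (f"{_MONTHS[day.month - 1]} {day.day}, {day.year}",
                TimexType.DATE, day.isoformat(), "NA", True)
    if style == 3:  # 2-place date in the admission year
        day2 = _dt.date(adm.year, day.month, day.day)
        return (f"{day2.month:02d}/{day2.day:02d}", TimexType.DATE,
                day2.isoformat(), "NA", True)
    if style == 4:
        return (_WEEKDAYS[int(rng.integers(0, len(_WEEKDAYS)))],
                TimexType.DATE, "", "NA", True)
    return (_MONTHS[day.month - 1], TimexType.DATE, "", "NA", True)


def _date_relative(rng, adm, dis):
    style = int(rng.integers(0, 6))
    n = int(rng.integers(2, 7))
    if style == 0:
        unit = ["days", "weeks", "months"][int(rng.integers(0, 3))]
        return (f"{n} {unit} prior to admission", TimexType.DATE, "", "NA", False)
    if style == 1:
        return (f"{n} days ago", TimexType.DATE, "", "NA", False)
    if style == 2:
        return ("the day of admission", TimexType.DATE, "", "NA", False)
    if style == 3:
        return ("the day of discharge", TimexType.DATE, "", "NA", False)
    if style == 4:
        return (f"postoperative day {_WORDED[n]}", TimexType.DATE, "", "NA", False)
    return (f"POD#{n}", TimexType.DATE, "", "NA", False)


def _duration(rng, adm, dis):
    style = int(rng.integers(0, 6))
    n = int(rng.integers(2, 8))
    if style == 0:
        return (f"{n} days", TimexType.DURATION, f"P{n}D", "NA", False)
    if style == 1:
        return (f"{_WORDED[n]} weeks" if n in _WORDED else f"{n} weeks",
                TimexType.DURATION, f"P{n}W", "NA", False)
    if style == 2:
        return ("several days", TimexType.DURATION, "P3D", "APPROX", False)
    if style == 3:
        return (f"the past {n} weeks", TimexType.DURATION, f"P{n}W", "NA", False)
    if style == 4:
        return ("a week", TimexType.DURATION, "P1W", "NA", False)
    return (f"{n} months", TimexType.DURATION, f"P{n}M", "NA", False)


def _time(rng, adm, dis):
    style = int(rng.integers(0, 3))
    if style == 0:
        h = int(rng.integers(6, 12))
        return (f"{h} a.m.", TimexType.TIME,
                f"{adm.isoformat()}T{h:02d}:00", "NA", True)
    if style == 1:
        h = int(rng.integers(1, 6))
        return (f"{h} p.m.", TimexType.TIME,
                f"{adm.isoformat()}T{h + 12:02d}:00", "NA", True)
    h, m = int(rng.integers(7, 19)), int(rng.integers(0, 60))
    return (f"{h}:{m:02d}", TimexType.TIME,
            f"{adm.isoformat()}T{h:02d}:{m:02d}", "NA", True)


def _frequency(rng, adm, dis):
    style = int(rng.integers(0, 6))
    if style == 0:
        return ("b.i.d.", TimexType.FREQUENCY, "RPT12H", "NA", False)
    if style == 1:
        return ("t.i.d.", TimexType.FREQUENCY, "RPT8H", "NA", False)
    if style == 2:
        return ("daily", TimexType.FREQUENCY, "RP1D", "NA", False)
    if style == 3:
        return ("twice a day", TimexType.FREQUENCY, "RPT12H", "NA", False)
    if style == 4:
        return ("q6h", TimexType.FREQUENCY, "RPT6H", "NA", False)
    return (f"x {int(rng.integers(2, 12))}", TimexType.FREQUENCY, "", "NA", False)


_FACTORIES = {
    "date_explicit": _date_explicit,
    "date_relative": _date_relative,
    "duration": _duration,
    "time": _time,
    "frequency": _frequency,
}

# non-temporal filler so sentence-level corpora contain both classes
_FILLERS = [
    "The lungs were clear to auscultation bilaterally.",
    "Abdomen was soft and nontender.",
    "Laboratory values were within normal limits.",
    "The patient tolerated the procedure well.",
    "No acute distress was noted on examination.",
    "She was counseled regarding medication adherence.",
]

_CARRIERS = {
    "date_explicit": [
        "The patient was seen in clinic on {P}.",
        "An echocardiogram was obtained on {P}.",
        "She presented to the emergency department on {P}.",
        "Follow up was scheduled for {P}.",
    ],
    "date_relative": [
        "Symptoms began {P}.",
        "She underwent resection {P}.",
        "The drain was removed on {P}.",
        "He was extubated on {P}.",
    ],
    "duration": [
        "Symptoms persisted for {P}.",
        "She was treated with antibiotics for {P}.",
        "The cough lasted {P}.",
        "He remained afebrile for {P}.",
    ],
    "time": [
        "The patient arrived at {P}.",
        "Surgery began at {P}.",
        "Vitals were recorded at {P}.",
    ],
    "frequency": [
        "Aspirin was continued {P}.",
        "He takes metoprolol {P}.",
        "Home nursing will administer heparin {P}.",
    ],
}


# ---------------------------------------------------------------------------

def _make_document(doc_index: int, cfg: GeneratorConfig, rng) -> tuple[Document, dict]:
    adm = _dt.date(2013, 1, 1) + _dt.timedelta(days=int(rng.integers(0, 1000)))
    dis = adm + _dt.timedelta(days=int(rng.integers(3, 15)))
    doc_id = f"synth{doc_index:03d}"

    categories = sorted(k for k, w in cfg.mixture.items() if w > 0)
    weights = np.array([cfg.mixture[c] for c in categories], dtype=float)
    weights /= weights.sum()
    lo, hi = cfg.phrases_per_doc
    n_phrases = int(rng.integers(lo, hi + 1))

    parts: list[str] = []
    offset = 0
    annotations: list[TimexAnnotation] = []
    book: dict[str, dict] = {}

    def append(chunk: str) -> None:
        nonlocal offset
        parts.append(chunk)
        offset += len(chunk)

    def add_ann(phrase: str, sent: str, ttype, value, mod, category, explicit) -> None:
        pos = sent.index(phrase)
        ann_id = f"t{len(annotations)}"
        annotations.append(TimexAnnotation(
            ann_id=ann_id, start=offset + pos, end=offset + pos + len(phrase),
            text=phrase, ttype=ttype, value=value, modifier=mod))
        book[ann_id] = {"category": category, "explicit": bool(explicit)}

    # header with annotated admission/discharge dates
    for label, day in (("Admission Date", adm), ("Discharge Date", dis)):
        phrase = f"{day.month:02d}/{day.day:02d}/{day.year}"
        line = f"{label}: {phrase}\n"
        add_ann(phrase, line, TimexType.DATE, day.isoformat(), "NA",
                "date_explicit", True)
        append(line)
    append("\n")

    per_section = np.array_split(np.arange(n_phrases), len(cfg.sections))
    for section, phrase_ids in zip(cfg.sections, per_section):
        append(f"{section}:\n")
        for _ in phrase_ids:
            cat = categories[int(rng.choice(len(categories), p=weights))]
            phrase, ttype, value, mod, explicit = _FACTORIES[cat](rng, adm, dis)
            carrier = _CARRIERS[cat][int(rng.integers(0, len(_CARRIERS[cat])))]
            sent = carrier.replace("{P}", phrase) + " "
            add_ann(phrase, sent, ttype, value, mod, cat, explicit)
            append(sent)
            if rng.random() < 0.4:
                append(_FILLERS[int(rng.integers(0, len(_FILLERS)))] + " ")
        append("\n\n")

    doc = Document(doc_id=doc_id, text="".join(parts),
                   admission_date=adm, discharge_date=dis,
                   annotations=annotations)
    return doc, book


def generate_corpus(cfg: GeneratorConfig) -> tuple[list[Document], dict]:
    """Generate the corpus plus ground-truth bookkeeping.

    Bookkeeping maps doc_id → {ann_id → {"category", "explicit"}}; the
    relative/implicit/vague subset is exactly the DATE/DURATION annotations
    with ``explicit == False``.
    """
    rng = np.random.default_rng(cfg.seed)
    docs: list[Document] = []
    bookkeeping: dict[str, dict] = {}
    for i in range(cfg.n_documents):
        doc, book = _make_document(i, cfg, rng)
        docs.append(doc)
        bookkeeping[doc.doc_id] = book
    return docs, bookkeeping


# ---------------------------------------------------------------------------
# System-run fabrication with known error composition

_FLIP = {
    TimexType.DATE: TimexType.DURATION,
    TimexType.DURATION: TimexType.DATE,
    TimexType.TIME: TimexType.DATE,
    TimexType.FREQUENCY: TimexType.DURATION,
}


def _corrupt_value(value: str) -> str:
    if value.startswith("P"):  # bump the first numeral of a duration
        for i, ch in enumerate(value):
            if ch.isdigit():
                return value[:i] + str(int(ch) + 1) + value[i + 1:]
        return value + "1D"
    try:
        day = _dt.date.fromisoformat(value[:10])
        return (day + _dt.timedelta(days=1)).isoformat() + value[10:]
    except ValueError:
        return value + "X"


def generate_system_run(
    gold_docs: list[Document],
    error_rates: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[dict[str, list[TimexAnnotation]], dict[str, dict]]:
    """Perturb gold annotations into a fake system run with a known log.

    Rates (each in [0, 1]): ``drop`` removes annotations (missed), ``flip``
    swaps the type (label error; the value is cleared since it no longer
    fits the type), ``value`` corrupts a nonempty value (value error), and
    ``add`` emits spurious annotations over unannotated tokens (added).
    """
    rates = {"drop": 0.0, "add": 0.0, "flip": 0.0, "value": 0.0}
    rates.update(error_rates or {})
    if any(not 0.0 <= v <= 1.0 for v in rates.values()):
        raise ValueError("error rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    system: dict[str, list[TimexAnnotation]] = {}
    log: dict[str, dict] = {}
    for doc in gold_docs:
        out: list[TimexAnnotation] = []
        entry = {"dropped": [], "flipped": [], "value": [], "added": []}
        for ann in doc.annotations:
            if rng.random() < rates["drop"]:
                entry["dropped"].append(ann.ann_id)
                continue
            if rng.random() < rates["flip"]:
                out.append(TimexAnnotation(
                    ann_id=ann.ann_id, start=ann.start, end=ann.end,
                    text=ann.text, ttype=_FLIP[ann.ttype], value="",
                    modifier=ann.modifier))
                entry["flipped"].append(ann.ann_id)
                continue
            if ann.value and rng.random() < rates["value"]:
                out.append(TimexAnnotation(
                    ann_id=ann.ann_id, start=ann.start, end=ann.end,
                    text=ann.text, ttype=ann.ttype,
                    value=_corrupt_value(ann.value), modifier=ann.modifier))
                entry["value"].append(ann.ann_id)
                continue
            out.append(ann)

        n_add = int(rng.binomial(max(1, len(doc.annotations)), rates["add"]))
        taken = [(a.start, a.end) for a in doc.annotations]
        import re as _re
        tokens = [(m.start(), m.end()) for m in _re.finditer(r"[A-Za-z]{3,}", doc.text)
                  if not any(m.start() < e and s < m.end() for s, e in taken)]
        for k in range(min(n_add, len(tokens))):
            s, e = tokens[int(rng.integers(0, len(tokens)))]
            if any(s < a.end and a.start < e for a in out):
                continue
            ann_id = f"add{k}"
            out.append(TimexAnnotation(
                ann_id=ann_id, start=s, end=e, text=doc.text[s:e],
                ttype=TimexType.DATE, value="", modifier="NA"))
            entry["added"].append(ann_id)
        system[doc.doc_id] = sorted(out, key=lambda a: a.start)
        log[doc.doc_id] = entry
    return system, log
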