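"""Documents, standoff TIMEX3 annotations, and sentence/token segmentation.

The corpus unit is a ``Document``: the raw note text plus an ordered list of
standoff :class:`TimexAnnotation` records and optional admission/discharge
reference dates.  Character offsets are 0-based and half-open throughout;
every annotation's surface text must equal the text slice at its span.

The standoff dialect is one XML file per note::

    <annotations doc_id="note01" admission_date="2014-01-08">
      <TIMEX3 id="t0" start="9" end="15" text="2 days" type="DURATION"
              val="P2D" mod="NA"/>
    </annotations>
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field
from enum import Enum
from xml.sax.saxutils import quoteattr

from lxml import etree

__all__ = [
    "TimexType", "TimexAnnotation", "Sentence", "Document",
    "read_standoff_xml", "write_standoff_xml", "segment",
    "ValidationError",
]


class ValidationError(ValueError):
    """An annotation violates a Document/TimexAnnotation invariant."""


class TimexType(str, Enum):
    DATE = "DATE"
    TIME = "TIME"
    DURATION = "DURATION"
    FREQUENCY = "FREQUENCY"


#: ISO-8601 duration grammar P[n]Y[n]M[n]W[n]D[T[n]H[n]M]
_ISO_DURATION_RE = re.compile(
    r"^P(?=.)(\d+Y)?(\d+M)?(\d+W)?(\d+D)?(T(?=.)(\d+H)?(\d+M)?(\d+S)?)?$"
)
_ISO_DATE_RE = re.compile(
    r"^\d{4}(-\d{2}(-\d{2}([T ]\d{2}:\d{2}(:\d{2})?)?)?)?$"
)


def is_iso_duration(value: str) -> bool:
    return bool(_ISO_DURATION_RE.match(value))


def is_iso_datetime(value: str) -> bool:
    return bool(_ISO_DATE_RE.match(value))


@dataclass(frozen=True)
class TimexAnnotation:
    """One TIMEX3 annotation: char span, surface text, type, value, modifier."""

    ann_id: str
    start: int
    end: int
    text: str
    ttype: TimexType
    value: str = ""
    modifier: str = "NA"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"annotation {self.ann_id}: start {self.start} >= end {self.end}"
            )
        if not isinstance(self.ttype, TimexType):
            object.__setattr__(self, "ttype", TimexType(self.ttype))
        if self.value:
            if self.ttype in (TimexType.DATE, TimexType.TIME):
                if not is_iso_datetime(self.value):
                    raise ValidationError(
                        f"annotation {self.ann_id}: value {self.value!r} is not "
                        f"an ISO-8601 date/time"
                    )
            elif self.ttype is TimexType.DURATION:
                if not is_iso_duration(self.value):
                    raise ValidationError(
                        f"annotation {self.ann_id}: value {self.value!r} does not "
                        f"match the ISO-8601 duration grammar"
                    )

    def overlaps(self, start: int, end: int) -> bool:
        """Lenient span intersection against a half-open interval."""
        return self.start < end and start < self.end


@dataclass(frozen=True)
class Sentence:
    """A sentence span plus its whitespace-token spans, all into the note text."""

    start: int
    end: int
    tokens: tuple[tuple[int, int], ...]

    def token_texts(self, text: str) -> list[str]:
        return [text[s:e] for s, e in self.tokens]


@dataclass
class Document:
    doc_id: str
    text: str
    admission_date: _dt.date | None = None
    discharge_date: _dt.date | None = None
    annotations: list[TimexAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for ann in self.annotations:
            if not (0 <= ann.start < ann.end <= len(self.text)):
                raise ValidationError(
                    f"doc {self.doc_id}: annotation {ann.ann_id} span "
                    f"({ann.start},{ann.end}) outside text of length {len(self.text)}"
                )
            slice_ = self.text[ann.start:ann.end]
            if slice_ != ann.text:
                raise ValidationError(
                    f"doc {self.doc_id}: annotation {ann.ann_id} text "
                    f"{ann.text!r} != text slice {slice_!r}"
                )

    def replace_annotations(self, annotations: list[TimexAnnotation]) -> "Document":
        return Document(
            doc_id=self.doc_id,
            text=self.text,
            admission_date=self.admission_date,
            discharge_date=self.discharge_date,
            annotations=list(annotations),
        )


# ---------------------------------------------------------------------------
# Standoff XML I/O

def read_standoff_xml(xml_text: str, note_text: str, doc_id: str | None = None) -> Document:
    """Parse a standoff annotation file against its note text.

    Surface-text consistency is validated: a ``text`` attribute that does not
    equal the note slice at (start, end) raises :class:`ValidationError`
    naming the offending annotation id.
    """
    try:
        root = etree.fromstring(xml_text.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed standoff XML: {exc}") from exc

    def _date(attr: str) -> _dt.date | None:
        raw = root.get(attr)
        return _dt.date.fromisoformat(raw) if raw else None

    annotations = []
    for el in root.iter("TIMEX3"):
        annotations.append(
            TimexAnnotation(
                ann_id=el.get("id", f"t{len(annotations)}"),
                start=int(el.get("start")),
                end=int(el.get("end")),
                text=el.get("text", ""),
                ttype=TimexType(el.get("type")),
                value=el.get("val", ""),
                modifier=el.get("mod", "NA"),
            )
        )
    return Document(
        doc_id=doc_id or root.get("doc_id", "doc"),
        text=note_text,
        admission_date=_date("admission_date"),
        discharge_date=_date("discharge_date"),
        annotations=annotations,
    )


def write_standoff_xml(doc: Document) -> str:
    """Serialize a Document's annotations; round-trips through the reader."""
    doc.validate()
    head = [f'<annotations doc_id={quoteattr(doc.doc_id)}']
    if doc.admission_date:
        head.append(f' admission_date="{doc.admission_date.isoformat()}"')
    if doc.discharge_date:
        head.append(f' discharge_date="{doc.discharge_date.isoformat()}"')
    head.append(">")
    lines = ["".join(head)]
    for a in doc.annotations:
        lines.append(
            f'  <TIMEX3 id={quoteattr(a.ann_id)} start="{a.start}" end="{a.end}"'
            f' text={quoteattr(a.text)} type="{a.ttype.value}"'
            f' val={quoteattr(a.value)} mod={quoteattr(a.modifier)}/>'
        )
    lines.append("</annotations>")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Segmentation

# Abbreviations that end in a period but do not end a sentence.
_ABBREV_GUARD = {
    "dr.", "mr.", "mrs.", "ms.", "st.", "vs.", "e.g.", "i.e.", "etc.",
    "b.i.d.", "t.i.d.", "q.i.d.", "q.d.", "p.o.", "p.r.n.", "a.m.", "p.m.",
    "approx.", "no.",
}

_TOKEN_RE = re.compile(r"\S+")
_BOUNDARY_RE = re.compile(r"[.?!]+[\"')\]]*\s+")


def _tokens_in(text: str, start: int, end: int) -> tuple[tuple[int, int], ...]:
    return tuple((m.start() + start, m.end() + start)
                 for m in _TOKEN_RE.finditer(text[start:end]))


def segment(text: str) -> list[Sentence]:
    """Rule-based sentence segmentation with whitespace tokenization.

    Splits after ``.``/``?``/``!`` followed by whitespace, unless the word
    carrying the period is a known clinical/ honorific abbreviation or the
    next character is lowercase.  Newline pairs (blank lines / section
    breaks) always split.  Tokens are maximal non-whitespace runs, so token
    spans slice back to their exact surface strings.
    """
    sentences: list[Sentence] = []
    if not text.strip():
        return sentences

    boundaries = [0]
    for m in _BOUNDARY_RE.finditer(text):
        end = m.end()
        if end >= len(text):
            continue
        # word containing the terminator, e.g. "Dr." or "b.i.d."
        wstart = m.start()
        while wstart > 0 and not text[wstart - 1].isspace():
            wstart -= 1
        word = text[wstart:m.start() + len(m.group(0).rstrip())].strip().lower()
        nxt = text[end]
        if word in _ABBREV_GUARD and "\n\n" not in m.group(0):
            continue
        if nxt.islower():
            continue
        boundaries.append(end)
    for m in re.finditer(r"\n\s*\n", text):
        if m.end() < len(text):
            boundaries.append(m.end())
    boundaries = sorted(set(boundaries))
    boundaries.append(len(text))

    for s, e in zip(boundaries, boundaries[1:]):
        # trim to non-whitespace content
        seg = text[s:e]
        lstrip = len(seg) - len(seg.lstrip())
        rstrip = len(seg) - len(seg.rstrip())
        s2, e2 = s + lstrip, e - rstrip
        if s2 >= e2:
            continue
        sentences.append(Sentence(start=s2, end=e2, tokens=_tokens_in(text, s2, e2)))
    return sentences


def sentence_containing(sentences: list[Sentence], start: int, end: int) -> Sentence | None:
    """First sentence whose span overlaps [start, end)."""
    for s in sentences:
        if s.start < end and start < s.end:
            return s
    return None


# ---------------------------------------------------------------------------
# Corpus directories: notes/<id>.txt + annotations/<id>.xml

def save_corpus_dir(docs: list[Document], directory) -> None:
    from pathlib import Path
    d = Path(directory)
    (d / "notes").mkdir(parents=True, exist_ok=True)
    (d / "annotations").mkdir(parents=True, exist_ok=True)
    for doc in docs:
        (d / "notes" / f"{doc.doc_id}.txt").write_text(doc.text, encoding="utf-8")
        (d / "annotations" / f"{doc.doc_id}.xml").write_text(
            write_standoff_xml(doc), encoding="utf-8")


def load_corpus_dir(directory) -> list[Document]:
    from pathlib import Path
    d = Path(directory)
    docs = []
    for note in sorted((d / "notes").glob("*.txt")):
        xml_path = d / "annotations" / f"{note.stem}.xml"
        text = note.read_text(encoding="utf-8")
        if xml_path.exists():
            docs.append(read_standoff_xml(xml_path.read_text(encoding="utf-8"),
                                          text, doc_id=note.stem))
        else:
            docs.append(Document(doc_id=note.stem, text=text))
    return docs
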