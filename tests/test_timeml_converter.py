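"""ISO normalization and entity→TIMEX3 conversion, including TTD routing."""

import datetime as dt

import pytest

from clintern.corpus_io import Document, TimexType, is_iso_duration
from clintern.embedding_features import FeatureVariant, PhraseFeature
from clintern.recognizer import EntityKind, ScateEntity, Unit, recognize
from clintern.timeml_converter import (
    ApproxTable, ConversionConfig, NormalizationError, approximate_quantity,
    convert_entities, iso_duration, normalize_explicit_date, scate_to_timeml,
)

import numpy as np


def ent(text, kind, start=0, **kw):
    return ScateEntity(start=start, end=start + len(text), text=text,
                       kind=kind, **kw)


def doc_with(text, admission=None, discharge=None):
    return Document(doc_id="d", text=text, admission_date=admission,
                    discharge_date=discharge)


class TestIsoDuration:
    @pytest.mark.parametrize("qty,unit,expected", [
        (2, Unit.day, "P2D"),
        (1, Unit.week, "P1W"),
        (3, Unit.month, "P3M"),
        (5, Unit.year, "P5Y"),
        (6, Unit.hour, "PT6H"),
        (30, Unit.minute, "PT30M"),
    ])
    def test_mapping(self, qty, unit, expected):
        assert iso_duration(qty, unit) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(NormalizationError):
            iso_duration(0, Unit.day)


class TestApproximateQuantity:
    def test_default_table(self):
        table = ApproxTable()
        assert approximate_quantity("several", table) == (3, "APPROX")
        assert approximate_quantity("couple", table) == (2, "APPROX")

    def test_unknown_word(self):
        with pytest.raises(NormalizationError):
            approximate_quantity("soon", ApproxTable())

    def test_quantities_must_be_positive(self):
        with pytest.raises(ValueError):
            ApproxTable(table={"several": 0})


class TestNormalizeExplicitDate:
    def test_us_slash_date(self):
        e = ent("2/4/2013", EntityKind.ExplicitDate)
        assert normalize_explicit_date(e, doc_with("2/4/2013")) == "2013-02-04"

    def test_day_first_flag(self):
        e = ent("2/4/2013", EntityKind.ExplicitDate)
        cfg = ConversionConfig(day_first=True)
        assert normalize_explicit_date(e, doc_with("2/4/2013"), cfg) == "2013-04-02"

    def test_two_place_year_fill_from_admission(self):
        e = ent("01/10", EntityKind.TwoPlaceDate)
        doc = doc_with("01/10", admission=dt.date(2014, 1, 8))
        assert normalize_explicit_date(e, doc) == "2014-01-10"

    def test_two_place_outside_window_uses_nearer_year(self):
        # admission late December; 01/10 belongs to the following year
        e = ent("01/10", EntityKind.TwoPlaceDate)
        doc = doc_with("01/10", admission=dt.date(2014, 12, 28),
                       discharge=dt.date(2015, 1, 6))
        assert normalize_explicit_date(e, doc) == "2015-01-10"

    def test_month_name_date(self):
        e = ent("January 3, 2021", EntityKind.ExplicitDate)
        assert normalize_explicit_date(e, doc_with("January 3, 2021")) == "2021-01-03"

    def test_bare_month_not_normalizable(self):
        e = ent("February", EntityKind.ExplicitDate)
        with pytest.raises(NormalizationError):
            normalize_explicit_date(e, doc_with("February"))


class _ConstantModel:
    """TTD stand-in predicting a fixed label."""

    variant = FeatureVariant.PhraseOnly
    dim = 8

    def __init__(self, label):
        self.label = label

    def predict_label(self, feature):
        return self.label


def _dummy_feature():
    return PhraseFeature(vector=np.zeros(8), variant=FeatureVariant.PhraseOnly)


class TestScateToTimeml:
    def test_naive_rule_period_to_duration(self):
        e = ent("2 days", EntityKind.Period, quantity=2, unit=Unit.day)
        ann = scate_to_timeml(e, doc_with("2 days"))
        assert ann.ttype is TimexType.DURATION and ann.value == "P2D"

    def test_model_routes_period_to_date_with_empty_value(self):
        e = ent("2 days", EntityKind.Period, quantity=2, unit=Unit.day)
        cfg = ConversionConfig(ttd_model=_ConstantModel("DATE"))
        ann = scate_to_timeml(e, doc_with("2 days"), cfg, feature=_dummy_feature())
        assert ann.ttype is TimexType.DATE and ann.value == ""

    def test_model_requires_feature(self):
        e = ent("2 days", EntityKind.Period, quantity=2, unit=Unit.day)
        cfg = ConversionConfig(ttd_model=_ConstantModel("DATE"))
        with pytest.raises(ValueError, match="feature"):
            scate_to_timeml(e, doc_with("2 days"), cfg)

    def test_frequency_normalized_from_lexicon(self):
        e = ent("b.i.d.", EntityKind.Frequency, expansion="twice a day",
                norm_value="RPT12H")
        ann = scate_to_timeml(e, doc_with("b.i.d."))
        assert ann.ttype is TimexType.FREQUENCY and ann.value == "RPT12H"

    def test_frequency_without_lexicon_value_is_empty(self):
        e = ent("x 10", EntityKind.Frequency)
        assert scate_to_timeml(e, doc_with("x 10")).value == ""

    def test_approx_period_gets_modifier(self):
        e = ent("several days", EntityKind.Period, unit=Unit.day,
                approx_word="several")
        ann = scate_to_timeml(e, doc_with("several days"))
        assert ann.value == "P3D" and ann.modifier == "APPROX"


class TestConversionProperties:
    def test_all_ambiguous_become_duration_without_model(self, small_corpus):
        """Naive-rule reproduction over recognizer output on real-ish notes."""
        docs, _ = small_corpus
        for doc in docs[:8]:
            ents = recognize(doc.text)
            anns = convert_entities(ents, doc)
            for e, a in zip(ents, anns):
                if e.kind in (EntityKind.Period, EntityKind.CalendarInterval):
                    assert a.ttype is TimexType.DURATION

    def test_duration_values_match_iso_grammar(self, small_corpus):
        docs, _ = small_corpus
        for doc in docs[:8]:
            anns = convert_entities(recognize(doc.text), doc)
            for a in anns:
                if a.ttype is TimexType.DURATION and a.value:
                    assert is_iso_duration(a.value), a.value

    def test_conversion_is_total(self, small_corpus):
        docs, _ = small_corpus
        for doc in docs[:8]:
            ents = recognize(doc.text)
            assert len(convert_entities(ents, doc)) == len(ents)
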