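"""The artificial language: lexicon integrity, uniphones, event streams."""

import collections

import numpy as np
import pytest

from marklearn.language import (
    CONSTANT_CUE,
    FREQUENCIES,
    Event,
    PhoneMappingError,
    behavioral_trial_order,
    build_language_spec,
    events_from_tokens,
    generate_events,
    noun_to_uniphones,
    noun_token_stream,
    read_events,
    uniphones_to_form,
    write_events,
)


class TestLexicon:
    def test_counts_and_frequencies(self, spec):
        assert len(spec.nouns) == 32
        for k in (1, 2, 3, 4):
            cls = spec.nouns_of_class(k)
            assert len(cls) == 8
            assert tuple(n.frequency for n in cls) == FREQUENCIES
            assert sum(n.frequency for n in cls) == 103
        assert spec.trials_per_epoch == 412
        assert len(set(spec.objects)) == 32

    def test_markers(self, spec):
        assert spec.markers.premarkers[1] == "ima"
        assert spec.markers.postmarkers[1] == "ove/ovu"
        assert spec.markers.abstract_marker(1) == "marker1"
        assert spec.markers.unspecific_premarker == "imo"
        assert spec.markers.unspecific_postmarker == "agi"

    def test_feature_structure(self, spec):
        f = spec.features
        assert f.class_to_meaning_set[1] == {"D1meaning"}
        assert f.class_to_form_set[1] == {"D1form", "O1form", "O2form"}
        # deliberate ambiguity: class 4 shares form with 2 and meaning with 3
        assert f.class_to_form_set[2] == f.class_to_form_set[4]
        assert f.class_to_meaning_set[3] == f.class_to_meaning_set[4]
        counts = {
            o: sum(o in f.class_to_form_set[k] for k in (1, 2, 3, 4))
            for o in ("O1form", "O2form", "O3form")
        }
        assert counts == {"O1form": 3, "O2form": 2, "O3form": 3}

    def test_ambiguity_derived_mechanically(self, spec):
        f = spec.features
        assert f.ambiguous_classes(2, "form") == {4}
        assert f.ambiguous_classes(4, "form") == {2}
        assert f.ambiguous_classes(1, "form") == set()
        assert f.ambiguous_classes(3, "meaning") == {4}
        assert f.ambiguous_classes(1, "meaning") == set()


class TestUniphones:
    @pytest.mark.parametrize(
        "form, phones",
        [
            ("oksham", ["#o", "k", "ʃ", "a", "m#"]),
            ("ima", ["#i", "m", "a#"]),
            ("aftong", ["#a", "f", "t", "o", "ŋ#"]),
            ("nechran", ["#n", "e", "x", "r", "a", "n#"]),
            ("kitsogis", ["#k", "i", "ts", "o", "g", "i", "s#"]),
        ],
    )
    def test_tokenization(self, form, phones):
        assert noun_to_uniphones(form) == phones

    def test_unmappable_residue_is_reported(self):
        with pytest.raises(PhoneMappingError, match="3am"):
            noun_to_uniphones("ok3am")

    def test_roundtrip_whole_lexicon(self, spec):
        for noun in spec.nouns:
            assert uniphones_to_form(spec.uniphones(noun.form)) == noun.form


class TestEventStreams:
    def test_premarking_encoding(self, spec):
        events = generate_events(spec, "pre", "sim1", 412, seed=0)
        assert len(events) == 412
        assert all(len(ev.cues) == 2 for ev in events)
        assert all(CONSTANT_CUE in ev.cues for ev in events)
        oksham = next(ev for ev in events if "ʃ" in ev.outcomes)
        assert len(oksham.outcomes) == 10  # 1 meaning + 3 form + 5 phones + object
        assert oksham.cues == {"marker1", CONSTANT_CUE}
        assert "dog" in oksham.outcomes and "D1meaning" in oksham.outcomes

    def test_postmarking_is_role_swap_of_premarking(self, spec, rng):
        tokens = noun_token_stream(spec, 100, rng)
        pre = events_from_tokens(spec, tokens, "pre", "sim1")
        post = events_from_tokens(spec, tokens, "post", "sim1")
        for p, q in zip(pre, post):
            assert len(q.outcomes) == 1
            assert q.outcomes == p.cues - {CONSTANT_CUE}
            assert q.cues - {CONSTANT_CUE} == p.outcomes

    def test_sim2_encoding(self, spec):
        events = generate_events(spec, "pre", "sim2", 412, seed=0)
        for ev in events:
            assert len(ev.outcomes) == 1
            assert CONSTANT_CUE in ev.cues
            obj = next(iter(ev.outcomes))
            assert obj in spec.objects
        # no meaning features and no objects on the cue side
        all_cues = set().union(*(ev.cues for ev in events))
        assert not all_cues & spec.features.meaning_features
        assert not all_cues & set(spec.objects)

    def test_multiset_sampler_exact_epoch_counts(self, spec, rng):
        tokens = noun_token_stream(spec, 412, rng)
        counts = collections.Counter(t.form for t in tokens)
        for noun in spec.nouns:
            assert counts[noun.form] == noun.frequency

    def test_iid_sampler_counts_in_expectation(self, spec, rng):
        n = 412 * 30
        tokens = noun_token_stream(spec, n, rng, sampler="iid")
        counts = collections.Counter(t.form for t in tokens)
        for noun in spec.nouns:
            expected = n * noun.frequency / 412
            sd = np.sqrt(expected * (1 - noun.frequency / 412))
            assert abs(counts[noun.form] - expected) < 5 * sd

    def test_unknown_labels_rejected(self, spec, rng):
        tokens = noun_token_stream(spec, 5, rng)
        with pytest.raises(ValueError):
            events_from_tokens(spec, tokens, "mid", "sim1")
        with pytest.raises(ValueError):
            events_from_tokens(spec, tokens, "pre", "sim3")


class TestBehavioralOrder:
    def test_pseudorandomization_rule(self, spec):
        order = behavioral_trial_order(spec, seed=3)
        assert len(order) == 412
        # low-frequency nouns are kept out of the first 112 trials
        head = order[:112]
        assert all(t.frequency >= 11 for t in head)
        per_class = collections.Counter(t.noun_class for t in head)
        assert per_class == {1: 28, 2: 28, 3: 28, 4: 28}
        # the whole list is a permutation of the frequency multiset
        counts = collections.Counter(t.form for t in order)
        assert counts == {n.form: n.frequency for n in spec.nouns}


class TestEventIO:
    def test_roundtrip(self, spec, tmp_path):
        events = generate_events(spec, "post", "sim1", 50, seed=1)
        path = write_events(events, tmp_path / "events.tsv")
        back = read_events(path)
        assert [(e.cues, e.outcomes) for e in back] == [
            (e.cues, e.outcomes) for e in events
        ]

    def test_bad_header_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("foo\tbar\n")
        with pytest.raises(ValueError):
            read_events(p)


class TestEventInvariants:
    def test_disjoint_and_nonempty(self):
        with pytest.raises(ValueError):
            Event(frozenset(), frozenset({"o"}))
        with pytest.raises(ValueError):
            Event(frozenset({"a"}), frozenset({"a"}))

    def test_canonical_yaml_matches_builder(self, spec, tmp_path):
        import yaml
        from pathlib import Path

        shipped = Path(__file__).resolve().parents[1] / "src/marklearn/data/language.yaml"
        assert yaml.safe_load(shipped.read_text()) == spec.to_dict()
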