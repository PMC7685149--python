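"""The artificial noun-class language and its training event streams.

The lexicon is a four-class artificial noun system.  Each class pairs one
*meaning* category (animal, plant, or random objects) with one *form*
(stress-pattern) category.  Classes are announced either by a premarker
(``ima``-type particles before the noun) or a postmarker (``-ove``-type
suffixes), and simulations consume the abstract marker identities
``marker1`` .. ``marker4``.

Category features follow the distinct/overlapping design: each meaning
category is a single distinct feature (``D1meaning`` ...), while each form
category is a set of one distinct feature plus two features shared with
other classes (``D1form`` + ``O1form`` + ``O2form`` ...).  Class 4 is the
deliberately ambiguous class: it shares its form set with class 2 and its
meaning feature with class 3.

Noun word forms enter the models as *uniphones*: single phones with the
word-initial and word-final phone marked by ``#``.  Within every class the
eight nouns follow the geometric presentation-frequency profile
32/23/16/11/8/6/4/3, so one full pass over the language ("epoch") is
4 x 103 = 412 trials.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import yaml

__all__ = [
    "CONSTANT_CUE",
    "FREQUENCIES",
    "Event",
    "FeatureInventory",
    "LanguageSpec",
    "MarkerInventory",
    "NounEntry",
    "PhoneMappingError",
    "SpecIntegrityError",
    "behavioral_trial_order",
    "build_language_spec",
    "events_from_tokens",
    "generate_events",
    "noun_to_uniphones",
    "noun_token_stream",
    "read_events",
    "uniphones_to_form",
    "write_events",
]

CONSTANT_CUE = "constant"

#: Within-class presentation counts per 412-trial epoch (geometric profile).
FREQUENCIES = (32, 23, 16, 11, 8, 6, 4, 3)

#: Greedy longest-match-first grapheme -> phone table.  Digraphs first, all
#: remaining letters map to themselves.  Phonetic fidelity is irrelevant for
#: the simulations; only cue *identity* matters.
PHONE_TABLE: tuple[tuple[str, str], ...] = (
    ("sh", "ʃ"),
    ("ng", "ŋ"),
    ("ch", "x"),
    ("ts", "ts"),
) + tuple((c, c) for c in "abcdefghijklmnopqruvwyz") + (("s", "s"), ("t", "t"), ("x", "x"))

_PHONE_INVERSE = {"ʃ": "sh", "ŋ": "ng", "x": "ch"}

# Lexicon, one row per frequency tier (Table layout: class 1..4).
_NOUNS = {
    1: ("oksham", "luobar", "anhatar", "simad", "nechran", "kekunam", "kitsogis", "magril"),
    2: ("kanjur", "ennovis", "ruis", "lopranik", "aftong", "palneng", "tivitkal", "meromer"),
    3: ("anveal", "psondew", "hatrumir", "kilal", "repis", "tokran", "istefur", "merkatim"),
    4: ("jajosan", "serim", "erkefal", "vimeros", "burbad", "ksoster", "natrul", "rutonak"),
}

_OBJECTS = {
    1: ("dog", "cat", "chicken", "horse", "pig", "mouse", "sheep", "rabbit"),
    2: ("rose", "sunflower", "tulip", "orchid", "dandelion", "poppy", "daisy", "forgetmenot"),
    3: ("car", "chair", "banana", "lake", "sewingmachine", "kite", "fence", "foot"),
    4: ("airplane", "shelf", "apple", "mountain", "flatiron", "ball", "umbrella", "ear"),
}

_MEANING_SETS = {
    1: frozenset({"D1meaning"}),
    2: frozenset({"D2meaning"}),
    3: frozenset({"D3meaning"}),
    4: frozenset({"D3meaning"}),
}

_FORM_SETS = {
    1: frozenset({"D1form", "O1form", "O2form"}),
    2: frozenset({"D3form", "O1form", "O3form"}),
    3: frozenset({"D2form", "O2form", "O3form"}),
    4: frozenset({"D3form", "O1form", "O3form"}),
}

_STRESS = {1: "stress1", 2: "stress3/4", 3: "stress2", 4: "stress3/4"}

_PREMARKERS = {1: "ima", 2: "imo", 3: "ime", 4: "imi"}
_POSTMARKERS = {1: "ove/ovu", 2: "ira/ire", 3: "agi/ago", 4: "epo/epa"}

_CARRIER_PHRASES = ("unta boltohe", "ena dikanhe")


class SpecIntegrityError(ValueError):
    """The hard-coded language tables violate one of their invariants."""


class PhoneMappingError(ValueError):
    """A word form contains graphemes the phone table cannot consume."""


@dataclass(frozen=True)
class NounEntry:
    form: str
    noun_class: int
    frequency: int
    object_meaning: str
    stress_pattern: str


@dataclass(frozen=True)
class FeatureInventory:
    """Distinct meaning features and partly overlapping form features per class."""

    class_to_meaning_set: dict[int, frozenset[str]]
    class_to_form_set: dict[int, frozenset[str]]

    @property
    def meaning_features(self) -> frozenset[str]:
        return frozenset().union(*self.class_to_meaning_set.values())

    @property
    def form_features(self) -> frozenset[str]:
        return frozenset().union(*self.class_to_form_set.values())

    def feature_set(self, noun_class: int, dimension: str) -> frozenset[str]:
        if dimension == "meaning":
            return self.class_to_meaning_set[noun_class]
        if dimension == "form":
            return self.class_to_form_set[noun_class]
        raise ValueError(f"unknown dimension: {dimension!r}")

    def ambiguous_classes(self, noun_class: int, dimension: str) -> frozenset[int]:
        """Other classes whose feature set on ``dimension`` is identical.

        These are the competitor classes whose binary choices are excluded
        from the pairwise-mean choice probability, because the shared feature
        set genuinely licenses both markers.
        """
        own = self.feature_set(noun_class, dimension)
        return frozenset(
            k for k in self.class_to_meaning_set
            if k != noun_class and self.feature_set(k, dimension) == own
        )


@dataclass(frozen=True)
class MarkerInventory:
    premarkers: dict[int, str]
    postmarkers: dict[int, str]
    unspecific_premarker: str
    unspecific_postmarker: str

    @staticmethod
    def abstract_marker(noun_class: int) -> str:
        """The marker identity the simulations consume (``marker1`` ...)."""
        return f"marker{noun_class}"


@dataclass(frozen=True)
class Event:
    """One learning trial: a cue set predicting an outcome set."""

    cues: frozenset[str]
    outcomes: frozenset[str]
    trial_index: int = 1

    def __post_init__(self) -> None:
        if not self.cues or not self.outcomes:
            raise ValueError("cue and outcome sets must be non-empty")
        if self.cues & self.outcomes:
            raise ValueError("cue and outcome sets must be disjoint")


@dataclass(frozen=True)
class LanguageSpec:
    nouns: tuple[NounEntry, ...]
    features: FeatureInventory
    markers: MarkerInventory
    phone_table: tuple[tuple[str, str], ...]
    carrier_phrases: tuple[str, str]
    _uniphone_cache: dict[str, tuple[str, ...]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def nouns_of_class(self, noun_class: int) -> tuple[NounEntry, ...]:
        return tuple(n for n in self.nouns if n.noun_class == noun_class)

    def uniphones(self, form: str) -> tuple[str, ...]:
        if form not in self._uniphone_cache:
            self._uniphone_cache[form] = tuple(noun_to_uniphones(form, self.phone_table))
        return self._uniphone_cache[form]

    def noun_features(self, noun: NounEntry) -> frozenset[str]:
        """Meaning set + form set + uniphones + object meaning of a noun token."""
        return (
            self.features.class_to_meaning_set[noun.noun_class]
            | self.features.class_to_form_set[noun.noun_class]
            | frozenset(self.uniphones(noun.form))
            | {noun.object_meaning}
        )

    @property
    def objects(self) -> tuple[str, ...]:
        return tuple(n.object_meaning for n in self.nouns)

    @property
    def trials_per_epoch(self) -> int:
        return sum(n.frequency for n in self.nouns)

    def to_dict(self) -> dict:
        return {
            "nouns": [
                {
                    "form": n.form,
                    "class": n.noun_class,
                    "frequency": n.frequency,
                    "object": n.object_meaning,
                    "stress": n.stress_pattern,
                    "uniphones": list(self.uniphones(n.form)),
                }
                for n in self.nouns
            ],
            "meaning_sets": {k: sorted(v) for k, v in self.features.class_to_meaning_set.items()},
            "form_sets": {k: sorted(v) for k, v in self.features.class_to_form_set.items()},
            "premarkers": dict(self.markers.premarkers),
            "postmarkers": dict(self.markers.postmarkers),
            "unspecific_premarker": self.markers.unspecific_premarker,
            "unspecific_postmarker": self.markers.unspecific_postmarker,
            "phone_table": [list(p) for p in self.phone_table if p[0] != p[1]],
            "carrier_phrases": list(self.carrier_phrases),
        }

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), allow_unicode=True, sort_keys=False))
        return path


def noun_to_uniphones(
    form: str, phone_table: Sequence[tuple[str, str]] = PHONE_TABLE
) -> list[str]:
    """Split a word form into uniphones, marking word boundaries.

    Graphemes are consumed greedily, longest match first, so e.g. ``sh`` is
    one phone.  The first phone is prefixed and the last phone suffixed with
    ``#`` (``oksham`` -> ``#o k ʃ a m#``).
    """
    ordered = sorted(phone_table, key=lambda kv: -len(kv[0]))
    phones: list[str] = []
    i = 0
    while i < len(form):
        for grapheme, phone in ordered:
            if form.startswith(grapheme, i):
                phones.append(phone)
                i += len(grapheme)
                break
        else:
            raise PhoneMappingError(
                f"cannot map {form!r} at position {i} (residue {form[i:]!r})"
            )
    if len(phones) == 1:
        return [f"#{phones[0]}#"]
    return [f"#{phones[0]}", *phones[1:-1], f"{phones[-1]}#"]


def uniphones_to_form(phones: Iterable[str]) -> str:
    """Invert :func:`noun_to_uniphones` (strip boundaries, undo digraphs)."""
    out = []
    for p in phones:
        p = p.strip("#")
        out.append(_PHONE_INVERSE.get(p, p))
    return "".join(out)


def build_language_spec() -> LanguageSpec:
    """Construct the full artificial language and check its invariants."""
    nouns = tuple(
        NounEntry(
            form=_NOUNS[k][i],
            noun_class=k,
            frequency=FREQUENCIES[i],
            object_meaning=_OBJECTS[k][i],
            stress_pattern=_STRESS[k],
        )
        for k in (1, 2, 3, 4)
        for i in range(8)
    )
    spec = LanguageSpec(
        nouns=nouns,
        features=FeatureInventory(dict(_MEANING_SETS), dict(_FORM_SETS)),
        markers=MarkerInventory(
            premarkers=dict(_PREMARKERS),
            postmarkers=dict(_POSTMARKERS),
            unspecific_premarker="imo",
            unspecific_postmarker="agi",
        ),
        phone_table=PHONE_TABLE,
        carrier_phrases=_CARRIER_PHRASES,
    )
    _validate(spec)
    return spec


def _validate(spec: LanguageSpec) -> None:
    if len(spec.nouns) != 32:
        raise SpecIntegrityError("expected 32 nouns")
    for k in (1, 2, 3, 4):
        cls = spec.nouns_of_class(k)
        if len(cls) != 8:
            raise SpecIntegrityError(f"class {k} must have 8 nouns")
        if tuple(n.frequency for n in cls) != FREQUENCIES:
            raise SpecIntegrityError(f"class {k} frequencies wrong")
        if sum(n.frequency for n in cls) != 103:
            raise SpecIntegrityError(f"class {k} frequency sum != 103")
    if spec.trials_per_epoch != 412:
        raise SpecIntegrityError("epoch must hold 412 trials")
    objects = [n.object_meaning for n in spec.nouns]
    if len(set(objects)) != 32:
        raise SpecIntegrityError("object meanings must be unique")
    feats = spec.features
    counts = {f: sum(f in s for s in feats.class_to_form_set.values())
              for f in ("O1form", "O2form", "O3form")}
    if counts != {"O1form": 3, "O2form": 2, "O3form": 3}:
        raise SpecIntegrityError(f"overlapping feature counts wrong: {counts}")
    if feats.class_to_form_set[2] != feats.class_to_form_set[4]:
        raise SpecIntegrityError("classes 2 and 4 must share a form set")
    if feats.class_to_meaning_set[3] != feats.class_to_meaning_set[4]:
        raise SpecIntegrityError("classes 3 and 4 must share a meaning set")
    for n in spec.nouns:  # every form must tokenize and round-trip
        if uniphones_to_form(spec.uniphones(n.form)) != n.form:
            raise SpecIntegrityError(f"uniphone round-trip failed for {n.form!r}")


# ---------------------------------------------------------------------------
# Training streams

Marking = Literal["pre", "post"]
Encoding = Literal["sim1", "sim2"]


def noun_token_stream(
    spec: LanguageSpec,
    n_trials: int,
    rng: np.random.Generator,
    sampler: Literal["multiset", "iid"] = "multiset",
) -> list[NounEntry]:
    """Draw the noun-token sequence driving a training run.

    ``multiset`` (default) shuffles the exact 412-token frequency multiset
    per epoch and concatenates epochs, truncating to ``n_trials``; ``iid``
    samples tokens independently with frequency-proportional weights.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if sampler == "iid":
        weights = np.array([n.frequency for n in spec.nouns], dtype=float)
        weights /= weights.sum()
        idx = rng.choice(len(spec.nouns), size=n_trials, p=weights)
        return [spec.nouns[i] for i in idx]
    if sampler != "multiset":
        raise ValueError(f"unknown sampler: {sampler!r}")
    epoch = [n for n in spec.nouns for _ in range(n.frequency)]
    tokens: list[NounEntry] = []
    while len(tokens) < n_trials:
        order = rng.permutation(len(epoch))
        tokens.extend(epoch[i] for i in order)
    return tokens[:n_trials]


def events_from_tokens(
    spec: LanguageSpec,
    tokens: Sequence[NounEntry],
    marking: Marking,
    encoding: Encoding = "sim1",
) -> list[Event]:
    """Encode a noun-token sequence as cue -> outcome learning events.

    Category-level training (``sim1``) swaps roles between marking orders:
    premarking predicts the noun bundle from ``{marker, constant}``,
    postmarking predicts the marker from the noun bundle plus constant.
    Noun-level training (``sim2``) uses form features + uniphones + constant
    as cues and the object meaning as the single outcome in both marking
    conditions (the marking manipulation is a training-schedule manipulation
    there, not an encoding one).
    """
    if marking not in ("pre", "post"):
        raise ValueError(f"unknown marking: {marking!r}")
    if encoding not in ("sim1", "sim2"):
        raise ValueError(f"unknown encoding: {encoding!r}")
    events = []
    for t, noun in enumerate(tokens, start=1):
        marker = MarkerInventory.abstract_marker(noun.noun_class)
        if encoding == "sim1":
            bundle = spec.noun_features(noun)
            if marking == "pre":
                ev = Event(frozenset({marker, CONSTANT_CUE}), bundle, t)
            else:
                ev = Event(bundle | {CONSTANT_CUE}, frozenset({marker}), t)
        else:
            cues = (
                spec.features.class_to_form_set[noun.noun_class]
                | frozenset(spec.uniphones(noun.form))
                | {CONSTANT_CUE}
            )
            ev = Event(cues, frozenset({noun.object_meaning}), t)
        events.append(ev)
    return events


def generate_events(
    spec: LanguageSpec,
    marking: Marking,
    encoding: Encoding,
    n_trials: int,
    seed: int | np.random.Generator,
    sampler: Literal["multiset", "iid"] = "multiset",
) -> list[Event]:
    """Sample a noun-token stream and encode it as training events."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tokens = noun_token_stream(spec, n_trials, rng, sampler=sampler)
    return events_from_tokens(spec, tokens, marking, encoding)


def behavioral_trial_order(spec: LanguageSpec, seed: int | np.random.Generator) -> list[NounEntry]:
    """The pseudorandomized 412-token order of the behavioral training phase.

    28 tokens are first drawn at random from the four highest-frequency nouns
    of every class (112 tokens in total) and shuffled, so that low-frequency
    items cannot appear too early; the remaining 300 tokens are shuffled and
    appended.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    head: list[NounEntry] = []
    tail: list[NounEntry] = []
    for k in (1, 2, 3, 4):
        cls = spec.nouns_of_class(k)
        high = [n for n in cls for _ in range(n.frequency) if n.frequency >= 11]
        pick = rng.choice(len(high), size=28, replace=False)
        chosen = [high[i] for i in sorted(pick)]
        head.extend(chosen)
        remaining = list(high)
        for n in chosen:
            remaining.remove(n)
        tail.extend(remaining)
        tail.extend(n for n in cls for _ in range(n.frequency) if n.frequency < 11)
    head = [head[i] for i in rng.permutation(len(head))]
    tail = [tail[i] for i in rng.permutation(len(tail))]
    return head + tail


# ---------------------------------------------------------------------------
# Event-stream text format (tab-separated Cues/Outcomes/Frequency, labels
# joined with "_" inside a set -- the de-facto discriminative-learning format)


def write_events(events: Sequence[Event], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("Cues\tOutcomes\tFrequency\n")
        for ev in events:
            fh.write(f"{'_'.join(sorted(ev.cues))}\t{'_'.join(sorted(ev.outcomes))}\t1\n")
    return path


def read_events(path: str | Path) -> list[Event]:
    events = []
    with Path(path).open(encoding="utf-8") as fh:
        header = fh.readline()
        if not re.match(r"Cues\tOutcomes(\tFrequency)?\s*$", header):
            raise ValueError(f"unrecognized event-stream header: {header!r}")
        t = 1
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            cues, outcomes = parts[0], parts[1]
            freq = int(parts[2]) if len(parts) > 2 else 1
            for _ in range(freq):
                events.append(Event(frozenset(cues.split("_")), frozenset(outcomes.split("_")), t))
                t += 1
    return events
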