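"""Lexicon construction for transitional-probability speech-stream experiments.

An artificial lexicon pairs eight trisyllabic nonsense "words" with eight
foils built from the same syllables.  Four words are *high-TP*: each of
their 12 syllables occurs in exactly one word, so every internal syllable
transition has probability 1.0.  The other four are *low-TP*: they are
woven from only 4 syllables, each of which occurs in three different words
and in each of the three positions exactly once (a 4x3 Latin rectangle),
so every internal transition has probability 1/3.  Foils recombine the
familiarization syllables into sequences whose adjacent pairs never
occurred together inside a word (design TP = 0).

Two canonical syllabaries (A and B) are shipped verbatim; a seeded solver
can build fresh lexicons from any 12+4 syllable inventory under the same
combinatorial constraints.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LexiconError",
    "SolverError",
    "Word",
    "Foil",
    "Lexicon",
    "Trial",
    "TrialList",
    "TPTable",
    "syllabify",
    "load_canonical_syllabary",
    "build_lexicon",
    "design_tp",
    "design_tp_table",
    "build_foils",
    "build_2afc_trials",
]

HIGH = "high"
LOW = "low"

#: Words occur this many times each in the default familiarization stream;
#: design TPs are token ratios and therefore independent of the value, but
#: the supporting counts scale with it.
DEFAULT_TOKENS_PER_WORD = 60


class LexiconError(ValueError):
    """A lexicon, foil set or trial list violates a design invariant."""


class SolverError(RuntimeError):
    """The constrained search exhausted its budget; reports the constraint."""


def syllabify(item: str) -> tuple[str, ...]:
    """Split a CV-structured string into consecutive two-letter syllables."""
    if len(item) % 2 != 0:
        raise LexiconError(f"{item!r} is not a sequence of CV syllables")
    return tuple(item[i : i + 2] for i in range(0, len(item), 2))


@dataclass(frozen=True)
class Word:
    id: str
    syllables: tuple[str, str, str]
    tp_class: str

    def __post_init__(self) -> None:
        if len(self.syllables) != 3:
            raise LexiconError(f"word {self.id!r} must have exactly 3 syllables")
        if self.tp_class not in (HIGH, LOW):
            raise LexiconError(f"unknown tp_class {self.tp_class!r}")

    @property
    def bigrams(self) -> tuple[tuple[str, str], tuple[str, str]]:
        s = self.syllables
        return ((s[0], s[1]), (s[1], s[2]))


@dataclass(frozen=True)
class Foil:
    id: str
    syllables: tuple[str, str, str]
    tp_class: str
    source_word_id: str

    @property
    def bigrams(self) -> tuple[tuple[str, str], tuple[str, str]]:
        s = self.syllables
        return ((s[0], s[1]), (s[1], s[2]))


def _word_from_string(item: str, tp_class: str) -> Word:
    return Word(id=item, syllables=syllabify(item), tp_class=tp_class)


def _foil_from_string(item: str, tp_class: str, source: str) -> Foil:
    return Foil(id=item, syllables=syllabify(item), tp_class=tp_class,
                source_word_id=source)


@dataclass
class Lexicon:
    """Eight words plus eight foils over a 16-syllable inventory."""

    syllabary_id: str
    words: list[Word]
    foils: list[Foil] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors -------------------------------------------------------
    @property
    def high_words(self) -> list[Word]:
        return [w for w in self.words if w.tp_class == HIGH]

    @property
    def low_words(self) -> list[Word]:
        return [w for w in self.words if w.tp_class == LOW]

    @property
    def high_syllables(self) -> set[str]:
        return {s for w in self.high_words for s in w.syllables}

    @property
    def low_syllables(self) -> set[str]:
        return {s for w in self.low_words for s in w.syllables}

    @property
    def syllables(self) -> set[str]:
        return self.high_syllables | self.low_syllables

    def freq_class(self, syllable: str) -> str:
        """high = unique to one word; low = shared across three words."""
        if syllable in self.high_syllables:
            return HIGH
        if syllable in self.low_syllables:
            return LOW
        raise LexiconError(f"syllable {syllable!r} not in lexicon")

    def word(self, word_id: str) -> Word:
        for w in self.words:
            if w.id == word_id:
                return w
        raise LexiconError(f"unknown word id {word_id!r}")

    def word_bigrams(self) -> set[tuple[str, str]]:
        return {bg for w in self.words for bg in w.bigrams}

    def foil_bigrams(self) -> set[tuple[str, str]]:
        return {bg for f in self.foils for bg in f.bigrams}

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if len(self.words) != 8:
            raise LexiconError(f"expected 8 words, got {len(self.words)}")
        if len(self.high_words) != 4 or len(self.low_words) != 4:
            raise LexiconError("expected 4 high-TP and 4 low-TP words")
        if len({w.id for w in self.words}) != 8:
            raise LexiconError("word ids must be unique")

        high = self.high_syllables
        low = self.low_syllables
        if high & low:
            raise LexiconError(f"syllables shared across classes: {high & low}")
        if len(high) != 12:
            raise LexiconError(f"expected 12 distinct high syllables, got {len(high)}")
        if len(low) != 4:
            raise LexiconError(f"expected 4 distinct low syllables, got {len(low)}")

        # high syllables unique to one word
        seen: dict[str, str] = {}
        for w in self.high_words:
            for s in w.syllables:
                if s in seen:
                    raise LexiconError(
                        f"high syllable {s!r} occurs in both {seen[s]!r} and {w.id!r}")
                seen[s] = w.id

        # low design: each syllable in exactly 3 words, once per position
        incidence: dict[tuple[str, int], int] = {}
        for w in self.low_words:
            for pos, s in enumerate(w.syllables):
                incidence[(s, pos)] = incidence.get((s, pos), 0) + 1
        for s in low:
            for pos in range(3):
                if incidence.get((s, pos), 0) != 1:
                    raise LexiconError(
                        f"low syllable {s!r} must occupy position {pos + 1} exactly once")

        # high-word bigrams are distinct automatically (unique syllables);
        # the 8 low-word bigrams must be checked, so check all 16 at once
        bigrams = [bg for w in self.words for bg in w.bigrams]
        if len(set(bigrams)) != 16:
            raise LexiconError("within-word bigrams must be pairwise distinct")

        if self.foils:
            self._validate_foils()

    def _validate_foils(self) -> None:
        if len(self.foils) != 8:
            raise LexiconError(f"expected 8 foils, got {len(self.foils)}")
        word_bgs = self.word_bigrams()
        clash = self.foil_bigrams() & word_bgs
        if clash:
            raise LexiconError(f"foil bigrams occur within words: {clash}")

        counts: dict[str, int] = {}
        for f in self.foils:
            for s in f.syllables:
                counts[s] = counts.get(s, 0) + 1
        for s in self.high_syllables:
            if counts.get(s, 0) != 1:
                raise LexiconError(
                    f"high syllable {s!r} must occur exactly once across foils")
        for s in self.low_syllables:
            if counts.get(s, 0) != 3:
                raise LexiconError(
                    f"low syllable {s!r} must occur exactly 3 times across foils")

        # every foil syllable sits in a position it occupies in some word
        word_occupancy = {(s, pos) for w in self.words
                          for pos, s in enumerate(w.syllables)}
        for f in self.foils:
            for pos, s in enumerate(f.syllables):
                if (s, pos) not in word_occupancy:
                    raise LexiconError(
                        f"foil {f.id!r}: syllable {s!r} never occupies "
                        f"position {pos + 1} in any word")

        source_ids = {f.source_word_id for f in self.foils}
        if source_ids != {w.id for w in self.words}:
            raise LexiconError("each foil must be associated with a distinct word")
        for f in self.foils:
            if f.tp_class != self.word(f.source_word_id).tp_class:
                raise LexiconError(f"foil {f.id!r} class differs from its source word")

    # -- serialization ---------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for w in self.words:
            rows.append(dict(kind="word", id=w.id, tp_class=w.tp_class,
                             syl1=w.syllables[0], syl2=w.syllables[1],
                             syl3=w.syllables[2], source_word=""))
        for f in self.foils:
            rows.append(dict(kind="foil", id=f.id, tp_class=f.tp_class,
                             syl1=f.syllables[0], syl2=f.syllables[1],
                             syl3=f.syllables[2], source_word=f.source_word_id))
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"syllabary_id": self.syllabary_id,
             "records": self.to_frame().to_dict(orient="records")},
            indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, syllabary_id: str = "custom") -> "Lexicon":
        words = [Word(id=r.id, syllables=(r.syl1, r.syl2, r.syl3), tp_class=r.tp_class)
                 for r in frame[frame["kind"] == "word"].itertuples()]
        foils = [Foil(id=r.id, syllables=(r.syl1, r.syl2, r.syl3),
                      tp_class=r.tp_class, source_word_id=r.source_word)
                 for r in frame[frame["kind"] == "foil"].itertuples()]
        return cls(syllabary_id=syllabary_id, words=words, foils=foils)

    @classmethod
    def from_tsv(cls, path: str | Path, syllabary_id: str = "custom") -> "Lexicon":
        return cls.from_frame(pd.read_csv(path, sep="\t", keep_default_na=False),
                              syllabary_id=syllabary_id)


# ---------------------------------------------------------------------------
# Canonical syllabaries (words and foils as printed, foil listed beside the
# word it is associated with).

_CANONICAL: dict[str, dict[str, list[tuple[str, str]]]] = {
    "A": {
        HIGH: [("tucida", "tumica"), ("bupepo", "bugego"),
               ("modego", "modopo"), ("bibaca", "bitida")],
        LOW: [("dotige", "dobage"), ("tidomi", "tidemi"),
              ("migedo", "mipedo"), ("gemiti", "geciti")],
    },
    "B": {
        HIGH: [("todidu", "tomeco"), ("cegita", "cegube"),
               ("gapabe", "gapita"), ("bomaco", "botedu")],
        LOW: [("pitegu", "pimagu"), ("tepime", "tepame"),
              ("megupi", "megipi"), ("gumete", "gudite")],
    },
}


def load_canonical_syllabary(syllabary_id: str) -> Lexicon:
    """Load one of the two shipped syllabaries (``"A"`` or ``"B"``) verbatim."""
    try:
        table = _CANONICAL[syllabary_id]
    except KeyError:
        raise LexiconError(
            f"unknown syllabary {syllabary_id!r}; expected 'A' or 'B'") from None
    words, foils = [], []
    for tp_class in (HIGH, LOW):
        for word, foil in table[tp_class]:
            words.append(_word_from_string(word, tp_class))
            foils.append(_foil_from_string(foil, tp_class, source=word))
    return Lexicon(syllabary_id=syllabary_id, words=words, foils=foils)


# ---------------------------------------------------------------------------
# Design transitional probabilities


def design_tp(lexicon: Lexicon, x: str, y: str,
              tokens_per_word: int = DEFAULT_TOKENS_PER_WORD) -> float:
    """TP(y | x) over the familiarization design with uniform word frequencies.

    Token counts: each word contributes ``tokens_per_word`` tokens of each of
    its syllables.  Word-final tokens of ``x`` count in the denominator, so
    e.g. a syllable occurring in three low-TP words yields 1/3 for its single
    attested continuation.
    """
    if x not in lexicon.syllables:
        raise LexiconError(f"syllable {x!r} not in lexicon")
    n_x = sum(w.syllables.count(x) for w in lexicon.words) * tokens_per_word
    n_xy = sum(bg == (x, y) for w in lexicon.words for bg in w.bigrams)
    return n_xy * tokens_per_word / n_x


@dataclass
class TPTable:
    """Ordered-bigram transitional probabilities with supporting counts."""

    bigram_counts: dict[tuple[str, str], int]
    antecedent_counts: dict[str, int]

    def probability(self, x: str, y: str) -> float:
        if x not in self.antecedent_counts:
            raise LexiconError(f"antecedent {x!r} has no attested tokens")
        return self.bigram_counts.get((x, y), 0) / self.antecedent_counts[x]

    def continuations(self, x: str) -> dict[str, float]:
        n = self.antecedent_counts.get(x)
        if not n:
            return {}
        return {y: c / n for (a, y), c in self.bigram_counts.items() if a == x}

    def check_normalization(self, atol: float = 1e-9) -> None:
        for x in self.antecedent_counts:
            conts = self.continuations(x)
            if conts and abs(sum(conts.values()) - 1.0) > atol:
                raise LexiconError(f"TPs for antecedent {x!r} do not sum to 1")

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(antecedent=x, continuation=y, count=c,
                     antecedent_count=self.antecedent_counts[x],
                     probability=c / self.antecedent_counts[x])
                for (x, y), c in sorted(self.bigram_counts.items())]
        return pd.DataFrame(rows)


def design_tp_table(lexicon: Lexicon,
                    tokens_per_word: int = DEFAULT_TOKENS_PER_WORD) -> TPTable:
    """Design-level TP table over all within-word bigrams."""
    bigram_counts: dict[tuple[str, str], int] = {}
    antecedent_counts: dict[str, int] = {}
    for w in lexicon.words:
        for s in w.syllables:
            antecedent_counts[s] = antecedent_counts.get(s, 0) + tokens_per_word
        for bg in w.bigrams:
            bigram_counts[bg] = bigram_counts.get(bg, 0) + tokens_per_word
    return TPTable(bigram_counts, antecedent_counts)


# ---------------------------------------------------------------------------
# Seeded lexicon solver


def _low_word_designs(low_syllables: Sequence[str]):
    """All 4x3 Latin rectangles over the 4 low syllables whose 8 internal
    bigrams are pairwise distinct.  Rows are the four low words; each column
    is a permutation of the syllable set, so each syllable occurs in three
    words and once per position."""
    syls = list(low_syllables)
    for col1 in itertools.permutations(syls):
        for col2 in itertools.permutations(syls):
            if any(a == b for a, b in zip(col1, col2)):
                continue
            for col3 in itertools.permutations(syls):
                if any(c in (a, b) for a, b, c in zip(col1, col2, col3)):
                    continue
                words = list(zip(col1, col2, col3))
                bigrams = [bg for w in words for bg in ((w[0], w[1]), (w[1], w[2]))]
                if len(set(bigrams)) == 8:
                    yield words


def build_lexicon(high_syllables: Sequence[str], low_syllables: Sequence[str],
                  seed: int | None = None,
                  syllabary_id: str = "custom") -> Lexicon:
    """Build a fresh lexicon (words + foils) from a 12+4 syllable inventory.

    The 12 high syllables are partitioned into four words; the 4 low
    syllables are arranged into a Latin-rectangle word set with distinct
    internal bigrams.  Deterministic under ``seed``.
    """
    high_syllables = list(high_syllables)
    low_syllables = list(low_syllables)
    if len(set(high_syllables)) != 12:
        raise LexiconError("need 12 distinct high syllables")
    if len(set(low_syllables)) != 4:
        raise LexiconError("need 4 distinct low syllables")
    if set(high_syllables) & set(low_syllables):
        raise LexiconError("high and low syllable sets must be disjoint")

    rng = np.random.default_rng(seed)

    shuffled = list(rng.permutation(high_syllables))
    high_words = [tuple(shuffled[i : i + 3]) for i in range(0, 12, 3)]

    designs = list(_low_word_designs(low_syllables))
    if not designs:  # cannot happen for 4 distinct syllables; guard anyway
        raise SolverError("no bigram-distinct Latin-rectangle design exists "
                          "for the given low syllables")
    low_words = designs[rng.integers(len(designs))]

    words = [Word(id="".join(s), syllables=s, tp_class=HIGH) for s in high_words]
    words += [Word(id="".join(s), syllables=tuple(s), tp_class=LOW)
              for s in low_words]
    lexicon = Lexicon(syllabary_id=syllabary_id, words=words)
    lexicon.foils = build_foils(lexicon, seed=rng.integers(2**31))
    lexicon.validate()
    return lexicon


def _seeded_derangement(items: Sequence, rng: np.random.Generator,
                        max_tries: int = 1000) -> list:
    idx = np.arange(len(items))
    for _ in range(max_tries):
        perm = rng.permutation(idx)
        if not np.any(perm == idx):
            return [items[i] for i in perm]
    raise SolverError("could not find a derangement (final-syllable rotation)")


def build_foils(lexicon: Lexicon, seed: int | None = None) -> list[Foil]:
    """Construct the eight zero-TP foils for a word set.

    Low-word foils keep their word's initial and final syllables and replace
    the medial with a high syllable drawn (bijectively) from the high words'
    medial position.  High-word foils keep their initial, take a low syllable
    as medial, and borrow the final syllable of a *different* high word
    (a derangement over finals).  Each high syllable is used once and each
    low syllable three times across the foil set, mirroring the words'
    frequency-by-position profile, and no foil bigram occurs within any word.
    """
    rng = np.random.default_rng(seed)
    high_words = lexicon.high_words
    low_words = lexicon.low_words

    high_medials = [w.syllables[1] for w in high_words]
    medial_for_low = list(rng.permutation(high_medials))

    low_syls = sorted(lexicon.low_syllables)
    medial_for_high = list(rng.permutation(low_syls))

    deranged_finals = _seeded_derangement([w.syllables[2] for w in high_words], rng)

    foils: list[Foil] = []
    for w, medial in zip(low_words, medial_for_low):
        syls = (w.syllables[0], medial, w.syllables[2])
        foils.append(Foil(id="".join(syls), syllables=syls, tp_class=LOW,
                          source_word_id=w.id))
    for w, medial, final in zip(high_words, medial_for_high, deranged_finals):
        syls = (w.syllables[0], medial, final)
        foils.append(Foil(id="".join(syls), syllables=syls, tp_class=HIGH,
                          source_word_id=w.id))

    word_bgs = lexicon.word_bigrams()
    clash = {bg for f in foils for bg in f.bigrams} & word_bgs
    if clash:  # impossible for class-mixed bigrams; guards degenerate input
        raise SolverError(f"foil bigram(s) also occur within words: {clash}")
    return foils


# ---------------------------------------------------------------------------
# 2-AFC trial construction


@dataclass(frozen=True)
class Trial:
    word_id: str
    foil_id: str
    order: str  # "word-first" | "foil-first"
    block: int  # 1 | 2


@dataclass
class TrialList:
    """Sixteen word/foil recognition trials in two blocks of eight.

    Each word appears once per block against two distinct same-class foils;
    within each block half of the trials (two high-TP and two low-TP words)
    are word-first, with the assignment reversed in the other block.
    """

    trials: list[Trial]
    fixation_ms: int = 1000
    isi_ms: int = 500
    timeout_ms: int = 10_000

    def validate(self, lexicon: Lexicon) -> None:
        if len(self.trials) != 16:
            raise LexiconError(f"expected 16 trials, got {len(self.trials)}")
        for block in (1, 2):
            block_trials = [t for t in self.trials if t.block == block]
            if len(block_trials) != 8:
                raise LexiconError(f"block {block} must contain 8 trials")
            word_ids = [t.word_id for t in block_trials]
            if len(set(word_ids)) != 8:
                raise LexiconError(f"each word must appear once in block {block}")
            for tp_class in (HIGH, LOW):
                first = sum(t.order == "word-first" for t in block_trials
                            if lexicon.word(t.word_id).tp_class == tp_class)
                if first != 2:
                    raise LexiconError(
                        f"block {block}: {tp_class}-TP word-first count {first} != 2")
        for w in lexicon.words:
            foil_ids = {t.foil_id for t in self.trials if t.word_id == w.id}
            if len(foil_ids) != 2:
                raise LexiconError(
                    f"word {w.id!r} must be paired with two distinct foils")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(t) for t in self.trials])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_2afc_trials(lexicon: Lexicon, seed: int | None = None) -> TrialList:
    """Build the 16-trial two-alternative forced-choice test list."""
    if len(lexicon.foils) != 8:
        raise LexiconError("lexicon must carry 8 foils to build trials")
    rng = np.random.default_rng(seed)

    trials: list[Trial] = []
    for tp_class in (HIGH, LOW):
        words = [w for w in lexicon.words if w.tp_class == tp_class]
        foils = [f for f in lexicon.foils if f.tp_class == tp_class]
        foils = list(rng.permutation(np.array(foils, dtype=object)))
        halves = {1: foils[:2], 2: foils[2:]}
        # two of the four words word-first in block 1, reversed in block 2
        word_first_b1 = set(
            rng.choice([w.id for w in words], size=2, replace=False))
        for block in (1, 2):
            block_foils = halves[block]
            for i, w in enumerate(rng.permutation(np.array(words, dtype=object))):
                f = block_foils[i % 2]
                first_b1 = w.id in word_first_b1
                word_first = first_b1 if block == 1 else not first_b1
                trials.append(Trial(word_id=w.id, foil_id=f.id,
                                    order="word-first" if word_first else "foil-first",
                                    block=block))

    by_block: list[Trial] = []
    for block in (1, 2):
        block_trials = [t for t in trials if t.block == block]
        by_block.extend(rng.permutation(np.array(block_trials, dtype=object)))
    out = TrialList(trials=list(by_block))
    out.validate(lexicon)
    return out
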