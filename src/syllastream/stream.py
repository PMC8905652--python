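"""Constrained familiarization-stream generation and timeline construction.

The familiarization stream presents each of the eight words 60 times (10
repetitions per block over 6 blocks, 480 word tokens) under two adjacency
constraints, enforced across block joins as well: a word never follows
itself, and a word never follows a word whose final syllable matches its
own initial syllable (which would locally recreate a within-word bigram at
a boundary).  Under those constraints every high-TP word has 7 legal
successors and every low-TP word 6, so the word-level across-boundary
transitional probabilities summarize to 1/7 ~ 0.14 and 1/6 ~ 0.17.

Syllables last 300 ms and are followed by a 50 ms silent gap, giving a
1,050 ms word period and an 8.4 min stream.  A fraction of syllable tokens
(15% by default) carry a superimposed chirp for the attention cover task,
balanced across words and syllable positions.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .lexicon import HIGH, LOW, Lexicon, TPTable

__all__ = [
    "StreamError",
    "WordSequence",
    "ChirpAssignment",
    "Timeline",
    "generate_word_sequence",
    "audit_word_sequence",
    "word_level_boundary_tp",
    "token_tp_table",
    "assign_chirps",
    "build_timeline",
    "render_wav",
]

SYLLABLE_MS = 300
GAP_MS = 50


class StreamError(RuntimeError):
    """Stream generation failed or a sequence violates its constraints."""


@dataclass
class WordSequence:
    """An ordered word-token sequence with its block structure."""

    lexicon: Lexicon
    word_ids: list[str]
    blocks: list[int]  # 1-based block index per position
    reps_per_block: int = 10
    n_blocks: int = 6

    def __len__(self) -> int:
        return len(self.word_ids)

    def syllable_tokens(self) -> list[tuple[str, str, int]]:
        """Flattened (syllable, word_id, position 1-3) token sequence."""
        out = []
        for wid in self.word_ids:
            for pos, s in enumerate(self.lexicon.word(wid).syllables, start=1):
                out.append((s, wid, pos))
        return out


def _forbidden_successors(lexicon: Lexicon) -> dict[str, set[str]]:
    """Successors excluded after each word: itself, plus any word whose
    initial syllable equals the word's final syllable."""
    forbidden: dict[str, set[str]] = {}
    for w in lexicon.words:
        bad = {w.id}
        for v in lexicon.words:
            if v.syllables[0] == w.syllables[2]:
                bad.add(v.id)
        forbidden[w.id] = bad
    return forbidden


def legal_successors(lexicon: Lexicon, word_id: str) -> set[str]:
    """Words allowed to follow ``word_id`` under the adjacency constraints."""
    return {w.id for w in lexicon.words} - _forbidden_successors(lexicon)[word_id]


def generate_word_sequence(lexicon: Lexicon, reps_per_block: int = 10,
                           n_blocks: int = 6, seed: int | None = None,
                           max_restarts: int = 50,
                           max_backtracks: int = 20_000) -> WordSequence:
    """Generate a constrained pseudo-random word sequence.

    Randomized depth-first search with backtracking fills each block with
    exact per-word counts; after ``max_backtracks`` dead ends the whole
    attempt restarts with fresh randomness (still derived from ``seed``).
    """
    rng = np.random.default_rng(seed)
    ids = [w.id for w in lexicon.words]
    forbidden = _forbidden_successors(lexicon)
    total = len(ids) * reps_per_block * n_blocks

    for _ in range(max_restarts):
        seq: list[str] = []
        counts = [{wid: reps_per_block for wid in ids} for _ in range(n_blocks)]
        # stack of candidate iterators (lists) per position
        stack: list[list[str]] = []
        backtracks = 0

        def candidates(pos: int) -> list[str]:
            block = pos // (len(ids) * reps_per_block)
            prev = seq[-1] if seq else None
            cand = [wid for wid in ids if counts[block][wid] > 0
                    and (prev is None or wid not in forbidden[prev])]
            return list(rng.permutation(cand))

        stack.append(candidates(0))
        while stack:
            if not stack[-1]:
                stack.pop()
                if seq:
                    wid = seq.pop()
                    counts[len(seq) // (len(ids) * reps_per_block)][wid] += 1
                backtracks += 1
                if backtracks > max_backtracks:
                    break
                continue
            wid = stack[-1].pop()
            block = len(seq) // (len(ids) * reps_per_block)
            counts[block][wid] -= 1
            seq.append(wid)
            if len(seq) == total:
                blocks = [i // (len(ids) * reps_per_block) + 1
                          for i in range(total)]
                out = WordSequence(lexicon=lexicon, word_ids=seq, blocks=blocks,
                                   reps_per_block=reps_per_block,
                                   n_blocks=n_blocks)
                audit_word_sequence(out)
                return out
            stack.append(candidates(len(seq)))
    raise StreamError(
        "could not generate a constraint-satisfying sequence "
        f"({max_restarts} restarts exhausted); the lexicon's adjacency "
        "constraints may be unsatisfiable at these counts")


def audit_word_sequence(seq: WordSequence) -> None:
    """Brute-force constraint scan, independent of the generator's bookkeeping.

    Checks exact per-block word counts, no immediate word repetition, and no
    final-syllable/initial-syllable match at any transition (block joins
    included).  Raises :class:`StreamError` on any violation.
    """
    lex = seq.lexicon
    per_block = len(lex.words) * seq.reps_per_block
    if len(seq.word_ids) != per_block * seq.n_blocks:
        raise StreamError("sequence length does not match reps x blocks")
    for b in range(seq.n_blocks):
        chunk = seq.word_ids[b * per_block : (b + 1) * per_block]
        for w in lex.words:
            n = chunk.count(w.id)
            if n != seq.reps_per_block:
                raise StreamError(
                    f"word {w.id!r} occurs {n}x in block {b + 1}, "
                    f"expected {seq.reps_per_block}")
    for i in range(len(seq.word_ids) - 1):
        a, b = seq.word_ids[i], seq.word_ids[i + 1]
        if a == b:
            raise StreamError(f"word {a!r} repeats at position {i}")
        if lex.word(a).syllables[2] == lex.word(b).syllables[0]:
            raise StreamError(
                f"boundary bigram recreated at position {i}: {a!r} -> {b!r}")
    expected_blocks = [i // per_block + 1 for i in range(len(seq.word_ids))]
    if seq.blocks != expected_blocks:
        raise StreamError("block labels inconsistent with position")


def word_level_boundary_tp(seq: WordSequence, tp_class: str) -> float:
    """Across-boundary TP summary for one word class.

    For each word A of the class, empirical successor probabilities
    ``count(A -> B) / count(A non-final)`` are averaged (unweighted) over
    A's *legal* successors; the summary is the mean over the class's words.
    On a default stream this equals 1/7 (high) or 1/6 (low) up to the single
    stream-final token.
    """
    lex = seq.lexicon
    words = [w for w in lex.words if w.tp_class == tp_class]
    if not words:
        raise StreamError(f"no words of class {tp_class!r}")
    ids = seq.word_ids
    per_word = []
    for w in words:
        legal = legal_successors(lex, w.id)
        n_nonfinal = sum(1 for wid in ids[:-1] if wid == w.id)
        if n_nonfinal == 0:
            raise StreamError(f"word {w.id!r} has no transitions")
        probs = []
        for succ in legal:
            n_ab = sum(1 for i in range(len(ids) - 1)
                       if ids[i] == w.id and ids[i + 1] == succ)
            probs.append(n_ab / n_nonfinal)
        per_word.append(float(np.mean(probs)))
    return float(np.mean(per_word))


def token_tp_table(seq: WordSequence) -> TPTable:
    """Empirical syllable-token TP table over the flattened stream."""
    tokens = [t[0] for t in seq.syllable_tokens()]
    bigram_counts: dict[tuple[str, str], int] = {}
    antecedent_counts: dict[str, int] = {}
    for x, y in zip(tokens[:-1], tokens[1:]):
        bigram_counts[(x, y)] = bigram_counts.get((x, y), 0) + 1
        antecedent_counts[x] = antecedent_counts.get(x, 0) + 1
    table = TPTable(bigram_counts, antecedent_counts)
    table.check_normalization()
    return table


@dataclass
class ChirpAssignment:
    """Chirp flags per syllable token, balanced over (word, position) cells."""

    flags: np.ndarray  # bool, one per syllable token
    rate: float
    per_cell: dict[tuple[str, int], int]  # (word_id, position) -> n flags

    @property
    def total(self) -> int:
        return int(self.flags.sum())


def assign_chirps(seq: WordSequence, rate: float = 0.15,
                  total: int | None = None,
                  seed: int | None = None) -> ChirpAssignment:
    """Flag syllable tokens for the chirp cover task.

    The total (``rate`` x number of syllable tokens unless overridden) is
    split as evenly as possible over the (word id x position) cells; any
    remainder is dealt round-robin over a seeded cell order, so all words
    receive chirps at all positions whenever the total allows.
    """
    if total is None:
        if not 0 < rate <= 1:
            raise StreamError("chirp rate must be in (0, 1]")
        total = round(rate * 3 * len(seq))
    if total < 0 or total > 3 * len(seq):
        raise StreamError("chirp total out of range")

    rng = np.random.default_rng(seed)
    ids = [w.id for w in seq.lexicon.words]
    cells = [(wid, pos) for wid in ids for pos in (1, 2, 3)]
    base, rem = divmod(total, len(cells))
    order = list(rng.permutation(len(cells)))
    quotas = {cell: base for cell in cells}
    for k in order[:rem]:
        quotas[cells[k]] += 1

    # token index of (occurrence i of word w, position p)
    occurrences: dict[str, list[int]] = {wid: [] for wid in ids}
    for i, wid in enumerate(seq.word_ids):
        occurrences[wid].append(i)

    flags = np.zeros(3 * len(seq), dtype=bool)
    for (wid, pos), q in quotas.items():
        occ = occurrences[wid]
        if q > len(occ):
            raise StreamError(
                f"cannot place {q} chirps on {len(occ)} tokens of {wid!r}")
        chosen = rng.choice(len(occ), size=q, replace=False)
        for k in chosen:
            flags[occ[k] * 3 + (pos - 1)] = True
    return ChirpAssignment(flags=flags, rate=total / (3 * len(seq)),
                           per_cell=quotas)


@dataclass
class Timeline:
    """Millisecond-resolved syllable event table for one stream."""

    events: pd.DataFrame  # onset_ms, duration_ms, syllable, word_id, position,
    #                       block, half, tp_class, chirp, word_onset
    syllable_ms: int = SYLLABLE_MS
    gap_ms: int = GAP_MS

    @property
    def word_period_ms(self) -> int:
        return 3 * (self.syllable_ms + self.gap_ms)

    @property
    def total_duration_ms(self) -> int:
        n_words = int(self.events["word_onset"].sum())
        return n_words * self.word_period_ms

    def word_onsets(self) -> pd.DataFrame:
        return self.events[self.events["word_onset"]].reset_index(drop=True)

    def to_tsv(self, path: str | Path | None = None) -> str:
        buf = io.StringIO()
        self.events.to_csv(buf, sep="\t", index=False)
        payload = buf.getvalue()
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_tsv(cls, path: str | Path, syllable_ms: int = SYLLABLE_MS,
                 gap_ms: int = GAP_MS) -> "Timeline":
        return cls(events=pd.read_csv(path, sep="\t"),
                   syllable_ms=syllable_ms, gap_ms=gap_ms)


def build_timeline(seq: WordSequence, chirps: ChirpAssignment | None = None,
                   syllable_ms: int = SYLLABLE_MS,
                   gap_ms: int = GAP_MS) -> Timeline:
    """Lay the word sequence out in time: 300 ms syllables, each followed by
    a 50 ms gap (3 x 350 = 1,050 ms per word)."""
    lex = seq.lexicon
    period = syllable_ms + gap_ms
    half_split = seq.n_blocks // 2
    rows = []
    token = 0
    for i, (wid, block) in enumerate(zip(seq.word_ids, seq.blocks)):
        word = lex.word(wid)
        for pos, s in enumerate(word.syllables, start=1):
            rows.append(dict(
                onset_ms=i * 3 * period + (pos - 1) * period,
                duration_ms=syllable_ms,
                syllable=s,
                word_id=wid,
                position=pos,
                block=block,
                half=1 if block <= half_split else 2,
                tp_class=word.tp_class,
                chirp=bool(chirps.flags[token]) if chirps is not None else False,
                word_onset=pos == 1,
            ))
            token += 1
    events = pd.DataFrame(rows)
    if not events["onset_ms"].is_monotonic_increasing:
        raise StreamError("event onsets must be strictly increasing")
    return Timeline(events=events, syllable_ms=syllable_ms, gap_ms=gap_ms)


# ---------------------------------------------------------------------------
# Audio rendering


def _syllable_frequencies(syllables: Sequence[str]) -> dict[str, float]:
    # distinct fixed tones, semitone-spaced from 220 Hz
    return {s: 220.0 * 2 ** (i / 12)
            for i, s in enumerate(sorted(set(syllables)))}


def render_wav(timeline: Timeline, out: str | Path,
               sample_rate: int = 44_100, amplitude: float = 0.4,
               chirp_amplitude: float = 0.3) -> np.ndarray:
    """Render the stream as a mono PCM-16 WAV file.

    Each syllable becomes a fixed-frequency 300 ms tone (distinct tone per
    syllable label, 10 ms cosine ramps); chirp-flagged syllables carry a
    superimposed 0.1 s sawtooth sweep from 450 to 1,450 Hz; gaps are digital
    silence.  Returns the float waveform for inspection.
    """
    from scipy.io import wavfile
    from scipy.signal import sawtooth

    events = timeline.events
    freqs = _syllable_frequencies(events["syllable"])
    n_total = int(round(timeline.total_duration_ms / 1000 * sample_rate))
    wave = np.zeros(n_total)

    n_syl = int(round(timeline.syllable_ms / 1000 * sample_rate))
    t = np.arange(n_syl) / sample_rate
    ramp_n = int(0.01 * sample_rate)
    env = np.ones(n_syl)
    if ramp_n:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
        env[:ramp_n] = ramp
        env[-ramp_n:] = ramp[::-1]

    n_chirp = int(0.1 * sample_rate)
    tc = np.arange(n_chirp) / sample_rate
    # linear 450 -> 1450 Hz sweep; phase is the integral of the frequency
    phase = 2 * np.pi * (450 * tc + 0.5 * (1450 - 450) / 0.1 * tc**2)
    chirp = chirp_amplitude * sawtooth(phase)

    for row in events.itertuples():
        start = int(round(row.onset_ms / 1000 * sample_rate))
        tone = amplitude * np.sin(2 * np.pi * freqs[row.syllable] * t) * env
        wave[start : start + n_syl] += tone
        if row.chirp:
            wave[start : start + n_chirp] += chirp

    peak = np.max(np.abs(wave))
    if peak > 1:
        wave = wave / peak
    wavfile.write(str(out), sample_rate, (wave * 32767).astype(np.int16))
    return wave
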