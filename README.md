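# syllastream

Design, simulation and analysis of auditory statistical-learning
experiments built on transitional-probability speech streams, with an
EEG/ERP analysis pipeline and the behavioral statistics that go with it.

## The problem

In the triplet paradigm of auditory statistical learning (aSL), listeners
hear a continuous stream of trisyllabic nonsense "words" with no acoustic
cues to word boundaries; the only segmentation cue is the transitional
probability (TP) between syllables, TP(y|x) = P(next = y | current = x).
Within-word TPs are high by design; TPs across word boundaries are low.
Learning is probed behaviorally with a two-alternative forced choice
(2-AFC) between words and zero-TP foils, and neurally through
word-onset-locked ERPs (N100 and N400 components) recorded during
familiarization.

This package builds every piece of such an experiment and its analysis:

* **lexicon** — eight words per syllabary: four *high-TP* words
  (12 syllables unique to one word each, internal TP = 1.00) and four
  *low-TP* words woven from 4 shared syllables in a Latin-rectangle
  design (each syllable in three words, once per position, internal
  TP = 0.33); eight foils whose adjacent syllable pairs never occur
  within any word (TP = 0); and the 16-trial 2-AFC list. The two
  canonical syllabaries ship verbatim; a seeded solver builds fresh ones.
* **stream** — constrained pseudo-random familiarization streams (each
  word 10× per block over 6 blocks; no immediate repetition; no
  final/initial syllable match at a boundary), giving across-boundary
  word-level TPs of 1/7 ≈ 0.14 (high) and 1/6 ≈ 0.17 (low); millisecond
  timelines (300 ms syllables + 50 ms gaps = 1,050 ms per word, 8.4 min
  per stream); balanced chirp-flag assignment for the attention cover
  task; WAV rendering.
* **synthdata** — synthetic 2-AFC scores (beta-binomial over 8 trials
  per word class, calibrated to the reference study's cell means/SDs)
  and continuous 512 Hz EEG with injected N100/N400-like deflections,
  per-subject random effects, Gaussian noise and occasional >100 µV
  artifacts.
* **erp** — mastoid re-referencing, zero-phase 0.1–30 Hz Butterworth
  band-pass, epoching from −300 to 1,200 ms with −300..0 ms baseline,
  ±100 µV artifact rejection, the two-thirds per-condition inclusion
  rule, condition averaging, and ROI/window mean-amplitude extraction.
* **stats** — one-sample t-tests against 50% chance, repeated-measures
  and mixed ANOVA with Greenhouse–Geisser correction (SPSS-style
  unweighted-means Type III partitioning for unbalanced groups), partial
  eta squared ηp² = F·df1/(F·df1 + df2), observed power under the
  noncentral F with λ = F·df1, and Bonferroni-adjusted pairwise tests.
* **workflow** — YAML configuration, seed propagation, and an
  end-to-end `reproduce` run producing a machine-readable report.

## Worked example

```python
from syllastream import lexicon as lx, stream as sm, stats as st

lexicon = lx.load_canonical_syllabary("A")
print(lx.design_tp(lexicon, "tu", "ci"))   # 1.0   (high-TP internal bigram)
print(lx.design_tp(lexicon, "do", "ti"))   # 0.3333...  (60 dotige / 180 do)
print(lx.design_tp(lexicon, "do", "ba"))   # 0.0   (foil bigram)

seq = sm.generate_word_sequence(lexicon, seed=1)   # 480 word tokens
print(sm.word_level_boundary_tp(seq, "high"))      # 0.14285714  -> 0.14
print(sm.word_level_boundary_tp(seq, "low"))       # 0.16666666  -> 0.17

timeline = sm.build_timeline(seq, sm.assign_chirps(seq, rate=0.15, seed=2))
print(timeline.word_period_ms, timeline.total_duration_ms)  # 1050 504000

res = st.one_sample_t_from_summary(mean=65.5, sd=20.08, n=21, mu=50.0)
print(round(res.t, 3), round(res.p, 4))            # 3.537 0.002
```

The boundary-TP summaries are exact consequences of the adjacency
constraints: a high-TP word has 7 legal successors and a low-TP word 6,
so the unweighted mean successor probability is 1/7 and 1/6 on any valid
stream. The t statistic reproduces the explicit-task low-TP result of
the reference behavioral table from its printed mean and SD.

An end-to-end run (design → stream → simulate → ERP → stats → report):

```bash
syllastream reproduce --seed 1 --out out/
```

## Layout

```
src/syllastream/   lexicon, stream, synthdata, erp, stats, workflow, cli
tests/             pytest suite (unit, property and acceptance tests)
scripts/           acceptance.py
docs/methods.md    models, conventions and design choices in detail
```
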