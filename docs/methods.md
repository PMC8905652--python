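# Methods

This note records the models, conventions and numerical choices behind
the package, and what its synthetic data can and cannot establish.

## Lexicon design

A syllabary holds 16 CV syllables. Four **high-TP words** partition 12
of them (each syllable unique to one word and one position), so every
internal transition has design TP 1.00. Four **low-TP words** are built
from the remaining 4 syllables as a 4×3 Latin rectangle: each word omits
one syllable, each syllable occurs once per serial position, and the 8
internal bigrams are pairwise distinct. Each low syllable therefore
occurs in three words, and with uniform word frequencies its single
attested continuation from any given word has TP 60/180 = 1/3.

Design TPs are token ratios, TP(y|x) = tokens(x→y) / tokens(x), with
word-final tokens of x counted in the denominator. Word frequency is
fixed at 60 tokens per word (the default stream's value) but
parameterized; TP values are invariant to it.

**Foils.** The foil rules are the ones consistent with the canonical
word/foil tables. Low-word foils keep their word's initial and final
syllables and replace the medial with a high syllable drawn bijectively
from the high words' medial position. High-word foils keep their
initial, take a low syllable (position-2-compatible) as medial, and
borrow the final of a *different* high word (a derangement over finals).
This reproduces the canonical frequency profile — each high syllable
once, each low syllable three times across the foil set, every foil
syllable in a position it occupies in some word — and guarantees zero-TP
internal bigrams, since every foil bigram mixes frequency classes while
every word bigram is class-pure. The canonical foils are also loadable
verbatim, so analyses never depend on the solver.

**2-AFC list.** 16 trials in two blocks of eight; each word appears once
per block against two distinct same-class foils (disjoint foil halves per
block); within each block two high-TP and two low-TP words are
word-first, reversed in the other block; trial order is shuffled within
block. Timing constants: 1,000 ms fixation, 500 ms ISI, 10 s timeout.

## Stream construction

Each word appears exactly 10 times per block across 6 blocks (480
tokens, 60 per word). Two adjacency constraints hold everywhere,
including across block joins (blocks are contiguous audio): no immediate
word repetition, and no transition in which the next word begins with
the current word's final syllable. Generation is randomized depth-first
search with backtracking and full restart after a bounded number of dead
ends; every emitted sequence is re-audited by an independent brute-force
scan. Under these constraints each high-TP word has 7 legal successors
and each low-TP word 6 (it additionally excludes the word starting with
its final syllable), so the word-level boundary TP summary — the
unweighted mean of empirical successor probabilities over legal
successors, averaged within class — equals 1/7 and 1/6 exactly up to the
single stream-final token.

Empirical syllable-token TPs are audited separately: within-word
high-TP bigrams stay at 1.0 (high finals are unique, so no boundary can
recreate them), while low-TP internal bigrams exceed 1/3 on a real
stream (≈0.39) because boundary coincidences add mass.

**Timing.** Every syllable lasts 300 ms and is followed by a 50 ms
silent gap — three gaps per word, because 3×(300+50) = 1,050 ms matches
the word period, whereas gaps only *between* syllables (1,000 ms) would
not. Total stream: 480 × 1,050 ms = 504,000 ms = 8.4 min (1.4 min per
block).

**Chirps.** The cover-task chirp flags default to 15% of the 1,440
syllable tokens (216), split evenly over the 24 (word × position) cells
(9 each) so every word is flagged at every position; remainders of
non-divisible totals are dealt round-robin over a seeded cell order.
The reference description is internally inconsistent about the total
(15% of syllables = 216, but detections are reported "out of 144"), so
an explicit `total` override (e.g. 144 → 6 per cell) is supported and
neither value is asserted as ground truth. Chirp adjacency is left
unconstrained. Audio rendering assigns each syllable a fixed semitone-
spaced tone (a deliberate synthetic stand-in for recorded syllables) and
superimposes a 0.1 s sawtooth sweep from 450 to 1,450 Hz on flagged
syllables.

## Synthetic behavior

Per subject × task × word class, the number correct out of 8 trials is
beta-binomial: p_i ~ Beta with the cell's mean accuracy and intra-class
correlation ρ, k ~ Binomial(8, p_i). Default cells are calibrated to the
reference study's observed means and SDs (adults n=21, children n=20
after exclusions), with ρ solved from the observed between-subject SD.
One cell (children, implicit, high-TP) is slightly *under*-dispersed
relative to a binomial, which no beta-binomial can represent; its ρ
clamps to 0 and its simulated SD is ~0.5 points high. Scores are
multiples of 12.5 by construction. Cells are drawn independently across
tasks and classes; real subjects likely correlate across cells, so
between-cell covariance is not emulated.

## Synthetic EEG

Continuous recordings (default 512 Hz, 15 scalp channels covering the
canonical ROIs plus mastoids M1/M2, units µV) are white Gaussian noise
plus Gaussian-in-time negative deflections injected at every word onset:

* **N100**: peak 100 ms, temporal SD 25 ms, fronto-central weighting;
* **N400**: peak 400 ms (adults) / 450 ms (children, mirroring the
  later analysis window), temporal SD 70 ms, central weighting.

Condition amplitudes (task × word type × half, in µV) are simulation
parameters, not observed values; defaults inject a larger N400 for
high- than low-TP words (3 vs 1 µV) and a larger N100 in the second
half (3 vs 2 µV). Each subject adds a per-component N(0, 1 µV) random
amplitude offset. A configurable fraction of word epochs (default 0.15,
a calibration choice) receives a 100 ms, 150 µV square pulse on one
random scalp channel to exercise the rejection path. The injected
amplitude maps onto a measured ROI window mean through the template's
window average (≈0.92 for the N400 defaults), which the tests compute in
closed form.

Not emulated: 1/f and line noise, ocular/muscle components, volume
conduction and channel covariance, latency jitter, habituation. Passing
tests therefore establish that the *pipeline* is unbiased and correctly
calibrated under its assumed signal model, not that the pipeline is
robust to every property of real recordings.

## ERP pipeline conventions

* Re-reference: subtract the algebraic mastoid mean sample-wise.
* Filter: Butterworth band-pass 0.1–30 Hz, order 4 per pass, applied
  forward–backward (`sosfiltfilt`), i.e. zero-phase with squared
  magnitude response.
* Epochs: −300..1,200 ms around word onset; 0 ms is the word-onset
  sample; epoch length = round(1.5 s × rate) samples (768 at 512 Hz).
  Baseline: subtract the per-channel mean over −300..0 ms, bounds
  inclusive at sample resolution. Events lacking full context are
  dropped with a logged warning.
* Rejection: an epoch is excluded iff any channel at any sample of the
  baseline-corrected epoch *strictly* exceeds ±100 µV.
* Inclusion: a participant is kept iff every task × word-type × half
  cell retains at least ⌈(2/3) × cell size⌉ epochs.
* Measurement windows: N100 80–120 ms (both groups); N400 350–450 ms
  (adults) / 400–500 ms (children), bounds inclusive. Canonical ROIs:
  fronto-central {F1,Fz,F2,FC1,FCz,FC2,C1,Cz,C2}, frontal
  {AF3,AFz,AF4,F1,Fz,F2,FC1,FCz,FC2}, central
  {FC1,FCz,FC2,C1,Cz,C2,CP1,CPz,CP2}. ROIs are explicit configuration
  (the reference analysis chose them where amplitudes were maximal, a
  data-driven step this package does not re-derive).

## Statistics conventions

* One-sample t against 50% chance, two-tailed, SD with n−1; zero
  variance returns t = ±∞ with p = 0 (flagged convention).
* Repeated-measures/mixed ANOVA uses the classical univariate approach:
  each within effect is projected onto orthonormal within-cell
  contrasts and tested against its subject × effect error stratum.
  With unequal group sizes, within-effect sums of squares use
  unweighted (Type III-equivalent) marginal means — the convention
  under which the reference marginals (58.1% adults, 58.8% explicit)
  are exact — while the one-way between effect is the standard
  partition. Verified against R `car::Anova(type = 3)` and, on balanced
  designs, against `pingouin`.
* Greenhouse–Geisser ε comes from the pooled within-group covariance of
  the contrast scores, clipped to [1/(k−1), 1]; two-level factors have
  ε = 1 identically, so GG correction is moot in the all-two-level
  designs here but implemented generally.
* ηp² = F·df1/(F·df1 + df2) ≡ SS_effect/(SS_effect + SS_error).
* Observed power: P(F′(df1, df2, λ) > F_crit(α)) with λ = F·df1 at
  α = 0.05 — the convention that reproduces the reference values
  (e.g. F(1,39) = 4.791 → ηp² = 0.109, power = 0.569). λ = 0 returns α
  directly (scipy's noncentral F is unreliable at zero noncentrality).
* Bonferroni: p → min(1, m·p).
* All reported p-values are two-tailed. One printed reference t/p pair
  (implicit low-TP adults) is not reproducible from its summary cells
  under any standard convention and is treated as a likely typo.

## Calibration problem sizes

The pipeline-level calibration properties run on a scaled-down but
structurally complete experiment chosen as the package's standard
calibration harness: 64 Hz sampling, 2 word repetitions per block
(96 word tokens, ~101 s), the 9-channel central ROI plus mastoids, one
N400 component. Type-I calibration: 500 replicates × 6 subjects with no
injected condition difference; the word-type effect rejects at 5% ± 2 SE.
Recovery: 200 replicates × 4 subjects with a 2 µV injected N400
difference; the mean recovered delta (after dividing by the closed-form
window gain) is within 5% of truth. The default `reproduce` run keeps
the full-size stream and behavioral groups but simulates 3 EEG subjects
per group; all sizes are configurable.

## Known limitations

* The stream generator assumes the standard 8-word lexicon structure;
  severely degenerate custom lexicons can make the adjacency
  constraints unsatisfiable, which is reported, not silently relaxed.
* ICA-based ocular correction is out of scope; threshold rejection is
  the only artifact path, matching the synthetic data's artifact model.
* The four counterbalancing material lists of the reference design are
  not reconstructed (their construction is undocumented); syllabary
  assignment to tasks is configurable instead.
* `mixed_anova` supports one between-subject factor.
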