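"""Synthetic behavioral and EEG data with the structure the analyses assume.

Nothing here claims biophysical realism: the generator exists so that the
entire downstream pipeline (epoching, rejection, inclusion, ROI
measurement, ANOVA) is exercised end-to-end with known ground truth.

* 2-AFC behavior: per-subject percent-correct scores over 8 trials per
  word class, drawn from a beta-binomial whose cell means and
  between-subject dispersions default to the reference study's observed
  cells (adults n=21 / children n=20 after exclusions).
* EEG: continuous multichannel noise at 512 Hz into which Gaussian-in-time
  N100/N400-like negative deflections are injected at every word onset,
  with condition-dependent amplitudes, a per-subject random amplitude
  offset, and an occasional large (>100 uV) artifact so the rejection path
  is exercised.
* Chirp detection: Bernoulli hits/false alarms over the chirp assignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .erp import DEFAULT_MONTAGE, CANONICAL_ROIS, ContinuousEEG
from .stream import ChirpAssignment, Timeline

__all__ = [
    "BehaviorCell",
    "BehaviorProfile",
    "default_behavior_profile",
    "simulate_behavior",
    "ComponentTemplate",
    "EffectSpec",
    "default_effect_spec",
    "simulate_eeg",
    "simulate_subject_eeg",
    "simulate_chirp_detection",
    "TABLE2_CELLS",
]

N_TRIALS_PER_CLASS = 8

#: Reference 2-AFC cells: (group, task, tp_class) -> (mean %, SD %).
#: These calibrate the default behavior profile and provide the printed
#: inputs for marginal/t-test recomputation.
TABLE2_CELLS: dict[tuple[str, str, str], tuple[float, float]] = {
    ("children", "implicit", "high"): (50.1, 17.17),
    ("children", "implicit", "low"): (45.1, 19.16),
    ("children", "explicit", "high"): (55.7, 15.43),
    ("children", "explicit", "low"): (52.5, 17.54),
    ("adults", "implicit", "high"): (47.1, 17.68),
    ("adults", "implicit", "low"): (58.4, 14.46),
    ("adults", "explicit", "high"): (61.4, 20.12),
    ("adults", "explicit", "low"): (65.5, 20.08),
}

DEFAULT_GROUP_N = {"adults": 21, "children": 20}


@dataclass(frozen=True)
class BehaviorCell:
    """True accuracy and between-subject dispersion for one design cell."""

    accuracy: float  # in [0, 1]
    rho: float  # beta-binomial intra-class correlation, in [0, 1)

    def __post_init__(self) -> None:
        if not 0 <= self.accuracy <= 1:
            raise ValueError(f"accuracy {self.accuracy} outside [0, 1]")
        if not 0 <= self.rho < 1:
            raise ValueError(f"dispersion rho {self.rho} outside [0, 1)")


@dataclass
class BehaviorProfile:
    """Per-(group x task x word class) response model for the 2-AFC test."""

    cells: dict[tuple[str, str, str], BehaviorCell]
    n_subjects: dict[str, int]
    n_trials: int = N_TRIALS_PER_CLASS


def _rho_from_sd(mean_pct: float, sd_pct: float, n_trials: int) -> float:
    """Intra-class rho that makes the beta-binomial score SD match ``sd_pct``.

    A beta-binomial cannot be under-dispersed relative to the binomial, so
    cells whose observed SD falls below the binomial SD clamp to rho = 0.
    """
    p = mean_pct / 100
    var_k = (sd_pct / 100 * n_trials) ** 2
    base = n_trials * p * (1 - p)
    if base == 0:
        return 0.0
    rho = (var_k / base - 1) / (n_trials - 1)
    return float(min(max(rho, 0.0), 0.999))


def default_behavior_profile() -> BehaviorProfile:
    """Profile calibrated to the reference study's observed cells."""
    cells = {key: BehaviorCell(accuracy=mean / 100,
                               rho=_rho_from_sd(mean, sd, N_TRIALS_PER_CLASS))
             for key, (mean, sd) in TABLE2_CELLS.items()}
    return BehaviorProfile(cells=cells, n_subjects=dict(DEFAULT_GROUP_N))


def simulate_behavior(profile: BehaviorProfile,
                      seed: int | None = None) -> pd.DataFrame:
    """Draw per-subject percent-correct scores.

    Each subject x task x class score is ``100 * k / n_trials`` with
    ``k ~ BetaBinomial(n_trials, accuracy, rho)`` (rho = 0 degenerates to a
    plain binomial).  Scores are therefore multiples of ``100 / n_trials``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    groups = sorted({g for g, _, _ in profile.cells})
    for group in groups:
        for i in range(profile.n_subjects[group]):
            subject = f"{group}_{i + 1:02d}"
            for (g, task, tp_class), cell in sorted(profile.cells.items()):
                if g != group:
                    continue
                if cell.rho > 0:
                    ab = 1 / cell.rho - 1
                    p = rng.beta(cell.accuracy * ab, (1 - cell.accuracy) * ab)
                else:
                    p = cell.accuracy
                k = rng.binomial(profile.n_trials, p)
                rows.append(dict(subject=subject, group=group, task=task,
                                 tp_class=tp_class,
                                 pct_correct=100 * k / profile.n_trials))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# EEG simulation


@dataclass(frozen=True)
class ComponentTemplate:
    """A Gaussian-in-time deflection with a fixed scalp weighting.

    ``width_ms`` is the Gaussian standard deviation; negative-going
    components carry ``polarity = -1`` and positive amplitudes, so the
    injected deflection is ``polarity * amplitude * exp(...)``.
    """

    name: str
    peak_ms: float
    width_ms: float
    polarity: int = -1
    weights: Mapping[str, float] = field(default_factory=dict)

    def waveform(self, times_ms: np.ndarray) -> np.ndarray:
        """Unit-amplitude temporal profile on a millisecond grid."""
        return np.exp(-0.5 * ((times_ms - self.peak_ms) / self.width_ms) ** 2)

    def window_gain(self, window_ms: tuple[float, float],
                    sfreq: float) -> float:
        """Average of the unit template over the samples of a measurement
        window — the factor linking injected amplitude to ROI window mean."""
        start = round(window_ms[0] / 1000 * sfreq)
        stop = round(window_ms[1] / 1000 * sfreq)
        t = np.arange(start, stop + 1) / sfreq * 1000
        return float(self.waveform(t).mean())


@dataclass
class EffectSpec:
    """Injected components, condition amplitudes and noise for one group.

    ``amplitudes[name][(task, tp_class, half)]`` is the deflection magnitude
    in uV (applied with the component's polarity).  ``subject_sd`` is the SD
    of a per-subject, per-component random amplitude offset; ``noise_sd``
    the white-noise SD; ``artifact_rate`` the fraction of word epochs that
    receive a >100 uV square deflection of ``artifact_uv``.
    """

    components: list[ComponentTemplate]
    amplitudes: dict[str, dict[tuple[str, str, str], float]]
    subject_sd: float = 1.0
    noise_sd: float = 15.0
    artifact_rate: float = 0.15
    artifact_uv: float = 150.0

    def validate(self, channels: Sequence[str],
                 epoch_ms: tuple[float, float] = (-300.0, 1200.0)) -> None:
        for comp in self.components:
            unknown = [c for c in comp.weights if c not in channels]
            if unknown:
                raise KeyError(
                    f"component {comp.name!r}: unknown channel(s) {unknown}")
            if not epoch_ms[0] <= comp.peak_ms <= epoch_ms[1]:
                raise ValueError(
                    f"component {comp.name!r} peaks outside the epoch window")


CONDITIONS = [(task, tp_class, half)
              for task in ("implicit", "explicit")
              for tp_class in ("high", "low")
              for half in (1, 2)]


def default_effect_spec(group: str = "adults") -> EffectSpec:
    """Simulation defaults: fronto-central N100 (peak 100 ms, SD 25 ms) and
    central N400 (peak 400 ms adults / 450 ms children, SD 70 ms).

    Default amplitudes inject a larger N400 for high- than low-TP words
    (-3 vs -1 uV) and a larger N100 in the second half (-3 vs -2 uV); these
    magnitudes are simulation parameters, not observed values.
    """
    n400_peak = 400.0 if group == "adults" else 450.0
    components = [
        ComponentTemplate(name="N100", peak_ms=100.0, width_ms=25.0,
                          weights={c: 1.0 for c in CANONICAL_ROIS["fronto_central"]}),
        ComponentTemplate(name="N400", peak_ms=n400_peak, width_ms=70.0,
                          weights={c: 1.0 for c in CANONICAL_ROIS["central"]}),
    ]
    amplitudes = {
        "N100": {(task, tp, half): 2.0 if half == 1 else 3.0
                 for task, tp, half in CONDITIONS},
        "N400": {(task, tp, half): 3.0 if tp == "high" else 1.0
                 for task, tp, half in CONDITIONS},
    }
    return EffectSpec(components=components, amplitudes=amplitudes)


def simulate_subject_eeg(timeline: Timeline, effects: EffectSpec,
                         task: str, seed: int | np.random.SeedSequence,
                         sfreq: float = 512.0,
                         channels: Sequence[str] = DEFAULT_MONTAGE,
                         pad_s: float = 2.0) -> ContinuousEEG:
    """Simulate one participant's continuous recording for one task.

    The record is padded by ``pad_s`` seconds on both sides so every word
    onset has full epoch context.  Word onsets within the recording are at
    ``pad_s * 1000 + onset_ms``; downstream epoching should shift event
    onsets accordingly (see :func:`simulated_event_table`).
    """
    effects.validate(channels)
    rng = np.random.default_rng(seed)
    channels = list(channels)
    n_samples = int(round((timeline.total_duration_ms / 1000 + 2 * pad_s) * sfreq))

    if effects.noise_sd > 0:
        data = rng.normal(0.0, effects.noise_sd, size=(len(channels), n_samples))
    else:
        data = np.zeros((len(channels), n_samples))

    onsets = simulated_event_table(timeline, task, pad_s=pad_s)

    subject_offsets = {comp.name: rng.normal(0.0, effects.subject_sd)
                       if effects.subject_sd > 0 else 0.0
                       for comp in effects.components}

    for comp in effects.components:
        half_span_ms = 5 * comp.width_ms
        n_half = int(round(half_span_ms / 1000 * sfreq))
        rel = np.arange(-n_half, n_half + 1)
        rel_ms = rel / sfreq * 1000 + comp.peak_ms
        template = comp.waveform(rel_ms)
        ch_idx = np.array([channels.index(c) for c in comp.weights])
        wts = np.array(list(comp.weights.values()))
        amps = effects.amplitudes.get(comp.name, {})
        for row in onsets.itertuples():
            amp = amps.get((row.task, row.tp_class, row.half), 0.0)
            amp = amp + subject_offsets[comp.name]
            if amp == 0.0:
                continue
            center = round(row.onset_ms / 1000 * sfreq) + round(
                comp.peak_ms / 1000 * sfreq)
            lo, hi = center - n_half, center + n_half + 1
            if lo < 0 or hi > n_samples:
                continue
            data[np.ix_(ch_idx, np.arange(lo, hi))] += (
                comp.polarity * amp * wts[:, None] * template[None, :])

    if effects.artifact_rate > 0:
        hit = rng.random(len(onsets)) < effects.artifact_rate
        scalp = [i for i, c in enumerate(channels) if c not in ("M1", "M2")]
        n_art = int(round(0.1 * sfreq))  # 100 ms square pulse
        for row, is_hit in zip(onsets.itertuples(), hit):
            if not is_hit:
                continue
            ch = scalp[rng.integers(len(scalp))]
            start_ms = row.onset_ms + rng.uniform(100, 1000)
            lo = int(round(start_ms / 1000 * sfreq))
            sign = 1 if rng.random() < 0.5 else -1
            data[ch, lo : lo + n_art] += sign * effects.artifact_uv

    return ContinuousEEG(ch_names=channels, sfreq=sfreq, data=data)


def simulated_event_table(timeline: Timeline, task: str,
                          pad_s: float = 2.0) -> pd.DataFrame:
    """Word-onset events aligned to a padded simulated recording."""
    onsets = timeline.word_onsets().copy()
    onsets["onset_ms"] = onsets["onset_ms"] + pad_s * 1000
    onsets["task"] = task
    return onsets[["onset_ms", "task", "tp_class", "block", "half", "word_id"]]


def simulate_eeg(timeline: Timeline, effects: EffectSpec, n_subjects: int,
                 task: str = "implicit", seed: int | None = None,
                 sfreq: float = 512.0,
                 channels: Sequence[str] = DEFAULT_MONTAGE,
                 ) -> Iterator[tuple[str, ContinuousEEG]]:
    """Lazily yield ``(subject_id, recording)`` pairs, one per participant.

    Per-subject randomness is spawned from ``seed`` so any one subject is
    reproducible independently of how many are consumed.
    """
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    for i, ss in enumerate(children):
        yield f"S{i + 1:02d}", simulate_subject_eeg(
            timeline, effects, task=task, seed=ss, sfreq=sfreq,
            channels=channels)


def simulate_chirp_detection(chirps: ChirpAssignment, hit_rate: float,
                             fa_rate: float,
                             seed: int | None = None) -> dict[str, int]:
    """Bernoulli detection model over the chirp assignment.

    Returns hits and misses over flagged syllables and false alarms over
    unflagged ones.
    """
    if not (0 <= hit_rate <= 1 and 0 <= fa_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_flagged = int(chirps.flags.sum())
    n_clear = int((~chirps.flags).sum())
    hits = int(rng.binomial(n_flagged, hit_rate)) if n_flagged else 0
    fas = int(rng.binomial(n_clear, fa_rate)) if n_clear else 0
    return {"hits": hits, "misses": n_flagged - hits, "false_alarms": fas,
            "n_targets": n_flagged}
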