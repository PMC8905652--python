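"""Configuration and end-to-end orchestration.

``reproduce`` runs the whole pipeline — lexicon design, constrained stream
generation, TP audits, behavior simulation with t-tests and mixed ANOVA,
EEG simulation with the ERP pipeline and repeated-measures ANOVAs — from a
single :class:`ExperimentConfig` and a master seed, and collects every
result into a :class:`ReportBundle` whose payload is byte-stable under a
fixed configuration.

The EEG stage simulates ``eeg_n_per_group`` participants per group (a
package default sized for routine runs; the behavioral stage always uses
the configured group sizes, 21 adults / 20 children by default).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import erp as erp_mod
from . import lexicon as lex_mod
from . import stats as stats_mod
from . import stream as stream_mod
from . import synthdata as synth_mod

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "ReportBundle",
    "validate_config",
    "reproduce",
    "acceptance_quantities",
]


@dataclass
class ExperimentConfig:
    """Everything a full run needs, with the reference-study defaults."""

    # design
    syllabary_implicit: str = "A"
    syllabary_explicit: str = "B"
    # stream
    reps_per_block: int = 10
    n_blocks: int = 6
    syllable_ms: int = 300
    gap_ms: int = 50
    chirp_rate: float = 0.15
    chirp_total: int | None = None
    # EEG simulation / analysis
    sfreq: float = 512.0
    eeg_n_per_group: int = 3
    noise_sd: float = 15.0
    artifact_rate: float = 0.15
    artifact_threshold_uv: float = 100.0
    inclusion_min_fraction: float = 2 / 3
    epoch_window_ms: tuple[float, float] = (-300.0, 1200.0)
    baseline_ms: tuple[float, float] = (-300.0, 0.0)
    #: component -> ROI name, per group
    rois: dict[str, dict[str, str]] = field(default_factory=lambda: {
        "adults": {"N100": "central", "N400": "central"},
        "children": {"N100": "fronto_central", "N400": "central"},
    })
    # behavior
    n_adults: int = 21
    n_children: int = 20
    alpha: float = 0.05
    # seeding
    seed: int = 0

    def to_yaml(self, path: str | Path | None = None) -> str:
        payload = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("epoch_window_ms", "baseline_ms"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def validate_config(config: ExperimentConfig) -> list[str]:
    """Return a list of problems (empty iff the config is valid)."""
    problems: list[str] = []
    for sid in (config.syllabary_implicit, config.syllabary_explicit):
        if sid not in ("A", "B"):
            problems.append(f"unknown syllabary {sid!r}")
    if config.reps_per_block < 1 or config.n_blocks < 1:
        problems.append("reps_per_block and n_blocks must be >= 1")
    if config.n_blocks % 2 != 0:
        problems.append("n_blocks must be even to define exposure halves")
    if config.syllable_ms <= 0 or config.gap_ms < 0:
        problems.append("syllable/gap durations must be positive")
    if not 0 < config.chirp_rate <= 1:
        problems.append(f"chirp rate {config.chirp_rate} out of range (0, 1]")
    if config.sfreq <= 60:
        problems.append("sampling rate must exceed twice the 30 Hz band edge")
    if not 0 < config.inclusion_min_fraction <= 1:
        problems.append("inclusion fraction must lie in (0, 1]")
    if not 0 < config.alpha < 1:
        problems.append("alpha must lie in (0, 1)")
    lo, hi = config.epoch_window_ms
    for group, comps in config.rois.items():
        if group not in erp_mod.COMPONENT_WINDOWS:
            problems.append(f"unknown group {group!r}")
            continue
        for comp, roi_name in comps.items():
            if roi_name not in erp_mod.CANONICAL_ROIS:
                problems.append(f"unknown ROI {roi_name!r}")
            window = erp_mod.COMPONENT_WINDOWS[group].get(comp)
            if window is None:
                problems.append(f"no measurement window for component {comp!r}")
            elif not (lo <= window[0] <= window[1] <= hi):
                problems.append(
                    f"{group}/{comp} window {window} outside epoch {config.epoch_window_ms}")
    b0, b1 = config.baseline_ms
    if not (lo <= b0 < b1 <= hi):
        problems.append(f"baseline {config.baseline_ms} outside epoch window")
    return problems


@dataclass
class ReportBundle:
    """Machine-readable results of one full run."""

    payload: dict[str, Any]
    provenance: dict[str, Any]

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps({"provenance": self.provenance,
                           "results": self.payload},
                          indent=2, sort_keys=True, default=_jsonable)
        if path is not None:
            Path(path).write_text(text)
        return text


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _stage_seeds(master_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n)]


def _design_audit(lexicon: lex_mod.Lexicon) -> dict[str, float]:
    high_tps = [lex_mod.design_tp(lexicon, *bg)
                for w in lexicon.high_words for bg in w.bigrams]
    low_tps = [lex_mod.design_tp(lexicon, *bg)
               for w in lexicon.low_words for bg in w.bigrams]
    foil_tps = [lex_mod.design_tp(lexicon, *bg)
                for f in lexicon.foils for bg in f.bigrams]
    return {
        "within_word_tp_high": float(np.mean(high_tps)),
        "within_word_tp_low": float(np.mean(low_tps)),
        "foil_bigram_tp_max": float(np.max(foil_tps)),
    }


def _run_task_stream(lexicon: lex_mod.Lexicon, config: ExperimentConfig,
                     seed: int) -> tuple[stream_mod.WordSequence,
                                         stream_mod.Timeline,
                                         dict[str, Any]]:
    seq = stream_mod.generate_word_sequence(
        lexicon, reps_per_block=config.reps_per_block,
        n_blocks=config.n_blocks, seed=seed)
    stream_mod.audit_word_sequence(seq)
    chirps = stream_mod.assign_chirps(seq, rate=config.chirp_rate,
                                      total=config.chirp_total, seed=seed + 1)
    timeline = stream_mod.build_timeline(seq, chirps,
                                         syllable_ms=config.syllable_ms,
                                         gap_ms=config.gap_ms)
    audit = {
        "n_word_tokens": len(seq),
        "boundary_tp_high": stream_mod.word_level_boundary_tp(seq, "high"),
        "boundary_tp_low": stream_mod.word_level_boundary_tp(seq, "low"),
        "n_chirps": chirps.total,
        "word_period_ms": timeline.word_period_ms,
        "total_duration_ms": timeline.total_duration_ms,
        "block_duration_ms": timeline.total_duration_ms // config.n_blocks,
    }
    return seq, timeline, audit


def _behavior_stage(config: ExperimentConfig, seed: int) -> dict[str, Any]:
    profile = synth_mod.default_behavior_profile()
    profile.n_subjects = {"adults": config.n_adults,
                          "children": config.n_children}
    table = synth_mod.simulate_behavior(profile, seed=seed)
    ttests = []
    for (group, task, tp_class), sub in table.groupby(
            ["group", "task", "tp_class"], observed=True):
        res = stats_mod.one_sample_t(sub["pct_correct"].to_numpy(), mu=50.0)
        ttests.append(dict(group=group, task=task, tp_class=tp_class,
                           t=res.t, df=res.df, p=res.p, mean=res.mean))
    anova = stats_mod.mixed_anova(table, dv="pct_correct", between="group",
                                  within=["task", "tp_class"])
    return {"table": table, "ttests": pd.DataFrame(ttests), "anova": anova}


def _erp_stage(timelines: dict[str, stream_mod.Timeline],
               config: ExperimentConfig, group: str,
               seed: int) -> dict[str, Any]:
    """Simulate one group's EEG for both tasks and run the ERP pipeline."""
    effects = synth_mod.default_effect_spec(group)
    effects.noise_sd = config.noise_sd
    effects.artifact_rate = config.artifact_rate

    subject_epochs: dict[str, erp_mod.EpochSet] = {}
    retention: dict[str, float] = {}
    included: dict[str, bool] = {}
    task_seeds = _stage_seeds(seed, len(timelines))
    for (task, timeline), tseed in zip(timelines.items(), task_seeds):
        for subject, eeg in synth_mod.simulate_eeg(
                timeline, effects, n_subjects=config.eeg_n_per_group,
                task=task, seed=tseed, sfreq=config.sfreq):
            eeg = erp_mod.rereference_mastoids(eeg)
            eeg = erp_mod.bandpass(eeg)
            events = synth_mod.simulated_event_table(timeline, task)
            epochs = erp_mod.epoch(eeg, events,
                                   window_ms=config.epoch_window_ms,
                                   baseline_ms=config.baseline_ms)
            epochs = erp_mod.reject_artifacts(
                epochs, threshold_uv=config.artifact_threshold_uv)
            if subject in subject_epochs:
                prev = subject_epochs[subject]
                epochs = erp_mod.EpochSet(
                    data=np.concatenate([prev.data, epochs.data]),
                    labels=pd.concat([prev.labels, epochs.labels],
                                     ignore_index=True),
                    times_ms=prev.times_ms, ch_names=prev.ch_names,
                    sfreq=prev.sfreq,
                    retained=np.concatenate([prev.retained, epochs.retained]))
            subject_epochs[subject] = epochs

    for subject, epochs in subject_epochs.items():
        retention[subject] = float(epochs.retained.mean())
        included[subject] = erp_mod.include_participant(
            epochs, min_fraction=config.inclusion_min_fraction)
    kept = {s: e for s, e in subject_epochs.items() if included[s]}

    rois = {comp: erp_mod.RoiSpec(
                name=roi_name,
                channels=erp_mod.CANONICAL_ROIS[roi_name],
                window_ms=erp_mod.COMPONENT_WINDOWS[group][comp])
            for comp, roi_name in config.rois[group].items()}
    out: dict[str, Any] = {
        "n_simulated": len(subject_epochs),
        "n_included": len(kept),
        "retention": retention,
    }
    if kept:
        table = erp_mod.build_erp_table(kept, rois)
        out["erp_table"] = table
        anovas = {}
        for comp in rois:
            sub = table[table["component"] == comp]
            if sub["subject"].nunique() >= 2:
                anovas[comp] = stats_mod.rm_anova(
                    sub, dv="amplitude", within=["task", "tp_class", "half"])
        out["anova"] = anovas
    return out


def reproduce(config: ExperimentConfig | None = None,
              out_dir: str | Path | None = None) -> ReportBundle:
    """Run the full pipeline: design -> stream -> simulate -> erp -> stats.

    Raises with the failing stage's name on any error.  With ``out_dir``
    set, writes the report JSON plus CSV/TSV artifacts.
    """
    config = config or ExperimentConfig()
    problems = validate_config(config)
    if problems:
        raise ValueError(f"stage config: invalid configuration: {problems}")

    seeds = _stage_seeds(config.seed, 6)
    payload: dict[str, Any] = {}
    stage = "design"
    try:
        lexicons = {
            "implicit": lex_mod.load_canonical_syllabary(config.syllabary_implicit),
            "explicit": lex_mod.load_canonical_syllabary(config.syllabary_explicit),
        }
        payload["design"] = {
            task: _design_audit(lx) for task, lx in lexicons.items()}

        stage = "stream"
        timelines: dict[str, stream_mod.Timeline] = {}
        stream_audit = {}
        for i, (task, lx) in enumerate(lexicons.items()):
            _, timeline, audit = _run_task_stream(lx, config, seeds[0] + i)
            timelines[task] = timeline
            stream_audit[task] = audit
        payload["stream"] = stream_audit

        stage = "behavior"
        payload["behavior"] = _behavior_stage(config, seeds[1])

        stage = "erp"
        payload["erp"] = {
            "adults": _erp_stage(timelines, config, "adults", seeds[2]),
            "children": _erp_stage(timelines, config, "children", seeds[3]),
        }

        stage = "acceptance"
        payload["acceptance"] = acceptance_quantities(config.seed)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    bundle = ReportBundle(
        payload=payload,
        provenance={"config_hash": config.hash(), "seed": config.seed,
                    "package": "syllastream", "version": "0.1.0"})
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        bundle.to_json(out_dir / "report.json")
        config.to_yaml(out_dir / "config.yaml")
        payload["behavior"]["table"].to_csv(out_dir / "behavior.csv", index=False)
        payload["behavior"]["anova"].to_csv(out_dir / "behavior_anova.csv",
                                            index=False)
        for group, res in payload["erp"].items():
            if "erp_table" in res:
                res["erp_table"].to_csv(out_dir / f"erp_{group}.csv", index=False)
        for task, timeline in timelines.items():
            timeline.to_tsv(out_dir / f"events_{task}.tsv")
    return bundle


def acceptance_quantities(seed: int = 0) -> dict[str, dict[str, float]]:
    """Recompute the design, timing, behavioral-marginal and statistical
    convention quantities from scratch.

    Values are on the scale the reference quantities are printed on
    (probabilities rounded to 2 decimals where they are; percents to 1).
    """
    out: dict[str, dict[str, float]] = {}

    lexicon = lex_mod.load_canonical_syllabary("A")
    out["t1"] = {"value": lex_mod.design_tp(lexicon, "tu", "ci"), "n": 8}
    out["t2"] = {"value": round(lex_mod.design_tp(lexicon, "do", "ti"), 2),
                 "n": 8}

    seq = stream_mod.generate_word_sequence(lexicon, seed=seed)
    out["t3"] = {"value": round(
        stream_mod.word_level_boundary_tp(seq, "high"), 2), "n": len(seq)}
    out["t4"] = {"value": round(
        stream_mod.word_level_boundary_tp(seq, "low"), 2), "n": len(seq)}

    chirps = stream_mod.assign_chirps(seq, rate=0.15, seed=seed)
    timeline = stream_mod.build_timeline(seq, chirps)
    out["t5"] = {"value": float(timeline.word_period_ms), "n": len(seq)}
    out["t6"] = {"value": timeline.total_duration_ms / 60_000, "n": len(seq)}

    cells = synth_mod.TABLE2_CELLS
    adults = [cells[k][0] for k in cells if k[0] == "adults"]
    explicit = [cells[k][0] for k in cells if k[1] == "explicit"]
    out["t7"] = {"value": round(float(np.mean(adults)), 1), "n": len(adults)}
    out["t8"] = {"value": round(float(np.mean(explicit)), 1), "n": len(explicit)}

    mean, sd = cells[("adults", "explicit", "high")]
    out["t9"] = {"value": round(stats_mod.one_sample_t_from_summary(
        mean, sd, 21).t, 3), "n": 21}
    mean, sd = cells[("adults", "explicit", "low")]
    out["t10"] = {"value": round(stats_mod.one_sample_t_from_summary(
        mean, sd, 21).t, 3), "n": 21}

    out["t11"] = {"value": round(stats_mod.partial_eta_sq(4.791, 1, 39), 3),
                  "n": 41}
    out["t12"] = {"value": round(stats_mod.observed_power(4.791, 1, 39), 3),
                  "n": 41}
    return out
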