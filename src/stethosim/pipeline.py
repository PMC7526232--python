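"""End-to-end orchestration: simulate → preprocess → score → evaluate.

A :class:`PipelineConfig` plus a seed fully determines every output byte
(modulo log timestamps).  The scorer is pluggable: the rule-based detector is
the default, but any callable mapping a preprocessed waveform to a score
pair — e.g. scores imported from an external classifier's CSV — can stand in.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
import yaml

from . import detect, evaluate, simulate
from .preprocess import FilterSpec, preprocess as _preprocess
from .errors import PipelineStageError

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "exclude_aberrant",
    "truth_labels",
    "score_cohort",
    "evaluate_scores",
]

log = logging.getLogger(__name__)

SOUND_TYPES = ("crackle", "wheeze")


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, YAML-serializable."""

    seed: int = 0
    cohort: simulate.CohortConfig = field(default_factory=simulate.CohortConfig)
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    detector: detect.DetectorConfig = field(default_factory=detect.DetectorConfig)
    normalize_target: float = 0.9
    tpr_definition: str = "agreement"
    criterion: str = "ppa_plus_npa"
    kappa_subset_fraction: float = 0.2
    out_dir: str | None = None
    write_audio: bool = False
    write_plots: bool = True

    # -- YAML round trip ----------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "out_dir": self.out_dir,
            "write_audio": self.write_audio,
            "write_plots": self.write_plots,
            "cohort": {
                "group_sizes": dict(self.cohort.group_sizes),
                "quadrants": list(self.cohort.quadrants),
                "exclusions_per_device": self.cohort.exclusions_per_device,
                "duration_s": self.cohort.duration_s,
                "master_rate_hz": self.cohort.master_rate_hz,
                "female_fraction": self.cohort.female_fraction,
            },
            "devices": [dataclasses.asdict(dv) for dv in self.cohort.devices],
            "events": dataclasses.asdict(self.cohort.events),
            "filter": dataclasses.asdict(self.filter_spec),
            "detector": dataclasses.asdict(self.detector),
            "evaluation": {
                "tpr_definition": self.tpr_definition,
                "criterion": self.criterion,
                "kappa_subset_fraction": self.kappa_subset_fraction,
                "normalize_target": self.normalize_target,
            },
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cohort_kw = dict(d.get("cohort", {}))
        if "quadrants" in cohort_kw:
            cohort_kw["quadrants"] = tuple(cohort_kw["quadrants"])
        if "devices" in d:
            cohort_kw["devices"] = tuple(
                simulate.DeviceProfile(**dv) for dv in d["devices"]
            )
        if "events" in d:
            ev = dict(d["events"])
            for k, v in ev.items():
                if isinstance(v, list):
                    ev[k] = tuple(v)
            cohort_kw["events"] = simulate.EventModelConfig(**ev)
        ev_kw = dict(d.get("evaluation", {}))
        det = dict(d.get("detector", {}))
        return cls(
            seed=d.get("seed", 0),
            cohort=simulate.CohortConfig(**cohort_kw),
            filter_spec=FilterSpec(**d.get("filter", {})),
            detector=detect.DetectorConfig(**det),
            normalize_target=ev_kw.pop("normalize_target", 0.9),
            tpr_definition=ev_kw.get("tpr_definition", "agreement"),
            criterion=ev_kw.get("criterion", "ppa_plus_npa"),
            kappa_subset_fraction=ev_kw.get("kappa_subset_fraction", 0.2),
            out_dir=d.get("out_dir"),
            write_audio=d.get("write_audio", False),
            write_plots=d.get("write_plots", True),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def exclude_aberrant(manifest: pd.DataFrame) -> pd.DataFrame:
    """Drop excluded (aberrant) rows, logging per-device exclusion counts."""
    excl = manifest[manifest["excluded"]]
    for device, n in excl.groupby("device").size().items():
        log.info("excluding %d aberrant recording(s) from device %s", n, device)
    kept = manifest[~manifest["excluded"]].reset_index(drop=True)
    if kept.empty:
        log.warning("all recordings flagged as excluded; manifest is empty")
    return kept


def truth_labels(cohort: simulate.Cohort) -> pd.DataFrame:
    """Ground-truth presence labels per recording, from the injected events."""
    rows = []
    for rec_id, rec in cohort.records.items():
        kinds = {e.kind for e in rec.truth_events}
        rows.append({
            "recording_id": rec_id,
            "crackle_true": "crackle" in kinds,
            "wheeze_true": "wheeze" in kinds,
        })
    return pd.DataFrame(rows).set_index("recording_id")


def _default_scorer(config: PipelineConfig) -> Callable:
    def scorer(w: simulate.Waveform) -> detect.ScorePair:
        prepped = _preprocess(w, config.filter_spec,
                                        target_peak=config.normalize_target)
        return detect.score_recording(prepped, config.detector)
    return scorer


def score_cohort(cohort: simulate.Cohort, config: PipelineConfig,
                 scorer: Callable | None = None,
                 recording_ids: list[str] | None = None) -> pd.DataFrame:
    """Render, preprocess and score recordings (lazily, one at a time).

    Excluded recordings are skipped unless explicitly listed.  Returns a
    DataFrame indexed by recording_id with crackle_score / wheeze_score.
    """
    scorer = scorer or _default_scorer(config)
    if recording_ids is None:
        recording_ids = [r for r, rec in cohort.records.items()
                         if not rec.excluded]
    rows = []
    for rec_id in recording_ids:
        w = cohort.render_recording_audio(rec_id)
        s = scorer(w)
        rows.append({"recording_id": rec_id,
                     "crackle_score": s.crackle_score,
                     "wheeze_score": s.wheeze_score})
    return pd.DataFrame(rows).set_index("recording_id")


def _interval_dict(iv: evaluate.ThresholdInterval) -> dict:
    return {
        "cutoff_lo": iv.cutoff_lo, "cutoff_hi": iv.cutoff_hi,
        "ppa": iv.ppa, "npa": iv.npa,
        "table": dataclasses.asdict(iv.table),
    }


def evaluate_scores(scores: pd.DataFrame, truth: pd.DataFrame,
                    manifest: pd.DataFrame, config: PipelineConfig,
                    out_dir: Path | None = None) -> dict:
    """Per-device, per-sound-type ROC analysis of a score table.

    For each device and sound type this builds the full operating-point
    list, selects the optimal cutoff interval, and also reports agreement at
    the maximum-sensitivity "> 0.00" cutoff.  ROC tables (CSV) and curves
    (PNG) are written when ``out_dir`` is given.
    """
    analyzed = exclude_aberrant(manifest)
    report: dict = {"devices": {}}
    for device in analyzed["device"].unique():
        ids = analyzed.loc[analyzed["device"] == device, "recording_id"]
        dev_report = {}
        for sound in SOUND_TYPES:
            s = scores.loc[ids, f"{sound}_score"]
            r = truth.loc[ids, f"{sound}_true"]
            points = evaluate.roc(s, r, config.tpr_definition)
            best = evaluate.optimal_cutoff_interval(points, config.criterion)
            zero_ppa, zero_npa, zero_tpr = evaluate.ppa_npa(
                evaluate.confusion(s > 0.0, r), config.tpr_definition)
            dev_report[sound] = {
                "n": int(len(ids)),
                "n_positive": int(r.sum()),
                "optimal_interval": _interval_dict(best),
                "at_zero_cutoff": {"ppa": zero_ppa, "npa": zero_npa,
                                   "tpr": zero_tpr},
            }
            if out_dir is not None:
                _write_roc_outputs(points, device, sound, out_dir,
                                   config.write_plots)
        report["devices"][device] = dev_report
    return report


def _write_roc_outputs(points, device: str, sound: str, out_dir: Path,
                       write_plots: bool) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame([
        {"cutoff": p.cutoff, "tp": p.table.tp, "fp": p.table.fp,
         "tn": p.table.tn, "fn": p.table.fn, "ppa": p.ppa, "npa": p.npa}
        for p in points
    ])
    df.to_csv(out_dir / f"roc_{device}_{sound}.csv", index=False)
    if not write_plots:
        return
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    x = [1 - (p.npa if p.npa is not None else 0.0) for p in points]
    y = [p.ppa if p.ppa is not None else 0.0 for p in points]
    order = np.argsort(x)
    ax.plot(np.asarray(x)[order], np.asarray(y)[order], "o-", ms=3)
    ax.plot([0, 1], [0, 1], ":", color="grey", lw=0.8)
    ax.set_xlabel("1 − NPA")
    ax.set_ylabel("PPA")
    ax.set_title(f"{device} / {sound}")
    fig.tight_layout()
    fig.savefig(out_dir / f"roc_{device}_{sound}.png", dpi=120)
    plt.close(fig)


def interrater_kappa(cohort: simulate.Cohort, scores: pd.DataFrame,
                     config: PipelineConfig,
                     scorer: Callable | None = None) -> dict:
    """Re-tag a participant subset with an identical second pass.

    Emulates the study's blinded second rater applying the same strict
    labelling criteria to recordings from a fraction (default 20%) of
    participants: the deterministic labelling operator is run a second time
    with the same configuration and Cohen's kappa is computed per sound
    type between the two tag vectors.
    """
    pids = sorted(cohort.participants["participant_id"])
    n_sub = max(1, int(round(config.kappa_subset_fraction * len(pids))))
    rng = np.random.default_rng(np.random.SeedSequence((cohort.seed, 7)))
    subset = set(rng.choice(pids, size=n_sub, replace=False))
    rec_ids = [r for r, rec in cohort.records.items()
               if rec.participant_id in subset and not rec.excluded]
    second = score_cohort(cohort, config, scorer, recording_ids=rec_ids)
    out: dict = {"n_participants": n_sub, "n_recordings": len(rec_ids)}
    kappas = []
    for sound in SOUND_TYPES:
        a = (scores.loc[rec_ids, f"{sound}_score"] > 0.0).to_numpy()
        b = (second.loc[rec_ids, f"{sound}_score"] > 0.0).to_numpy()
        k = evaluate.cohen_kappa(a, b)
        out[sound] = k
        kappas.append(k)
    out["joint_min"] = min(kappas)
    return out


def _stage(name: str):
    """Decorator-free helper: re-raise stage failures with the stage name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(name, str(exc)) from exc
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig,
                 scorer: Callable | None = None) -> dict:
    """Execute the full pipeline and return the report bundle (a dict).

    Stages: simulate the cohort → score every analyzable recording (with
    normalization + band-pass preprocessing) → evaluate per-device ROC with
    optimized cutoff intervals, inter-rater kappa on a re-tagged subset, and
    the cohort summary.  When ``config.out_dir`` is set, writes manifest,
    scores, ROC tables/plots and ``report.json`` there; idempotent per seed.
    """
    out_dir = Path(config.out_dir) if config.out_dir else None

    with _stage("simulate"):
        cohort = simulate.generate_cohort(config.cohort, config.seed,
                                          out_dir=out_dir,
                                          write_audio=config.write_audio)
    with _stage("score"):
        scores = score_cohort(cohort, config, scorer)
    with _stage("evaluate"):
        truth = truth_labels(cohort)
        report = evaluate_scores(scores, truth, cohort.manifest, config,
                                 out_dir)
        report["kappa"] = interrater_kappa(cohort, scores, config, scorer)
        cs = evaluate.cohort_summary(cohort.manifest, cohort.participants)
        report["cohort_summary"] = dataclasses.asdict(cs)
        report["seed"] = config.seed
        report["n_recordings_total"] = int(len(cohort.manifest))
        report["n_recordings_analyzed"] = int((~cohort.manifest["excluded"]).sum())

    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        scores.to_csv(out_dir / "scores.csv")
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=float)
    return report
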