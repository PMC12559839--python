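"""End-to-end orchestration: simulate -> preprocess -> TFR -> surrogate
statistics -> band-power summary -> mixed model, with a run manifest.

The pipeline is deterministic under a fixed config seed: each stage derives
its own seed as SeedSequence([seed, stage_counter]), so stages can be rerun
in isolation and a rerun of the same config produces identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bandpower import fit_model, followups, summarize
from .containers import BANDS_HZ, TASKS, WINDOWS_MS
from .edf import write_edf
from .events import write_events_csv
from .preprocess import preprocess_session
from .surrogate import contrast, within_condition
from .synth import SynthConfig, generate_cohort
from .timefreq import build_wavelet_bank, db_normalize, trial_average, wavelet_power

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "preprocess", "tfr", "stats", "summarize", "lme")


@dataclass
class PipelineConfig:
    """Everything a run needs; round-trips losslessly through YAML."""

    out_dir: str = "speechlfp_run"
    seed: int = 0
    synth: dict = field(default_factory=dict)  # SynthConfig overrides
    line_hz: float | None = None  # synthetic data carry no line noise
    n_freqs: int = 50
    n_shuffles: int = 2241
    alpha: float = 0.001
    run_stats: bool = True
    write_edf: bool = False
    include_participants: list | None = None

    _KNOWN = ("out_dir", "seed", "synth", "line_hz", "n_freqs", "n_shuffles",
              "alpha", "run_stats", "write_edf", "include_participants")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls._KNOWN)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _stage_seed(seed: int, counter: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(seed), int(counter)])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    stages: dict = field(default_factory=dict)  # stage -> {files, counts, seconds}
    failed_stage: str | None = None

    def record(self, stage: str, files: list, counts: dict, seconds: float) -> None:
        self.stages[stage] = {
            "files": {str(p): _sha256(Path(p)) for p in files},
            "counts": counts, "seconds": round(seconds, 3),
        }

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages, writing artifacts and a manifest under out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dataclasses.asdict(config))
    try:
        _run_stages(config, out, manifest)
    except Exception:
        manifest.write(out / "manifest.json")
        raise
    manifest.write(out / "manifest.json")
    return manifest


def _run_stages(config: PipelineConfig, out: Path, manifest: RunManifest) -> None:
    # -- simulate -----------------------------------------------------------
    t0 = time.perf_counter()
    synth_seed = int(_stage_seed(config.seed, 0).generate_state(1)[0] % (2 ** 31))
    scfg = SynthConfig(**{"seed": synth_seed, **config.synth})
    cohort = generate_cohort(scfg)
    if config.include_participants:
        cohort = [c for c in cohort if c[0].participant_id in config.include_participants]
    files = []
    if config.write_edf:
        for session, ann, _ in cohort:
            stem = f"{session.participant_id}_{session.hemisphere}"
            write_edf(session, out / f"{stem}.edf")
            write_events_csv(ann, out / f"{stem}_events.csv")
            files += [out / f"{stem}.edf", out / f"{stem}_events.csv"]
    manifest.record("simulate", files, {"sessions": len(cohort)},
                    time.perf_counter() - t0)
    logger.info("simulate: %d sessions", len(cohort))

    # -- preprocess ---------------------------------------------------------
    t0 = time.perf_counter()
    manifest.failed_stage = "preprocess"
    epoch_sets, n_dropped = [], 0
    for session, ann, _ in cohort:
        epochs, report = preprocess_session(session, ann, line_hz=config.line_hz)
        n_dropped += report.n_dropped
        epoch_sets.append(epochs)
    manifest.record("preprocess", [], {"sessions": len(epoch_sets),
                                       "trials_dropped": n_dropped},
                    time.perf_counter() - t0)
    logger.info("preprocess: %d sessions, %d trials dropped", len(epoch_sets), n_dropped)

    # -- time-frequency -----------------------------------------------------
    t0 = time.perf_counter()
    manifest.failed_stage = "tfr"
    bank = build_wavelet_bank(n_freqs=config.n_freqs)
    tensors = [db_normalize(wavelet_power(ep, bank)) for ep in epoch_sets]
    manifest.record("tfr", [], {"n_freqs": config.n_freqs},
                    time.perf_counter() - t0)

    # -- surrogate statistics ----------------------------------------------
    t0 = time.perf_counter()
    manifest.failed_stage = "stats"
    stats_files = []
    if config.run_stats:
        stats_seed = _stage_seed(config.seed, 3).generate_state(1)[0] % (2 ** 31)
        sig = {}
        for ti, task in enumerate(TASKS):
            res = within_condition(tensors, task, n_shuffles=config.n_shuffles,
                                   seed=int(stats_seed) + ti, alpha=config.alpha)
            sig[f"within_{task}"] = float(res.mask.mean())
        pairs = [("sentence", "vowel"), ("ddk", "vowel"), ("sentence", "ddk")]
        for pi, (a, b) in enumerate(pairs):
            res = contrast([t.select_task(a) for t in tensors],
                           [t.select_task(b) for t in tensors],
                           n_shuffles=config.n_shuffles,
                           seed=int(stats_seed) + 100 + pi, alpha=config.alpha,
                           label=f"{a}-{b}")
            sig[f"contrast_{a}-{b}"] = float(res.mask.mean())
        p = out / "significant_fraction.json"
        p.write_text(json.dumps(sig, indent=2))
        stats_files.append(p)
    manifest.record("stats", stats_files, {}, time.perf_counter() - t0)

    # -- band-power summary -------------------------------------------------
    t0 = time.perf_counter()
    manifest.failed_stage = "summarize"
    maps = [trial_average(tensor, task) for tensor in tensors for task in TASKS]
    table = summarize(maps)
    table_path = out / "bandpower.csv"
    table.to_csv(table_path, index=False)
    manifest.record("summarize", [table_path], {"rows": len(table)},
                    time.perf_counter() - t0)

    # -- mixed models -------------------------------------------------------
    t0 = time.perf_counter()
    manifest.failed_stage = "lme"
    lme_files = []
    results = {}
    for band in BANDS_HZ:
        for window in WINDOWS_MS:
            res = fit_model(table, band, window)
            fu = followups(res)
            results[f"{band}_{window}"] = {
                "anova": res.anova.to_dict(orient="records"),
                "followups": fu.to_dict(orient="records"),
                "participant_var": res.participant_var,
                "residual_var": res.residual_var,
                "singular": res.singular,
            }
            res.anova.to_csv(out / f"lme_{band}_{window}.csv", index=False)
            lme_files.append(out / f"lme_{band}_{window}.csv")
    (out / "lme_results.json").write_text(json.dumps(results, indent=2))
    lme_files.append(out / "lme_results.json")
    manifest.record("lme", lme_files, {"models": len(results)},
                    time.perf_counter() - t0)
    manifest.failed_stage = None
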