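"""Readers, writers, and the end-to-end pipeline driver.

All tabular artifacts are plain CSV with documented schemas; results are
JSON.  Every pipeline run writes a manifest (configuration hash, seeds,
package version) next to its outputs, from which every numeric artifact is
regenerable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .inference import FitConfig, posterior_predictive
from .metrics import correlate, initial_expectation, valence_bias_table
from .model_comparison import rfx_bms
from .model_space import MODELS
from .recovery import evidence_matrix, fit_cohort
from .synthetic_cohort import (
    CONFIDENCE_COLUMNS, CohortConfig, CohortTruth, paper_like_preset, sample_cohort,
)
from .task_engine import ABILITIES, AGENTS, SESSIONS, TRIAL_COLUMNS


class SchemaError(ValueError):
    """A table violated the documented schema; the message names the location."""


def write_trials(trials: pd.DataFrame, path) -> None:
    trials[list(TRIAL_COLUMNS)].to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read and validate a long-format trial table.

    Checks: required columns present; ratings and feedback within [0, 100];
    condition labels from the known sets; each participant x session x cell
    holds trials 1..20.
    """
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    for col, allowed in (("session", SESSIONS), ("agent", AGENTS),
                         ("ability", ABILITIES)):
        bad = ~df[col].isin(allowed)
        if bad.any():
            row = int(df.index[bad][0])
            raise SchemaError(
                f"{path}: row {row}, column '{col}': value {df.loc[row, col]!r} "
                f"not in {allowed}")
    for col in ("expectation", "feedback"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals > 100)
        if bad.any():
            row = int(df.index[bad][0])
            raise SchemaError(
                f"{path}: row {row}, column '{col}': value {df.loc[row, col]!r} "
                "outside [0, 100]")
    pe_err = (df["feedback"] - df["expectation"] - df["pe"]).abs()
    if (pe_err > 1e-6).any():
        row = int(df.index[pe_err > 1e-6][0])
        raise SchemaError(f"{path}: row {row}: pe != feedback - expectation")
    counts = df.groupby(["participant", "session", "agent", "ability"])["trial"]
    for key, trials_seen in counts:
        if sorted(trials_seen) != list(range(1, 21)):
            raise SchemaError(f"{path}: cell {key}: expected trials 1..20, "
                              f"got {len(trials_seen)} rows")
    return df


def write_confidence(confidence: pd.DataFrame, path) -> None:
    confidence[list(CONFIDENCE_COLUMNS)].to_csv(path, index=False)


def read_confidence(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CONFIDENCE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    bad = (df["confidence"] < 0) | (df["confidence"] > 100)
    if bad.any():
        row = int(df.index[bad][0])
        raise SchemaError(f"{path}: row {row}, column 'confidence': outside [0, 100]")
    return df


def write_truth(truth: CohortTruth, path) -> None:
    Path(path).write_text(truth.to_json())


def read_truth(path) -> CohortTruth:
    return CohortTruth.from_json(Path(path).read_text())


def write_evidence(L: np.ndarray, models, path, participants=None) -> None:
    df = pd.DataFrame(L, columns=list(models))
    df.insert(0, "participant", participants if participants is not None
              else np.arange(L.shape[0]))
    df.to_csv(path, index=False)


def read_evidence(path) -> tuple:
    df = pd.read_csv(path)
    models = [c for c in df.columns if c != "participant"]
    return df[models].to_numpy(dtype=float), models


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """One reproducible end-to-end run: simulate -> fit -> compare -> metrics."""

    out_dir: str
    cohort: CohortConfig = dataclasses.field(default_factory=paper_like_preset)
    models: tuple = tuple(MODELS)
    fit: FitConfig = dataclasses.field(default_factory=FitConfig)
    method: str = "map"
    seed: int = 0
    sessions: tuple = ("T1", "T2")

    def to_json_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def config_hash(cfg: PipelineConfig) -> str:
    """Hash of the scientific configuration; output paths do not participate."""
    d = cfg.to_json_dict()
    d.pop("out_dir", None)
    payload = json.dumps(d, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis chain and write every artifact.

    Stages: cohort simulation, per-participant fits of the requested model
    subset, per-session PSIS-LOO evidence and RFX-BMS, valence-bias and
    learning-rate tables from the extended valence model, the Spearman/FDR
    correlation family, and posterior-predictive overlays.  Deterministic
    given the config; a manifest ties outputs to the configuration hash.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": config_hash(config), "stages": {}}

    def stage(name, fn):
        try:
            return fn()
        except Exception as e:  # noqa: BLE001
            raise RuntimeError(f"pipeline stage '{name}' failed: {e}") from e

    sample = stage("simulate", lambda: sample_cohort(config.cohort))
    write_trials(sample.trials, out / "trials.csv")
    write_confidence(sample.confidence, out / "confidence.csv")
    write_truth(sample.truth, out / "truth.json")
    report["stages"]["simulate"] = {"participants": int(config.cohort.n_participants),
                                    "rows": int(len(sample.trials))}

    fits = stage("fit", lambda: fit_cohort(
        sample, list(config.models), method=config.method,
        config=config.fit, seed=config.seed))
    fit_summaries = {m: {int(p): s.summary_dict() for p, s in fits[m].items()}
                     for m in fits}
    (out / "fits.json").write_text(json.dumps(fit_summaries, indent=1))
    report["stages"]["fit"] = {"models": list(config.models),
                               "method": config.method}

    bms_out = {}
    for session in config.sessions:
        L = stage("compare", lambda s=session: evidence_matrix(
            fits, list(config.models), session=s))
        write_evidence(L, config.models, out / f"evidence_{session}.csv")
        bms = rfx_bms(L, models=list(config.models), seed=config.seed)
        (out / f"bms_{session}.json").write_text(json.dumps(bms.to_json_dict(), indent=1))
        bms_out[session] = {"pxp": bms.pxp.tolist(), "bor": float(bms.bor),
                            "frequencies": bms.frequencies.tolist(),
                            "winner": config.models[int(np.argmax(bms.pxp))]}
    report["stages"]["compare"] = bms_out

    metrics_report = {}
    if "M7" in fits:
        m7 = {pid: s.means for pid, s in fits["M7"].items()}
        bias = valence_bias_table(m7)
        bias.to_csv(out / "bias_scores.csv", index=False)
        init_self = initial_expectation(sample.trials, "Self", "T1")
        bias_self_t1 = (bias[(bias.agent == "Self") & (bias.session == "T1")]
                        .set_index("participant")["bias"].reindex(init_self.index))
        bias_other_t1 = (bias[(bias.agent == "Other") & (bias.session == "T1")]
                         .set_index("participant")["bias"])
        init_other = initial_expectation(sample.trials, "Other", "T1")
        fam = correlate({
            "init_self_x_bias_self_T1": (init_self.to_numpy(),
                                         bias_self_t1.to_numpy()),
            "init_other_x_bias_other_T1": (init_other.to_numpy(),
                                           bias_other_t1.reindex(init_other.index).to_numpy()),
        })
        fam.to_csv(out / "correlations.csv", index=False)
        metrics_report = {
            "t1_self_bias_mean": float(bias[(bias.agent == "Self")
                                            & (bias.session == "T1")]["bias"].mean()),
            "t1_other_bias_mean": float(bias[(bias.agent == "Other")
                                             & (bias.session == "T1")]["bias"].mean()),
            "mean_alpha_t1": float(bias[bias.session == "T1"]["mean_alpha"].mean()),
            "mean_alpha_t2": float(bias[bias.session == "T2"]["mean_alpha"].mean()),
        }
        ppc_rows = []
        for pid, summary in fits["M7"].items():
            tr = sample.trials[sample.trials["participant"] == pid]
            df, r2 = posterior_predictive("M7", summary, tr)
            df.insert(0, "participant", pid)
            df["r2"] = r2
            ppc_rows.append(df)
        pd.concat(ppc_rows).to_csv(out / "posterior_predictive.csv", index=False)
    report["stages"]["metrics"] = metrics_report

    manifest = {
        "config": config.to_json_dict(),
        "config_hash": report["config_hash"],
        "seed": config.seed,
        "version": __version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (out / "report.json").write_text(json.dumps(report, indent=1))
    return report
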