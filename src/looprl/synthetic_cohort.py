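"""Synthetic two-session cohorts with the statistical structure the analysis assumes.

Each simulated participant runs the full closed-loop task (4 conditions x 20
trials x 2 sessions) with ratings produced by a generating learning model plus
truncated observation noise, and adaptive feedback produced by the task
engine.  Two parameter regimes are available:

* ``structured`` — population effects mirroring the empirical phenomenology:
  a self-specific negativity asymmetry in T1 learning rates, an other-related
  positivity asymmetry, multiplicative suppression of T2 learning rates,
  a latent-factor-induced correlation between self starting values and the
  T1 self valence bias, and confidence trajectories (rise over T1, slight T2
  decay) coupled to learning rates.
* ``uniform`` — independent uniform parameters per participant, the regime
  used for parameter- and model-recovery experiments.

T2 starting values carry the end-of-T1 latent belief of each category over
into the relabelled cell, so session-two beliefs begin where session one
ended.  Ground-truth parameters are stored alongside the data and never
consumed by inference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import task_engine as te
from .model_space import get_model, simulate_trajectory

TIMEPOINTS = ("pre-T1", "post-T1", "pre-T2", "post-T2")

CONFIDENCE_COLUMNS = ("participant", "agent", "ability", "timepoint", "confidence")


@dataclass(frozen=True)
class CohortConfig:
    """Everything that determines a synthetic cohort (the seed fixes the rest)."""

    n_participants: int = 30
    model_id: str = "M7"
    seed: int = 0
    regime: str = "structured"
    sigma: float = 8.0                 # observation noise, percentile units

    # uniform regime
    alpha_range: tuple = (0.05, 0.6)
    w_range: tuple = (0.2, 0.8)
    sv_range: tuple = (10.0, 90.0)

    # structured regime: population moments
    alpha_level_mean: float = 0.40     # learning-rate level averaged over valence
    alpha_level_sd: float = 0.10
    self_negativity: float = 0.11      # mean alpha_self,PE- minus alpha_self,PE+ at T1
    other_negativity: float = -0.09    # same for Other (negative = positivity bias)
    delta_sd: float = 0.20             # between-participant sd of the asymmetry
    t2_suppression: float = 0.5        # multiplicative factor on T2 learning rates
    suppression_sd: float = 0.18
    sv_mean: float = 50.0
    sv_sd: float = 12.0
    sv_cell_jitter_sd: float = 4.0
    sv_bias_corr: float = 0.45         # target corr(self T1 SV, self T1 bias score)
    w_mean: float = 0.35
    w_sd: float = 0.15

    # confidence trajectory
    conf_pre_t1: float = 40.0
    conf_between_sd: float = 10.0
    conf_t1_gain: float = 11.0
    conf_self_extra_gain: float = 8.0
    conf_t2_decay: float = 1.5
    conf_alpha_coupling: float = 5.0   # confidence points per SD of mean T1 alpha
    conf_gain_sd: float = 9.0
    conf_noise_sd: float = 4.0

    carryover_t2_sv: bool = True

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.regime not in ("structured", "uniform"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if abs(self.sv_bias_corr) > 0.95:
            raise ValueError("infeasible sv_bias_corr (|rho| > 0.95 with "
                             "truncated parameter distributions)")
        if self.regime == "structured" and self.model_id not in ("M6", "M7"):
            raise ValueError("structured regime requires a session-split "
                             "valence model (M6 or M7)")


@dataclass
class CohortTruth:
    """Generating parameters per participant; never consumed by inference."""

    model_id: str
    param_names: tuple
    participants: list          # list of {"participant": int, "params": dict, ...}

    def params_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.participants:
            rows.append({"participant": p["participant"], **p["params"]})
        return pd.DataFrame(rows).set_index("participant")

    def to_json(self) -> str:
        return json.dumps({"model_id": self.model_id,
                           "param_names": list(self.param_names),
                           "participants": self.participants}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "CohortTruth":
        d = json.loads(text)
        return cls(d["model_id"], tuple(d["param_names"]), d["participants"])


@dataclass
class CohortSample:
    trials: pd.DataFrame
    confidence: pd.DataFrame
    truth: CohortTruth
    config: CohortConfig


def _structured_params(cfg: CohortConfig, spec, rng: np.random.Generator) -> tuple:
    """Sample one participant's structured M6/M7 parameter set.

    Returns (theta, extras) where extras carries the latent factors reused by
    the confidence generator (mean T1 alpha, suppression, confidence factor).
    """
    rho = cfg.sv_bias_corr
    z = rng.standard_normal()          # shared SV/bias factor
    g = rng.standard_normal()          # confidence factor

    level_self = np.clip(cfg.alpha_level_mean + cfg.alpha_level_sd * rng.standard_normal(),
                         0.05, 0.9)
    level_other = np.clip(cfg.alpha_level_mean + cfg.alpha_level_sd * rng.standard_normal(),
                          0.05, 0.9)
    e1 = rng.standard_normal()
    delta_self = cfg.self_negativity + cfg.delta_sd * (
        np.sqrt(rho) * (-z) + np.sqrt(1 - rho) * e1)
    delta_other = cfg.other_negativity + cfg.delta_sd * rng.standard_normal()
    suppression = float(np.clip(cfg.t2_suppression - cfg.suppression_sd * g, 0.05, 0.95))

    def pair(level, delta):
        ap = np.clip(level - delta / 2, 0.01, 0.99)
        am = np.clip(level + delta / 2, 0.01, 0.99)
        return float(ap), float(am)

    a_sp, a_sm = pair(level_self, delta_self)
    a_op, a_om = pair(level_other, delta_other)

    sv_self = float(np.clip(cfg.sv_mean + cfg.sv_sd * (
        np.sqrt(rho) * z + np.sqrt(1 - rho) * rng.standard_normal()), 2, 98))
    sv_other = float(np.clip(cfg.sv_mean + cfg.sv_sd * rng.standard_normal(), 2, 98))

    params = {}
    for a, (ap, am) in (("Self", (a_sp, a_sm)), ("Other", (a_op, a_om))):
        params[f"alpha_T1_{a}_PE+"] = ap
        params[f"alpha_T1_{a}_PE-"] = am
        params[f"alpha_T2_{a}_PE+"] = float(np.clip(ap * suppression, 0.005, 0.99))
        params[f"alpha_T2_{a}_PE-"] = float(np.clip(am * suppression, 0.005, 0.99))
    if spec.has_w:
        for s in te.SESSIONS:
            params[f"w_{s}"] = float(np.clip(
                cfg.w_mean + cfg.w_sd * rng.standard_normal(), 0.0, 0.95))
    for a, base in (("Self", sv_self), ("Other", sv_other)):
        for b in te.ABILITIES:
            params[f"sv_T1_{a}_{b}"] = float(np.clip(
                base + cfg.sv_cell_jitter_sd * rng.standard_normal(), 1, 99))
            params[f"sv_T2_{a}_{b}"] = 50.0    # placeholder; overwritten by carry-over
    params["sigma"] = cfg.sigma
    extras = {
        "mean_alpha_t1": 0.25 * (a_sp + a_sm + a_op + a_om),
        "mean_alpha_t1_self": 0.5 * (a_sp + a_sm),
        "mean_alpha_t1_other": 0.5 * (a_op + a_om),
        "suppression": suppression,
        "conf_factor": g,
    }
    return params, extras


def _uniform_params(cfg: CohortConfig, spec, rng: np.random.Generator) -> tuple:
    params = {}
    for name in spec.param_names:
        if name.startswith("alpha"):
            params[name] = float(rng.uniform(*cfg.alpha_range))
        elif name.startswith("w_"):
            params[name] = float(rng.uniform(*cfg.w_range))
        elif name.startswith(("sv_", "mean_")):
            params[name] = float(rng.uniform(*cfg.sv_range))
        else:
            params[name] = cfg.sigma
    alphas = [v for k, v in params.items() if k.startswith("alpha")]
    level = float(np.mean(alphas)) if alphas else 0.0
    extras = {"mean_alpha_t1": level, "mean_alpha_t1_self": level,
              "mean_alpha_t1_other": level,
              "suppression": 1.0, "conf_factor": rng.standard_normal()}
    return params, extras


def _confidence_rows(cfg: CohortConfig, pid: int, extras: dict,
                     rng: np.random.Generator) -> list:
    rows = []
    zalpha = {
        "Self": (extras["mean_alpha_t1_self"] - cfg.alpha_level_mean) / cfg.alpha_level_sd,
        "Other": (extras["mean_alpha_t1_other"] - cfg.alpha_level_mean) / cfg.alpha_level_sd,
    }
    for agent in te.AGENTS:
        base = cfg.conf_pre_t1 + cfg.conf_between_sd * rng.standard_normal()
        gain = (cfg.conf_t1_gain
                + (cfg.conf_self_extra_gain if agent == "Self" else 0.0)
                + cfg.conf_alpha_coupling * zalpha[agent]
                + cfg.conf_gain_sd * extras["conf_factor"])
        levels = {
            "pre-T1": base,
            "post-T1": base + gain,
            "pre-T2": base + gain + rng.normal(0, 1),
            "post-T2": base + gain - cfg.conf_t2_decay + rng.normal(0, 1),
        }
        for ability in te.ABILITIES:
            for tp in TIMEPOINTS:
                conf = levels[tp] + cfg.conf_noise_sd * rng.standard_normal()
                rows.append({"participant": pid, "agent": agent,
                             "ability": ability, "timepoint": tp,
                             "confidence": float(np.clip(conf, 0, 100))})
    return rows


def sample_cohort(cfg: CohortConfig) -> CohortSample:
    """Generate trials, confidence records, and ground truth for one cohort."""
    spec = get_model(cfg.model_id)
    designs = te.make_design(cfg.seed, cfg.n_participants)
    all_records = []
    conf_rows = []
    truth_entries = []
    for pid in range(cfg.n_participants):
        ss = np.random.SeedSequence([int(cfg.seed) % (2**31), 101, pid])
        r_par, r_t1, r_t2, r_conf, r_order = [
            np.random.default_rng(s) for s in ss.spawn(5)]
        if cfg.regime == "structured":
            params, extras = _structured_params(cfg, spec, r_par)
        else:
            params, extras = _uniform_params(cfg, spec, r_par)
        design = designs[pid]
        theta = spec.pack(**params)
        noise = cfg.sigma > 0
        rec1, final = simulate_trajectory(
            spec, theta, design, "T1", rng=r_t1, noise=noise,
            interleave_rng=r_order, return_final=True)
        if cfg.carryover_t2_sv:
            for a in te.AGENTS:
                for b in te.ABILITIES:
                    prev = "Low" if b == "High" else "High"
                    params[f"sv_T2_{a}_{b}"] = float(np.clip(final[(a, prev)], 1, 99))
        elif cfg.regime == "uniform":
            pass  # keep the independently drawn T2 SVs
        theta = spec.pack(**params)
        rec2 = simulate_trajectory(spec, theta, design, "T2", rng=r_t2,
                                   noise=noise, interleave_rng=r_order)
        all_records.extend(rec1)
        all_records.extend(rec2)
        conf_rows.extend(_confidence_rows(cfg, pid, extras, r_conf))
        truth_entries.append({"participant": pid, "params": params,
                              "extras": extras})
    trials = te.records_to_frame(all_records)
    confidence = pd.DataFrame(conf_rows)[list(CONFIDENCE_COLUMNS)]
    truth = CohortTruth(cfg.model_id, spec.param_names, truth_entries)
    return CohortSample(trials, confidence, truth, cfg)


def paper_like_preset(n_participants: int = 99, seed: int = 7) -> CohortConfig:
    """The documented default cohort: structured M7 population effects.

    Generating moments target the qualitative empirical pattern: a negative
    mean self valence bias and positive other bias at T1, halved learning
    rates at T2, a positive correlation between initial self expectation and
    self bias, and confidence that rises over T1 and decays slightly at T2.
    """
    return CohortConfig(n_participants=n_participants, model_id="M7", seed=seed,
                        regime="structured")


def recovery_preset(model_id: str = "M7", n_participants: int = 30,
                    seed: int = 0, sigma: float = 8.0) -> CohortConfig:
    """Uniform-parameter cohort for parameter- and model-recovery experiments."""
    return CohortConfig(n_participants=n_participants, model_id=model_id,
                        seed=seed, regime="uniform", sigma=sigma)
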