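"""Parameter-, model-recovery, and directional-reproduction experiments.

These are the package's validation surface: simulate cohorts with known
ground truth, run the full fitting and model-selection machinery on them,
and quantify how well generating parameters and generating models are
identified.  The same entry points back the test suite and the acceptance
script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .inference import FitConfig, fit_participant
from .metrics import correlate, initial_expectation, spearman_ci, valence_bias_table
from .model_comparison import psis_loo, rfx_bms
from .model_space import get_model
from .synthetic_cohort import CohortSample, paper_like_preset, recovery_preset, sample_cohort

#: models able to exactly mimic a generating model's trajectories at that
#: model's parameter regime (its own id included)
NESTING_EQUIVALENT = {
    "M1": ("M1", "M2", "M3", "M4", "M5", "M6", "M7", "M8"),
    "M2": ("M2", "M5"),
    "M3": ("M3", "M6", "M7"),
    "M4": ("M4", "M5", "M6", "M7", "M8"),
    "M5": ("M5",),
    "M6": ("M6", "M7"),
    "M7": ("M7",),
    "M8": ("M8",),
    "M9": ("M9",),
}


def fit_cohort(sample: CohortSample, model_ids, method: str = "map",
               config: FitConfig | None = None, seed: int = 0) -> dict:
    """Fit each model to each participant; returns {model_id: {pid: summary}}."""
    from dataclasses import replace

    base = config or FitConfig()
    fits: dict = {m: {} for m in model_ids}
    pids = sorted(sample.trials["participant"].unique())
    for m in model_ids:
        spec = get_model(m)
        m_off = int(m[1:]) if m[1:].isdigit() else 0
        for pid in pids:
            cfg = replace(base, seed=int((seed * 1000 + pid * 10 + m_off) % (2**31)))
            tr = sample.trials[sample.trials["participant"] == pid]
            fits[m][pid] = fit_participant(spec, tr, cfg, method=method)
    return fits


def evidence_matrix(fits: dict, model_ids, session: str | None = None) -> np.ndarray:
    """Participants x models matrix of total PSIS-LOO scores.

    With ``session`` given, only that session's trials enter the totals
    (columns of the pointwise log-lik matrix are in canonical cell order,
    T1 cells first).
    """
    pids = sorted(fits[model_ids[0]].keys())
    L = np.empty((len(pids), len(model_ids)))
    for j, m in enumerate(model_ids):
        for i, pid in enumerate(pids):
            ll = fits[m][pid].loglik
            if session is not None:
                half = ll.shape[1] // 2
                ll = ll[:, :half] if session == "T1" else ll[:, half:]
            L[i, j] = psis_loo(ll).elpd
    return L


def parameter_recovery(seed: int = 11, n_participants: int = 30,
                       sigma: float = 8.0, method: str = "map",
                       config: FitConfig | None = None) -> dict:
    """Fit M7 to a uniform-parameter M7 cohort and score recovery.

    Reports the Spearman rank correlation between generating and recovered
    values per learning-rate index, and the mean absolute error of the
    starting values (percentile points).
    """
    cfg = recovery_preset("M7", n_participants, seed=seed, sigma=sigma)
    sample = sample_cohort(cfg)
    spec = get_model("M7")
    fits = fit_cohort(sample, ["M7"], method=method, config=config, seed=seed)["M7"]
    gen = sample.truth.params_frame()
    rec = pd.DataFrame({pid: s.means for pid, s in fits.items()}).T.sort_index()
    alpha_corr = {}
    for name in spec.param_names:
        if name.startswith("alpha"):
            rho, _ = stats.spearmanr(gen[name], rec[name])
            alpha_corr[name] = float(rho)
    sv_cols = [n for n in spec.param_names if n.startswith("sv")]
    sv_mae = float(np.mean(np.abs(gen[sv_cols].to_numpy() - rec[sv_cols].to_numpy())))
    return {
        "alpha_rank_corr": alpha_corr,
        "min_alpha_rank_corr": min(alpha_corr.values()),
        "sv_mae": sv_mae,
        "generating": gen,
        "recovered": rec,
    }


def model_recovery(seed: int = 23, gen_models=("M1", "M3", "M7"),
                   fit_models=("M1", "M3", "M7"), n_participants: int = 30,
                   sigma: float = 8.0, method: str = "map",
                   config: FitConfig | None = None) -> dict:
    """Generate a cohort from each model, compare all candidates by RFX-BMS.

    A recovery counts as correct when the highest-pxp model is the generating
    model or one able to exactly mimic it at the generating parameter regime.
    """
    results = {}
    for k, gm in enumerate(gen_models):
        cfg = recovery_preset(gm, n_participants, seed=seed + 100 * k, sigma=sigma)
        sample = sample_cohort(cfg)
        fits = fit_cohort(sample, fit_models, method=method, config=config,
                          seed=seed + 100 * k)
        L = evidence_matrix(fits, list(fit_models))
        bms = rfx_bms(L, models=list(fit_models), seed=seed)
        winner = fit_models[int(np.argmax(bms.pxp))]
        allowed = [m for m in fit_models if m in NESTING_EQUIVALENT[gm]]
        results[gm] = {
            "evidence": L,
            "bms": bms,
            "winner": winner,
            "winner_pxp": float(bms.pxp.max()),
            "correct": winner in allowed,
            "allowed": allowed,
        }
    results["n_correct"] = sum(r["correct"] for m, r in results.items()
                               if isinstance(r, dict))
    return results


def directional_reproduction(seed: int = 42, n_participants: int = 60,
                             method: str = "map",
                             config: FitConfig | None = None) -> dict:
    """Fit M7 to a paper-like preset cohort and compute the headline statistics.

    Returns fitted cohort means of the valence bias scores per agent and
    session, mean learning rates per session, and the Spearman correlation
    between initial self expectation (trial-1 ratings averaged over the two
    self cells at T1) and the T1 self valence bias.
    """
    cfg = paper_like_preset(n_participants, seed=seed)
    sample = sample_cohort(cfg)
    fits = fit_cohort(sample, ["M7"], method=method, config=config, seed=seed)["M7"]
    return directional_stats(sample, fits)


def directional_stats(sample: CohortSample, fits: dict) -> dict:
    """Cohort-level statistics from fitted M7 summaries (see
    :func:`directional_reproduction`)."""
    bias = valence_bias_table({pid: s.means for pid, s in fits.items()})

    def mean_bias(agent, session):
        sel = bias[(bias.agent == agent) & (bias.session == session)]
        return float(sel["bias"].mean())

    def mean_alpha(session):
        return float(bias[bias.session == session]["mean_alpha"].mean())

    init_self = initial_expectation(sample.trials, "Self", "T1")
    self_bias_t1 = (bias[(bias.agent == "Self") & (bias.session == "T1")]
                    .set_index("participant")["bias"].reindex(init_self.index))
    rho, ci, p = spearman_ci(init_self.to_numpy(), self_bias_t1.to_numpy())

    # confidence couplings on the same cohort
    conf = sample.confidence
    post_t1_self = (conf[(conf.agent == "Self") & (conf.timepoint == "post-T1")]
                    .groupby("participant")["confidence"].mean())
    pre_t2_self = (conf[(conf.agent == "Self") & (conf.timepoint == "pre-T2")]
                   .groupby("participant")["confidence"].mean())
    m7 = {pid: s.means for pid, s in fits.items()}
    from .metrics import mean_learning_rate
    alpha_t1_self = pd.Series({pid: mean_learning_rate(p_, "Self", "T1")
                               for pid, p_ in m7.items()})
    alpha_t2_self = pd.Series({pid: mean_learning_rate(p_, "Self", "T2")
                               for pid, p_ in m7.items()})
    fam = correlate({
        "init_self_x_bias_self_T1": (init_self.to_numpy(), self_bias_t1.to_numpy()),
        "conf_postT1_self_x_alpha_T1_self": (post_t1_self.reindex(alpha_t1_self.index).to_numpy(),
                                             alpha_t1_self.to_numpy()),
        "conf_preT2_self_x_alpha_T2_self": (pre_t2_self.reindex(alpha_t2_self.index).to_numpy(),
                                            alpha_t2_self.to_numpy()),
    })
    return {
        "bias_table": bias,
        "t1_self_bias_mean": mean_bias("Self", "T1"),
        "t1_other_bias_mean": mean_bias("Other", "T1"),
        "t2_self_bias_mean": mean_bias("Self", "T2"),
        "t2_other_bias_mean": mean_bias("Other", "T2"),
        "mean_alpha_t1": mean_alpha("T1"),
        "mean_alpha_t2": mean_alpha("T2"),
        "init_self_bias_rho": float(rho),
        "init_self_bias_p": float(p),
        "correlations": fam,
    }
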