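"""Derived statistics: valence bias scores, learning-rate aggregates, and the
Spearman/FDR correlation plumbing that links biases to expectations and
confidence.

The valence bias score of an agent x session learning-rate pair is

    (alpha_PE+ - alpha_PE-) / (alpha_PE+ + alpha_PE-)  in [-1, 1];

positive values mean stronger updating from better-than-expected feedback.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .task_engine import AGENTS, SESSIONS


def valence_bias(alpha_plus, alpha_minus):
    """Normalized learning-rate asymmetry; NaN (flagged missing) when both rates are 0."""
    ap = np.asarray(alpha_plus, dtype=float)
    am = np.asarray(alpha_minus, dtype=float)
    if np.any(ap < 0) or np.any(am < 0):
        raise ValueError("learning rates must be non-negative")
    total = ap + am
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, (ap - am) / total, np.nan)
    return float(out) if out.ndim == 0 else out


def mean_learning_rate(params: dict, agent: str, session: str) -> float:
    """Learning rate averaged over PE valence for one agent x session (M6/M7 fits)."""
    ap = params[f"alpha_{session}_{agent}_PE+"]
    am = params[f"alpha_{session}_{agent}_PE-"]
    return 0.5 * (ap + am)


def valence_bias_table(fits: dict) -> pd.DataFrame:
    """Tidy per-participant valence bias scores from session-split valence fits.

    ``fits`` maps participant id -> parameter dict (name -> posterior mean)
    of an M6/M7-style fit.  One row per participant x agent x session.
    """
    rows = []
    for pid, params in fits.items():
        for s in SESSIONS:
            for a in AGENTS:
                rows.append({
                    "participant": pid, "session": s, "agent": a,
                    "bias": valence_bias(params[f"alpha_{s}_{a}_PE+"],
                                         params[f"alpha_{s}_{a}_PE-"]),
                    "mean_alpha": mean_learning_rate(params, a, s),
                })
    return pd.DataFrame(rows)


def initial_expectation(trials: pd.DataFrame, agent: str, session: str,
                        former_ability: str | None = None) -> pd.Series:
    """Per-participant initial expectation: the trial-1 rating of a condition.

    At T1 the two ability cells are averaged (they are still indistinguishable
    to the participant before any feedback); at T2 pass ``former_ability`` to
    select the cell by its T1 ability label (the current label is reversed).
    """
    sub = trials[(trials["agent"] == agent) & (trials["session"] == session)
                 & (trials["trial"] == 1)]
    if session == "T2" and former_ability is not None:
        current = "Low" if former_ability == "High" else "High"
        sub = sub[sub["ability"] == current]
    return sub.groupby("participant")["expectation"].mean()


def spearman_ci(x, y, conf: float = 0.95):
    """Spearman rho with a Fisher-z confidence interval and two-sided p.

    The CI uses the Bonett-Wright standard error sqrt((1 + rho^2/2)/(n - 3)),
    a rank-based correction of the Pearson Fisher interval.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need >= 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: rho undefined")
    rho, p = stats.spearmanr(x, y)
    z = np.arctanh(np.clip(rho, -0.999999, 0.999999))
    se = np.sqrt((1 + rho**2 / 2) / (len(x) - 3))
    crit = stats.norm.ppf(0.5 + conf / 2)
    lo, hi = np.tanh(z - crit * se), np.tanh(z + crit * se)
    return float(rho), (float(lo), float(hi)), float(p)


def correlate(pairs: dict, conf: float = 0.95) -> pd.DataFrame:
    """Spearman correlations for a declared family of tests, BH-FDR adjusted.

    ``pairs`` maps a test label to an (x, y) tuple of paired per-participant
    values; the Benjamini-Hochberg correction is applied across the whole
    family.  Returns one row per test: rho, CI, p, p_fdr.
    """
    from statsmodels.stats.multitest import multipletests

    rows = []
    for label, (x, y) in pairs.items():
        rho, (lo, hi), p = spearman_ci(x, y, conf)
        rows.append({"test": label, "n": len(np.asarray(x)), "rho": rho,
                     "ci_low": lo, "ci_high": hi, "p": p})
    df = pd.DataFrame(rows)
    df["p_fdr"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df
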