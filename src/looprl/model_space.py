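"""The nine-model space of delta-rule learning models for expectation ratings.

Every learning model updates a latent performance expectation per condition by
a Rescorla-Wagner delta rule,

    EXP[t+1] = EXP[t] + alpha * PE[t],        PE[t] = FB[t] - EXP[t],

with the learning rate ``alpha`` partitioned differently across models:

==  =========================================  ==============================
id  alpha partition                            extras
==  =========================================  ==============================
M1  agent                                      shared across sessions
M2  agent x ability                            shared across sessions
M3  agent x PE valence                         shared across sessions
M4  session x agent
M5  session x agent x ability
M6  session x agent x PE valence
M7  session x agent x PE valence               per-session weighting factor w
M8  session x agent x PE congruency
M9  (no learning) one free mean per condition
==  =========================================  ==============================

M7, the extended valence model, additionally discounts updates from extreme
feedback: the update is scaled by ``1 - w_s * ND(FB)`` where ``ND`` is the
relative normal density over the percentile scale (peak 1 at 50) and ``w_s``
is a free per-session weight.  All models except M9 carry freely estimated
starting values (SV, one per session x agent x ability cell, the trial-1
prediction); every model has a single observation noise ``sigma``, the scale
of a [0, 100]-truncated normal around the latent prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import log_ndtr

from .task_engine import ABILITIES, AGENTS, SESSIONS, ParticipantDesign, run_session

#: scale of the normal-density discounting curve over the feedback scale.
#: Fixed (not a free parameter): roughly scale/6, so the density is near zero
#: at the extremes of the percentile scale, matching a curve that leaves
#: mid-scale feedback undiscounted.
DEFAULT_SIGMA_ND = 17.0

_SPLIT_LEVELS = {
    "none": (None,),
    "ability": ("High", "Low"),
    "valence": ("PE+", "PE-"),
    "congruency": ("congruent", "incongruent"),
}


def nd_weight(fb, sigma_nd: float = DEFAULT_SIGMA_ND):
    """Relative normal density of a feedback percentile (mean 50, scale sigma_nd).

    Normalized to 1 at the scale midpoint, symmetric, decreasing toward 0/100.
    """
    if sigma_nd <= 0:
        raise ValueError("sigma_nd must be positive")
    fb = np.asarray(fb, dtype=float)
    out = np.exp(-((fb - 50.0) ** 2) / (2.0 * sigma_nd**2))
    return float(out) if out.ndim == 0 else out


def congruency(ability: str, pe_sign: int) -> str:
    """PE congruency with a cell's majority valence at the current session.

    High-ability cells are dominated by positive PEs, low-ability cells by
    negative ones, so a positive PE is congruent iff the cell is High.
    """
    if pe_sign not in (+1, -1):
        raise ValueError("pe_sign must be +1 or -1")
    if (ability == "High") == (pe_sign > 0):
        return "congruent"
    return "incongruent"


def delta_update(exp, fb, alpha, w=0.0, sigma_nd: float = DEFAULT_SIGMA_ND):
    """One delta-rule step: EXP + alpha*PE*(1 - w*ND(FB))."""
    return exp + alpha * (fb - exp) * (1.0 - w * nd_weight(fb, sigma_nd))


@dataclass(frozen=True)
class ModelSpec:
    """Structure of one member of the model space (parameter layout and update rule)."""

    model_id: str
    label: str
    by_session: bool = False
    split: str = "none"
    has_w: bool = False
    mean_model: bool = False

    # ---- parameter layout -------------------------------------------------
    @property
    def alpha_labels(self) -> tuple:
        if self.mean_model:
            return ()
        sess = SESSIONS if self.by_session else ("",)
        labels = []
        for s in sess:
            for a in AGENTS:
                for lv in _SPLIT_LEVELS[self.split]:
                    parts = [p for p in (s, a, lv) if p]
                    labels.append("alpha_" + "_".join(parts))
        return tuple(labels)

    @property
    def n_alpha(self) -> int:
        return len(self.alpha_labels)

    @property
    def sv_labels(self) -> tuple:
        prefix = "mean" if self.mean_model else "sv"
        return tuple(
            f"{prefix}_{s}_{a}_{b}" for s in SESSIONS for a in AGENTS for b in ABILITIES
        )

    @property
    def param_names(self) -> tuple:
        names = list(self.alpha_labels)
        if self.has_w:
            names += [f"w_{s}" for s in SESSIONS]
        names += list(self.sv_labels)
        names.append("sigma")
        return tuple(names)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def bounds(self) -> tuple:
        b = [(0.0, 1.0)] * self.n_alpha
        if self.has_w:
            b += [(0.0, 1.0)] * 2
        b += [(0.0, 100.0)] * 8
        b.append((1e-3, 80.0))  # sigma
        return tuple(b)

    # ---- indexing helpers -------------------------------------------------
    def alpha_index(self, session: str, agent: str, ability: str, pe_sign: int) -> int:
        """Index into the parameter vector of the learning rate governing one update."""
        if self.mean_model:
            raise ValueError("mean model has no learning rates")
        n_lv = len(_SPLIT_LEVELS[self.split])
        idx = 0
        if self.by_session:
            idx += SESSIONS.index(session) * 2 * n_lv
        idx += AGENTS.index(agent) * n_lv
        if self.split == "ability":
            idx += ABILITIES.index(ability)
        elif self.split == "valence":
            idx += 0 if pe_sign > 0 else 1
        elif self.split == "congruency":
            idx += 0 if congruency(ability, pe_sign) == "congruent" else 1
        return idx

    def w_index(self, session: str) -> int:
        if not self.has_w:
            raise ValueError(f"{self.model_id} has no weighting factor")
        return self.n_alpha + SESSIONS.index(session)

    def sv_index(self, session: str, agent: str, ability: str) -> int:
        base = self.n_alpha + (2 if self.has_w else 0)
        return (base + SESSIONS.index(session) * 4
                + AGENTS.index(agent) * 2 + ABILITIES.index(ability))

    @property
    def sigma_index(self) -> int:
        return self.n_params - 1

    def pack(self, **kwargs) -> np.ndarray:
        """Build a parameter vector from named values."""
        theta = np.empty(self.n_params)
        names = self.param_names
        missing = set(names) - set(kwargs)
        extra = set(kwargs) - set(names)
        if missing or extra:
            raise ValueError(f"missing={sorted(missing)} unexpected={sorted(extra)}")
        for i, n in enumerate(names):
            theta[i] = kwargs[n]
        return theta

    def unpack(self, theta: np.ndarray) -> dict:
        return dict(zip(self.param_names, np.asarray(theta, dtype=float)))


MODELS = {
    "M1": ModelSpec("M1", "Unity"),
    "M2": ModelSpec("M2", "Ability", split="ability"),
    "M3": ModelSpec("M3", "Valence", split="valence"),
    "M4": ModelSpec("M4", "Unity (session-specific)", by_session=True),
    "M5": ModelSpec("M5", "Ability (session-specific)", by_session=True, split="ability"),
    "M6": ModelSpec("M6", "Valence (session-specific)", by_session=True, split="valence"),
    "M7": ModelSpec("M7", "Extended Valence", by_session=True, split="valence", has_w=True),
    "M8": ModelSpec("M8", "Expectation (congruency)", by_session=True, split="congruency"),
    "M9": ModelSpec("M9", "Mean", mean_model=True),
}


def get_model(model_id: str) -> ModelSpec:
    try:
        return MODELS[model_id]
    except KeyError:
        raise KeyError(f"unknown model id {model_id!r}; known: {sorted(MODELS)}") from None


# ---------------------------------------------------------------------------
# trial containers and batched prediction
# ---------------------------------------------------------------------------

@dataclass
class CellData:
    """Observed trials of one condition cell, in trial order."""

    session: str
    agent: str
    ability: str
    feedback: np.ndarray
    observed: np.ndarray


def cells_from_frame(trials) -> list:
    """Split a long-format trial table into canonical per-cell arrays.

    Cells are ordered session (T1, T2) x agent (Self, Other) x ability
    (High, Low); sessions or cells absent from the table are skipped.
    """
    cells = []
    for s in SESSIONS:
        for a in AGENTS:
            for b in ABILITIES:
                sub = trials[(trials["session"] == s)
                             & (trials["agent"] == a)
                             & (trials["ability"] == b)]
                if len(sub) == 0:
                    continue
                sub = sub.sort_values("trial")
                cells.append(CellData(
                    s, a, b,
                    feedback=sub["feedback"].to_numpy(dtype=float),
                    observed=sub["expectation"].to_numpy(dtype=float),
                ))
    return cells


def predict_cell(spec: ModelSpec, theta: np.ndarray, cell: CellData,
                 sigma_nd: float = DEFAULT_SIGMA_ND) -> np.ndarray:
    """Latent expectation trajectory predicted for one cell, batched over
    parameter vectors.

    ``theta`` has shape (B, P); the result has shape (B, T).  Trial t's
    prediction is the latent expectation before feedback t; trial 1 is the SV
    (M9: the condition mean throughout).  The recursion is driven by the
    observed feedback sequence only.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    T = len(cell.feedback)
    if spec.mean_model:
        mu = theta[:, spec.sv_index(cell.session, cell.agent, cell.ability)]
        return np.repeat(mu[:, None], T, axis=1)
    pred = np.empty((theta.shape[0], T))
    exp = theta[:, spec.sv_index(cell.session, cell.agent, cell.ability)].copy()
    i_pos = spec.alpha_index(cell.session, cell.agent, cell.ability, +1)
    i_neg = spec.alpha_index(cell.session, cell.agent, cell.ability, -1)
    w = theta[:, spec.w_index(cell.session)] if spec.has_w else 0.0
    for t in range(T):
        pred[:, t] = exp
        fb = cell.feedback[t]
        pe = fb - exp
        alpha = np.where(pe >= 0, theta[:, i_pos], theta[:, i_neg])
        gain = 1.0 - w * nd_weight(fb, sigma_nd) if spec.has_w else 1.0
        exp = exp + alpha * pe * gain
    return pred


def update_expectation(spec: ModelSpec, theta: np.ndarray, exp: float,
                       session: str, agent: str, ability: str, fb: float,
                       sigma_nd: float = DEFAULT_SIGMA_ND) -> float:
    """Single model-aware delta-rule step for one cell (PE = 0 is a no-op)."""
    if spec.mean_model:
        raise ValueError("mean model does not update expectations")
    theta = np.asarray(theta, dtype=float)
    pe = fb - exp
    if pe == 0:
        return float(exp)
    alpha = theta[spec.alpha_index(session, agent, ability, +1 if pe > 0 else -1)]
    w = theta[spec.w_index(session)] if spec.has_w else 0.0
    return float(delta_update(exp, fb, alpha, w, sigma_nd))


def _log_diff_ndtr(b: np.ndarray, a: np.ndarray) -> np.ndarray:
    """log(Phi(b) - Phi(a)) for a < b, stable in both tails."""
    b = np.asarray(b, dtype=float)
    a = np.asarray(a, dtype=float)
    # reflect when the interval sits in the upper tail
    flip = (a + b) > 0
    lo = np.where(flip, -b, a)
    hi = np.where(flip, -a, b)
    l_hi = log_ndtr(hi)
    l_lo = log_ndtr(lo)
    with np.errstate(divide="ignore"):
        return l_hi + np.log1p(-np.exp(np.minimum(l_lo - l_hi, -1e-300)))


def truncnorm_logpdf(x, mu, sigma, lo: float = 0.0, hi: float = 100.0):
    """Log density of a normal truncated to [lo, hi] (broadcasting arguments)."""
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    z = (x - mu) / sigma
    log_z = _log_diff_ndtr((hi - mu) / sigma, (lo - mu) / sigma)
    out = -0.5 * z**2 - 0.5 * np.log(2 * np.pi) - np.log(sigma) - log_z
    return np.where((x < lo) | (x > hi), -np.inf, out)


def _predict_stacked(spec: ModelSpec, theta: np.ndarray, cells,
                     sigma_nd: float) -> np.ndarray:
    """Predictions for equal-length cells, vectorized over cells and batch.

    Returns shape (B, C*T) with cells concatenated in list order; numerically
    identical to per-cell :func:`predict_cell`, just one time loop of T steps.
    """
    B = theta.shape[0]
    C = len(cells)
    T = len(cells[0].feedback)
    fb = np.array([c.feedback for c in cells])                      # (C, T)
    sv_idx = [spec.sv_index(c.session, c.agent, c.ability) for c in cells]
    if spec.mean_model:
        return np.repeat(theta[:, sv_idx][:, :, None], T, axis=2).reshape(B, C * T)
    i_pos = [spec.alpha_index(c.session, c.agent, c.ability, +1) for c in cells]
    i_neg = [spec.alpha_index(c.session, c.agent, c.ability, -1) for c in cells]
    if spec.has_w:
        w = theta[:, [spec.w_index(c.session) for c in cells]]      # (B, C)
        nd = nd_weight(fb, sigma_nd)                                # (C, T)
    exp = theta[:, sv_idx].copy()                                   # (B, C)
    pred = np.empty((B, C, T))
    for t in range(T):
        pred[:, :, t] = exp
        pe = fb[:, t][None, :] - exp
        alpha = np.where(pe >= 0, theta[:, i_pos], theta[:, i_neg])
        gain = 1.0 - w * nd[:, t][None, :] if spec.has_w else 1.0
        exp = exp + alpha * pe * gain
    return pred.reshape(B, C * T)


def pointwise_loglik(spec: ModelSpec, theta: np.ndarray, cells,
                     sigma_nd: float = DEFAULT_SIGMA_ND) -> np.ndarray:
    """Per-trial log density of the observed ratings under the model.

    Observations are scored by a [0, 100]-truncated normal centred on the
    model's latent prediction with scale ``sigma``; the first trial of each
    cell is scored against the SV.  ``theta`` may be a single vector or a
    (B, P) batch; returns shape (B, total trials) with cells concatenated in
    canonical order.
    """
    if hasattr(cells, "columns"):
        cells = cells_from_frame(cells)
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    sigma = theta[:, spec.sigma_index]
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    if not cells:
        return np.zeros((theta.shape[0], 0))
    lengths = {len(c.feedback) for c in cells}
    if len(lengths) == 1:
        pred = _predict_stacked(spec, theta, cells, sigma_nd)
        obs = np.concatenate([c.observed for c in cells])
        return truncnorm_logpdf(obs[None, :], pred, sigma[:, None])
    parts = []
    for cell in cells:
        pred = predict_cell(spec, theta, cell, sigma_nd)
        parts.append(truncnorm_logpdf(cell.observed[None, :], pred, sigma[:, None]))
    return np.concatenate(parts, axis=1)


def simulate_trajectory(spec: ModelSpec, theta: np.ndarray, design: ParticipantDesign,
                        session: str, rng: np.random.Generator | None = None,
                        noise: bool = True,
                        sigma_nd: float = DEFAULT_SIGMA_ND,
                        interleave_rng: np.random.Generator | None = None,
                        initial_latent: dict | None = None,
                        return_final: bool = False):
    """Simulate one session of the closed loop between a model agent and the task.

    The latent expectation per cell starts at the SV (or at values supplied in
    ``initial_latent``, keyed by (agent, ability)), updates by the model's rule
    with PE = FB - latent, and is read out on every trial as a rating — exact
    when ``noise`` is off, otherwise a [0, 100]-truncated normal draw with the
    model's sigma.  Feedback follows the adaptive rule applied to the reported
    ratings.  Returns the TrialRecords, or ``(records, final_latent)`` with the
    post-session latent expectation per (agent, ability) cell when
    ``return_final`` is set (used to carry beliefs over into the next session).
    """
    if spec.mean_model:
        raise ValueError("mean model has no trajectory dynamics")
    theta = np.asarray(theta, dtype=float)
    sigma = theta[spec.sigma_index]
    if noise and rng is None:
        raise ValueError("rng required when noise is on")
    latent: dict = {}
    n_seen: dict = {}

    def behave(cond, hist):
        key = (cond.agent, cond.ability)
        if key not in latent:
            if initial_latent is not None and key in initial_latent:
                latent[key] = float(initial_latent[key])
            else:
                latent[key] = theta[spec.sv_index(session, cond.agent, cond.ability)]
            n_seen[key] = 0
        while n_seen[key] < len(hist):
            fb_prev = hist[n_seen[key]][1]
            latent[key] = update_expectation(
                spec, theta, latent[key], session, cond.agent, cond.ability,
                fb_prev, sigma_nd)
            n_seen[key] += 1
        if not noise or sigma == 0:
            return float(np.clip(latent[key], 0.0, 100.0))
        mu = latent[key]
        a, b = (0.0 - mu) / sigma, (100.0 - mu) / sigma
        return float(stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, random_state=rng))

    records = run_session(behave, design, session, rng=interleave_rng)
    if not return_final:
        return records
    # flush the update from each cell's last feedback so the carried-over
    # belief reflects the full session
    hist_by_cell: dict = {}
    for r in records:
        hist_by_cell.setdefault((r.agent, r.ability), []).append((r.expectation, r.feedback))
    final = {}
    for key, hist in hist_by_cell.items():
        val = latent[key]
        for _, fb in hist[n_seen[key]:]:
            val = update_expectation(spec, theta, val, session, key[0], key[1],
                                     fb, sigma_nd)
        final[key] = val
    return records, final
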