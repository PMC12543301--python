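"""Adaptive-feedback task engine for the LOOP (Learning of Own Performance) paradigm.

The task presents, per participant and session, four interleaved learning
conditions (Agent: Self/Other x Ability: High/Low), each bound to one of four
estimation categories and comprising 20 trials.  Feedback on each trial is a
percentile computed from the participant's own recent expectation ratings (the
trailing mean of the last five ratings in that category, 50 before the first
rating) plus a predefined signed modifier.  High-ability cells receive 70%
positive modifiers, low-ability cells 30%.  At the second session (T2) the
ability contingency of every category is reversed: the modifier sequence is
negated, so prediction errors keep their magnitudes but flip valence.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Callable, Sequence

import numpy as np
import pandas as pd

SESSIONS = ("T1", "T2")
AGENTS = ("Self", "Other")
ABILITIES = ("High", "Low")
CATEGORIES = ("heights", "weights", "quantities", "distances")

#: canonical order of the four (agent, ability) cells within a session
CELLS = tuple((a, b) for a in AGENTS for b in ABILITIES)

N_TRIALS = 20
N_POSITIVE_HIGH = 14  # 70% of 20
N_POSITIVE_LOW = 6    # 30% of 20

#: default modifier magnitudes (percentile points), cycled to 20 per cell
DEFAULT_MAGNITUDES = (5.0, 8.0, 11.0, 14.0, 17.0, 20.0, 23.0, 26.0)

MAX_INCENTIVE_CENTS = 6.0

TRIAL_COLUMNS = (
    "participant", "session", "agent", "ability", "category",
    "trial", "expectation", "feedback", "pe", "modifier",
)


@dataclass(frozen=True)
class ConditionKey:
    """One learning condition: a session-specific (agent, ability) cell and its category."""

    session: str
    agent: str
    ability: str
    category: str

    def __post_init__(self):
        if self.session not in SESSIONS:
            raise ValueError(f"unknown session {self.session!r}")
        if self.agent not in AGENTS:
            raise ValueError(f"unknown agent {self.agent!r}")
        if self.ability not in ABILITIES:
            raise ValueError(f"unknown ability {self.ability!r}")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass(frozen=True)
class FeedbackPlan:
    """Ordered signed modifier values (percentile units) for one cell's 20 trials."""

    modifiers: tuple

    def __post_init__(self):
        if any(m == 0 for m in self.modifiers):
            raise ValueError("modifiers must be nonzero")

    @property
    def n_positive(self) -> int:
        return sum(1 for m in self.modifiers if m > 0)

    @property
    def abs_multiset(self) -> tuple:
        return tuple(sorted(abs(m) for m in self.modifiers))


@dataclass
class TrialRecord:
    participant: int
    session: str
    agent: str
    ability: str
    category: str
    trial: int
    expectation: float
    feedback: float
    pe: float
    modifier: float
    clipped: bool = False


@dataclass
class ParticipantDesign:
    """Category assignment and per-cell feedback plans for one participant.

    ``assignment`` maps each T1 (agent, ability) cell to its estimation
    category; the mapping of categories to cells is identical at T2 except
    that the ability label of every category flips.  ``plans`` is keyed by
    (session, agent, ability) with ability being the *current* session label.
    """

    participant: int
    assignment: dict
    plans: dict

    def condition(self, session: str, agent: str, ability: str) -> ConditionKey:
        if session == "T1":
            category = self.assignment[(agent, ability)]
        else:
            # at T2 the cell labelled `ability` holds the category that was
            # the opposite ability at T1
            other = "Low" if ability == "High" else "High"
            category = self.assignment[(agent, other)]
        return ConditionKey(session, agent, ability, category)

    def cells(self, session: str):
        return [self.condition(session, a, b) for a, b in CELLS]

    def to_json_dict(self) -> dict:
        return {
            "participant": self.participant,
            "assignment": {f"{a}|{b}": c for (a, b), c in self.assignment.items()},
            "plans": {f"{s}|{a}|{b}": list(p.modifiers) for (s, a, b), p in self.plans.items()},
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "ParticipantDesign":
        assignment = {tuple(k.split("|")): v for k, v in d["assignment"].items()}
        plans = {tuple(k.split("|")): FeedbackPlan(tuple(v)) for k, v in d["plans"].items()}
        return cls(d["participant"], assignment, plans)


def reference_belief(history: Sequence[float]) -> float:
    """Trailing mean of the last five expectation ratings of a category (50 if none yet)."""
    for r in history:
        if not (0 <= r <= 100):
            raise ValueError(f"rating {r} outside [0, 100]")
    if len(history) == 0:
        return 50.0
    tail = list(history)[-5:]
    return float(np.mean(tail))


def compute_feedback(reference: float, modifier: float) -> float:
    """Feedback percentile: reference belief plus modifier, clipped to the scale."""
    if not (0 <= reference <= 100):
        raise ValueError(f"reference {reference} outside [0, 100]")
    return float(np.clip(reference + modifier, 0.0, 100.0))


def trial_incentive(expectation: float, feedback: float,
                    max_cents: float = MAX_INCENTIVE_CENTS) -> float:
    """Accuracy incentive in cents: the full amount at zero expectation error,
    falling linearly to zero at the maximal possible error of 100 points."""
    return max_cents * max(0.0, 1.0 - abs(feedback - expectation) / 100.0)


def reverse_contingencies(plan: FeedbackPlan) -> FeedbackPlan:
    """T2 plan for a category: negate every modifier.

    This flips the sign pattern to that of the opposite ability level while
    preserving the multiset of modifier magnitudes, so prediction errors are
    identical in absolute magnitude across sessions but differ in valence.
    """
    return FeedbackPlan(tuple(-m for m in plan.modifiers))


def _sign_pattern(n_positive: int, rng: np.random.Generator,
                  constrain_start: bool = True) -> np.ndarray:
    signs = np.array([1.0] * n_positive + [-1.0] * (N_TRIALS - n_positive))
    majority = 1.0 if n_positive >= N_TRIALS / 2 else -1.0
    for _ in range(1000):
        rng.shuffle(signs)
        if not constrain_start:
            return signs.copy()
        # avoid two leading trials that both contradict the cell's majority valence
        if not (signs[0] != majority and signs[1] != majority):
            return signs.copy()
    raise RuntimeError("could not satisfy start constraint")  # pragma: no cover


def _cell_plan(ability: str, rng: np.random.Generator,
               magnitudes: Sequence[float], constrain_start: bool) -> FeedbackPlan:
    n_pos = N_POSITIVE_HIGH if ability == "High" else N_POSITIVE_LOW
    signs = _sign_pattern(n_pos, rng, constrain_start)
    mags = np.resize(np.asarray(magnitudes, dtype=float), N_TRIALS)
    mags = rng.permutation(mags)
    return FeedbackPlan(tuple(signs * mags))


def make_design(seed: int, n_participants: int,
                magnitudes: Sequence[float] = DEFAULT_MAGNITUDES,
                constrain_start: bool = True) -> list:
    """Counterbalanced designs for ``n_participants`` participants.

    Categories rotate through the four (agent, ability) cells in a Latin-square
    cycle across participants, so every category serves every cell as evenly as
    possible.  All randomness (sign order, magnitude order) derives from
    ``seed``; the same seed reproduces the design byte for byte.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    rng = np.random.default_rng(seed)
    designs = []
    for p in range(n_participants):
        assignment = {cell: CATEGORIES[(i + p) % 4] for i, cell in enumerate(CELLS)}
        plans = {}
        for agent, ability in CELLS:
            t1 = _cell_plan(ability, rng, magnitudes, constrain_start)
            plans[("T1", agent, ability)] = t1
        for agent, ability in CELLS:
            # the T2 cell labelled `ability` continues the category that was the
            # opposite ability at T1; its modifiers are the negated T1 sequence
            other = "Low" if ability == "High" else "High"
            plans[("T2", agent, ability)] = reverse_contingencies(plans[("T1", agent, other)])
        designs.append(ParticipantDesign(p, assignment, plans))
    return designs


def run_session(agent_behavior: Callable, design: ParticipantDesign, session: str,
                rng: np.random.Generator | None = None) -> list:
    """Run one session's closed loop between ratings and adaptive feedback.

    ``agent_behavior(condition, history)`` must return a rating in [0, 100],
    where ``history`` is the list of (expectation, feedback) pairs already
    recorded for that condition.  Trials of the four cells are interleaved
    round-robin; if ``rng`` is given, cell order is shuffled within each
    round of four, as in the pseudo-random presentation of the task.
    """
    conditions = design.cells(session)
    histories = {c: [] for c in conditions}
    trial_idx = {c: 0 for c in conditions}
    records = []
    for rnd in range(N_TRIALS):
        order = list(range(4))
        if rng is not None:
            order = list(rng.permutation(4))
        for i in order:
            cond = conditions[i]
            hist = histories[cond]
            exp = float(agent_behavior(cond, hist))
            if not (0 <= exp <= 100):
                raise ValueError(f"agent rating {exp} outside [0, 100]")
            ref = reference_belief([h[0] for h in hist])
            t = trial_idx[cond]
            modifier = design.plans[(session, cond.agent, cond.ability)].modifiers[t]
            fb = compute_feedback(ref, modifier)
            records.append(TrialRecord(
                participant=design.participant, session=session,
                agent=cond.agent, ability=cond.ability, category=cond.category,
                trial=t + 1, expectation=exp, feedback=fb, pe=fb - exp,
                modifier=float(modifier), clipped=bool(ref + modifier != fb),
            ))
            hist.append((exp, fb))
            trial_idx[cond] = t + 1
    return records


def records_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(r) for r in records])
    return df[list(TRIAL_COLUMNS)]
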