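"""Dose schedules and the two-state Markov model of medication adherence.

A prescription is a deterministic sequence of planned dose events (the
regimen).  Whether each dose is actually taken is modelled by a two-state
Markov chain over consecutive doses: a patient who took yesterday's dose
takes today's with probability p_t; one who missed yesterday's misses again
with probability q_nt.  The chain's transition matrix is

    P = [[p_t, 1 − p_t],
         [1 − q_nt, q_nt]]

over the state order (Taking, NotTaking).  Its stationary distribution gives
the long-run fraction of missed doses, (1−p_t)/((1−p_t)+(1−q_nt)) — for the
reference scenario (p_t=0.90, q_nt=0.25) about 11.8%, i.e. a patient missing
roughly one dose in nine.
"""

from __future__ import annotations

import numpy as np

from .params import AdherenceSpec, Regimen

__all__ = [
    "AdherenceTrace",
    "build_dose_times",
    "transition_matrix",
    "simulate_adherence",
    "stationary_missed_fraction",
    "taken_fraction",
]

#: an adherence trace is a 0/1 integer array aligned with the planned doses.
AdherenceTrace = np.ndarray


def build_dose_times(r: Regimen) -> np.ndarray:
    """Planned dose times (h): start_h + k·interval_h, strictly inside the window.

    The first dose marks treatment initiation; no dose is planned at or after
    start_h + duration_h.
    """
    n = int(np.floor(r.duration_h / r.interval_h))
    return r.start_h + r.interval_h * np.arange(n, dtype=float)


def transition_matrix(p_t: float, q_nt: float) -> np.ndarray:
    """Row-stochastic 2×2 matrix of the adherence chain, order (Taking, NotTaking)."""
    if not (0.0 <= p_t <= 1.0 and 0.0 <= q_nt <= 1.0):
        raise ValueError(f"p_t and q_nt must be probabilities, got {p_t!r}, {q_nt!r}")
    return np.array([[p_t, 1.0 - p_t], [1.0 - q_nt, q_nt]])


def simulate_adherence(spec: AdherenceSpec, n_doses: int) -> AdherenceTrace:
    """Realize a taken/missed sequence for ``n_doses`` planned doses.

    The first element is drawn from the transition out of ``initial_state``
    (the chain conditions on the patient's behaviour the previous time).
    Reproducible: a fixed seed yields a bit-identical trace.
    """
    if n_doses < 0:
        raise ValueError(f"n_doses must be >= 0, got {n_doses!r}")
    rng = np.random.default_rng(spec.seed)
    taken = np.empty(n_doses, dtype=np.int64)
    state = 1 if spec.initial_state == "Taking" else 0  # 1 = Taking
    u = rng.random(n_doses)
    for i in range(n_doses):
        if state == 1:
            state = 1 if u[i] < spec.p_t else 0
        else:
            state = 0 if u[i] < spec.q_nt else 1
        taken[i] = state
    return taken


def stationary_missed_fraction(p_t: float, q_nt: float) -> float:
    """Stationary probability of the NotTaking state.

    Solving πP = π for the two-state chain gives
    π_NT = (1−p_t) / ((1−p_t) + (1−q_nt)); requires an irreducible chain
    (p_t < 1 or q_nt < 1).
    """
    if not (0.0 <= p_t <= 1.0 and 0.0 <= q_nt <= 1.0):
        raise ValueError(f"p_t and q_nt must be probabilities, got {p_t!r}, {q_nt!r}")
    denom = (1.0 - p_t) + (1.0 - q_nt)
    if denom == 0.0:
        raise ValueError("degenerate chain: p_t = q_nt = 1 has no unique stationary law")
    return (1.0 - p_t) / denom


def taken_fraction(trace: AdherenceTrace) -> float:
    """Fraction of planned doses actually taken."""
    trace = np.asarray(trace)
    if trace.size == 0:
        raise ValueError("empty adherence trace")
    return float(np.mean(trace))
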