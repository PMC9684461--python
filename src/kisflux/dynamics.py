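"""Single-gene mRNA dynamics: dM/dt = TR(t) - kd * M.

With piecewise-constant transcription the linear ODE solves in closed
form per segment, M(t) = M* + (M_start - M*) exp(-kd dt) with
M* = TR/kd, which makes the buffering-speed trade-off explicit: scaling
TR and kd together leaves the steady state unchanged but shortens the
relaxation half-time ln2/kd — higher turnover buys faster response at
the same expression level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class KineticModel:
    """Piecewise-constant transcription schedule plus first-order decay.

    Parameters
    ----------
    tr_schedule
        Sequence of (start_minute, tr) pairs, first start at 0; each TR
        holds until the next start. a.u./min, TR >= 0.
    kd
        Decay rate, 1/min, > 0.
    m0
        Initial mRNA level, a.u.
    """

    tr_schedule: tuple[tuple[float, float], ...]
    kd: float
    m0: float

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("kd must be > 0")
        sched = tuple((float(t), float(tr)) for t, tr in self.tr_schedule)
        if not sched or sched[0][0] != 0.0:
            raise ValueError("tr_schedule must start at t=0")
        starts = [t for t, _ in sched]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("tr_schedule starts must be strictly increasing")
        if any(tr < 0 for _, tr in sched):
            raise ValueError("TR must be >= 0")
        object.__setattr__(self, "tr_schedule", sched)


def steady_state(tr: float, kd: float) -> float:
    """Steady-state mRNA level M* = TR / kd."""
    if kd <= 0:
        raise ValueError("kd must be > 0")
    return tr / kd


def simulate_response(model: KineticModel, t_grid) -> np.ndarray:
    """Closed-form trajectory of M on an increasing time grid from 0.

    Within each constant-TR segment,
    M(t) = M* + (M_seg_start - M*) * exp(-kd * (t - t_seg_start)).
    """
    t = np.asarray(t_grid, dtype=float)
    if t.size == 0 or t[0] != 0.0 or (np.diff(t) <= 0).any():
        raise ValueError("t_grid must increase strictly from 0")

    starts = np.array([s for s, _ in model.tr_schedule])
    trs = np.array([tr for _, tr in model.tr_schedule])
    ends = np.append(starts[1:], np.inf)

    out = np.empty_like(t)
    m_start = model.m0
    for t0, t1, tr in zip(starts, ends, trs):
        m_star = tr / model.kd
        mask = (t >= t0) & (t < t1)
        out[mask] = m_star + (m_start - m_star) * np.exp(-model.kd * (t[mask] - t0))
        if np.isfinite(t1):
            m_start = m_star + (m_start - m_star) * np.exp(-model.kd * (t1 - t0))
    return out


def response_halftime(kd: float) -> float:
    """Time to cover half the gap to a new steady state: ln2 / kd."""
    if kd <= 0:
        raise ValueError("kd must be > 0")
    return float(np.log(2) / kd)


def parse_schedule(text: str) -> tuple[tuple[float, float], ...]:
    """Parse a schedule string like ``"0:1,10:2"`` into (start, tr) pairs."""
    pairs = []
    for chunk in text.split(","):
        t, tr = chunk.split(":")
        pairs.append((float(t), float(tr)))
    return tuple(pairs)
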