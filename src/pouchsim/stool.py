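"""Fecal-stasis surrogate: fill/empty cycle with inflammatory potential.

Stool is modeled as a slow-flowing liquid, not with fluid dynamics: a
new parcel enters the pouch every 15-minute step, the pouch fills in
``fill_steps`` steps (default 16, i.e. 4 hours) and is then emptied,
restarting the cycle.  Each parcel carries an inflammatory potential
that grows linearly with residence time,

    IP_t = IP_{t-1} + delta_IP,

and drives TLR activation on the epithelium it touches.  Filling
proceeds from the terminal (distal) end toward the inflow, so terminal
units accumulate the longest contact with the oldest, highest-IP stool
-- the generative mechanism for the distal-dominant metaplasia
gradient.  A config switch flips to proximal-first filling (which
reverses the gradient) or to a single pouch-wide IP scalar instead of
per-parcel accounting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Tuple

import numpy as np

__all__ = [
    "StoolParams",
    "StoolState",
    "step_stool",
    "contact_exposure",
    "cycle_exposure_profile",
    "calibrate_delta_ip",
    "CalibrationError",
]


@dataclass
class StoolParams:
    fill_steps: int = 16          # 4 h at 15 min/step
    delta_ip: float = 0.0         # IP gain per parcel per step of residence
    ip0: float = 0.0              # IP of freshly entered stool
    terminal_first: bool = True   # fill from the distal end (stasis surrogate)
    per_parcel: bool = True       # False: one pouch-wide IP scalar
    k_tlr: float = 1.0            # TLR drive per unit of IP

    def __post_init__(self) -> None:
        if self.fill_steps < 1:
            raise ValueError("fill_steps must be >= 1")
        if self.delta_ip < 0 or self.ip0 < 0 or self.k_tlr < 0:
            raise ValueError("stool rates must be non-negative")


@dataclass
class StoolState:
    """Pouch fill level and per-parcel inflammatory potential."""

    step_in_cycle: int = 0
    parcel_entry: List[int] = field(default_factory=list)  # absolute entry steps
    parcel_ips: List[float] = field(default_factory=list)  # entry order
    emptied_at: List[int] = field(default_factory=list)    # absolute steps

    _fill_steps: int = 16  # mirrored from params at each step

    @property
    def fill_fraction(self) -> float:
        return self.step_in_cycle / self._fill_steps


def step_stool(state: StoolState, params: StoolParams, step: int) -> StoolState:
    """Advance the stool model by one 15-minute step.

    Every resident parcel's IP grows by delta_IP, one new parcel enters,
    and when the pouch is full (every ``fill_steps`` steps) it empties:
    parcels are cleared and the cycle restarts.  ``step`` is the absolute
    simulation step (1-based within the run) recorded for emptying events.
    IPs are evaluated from each parcel's residence time, so the linear
    recurrence IP_t = IP_{t-1} + delta_IP holds exactly, free of float
    accumulation error.  Mutates and returns ``state``.
    """
    state._fill_steps = params.fill_steps
    state.parcel_entry.append(step)
    state.parcel_ips = [
        params.ip0 + (step - e) * params.delta_ip for e in state.parcel_entry
    ]
    state.step_in_cycle += 1
    if state.step_in_cycle >= params.fill_steps:
        state.emptied_at.append(step)
        state.parcel_entry = []
        state.parcel_ips = []
        state.step_in_cycle = 0
    return state


def axial_band_of(n_axial: int, params: StoolParams) -> np.ndarray:
    """Parcel ordinal (0 = first of the cycle) covering each axial row.

    Terminal-first: the first parcel of a cycle settles against the
    terminal (highest-axial) rows, the next one stacks proximally.
    """
    a = np.arange(n_axial)
    if params.terminal_first:
        pos = n_axial - 1 - a
    else:
        pos = a
    return (pos * params.fill_steps) // n_axial


def contact_exposure(
    state: StoolState, n_axial: int, params: StoolParams
) -> np.ndarray:
    """Per-axial-row TLR drive from currently contacting stool.

    A row is contacted when the parcel band covering it has entered this
    cycle; the drive is ``k_tlr`` times that parcel's IP (or the mean IP
    of all resident parcels in pouch-wide-scalar mode).  With
    fill_fraction 0 the drive is zero everywhere; at fill_fraction 1
    every row is contacted.
    """
    drive = np.zeros(n_axial)
    m = len(state.parcel_ips)
    if m == 0:
        return drive
    band = axial_band_of(n_axial, params)
    contacted = band < m
    if params.per_parcel:
        ips = np.asarray(state.parcel_ips)
        drive[contacted] = params.k_tlr * ips[band[contacted]]
    else:
        drive[contacted] = params.k_tlr * float(np.mean(state.parcel_ips))
    return drive


def cycle_exposure_profile(n_axial: int, params: StoolParams) -> np.ndarray:
    """Cumulative per-row TLR drive over one whole fill/empty cycle.

    Brute accumulation of :func:`contact_exposure` over ``fill_steps``
    steps starting from an empty pouch.  With terminal-first filling the
    profile is monotone non-increasing from the terminal end toward the
    inflow (closed form for band b: k_tlr * delta_IP * (F-b)(F-b-1)/2
    with F = fill_steps, plus the ip0 contact terms).
    """
    state = StoolState(_fill_steps=params.fill_steps)
    total = np.zeros(n_axial)
    for t in range(1, params.fill_steps + 1):
        step_stool(state, params, t)
        total += contact_exposure(state, n_axial, params)
    return total


class CalibrationError(RuntimeError):
    def __init__(self, message: str, trace: List[Tuple[float, float]]):
        super().__init__(message)
        self.trace = trace


def calibrate_delta_ip(
    run_fn: Callable[[float], float],
    target_metaplasia_fraction: float,
    lo: float = 0.0,
    hi: float = 1.0,
    tol: float = 1e-3,
    max_iter: int = 30,
) -> Tuple[float, List[Tuple[float, float]]]:
    """Bisection on delta_IP until the terminal-quartile metaplastic unit
    fraction crosses the target.

    ``run_fn(delta_ip)`` runs the (reduced-scale) pouchitis scenario and
    returns the terminal-quartile metaplastic fraction; it must be
    non-decreasing in delta_ip.  Returns (calibrated delta_IP, search
    trace of (delta_ip, fraction) pairs).  A target of 0 returns the
    lower bound untried-above; an unreachable target raises
    :class:`CalibrationError` carrying the trace.
    """
    trace: List[Tuple[float, float]] = []
    if target_metaplasia_fraction <= 0.0:
        return lo, trace
    f_hi = run_fn(hi)
    trace.append((hi, f_hi))
    if f_hi < target_metaplasia_fraction:
        raise CalibrationError(
            f"target fraction {target_metaplasia_fraction} unreachable: "
            f"upper bound delta_IP={hi} yields {f_hi}",
            trace,
        )
    a, b = lo, hi
    for _ in range(max_iter):
        if b - a <= tol:
            break
        mid = 0.5 * (a + b)
        f_mid = run_fn(mid)
        trace.append((mid, f_mid))
        if f_mid >= target_metaplasia_fraction:
            b = mid
        else:
            a = mid
    return b, trace
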