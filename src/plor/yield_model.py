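"""The multiplicative step-yield model E = Ei * Ee**n and termination statistics.

A k-step PLOR reaction has one initiation step and n = k - 1 restart steps.
Treating initiation success and each restart survival as independent
per-complex probabilities gives the overall yield E = Ei * Ee**n, which is
exactly log-linear in n — so the model is fit by unweighted least squares on
log E.  Termination efficiency is the fraction of transcripts released at
the terminator: T / (T + FL).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import FitError


@dataclass(frozen=True)
class YieldParams:
    """Initiation efficiency Ei, per-step elongation efficiency Ee, and n."""

    Ei: float
    Ee: float
    n: int

    def __post_init__(self) -> None:
        if not 0 < self.Ei <= 1:
            raise FitError(f"Ei must be in (0, 1], got {self.Ei}")
        if not 0 < self.Ee <= 1:
            raise FitError(f"Ee must be in (0, 1], got {self.Ee}")
        if self.n < 0 or self.n != int(self.n):
            raise FitError(f"n must be a non-negative integer, got {self.n}")


@dataclass(frozen=True)
class YieldFit:
    """fit_yield_params outcome; ``clipped`` flags estimates pulled back into (0,1]."""

    Ei: float
    Ee: float
    clipped: bool
    rss_log: float
    max_abs_resid_log: float
    n_obs: int


@dataclass(frozen=True)
class TerminationStats:
    """Termination efficiency T/(T+FL) and read-through ratio FL/T."""

    T: float
    FL: float
    efficiency: float
    ratio_FL_T: Optional[float]


def overall_yield(params: YieldParams) -> float:
    """Overall transcription yield E = Ei * Ee**n."""
    return params.Ei * params.Ee ** params.n


def steps_to_n(k_steps: int) -> int:
    """Post-initiation step count n for a k-step reaction: n = k - 1."""
    if k_steps < 1:
        raise FitError(f"a reaction has at least one step, got {k_steps}")
    return k_steps - 1


def fit_yield_params(observations: Sequence[tuple[int, float]]) -> YieldFit:
    """Least-squares fit of (Ei, Ee) from (n, E) observations.

    The model is exactly log-linear, log E = log Ei + n log Ee, so the fit is
    ordinary least squares in log space.  Back-transformed estimates above 1
    are clipped to 1 with ``clipped=True`` — efficiencies are probabilities.
    Needs >= 2 observations at distinct n; any E <= 0 is invalid.
    """
    if len(observations) < 2:
        raise FitError("need at least 2 observations")
    ns = np.array([n for n, _ in observations], dtype=float)
    es = np.array([e for _, e in observations], dtype=float)
    if np.any(es <= 0):
        raise FitError("all E values must be positive")
    if np.all(ns == ns[0]):
        raise FitError("underdetermined: all observations at the same n")
    log_e = np.log(es)
    slope, intercept = np.polyfit(ns, log_e, 1)
    ei, ee = math.exp(intercept), math.exp(slope)
    clipped = ei > 1 or ee > 1
    ei, ee = min(ei, 1.0), min(ee, 1.0)
    resid = log_e - (intercept + slope * ns)
    return YieldFit(
        Ei=ei,
        Ee=ee,
        clipped=clipped,
        rss_log=float(resid @ resid),
        max_abs_resid_log=float(np.max(np.abs(resid))),
        n_obs=len(observations),
    )


def termination_efficiency(T: float, FL: float) -> TerminationStats:
    """Termination statistics from terminated and full-length band signals.

    efficiency = T / (T + FL); ratio_FL_T = FL / T, reported as None when
    there is no terminated signal.
    """
    if T < 0 or FL < 0:
        raise FitError(f"band signals must be non-negative, got T={T}, FL={FL}")
    if T + FL == 0:
        raise FitError("no signal: T + FL is zero")
    return TerminationStats(
        T=T,
        FL=FL,
        efficiency=T / (T + FL),
        ratio_FL_T=FL / T if T > 0 else None,
    )
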