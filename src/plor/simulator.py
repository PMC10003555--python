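"""Seeded stochastic simulator of single-round pause-restart transcription.

Each DNA template carries at most one polymerase, so a k-step reaction is a
per-molecule chain of Bernoulli events: initiation succeeds with probability
Ei; the complex survives each of the n = k - 1 restarts with probability Ee
(stalling is per step, not per nucleotide, matching the step-level yield
model E = Ei * Ee**n); survivors reaching the intrinsic terminator release a
terminated product with probability p_term and otherwise run off to full
length.  Ligand (adenine) shifts p_term along a hyperbolic binding-occupancy
curve between the ligand-free and ligand-saturated termination
probabilities.

The simulator emits synthetic band tables — counts scaled by lognormal
multiplicative noise — and serves as the fixture generator for the
quantification and fitting modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .errors import BandTableError, FitError, ScheduleError
from .schedule_design import Schedule, validate_schedule
from .sequence_core import Transcript, annotate_terminator


@dataclass(frozen=True)
class SimParams:
    """Single-round simulation parameters.

    p0/p1 are the termination probabilities at zero and saturating ligand;
    Kd is the apparent dissociation constant (uM) of the ligand-riboswitch
    interaction; noise_sigma is the sigma of the lognormal multiplicative
    band-intensity noise.
    """

    n_molecules: int = 100_000
    Ei: float = 0.9
    Ee: float = 0.9
    p0: float = 0.85
    p1: float = 0.55
    Kd: float = 1.0  # uM
    adenine: float = 0.0  # uM
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise FitError("n_molecules must be >= 1")
        if not 0 < self.Ei <= 1 or not 0 < self.Ee <= 1:
            raise FitError("Ei and Ee must be in (0, 1]")
        if not 0 <= self.p0 <= 1 or not 0 <= self.p1 <= 1:
            raise FitError("p0 and p1 must be probabilities")
        if self.Kd <= 0:
            raise FitError(f"Kd must be positive, got {self.Kd}")
        if self.adenine < 0 or self.noise_sigma < 0:
            raise FitError("adenine and noise_sigma must be non-negative")


@dataclass(frozen=True)
class SimResult:
    """Molecule counts of one simulated run plus the realized p_term."""

    initiated: int
    stalled: Mapping[int, int]  # step index -> molecules lost at that restart
    terminated: int
    full_length: int
    p_term: float
    terminated_length: int
    full_length_nt: int
    params: SimParams
    condition: str = "sim"

    @property
    def total_transcripts(self) -> int:
        return self.terminated + self.full_length


def p_term(adenine: float, p0: float, p1: float, Kd: float) -> float:
    """Termination probability at a given ligand concentration (uM).

    Hyperbolic interpolation between the ligand-free (p0) and
    ligand-saturated (p1) limits by fractional occupancy adenine/(Kd+adenine):
    p = p0 - (p0 - p1) * adenine / (Kd + adenine).
    """
    if Kd <= 0:
        raise FitError(f"Kd must be positive, got {Kd}")
    if adenine < 0:
        raise FitError("adenine concentration must be non-negative")
    return p0 - (p0 - p1) * adenine / (Kd + adenine)


def simulate_single_round(params: SimParams, sched: Schedule, tx: Transcript) -> SimResult:
    """Simulate one single-round PLOR reaction as chained binomial draws.

    Requires a schedule that carries the transcript to run-off (validated
    first) and an annotatable terminator.  All randomness comes from one
    generator seeded with ``params.seed``; identical parameters give
    bitwise-identical counts.
    """
    report = validate_schedule(tx, sched)
    if not report.complete:
        raise ScheduleError(
            f"schedule does not complete the transcript "
            f"(stalled at step {report.stalled_at_step}, stopped at {report.stopped_at})"
        )
    term = annotate_terminator(tx)
    rng = np.random.default_rng(params.seed)
    p = p_term(params.adenine, params.p0, params.p1, params.Kd)

    initiated = int(rng.binomial(params.n_molecules, params.Ei))
    stalled: dict[int, int] = {}
    alive = initiated
    for step in sched.steps[1:]:  # restarts: steps 2..k
        survivors = int(rng.binomial(alive, params.Ee))
        stalled[step.index] = alive - survivors
        alive = survivors
    terminated = int(rng.binomial(alive, p))
    return SimResult(
        initiated=initiated,
        stalled=stalled,
        terminated=terminated,
        full_length=alive - terminated,
        p_term=p,
        terminated_length=term.terminated_length,
        full_length_nt=tx.length,
        params=params,
        condition=f"adenine_{params.adenine:g}uM",
    )


def emit_band_table(
    sim: SimResult,
    noise_sigma: Optional[float] = None,
    seed: Optional[int] = None,
    replicates: int = 3,
) -> pd.DataFrame:
    """Synthetic band-intensity table from simulated counts.

    Per replicate, the T and FL intensities are the molecule counts scaled by
    independent lognormal(0, noise_sigma) factors; sigma 0 reproduces counts
    exactly.  Product lengths are attached so per-length correction can be
    exercised.  Defaults for sigma and seed come from the simulation params.
    """
    if sim.total_transcripts == 0:
        raise BandTableError("no signal to emit: zero transcripts")
    if replicates < 1:
        raise BandTableError("replicates must be >= 1")
    sigma = sim.params.noise_sigma if noise_sigma is None else noise_sigma
    if sigma < 0:
        raise BandTableError("noise_sigma must be non-negative")
    rng = np.random.default_rng(sim.params.seed + 1 if seed is None else seed)
    rows = []
    for rep in range(1, replicates + 1):
        for band, count, length in (
            ("T", sim.terminated, sim.terminated_length),
            ("FL", sim.full_length, sim.full_length_nt),
        ):
            factor = float(rng.lognormal(0.0, sigma)) if sigma > 0 else 1.0
            rows.append(
                {
                    "lane": f"{sim.condition}_r{rep}",
                    "condition": sim.condition,
                    "replicate": rep,
                    "band": band,
                    "intensity": count * factor,
                    "length_nt": length,
                }
            )
    return pd.DataFrame(rows)
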