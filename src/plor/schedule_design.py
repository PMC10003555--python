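"""Pause scheduling: halt positions, segment tiling, NTP batches, label design.

The PLOR "pause-restart" principle: with only a subset of the four NTPs
present, T7 RNAP elongates until the first template position that requires a
missing NTP and halts with its 3' end on the last incorporable base.  A
multi-step schedule of included-NTP subsets therefore tiles the transcript
into contiguous segments, and the base composition of each segment fixes the
stoichiometric NTP batch for that step: at 1x, each NTP is supplied at
(count in segment) x (DNA concentration), exactly enough for one RNA per
template molecule.

This module predicts those segments for a given schedule, computes the
per-step batches (with fold-excess and explicit overrides), solves the
inverse problem of isolating a labeled NTP to chosen positions, and builds
human-readable design sheets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from .errors import LabelDesignError, ScheduleError
from .sequence_core import Transcript, annotate_terminator

BASES = ("A", "C", "G", "U")


# --- domain types ---------------------------------------------------------

@dataclass(frozen=True)
class Stoichiometric:
    """Supply each included NTP at fold x (segment count x DNA conc)."""

    fold: float = 1.0

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ScheduleError(f"fold must be positive, got {self.fold}")


@dataclass(frozen=True)
class Explicit:
    """Supply NTPs at explicitly given concentrations (uM), e.g. the hot start."""

    conc: Mapping[str, float]


@dataclass(frozen=True)
class StepSpec:
    """One PLOR step: which NTPs are present, how much, and any label swap.

    ``label_substitution`` = (base, label name) means the labeled analog
    fully replaces that NTP in this step (e.g. ("U", "Cy3")).
    ``condition`` carries free-form reaction metadata (Mg mM, adenine mM, ...).
    """

    index: int
    included: frozenset[str]
    amount_policy: Stoichiometric | Explicit = field(default_factory=Stoichiometric)
    label_substitution: Optional[tuple[str, str]] = None
    condition: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "included", frozenset(self.included))
        bad = self.included - set(BASES)
        if bad or not self.included:
            raise ScheduleError(
                f"step {self.index}: included must be a nonempty subset of "
                f"{{A,C,G,U}}, got {sorted(self.included) or '{}'}"
            )
        if self.label_substitution is not None and self.label_substitution[0] not in self.included:
            raise ScheduleError(
                f"step {self.index}: label base {self.label_substitution[0]} "
                "is not among the included NTPs"
            )


@dataclass(frozen=True)
class Schedule:
    """An ordered PLOR step schedule with reaction-scale metadata."""

    steps: tuple[StepSpec, ...]
    dna_conc: float = 5.0  # uM
    rnap_conc: float = 5.0  # uM, metadata only

    def __post_init__(self) -> None:
        object.__setattr__(self, "steps", tuple(self.steps))
        if not self.steps:
            raise ScheduleError("schedule has no steps")
        for i, s in enumerate(self.steps, start=1):
            if s.index != i:
                raise ScheduleError(
                    f"step indices must run 1..{len(self.steps)} consecutively; "
                    f"position {i} has index {s.index}"
                )

    def __len__(self) -> int:
        return len(self.steps)


@dataclass(frozen=True)
class Segment:
    """The transcript interval synthesized in one step (1-based inclusive)."""

    step_index: int
    start: int
    end: int
    composition: Mapping[str, int]

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class NTPBatch:
    """The uM amounts of each NTP for one step; zero for excluded bases."""

    conc: Mapping[str, float]
    fold: Optional[float]
    label: Optional[tuple[str, str]] = None


@dataclass(frozen=True)
class ScheduleReport:
    """validate_schedule outcome: stalls and incompleteness are entries, not errors."""

    complete: bool
    n_steps: int
    progress: tuple[tuple[int, int, int], ...]  # (step index, start, halt position)
    warnings: tuple[str, ...]
    stalled_at_step: Optional[int] = None
    stopped_at: Optional[int] = None


# --- forward operations ---------------------------------------------------

def halt_position(tx: Transcript, start: int, included: frozenset[str] | set[str]) -> int:
    """Last position incorporable from ``start`` given the included NTPs.

    Returns the largest p >= start-1 such that every base in [start, p] is in
    ``included``; start-1 means zero progress, and the transcript length means
    no missing base remains downstream (run-off).
    """
    seq = tx.rna.residues
    if not 1 <= start <= len(seq) + 1:
        raise ScheduleError(f"start {start} outside transcript [1, {len(seq) + 1}]")
    p = start - 1
    while p < len(seq) and seq[p] in included:
        p += 1
    return p


def _composition(tx: Transcript, start: int, end: int) -> dict[str, int]:
    seg = tx.rna.residues[start - 1 : end]
    return {b: seg.count(b) for b in BASES}


def build_segments(
    tx: Transcript, sched: Schedule, allow_partial: bool = False
) -> list[Segment]:
    """Tile the transcript into step segments by iterating the halting rule.

    Each step restarts at the previous 3' end + 1 and halts per
    :func:`halt_position`.  A step that makes no progress raises "stalled";
    a schedule whose final segment stops short of the transcript end raises
    "incomplete" unless ``allow_partial``.
    """
    segments: list[Segment] = []
    pos = 1
    for step in sched.steps:
        end = halt_position(tx, pos, step.included)
        if end < pos:
            raise ScheduleError(
                f"stalled step {step.index}: first required base "
                f"{tx.rna.residues[pos - 1]} at {pos} is excluded"
            )
        segments.append(
            Segment(step.index, pos, end, _composition(tx, pos, end))
        )
        pos = end + 1
        if pos > tx.length:
            break
    if pos <= tx.length and not allow_partial:
        raise ScheduleError(f"incomplete schedule, stopped at {pos - 1}")
    return segments


def batch_for_segment(seg: Segment, sched: Schedule, step: StepSpec) -> NTPBatch:
    """The NTP batch implied by a segment's composition and the step's policy.

    Stoichiometric: conc(b) = count(b) x dna_conc x fold, zero for excluded
    NTPs.  Explicit: the override concentrations pass through unchanged.
    A label substitution is reported on the batch with the labeled species
    carrying the same concentration as the NTP it replaces.
    """
    for b, n in seg.composition.items():
        if n > 0 and b not in step.included:
            raise ScheduleError(
                f"internal consistency error: segment of step {step.index} "
                f"contains {b} outside the included set"
            )
    if isinstance(step.amount_policy, Explicit):
        conc = {b: float(step.amount_policy.conc.get(b, 0.0)) for b in BASES}
        return NTPBatch(conc=conc, fold=None, label=step.label_substitution)
    fold = step.amount_policy.fold
    conc = {
        b: (seg.composition.get(b, 0) * sched.dna_conc * fold if b in step.included else 0.0)
        for b in BASES
    }
    return NTPBatch(conc=conc, fold=fold, label=step.label_substitution)


def design_sheet(tx: Transcript, sched: Schedule, min_run: int = 6) -> pd.DataFrame:
    """One row per step: subset, segment bounds, composition, batch uM, label.

    The frame's ``attrs`` carry the predicted product sizes (full-length
    transcript and terminated length from the U-tract annotation).
    """
    segments = build_segments(tx, sched)
    rows = []
    for seg, step in zip(segments, sched.steps):
        batch = batch_for_segment(seg, sched, step)
        rows.append(
            {
                "step": step.index,
                "included": "".join(b for b in BASES if b in step.included),
                "start": seg.start,
                "end": seg.end,
                **{f"n_{b}": seg.composition[b] for b in BASES},
                **{f"{b}TP_uM": round(batch.conc[b], 1) for b in BASES},
                "fold": batch.fold,
                "label": f"{batch.label[1]}-{batch.label[0]}TP" if batch.label else "",
                "condition": dict(step.condition),
            }
        )
    sheet = pd.DataFrame(rows)
    term = annotate_terminator(tx, min_run=min_run)
    sheet.attrs["full_length_nt"] = tx.length
    sheet.attrs["terminated_nt"] = term.terminated_length
    sheet.attrs["dna_uM"] = sched.dna_conc
    return sheet


def validate_schedule(tx: Transcript, sched: Schedule) -> ScheduleReport:
    """Dry-run a schedule, reporting stalls/incompleteness instead of raising.

    Also warns when a non-final step includes all four NTPs (the polymerase
    cannot pause) — legal, but usually a design mistake.
    """
    warnings_: list[str] = []
    progress: list[tuple[int, int, int]] = []
    pos = 1
    stalled_at = None
    for step in sched.steps:
        if len(step.included) == 4 and step.index < len(sched):
            warnings_.append(f"step {step.index} cannot pause (all four NTPs included)")
        if pos > tx.length or stalled_at is not None:
            progress.append((step.index, pos, pos - 1))
            continue
        end = halt_position(tx, pos, step.included)
        progress.append((step.index, pos, end))
        if end < pos:
            stalled_at = step.index
            warnings_.append(f"stalled at step {step.index}, position {pos}")
            continue
        pos = end + 1
    complete = stalled_at is None and pos > tx.length
    return ScheduleReport(
        complete=complete,
        n_steps=len(sched),
        progress=tuple(progress),
        warnings=tuple(warnings_),
        stalled_at_step=stalled_at,
        stopped_at=None if complete else pos - 1,
    )


# --- inverse design -------------------------------------------------------

def _valid_stops(seq: str, start: int) -> list[int]:
    """All positions b >= start where a step beginning at ``start`` can halt.

    A halt at b requires the next base to be absent from the segment, i.e.
    seq[b+1] not in bases([start, b]); the transcript end is always a stop.
    """
    stops = []
    seen: set[str] = set()
    for b in range(start, len(seq) + 1):
        seen.add(seq[b - 1])
        if b == len(seq) or seq[b] not in seen:
            stops.append(b)
    return stops


def _min_steps_to(seq: str, target_end: int) -> Optional[list[int]]:
    """Greedy farthest-stop tiling of [1, target_end]; None if unreachable.

    Farthest-reach greedy is optimal here: a later start can only shrink a
    segment's base set, so its farthest stop never decreases.
    """
    ends: list[int] = []
    pos = 1
    while pos <= target_end:
        reach = [b for b in _valid_stops(seq, pos) if b <= target_end]
        if not reach:
            return None
        best = max(reach)
        ends.append(best)
        pos = best + 1
    return ends


def _step_for(index: int, seq: str, start: int, end: int) -> StepSpec:
    return StepSpec(index=index, included=frozenset(seq[start - 1 : end]))


def design_label_schedule(
    tx: Transcript,
    label_positions: Sequence[int],
    label_base: str,
    dna_conc: float = 5.0,
    label_name: str = "label",
    method: str = "greedy",
) -> Schedule:
    """Minimal-step schedule isolating ``label_base`` to the given positions.

    One designated step's segment contains ``label_base`` exactly at the
    requested positions (its NTP swapped for the labeled analog); the final
    step includes all four NTPs for run-off.  Positions immediately followed
    by the same base are not isolatable: the polymerase cannot pause between
    consecutive identical residues.

    The labeling step is kept out of the initiation step whenever possible:
    initiation runs with a large non-stoichiometric NTP excess, where a
    fluorophore analog would be wasted and incorporated poorly.  Only when
    every feasible design must label from position 1 onward does the
    initiation step carry the label.

    ``method="greedy"`` uses the provably minimal farthest-stop prefix tiling;
    ``method="exhaustive"`` does a breadth-first search over all valid stop
    placements (transcripts <= 64 nt) and serves as an independent oracle.
    """
    seq = tx.rna.residues
    pos_set = sorted(set(label_positions))
    if not pos_set:
        raise LabelDesignError("no label positions requested")
    for p in pos_set:
        if not 1 <= p <= len(seq):
            raise LabelDesignError(f"label position {p} outside transcript [1, {len(seq)}]")
        if seq[p - 1] != label_base:
            raise LabelDesignError(
                f"transcript has {seq[p - 1]} at {p}, not {label_base}"
            )
    lo, hi = pos_set[0], pos_set[-1]
    if method not in ("greedy", "exhaustive"):
        raise ValueError(f"unknown method {method!r}")
    if method == "exhaustive" and len(seq) > 64:
        raise LabelDesignError("exhaustive search is limited to transcripts of <= 64 nt")

    # candidate labeling segments [s, e]: label_base occurs exactly at pos_set
    prev_b = max((i for i in range(1, lo) if seq[i - 1] == label_base), default=0)
    candidates: list[tuple[int, int]] = []  # (s, e); e == len(seq) means final step
    for s in range(prev_b + 1, lo + 1):
        inner = [i for i in range(s, hi + 1) if seq[i - 1] == label_base]
        if inner != pos_set:
            continue
        for e in _valid_stops(seq, s):
            if e < hi:
                continue
            if label_base in seq[hi : e]:  # another occurrence before the stop
                break
            candidates.append((s, e))
        # final-step candidate: segment runs to the end under all four NTPs
        if label_base not in seq[hi:]:
            candidates.append((s, len(seq)))
    candidates = sorted(set(candidates))
    # avoid labeling in the initiation step unless nothing else is feasible
    later = [c for c in candidates if c[0] >= 2]
    if later:
        candidates = later
    if not candidates:
        nxt = hi + 1
        if nxt <= len(seq) and seq[nxt - 1] == label_base:
            raise LabelDesignError(f"label not isolatable at {hi}")
        raise LabelDesignError(
            f"label not isolatable at {pos_set}: no pauseable segment bounds exist"
        )

    best: Optional[tuple[int, int, list[int], tuple[int, int]]] = None
    for s, e in candidates:
        if method == "greedy":
            prefix = _min_steps_to(seq, s - 1) if s > 1 else []
        else:
            prefix = _bfs_steps_to(seq, s - 1) if s > 1 else []
        if prefix is None:
            continue
        total = len(prefix) + 1 + (1 if e < len(seq) else 0)
        first_len = prefix[0] if prefix else e
        key = (total, -first_len)
        if best is None or key < (best[0], best[1]):
            best = (key[0], key[1], prefix, (s, e))
    if best is None:
        raise LabelDesignError(
            f"label not isolatable at {pos_set}: prefix cannot be tiled"
        )

    _, _, prefix_ends, (s, e) = best
    steps: list[StepSpec] = []
    pos = 1
    for end in prefix_ends:
        steps.append(_step_for(len(steps) + 1, seq, pos, end))
        pos = end + 1
    if e < len(seq):
        label_step = StepSpec(
            index=len(steps) + 1,
            included=frozenset(seq[s - 1 : e]),
            label_substitution=(label_base, label_name),
        )
        steps.append(label_step)
        steps.append(StepSpec(index=len(steps) + 1, included=frozenset(BASES)))
    else:
        steps.append(
            StepSpec(
                index=len(steps) + 1,
                included=frozenset(BASES),
                label_substitution=(label_base, label_name),
            )
        )
    return Schedule(steps=tuple(steps), dna_conc=dna_conc)


def _bfs_steps_to(seq: str, target_end: int) -> Optional[list[int]]:
    """Shortest stop placement for [1, target_end] by BFS over all valid stops."""
    from collections import deque

    parent: dict[int, int] = {1: 0}
    queue = deque([1])
    while queue:
        pos = queue.popleft()
        if pos == target_end + 1:
            ends = []
            while pos != 1:
                ends.append(pos - 1)
                pos = parent[pos]
            return ends[::-1]
        for b in _valid_stops(seq, pos):
            if b <= target_end and b + 1 not in parent:
                parent[b + 1] = pos
                queue.append(b + 1)
    return None


def design_even_schedule(tx: Transcript, k: int, dna_conc: float = 5.0) -> Schedule:
    """A complete k-step schedule with pause boundaries as even as possible.

    Non-final boundaries are placed at the valid halt position nearest to the
    ideal i*L/k split; the final step includes all four NTPs for run-off.
    Used to emulate alternative pause-restart strategies (3-, 6-, 10-step
    reactions) whose exact pause points are an experimental choice.
    """
    seq = tx.rna.residues
    if k < 1:
        raise ScheduleError("k must be >= 1")
    steps: list[StepSpec] = []
    pos = 1
    for i in range(1, k):
        target = round(i * len(seq) / k)
        room = len(seq) - (k - i)  # leave >= 1 nt per remaining step
        stops = [b for b in _valid_stops(seq, pos) if b <= room]
        if not stops:
            raise ScheduleError(f"cannot place pause {i}: no valid stop after {pos}")
        end = min(stops, key=lambda b: (abs(b - target), b))
        steps.append(_step_for(i, seq, pos, end))
        pos = end + 1
    steps.append(StepSpec(index=k, included=frozenset(BASES)))
    sched = Schedule(steps=tuple(steps), dna_conc=dna_conc)
    report = validate_schedule(tx, sched)
    if not report.complete:
        raise ScheduleError(f"even schedule construction failed: {report.warnings}")
    return sched


# --- config ingestion -----------------------------------------------------

def schedule_from_dict(cfg: Mapping) -> Schedule:
    """Build a :class:`Schedule` from a parsed config mapping.

    Per step: ``included: [A,C,U]``, and optionally ``fold: 1.0`` or
    ``explicit: {A: 400, G: 600, U: 64}``, ``label: {base: U, name: Cy3}``,
    ``condition: {Mg_mM: 6, adenine_mM: 1}``.
    """
    try:
        raw_steps = cfg["steps"]
    except KeyError as exc:
        raise ScheduleError("schedule config has no 'steps' list") from exc
    steps = []
    for i, raw in enumerate(raw_steps, start=1):
        if "explicit" in raw:
            policy: Stoichiometric | Explicit = Explicit(
                {str(b).upper(): float(v) for b, v in raw["explicit"].items()}
            )
        else:
            policy = Stoichiometric(float(raw.get("fold", 1.0)))
        label = None
        if raw.get("label"):
            label = (str(raw["label"]["base"]).upper(), str(raw["label"].get("name", "label")))
        steps.append(
            StepSpec(
                index=i,
                included=frozenset(str(b).upper() for b in raw["included"]),
                amount_policy=policy,
                label_substitution=label,
                condition=dict(raw.get("condition", {})),
            )
        )
    return Schedule(
        steps=tuple(steps),
        dna_conc=float(cfg.get("dna_uM", 5.0)),
        rnap_conc=float(cfg.get("rnap_uM", 5.0)),
    )


def load_schedule(path: str | Path) -> Schedule:
    """Read a YAML schedule config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise ScheduleError(f"{path} is not a mapping-style schedule config")
    return schedule_from_dict(cfg)
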