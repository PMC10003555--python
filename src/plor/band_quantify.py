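"""Band-intensity table ingestion and per-condition termination statistics.

Densitometry of the product gel yields, per lane, a terminated (T) and a
full-length (FL) band intensity.  This module reads such tables from
delimited text, optionally converts mass-proportional stain signal to
molecule-proportional signal (intensity / length), and aggregates
per-replicate termination efficiencies into per-condition mean +/- sd.

Efficiency is averaged over per-replicate efficiencies, not pooled
intensities, so replicates with different exposures contribute equally; the
statistic is scale-free within a replicate.  The sample (n-1) standard
deviation is reported, absent for single replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from .errors import BandTableError
from .yield_model import termination_efficiency

REQUIRED_COLUMNS = ("lane", "condition", "replicate", "band", "intensity")


@dataclass(frozen=True)
class ConditionSummary:
    """Replicate-aggregated termination statistics for one condition."""

    condition: str
    n_replicates: int
    mean_efficiency: float
    sd_efficiency: Optional[float]
    mean_ratio_FL_T: Optional[float]
    sd_ratio_FL_T: Optional[float]


@dataclass(frozen=True)
class QuantResult:
    """summarize outcome: per-condition summaries plus exclusion warnings."""

    conditions: tuple[ConditionSummary, ...]
    n_excluded: int
    warnings: tuple[str, ...]

    def by_condition(self) -> dict[str, ConditionSummary]:
        return {c.condition: c for c in self.conditions}


def read_band_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a delimited band-intensity table.

    Expects a header with ``lane, condition, replicate, band, intensity`` and
    optionally ``length_nt``; comma or tab delimiters are auto-detected.
    Unknown columns are preserved as metadata.  band must be T or FL;
    intensities must be non-negative; each (condition, replicate, band)
    may appear at most once.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [str(c).strip() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise BandTableError(f"missing column: {', '.join(missing)}")
    return validate_band_table(df)


def validate_band_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an in-memory band table (same rules as :func:`read_band_table`)."""
    df = df.copy()
    df["band"] = df["band"].astype(str).str.strip().str.upper()
    bad_band = sorted(set(df["band"]) - {"T", "FL"})
    if bad_band:
        raise BandTableError(f"band must be T or FL, got {bad_band}")
    df["intensity"] = pd.to_numeric(df["intensity"], errors="raise")
    if (df["intensity"] < 0).any():
        rows = df.index[df["intensity"] < 0].tolist()
        raise BandTableError(f"negative intensity in rows {rows}")
    df["replicate"] = df["replicate"].astype(int)
    if (df["replicate"] < 1).any():
        raise BandTableError("replicate numbers must be >= 1")
    dup = df.duplicated(subset=["condition", "replicate", "band"], keep=False)
    if dup.any():
        keys = df.loc[dup, ["condition", "replicate", "band"]].drop_duplicates()
        raise BandTableError(
            "duplicate band rows for "
            + "; ".join(f"{c}/{r}/{b}" for c, r, b in keys.itertuples(index=False))
        )
    return df


def molar_correct(tbl: pd.DataFrame, mode: str = "none") -> pd.DataFrame:
    """Optionally convert stain signal (mass-proportional) to per-molecule signal.

    ``none`` returns the table unchanged; ``per_length`` divides each
    intensity by its ``length_nt``, which requires a length on every row.
    Stains report mass, so a 120-nt full-length band outshines a 100-nt
    terminated band molecule-for-molecule; single-fluorophore signals are
    already per-molecule and need no correction.
    """
    if mode == "none":
        return tbl
    if mode != "per_length":
        raise BandTableError(f"unknown correction mode {mode!r}")
    if "length_nt" not in tbl.columns:
        raise BandTableError("per_length correction requires a length_nt column")
    lengths = pd.to_numeric(tbl["length_nt"], errors="coerce")
    if lengths.isna().any() or (lengths <= 0).any():
        rows = tbl.index[lengths.isna() | (lengths <= 0)].tolist()
        raise BandTableError(f"per_length correction: missing/invalid length_nt in rows {rows}")
    out = tbl.copy()
    out["intensity"] = out["intensity"] / lengths
    return out


def summarize(tbl: pd.DataFrame) -> QuantResult:
    """Per-condition termination statistics with replicate aggregation.

    Each (condition, replicate) pair needs both a T and an FL row; pairs
    missing one band are excluded and counted in ``n_excluded``.  Efficiency
    and FL/T are computed per replicate, then averaged per condition.
    """
    tbl = validate_band_table(tbl)
    warnings_: list[str] = []
    n_excluded = 0
    summaries: list[ConditionSummary] = []
    for condition, grp in tbl.groupby("condition", sort=False):
        effs: list[float] = []
        ratios: list[float] = []
        for rep, pair in grp.groupby("replicate", sort=True):
            bands = dict(zip(pair["band"], pair["intensity"]))
            if "T" not in bands or "FL" not in bands:
                n_excluded += 1
                warnings_.append(f"{condition}/replicate {rep}: missing band, excluded")
                continue
            try:
                stats = termination_efficiency(bands["T"], bands["FL"])
            except Exception:
                n_excluded += 1
                warnings_.append(f"{condition}/replicate {rep}: no signal, excluded")
                continue
            effs.append(stats.efficiency)
            if stats.ratio_FL_T is not None:
                ratios.append(stats.ratio_FL_T)
        if not effs:
            warnings_.append(f"{condition}: no usable replicates")
            continue
        summaries.append(
            ConditionSummary(
                condition=str(condition),
                n_replicates=len(effs),
                mean_efficiency=float(_mean(effs)),
                sd_efficiency=_sd(effs),
                mean_ratio_FL_T=float(_mean(ratios)) if ratios else None,
                sd_ratio_FL_T=_sd(ratios) if ratios else None,
            )
        )
    return QuantResult(
        conditions=tuple(summaries), n_excluded=n_excluded, warnings=tuple(warnings_)
    )


def _mean(xs: list[float]) -> float:
    return sum(xs) / len(xs)


def _sd(xs: list[float]) -> Optional[float]:
    if len(xs) < 2:
        return None
    m = _mean(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - 1))
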