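"""Reduction of raw colorimetric enzyme-assay readings to fractional inhibition.

The DNS (3,5-dinitrosalicylic acid) assay quantifies reducing sugars released
by alpha-amylase: absorbance at 540 nm falls as the enzyme is inhibited.  Each
well condition is summarised by three absorbances — the extract well, the
positive control (fully inhibited reaction) and the negative control
(uninhibited reaction) — and percent inhibition is the linear interpolation of
the extract reading between the two controls:

    %Inh = 100 * [1 - (A_extract - A_pos) / (A_neg - A_pos)]

Values slightly outside [0, 100] arise from measurement noise and are
retained with a warning; clamping happens only when converting to the
fraction affected ``fa`` in [0, 1], the quantity the median-effect model
operates on.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AssayWarning",
    "DegenerateControlsError",
    "AbsorbanceTriple",
    "DoseEffectPoint",
    "percent_inhibition",
    "to_fraction_affected",
    "aggregate_replicates",
    "read_dose_effect_csv",
    "write_dose_effect_csv",
    "reduce_absorbance_table",
    "points_from_frame",
]


class AssayWarning(UserWarning):
    """Raised (as a warning) for retained-but-suspect assay values."""


class DegenerateControlsError(ValueError):
    """Positive and negative controls coincide, so inhibition is undefined."""


@dataclass(frozen=True)
class AbsorbanceTriple:
    """Extract / positive-control / negative-control absorbances (AU, 540 nm).

    The positive control is the fully inhibited reaction (lowest signal from
    released sugars); the negative control is the uninhibited reaction.
    """

    abs_extract: float
    abs_positive: float
    abs_negative: float

    def __post_init__(self) -> None:
        for name in ("abs_extract", "abs_positive", "abs_negative"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v!r}")
        if self.abs_negative == self.abs_positive:
            raise DegenerateControlsError(
                "negative control equals positive control "
                f"(both {self.abs_positive}); percent inhibition is undefined"
            )


@dataclass(frozen=True)
class DoseEffectPoint:
    """One (dose, fraction affected) observation for an agent or a mixture.

    ``dose`` carries no unit; the unit travels as an opaque label alongside
    the data (CSV column ``dose_unit``, fit field ``dose_unit``).  ``fa`` is
    the fraction of enzyme activity inhibited, in [0, 1].  After replicate
    aggregation, ``n_replicates`` and ``fa_sd`` record provenance.
    """

    dose: float
    fa: float
    replicate_id: int | None = None
    n_replicates: int = 1
    fa_sd: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.dose):
            raise ValueError(f"dose must be finite, got {self.dose!r}")
        if not math.isfinite(self.fa):
            raise ValueError(f"fa must be finite, got {self.fa!r}")
        if not 0.0 <= self.fa <= 1.0:
            raise ValueError(f"fa must lie in [0, 1], got {self.fa!r}")

    @property
    def fu(self) -> float:
        """Fraction unaffected, 1 - fa."""
        return 1.0 - self.fa


def percent_inhibition(triple: AbsorbanceTriple) -> float:
    """Percent inhibition from one absorbance triple.

    Affine in ``abs_extract``: the extract reading is interpolated between the
    negative control (0 %) and the positive control (100 %).  Values outside
    [0, 100] — possible with noisy readings — are returned unchanged but
    flagged with :class:`AssayWarning`.
    """
    span = triple.abs_negative - triple.abs_positive
    pct = 100.0 * (1.0 - (triple.abs_extract - triple.abs_positive) / span)
    if pct < 0.0 or pct > 100.0:
        warnings.warn(
            f"percent inhibition {pct:.3g} outside [0, 100]; retained as-is",
            AssayWarning,
            stacklevel=2,
        )
    return pct


def to_fraction_affected(percent: float) -> float:
    """Convert percent inhibition to the fraction affected ``fa = percent/100``.

    Out-of-range values are clamped to [0, 1] with an :class:`AssayWarning`;
    non-finite input is an error.
    """
    if not math.isfinite(percent):
        raise ValueError(f"percent inhibition must be finite, got {percent!r}")
    fa = percent / 100.0
    if fa < 0.0 or fa > 1.0:
        clamped = min(max(fa, 0.0), 1.0)
        warnings.warn(
            f"fa {fa:.4g} outside [0, 1]; clamped to {clamped:.4g}",
            AssayWarning,
            stacklevel=2,
        )
        return clamped
    return fa


def aggregate_replicates(points: Sequence[DoseEffectPoint]) -> list[DoseEffectPoint]:
    """Collapse replicate measurements to one point per unique dose.

    The aggregate ``fa`` is the arithmetic mean across replicates; the
    replicate count and the sample standard deviation (ddof=1, ``None`` for a
    single replicate) are kept on the returned points.  Doses appear in order
    of first occurrence.  All points are assumed to share a dose unit.
    """
    if not points:
        raise ValueError("cannot aggregate an empty list of points")
    by_dose: dict[float, list[DoseEffectPoint]] = {}
    for p in points:
        by_dose.setdefault(p.dose, []).append(p)
    out = []
    for dose, group in by_dose.items():
        fas = np.array([p.fa for p in group], dtype=float)
        sd = float(np.std(fas, ddof=1)) if len(fas) > 1 else None
        out.append(
            DoseEffectPoint(
                dose=dose,
                fa=float(np.mean(fas)),
                n_replicates=len(fas),
                fa_sd=sd,
            )
        )
    return out


# --- tabular I/O -----------------------------------------------------------

_FA_COLUMNS = {"agent", "dose", "dose_unit", "fa"}
_ABS_COLUMNS = {"agent", "dose", "dose_unit", "abs_extract", "abs_positive", "abs_negative"}


def read_dose_effect_csv(path: str | Path) -> pd.DataFrame:
    """Read a dose-effect CSV into a tidy frame with a guaranteed ``fa`` column.

    Two layouts are accepted, distinguished by the header (never inferred
    from value magnitudes):

    * reduced:  ``agent, dose, dose_unit, fa[, replicate]``
    * raw:      ``agent, dose, dose_unit, abs_extract, abs_positive,
      abs_negative[, replicate]`` — reduced on the fly via
      :func:`percent_inhibition` and :func:`to_fraction_affected`.
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    if _FA_COLUMNS <= cols:
        out = df.copy()
    elif _ABS_COLUMNS <= cols:
        out = reduce_absorbance_table(df)
    else:
        raise ValueError(
            f"{path}: header must contain either {sorted(_FA_COLUMNS)} or "
            f"{sorted(_ABS_COLUMNS)}; got {sorted(cols)}"
        )
    if "replicate" not in out.columns:
        out["replicate"] = pd.NA
    return out


def reduce_absorbance_table(df: pd.DataFrame) -> pd.DataFrame:
    """Reduce a raw-absorbance frame to ``agent, dose, dose_unit, fa``."""
    missing = _ABS_COLUMNS - set(df.columns)
    if missing:
        raise ValueError(f"missing absorbance columns: {sorted(missing)}")
    fa = [
        to_fraction_affected(
            percent_inhibition(
                AbsorbanceTriple(row.abs_extract, row.abs_positive, row.abs_negative)
            )
        )
        for row in df.itertuples()
    ]
    out = df[["agent", "dose", "dose_unit"]].copy()
    if "replicate" in df.columns:
        out["replicate"] = df["replicate"]
    out["fa"] = fa
    return out


def write_dose_effect_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a reduced dose-effect frame as UTF-8 CSV with header."""
    missing = _FA_COLUMNS - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    df.to_csv(path, index=False, encoding="utf-8")


def points_from_frame(df: pd.DataFrame, agent: str) -> list[DoseEffectPoint]:
    """Extract one agent's rows from a reduced frame as DoseEffectPoint list."""
    sub = df[df["agent"] == agent]
    if sub.empty:
        raise ValueError(f"no rows for agent {agent!r}")
    pts = []
    for row in sub.itertuples():
        rep = getattr(row, "replicate", None)
        rep = None if pd.isna(rep) else int(rep)
        pts.append(DoseEffectPoint(dose=float(row.dose), fa=float(row.fa), replicate_id=rep))
    return pts
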