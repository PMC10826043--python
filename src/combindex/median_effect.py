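"""Mass-action median-effect model: fitting and dose <-> effect transforms.

The median-effect equation relates dose D to the fraction affected fa,

    fa / fu = (D / Dm)^m,        fu = 1 - fa,

where Dm is the median-effect dose (the dose giving 50 % effect, i.e. the
IC50) and m the sigmoidicity coefficient (m = 1 hyperbolic, m > 1 sigmoidal).
Taking base-10 logarithms linearises it,

    log(fa/fu) = m log(D) - m log(Dm),

so an ordinary least-squares line through (log D, log(fa/fu)) yields m as the
slope and Dm as the antilog of the x-intercept.  The Pearson correlation r of
the transformed points measures conformity to the mass-action model.

Base 10 is used throughout, matching the classic median-effect plot
convention; Dm, m and r are invariant to the base as long as log and antilog
match.  The fit is unweighted OLS on the transformed variables — points with
fa = 0 or fa = 1 have no finite transform and are excluded with an explicit
report rather than epsilon-nudged, which would silently bias m.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .assay import DoseEffectPoint

__all__ = [
    "MedianEffectFit",
    "FitWarning",
    "fit_median_effect",
    "effect_at_dose",
    "dose_for_effect",
]


class FitWarning(UserWarning):
    """Non-fatal fitting diagnostics (excluded points, thin data, m <= 0)."""


@dataclass(frozen=True)
class MedianEffectFit:
    """Fitted median-effect parameters for one agent (or one mixture).

    Parameters
    ----------
    dm : median-effect dose, in the same unit as the input doses; > 0.
    m : sigmoidicity coefficient (slope of the median-effect plot).
    r : signed Pearson correlation of the transformed (log D, log fa/fu)
        points; 1.0 by convention for an exact two-point fit.
    n_points : number of points actually used in the fit.
    dose_unit : opaque unit label carried along for reporting.
    agent : optional agent name for reporting.
    """

    dm: float
    m: float
    r: float = 1.0
    n_points: int = 0
    dose_unit: str = ""
    agent: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.dm) and self.dm > 0):
            raise ValueError(f"Dm must be finite and > 0, got {self.dm!r}")
        if not math.isfinite(self.m) or self.m == 0:
            raise ValueError(f"m must be finite and nonzero, got {self.m!r}")
        if self.m < 0:
            warnings.warn(
                f"m = {self.m:.4g} <= 0: effect decreases with dose, which is "
                "not expected for an inhibitor",
                FitWarning,
                stacklevel=2,
            )
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"r must lie in [-1, 1], got {self.r!r}")


def _usable(points: Sequence[DoseEffectPoint]) -> tuple[list[DoseEffectPoint], list[DoseEffectPoint]]:
    usable, excluded = [], []
    for p in points:
        if p.dose > 0 and 0.0 < p.fa < 1.0:
            usable.append(p)
        else:
            excluded.append(p)
    return usable, excluded


def fit_median_effect(
    points: Sequence[DoseEffectPoint],
    *,
    dose_unit: str = "",
    agent: str = "",
) -> MedianEffectFit:
    """Fit the median-effect line by OLS on the log-transformed data.

    Points with dose <= 0 or fa outside the open interval (0, 1) cannot be
    transformed; they are excluded and reported via :class:`FitWarning`.
    Fewer than 2 usable points, or zero dose variance, is an error.  Fewer
    than 4 usable points triggers a thin-data warning.
    """
    usable, excluded = _usable(points)
    if excluded:
        desc = ", ".join(f"(D={p.dose:g}, fa={p.fa:g})" for p in excluded)
        warnings.warn(
            f"excluded {len(excluded)} point(s) outside the fittable domain "
            f"(need dose > 0 and 0 < fa < 1): {desc}",
            FitWarning,
            stacklevel=2,
        )
    if len(usable) < 2:
        desc = ", ".join(f"(D={p.dose:g}, fa={p.fa:g})" for p in excluded)
        raise ValueError(
            f"need at least 2 usable points, got {len(usable)}; "
            f"excluded: [{desc}]"
        )
    if len(usable) < 4:
        warnings.warn(
            f"only {len(usable)} usable points; the fit is poorly constrained",
            FitWarning,
            stacklevel=2,
        )

    x = np.log10([p.dose for p in usable])
    y = np.log10([p.fa / p.fu for p in usable])
    if np.ptp(x) == 0:
        raise ValueError("all usable points share one dose; slope is undefined")

    res = stats.linregress(x, y)
    m = float(res.slope)
    if m == 0:
        raise ValueError("fitted slope m is exactly 0; Dm is undefined")
    dm = 10.0 ** (-float(res.intercept) / m)
    r = float(res.rvalue)
    if len(usable) == 2:
        r = math.copysign(1.0, r) if r != 0 else 1.0
    return MedianEffectFit(
        dm=dm, m=m, r=r, n_points=len(usable), dose_unit=dose_unit, agent=agent
    )


def effect_at_dose(fit: MedianEffectFit, dose):
    """Fraction affected at dose D: fa = 1 / (1 + (Dm/D)^m).

    Accepts a scalar or array dose; strictly increasing in D when m > 0.
    """
    d = np.asarray(dose, dtype=float)
    if np.any(d <= 0):
        raise ValueError(f"dose must be > 0, got {dose!r}")
    fa = 1.0 / (1.0 + (fit.dm / d) ** fit.m)
    return float(fa) if np.isscalar(dose) or np.ndim(dose) == 0 else fa


def dose_for_effect(fit: MedianEffectFit, fa):
    """Dose producing fraction affected fa: D = Dm * (fa/(1-fa))^(1/m).

    The unique inverse of :func:`effect_at_dose`; fa must lie strictly in
    (0, 1) (the model reaches 0 and 1 only asymptotically).
    """
    f = np.asarray(fa, dtype=float)
    if np.any((f <= 0) | (f >= 1)):
        raise ValueError(f"fa must lie strictly in (0, 1), got {fa!r}")
    d = fit.dm * (f / (1.0 - f)) ** (1.0 / fit.m)
    return float(d) if np.isscalar(fa) or np.ndim(fa) == 0 else d
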