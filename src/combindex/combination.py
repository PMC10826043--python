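"""Binary-combination design and interaction quantification (CI, DRI, isobolograms).

Two inhibitors A and B are compared at a shared effect level x via the
combination index

    CI = C_A,x / IC_x,A  +  C_B,x / IC_x,B,

where C_A,x and C_B,x are the component doses of a mixture producing x%
effect and IC_x,A, IC_x,B the doses of each agent alone producing the same
effect (obtained by inverting each agent's median-effect fit).  CI < 1
indicates synergism, CI = 1 additivity in the Loewe sense, CI > 1
antagonism.  The dose-reduction index of a component,

    DRI = IC_x(alone) / C(in combination),

is the fold reduction in that component's dose afforded by the combination
at equal effect; the two metrics are tied by the identity
CI = 1/DRI_A + 1/DRI_B.

The mixture design implemented here is effect-matched rather than
fixed-ratio: at each target level x, the mixture combines each agent's own
equi-effective dose IC_x, so the component ratio drifts across levels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

from .median_effect import MedianEffectFit, dose_for_effect, fit_median_effect
from .assay import DoseEffectPoint

__all__ = [
    "MixtureObservation",
    "CombinationMetrics",
    "IsobologramLevel",
    "IsobologramPoint",
    "Isobologram",
    "DEFAULT_EFFECT_LEVELS",
    "design_effect_matched_mixtures",
    "combination_index",
    "dose_reduction_index",
    "classify",
    "fa_ci_curve",
    "isobologram",
    "combination_median_effect",
]

DEFAULT_EFFECT_LEVELS: tuple[float, ...] = (0.10, 0.30, 0.50, 0.70, 0.90)


@dataclass(frozen=True)
class MixtureObservation:
    """Component doses of a binary mixture and its observed effect.

    ``fa`` is ``None`` for a design template that has not been measured yet.
    """

    c_a: float
    c_b: float
    fa: float | None = None
    level_label: str | None = None

    def __post_init__(self) -> None:
        if self.c_a < 0 or self.c_b < 0:
            raise ValueError(f"component doses must be >= 0, got ({self.c_a}, {self.c_b})")
        if self.c_a + self.c_b <= 0:
            raise ValueError("at least one component dose must be positive")
        if self.fa is not None and not 0.0 < self.fa < 1.0:
            raise ValueError(f"observed fa must lie strictly in (0, 1), got {self.fa!r}")

    @property
    def total_dose(self) -> float:
        return self.c_a + self.c_b


@dataclass(frozen=True)
class CombinationMetrics:
    """Interaction metrics for one mixture observation at its effect level."""

    fa: float
    ic_a: float
    ic_b: float
    ci: float
    dri_a: float
    dri_b: float
    interaction_class: str

    def __post_init__(self) -> None:
        if self.ci <= 0:
            raise ValueError(f"CI must be > 0, got {self.ci!r}")
        recon = 1.0 / self.dri_a + 1.0 / self.dri_b
        if not math.isclose(self.ci, recon, rel_tol=1e-9):
            raise ValueError(
                f"inconsistent metrics: CI={self.ci!r} but 1/DRI_A + 1/DRI_B={recon!r}"
            )


def design_effect_matched_mixtures(
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    effect_levels: Sequence[float] = DEFAULT_EFFECT_LEVELS,
) -> list[MixtureObservation]:
    """Design binary mixtures matched to single-agent effect levels.

    For each target level x the mixture pairs the dose of A alone producing
    x with the dose of B alone producing x: (IC_x,A, IC_x,B).  Returned
    observations are templates with ``fa`` unset; the label records the
    nominal level (e.g. ``"IC50-matched"``).
    """
    mixtures = []
    for x in effect_levels:
        if not 0.0 < x < 1.0:
            raise ValueError(f"effect level must lie strictly in (0, 1), got {x!r}")
        mixtures.append(
            MixtureObservation(
                c_a=dose_for_effect(fit_a, x),
                c_b=dose_for_effect(fit_b, x),
                fa=None,
                level_label=f"IC{round(100 * x):g}-matched",
            )
        )
    return mixtures


def dose_reduction_index(
    obs: MixtureObservation,
    fit: MedianEffectFit,
    component: Literal["A", "B"],
) -> float:
    """Fold dose reduction for one component at the observed effect level.

    DRI = (dose of the agent alone producing the observed fa) / (the
    component's dose in the mixture).  Defined at the observed effect level,
    which reduces to the IC50 ratio when fa = 0.5.
    """
    if obs.fa is None:
        raise ValueError("observation has no measured fa")
    dose = obs.c_a if component == "A" else obs.c_b if component == "B" else None
    if dose is None:
        raise ValueError(f"component must be 'A' or 'B', got {component!r}")
    if dose <= 0:
        raise ValueError(
            f"component {component} has zero dose in the mixture; DRI is infinite"
        )
    return dose_for_effect(fit, obs.fa) / dose


def classify(ci: float, tolerance: float = 0.0) -> str:
    """Interaction class from a combination index.

    Strictly: CI < 1 synergism, CI = 1 additivity, CI > 1 antagonism.  A
    nonzero ``tolerance`` widens the additivity band to [1-tol, 1+tol] for
    noisy data.
    """
    if not math.isfinite(ci) or ci <= 0:
        raise ValueError(f"CI must be finite and > 0, got {ci!r}")
    if tolerance < 0:
        raise ValueError(f"tolerance must be >= 0, got {tolerance!r}")
    if ci < 1.0 - tolerance:
        return "synergism"
    if ci > 1.0 + tolerance:
        return "antagonism"
    return "additivity"


def combination_index(
    obs: MixtureObservation,
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    *,
    tolerance: float = 0.0,
) -> CombinationMetrics:
    """Combination index and per-component dose-reduction indices.

    At the observed effect level fa, each fit is inverted for the
    equi-effective single-agent dose, and
    CI = c_a/IC_fa,A + c_b/IC_fa,B.  A zero component dose is allowed (the
    single-agent limit); its DRI is reported as ``inf``.
    """
    if obs.fa is None:
        raise ValueError("observation has no measured fa")
    ic_a = dose_for_effect(fit_a, obs.fa)
    ic_b = dose_for_effect(fit_b, obs.fa)
    ci = obs.c_a / ic_a + obs.c_b / ic_b
    dri_a = ic_a / obs.c_a if obs.c_a > 0 else math.inf
    dri_b = ic_b / obs.c_b if obs.c_b > 0 else math.inf
    return CombinationMetrics(
        fa=obs.fa,
        ic_a=ic_a,
        ic_b=ic_b,
        ci=ci,
        dri_a=dri_a,
        dri_b=dri_b,
        interaction_class=classify(ci, tolerance),
    )


def fa_ci_curve(
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    *,
    combo_fit: MedianEffectFit | None = None,
    ratio: float | None = None,
    observations: Sequence[MixtureObservation] | None = None,
    fa_grid: Sequence[float] | None = None,
) -> list[tuple[float, float]]:
    """Combination index as a function of effect level (the fa-CI plot).

    Two modes:

    * constant-ratio — give ``combo_fit`` (median-effect fit of the mixture
      treated as one drug) and ``ratio`` (fraction of A in the total dose);
      at each fa in ``fa_grid`` the total dose is read off the mixture fit
      and split by the ratio.
    * observation — give explicit ``observations`` with measured fa; CI is
      computed at each observed point.
    """
    constant_ratio = combo_fit is not None and ratio is not None
    if constant_ratio == (observations is not None):
        raise ValueError(
            "give either (combo_fit and ratio) for constant-ratio mode or "
            "observations for observation mode, not both or neither"
        )
    if constant_ratio:
        if not 0.0 <= ratio <= 1.0:
            raise ValueError(f"ratio must lie in [0, 1], got {ratio!r}")
        grid = list(fa_grid) if fa_grid is not None else list(DEFAULT_EFFECT_LEVELS)
        curve = []
        for fa in grid:
            total = dose_for_effect(combo_fit, fa)
            obs = MixtureObservation(c_a=total * ratio, c_b=total * (1.0 - ratio), fa=fa)
            curve.append((fa, combination_index(obs, fit_a, fit_b).ci))
        return curve
    return [
        (obs.fa, combination_index(obs, fit_a, fit_b).ci) for obs in observations
    ]


@dataclass(frozen=True)
class IsobologramLevel:
    """Classical isobologram at one effect level: additive-line endpoints."""

    effect_level: float
    ic_a: float  # additive line x-intercept (dose of A alone)
    ic_b: float  # additive line y-intercept (dose of B alone)


@dataclass(frozen=True)
class IsobologramPoint:
    """One observation in normalized isobologram coordinates.

    ``x + y`` equals the observation's CI, so position relative to the
    additive line x + y = 1 encodes the interaction class: below (CI < 1)
    synergism, on additivity, above antagonism.
    """

    c_a: float
    c_b: float
    fa: float
    x: float  # c_a / IC_fa,A
    y: float  # c_b / IC_fa,B
    ci: float
    position: str  # "below" | "on" | "above"


@dataclass(frozen=True)
class Isobologram:
    levels: tuple[IsobologramLevel, ...]
    points: tuple[IsobologramPoint, ...]


def isobologram(
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    observations: Sequence[MixtureObservation],
    effect_levels: Sequence[float] = DEFAULT_EFFECT_LEVELS,
) -> Isobologram:
    """Isobologram data in classical and dose-normalized form.

    Classical: for each requested effect level, the additive line joins
    (IC_x,A, 0) and (0, IC_x,B) in raw dose space.  Normalized: every
    observation maps to (c_a/IC_fa,A, c_b/IC_fa,B) so a single additive line
    x + y = 1 serves all effect levels; each point is labeled below/on/above
    that line.
    """
    levels = tuple(
        IsobologramLevel(
            effect_level=x,
            ic_a=dose_for_effect(fit_a, x),
            ic_b=dose_for_effect(fit_b, x),
        )
        for x in effect_levels
    )
    points = []
    for obs in observations:
        metrics = combination_index(obs, fit_a, fit_b)
        x = obs.c_a / metrics.ic_a
        y = obs.c_b / metrics.ic_b
        cls = classify(metrics.ci)
        position = {"synergism": "below", "additivity": "on", "antagonism": "above"}[cls]
        points.append(
            IsobologramPoint(
                c_a=obs.c_a, c_b=obs.c_b, fa=obs.fa, x=x, y=y, ci=metrics.ci,
                position=position,
            )
        )
    return Isobologram(levels=levels, points=tuple(points))


def combination_median_effect(
    observations: Sequence[MixtureObservation],
    *,
    dose_unit_a: str = "",
    dose_unit_b: str = "",
    agent: str = "",
) -> MedianEffectFit:
    """Median-effect fit of a mixture treated as a single agent.

    The mixture "dose" is the arithmetic sum of the component doses, even
    when the components carry heterogeneous units; the resulting fit carries
    a composite unit tag and a warning is emitted in that case, since the
    summed dose then has no physical unit.
    """
    measured = [o for o in observations if o.fa is not None]
    if len(measured) < 2:
        raise ValueError(f"need at least 2 measured observations, got {len(measured)}")
    if dose_unit_a and dose_unit_b and dose_unit_a != dose_unit_b:
        unit = f"{dose_unit_a}+{dose_unit_b}"
        warnings.warn(
            f"summing component doses with heterogeneous units "
            f"({dose_unit_a} + {dose_unit_b}); the total dose is a nominal "
            "composite quantity",
            UserWarning,
            stacklevel=2,
        )
    else:
        unit = dose_unit_a or dose_unit_b
    points = [DoseEffectPoint(dose=o.total_dose, fa=o.fa) for o in measured]
    return fit_median_effect(points, dose_unit=unit, agent=agent)
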