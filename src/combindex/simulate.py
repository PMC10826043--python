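"""Synthetic dose-effect and mixture data with known ground truth.

Every pipeline stage is testable without laboratory data: single-agent
curves are drawn from the median-effect model itself, mixtures from the
Loewe-additivity null (or any prescribed interaction strength), and raw
absorbance triples from the exact inverse of the percent-inhibition
equation.

Noise model: replicate noise is Gaussian on the median-effect scale
log10(fa/fu), i.e. the same scale on which the model is linear and fitted.
Simulated fa therefore always stays inside (0, 1), and unweighted OLS on the
transformed data is the exact maximum-likelihood estimator under the
simulation, which makes parameter-recovery tests sharp.  A separate
raw-absorbance mode adds Gaussian noise to instrument readings instead, for
end-to-end realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .assay import AbsorbanceTriple, DoseEffectPoint
from .median_effect import MedianEffectFit, dose_for_effect, effect_at_dose

__all__ = [
    "SimulationSpec",
    "simulate_dose_effect",
    "simulate_mixture_fa",
    "simulate_loewe_mixtures",
    "inhibition_to_absorbance",
    "simulate_absorbance_readings",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Ground truth and sampling plan for one simulated dose-effect dataset.

    ``noise_sd`` is the standard deviation of Gaussian noise added on the
    log10(fa/fu) scale per replicate measurement.  All randomness comes from
    one generator seeded with ``seed``; the same spec always yields the same
    dataset.
    """

    true_dm: float
    true_m: float
    doses: tuple[float, ...]
    noise_sd: float = 0.0
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.true_dm) and self.true_dm > 0):
            raise ValueError(f"true_dm must be finite and > 0, got {self.true_dm!r}")
        if not (math.isfinite(self.true_m) and self.true_m > 0):
            raise ValueError(f"true_m must be finite and > 0, got {self.true_m!r}")
        if not self.doses or any(d <= 0 for d in self.doses):
            raise ValueError("doses must be a non-empty sequence of positive values")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd!r}")
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {self.replicates!r}")
        object.__setattr__(self, "doses", tuple(float(d) for d in self.doses))

    @property
    def fit(self) -> MedianEffectFit:
        """The ground-truth parameters as a fit object (r = 1 by definition)."""
        return MedianEffectFit(dm=self.true_dm, m=self.true_m, r=1.0)


def simulate_dose_effect(spec: SimulationSpec) -> list[DoseEffectPoint]:
    """Draw replicate dose-effect points from the median-effect model.

    For each dose D and replicate, y = m*log10(D/Dm) + eps with
    eps ~ N(0, noise_sd^2); fa = 10^y / (1 + 10^y).
    """
    rng = np.random.default_rng(spec.seed)
    points = []
    for d in spec.doses:
        y0 = spec.true_m * math.log10(d / spec.true_dm)
        eps = rng.normal(0.0, spec.noise_sd, size=spec.replicates)
        for rep, y in enumerate(y0 + eps):
            fa = 10.0**y / (1.0 + 10.0**y)
            points.append(DoseEffectPoint(dose=d, fa=float(fa), replicate_id=rep))
    return points


def simulate_mixture_fa(
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    c_a: float,
    c_b: float,
    ci_true: float = 1.0,
) -> float:
    """Effect of a binary mixture with a prescribed combination index.

    Returns the unique fa in (0, 1) solving

        c_a / IC_fa,A + c_b / IC_fa,B = ci_true,

    i.e. the Loewe-additive response when ci_true = 1, a synergistic world
    when ci_true < 1, an antagonistic one when ci_true > 1.  For positive m
    the left side is strictly decreasing in fa, so bisection (Brent) on
    (0, 1) finds the root to |dfa| < 1e-10.
    """
    if c_a < 0 or c_b < 0 or c_a + c_b <= 0:
        raise ValueError(f"need nonnegative doses with a positive total, got ({c_a}, {c_b})")
    if not (math.isfinite(ci_true) and ci_true > 0):
        raise ValueError(f"ci_true must be finite and > 0, got {ci_true!r}")
    # single-agent limits invert in closed form: c/IC_fa = ci  =>  IC_fa = c/ci
    if c_b == 0:
        return effect_at_dose(fit_a, c_a / ci_true)
    if c_a == 0:
        return effect_at_dose(fit_b, c_b / ci_true)
    return _solve(fit_a, fit_b, c_a, c_b, ci_true)


def _solve(fit_a, fit_b, c_a, c_b, ci_true):
    def excess(fa: float) -> float:
        total = 0.0
        if c_a > 0:
            total += c_a / dose_for_effect(fit_a, fa)
        if c_b > 0:
            total += c_b / dose_for_effect(fit_b, fa)
        return total - ci_true

    lo, hi = 1e-12, 1.0 - 1e-12
    f_lo, f_hi = excess(lo), excess(hi)
    if not (f_lo > 0 > f_hi):
        raise ValueError(
            "cannot bracket the mixture effect in (0, 1): for positive m the "
            "dose-sum excess falls from positive to negative, but "
            f"excess({lo:g}) = {f_lo:.3g} and excess({hi:g}) = {f_hi:.3g}"
        )
    return float(brentq(excess, lo, hi, xtol=1e-10))


def simulate_loewe_mixtures(
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    mixtures,
    ci_true: float = 1.0,
):
    """Fill the ``fa`` of each design template from the interaction model."""
    return [
        replace(m, fa=simulate_mixture_fa(fit_a, fit_b, m.c_a, m.c_b, ci_true))
        for m in mixtures
    ]


def inhibition_to_absorbance(
    fa: float, abs_positive: float, abs_negative: float
) -> AbsorbanceTriple:
    """Absorbance triple whose percent inhibition is exactly 100*fa.

    Inverse of the assay reduction: the extract reading is placed at the
    point of the control span corresponding to fa, so reducing the triple
    recovers fa to machine precision.
    """
    abs_extract = abs_positive + (1.0 - fa) * (abs_negative - abs_positive)
    return AbsorbanceTriple(
        abs_extract=abs_extract, abs_positive=abs_positive, abs_negative=abs_negative
    )


def simulate_absorbance_readings(
    spec: SimulationSpec,
    abs_positive: float = 0.10,
    abs_negative: float = 0.80,
    abs_noise_sd: float = 0.0,
) -> list[tuple[float, AbsorbanceTriple]]:
    """Raw-absorbance realism mode: Gaussian noise on the extract reading.

    Returns (dose, triple) pairs.  Unlike the log-scale noise of
    :func:`simulate_dose_effect`, additive absorbance noise can push the
    reduced percent inhibition outside [0, 100], exercising the warning and
    clamping paths of the assay module.  Noise uses the spec seed offset by
    one so the two modes are independent but jointly reproducible.
    """
    rng = np.random.default_rng(spec.seed + 1)
    out = []
    for d in spec.doses:
        fa = effect_at_dose(spec.fit, d)
        for _ in range(spec.replicates):
            clean = inhibition_to_absorbance(fa, abs_positive, abs_negative)
            noisy = max(0.0, clean.abs_extract + rng.normal(0.0, abs_noise_sd))
            out.append(
                (d, AbsorbanceTriple(noisy, abs_positive, abs_negative))
            )
    return out
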