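"""Reference values from a published alpha-amylase inhibition combination study.

An in-vitro DNS assay measured pancreatic alpha-amylase inhibition by the
clinical inhibitor acarbose, the flavonol kaempferol, and an ethanolic
propolis extract, alone and in effect-matched binary combinations with
acarbose (mixtures pairing each agent's own IC10/IC30/IC50/IC70/IC90).  The
study reported the single-agent and mixture median-effect parameters
(Dm, m, r) and, per mixture level, the observed effect, combination index,
equi-effective single-agent doses and dose-reduction indices.

These printed values serve as a worked example throughout the package: the
single-agent parameters are the inputs from which every mixture-level
quantity can be recomputed, and the printed CI/DRI columns are the expected
outputs.  Doses are mM for acarbose and kaempferol, mg/mL for the propolis
extract.  Note that the printed values were rounded to 2-3 significant
figures by the original authors, so recomputations agree to roughly that
precision, not exactly.
"""

from __future__ import annotations

import pandas as pd

from .median_effect import MedianEffectFit

__all__ = [
    "ACARBOSE",
    "KAEMPFEROL",
    "PROPOLIS",
    "SINGLE_AGENT_FITS",
    "COMBINATION_FITS",
    "DESIGN_LEVELS",
    "combination_rows",
]

#: Single-agent median-effect parameters (dose units: mM, mM, mg/mL).
ACARBOSE = MedianEffectFit(dm=0.061, m=1.32, r=1.00, n_points=5,
                           dose_unit="mM", agent="acarbose")
KAEMPFEROL = MedianEffectFit(dm=4.84, m=1.18, r=1.00, n_points=5,
                             dose_unit="mM", agent="kaempferol")
PROPOLIS = MedianEffectFit(dm=1.07, m=0.512, r=1.00, n_points=5,
                           dose_unit="mg/mL", agent="propolis")

SINGLE_AGENT_FITS = {f.agent: f for f in (ACARBOSE, KAEMPFEROL, PROPOLIS)}

#: Median-effect parameters reported for the mixtures treated as one agent
#: (total dose = sum of components, a nominal composite quantity).
COMBINATION_FITS = {
    "acarbose+kaempferol": MedianEffectFit(
        dm=2.01, m=0.935, r=0.99, n_points=5,
        dose_unit="mM", agent="acarbose+kaempferol",
    ),
    "acarbose+propolis": MedianEffectFit(
        dm=0.274, m=0.443, r=0.99, n_points=5,
        dose_unit="mM+mg/mL", agent="acarbose+propolis",
    ),
}

#: Nominal single-agent effect levels matched by the mixture design.
DESIGN_LEVELS = (0.10, 0.30, 0.50, 0.70, 0.90)

# Per-level published results: observed mixture effect, combination index
# with its interaction call, equi-effective single-agent doses at the
# observed effect, and the dose-reduction index of each component.
_AP_ROWS = [
    # fa,    CI,    class,  dose_a (mM), dose_b (mg/mL), dri_a, dri_b
    (0.235, 0.601, "synergism", 0.025, 0.106, 2.16, 7.28),
    (0.448, 0.903, "synergism", 0.052, 0.710, 1.62, 3.50),
    (0.651, 0.920, "synergism", 0.097, 3.61, 1.60, 3.39),
    (0.84, 0.748, "synergism", 0.212, 27.3, 1.84, 4.88),
    (0.91, 1.71, "antagonism", 0.348, 98.3, 1.09, 1.25),
]
_AK_ROWS = [
    (0.26, 0.795, "synergism", 0.027, 1.99, 2.39, 2.66),
    (0.537, 0.900, "synergism", 0.068, 5.49, 2.12, 2.33),
    (0.711, 0.972, "synergism", 0.119, 10.4, 1.97, 2.15),
    (0.86, 0.922, "synergism", 0.239, 22.6, 2.07, 2.27),
    (0.91, 1.82, "antagonism", 0.348, 34.5, 1.09, 1.11),
]

_COLUMNS = ["level", "fa", "ci", "interaction_class", "ic_a", "ic_b", "dri_a", "dri_b"]


def combination_rows(pair: str) -> pd.DataFrame:
    """Published per-level results for one acarbose pairing.

    Parameters
    ----------
    pair : "acarbose+propolis" or "acarbose+kaempferol".

    Returns
    -------
    DataFrame with columns ``level`` (nominal design effect level), ``fa``
    (observed mixture effect), ``ci``, ``interaction_class``, ``ic_a``/
    ``ic_b`` (equi-effective single-agent doses at the observed fa) and
    ``dri_a``/``dri_b``.
    """
    rows = {"acarbose+propolis": _AP_ROWS, "acarbose+kaempferol": _AK_ROWS}.get(pair)
    if rows is None:
        raise KeyError(f"unknown pair {pair!r}")
    return pd.DataFrame(
        [(lvl, *row) for lvl, row in zip(DESIGN_LEVELS, rows)], columns=_COLUMNS
    )
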