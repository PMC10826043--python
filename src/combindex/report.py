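"""Full-analysis orchestration and report rendering.

``run_full_analysis`` drives the whole pipeline for a declarative config:
reduce raw readings to fractions affected, fit the median-effect model to
each agent and each mixture, then compute per-level combination metrics and
isobologram coordinates for every requested pair.  The resulting
``AnalysisReport`` serializes deterministically: JSON carries full float
precision with sorted keys; CSV and markdown render values at 3 significant
figures for human reading.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__ as _pkg_version
from .assay import DoseEffectPoint, aggregate_replicates, points_from_frame, read_dose_effect_csv
from .combination import (
    MixtureObservation,
    combination_index,
    combination_median_effect,
    isobologram,
)
from .median_effect import MedianEffectFit, fit_median_effect

__all__ = [
    "AgentSpec",
    "PairSpec",
    "AnalysisConfig",
    "AnalysisReport",
    "run_full_analysis",
    "render_report",
    "report_from_json",
]


@dataclass(frozen=True)
class AgentSpec:
    """One agent to fit: name plus either inline points or a CSV source."""

    name: str
    points: tuple[DoseEffectPoint, ...] = ()
    csv: str | None = None
    dose_unit: str = ""


@dataclass(frozen=True)
class PairSpec:
    """One binary combination: agent names and its mixture observations."""

    agent_a: str
    agent_b: str
    observations: tuple[MixtureObservation, ...] = ()
    mixtures_csv: str | None = None
    ci_tolerance: float = 0.0

    @property
    def name(self) -> str:
        return f"{self.agent_a}+{self.agent_b}"


@dataclass(frozen=True)
class AnalysisConfig:
    agents: tuple[AgentSpec, ...]
    pairs: tuple[PairSpec, ...] = ()
    aggregate: bool = True
    seed: int | None = None
    inputs: tuple[str, ...] = ()


@dataclass
class AnalysisReport:
    """Per-agent fits plus per-level combination rows, with provenance."""

    fits: pd.DataFrame  # agent, Dm, m, r, n_points, dose_unit
    combinations: pd.DataFrame  # pair, level_label, fa, ci, class, doses, DRIs
    provenance: dict

    def validate(self) -> None:
        """Check the CI = 1/DRI_A + 1/DRI_B identity on every row."""
        for row in self.combinations.itertuples():
            recon = 1.0 / row.dri_a + 1.0 / row.dri_b
            if not math.isclose(row.ci, recon, rel_tol=1e-9):
                raise ValueError(
                    f"row {row.Index}: CI {row.ci!r} != 1/DRI_A + 1/DRI_B {recon!r}"
                )


_FIT_COLS = ["agent", "dm", "m", "r", "n_points", "dose_unit"]
_COMBO_COLS = [
    "pair", "level_label", "fa", "ci", "interaction_class",
    "c_a", "c_b", "ic_a", "ic_b", "dri_a", "dri_b",
]


def _load_agent_points(spec: AgentSpec) -> list[DoseEffectPoint]:
    if spec.points:
        return list(spec.points)
    if spec.csv is None:
        raise ValueError(f"agent {spec.name!r} has neither inline points nor a CSV source")
    frame = read_dose_effect_csv(spec.csv)
    return points_from_frame(frame, spec.name)


def _load_mixtures(spec: PairSpec) -> list[MixtureObservation]:
    if spec.observations:
        return list(spec.observations)
    if spec.mixtures_csv is None:
        raise ValueError(f"pair {spec.name!r} has neither observations nor a CSV source")
    df = pd.read_csv(spec.mixtures_csv)
    needed = {"c_a", "c_b", "fa"}
    if not needed <= set(df.columns):
        raise ValueError(f"{spec.mixtures_csv}: need columns {sorted(needed)}")
    return [
        MixtureObservation(
            c_a=float(r.c_a), c_b=float(r.c_b), fa=float(r.fa),
            level_label=str(r.level_label) if "level_label" in df.columns else None,
        )
        for r in df.itertuples()
    ]


def run_full_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Reduce, fit and score every agent and pair named in the config.

    Deterministic for fixed inputs.  Errors from the underlying modules are
    re-raised with the agent or pair name prepended for context.
    """
    fits: dict[str, MedianEffectFit] = {}
    fit_rows = []
    for agent in config.agents:
        try:
            pts = _load_agent_points(agent)
            if config.aggregate:
                pts = aggregate_replicates(pts)
            fit = fit_median_effect(pts, dose_unit=agent.dose_unit, agent=agent.name)
        except ValueError as err:
            raise ValueError(f"agent {agent.name!r}: {err}") from err
        fits[agent.name] = fit
        fit_rows.append(
            (agent.name, fit.dm, fit.m, fit.r, fit.n_points, fit.dose_unit)
        )

    combo_rows = []
    for pair in config.pairs:
        for side in (pair.agent_a, pair.agent_b):
            if side not in fits:
                raise ValueError(f"pair {pair.name!r} references unfitted agent {side!r}")
        fit_a, fit_b = fits[pair.agent_a], fits[pair.agent_b]
        try:
            observations = _load_mixtures(pair)
            combo_fit = combination_median_effect(
                observations,
                dose_unit_a=fit_a.dose_unit,
                dose_unit_b=fit_b.dose_unit,
                agent=pair.name,
            )
            fit_rows.append(
                (pair.name, combo_fit.dm, combo_fit.m, combo_fit.r,
                 combo_fit.n_points, combo_fit.dose_unit)
            )
            for obs in observations:
                metrics = combination_index(obs, fit_a, fit_b, tolerance=pair.ci_tolerance)
                combo_rows.append(
                    (pair.name, obs.level_label, metrics.fa, metrics.ci,
                     metrics.interaction_class, obs.c_a, obs.c_b,
                     metrics.ic_a, metrics.ic_b, metrics.dri_a, metrics.dri_b)
                )
        except ValueError as err:
            raise ValueError(f"pair {pair.name!r}: {err}") from err

    report = AnalysisReport(
        fits=pd.DataFrame(fit_rows, columns=_FIT_COLS),
        combinations=pd.DataFrame(combo_rows, columns=_COMBO_COLS),
        provenance={
            "package_version": _pkg_version,
            "inputs": sorted(config.inputs),
            "seed": config.seed,
            "n_agents": len(config.agents),
            "n_pairs": len(config.pairs),
        },
    )
    report.validate()
    return report


def _sig3(x) -> str:
    if isinstance(x, float):
        return f"{x:.3g}"
    return "" if x is None else str(x)


def render_report(report: AnalysisReport, format: str = "json") -> str:
    """Serialize a report; bit-stable for identical input.

    * ``json`` — full float precision, sorted keys.
    * ``csv`` — two sections (fits, combinations), full precision.
    * ``markdown`` — human-readable tables at 3 significant figures, with
      combination columns ordered effect level, CI, doses, DRIs.
    """
    if format == "json":
        payload = {
            "combinations": report.combinations.to_dict(orient="records"),
            "fits": report.fits.to_dict(orient="records"),
            "provenance": report.provenance,
        }
        return json.dumps(payload, sort_keys=True, indent=2, allow_nan=False) + "\n"
    if format == "csv":
        buf = io.StringIO()
        buf.write("# fits\n")
        report.fits.to_csv(buf, index=False)
        buf.write("# combinations\n")
        report.combinations.to_csv(buf, index=False)
        return buf.getvalue()
    if format == "markdown":
        lines = ["## Median-effect fits", ""]
        lines.append("| agent | Dm | m | r | n | unit |")
        lines.append("|---|---|---|---|---|---|")
        for t in report.fits.itertuples():
            lines.append(
                f"| {t.agent} | {_sig3(t.dm)} | {_sig3(t.m)} | {_sig3(t.r)} "
                f"| {t.n_points} | {t.dose_unit} |"
            )
        lines += ["", "## Combination metrics", ""]
        lines.append(
            "| pair | fa x 100 | CI | class | dose A | dose B | DRI A | DRI B |"
        )
        lines.append("|---|---|---|---|---|---|---|---|")
        for t in report.combinations.itertuples():
            lines.append(
                f"| {t.pair} | {_sig3(100 * t.fa)} | {_sig3(t.ci)} "
                f"| {t.interaction_class} | {_sig3(t.c_a)} | {_sig3(t.c_b)} "
                f"| {_sig3(t.dri_a)} | {_sig3(t.dri_b)} |"
            )
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown format {format!r}; use json, csv or markdown")


def report_from_json(text: str) -> AnalysisReport:
    """Rebuild a report from its JSON rendering (lossless round trip)."""
    payload = json.loads(text)
    fits = pd.DataFrame(payload["fits"])
    combos = pd.DataFrame(payload["combinations"])
    if not fits.empty:
        fits = fits[_FIT_COLS]
    if not combos.empty:
        combos = combos[_COMBO_COLS]
    return AnalysisReport(fits=fits, combinations=combos, provenance=payload["provenance"])
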