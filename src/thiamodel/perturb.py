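"""In-silico enzyme over-/under-expression scans.

Changing a gene's expression changes the abundance of its enzyme, and with it
Vmax (= kcat · [E]); Km is a property of the active site and is untouched.  A
:class:`PerturbationScenario` therefore multiplies the Vmax (or mass-action
k, for transporter-like steps) of every reaction carrying a given enzyme
label — the bifunctional TH1 kinase and synthase activities scale together.
A factor of 0 is a knockout; the scan's default fold of 100 emulates strong
overexpression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .model import PathwayModel
from .simulate import SimulationConfig, TimeCourseResult, simulate

__all__ = [
    "PerturbationScenario",
    "ScanReport",
    "apply_perturbation",
    "enumerate_standard_scenarios",
    "run_scan",
]

MAX_POWERSET_ENZYMES = 12


@dataclass
class PerturbationScenario:
    """A named set of per-enzyme Vmax fold changes applied to one model."""

    name: str
    fold_changes: dict[str, float] = field(default_factory=dict)
    target_metabolite: str = "TMP"

    def __post_init__(self) -> None:
        for label, f in self.fold_changes.items():
            if f < 0:
                raise ValueError(f"fold change for {label} must be >= 0, got {f}")


def apply_perturbation(model: PathwayModel, scenario: PerturbationScenario) -> PathwayModel:
    """Return a new model with the scenario's fold changes applied.

    Every reaction whose ``enzyme_label`` appears in ``fold_changes`` has its
    vmax (MM laws) or k (mass action / constant flux) multiplied by the
    factor; all other parameters and the input model are untouched.
    """
    known = set(model.enzyme_labels)
    unknown = [e for e in scenario.fold_changes if e not in known]
    if unknown:
        raise KeyError(
            f"unknown enzyme label(s) {unknown}; model labels: {sorted(known)}"
        )
    out = model.copy()
    for rxn in out.reactions:
        factor = scenario.fold_changes.get(rxn.enzyme_label)
        if factor is None or rxn.law is None:
            continue
        if rxn.law.vmax is not None:
            rxn.law.vmax *= factor
        elif rxn.law.k is not None:
            rxn.law.k *= factor
    out.metadata = dict(out.metadata, scenario=scenario.name)
    return out


def enumerate_standard_scenarios(
    model: PathwayModel,
    enzymes: Iterable[str],
    fold: float = 100.0,
    target_metabolite: str = "TMP",
    powerset: bool = False,
) -> list[PerturbationScenario]:
    """Build the standard overexpression scenario set.

    Default: one single-enzyme scenario per enzyme plus the all-enzymes
    combination (the combinatorial strategy).  With ``powerset=True``, every
    non-empty subset (2^n - 1 scenarios, refused above 12 enzymes).
    """
    enzymes = list(enzymes)
    known = set(model.enzyme_labels)
    missing = [e for e in enzymes if e not in known]
    if missing:
        raise KeyError(f"unknown enzyme label(s) {missing}; model labels: {sorted(known)}")
    if powerset:
        if len(enzymes) > MAX_POWERSET_ENZYMES:
            raise ValueError(
                f"power-set scan over {len(enzymes)} enzymes would produce "
                f"{2 ** len(enzymes) - 1} scenarios; restrict to at most "
                f"{MAX_POWERSET_ENZYMES} enzymes or use the default single+all set"
            )
        subsets = [
            list(c) for r in range(1, len(enzymes) + 1) for c in combinations(enzymes, r)
        ]
    else:
        subsets = [[e] for e in enzymes]
        if len(enzymes) > 1:
            subsets.append(enzymes)
    return [
        PerturbationScenario(
            name="+".join(sub) + f" x{fold:g}",
            fold_changes={e: fold for e in sub},
            target_metabolite=target_metabolite,
        )
        for sub in subsets
    ]


@dataclass
class ScanReport:
    """Per-scenario outcomes for the target metabolite, baseline included."""

    target_metabolite: str
    rows: pd.DataFrame  # scenario, final, plateau flag/value, peak time/value, auc, ok
    trajectories: dict[str, TimeCourseResult]

    def ranking(self, criterion: str = "final") -> pd.DataFrame:
        """Scenarios ordered best-first by 'final', 'peak' or 'auc'."""
        col = {"final": "final", "peak": "peak_value", "auc": "auc"}[criterion]
        ok = self.rows[self.rows["ok"]]
        return ok.sort_values(col, ascending=False).reset_index(drop=True)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.rows.to_csv(path, sep="\t", index=False)
        return path


def run_scan(
    model: PathwayModel,
    scenarios: Iterable[PerturbationScenario],
    config: SimulationConfig | None = None,
    target_metabolite: str | None = None,
) -> ScanReport:
    """Simulate the baseline and every scenario; collect target outcomes.

    A failing scenario is flagged (``ok = False``, error recorded) without
    aborting the rest of the scan.
    """
    config = config or SimulationConfig()
    scenarios = list(scenarios)
    target = target_metabolite or (
        scenarios[0].target_metabolite if scenarios else "TMP"
    )
    baseline = PerturbationScenario(name="baseline", fold_changes={}, target_metabolite=target)

    rows = []
    trajectories: dict[str, TimeCourseResult] = {}
    for scenario in [baseline, *scenarios]:
        row: dict = {"scenario": scenario.name, "ok": True, "error": ""}
        try:
            perturbed = apply_perturbation(model, scenario)
            result = simulate(perturbed, config)
            series = result.series(target)
            reached, plateau_value = result.plateau_reached(target)
            t_peak, v_peak = result.peak(target)
            row.update(
                final=result.final_value(target),
                plateau_reached=reached,
                plateau_value=plateau_value,
                peak_time=t_peak,
                peak_value=v_peak,
                auc=float(np.trapezoid(series, result.times)),
            )
            trajectories[scenario.name] = result
        except Exception as exc:  # keep scanning; report the failure
            row.update(
                ok=False,
                error=str(exc),
                final=np.nan,
                plateau_reached=False,
                plateau_value=np.nan,
                peak_time=np.nan,
                peak_value=np.nan,
                auc=np.nan,
            )
        rows.append(row)
    frame = pd.DataFrame(
        rows,
        columns=[
            "scenario",
            "final",
            "plateau_reached",
            "plateau_value",
            "peak_time",
            "peak_value",
            "auc",
            "ok",
            "error",
        ],
    )
    return ScanReport(target_metabolite=target, rows=frame, trajectories=trajectories)
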