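"""Stoichiometric flux-balance analysis and kinetic gap-filling.

When a reaction has no published kinetic constants, its steady-state flux can
still be predicted from the network's stoichiometry: maximize a linear
objective over fluxes v subject to N·v = 0 for every internal (non-clamped)
metabolite and per-reaction bounds.  The predicted flux is then converted
into a kinetic law whose rate at the model's initial concentrations equals
that flux, so the assembled ODE model starts on the predicted steady flux.

The default objective maximizes the gross production of a target metabolite
(TMP by default) — the sum of fluxes weighted by their positive stoichiometric
coefficients for that species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .model import KineticLaw, PathwayModel

__all__ = [
    "StoichModel",
    "FluxSolution",
    "build_stoich",
    "solve_fba",
    "gapfill_parameters",
]

DEFAULT_FLUX_CAP = 1.0  # nmol/L/s; generous relative to the pathway's nmol-scale rates


@dataclass
class StoichModel:
    """Steady-state LP data: N (internal metabolites x reactions), bounds, objective."""

    stoich_matrix: np.ndarray
    reaction_ids: list[str]
    internal_metabolite_ids: list[str]
    lower: np.ndarray
    upper: np.ndarray
    objective: np.ndarray  # coefficients to MAXIMIZE

    def __post_init__(self) -> None:
        n_m, n_r = self.stoich_matrix.shape
        if n_m != len(self.internal_metabolite_ids) or n_r != len(self.reaction_ids):
            raise ValueError("stoichiometric matrix dimensions inconsistent with roster")
        if np.any(self.lower > self.upper):
            bad = self.reaction_ids[int(np.argmax(self.lower > self.upper))]
            raise ValueError(f"lower bound exceeds upper bound for reaction {bad}")


@dataclass
class FluxSolution:
    """An LP outcome: per-reaction fluxes, objective value and solver status."""

    fluxes: dict[str, float]
    objective_value: float
    status: str  # optimal | infeasible | unbounded

    @property
    def ok(self) -> bool:
        return self.status == "optimal"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"reaction_id": list(self.fluxes), "flux": list(self.fluxes.values())}
        )


def build_stoich(
    model: PathwayModel,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    objective: Mapping[str, float] | str | None = None,
    default_bounds: tuple[float, float] = (0.0, DEFAULT_FLUX_CAP),
) -> StoichModel:
    """Assemble the steady-state LP from a pathway model.

    Clamped (boundary) species are reservoirs and are excluded from the
    steady-state constraint.  ``bounds`` overrides the default per-reaction
    flux window; reversible reactions default to a symmetric window.
    ``objective`` is either an explicit {reaction_id: coefficient} map or a
    metabolite id, meaning "maximize gross production of that species".
    """
    bounds = bounds or {}
    for rid in bounds:
        try:
            model.reaction(rid)
        except KeyError:
            raise KeyError(f"bounds reference unknown reaction {rid!r}") from None

    internal = [m.id for m in model.metabolites if not m.boundary]
    internal_idx = {m: i for i, m in enumerate(internal)}
    reaction_ids = [r.id for r in model.reactions]
    n = np.zeros((len(internal), len(reaction_ids)))
    for j, rxn in enumerate(model.reactions):
        for met_id, coeff in rxn.stoichiometry.items():
            i = internal_idx.get(met_id)
            if i is not None:
                n[i, j] = coeff

    lo, hi = default_bounds
    lower = np.full(len(reaction_ids), lo)
    upper = np.full(len(reaction_ids), hi)
    for j, rxn in enumerate(model.reactions):
        if rxn.reversible:
            lower[j] = min(lo, -hi)
        if rxn.id in bounds:
            lower[j], upper[j] = bounds[rxn.id]

    c = np.zeros(len(reaction_ids))
    if objective is None:
        objective = "TMP"
    if isinstance(objective, str):
        if objective not in model._index:
            raise KeyError(f"objective metabolite {objective!r} not in model")
        for j, rxn in enumerate(model.reactions):
            coeff = rxn.stoichiometry.get(objective, 0.0)
            if coeff > 0:
                c[j] = coeff
    else:
        for rid, coeff in objective.items():
            if rid not in reaction_ids:
                raise KeyError(f"objective references unknown reaction {rid!r}")
            c[reaction_ids.index(rid)] = coeff

    return StoichModel(
        stoich_matrix=n,
        reaction_ids=reaction_ids,
        internal_metabolite_ids=internal,
        lower=lower,
        upper=upper,
        objective=c,
    )


def solve_fba(stoich: StoichModel) -> FluxSolution:
    """Maximize the objective subject to N·v = 0 and the flux bounds.

    Infeasible or unbounded problems are reported through ``status``, never
    raised.
    """
    res = linprog(
        -stoich.objective,  # linprog minimizes
        A_eq=stoich.stoich_matrix if len(stoich.internal_metabolite_ids) else None,
        b_eq=np.zeros(len(stoich.internal_metabolite_ids))
        if len(stoich.internal_metabolite_ids)
        else None,
        bounds=list(zip(stoich.lower, stoich.upper)),
        method="highs",
    )
    if res.status == 2:
        status = "infeasible"
    elif res.status == 3:
        status = "unbounded"
    elif res.success:
        status = "optimal"
    else:  # pragma: no cover - numerical trouble
        status = f"failed: {res.message}"
    fluxes = {
        rid: (float(res.x[j]) if res.x is not None else float("nan"))
        for j, rid in enumerate(stoich.reaction_ids)
    }
    value = -float(res.fun) if res.fun is not None else float("nan")
    return FluxSolution(fluxes=fluxes, objective_value=value, status=status)


def gapfill_parameters(
    model: PathwayModel,
    flux: FluxSolution,
    km_default: float = 10.0,
    mode: str | Mapping[str, str] = "MM1",
) -> PathwayModel:
    """Give every ``needs_fba`` reaction a kinetic law matching its predicted flux.

    With ``mode='MM1'`` (default) the law is single-substrate Michaelis-Menten
    on the reaction's first consumed metabolite, with Km = ``km_default`` and
    Vmax back-solved as ``flux * (Km + S0) / S0`` so the rate at the initial
    concentrations reproduces the predicted flux; the step then stays
    responsive to substrate depletion.  ``mode='constant_flux'`` pins the rate
    instead.  A per-reaction {reaction_id: mode} map mixes the two.  Zero
    predicted flux always becomes a zero constant flux.

    Raises ``ValueError`` (collecting all offending reactions) when a nonzero
    flux is predicted for a reaction whose substrate starts at zero, which no
    substrate-dependent law can satisfy.
    """
    if not flux.ok:
        raise ValueError(f"cannot gap-fill from a non-optimal flux solution ({flux.status})")
    out = model.copy()
    problems: list[str] = []
    for rxn in out.reactions:
        if not rxn.needs_fba:
            continue
        if rxn.id not in flux.fluxes:
            problems.append(f"reaction {rxn.id}: no predicted flux")
            continue
        v = flux.fluxes[rxn.id]
        rxn_mode = mode if isinstance(mode, str) else mode.get(rxn.id, "MM1")
        if abs(v) < 1e-15 or rxn_mode == "constant_flux":
            rxn.law = KineticLaw(law_type="constant_flux", k=max(v, 0.0))
            rxn.needs_fba = False
            continue
        substrates = [m for m, coeff in rxn.stoichiometry.items() if coeff < 0]
        if not substrates:
            rxn.law = KineticLaw(law_type="constant_flux", k=v)
            rxn.needs_fba = False
            continue
        s_id = substrates[0]
        s0 = out.metabolite(s_id).initial_concentration
        if s0 <= 0:
            problems.append(
                f"reaction {rxn.id}: predicted flux {v:.3g} but substrate {s_id} "
                "starts at zero concentration"
            )
            continue
        vmax = v * (km_default + s0) / s0
        rxn.law = KineticLaw(
            law_type="MM1", substrate_ids=(s_id,), vmax=vmax, km=km_default
        )
        rxn.needs_fba = False
    if problems:
        raise ValueError("gap-filling unsatisfiable:\n  " + "\n  ".join(problems))
    return out
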