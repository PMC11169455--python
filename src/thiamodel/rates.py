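"""Kinetic rate laws and their evaluation over a pathway model.

All rates are instantaneous reaction velocities in nmol/L/s.  Substrate
concentrations marginally below zero (stiff-solver excursions) are clamped to
zero before evaluation; excursions beyond ``NEGATIVE_STATE_TOL`` abort.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .model import PathwayModel

__all__ = [
    "NEGATIVE_STATE_TOL",
    "IntegrationStateError",
    "rate_mm1",
    "rate_mm2",
    "rate_mm2_ping_pong",
    "rate_mass_action",
    "evaluate_rates",
    "RateEvaluator",
]

#: states below -1e-9 nmol/L are treated as integration failures;
#: in (-1e-9, 0) they are clamped to 0.
NEGATIVE_STATE_TOL = 1e-9


class IntegrationStateError(ValueError):
    """Non-finite or significantly negative concentration reached the rate laws."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


def rate_mm1(vmax: float, km: float, s: float) -> float:
    """Irreversible single-substrate Michaelis-Menten rate Vmax*S/(Km+S).

    Zero at ``s == 0``; approaches ``vmax`` as ``s`` saturates; strictly
    increasing in ``s``.
    """
    _require(vmax > 0, f"vmax must be > 0, got {vmax}")
    _require(km > 0, f"km must be > 0, got {km}")
    _require(s >= 0, f"substrate concentration must be >= 0, got {s}")
    return vmax * s / (km + s)


def rate_mm2(vmax: float, km_a: float, km_b: float, a: float, b: float) -> float:
    """Two-substrate random-order (ternary complex) rate.

    v = Vmax*A*B / ((KmA+A)*(KmB+B)): zero when either substrate is absent,
    approaches Vmax when both saturate, monotone non-decreasing in each.
    """
    _require(vmax > 0, f"vmax must be > 0, got {vmax}")
    _require(km_a > 0 and km_b > 0, f"km_a/km_b must be > 0, got {km_a}, {km_b}")
    _require(a >= 0 and b >= 0, f"substrate concentrations must be >= 0, got {a}, {b}")
    return vmax * a * b / ((km_a + a) * (km_b + b))


def rate_mm2_ping_pong(vmax: float, km_a: float, km_b: float, a: float, b: float) -> float:
    """Two-substrate ping-pong (substituted-enzyme) rate.

    v = Vmax*A*B / (KmB*A + KmA*B + A*B).  Selectable per reaction via the
    ``MM2_ping_pong`` law type when the ternary-complex default is not wanted.
    """
    _require(vmax > 0, f"vmax must be > 0, got {vmax}")
    _require(km_a > 0 and km_b > 0, f"km_a/km_b must be > 0, got {km_a}, {km_b}")
    _require(a >= 0 and b >= 0, f"substrate concentrations must be >= 0, got {a}, {b}")
    denom = km_b * a + km_a * b + a * b
    if denom == 0.0:
        return 0.0
    return vmax * a * b / denom


def rate_mass_action(k: float, substrates: Sequence[float]) -> float:
    """Mass-action rate k * prod(substrates); first-order for transport steps."""
    _require(k >= 0, f"k must be >= 0, got {k}")
    out = k
    for s in substrates:
        _require(s >= 0, f"substrate concentration must be >= 0, got {s}")
        out *= s
    return out


class RateEvaluator:
    """Pre-indexed rate evaluation for one model (substrate lookups resolved once)."""

    def __init__(self, model: PathwayModel):
        self.model = model
        self._plan = []
        for rxn in model.reactions:
            law = rxn.law
            if law is None:
                raise ValueError(
                    f"reaction {rxn.id} has no kinetic law (unresolved needs_fba); "
                    "gap-fill before simulating"
                )
            idx = tuple(model.metabolite_index(s) for s in law.substrate_ids)
            self._plan.append((rxn.id, law, idx))

    def __call__(self, concentrations: np.ndarray) -> np.ndarray:
        c = np.asarray(concentrations, dtype=float)
        if not np.all(np.isfinite(c)):
            bad = self.model.metabolite_ids[int(np.argmax(~np.isfinite(c)))]
            raise IntegrationStateError(f"non-finite concentration for {bad}")
        if c.min(initial=0.0) < -NEGATIVE_STATE_TOL:
            bad = self.model.metabolite_ids[int(np.argmin(c))]
            raise IntegrationStateError(
                f"concentration of {bad} fell below -{NEGATIVE_STATE_TOL} nmol/L "
                f"({c.min():.3e})"
            )
        c = np.maximum(c, 0.0)
        v = np.empty(len(self._plan))
        for j, (_rid, law, idx) in enumerate(self._plan):
            t = law.law_type
            # a knockout (Vmax scaled to 0) silences the reaction outright
            if law.vmax == 0.0 and t in ("MM1", "MM2", "MM2_ping_pong"):
                v[j] = 0.0
            elif t == "MM1":
                v[j] = rate_mm1(law.vmax, law.km, c[idx[0]])
            elif t == "MM2":
                v[j] = rate_mm2(law.vmax, law.km_a, law.km_b, c[idx[0]], c[idx[1]])
            elif t == "MM2_ping_pong":
                v[j] = rate_mm2_ping_pong(
                    law.vmax, law.km_a, law.km_b, c[idx[0]], c[idx[1]]
                )
            elif t == "mass_action":
                v[j] = rate_mass_action(law.k, c[list(idx)])
            elif t == "constant_flux":
                v[j] = law.k
            else:  # pragma: no cover - guarded by validate()
                raise ValueError(f"unknown law_type {t!r}")
        return v


def evaluate_rates(model: PathwayModel, concentrations: Sequence[float]) -> np.ndarray:
    """Per-reaction rate vector at the given state, ordered as ``model.reactions``."""
    return RateEvaluator(model)(np.asarray(concentrations, dtype=float))
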