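"""Synthetic fixtures: toy networks with analytic behaviour, a reduced
thiamin network, a full-size synthetic rice B1 network, and growth curves.

Everything here is a pure function of its arguments and seed, and every
generated model passes :func:`thiamodel.model.validate` with zero
violations.  The networks serve two distinct purposes:

* :func:`make_influx_mm1_fixture` and :func:`make_mm_chain` have closed-form
  steady states (S* = k·Km/(Vmax−k) at every node) and anchor the numerical
  test surface.
* :func:`make_thiamin_toy` is a reduced thiamin-biosynthesis network — the
  THIC (pyrimidine) and THI1 (thiazole) branches converging through the
  bifunctional TH1 kinase/synthase into TMP, plus a TMP-consuming drain.  Its
  rate constants are fixed so that the canonical overexpression phenotypes
  hold: single-branch overexpression is limited by the co-substrate, TH1-only
  overexpression produces a transient TMP peak that relaxes back, and the
  triple overexpression gives the highest sustained TMP.
* :func:`make_rice_network` is a full-size synthetic transcription of the
  rice vitamin-B1 network (34 reactions, 29 metabolites across plastid,
  cytosol, mitochondrion and external compartments) with plausible but
  invented parameters; five transport steps are left without kinetic
  constants (``needs_fba``) to exercise stoichiometric gap-filling.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .model import KineticLaw, Metabolite, PathwayModel, Reaction
from .fba import build_stoich, gapfill_parameters, solve_fba

__all__ = [
    "make_influx_mm1_fixture",
    "make_mm_chain",
    "mm_chain_steady_states",
    "make_thiamin_toy",
    "make_rice_network",
    "gapfill_rice_network",
    "make_growth_curves",
]


def _mm1(vmax: float, km: float, substrate: str) -> KineticLaw:
    return KineticLaw("MM1", substrate_ids=(substrate,), vmax=vmax, km=km)


def _mm2(vmax: float, km_a: float, km_b: float, a: str, b: str) -> KineticLaw:
    return KineticLaw("MM2", substrate_ids=(a, b), vmax=vmax, km_a=km_a, km_b=km_b)


def _ma(k: float, *substrates: str) -> KineticLaw:
    return KineticLaw("mass_action", substrate_ids=substrates, k=k)


# ---------------------------------------------------------------------------
# analytic fixtures

def make_influx_mm1_fixture(
    k: float = 2.0, vmax: float = 10.0, km: float = 5.0, s0: float = 0.0
) -> PathwayModel:
    """Constant influx k into S consumed by one MM1 step into P.

    The unique steady state of S is k·Km/(Vmax−k) (influx must stay below
    Vmax); with the defaults that is 2·5/8 = 1.25 nmol/L.
    """
    if not k < vmax:
        raise ValueError("influx must be strictly below Vmax for a steady state")
    mets = [
        Metabolite("S", "substrate", "cytosol", s0),
        Metabolite("P", "product", "cytosol", 0.0),
    ]
    rxns = [
        Reaction("influx", "feed", {"S": 1.0}, KineticLaw("constant_flux", k=k)),
        Reaction("consume", "E1", {"S": -1.0, "P": 1.0}, _mm1(vmax, km, "S")),
    ]
    return PathwayModel(mets, rxns, metadata={"id": "influx_mm1"})


def make_mm_chain(n_reactions: int, seed: int = 0) -> PathwayModel:
    """Linear chain: constant influx into S1, then n MM1 steps S1→…→Sn→P.

    Vmax and Km are drawn uniformly from [1, 10] nmol/L(/s); the influx is
    set to half the smallest Vmax so an analytic steady state exists at every
    node (see :func:`mm_chain_steady_states`).  Same seed ⇒ identical model.
    """
    if n_reactions < 1:
        raise ValueError("need at least one reaction")
    rng = np.random.default_rng(seed)
    vmaxes = rng.uniform(1.0, 10.0, n_reactions)
    kms = rng.uniform(1.0, 10.0, n_reactions)
    influx = 0.5 * float(vmaxes.min())

    species = [f"S{i + 1}" for i in range(n_reactions)] + ["P"]
    mets = [Metabolite(s, compartment="cytosol") for s in species]
    rxns = [
        Reaction("influx", "feed", {"S1": 1.0}, KineticLaw("constant_flux", k=influx))
    ]
    for i in range(n_reactions):
        rxns.append(
            Reaction(
                f"step{i + 1}",
                f"E{i + 1}",
                {species[i]: -1.0, species[i + 1]: 1.0},
                _mm1(float(vmaxes[i]), float(kms[i]), species[i]),
            )
        )
    return PathwayModel(
        mets, rxns, metadata={"id": f"mm_chain_{n_reactions}", "seed": seed}
    )


def mm_chain_steady_states(model: PathwayModel) -> dict[str, float]:
    """Closed-form node steady states of a chain built by :func:`make_mm_chain`.

    At steady state every step carries the influx k, so each intermediate
    sits at S* = k·Km/(Vmax−k).  The terminal product accumulates and has no
    steady state (omitted).
    """
    influx = model.reaction("influx").law.k
    out: dict[str, float] = {}
    for rxn in model.reactions:
        if rxn.law.law_type != "MM1":
            continue
        s = rxn.law.substrate_ids[0]
        out[s] = influx * rxn.law.km / (rxn.law.vmax - influx)
    return out


# ---------------------------------------------------------------------------
# reduced thiamin network

# calibration constants (fixed, not fitted): the thiazole branch carries less
# flux than the pyrimidine branch so THI1 is the first bottleneck, the TMP
# drain is slow enough that a TH1 burst overshoots, and the initial precursor
# pools give TH1 overexpression something to condense.
_TOY_FEED = 1000.0         # clamped precursor reservoirs, nmol/L
_TOY_THIC_VMAX = 0.05      # pyrimidine-branch capacity, nmol/L/s
_TOY_THI1_VMAX = 0.02      # thiazole-branch capacity (limiting)
_TOY_BRANCH_KM = 500.0
_TOY_TH1_VMAX = 0.5        # both TH1 activities
_TOY_TH1_KM = 10.0
_TOY_DRAIN_VMAX = 0.2
_TOY_DRAIN_KM = 20.0
_TOY_POOLS = {"HMP_P": 10.0, "HMP_PP": 5.0, "HET_P": 10.0, "TMP": 0.5}


def make_thiamin_toy(seed: int = 0) -> PathwayModel:
    """Reduced thiamin-biosynthesis network (deterministic; seed kept for API
    uniformity).

    Two plastid branches — THIC: AIR + SAM → HMP-P and THI1: NAD (+ glycine)
    → HET-P — converge through the bifunctional TH1: a kinase step HMP-P →
    HMP-PP and a two-substrate condensation HMP-PP + HET-P → TMP, both
    sharing the enzyme label ``TH1``.  A saturable drain consumes TMP
    (downstream phosphatase/usage, lumped).  Branch feeds are clamped.
    """
    mets = [
        Metabolite("AIR", "5-aminoimidazole ribonucleotide", "plastid", _TOY_FEED, True),
        Metabolite("SAM", "S-adenosylmethionine", "plastid", _TOY_FEED, True),
        Metabolite("NAD", "nicotinamide adenine dinucleotide", "plastid", _TOY_FEED, True),
        Metabolite("GLY", "glycine", "plastid", _TOY_FEED, True),
        Metabolite("HMP_P", "hydroxymethylpyrimidine phosphate", "plastid", _TOY_POOLS["HMP_P"]),
        Metabolite("HMP_PP", "hydroxymethylpyrimidine diphosphate", "plastid", _TOY_POOLS["HMP_PP"]),
        Metabolite("HET_P", "hydroxyethylthiazole phosphate", "plastid", _TOY_POOLS["HET_P"]),
        Metabolite("TMP", "thiamin monophosphate", "plastid", _TOY_POOLS["TMP"]),
    ]
    rxns = [
        Reaction(
            "THIC",
            "THIC",
            {"AIR": -1.0, "SAM": -1.0, "HMP_P": 1.0},
            _mm2(_TOY_THIC_VMAX, _TOY_BRANCH_KM, _TOY_BRANCH_KM, "AIR", "SAM"),
        ),
        Reaction(
            "THI1",
            "THI1",
            {"NAD": -1.0, "GLY": -1.0, "HET_P": 1.0},
            _mm1(_TOY_THI1_VMAX, _TOY_BRANCH_KM, "NAD"),
        ),
        Reaction(
            "TH1_kinase",
            "TH1",
            {"HMP_P": -1.0, "HMP_PP": 1.0},
            _mm1(_TOY_TH1_VMAX, _TOY_TH1_KM, "HMP_P"),
        ),
        Reaction(
            "TH1_synthase",
            "TH1",
            {"HMP_PP": -1.0, "HET_P": -1.0, "TMP": 1.0},
            _mm2(_TOY_TH1_VMAX, _TOY_TH1_KM, _TOY_TH1_KM, "HMP_PP", "HET_P"),
        ),
        Reaction(
            "TMP_drain",
            "TMP_drain",
            {"TMP": -1.0},
            _mm1(_TOY_DRAIN_VMAX, _TOY_DRAIN_KM, "TMP"),
        ),
    ]
    return PathwayModel(mets, rxns, metadata={"id": "thiamin_toy", "seed": seed})


# ---------------------------------------------------------------------------
# full-size synthetic rice network

def make_rice_network() -> PathwayModel:
    """Synthetic full-size transcription of the rice vitamin-B1 network.

    34 reactions over 29 metabolites in four compartments: de novo synthesis
    in the plastid (THIC, THI1, TH1 kinase + synthase), dephosphorylation to
    thiamin by TH2 in cytosol and mitochondrion, activation to TDP by TDPK,
    thiazole salvage via THiM, and inter-compartmental/external transport.
    The topology follows the published pathway structure; every numeric
    parameter is a plausible invented value (this is a synthetic stand-in for
    the original model's unpublished parameter tables, and its simulated
    numbers are not claimed to reproduce the original's).  Five transport
    steps carry no kinetic constants and are flagged ``needs_fba`` for
    stoichiometric gap-filling (:func:`gapfill_rice_network`).
    """
    M = Metabolite
    mets = [
        # plastid (de novo synthesis); pool sizes start near their unperturbed
        # steady states so the default 10 ks horizon covers the relaxation
        M("AIR_p", "5-aminoimidazole ribonucleotide", "plastid", 10.0),
        M("SAM_p", "S-adenosylmethionine", "plastid", 20.0),
        M("SAH_p", "S-adenosylhomocysteine", "plastid", 10.0),
        M("NAD_p", "NAD", "plastid", 40.0),
        M("GLY_p", "glycine", "plastid", 100.0),
        M("ATP_p", "ATP", "plastid", 1.0e6),
        M("ADP_p", "ADP", "plastid", 1.0e4),
        M("HMP_P_p", "HMP-P", "plastid", 10.0),
        M("HMP_PP_p", "HMP-PP", "plastid", 5.0),
        M("HET_P_p", "HET-P", "plastid", 10.0),
        M("TMP_p", "thiamin monophosphate", "plastid", 1.0),
        # cytosol
        M("TMP_c", "thiamin monophosphate", "cytosol", 1.0),
        M("THI_c", "thiamin", "cytosol", 5.0),
        M("TDP_c", "thiamin diphosphate", "cytosol", 50.0),
        M("ATP_c", "ATP", "cytosol", 1.0e6),
        M("ADP_c", "ADP", "cytosol", 1.0e4),
        M("HET_c", "hydroxyethylthiazole", "cytosol", 10.0),
        M("HET_P_c", "HET-P", "cytosol", 2.0),
        M("PI_c", "phosphate", "cytosol", 10.0),
        # mitochondrion
        M("TMP_m", "thiamin monophosphate", "mitochondrion", 0.5),
        M("THI_m", "thiamin", "mitochondrion", 2.0),
        M("TDP_m", "thiamin diphosphate", "mitochondrion", 100.0),
        M("PI_m", "phosphate", "mitochondrion", 10.0),
        # external reservoirs (clamped)
        M("AIR_ext", "AIR feed", "external", 500.0, True),
        M("SAM_ext", "SAM feed", "external", 2000.0, True),
        M("GLY_ext", "glycine feed", "external", 5.0e4, True),
        M("NAD_ext", "NAD feed", "external", 1.0e4, True),
        M("HET_ext", "thiazole salvage feed", "external", 50.0, True),
        M("TDP_ext", "TDP sink", "external", 0.0, True),
    ]

    R = Reaction
    gap = dict(law=None, needs_fba=True)
    rxns = [
        # uptake and transport
        R("t_air", "transport", {"AIR_ext": -1.0, "AIR_p": 1.0}, _ma(1e-4, "AIR_ext")),
        R("t_sam", "transport", {"SAM_ext": -1.0, "SAM_p": 1.0}, _ma(5e-5, "SAM_ext")),
        R("t_gly", "transport", {"GLY_ext": -1.0, "GLY_p": 1.0}, _ma(1e-5, "GLY_ext")),
        R("t_nad", "transport", {"NAD_ext": -1.0, "NAD_p": 1.0}, _ma(2e-5, "NAD_ext")),
        R("t_het", "transport", {"HET_ext": -1.0, "HET_c": 1.0}, **gap),
        R("t_tmp_pc", "transport", {"TMP_p": -1.0, "TMP_c": 1.0}, _ma(0.01, "TMP_p")),
        R("t_tmp_cm", "transport", {"TMP_c": -1.0, "TMP_m": 1.0}, **gap),
        R("t_thi_mc", "transport", {"THI_m": -1.0, "THI_c": 1.0}, _ma(5e-3, "THI_m")),
        R("t_tdp_cm", "TDP_carrier", {"TDP_c": -1.0, "TDP_m": 1.0}, _ma(5e-3, "TDP_c")),
        R("t_hetp_cp", "transport", {"HET_P_c": -1.0, "HET_P_p": 1.0}, **gap),
        # core biosynthesis
        R(
            "THIC",
            "THIC",
            {"AIR_p": -1.0, "SAM_p": -1.0, "HMP_P_p": 1.0, "SAH_p": 1.0},
            _mm2(0.03, 10.0, 20.0, "AIR_p", "SAM_p"),
        ),
        R(
            "THI1",
            "THI1",
            {"NAD_p": -1.0, "GLY_p": -1.0, "HET_P_p": 1.0},
            _mm1(0.01, 60.0, "NAD_p"),
        ),
        R(
            "TH1_kinase",
            "TH1",
            {"HMP_P_p": -1.0, "ATP_p": -1.0, "HMP_PP_p": 1.0, "ADP_p": 1.0},
            _mm2(0.4, 8.0, 2.0e5, "HMP_P_p", "ATP_p"),
        ),
        R(
            "TH1_synthase",
            "TH1",
            {"HMP_PP_p": -1.0, "HET_P_p": -1.0, "TMP_p": 1.0},
            _mm2(0.3, 10.0, 10.0, "HMP_PP_p", "HET_P_p"),
        ),
        R(
            "THiM",
            "THiM",
            {"HET_c": -1.0, "ATP_c": -1.0, "HET_P_c": 1.0, "ADP_c": 1.0},
            _mm2(0.02, 20.0, 2.0e5, "HET_c", "ATP_c"),
        ),
        R("TH2_c", "TH2", {"TMP_c": -1.0, "THI_c": 1.0, "PI_c": 1.0}, _mm1(0.05, 5.0, "TMP_c")),
        R("TH2_m", "TH2", {"TMP_m": -1.0, "THI_m": 1.0, "PI_m": 1.0}, _mm1(0.02, 5.0, "TMP_m")),
        R(
            "TDPK",
            "TDPK",
            {"THI_c": -1.0, "ATP_c": -1.0, "TDP_c": 1.0, "ADP_c": 1.0},
            _mm1(0.03, 20.0, "THI_c"),
        ),
        # housekeeping, salvage, drains; first-order usage on every fed pool
        # keeps all relaxation times within the 10 ks simulation horizon
        R("atp_regen_p", "ATP_regen", {"ADP_p": -1.0, "ATP_p": 1.0}, _ma(1e-3, "ADP_p")),
        R("atp_regen_c", "ATP_regen", {"ADP_c": -1.0, "ATP_c": 1.0}, _ma(1e-3, "ADP_c")),
        R("sah_drain", "methyl_cycle", {"SAH_p": -1.0}, _ma(0.01, "SAH_p")),
        R("tdp_export_c", "transport", {"TDP_c": -1.0, "TDP_ext": 1.0}, _ma(5e-3, "TDP_c")),
        R("tdp_use_m", "cofactor_use", {"TDP_m": -1.0}, _ma(1e-3, "TDP_m")),
        R("thi_drain_c", "degradation", {"THI_c": -1.0}, _ma(1e-3, "THI_c")),
        R("sam_use_p", "methylation_demand", {"SAM_p": -1.0}, _ma(5e-3, "SAM_p")),
        R("t_tmp_cp", "transport", {"TMP_c": -1.0, "TMP_p": 1.0}, **gap),
        R("t_thi_cm", "transport", {"THI_c": -1.0, "THI_m": 1.0}, _ma(1e-3, "THI_c")),
        R("TDPase_c", "TDPase", {"TDP_c": -1.0, "TMP_c": 1.0}, _mm1(5e-3, 100.0, "TDP_c")),
        R("pi_export_c", "transport", {"PI_c": -1.0}, _ma(1e-3, "PI_c")),
        R("pi_export_m", "transport", {"PI_m": -1.0}, _ma(1e-3, "PI_m")),
        R("t_tdp_mc", "transport", {"TDP_m": -1.0, "TDP_c": 1.0}, **gap),
        R("nad_use_p", "NAD_use", {"NAD_p": -1.0}, _ma(5e-3, "NAD_p")),
        R("gly_use_p", "GLY_use", {"GLY_p": -1.0}, _ma(5e-3, "GLY_p")),
        R("air_use_p", "purine_branch", {"AIR_p": -1.0}, _ma(5e-3, "AIR_p")),
    ]
    return PathwayModel(mets, rxns, metadata={"id": "rice_b1_synthetic"})


#: transport caps (nmol/L/s) used when gap-filling the synthetic rice network
RICE_GAP_FLUX_CAP = 0.05


def rice_table_paths() -> tuple:
    """Paths of the packaged synthetic rice-network tables (reactions, metabolites).

    The shipped TSVs are the table-form of :func:`make_rice_network` and are
    the package's declarative model-exchange example; load them with
    :func:`thiamodel.model.load_model`.
    """
    from importlib.resources import files

    base = files("thiamodel") / "data" / "rice_b1_synthetic"
    return base / "reactions.tsv", base / "metabolites.tsv"


def gapfill_rice_network(
    model: PathwayModel | None = None, km_default: float = 10.0
) -> PathwayModel:
    """Gap-fill the synthetic rice network's five unparameterized transports.

    Runs flux balance with the documented defaults — maximize gross TMP_c
    production, fluxes in [0, 1] nmol/L/s with the unparameterized transports
    capped at :data:`RICE_GAP_FLUX_CAP` — then back-solves MM1 laws so each
    gap reaction reproduces its predicted flux at the initial concentrations.
    """
    model = model or make_rice_network()
    bounds = {
        r.id: (0.0, RICE_GAP_FLUX_CAP) for r in model.reactions if r.needs_fba
    }
    stoich = build_stoich(model, bounds=bounds, objective="TMP_c")
    flux = solve_fba(stoich)
    if not flux.ok:
        raise RuntimeError(f"rice-network FBA did not reach an optimum: {flux.status}")
    return gapfill_parameters(model, flux, km_default=km_default)


# ---------------------------------------------------------------------------
# growth curves

def make_growth_curves(
    groups: Mapping[str, tuple[float, int]],
    noise_sigma: float = 0.01,
    seed: int = 0,
    duration_h: float = 72.0,
    interval_h: float = 0.5,
    carrying_capacity: float = 1.5,
    od_start: float = 0.05,
) -> pd.DataFrame:
    """Tidy synthetic OD600 table: logistic growth plus Gaussian noise.

    ``groups`` maps a label to (intrinsic rate per hour, replicate count).
    Defaults mirror a plate-reader run: start OD 0.05, a reading every 30 min
    for 3 days.  OD(t) = K / (1 + ((K−x0)/x0)·e^{−rt}) + N(0, σ), floored at
    0.  Same seed ⇒ byte-identical table.
    """
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration_h + interval_h / 2, interval_h)
    rows = []
    for label in groups:
        rate, n_rep = groups[label]
        if rate < 0:
            raise ValueError(f"group {label!r}: rate must be >= 0")
        for rep in range(1, n_rep + 1):
            if rate == 0:
                od = np.full_like(times, od_start)
            else:
                od = carrying_capacity / (
                    1.0
                    + ((carrying_capacity - od_start) / od_start)
                    * np.exp(-rate * times)
                )
            od = od + rng.normal(0.0, noise_sigma, size=times.shape)
            od = np.maximum(od, 0.0)
            rows.append(
                pd.DataFrame(
                    {
                        "time_h": times,
                        "od600": od,
                        "label": label,
                        "replicate": rep,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)
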