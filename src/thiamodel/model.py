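"""Domain types for compartmental kinetic pathway models and their table I/O.

A :class:`PathwayModel` is a network of :class:`Metabolite` species and
:class:`Reaction` steps.  Each reaction carries a :class:`KineticLaw`
(Michaelis-Menten, two-substrate Michaelis-Menten, mass action, or a constant
flux) or is flagged ``needs_fba`` when no kinetic constants are known and the
rate must be gap-filled from a stoichiometric flux prediction
(:mod:`thiamodel.fba`).

Models are exchanged as two plain tables (metabolites, reactions), UTF-8,
comma- or tab-delimited (autodetected).  Stoichiometry is encoded per row as a
token list such as ``-1:HMP_PP,-1:HET_P,+1:TMP`` (negative = consumed).  All
concentrations are expressed in nmol/L and rates in nmol/L/s; compartments are
labels only — inter-compartmental transport is an ordinary reaction.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "COMPARTMENTS",
    "LAW_TYPES",
    "KineticLaw",
    "Metabolite",
    "Reaction",
    "PathwayModel",
    "ValidationReport",
    "ModelLoadError",
    "load_model",
    "write_tables",
    "validate",
]

COMPARTMENTS = ("plastid", "cytosol", "mitochondrion", "external")

#: law_type -> number of substrates the law reads (None = one or more)
LAW_TYPES: dict[str, int | None] = {
    "MM1": 1,
    "MM2": 2,
    "MM2_ping_pong": 2,
    "mass_action": None,
    "constant_flux": 0,
}


class ModelLoadError(ValueError):
    """Raised for schema violations, dangling references or duplicate ids."""


@dataclass
class Metabolite:
    """A chemical species with a compartment label and starting concentration.

    ``initial_concentration`` is an amount concentration in nmol/L and must be
    non-negative.  ``boundary`` marks clamped species whose concentration is
    held at its initial value during simulation (external reservoirs).
    """

    id: str
    name: str = ""
    compartment: str = "cytosol"
    initial_concentration: float = 0.0
    boundary: bool = False


@dataclass
class KineticLaw:
    """Rate-law descriptor evaluated against current concentrations.

    Supported forms (v in nmol/L/s, concentrations in nmol/L):

    ``MM1``
        v = Vmax * S / (Km + S)
    ``MM2``
        random-order ternary-complex double hyperbola,
        v = Vmax * A * B / ((KmA + A) * (KmB + B))
    ``MM2_ping_pong``
        v = Vmax * A * B / (KmB * A + KmA * B + A * B)
    ``mass_action``
        v = k * prod(substrates)
    ``constant_flux``
        v = k, independent of state
    """

    law_type: str
    substrate_ids: tuple[str, ...] = ()
    vmax: float | None = None
    km: float | None = None
    km_a: float | None = None
    km_b: float | None = None
    k: float | None = None

    def parameter_items(self) -> list[tuple[str, float]]:
        """(name, value) pairs for the parameters this law actually uses."""
        names = {
            "MM1": ("vmax", "km"),
            "MM2": ("vmax", "km_a", "km_b"),
            "MM2_ping_pong": ("vmax", "km_a", "km_b"),
            "mass_action": ("k",),
            "constant_flux": ("k",),
        }.get(self.law_type, ())
        return [(n, getattr(self, n)) for n in names if getattr(self, n) is not None]


@dataclass
class Reaction:
    """A reaction step: stoichiometry plus the kinetic law that drives it.

    ``stoichiometry`` maps metabolite id to a signed coefficient (negative =
    consumed).  ``enzyme_label`` groups reactions catalysed by the same gene
    product — the bifunctional TH1 kinase and synthase steps share the label
    ``TH1`` so an abundance change scales both (see
    :mod:`thiamodel.perturb`).
    """

    id: str
    enzyme_label: str
    stoichiometry: dict[str, float]
    law: KineticLaw | None
    reversible: bool = False
    needs_fba: bool = False


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __iter__(self):
        return iter(self.violations)

    def __len__(self):
        return len(self.violations)


@dataclass
class PathwayModel:
    """The full network: metabolite roster + reactions + clamped species."""

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {m.id: i for i, m in enumerate(self.metabolites)}

    # -- queries ---------------------------------------------------------
    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def boundary_ids(self) -> list[str]:
        return [m.id for m in self.metabolites if m.boundary]

    @property
    def enzyme_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.reactions:
            seen.setdefault(r.enzyme_label)
        return list(seen)

    def metabolite_index(self, met_id: str) -> int:
        return self._index[met_id]

    def metabolite(self, met_id: str) -> Metabolite:
        return self.metabolites[self._index[met_id]]

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    def initial_state(self) -> list[float]:
        return [m.initial_concentration for m in self.metabolites]

    def copy(self) -> "PathwayModel":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# validation

def _check_law(rxn: Reaction, add) -> None:
    law = rxn.law
    if law is None:
        if not rxn.needs_fba:
            add(f"reaction {rxn.id}: no kinetic law and not flagged needs_fba")
        return
    if rxn.needs_fba:
        add(f"reaction {rxn.id}: flagged needs_fba but already carries a law")
    if law.law_type not in LAW_TYPES:
        add(f"reaction {rxn.id}: unknown law_type {law.law_type!r}")
        return
    arity = LAW_TYPES[law.law_type]
    n_sub = len(law.substrate_ids)
    if arity is None:
        if n_sub < 1:
            add(f"reaction {rxn.id}: mass_action needs >= 1 substrate")
    elif n_sub != arity:
        add(
            f"reaction {rxn.id}: {law.law_type} expects {arity} substrate(s), "
            f"got {n_sub}"
        )
    for name, value in law.parameter_items():
        if name == "k":
            if value < 0:
                add(f"reaction {rxn.id}: k must be >= 0, got {value}")
        elif value <= 0:
            add(f"reaction {rxn.id}: {name} must be > 0, got {value}")
    required = {
        "MM1": ("vmax", "km"),
        "MM2": ("vmax", "km_a", "km_b"),
        "MM2_ping_pong": ("vmax", "km_a", "km_b"),
        "mass_action": ("k",),
        "constant_flux": ("k",),
    }[law.law_type]
    for name in required:
        if getattr(law, name) is None:
            add(f"reaction {rxn.id}: {law.law_type} requires parameter {name}")


def validate(model: PathwayModel) -> ValidationReport:
    """Structural validation.  Returns a report; never raises, never mutates.

    Checks id uniqueness, compartment membership, non-negative initial
    concentrations, referential integrity of stoichiometries and law
    substrates, law arity, parameter positivity, and that law substrates are
    consumed (negative coefficient) by their reaction.
    """
    report = ValidationReport()
    add = report.violations.append

    seen_m: set[str] = set()
    for m in model.metabolites:
        if m.id in seen_m:
            add(f"duplicate metabolite id {m.id!r}")
        seen_m.add(m.id)
        if m.compartment not in COMPARTMENTS:
            add(
                f"metabolite {m.id}: compartment {m.compartment!r} not in "
                f"{COMPARTMENTS}"
            )
        if not (m.initial_concentration >= 0):
            add(
                f"metabolite {m.id}: initial concentration must be >= 0, got "
                f"{m.initial_concentration}"
            )

    seen_r: set[str] = set()
    for rxn in model.reactions:
        if rxn.id in seen_r:
            add(f"duplicate reaction id {rxn.id!r}")
        seen_r.add(rxn.id)
        if not rxn.stoichiometry:
            add(f"reaction {rxn.id}: empty stoichiometry")
        for met_id in rxn.stoichiometry:
            if met_id not in seen_m and met_id not in model._index:
                add(f"reaction {rxn.id}: references undeclared metabolite {met_id!r}")
        _check_law(rxn, add)
        if rxn.law is not None:
            for s in rxn.law.substrate_ids:
                if s not in model._index:
                    add(f"reaction {rxn.id}: law substrate {s!r} not declared")
                elif rxn.stoichiometry.get(s, 0) >= 0:
                    add(
                        f"reaction {rxn.id}: law substrate {s} must appear with a "
                        "negative stoichiometric coefficient"
                    )
    return report


# ---------------------------------------------------------------------------
# table I/O

METABOLITE_COLUMNS = ["id", "name", "compartment", "initial_conc_nmol_per_L", "boundary"]
REACTION_COLUMNS = [
    "id",
    "enzyme",
    "stoichiometry",
    "law_type",
    "vmax",
    "km",
    "km_a",
    "km_b",
    "k",
    "substrates",
    "reversible",
    "needs_fba",
]


def _read_table(path: str | Path, required: Iterable[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ModelLoadError(f"table not found: {path}")
    # sep=None + python engine sniffs comma vs tab
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ModelLoadError(f"{path}: missing column(s) {missing}")
    if df.empty:
        raise ModelLoadError(f"{path}: table has no rows")
    return df


def _parse_float(cell: str, *, path, row: int, column: str) -> float | None:
    cell = cell.strip()
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError:
        raise ModelLoadError(
            f"{path} row {row}: column {column!r} is not numeric: {cell!r}"
        ) from None


def parse_stoichiometry(token_list: str, *, context: str = "") -> dict[str, float]:
    """Parse ``"-1:HMP_PP,-1:HET_P,+1:TMP"`` into a coefficient map.

    Coefficients may be integers, decimals, or rationals like ``1/2``.
    """
    stoich: dict[str, float] = {}
    for token in token_list.split(","):
        token = token.strip()
        if not token:
            continue
        try:
            coeff_s, met_id = token.split(":")
            coeff = float(Fraction(coeff_s.strip()))
        except (ValueError, ZeroDivisionError):
            raise ModelLoadError(f"{context}: bad stoichiometry token {token!r}") from None
        met_id = met_id.strip()
        if not met_id:
            raise ModelLoadError(f"{context}: bad stoichiometry token {token!r}")
        stoich[met_id] = stoich.get(met_id, 0.0) + coeff
    if not stoich:
        raise ModelLoadError(f"{context}: empty stoichiometry")
    return stoich


def format_stoichiometry(stoich: Mapping[str, float]) -> str:
    parts = []
    for met_id, coeff in stoich.items():
        if coeff == int(coeff):
            coeff_s = f"{int(coeff):+d}"
        else:
            coeff_s = f"{coeff:+g}"
        parts.append(f"{coeff_s}:{met_id}")
    return ",".join(parts)


def _truthy(cell: str) -> bool:
    return cell.strip() in {"1", "true", "True", "yes"}


def load_model(
    reaction_table: str | Path,
    metabolite_table: str | Path,
    metadata: dict | None = None,
) -> PathwayModel:
    """Load and validate a pathway model from its two declarative tables.

    Raises :class:`ModelLoadError` with the offending row number on schema
    violations, non-numeric parameters, duplicate ids or dangling metabolite
    references.  The returned model has passed :func:`validate` with zero
    violations; reactions lacking kinetic constants are flagged ``needs_fba``.
    """
    mdf = _read_table(metabolite_table, METABOLITE_COLUMNS)
    rdf = _read_table(reaction_table, REACTION_COLUMNS)

    metabolites = []
    for i, row in mdf.iterrows():
        conc = _parse_float(
            row["initial_conc_nmol_per_L"],
            path=metabolite_table,
            row=i + 2,
            column="initial_conc_nmol_per_L",
        )
        metabolites.append(
            Metabolite(
                id=row["id"].strip(),
                name=row["name"].strip(),
                compartment=row["compartment"].strip(),
                initial_concentration=0.0 if conc is None else conc,
                boundary=_truthy(row["boundary"]),
            )
        )

    reactions = []
    for i, row in rdf.iterrows():
        rownum = i + 2  # 1-based with header
        context = f"{reaction_table} row {rownum}"
        needs_fba = _truthy(row["needs_fba"])
        law_type = row["law_type"].strip()
        params = {
            c: _parse_float(row[c], path=reaction_table, row=rownum, column=c)
            for c in ("vmax", "km", "km_a", "km_b", "k")
        }
        substrates = tuple(
            s.strip() for s in row["substrates"].split(";") if s.strip()
        )
        if needs_fba:
            if law_type or any(v is not None for v in params.values()):
                raise ModelLoadError(
                    f"{context}: needs_fba reactions must leave law_type and all "
                    "kinetic parameter cells empty"
                )
            law = None
        else:
            if law_type not in LAW_TYPES:
                raise ModelLoadError(f"{context}: unknown law_type {law_type!r}")
            law = KineticLaw(law_type=law_type, substrate_ids=substrates, **params)
        reactions.append(
            Reaction(
                id=row["id"].strip(),
                enzyme_label=row["enzyme"].strip(),
                stoichiometry=parse_stoichiometry(row["stoichiometry"], context=context),
                law=law,
                reversible=_truthy(row["reversible"]),
                needs_fba=needs_fba,
            )
        )

    model = PathwayModel(metabolites, reactions, metadata=metadata or {})
    declared = {m.id for m in metabolites}
    for i, rxn in enumerate(model.reactions):
        for met_id in rxn.stoichiometry:
            if met_id not in declared:
                raise ModelLoadError(
                    f"{reaction_table} row {i + 2}: reaction {rxn.id} references "
                    f"undeclared metabolite {met_id!r}"
                )
    report = validate(model)
    if not report.ok:
        raise ModelLoadError(
            "model failed validation:\n  " + "\n  ".join(report.violations)
        )
    return model


def write_tables(model: PathwayModel, directory: str | Path, sep: str = "\t") -> tuple[Path, Path]:
    """Write the two declarative tables for *model* into *directory*.

    Returns ``(reactions_path, metabolites_path)``.  Round-trips through
    :func:`load_model` exactly (floats via repr).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    mrows = [
        {
            "id": m.id,
            "name": m.name,
            "compartment": m.compartment,
            "initial_conc_nmol_per_L": repr(m.initial_concentration),
            "boundary": int(m.boundary),
        }
        for m in model.metabolites
    ]
    rrows = []
    for r in model.reactions:
        law = r.law
        row = {c: "" for c in REACTION_COLUMNS}
        row.update(
            id=r.id,
            enzyme=r.enzyme_label,
            stoichiometry=format_stoichiometry(r.stoichiometry),
            reversible=int(r.reversible),
            needs_fba=int(r.needs_fba),
        )
        if law is not None:
            row["law_type"] = law.law_type
            row["substrates"] = ";".join(law.substrate_ids)
            for name, value in law.parameter_items():
                row[name] = repr(value)
        rrows.append(row)

    met_path = directory / "metabolites.tsv"
    rxn_path = directory / "reactions.tsv"
    pd.DataFrame(mrows, columns=METABOLITE_COLUMNS).to_csv(met_path, sep=sep, index=False)
    pd.DataFrame(rrows, columns=REACTION_COLUMNS).to_csv(rxn_path, sep=sep, index=False)
    return rxn_path, met_path
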