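"""Molecular-formula arithmetic, reaction transforms, route enumeration and
metal-organic assembly enumeration.

This module carries the "expected chemistry" side of the decision-maker: given
building blocks (amines, isocyanates, carbonyl pyridines, metal ions, ...) it
derives every product formula a campaign could plausibly make, and turns the
charged metal-organic assemblies into m/z look-up ladders (one m/z per charge
state, each charge state retaining ``Q - z`` counterions) for MS matching.

Masses come from the NIST table shipped with :mod:`pyteomics`; monoisotopic
masses are the default for m/z work, abundance-weighted average masses are
available for reporting.
"""

from __future__ import annotations

import itertools
import json
import re
from dataclasses import dataclass, field
from enum import Enum
from math import gcd
from typing import Iterable, Mapping, Sequence

import pandas as pd
from pyteomics import mass as _pmass

__all__ = [
    "ChemspaceError",
    "Formula",
    "Role",
    "BuildingBlock",
    "TransformRule",
    "Species",
    "RouteGraph",
    "RouteStage",
    "AssemblySpecies",
    "MzEntry",
    "MzTable",
    "formula_mass",
    "parse_charged_formula",
    "apply_transform",
    "enumerate_route",
    "assembly_charge",
    "enumerate_assemblies",
    "mz_series",
    "adduct_mz",
    "build_lookup_table",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "DEFAULT_ADDUCTS",
    "BUILTIN_RULES",
]


class ChemspaceError(ValueError):
    """Invalid formula, role mismatch, or unbalanced chemistry."""


ELECTRON_MASS = 0.00054857990943
PROTON_MASS = _pmass.nist_mass["H"][0][0] - ELECTRON_MASS

_WATER = {"H": 2, "O": 1}


def _monoisotopic(element: str) -> float:
    try:
        return _pmass.nist_mass[element][0][0]
    except KeyError:
        raise ChemspaceError(f"unknown element symbol: {element!r}") from None


def _average(element: str) -> float:
    isotopes = _pmass.nist_mass.get(element)
    if isotopes is None:
        raise ChemspaceError(f"unknown element symbol: {element!r}")
    num = sum(m * ab for key, (m, ab) in isotopes.items() if key != 0)
    den = sum(ab for key, (m, ab) in isotopes.items() if key != 0)
    if den == 0:  # element with no tabulated abundances (e.g. synthetic)
        return isotopes[0][0]
    return num / den


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)|(\()|(\))(\d*)")


class Formula:
    """Immutable elemental composition (element symbol -> count >= 1).

    Supports ``+``, ``-`` and integer ``*``; subtraction that would drive any
    element negative raises :class:`ChemspaceError`. Equality is equality of
    the underlying mappings.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | str):
        if isinstance(counts, str):
            counts = _parse_formula_string(counts)
        clean: dict[str, int] = {}
        for el, n in counts.items():
            if not isinstance(n, int):
                raise ChemspaceError(f"non-integer count for {el}: {n!r}")
            if n < 0:
                raise ChemspaceError(f"negative count for {el}: {n}")
            if n == 0:
                continue
            _monoisotopic(el)  # validates the symbol
            clean[el] = n
        if not clean:
            raise ChemspaceError("empty formula")
        self._counts = dict(sorted(clean.items()))

    @property
    def counts(self) -> Mapping[str, int]:
        return dict(self._counts)

    def mass(self, mode: str = "monoisotopic") -> float:
        return formula_mass(self, mode)

    def __getitem__(self, element: str) -> int:
        return self._counts.get(element, 0)

    def __add__(self, other: "Formula") -> "Formula":
        merged = dict(self._counts)
        for el, n in other._counts.items():
            merged[el] = merged.get(el, 0) + n
        return Formula(merged)

    def __sub__(self, other: "Formula") -> "Formula":
        merged = dict(self._counts)
        for el, n in other._counts.items():
            merged[el] = merged.get(el, 0) - n
            if merged[el] < 0:
                raise ChemspaceError(
                    f"subtraction drives {el} negative ({merged[el]})"
                )
        return Formula(merged)

    def __mul__(self, k: int) -> "Formula":
        if not isinstance(k, int) or k < 1:
            raise ChemspaceError(f"formula multiplier must be a positive int, got {k!r}")
        return Formula({el: n * k for el, n in self._counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Formula) and self._counts == other._counts

    def __hash__(self) -> int:
        return hash(tuple(self._counts.items()))

    def hill(self) -> str:
        """Hill-order string (C, H, then alphabetical)."""
        items = dict(self._counts)
        out = []
        for el in ("C", "H"):
            if el in items:
                n = items.pop(el)
                out.append(el + (str(n) if n > 1 else ""))
        for el in sorted(items):
            n = items[el]
            out.append(el + (str(n) if n > 1 else ""))
        return "".join(out)

    def __repr__(self) -> str:
        return f"Formula({self.hill()!r})"


_CHARGE_SUFFIX = re.compile(r"^(.*?)([+−-]\d*|\d+[+−-])$")


def _parse_formula_string(s: str) -> dict[str, int]:
    """Parse a Hill-order formula with optional parenthesized groups."""
    s = s.strip()
    if not s:
        raise ChemspaceError("empty formula string")
    pos = 0
    stack: list[dict[str, int]] = [{}]
    while pos < len(s):
        ch = s[pos]
        if ch == "(":
            stack.append({})
            pos += 1
        elif ch == ")":
            if len(stack) == 1:
                raise ChemspaceError(f"unbalanced ')' in formula {s!r}")
            group = stack.pop()
            pos += 1
            mult = 1
            mstr = ""
            while pos < len(s) and s[pos].isdigit():
                mstr += s[pos]
                pos += 1
            if mstr:
                mult = int(mstr)
            for el, n in group.items():
                stack[-1][el] = stack[-1].get(el, 0) + n * mult
        else:
            m = re.match(r"([A-Z][a-z]?)(\d*)", s[pos:])
            if not m:
                raise ChemspaceError(f"cannot parse formula {s!r} at position {pos}")
            el, nstr = m.groups()
            n = int(nstr) if nstr else 1
            stack[-1][el] = stack[-1].get(el, 0) + n
            pos += m.end()
    if len(stack) != 1:
        raise ChemspaceError(f"unbalanced '(' in formula {s!r}")
    return stack[0]


def parse_charged_formula(s: str) -> tuple[Formula, int]:
    """Parse ``"C6H5NO"`` -> (Formula, 0); ``"Zn2+"``/``"Zn+2"`` -> (Formula, +2).

    The charge suffix may be ``+``, ``-``, ``+n``, ``n+`` etc.; the Unicode
    minus sign is accepted.
    """
    s = s.strip().replace("−", "-")
    m = _CHARGE_SUFFIX.match(s)
    charge = 0
    body = s
    if m and m.group(1):
        body, suffix = m.groups()
        if suffix[0] in "+-":
            sign = 1 if suffix[0] == "+" else -1
            mag = int(suffix[1:]) if len(suffix) > 1 else 1
        else:
            sign = 1 if suffix[-1] == "+" else -1
            mag = int(suffix[:-1])
        charge = sign * mag
    return Formula(body), charge


def formula_mass(formula: Formula | str | Mapping[str, int], mode: str = "monoisotopic") -> float:
    """Mass in daltons of ``formula`` under the chosen isotope convention."""
    if not isinstance(formula, Formula):
        formula = Formula(formula)
    if mode == "monoisotopic":
        table = _monoisotopic
    elif mode == "average":
        table = _average
    else:
        raise ChemspaceError(f"unknown mass mode {mode!r}; use monoisotopic|average")
    return sum(n * table(el) for el, n in formula.counts.items())


class Role(str, Enum):
    ALKYNE_AMINE = "alkyne_amine"
    ISOCYANATE = "isocyanate"
    ISOTHIOCYANATE = "isothiocyanate"
    ARYL_HALIDE = "aryl_halide"
    AZIDE = "azide"
    CARBONYL_PYRIDINE = "carbonyl_pyridine"
    POLYTOPIC_AMINE = "polytopic_amine"
    METAL_ION = "metal_ion"
    COUNTERION = "counterion"
    GUEST = "guest"
    INTERMEDIATE = "intermediate"  # product of an earlier route stage


_NEUTRAL_ORGANIC = {
    Role.ALKYNE_AMINE,
    Role.ISOCYANATE,
    Role.ISOTHIOCYANATE,
    Role.ARYL_HALIDE,
    Role.AZIDE,
    Role.CARBONYL_PYRIDINE,
    Role.POLYTOPIC_AMINE,
    Role.GUEST,
}


@dataclass(frozen=True)
class BuildingBlock:
    """A reagent in a campaign: formula + role + reactive-site count + charge.

    ``topicity`` counts reactive sites: primary amines for polytopic amines,
    bidentate chelation sites for metal ions. ``charge`` is the ionic charge
    (0 for neutral organics, -1 for counterions).
    """

    id: str
    role: Role
    formula: Formula
    topicity: int = 0
    charge: int = 0

    def __post_init__(self):
        if self.role in (Role.POLYTOPIC_AMINE, Role.METAL_ION) and self.topicity < 1:
            raise ChemspaceError(
                f"block {self.id!r}: role {self.role.value} requires topicity >= 1"
            )
        if self.role in _NEUTRAL_ORGANIC and self.charge != 0:
            raise ChemspaceError(f"block {self.id!r}: neutral organic role with charge != 0")
        if self.role is Role.COUNTERION and self.charge != -1:
            raise ChemspaceError(f"block {self.id!r}: counterion charge must be -1")

    def mass(self, mode: str = "monoisotopic") -> float:
        return self.formula.mass(mode)


@dataclass(frozen=True)
class TransformRule:
    """A reaction transform: roles it consumes and the net formula change.

    ``delta`` maps element -> signed count change applied to the sum of the
    reactant formulas (once, or once per condensation bond when ``per_bond``).
    """

    name: str
    reactant_roles: tuple[Role, ...]
    delta: Mapping[str, int] = field(default_factory=dict)
    per_bond: bool = False

    def matches(self, reactants: Sequence["BuildingBlock | Species"]) -> bool:
        def ok(r, want):
            return want is Role.INTERMEDIATE or r.role == want

        if self.per_bond and len(self.reactant_roles) == 2:
            # one polytopic partner may bind several copies of the other
            return (
                len(reactants) >= 2
                and ok(reactants[0], self.reactant_roles[0])
                and all(ok(r, self.reactant_roles[1]) for r in reactants[1:])
            )
        if len(reactants) != len(self.reactant_roles):
            return False
        return all(ok(r, want) for r, want in zip(reactants, self.reactant_roles))


#: Transforms used by the divergent-synthesis campaign. Urea/thiourea formation
#: and CuAAC are pure additions; imine condensation loses one water per C=N
#: bond; Sonogashira coupling loses HBr (aryl bromide partners).
BUILTIN_RULES: dict[str, TransformRule] = {
    "urea": TransformRule("urea", (Role.ALKYNE_AMINE, Role.ISOCYANATE)),
    "thiourea": TransformRule("thiourea", (Role.ALKYNE_AMINE, Role.ISOTHIOCYANATE)),
    "imine_condensation": TransformRule(
        "imine_condensation",
        (Role.POLYTOPIC_AMINE, Role.CARBONYL_PYRIDINE),
        delta={"H": -2, "O": -1},
        per_bond=True,
    ),
    "sonogashira": TransformRule(
        "sonogashira", (Role.INTERMEDIATE, Role.ARYL_HALIDE), delta={"H": -1, "Br": -1}
    ),
    "cuaac": TransformRule("cuaac", (Role.INTERMEDIATE, Role.AZIDE)),
}


@dataclass(frozen=True)
class Species:
    """A (possibly intermediate) product with provenance back to its blocks."""

    id: str
    formula: Formula
    provenance: tuple[str, ...]
    stage: int = 0
    role: Role = Role.INTERMEDIATE

    def mass(self, mode: str = "monoisotopic") -> float:
        return self.formula.mass(mode)


def apply_transform(
    rule: TransformRule,
    reactants: Sequence[BuildingBlock | Species],
    bonds: int | None = None,
) -> Species:
    """Apply ``rule`` to ``reactants``, returning the product species.

    The product formula is the sum of reactant formulas plus the rule's delta
    (times ``bonds`` for per-bond rules; by default one bond per partner after
    the first reactant). Role mismatches and deltas that would drive an
    element count negative raise :class:`ChemspaceError`.
    """
    if not rule.matches(reactants):
        got = [r.role.value for r in reactants]
        want = [r.value for r in rule.reactant_roles]
        raise ChemspaceError(f"rule {rule.name!r} expects roles {want}, got {got}")
    if bonds is None:
        bonds = len(reactants) - 1 if rule.per_bond else 1
    if bonds < 1:
        raise ChemspaceError("bonds must be >= 1")
    total: dict[str, int] = {}
    for r in reactants:
        for el, n in r.formula.counts.items():
            total[el] = total.get(el, 0) + n
    k = bonds if rule.per_bond else 1
    for el, dn in rule.delta.items():
        total[el] = total.get(el, 0) + dn * k
        if total[el] < 0:
            raise ChemspaceError(
                f"rule {rule.name!r} drives {el} negative on {[r.id for r in reactants]}"
            )
    pid = "+".join(r.id for r in reactants) + f"@{rule.name}"
    prov = tuple(itertools.chain.from_iterable(
        r.provenance if isinstance(r, Species) else (r.id,) for r in reactants
    ))
    stage = 1 + max((r.stage for r in reactants if isinstance(r, Species)), default=0)
    return Species(pid, Formula(total), prov, stage)


@dataclass(frozen=True)
class RouteStage:
    """One divergent-route stage: branches of (rule, partner role).

    Each branch combines every product of the previous stage (or, at stage 1,
    every block matching the rule's first role) with every block of the
    partner role.
    """

    branches: tuple[tuple[TransformRule, Role], ...]


class RouteGraph:
    """DAG of species produced by staged combinatorial transforms."""

    def __init__(self) -> None:
        self.nodes: dict[str, Species] = {}
        self.edges: list[tuple[str, str, str]] = []  # (parent, child, rule)

    def add(self, sp: Species, parents: Sequence[BuildingBlock | Species], rule: str) -> None:
        self.nodes[sp.id] = sp
        for p in parents:
            self.edges.append((p.id, sp.id, rule))

    def products_at_stage(self, stage: int) -> list[Species]:
        return [s for s in self.nodes.values() if s.stage == stage]

    def stage_counts(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for s in self.nodes.values():
            out[s.stage] = out.get(s.stage, 0) + 1
        return out

    def terminal_products(self) -> list[Species]:
        if not self.nodes:
            return []
        last = max(s.stage for s in self.nodes.values())
        return self.products_at_stage(last)


def enumerate_route(
    blocks: Iterable[BuildingBlock],
    stages: Sequence[RouteStage],
) -> RouteGraph:
    """Enumerate every combinatorial product of a staged divergent route.

    Stage 1 pairs blocks of each branch rule's first role with blocks of the
    branch partner role; later stages pair every previous-stage product with
    the partner blocks. Raises if a required role has no blocks.
    """
    blocks = list(blocks)
    by_role: dict[Role, list[BuildingBlock]] = {}
    for b in blocks:
        by_role.setdefault(b.role, []).append(b)
    graph = RouteGraph()
    current: list[Species] = []
    for k, stage in enumerate(stages, start=1):
        produced: list[Species] = []
        for rule, partner_role in stage.branches:
            partners = by_role.get(partner_role, [])
            if not partners:
                raise ChemspaceError(
                    f"stage {k}: no building blocks with role {partner_role.value!r}"
                )
            if k == 1:
                first_role = rule.reactant_roles[0]
                firsts: list[BuildingBlock | Species] = by_role.get(first_role, [])
                if not firsts:
                    raise ChemspaceError(
                        f"stage 1: no building blocks with role {first_role.value!r}"
                    )
            else:
                firsts = current
            for a in firsts:
                for b in partners:
                    sp = apply_transform(rule, [a, b])
                    sp = Species(sp.id, sp.formula, sp.provenance, stage=k)
                    graph.add(sp, [a, b], rule.name)
                    produced.append(sp)
        current = produced
    return graph


def assembly_charge(metal_count: int, metal_charge: int) -> int:
    """Net cationic charge Q of an assembly: metal count x metal charge."""
    if metal_count < 1:
        raise ChemspaceError(f"metal_count must be >= 1, got {metal_count}")
    if metal_charge < 1:
        raise ChemspaceError(f"metal_charge must be >= 1, got {metal_charge}")
    return metal_count * metal_charge


@dataclass(frozen=True)
class AssemblySpecies:
    """A homoleptic metal-organic assembly [M_m L_l]^Q+.

    Each ligand L is one polytopic amine condensed with ``topicity`` carbonyl
    pyridines (one water lost per imine bond); the coordination balance
    ``m x capacity = l x topicity`` must hold exactly and Q = m x metal charge.
    """

    metal: BuildingBlock
    metal_count: int
    ligand_pyridine: BuildingBlock
    ligand_amine: BuildingBlock
    ligand_count: int

    def __post_init__(self):
        m, l = self.metal_count, self.ligand_count
        if m < 1 or l < 1:
            raise ChemspaceError("metal_count and ligand_count must be >= 1")
        if m * self.metal.topicity != l * self.ligand_amine.topicity:
            raise ChemspaceError(
                f"coordination imbalance: {m} x capacity {self.metal.topicity} != "
                f"{l} x topicity {self.ligand_amine.topicity}"
            )

    @property
    def net_charge(self) -> int:
        return assembly_charge(self.metal_count, self.metal.charge)

    @property
    def ligand_formula(self) -> Formula:
        t = self.ligand_amine.topicity
        return (
            self.ligand_amine.formula
            + t * self.ligand_pyridine.formula
            - t * Formula(_WATER)
        )

    @property
    def formula(self) -> Formula:
        return self.metal_count * self.metal.formula + self.ligand_count * self.ligand_formula

    def mass(self, mode: str = "monoisotopic") -> float:
        return self.formula.mass(mode)

    @property
    def label(self) -> str:
        return (
            f"[{self.metal.id}{self.metal_count}"
            f"({self.ligand_pyridine.id}{self.ligand_amine.topicity},{self.ligand_amine.id})"
            f"{self.ligand_count}]{self.net_charge}+"
        )


def enumerate_assemblies(
    pyridine: BuildingBlock,
    amine: BuildingBlock,
    metal: BuildingBlock,
    max_metals: int,
    include_mononuclear: bool = True,
) -> list[AssemblySpecies]:
    """All coordination-balanced homoleptic assemblies up to ``max_metals``.

    Under maximal site occupancy the stoichiometries (m, l) satisfy
    ``m x capacity = l x topicity``; solutions form the integer-multiple
    series of the minimal balanced pair. Returns the empty list when no
    solution fits below ``max_metals``.
    """
    cap, top = metal.topicity, amine.topicity
    if cap < 1 or top < 1:
        raise ChemspaceError("metal capacity and amine topicity must be >= 1")
    g = gcd(cap, top)
    m0, l0 = top // g, cap // g
    out: list[AssemblySpecies] = []
    k = 1
    while k * m0 <= max_metals:
        m, l = k * m0, k * l0
        if include_mononuclear or m > 1:
            out.append(AssemblySpecies(metal, m, pyridine, amine, l))
        k += 1
    return out


def mz_series(
    species: AssemblySpecies,
    counterion: BuildingBlock,
    mode: str = "monoisotopic",
) -> list[tuple[int, int, float]]:
    """Charge-ladder m/z values for a Q+ species shedding counterions.

    For each observed charge state z = 1..Q the ion retains n = Q - z
    counterions, so m/z = (species mass + n x counterion mass) / z. Returns
    the Q-entry ladder in ascending z.
    """
    q = species.net_charge
    if q < 1:
        raise ChemspaceError(f"species must carry positive charge, got Q={q}")
    m = species.mass(mode)
    cm = counterion.mass(mode)
    return [(z, q - z, (m + (q - z) * cm) / z) for z in range(1, q + 1)]


#: Positive-ion ESI adducts used for neutral organic products: label -> ion mass added.
DEFAULT_ADDUCTS: dict[str, float] = {
    "[M+H]+": PROTON_MASS,
    "[M+Na]+": _pmass.nist_mass["Na"][0][0] - ELECTRON_MASS,
    "[M+NH4]+": _pmass.nist_mass["N"][0][0] + 4 * _pmass.nist_mass["H"][0][0] - ELECTRON_MASS,
}


def adduct_mz(
    species: Species | BuildingBlock | Formula | float,
    adducts: Mapping[str, float] | None = None,
) -> list[tuple[str, float]]:
    """Singly charged adduct m/z values for a neutral species."""
    if adducts is None:
        adducts = DEFAULT_ADDUCTS
    if not adducts:
        raise ChemspaceError("empty adduct set")
    if isinstance(species, float | int):
        m = float(species)
    elif isinstance(species, Formula):
        m = species.mass()
    else:
        if getattr(species, "charge", 0) != 0:
            raise ChemspaceError(f"adduct_mz requires a neutral species, got charge {species.charge}")
        m = species.mass()
    if m <= 0:
        raise ChemspaceError(f"species mass must be positive, got {m}")
    return [(label, m + am) for label, am in adducts.items()]


@dataclass
class MzEntry:
    """One assembly and its full counterion charge ladder."""

    entry_id: str
    combination: str
    m: int
    l: int
    Q: int
    mass: float
    ladder: list[tuple[int, int, float]]  # (z, n, m/z)
    species: AssemblySpecies | None = None


@dataclass
class MzTable:
    """Precalculated expected-m/z ladders for MS matching.

    ``n_entries`` counts assemblies; ``n_values`` counts individual m/z
    values (Q per entry).
    """

    entries: list[MzEntry]
    tolerance: float = 0.5

    @property
    def n_entries(self) -> int:
        return len(self.entries)

    @property
    def n_values(self) -> int:
        return sum(len(e.ladder) for e in self.entries)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            for z, n, mz in e.ladder:
                rows.append(
                    dict(
                        entry_id=e.entry_id,
                        combination=e.combination,
                        m=e.m,
                        l=e.l,
                        Q=e.Q,
                        z=z,
                        n=n,
                        mz=mz,
                    )
                )
        return pd.DataFrame(
            rows, columns=["entry_id", "combination", "m", "l", "Q", "z", "n", "mz"]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path=None):
        payload = {
            "tolerance": self.tolerance,
            "n_entries": self.n_entries,
            "n_values": self.n_values,
            "entries": [
                {
                    "entry_id": e.entry_id,
                    "combination": e.combination,
                    "m": e.m,
                    "l": e.l,
                    "Q": e.Q,
                    "mass": e.mass,
                    "ladder": [{"z": z, "n": n, "mz": mz} for z, n, mz in e.ladder],
                }
                for e in self.entries
            ],
        }
        if path is None:
            return payload
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
        return payload

    @classmethod
    def from_json(cls, payload_or_path) -> "MzTable":
        """Rebuild a matching-ready table from :meth:`to_json` output.

        The reconstructed entries carry stoichiometry and ladders but not the
        full species objects (those require the building-block definitions).
        """
        if isinstance(payload_or_path, (str, bytes)) or hasattr(payload_or_path, "__fspath__"):
            with open(payload_or_path) as fh:
                payload = json.load(fh)
        else:
            payload = payload_or_path
        entries = [
            MzEntry(
                entry_id=e["entry_id"],
                combination=e["combination"],
                m=int(e["m"]),
                l=int(e["l"]),
                Q=int(e["Q"]),
                mass=float(e["mass"]),
                ladder=[(int(v["z"]), int(v["n"]), float(v["mz"])) for v in e["ladder"]],
            )
            for e in payload["entries"]
        ]
        return cls(entries=entries, tolerance=float(payload.get("tolerance", 0.5)))


def build_lookup_table(
    pyridines: Sequence[BuildingBlock],
    amines: Sequence[BuildingBlock],
    metals: Sequence[BuildingBlock],
    counterion: BuildingBlock,
    max_metals: Mapping[str, int] | int = 10,
    include_mononuclear: bool = True,
    tolerance: float = 0.5,
) -> MzTable:
    """Expected-m/z table over the full screening grid.

    One :class:`MzEntry` per balanced assembly over every pyridine x amine x
    metal combination; ``max_metals`` may be a single cap or a per-metal-id
    mapping. Duplicate block ids raise.
    """
    all_ids = [b.id for b in (*pyridines, *amines, *metals, counterion)]
    dupes = {i for i in all_ids if all_ids.count(i) > 1}
    if dupes:
        raise ChemspaceError(f"duplicate building-block ids: {sorted(dupes)}")
    entries: list[MzEntry] = []
    for pyr, am, met in itertools.product(pyridines, amines, metals):
        cap = max_metals[met.id] if isinstance(max_metals, Mapping) else max_metals
        combo = f"{pyr.id}+{am.id}+{met.id}"
        for sp in enumerate_assemblies(pyr, am, met, cap, include_mononuclear):
            entries.append(
                MzEntry(
                    entry_id=sp.label,
                    combination=combo,
                    m=sp.metal_count,
                    l=sp.ligand_count,
                    Q=sp.net_charge,
                    mass=sp.mass(),
                    ladder=mz_series(sp, counterion),
                    species=sp,
                )
            )
    return MzTable(entries=entries, tolerance=tolerance)
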