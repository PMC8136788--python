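"""Itemized donor-acceptor interaction-energy ledger.

Every structure's total interaction energy decomposes into independent,
mutually comparable terms (all kcal/mol, water phase unless stated):

    dE_bind      = E_complex - sum(E_sub)
    dE_pair      = E_complex - sum(E_base)                (Watson-Crick / MM)
    dE_Hoogsteen = E_complex - (dE_pair + sum(E_base))    (triad third base)
    dE_G-tetrad  = E_complex - (4 dE_pair + 4 E_base + E_ion) = 4 dE_ionic
    dE_stack     = E_complex - (sum(dE_pair) + sum(E_base))
    dE_int       = sum(dE_pair) + sum(dE_Hoogsteen) + sum(dE_ionic) + dE_stack

with counterpoise (CP) correction of the basis-set superposition error:

    E_BSSE(X)       = E^{AB}_{AB}(X) - E^{X}_{AB}(X)
    dE_bind^CP(AB)  = dE_bind(AB) - E_BSSE(A) - E_BSSE(B)

(superscript = basis present, subscript = geometry, parenthesis = the
fragment that actually carries atoms; ghost fragments contribute basis
functions only).

The hydration cycle for a monovalent ion entering a quadruplex:

    dE_M+binding = sum(dE_ionic) - dE_hydration

with water coordination numbers Li+ 4, Na+ 5, K+ 6.

Operations run either on a bundled fixture table of reference component
energies (no quantum-chemistry backend needed) or on backend-agnostic
``EnergyRecord`` sets, e.g. from :mod:`dnastack.qm`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from io import StringIO

import pandas as pd

__all__ = [
    "EnergyRecord",
    "RecordSet",
    "ComponentLedger",
    "HydrationModel",
    "FixtureTable",
    "load_fixture",
    "delta_bind",
    "counterpoise_correct",
    "delta_pair",
    "delta_hoogsteen",
    "delta_tetrad",
    "delta_stack",
    "per_bond",
    "third_base_stack",
    "delta_int",
    "duplex_ledger",
    "quadruplex_ledger",
    "ion_binding",
    "rank_stability",
    "round_half_away",
    "BOND_COUNTS",
    "COORDINATION_NUMBERS",
    "DEFAULT_HYDRATION_ENERGIES",
    "THIRD_BASE_CORE",
    "NEAREST_NEIGHBOR_ORDER",
]

# hydrogen/ionic bond counts used when no geometry is at hand
BOND_COUNTS = {
    "G-C": 3, "A-T": 2, "G-T": 2, "G-G": 2, "C-T": 2,
    "T-T": 2, "A-G": 2, "A-C": 2, "A-A": 2, "C-C": 1,
    "C+.G": 2, "G.G": 2, "T.A": 2, "A.A": 2,
    "rC+.G": 2, "rG.G": 2, "rT.A": 2, "rA.A": 2,
    "tetrad_ionic": 4, "quadruplex_ionic": 8,
}

# first-shell water coordination numbers of the monovalent ions
COORDINATION_NUMBERS = {"Li+": 4, "Na+": 5, "K+": 6}

# Synthetic default hydration energies (kcal/mol).  Individual values are a
# placeholder set chosen only to satisfy the physical constraints the
# analysis relies on: hydration stability Li+ > Na+ > K+ (affinity for water
# decreases with ion size) and a Na+/K+ hydration gap of 2.22 kcal/mol.
# Supply measured/computed values via ``ion_binding`` for real work.
DEFAULT_HYDRATION_ENERGIES = {"Li+": -41.00, "Na+": -34.00, "K+": -31.78}

# Watson-Crick core duplex of each triplex stack (for third-base stacking)
THIRD_BASE_CORE = {
    "C+.G-C/T.A-T": "G-C/A-T",
    "T.A-T/T.A-T": "A-T/A-T",
    "A.A-T/A.A-T": "A-T/A-T",
    "G.G-C/G.G-C": "G-C/G-C",
    "C+.G-C/C+.G-C": "G-C/G-C",
    "rT.A-T/rT.A-T": "A-T/A-T",
    "rA.A-T/rA.A-T": "A-T/A-T",
    "rG.G-C/rG.G-C": "G-C/G-C",
    "rC+.G-C/rC+.G-C": "G-C/G-C",
}

# Experimental nearest-neighbor duplex stability trend (comparison vector;
# inner lists are experimentally indistinguishable groups).  The model has
# no strand directionality, so X-Y/Y'-X' entries are collapsed.
NEAREST_NEIGHBOR_ORDER = [
    ["G-C/C-G"],
    ["G-C/G-C"],
    ["G-C/A-T", "G-C/T-A"],
    ["A-T/A-T"],
    ["A-T/T-A"],
]


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero (report-style, not banker's)."""
    factor = 10**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


# ---------------------------------------------------------------------------
# energy records (backend bookkeeping)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnergyRecord:
    """One backend energy, tagged by chemical system, basis and geometry.

    ``fragments`` lists (fragment_id, is_ghost); ghost fragments contribute
    basis functions but no atoms.  ``basis_context``/``geometry_context``
    name the system whose basis functions/geometry are in effect.
    """

    fragments: tuple  # ((id, ghost), ...)
    basis_context: str
    geometry_context: str
    phase: str  # gas | water
    energy: float  # kcal/mol

    @property
    def real_fragments(self) -> tuple:
        return tuple(sorted(f for f, ghost in self.fragments if not ghost))

    @property
    def key(self) -> tuple:
        ghosts = tuple(sorted(f for f, ghost in self.fragments if ghost))
        return (self.real_fragments, ghosts, self.basis_context, self.geometry_context)


class RecordSet:
    """Indexed collection of :class:`EnergyRecord`."""

    def __init__(self, records=()):
        self._by_key = {}
        for r in records:
            self.add(r)

    def add(self, record: EnergyRecord) -> None:
        self._by_key[record.key] = record

    def __iter__(self):
        return iter(self._by_key.values())

    def __len__(self):
        return len(self._by_key)

    def energy(self, real, ghosts=(), basis=None, geometry=None) -> float:
        real = tuple(sorted(real if isinstance(real, (tuple, list)) else [real]))
        ghosts = tuple(sorted(ghosts))
        basis = basis if basis is not None else "+".join(real + ghosts)
        geometry = geometry if geometry is not None else basis
        key = (real, ghosts, basis, geometry)
        if key not in self._by_key:
            raise KeyError(f"no energy record for {key}")
        return self._by_key[key].energy

    def has(self, real, ghosts=(), basis=None, geometry=None) -> bool:
        try:
            self.energy(real, ghosts, basis, geometry)
            return True
        except KeyError:
            return False


# ---------------------------------------------------------------------------
# fixture table
# ---------------------------------------------------------------------------


class FixtureTable:
    """Bundled table of reference component energies, indexed by structure id."""

    def __init__(self, frame: pd.DataFrame):
        self.frame = frame
        self._by_id = {
            rec["structure_id"]: rec for rec in frame.to_dict(orient="records")
        }

    def row(self, structure_id: str) -> "_FixtureRow":
        if structure_id not in self._by_id:
            raise KeyError(f"unknown structure id {structure_id!r}")
        return _FixtureRow(self._by_id[structure_id])

    def total(self, structure_id: str) -> float:
        return float(self.row(structure_id).total_kcal_mol)

    def ids(self, cls: str | None = None) -> list:
        if cls is None:
            return list(self._by_id)
        return list(self.frame.loc[self.frame["class"] == cls, "structure_id"])

    def consistency_report(self, tol: float = 0.01) -> pd.DataFrame:
        """Check printed per-bond values against total/n_bonds.

        The tolerance is ``tol`` or half a unit of the printed precision,
        whichever is looser (per-pair values print at 2 decimals, quadruplex
        ionic sums at 1).  Rows carrying a flag (the Li+ quadruplex
        ionic-bond-count ambiguity) are reported but not judged.
        """
        rows = []
        for sid in self.ids():
            r = self.row(sid)
            if pd.isna(r.per_bond_kcal_mol) or pd.isna(r.n_bonds):
                continue
            recomputed = r.total_kcal_mol / r.n_bonds
            printed = float(r.per_bond_kcal_mol)
            decimals = len((f"{printed!r}").rsplit(".", 1)[-1])
            row_tol = max(tol, 0.5 * 10.0 ** (-decimals))
            rows.append(
                {
                    "structure_id": sid,
                    "printed": printed,
                    "recomputed": recomputed,
                    "consistent": abs(recomputed - printed) <= row_tol,
                    "flagged": r.flagged,
                }
            )
        return pd.DataFrame(rows)


class _FixtureRow:
    def __init__(self, rec: dict):
        self._rec = rec

    def __getattr__(self, name):
        if name == "cls":
            return self._rec["class"]
        try:
            return self._rec[name]
        except KeyError as exc:
            raise AttributeError(name) from exc

    @property
    def flagged(self) -> bool:
        flag = self._rec.get("flag")
        return isinstance(flag, str) and bool(flag)


def load_fixture() -> FixtureTable:
    text = resources.files("dnastack.data").joinpath("component_energies.csv").read_text()
    body = "\n".join(l for l in text.splitlines() if not l.startswith("#"))
    frame = pd.read_csv(StringIO(body))
    return FixtureTable(frame)


# ---------------------------------------------------------------------------
# core formulas (records mode)
# ---------------------------------------------------------------------------


def delta_bind(records: RecordSet, complex_id, subsystem_ids) -> float:
    """E_complex minus the sum of isolated subsystem energies."""
    phases = {r.phase for r in records}
    if len(phases) > 1:
        raise ValueError(f"mixed phases in record set: {phases}")
    e_complex = records.energy(complex_id)
    return e_complex - sum(records.energy(s) for s in subsystem_ids)


def counterpoise_correct(records: RecordSet, fragments, complex_id=None) -> tuple:
    """CP-corrected binding energy and the per-fragment BSSE terms.

    Needs, per fragment X: the ghost record E^{AB}_{AB}(X) (X real, the rest
    ghost, complex basis and geometry) and the fragment-basis record
    E^{X}_{AB}(X) at the complex geometry.
    """
    fragments = list(fragments)
    complex_id = complex_id if complex_id is not None else tuple(sorted(fragments))
    basis = "+".join(sorted(fragments))
    raw = delta_bind(records, complex_id, fragments)
    bsse = {}
    for frag in fragments:
        ghosts = tuple(sorted(f for f in fragments if f != frag))
        e_ghost = records.energy([frag], ghosts=ghosts, basis=basis, geometry=basis)
        e_own = records.energy([frag], basis=frag, geometry=basis)
        bsse[frag] = e_ghost - e_own
    corrected = raw - sum(bsse.values())
    return corrected, bsse


def _pair_fragments(pair_id: str) -> list:
    left, right = pair_id.split("-") if "-" in pair_id else pair_id.split(".")
    if left == right:  # homo pairs need distinct fragment ids
        return [f"{pair_id}:{left}1", f"{pair_id}:{right}2"]
    return [f"{pair_id}:{left}", f"{pair_id}:{right}"]


def _records_pair(records: RecordSet, pair_id: str) -> float:
    frags = _pair_fragments(pair_id)
    if records.has([frags[0]], ghosts=(frags[1],), basis="+".join(sorted(frags)),
                   geometry="+".join(sorted(frags))):
        corrected, _ = counterpoise_correct(records, frags, complex_id=tuple(sorted(frags)))
        return corrected
    return delta_bind(records, tuple(sorted(frags)), frags)


# ---------------------------------------------------------------------------
# component energies (fixture or records)
# ---------------------------------------------------------------------------


def delta_pair(source, pair_id: str) -> float:
    """Watson-Crick / mismatch pairing energy of a two-base structure."""
    if isinstance(source, FixtureTable):
        return float(source.row(pair_id).total_kcal_mol)
    return _records_pair(source, pair_id)


def delta_hoogsteen(source, triad_id: str) -> float:
    """Hoogsteen pairing energy of the third base within a triad."""
    if isinstance(source, FixtureTable):
        return float(source.row(triad_id).total_kcal_mol)
    records = source
    e_complex = records.energy((triad_id,))
    e_bases = records.energy((triad_id + ":bases",))
    de_pair = records.energy((triad_id + ":pair",))  # embedded-pair energy term
    return e_complex - (de_pair + e_bases)


def delta_tetrad(source, tetrad_id: str) -> tuple:
    """(dE_G-tetrad, dE_ionic); the tetrad energy is exactly 4x the ionic bond."""
    if isinstance(source, FixtureTable):
        total = float(source.row(tetrad_id).total_kcal_mol)
        return total, total / 4.0
    records = source
    e_complex = records.energy((tetrad_id,))
    e_parts = records.energy((tetrad_id + ":parts",))  # 4 dE_pair + 4 E_base + E_ion
    total = e_complex - e_parts
    return total, total / 4.0


def delta_stack(source, stack_id: str) -> float:
    """Two-layer stacking energy."""
    if isinstance(source, FixtureTable):
        return float(source.row(stack_id).total_kcal_mol)
    records = source
    e_complex = records.energy((stack_id,))
    e_parts = records.energy((stack_id + ":parts",))  # sum dE_pair + sum E_base
    return e_complex - e_parts


def per_bond(total_energy: float, n_bonds: int, ndigits: int = 2) -> float:
    """Energy per bond at report precision (2 decimals for pairing tables,
    1 decimal for quadruplex ionic sums), ties rounded away from zero."""
    if n_bonds < 1:
        raise ValueError("bond count must be >= 1")
    return round_half_away(total_energy / n_bonds, ndigits)


def third_base_stack(source, triplex_stack_id: str) -> float:
    """Stacking energy of the third bases alone.

    Obtained by subtracting the Watson-Crick core duplex's stacking energy
    from the triplex stacking energy.
    """
    if triplex_stack_id not in THIRD_BASE_CORE:
        raise KeyError(f"no core duplex mapping for {triplex_stack_id!r}")
    core = THIRD_BASE_CORE[triplex_stack_id]
    return delta_stack(source, triplex_stack_id) - delta_stack(source, core)


# ---------------------------------------------------------------------------
# ledgers and aggregates
# ---------------------------------------------------------------------------


@dataclass
class ComponentLedger:
    """Itemized interaction-energy terms of one structure (kcal/mol)."""

    pair_terms: dict = field(default_factory=dict)  # id -> dE_pair
    hoogsteen_terms: dict = field(default_factory=dict)
    ionic_terms: dict = field(default_factory=dict)  # id -> per-bond dE_ionic sum entry
    stack_term: float = 0.0
    phase: str = "water"
    bond_counts: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def total(self) -> float:
        return (
            sum(self.pair_terms.values())
            + sum(self.hoogsteen_terms.values())
            + sum(self.ionic_terms.values())
            + self.stack_term
        )


def delta_int(ledger: ComponentLedger) -> float:
    """Overall interaction energy: the exact sum of the stored components
    (absent terms are zero by construction)."""
    return ledger.total()


def duplex_ledger(fixture: FixtureTable, stack_id: str) -> ComponentLedger:
    """Two-base/two-layer ledger: two pairing terms plus the stacking term."""
    layers = stack_id.split("/")
    ledger = ComponentLedger(stack_term=delta_pairless_stack(fixture, stack_id))
    for k, layer in enumerate(layers):
        pid = _canonical_pair_id(layer)
        ledger.pair_terms[f"layer{k}:{pid}"] = delta_pair(fixture, pid)
        ledger.bond_counts[f"layer{k}:{pid}"] = BOND_COUNTS[pid]
    return ledger


def delta_pairless_stack(fixture: FixtureTable, stack_id: str) -> float:
    return delta_stack(fixture, stack_id)


def _canonical_pair_id(layer: str) -> str:
    if layer in BOND_COUNTS:
        return layer
    a, b = layer.split("-")
    flipped = f"{b}-{a}"
    if flipped in BOND_COUNTS:
        return flipped
    raise KeyError(f"unknown pair {layer!r}")


def quadruplex_ledger(
    fixture: FixtureTable, ion: str, in_plane: bool = False
) -> ComponentLedger:
    """Four-base/two-layer ledger for G4...M+...G4.

    Eight guanine-guanine pairing terms (four per tetrad layer, using the
    G-G pair value), the G4/G4 stacking term, and the summed ionic term of
    the chosen ion.  ``in_plane`` is bookkeeping only; the bundled ionic sums
    describe the relaxed arrangement of each ion (out-of-plane Na+/K+,
    in-plane Li+).
    """
    sum_id = f"G4_{ion.rstrip('+')}_G4"
    ledger = ComponentLedger(stack_term=delta_stack(fixture, "G4/G4"))
    gg = delta_pair(fixture, "G-G")
    for k in range(8):
        ledger.pair_terms[f"G-G:{k}"] = gg
    ledger.ionic_terms[sum_id] = float(fixture.row(sum_id).total_kcal_mol)
    ledger.bond_counts[sum_id] = int(fixture.row(sum_id).n_bonds)
    ledger.metadata.update({"ion": ion, "in_plane": in_plane})
    return ledger


# ---------------------------------------------------------------------------
# hydration cycle
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HydrationModel:
    """Hydration bookkeeping for one monovalent ion species."""

    species: str
    coordination_number: int
    hydration_energy: float  # kcal/mol, dE_hydration
    ion_binding_energy: float | None = None  # dE_M+binding once computed


def ion_binding(sum_ionic: float, model: HydrationModel) -> HydrationModel:
    """Net energy for the hydrated ion to shed its shell and enter the
    quadruplex: dE_M+binding = sum(dE_ionic) - dE_hydration."""
    if model.coordination_number != COORDINATION_NUMBERS[model.species]:
        raise ValueError(
            f"{model.species} coordination number must be "
            f"{COORDINATION_NUMBERS[model.species]}"
        )
    return HydrationModel(
        species=model.species,
        coordination_number=model.coordination_number,
        hydration_energy=model.hydration_energy,
        ion_binding_energy=sum_ionic - model.hydration_energy,
    )


def hydration_model(species: str, hydration_energy: float | None = None) -> HydrationModel:
    energies = DEFAULT_HYDRATION_ENERGIES
    e = hydration_energy if hydration_energy is not None else energies[species]
    return HydrationModel(
        species=species,
        coordination_number=COORDINATION_NUMBERS[species],
        hydration_energy=e,
    )


# ---------------------------------------------------------------------------
# stability ordering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RankedEntry:
    name: str
    value: float
    tie_group: int  # entries within tolerance of each other share a group


def rank_stability(energies: dict, tolerance: float = 0.05) -> list:
    """Order named energies most negative (most stable) first.

    Entries within ``tolerance`` kcal/mol of the previous entry share a tie
    group (chained), reflecting that the printed precision cannot separate
    them.
    """
    items = sorted(energies.items(), key=lambda kv: (kv[1], kv[0]))
    out = []
    group = 0
    for k, (name, value) in enumerate(items):
        if k > 0 and abs(value - items[k - 1][1]) > tolerance:
            group += 1
        out.append(RankedEntry(name=name, value=value, tie_group=group))
    return out
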