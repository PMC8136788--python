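"""Bridge between assemblies and quantum-chemistry backends.

Writes single-point / optimization job decks (Gaussian-style dialect) for an
:class:`~dnastack.geometry.Assembly`, parses final energies from backend log
text into :class:`~dnastack.energy.EnergyRecord`, and provides a
deterministic mock backend that fabricates a complete, internally consistent
record set from planted component energies — so the whole ledger pipeline is
testable without running any electronic-structure code.

No quantum-chemistry program is executed here; the deck writer and parser
only speak the file formats.
"""

from __future__ import annotations

import re
import zlib
from dataclasses import dataclass

import numpy as np

from .energy import EnergyRecord, FixtureTable, RecordSet, _pair_fragments
from .geometry import Assembly

__all__ = [
    "HARTREE_TO_KCAL",
    "JobSpec",
    "write_deck",
    "parse_energy",
    "mock_backend",
    "mock_records_for_pair",
]

HARTREE_TO_KCAL = 627.509474  # kcal/mol per hartree


@dataclass(frozen=True)
class JobSpec:
    """One backend job: task, model chemistry, solvent and fragment layout."""

    task: str = "single_point"  # single_point | optimization
    method: str = "M05-2X"
    basis: str = "6-31G(d,p)"
    solvent: str = "none"  # none | continuum_water
    solvent_keyword: str = "SCRF=(CPCM,Solvent=Water)"  # override for other codes
    frozen_dihedrals: tuple = ()  # ((i, j, k, l), ...) 1-based atom indices
    ghost_fragments: tuple = ()  # fragment labels marked as ghosts
    charge: int = 0
    multiplicity: int = 1

    def __post_init__(self):
        if self.task not in ("single_point", "optimization"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.ghost_fragments and self.task != "single_point":
            raise ValueError("ghost fragments are valid only in single-point tasks")


def _fragment_of(assembly: Assembly, base_index: int) -> str:
    """Fragment label of a base: its chain id, falling back to its index."""
    b = assembly.bases()[base_index]
    return b.chain or str(base_index)


def write_deck(assembly: Assembly, jobspec: JobSpec) -> str:
    """Deterministic job deck text for one assembly.

    Coordinates are printed to 6 decimals; ghost atoms use the ``-Bq``
    element suffix; optimizations with frozen dihedrals emit a ModRedundant
    block.  Identical inputs yield byte-identical decks.
    """
    lines = []
    route = ["#P", f"{jobspec.method}/{jobspec.basis}"]
    if jobspec.task == "optimization":
        route.append("Opt=ModRedundant" if jobspec.frozen_dihedrals else "Opt")
    else:
        route.append("SP")
    if jobspec.solvent == "continuum_water":
        route.append(jobspec.solvent_keyword)
    lines.append(" ".join(route))
    lines.append("")
    lines.append("nucleobase assembly deck")
    lines.append("")
    lines.append(f"{jobspec.charge} {jobspec.multiplicity}")
    n_atoms = 0
    ghost_set = set(jobspec.ghost_fragments)
    any_ghost_atom = False
    for idx, base in enumerate(assembly.bases()):
        frag = base.chain or str(idx)
        ghost = frag in ghost_set
        for a in base.atoms:
            el = f"{a.element}-Bq" if ghost else a.element
            x, y, z = a.position
            lines.append(f" {el:<6s} {x:14.6f} {y:14.6f} {z:14.6f}")
            n_atoms += 1
            any_ghost_atom = any_ghost_atom or ghost
    for ion in assembly.ions:
        el = ion.species.rstrip("+")
        x, y, z = ion.position
        lines.append(f" {el:<6s} {x:14.6f} {y:14.6f} {z:14.6f}")
        n_atoms += 1
    if ghost_set and not any_ghost_atom:
        raise ValueError(f"ghost fragments {sorted(ghost_set)} cover no atoms")
    if jobspec.task == "optimization" and jobspec.frozen_dihedrals:
        lines.append("")
        for i, j, k, l in jobspec.frozen_dihedrals:
            for idx in (i, j, k, l):
                if not (1 <= idx <= n_atoms):
                    raise ValueError(f"frozen dihedral references atom {idx} of {n_atoms}")
            lines.append(f"D {i} {j} {k} {l} F")
    lines.append("")
    return "\n".join(lines)


_ENERGY_PATTERNS = (
    re.compile(r"SCF Done:\s+E\([^)]*\)\s*=\s*(-?\d+\.\d+)"),
    re.compile(r"FINAL ENERGY:\s*(-?\d+\.\d+)\s*(?:a\.u\.|hartree)", re.IGNORECASE),
)


def parse_energy(output_text: str, expected_context: dict) -> EnergyRecord:
    """Extract the final energy (hartree) from backend log text.

    Multi-job logs (e.g. optimization followed by a single point) yield the
    last energy; the record notes this in no way beyond being that value.
    ``expected_context`` supplies fragments/basis/geometry/phase labels.
    """
    matches = []
    for pat in _ENERGY_PATTERNS:
        matches += [(m.start(), float(m.group(1))) for m in pat.finditer(output_text)]
    if not matches:
        raise ValueError("no energy found in backend output")
    hartree = max(matches)[1]  # last occurrence in the file
    return EnergyRecord(
        fragments=tuple(expected_context["fragments"]),
        basis_context=expected_context["basis"],
        geometry_context=expected_context["geometry"],
        phase=expected_context.get("phase", "water"),
        energy=hartree * HARTREE_TO_KCAL,
    )


# ---------------------------------------------------------------------------
# mock backend
# ---------------------------------------------------------------------------


def _monomer_energy(fragment_id: str) -> float:
    """Stable pseudo-random monomer energy (kcal/mol), deterministic across
    runs and processes."""
    h = zlib.crc32(fragment_id.encode())
    return -200000.0 - (h % 100000) / 10.0


def mock_records_for_pair(
    pair_id: str,
    delta_pair: float,
    bsse: dict | None = None,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
    phase: str = "water",
) -> RecordSet:
    """Complete record set (monomers, complex, ghost and fragment-basis
    variants) whose ledger evaluation returns ``delta_pair``.

    With ``bsse`` planted per fragment, the uncorrected binding energy is
    inflated accordingly so that counterpoise correction recovers the
    planted value exactly at zero noise.
    """
    rng = rng or np.random.default_rng(0)
    frags = _pair_fragments(pair_id)
    bsse = bsse or {f: 0.0 for f in frags}
    complex_id = tuple(sorted(frags))
    basis = "+".join(sorted(frags))
    records = RecordSet()
    e_mono = {}
    for f in frags:
        e_mono[f] = _monomer_energy(f)
        records.add(
            EnergyRecord(
                fragments=((f, False),),
                basis_context=f,
                geometry_context=f,
                phase=phase,
                energy=e_mono[f],
            )
        )
    noise = float(rng.normal(0.0, noise_sigma)) if noise_sigma > 0 else 0.0
    # raw binding carries the BSSE artifact; CP correction removes it
    e_complex = sum(e_mono.values()) + delta_pair + sum(bsse.values()) + noise
    records.add(
        EnergyRecord(
            fragments=tuple((f, False) for f in complex_id),
            basis_context=basis,
            geometry_context=basis,
            phase=phase,
            energy=e_complex,
        )
    )
    for f in frags:
        others = tuple(sorted(x for x in frags if x != f))
        # fragment in its own basis at the complex geometry
        records.add(
            EnergyRecord(
                fragments=((f, False),),
                basis_context=f,
                geometry_context=basis,
                phase=phase,
                energy=e_mono[f],
            )
        )
        # fragment with ghost partner basis at the complex geometry
        records.add(
            EnergyRecord(
                fragments=((f, False),) + tuple((o, True) for o in others),
                basis_context=basis,
                geometry_context=basis,
                phase=phase,
                energy=e_mono[f] + bsse[f],
            )
        )
    return records


def mock_backend(
    structure_id: str,
    plant_table,
    noise_sigma: float = 0.0,
    seed: int = 0,
    phase: str = "water",
) -> RecordSet:
    """Deterministic mock records for one structure of the plant table.

    ``plant_table`` is a :class:`FixtureTable` or a mapping
    ``structure_id -> component energy``.  The emitted records are shaped so
    that the matching ledger operation (``delta_pair``, ``delta_hoogsteen``,
    ``delta_tetrad``, ``delta_stack``) reproduces the planted component
    exactly at zero noise, and within seeded Gaussian noise otherwise.
    """
    rng = np.random.default_rng(seed)

    def planted(sid: str) -> float:
        if isinstance(plant_table, FixtureTable):
            return plant_table.total(sid)
        if sid not in plant_table:
            raise KeyError(f"structure id {sid!r} absent from plant table")
        return float(plant_table[sid])

    def jitter() -> float:
        return float(rng.normal(0.0, noise_sigma)) if noise_sigma > 0 else 0.0

    cls = _structure_class(structure_id, plant_table)
    if cls == "pair":
        return mock_records_for_pair(
            structure_id, planted(structure_id), noise_sigma=noise_sigma, rng=rng, phase=phase
        )

    records = RecordSet()

    def add_simple(system_id: str, energy: float) -> None:
        records.add(
            EnergyRecord(
                fragments=((system_id, False),),
                basis_context=system_id,
                geometry_context=system_id,
                phase=phase,
                energy=energy,
            )
        )

    if cls == "hoogsteen":
        e_bases = _monomer_energy(structure_id + ":bases")
        de_pair = -10.0  # embedded-pair term; any fixed value cancels exactly
        add_simple(structure_id + ":bases", e_bases)
        add_simple(structure_id + ":pair", de_pair)
        add_simple(structure_id, e_bases + de_pair + planted(structure_id) + jitter())
    elif cls == "tetrad_ionic":
        e_parts = _monomer_energy(structure_id + ":parts")
        add_simple(structure_id + ":parts", e_parts)
        add_simple(structure_id, e_parts + planted(structure_id) + jitter())
    elif cls in ("stack", "sum_ionic"):
        e_parts = _monomer_energy(structure_id + ":parts")
        add_simple(structure_id + ":parts", e_parts)
        add_simple(structure_id, e_parts + planted(structure_id) + jitter())
    else:
        raise KeyError(f"structure id {structure_id!r} absent from plant table")
    return records


def _structure_class(structure_id: str, plant_table) -> str:
    if isinstance(plant_table, FixtureTable):
        return plant_table.row(structure_id).cls
    if "/" in structure_id:
        return "stack"
    if structure_id.startswith("G4_"):
        return "sum_ionic" if structure_id.endswith("_G4") else "tetrad_ionic"
    if "." in structure_id:
        return "hoogsteen"
    return "pair"
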