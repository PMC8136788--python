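"""Structure factors of nucleobase assemblies: HBL, GVA, TA and friends.

Three scalar factors summarize how a base assembly is put together:

* **HBL** (hydrogen bond length) — the hydrogen-to-acceptor distance of an
  inter-base hydrogen bond; experimental Watson-Crick pairs average ~1.90 A.
* **GVA** (glycosidic vector angle) — the angle between the glycosidic
  vectors of two paired bases (anchor nitrogen toward C1', or toward the
  replacement hydrogen in backbone-stripped models); ~72 deg for an ideal
  duplex pair.
* **TA** (twist angle) — the rotation of one stacked layer relative to
  another about the stacking axis; 36 deg for ideal B-DNA.

All metrics are functions of relative geometry only, so they are invariant
under rigid motions of the whole assembly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import HOOGSTEEN_EDGE, WC_EDGE, Assembly, PlacedBase

__all__ = [
    "HydrogenBond",
    "PairGeometry",
    "StackGeometry",
    "IonBondSet",
    "HBondCriteria",
    "detect_hbonds",
    "glycosidic_vector",
    "compute_gva",
    "compute_ta",
    "planarity",
    "ion_bonds",
    "pair_geometry",
    "classify_edge",
]


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric acceptance window for hydrogen-bond detection."""

    max_hbl: float = 2.5  # A, H...acceptor
    min_dha: float = 120.0  # deg, donor-H...acceptor


@dataclass(frozen=True)
class HydrogenBond:
    donor_base: int  # index into the layer's base list
    acceptor_base: int
    donor_atom: str  # donor heavy atom name
    hydrogen: str
    acceptor_atom: str
    hbl: float  # A
    dha: float  # deg
    bond_class: str  # NH-N | NH-O | other

    def involves(self, base_index: int) -> bool:
        return base_index in (self.donor_base, self.acceptor_base)


@dataclass(frozen=True)
class PairGeometry:
    base_indices: tuple
    bonds: tuple
    mean_hbl: float | None
    gva: float
    edge: str  # watson_crick | mismatch | hoogsteen | reversed_hoogsteen


@dataclass(frozen=True)
class StackGeometry:
    layer_indices: tuple
    ta: float  # deg
    rise: float  # A
    planarity_rms: tuple  # per-layer RMS, A


@dataclass(frozen=True)
class IonBondSet:
    ion_index: int
    species: str
    distances: tuple  # A, to guanine O6 within the cap
    in_plane: bool


_ION_DISTANCE_CAP = 4.0  # A
_IN_PLANE_OFFSET = 0.5  # A, axial offset below which an ion counts as in-plane


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------


def _donor_heavy_for(base: PlacedBase, hname: str) -> str:
    """Heavy atom covalently carrying the given hydrogen."""
    hpos = base.atom(hname).position
    best, best_d = None, np.inf
    for a in base.atoms:
        if a.element == "H":
            continue
        d = float(np.linalg.norm(a.position - hpos))
        if d < best_d:
            best, best_d = a.name, d
    if best is None or best_d > 1.3:
        raise ValueError(f"hydrogen {hname} has no covalent parent")
    return best


def detect_hbonds(
    assembly: Assembly,
    layer_index: int = 0,
    criteria: HBondCriteria = HBondCriteria(),
) -> list:
    """All inter-base hydrogen bonds within one layer.

    A bond is a donor hydrogen (from the donor table of the base variant)
    within ``criteria.max_hbl`` of an acceptor atom of another base, with
    donor-H...acceptor angle at least ``criteria.min_dha``.  Bonds are sorted
    by donor atom name, then base index.
    """
    layer = assembly.layers[layer_index]
    for b in layer:
        if not any(a.element == "H" for a in b.atoms):
            raise ValueError(
                "layer contains bases without hydrogens; rebuild them first "
                "(survey.rebuild_hydrogens)"
            )
    bonds = []
    for i, donor in enumerate(layer):
        for hname in donor.template.donor_hydrogens:
            if not donor.has_atom(hname):
                continue
            hpos = donor.atom(hname).position
            dheavy = _donor_heavy_for(donor, hname)
            dpos = donor.atom(dheavy).position
            for j, acc in enumerate(layer):
                if i == j:
                    continue
                for aname in acc.template.acceptor_atoms:
                    if not acc.has_atom(aname):
                        continue
                    apos = acc.atom(aname).position
                    hbl = float(np.linalg.norm(apos - hpos))
                    if hbl > criteria.max_hbl:
                        continue
                    v1 = dpos - hpos
                    v2 = apos - hpos
                    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    dha = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
                    if dha < criteria.min_dha:
                        continue
                    bclass = (
                        "NH-N"
                        if dheavy.startswith("N") and aname.startswith("N")
                        else "NH-O"
                        if dheavy.startswith("N") and aname.startswith("O")
                        else "other"
                    )
                    bonds.append(
                        HydrogenBond(
                            donor_base=i,
                            acceptor_base=j,
                            donor_atom=dheavy,
                            hydrogen=hname,
                            acceptor_atom=aname,
                            hbl=hbl,
                            dha=dha,
                            bond_class=bclass,
                        )
                    )
    bonds.sort(key=lambda b: (b.donor_atom, b.donor_base, b.acceptor_base, b.acceptor_atom))
    return bonds


# ---------------------------------------------------------------------------
# glycosidic vectors and angles
# ---------------------------------------------------------------------------


def glycosidic_vector(base: PlacedBase) -> np.ndarray:
    """Unit vector from the glycosidic anchor toward C1' (or its stand-in H).

    Backbone-stripped models use the hydrogen that replaces the sugar; parsed
    structures with an intact backbone use the C1' atom.
    """
    anchor_name = base.template.anchor_name
    if not base.has_atom(anchor_name):
        raise ValueError(f"base has no glycosidic anchor {anchor_name}")
    anchor = base.atom(anchor_name).position
    if base.has_atom("C1'"):
        endpoint = base.atom("C1'").position
    elif base.has_atom(base.template.substituent_name):
        endpoint = base.atom(base.template.substituent_name).position
    else:
        raise ValueError("base has neither C1' nor a glycosidic substituent H")
    v = endpoint - anchor
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("degenerate glycosidic vector")
    return v / n


def compute_gva(base_a: PlacedBase, base_b: PlacedBase) -> float:
    """Angle (deg, in [0, 180]) between two glycosidic vectors."""
    va, vb = glycosidic_vector(base_a), glycosidic_vector(base_b)
    return float(np.degrees(np.arccos(np.clip(np.dot(va, vb), -1.0, 1.0))))


def classify_edge(donor_acceptor_atoms: Sequence, purine: PlacedBase | None, gva: float) -> str:
    """Label a bond set by the purine edge it engages.

    ``donor_acceptor_atoms`` are the purine-side heavy atoms that participate.
    Hoogsteen-edge participation (N7/O6 for G, N7 for A) labels the pair
    hoogsteen, or reversed_hoogsteen when the glycosidic vectors are
    near-antiparallel (GVA > 120 deg).
    """
    if purine is None:
        return "mismatch"
    hg = set(HOOGSTEEN_EDGE.get(purine.identity, ()))
    wc = set(WC_EDGE.get(purine.key, WC_EDGE.get(purine.identity, ())))
    atoms = set(donor_acceptor_atoms)
    if atoms & {"N7"}:
        return "reversed_hoogsteen" if gva > 120.0 else "hoogsteen"
    if atoms & (wc - hg):
        return "watson_crick"
    return "mismatch"


def pair_geometry(
    assembly: Assembly,
    layer_index: int,
    i: int,
    j: int,
    criteria: HBondCriteria = HBondCriteria(),
) -> PairGeometry:
    """HBL/GVA record for one base pair within a layer."""
    layer = assembly.layers[layer_index]
    bonds = [
        b
        for b in detect_hbonds(assembly, layer_index, criteria)
        if {b.donor_base, b.acceptor_base} == {i, j}
    ]
    gva = compute_gva(layer[i], layer[j])
    mean_hbl = float(np.mean([b.hbl for b in bonds])) if bonds else None
    # canonical complements imply watson_crick when no Hoogsteen-edge atom acts
    purine = next((layer[k] for k in (i, j) if layer[k].identity in ("A", "G")), None)
    purine_idx = next((k for k in (i, j) if layer[k].identity in ("A", "G")), None)
    atoms = []
    for b in bonds:
        if b.donor_base == purine_idx:
            atoms.append(b.donor_atom)
        if b.acceptor_base == purine_idx:
            atoms.append(b.acceptor_atom)
    edge = classify_edge(atoms, purine, gva)
    if edge == "watson_crick" and frozenset((layer[i].identity, layer[j].identity)) not in (
        frozenset(("G", "C")),
        frozenset(("A", "T")),
    ):
        edge = "mismatch"
    return PairGeometry(
        base_indices=(i, j), bonds=tuple(bonds), mean_hbl=mean_hbl, gva=gva, edge=edge
    )


# ---------------------------------------------------------------------------
# planes, twist, rise
# ---------------------------------------------------------------------------


def _best_fit_normal(points: np.ndarray) -> np.ndarray:
    c = points.mean(axis=0)
    _, s, Vt = np.linalg.svd(points - c)
    if s[1] < 1e-9:  # collinear
        raise ValueError("degenerate (collinear) atom set: no unique plane")
    return Vt[2]


def planarity(assembly: Assembly, layer_index: int) -> float:
    """RMS distance (A) of a layer's atoms to their least-squares plane."""
    pts = np.vstack([b.positions() for b in assembly.layers[layer_index]])
    if len(pts) < 3:
        raise ValueError("need at least 3 atoms for a plane")
    n = _best_fit_normal(pts)
    d = (pts - pts.mean(axis=0)) @ n
    return float(np.sqrt(np.mean(d**2)))


def compute_ta(assembly: Assembly, lower_layer: int = 0, upper_layer: int = 1) -> StackGeometry:
    """Twist angle and rise between two layers.

    The stacking axis is the mean of the two layers' best-fit plane normals
    (sign-aligned); each layer is close to planar, so its own normal is
    well-conditioned, whereas a plane fitted through both layers pooled tips
    over once the rise rivals the in-plane spread.  Each base of the lower
    layer is matched to the base at the same position in the upper layer;
    the per-base twist is the
    angle between the two glycosidic vectors projected onto the plane
    orthogonal to the axis, and TA is their mean (unsigned, in [0, 180]).
    Rise is the distance between layer centroids along the axis.
    """
    lo = assembly.layers[lower_layer]
    up = assembly.layers[upper_layer]
    if len(lo) != len(up):
        raise ValueError("layers have different base counts; no implicit matching")
    pts_lo = np.vstack([b.positions() for b in lo])
    pts_up = np.vstack([b.positions() for b in up])
    n_lo = _best_fit_normal(pts_lo)
    n_up = _best_fit_normal(pts_up)
    if np.dot(n_lo, n_up) < 0:
        n_up = -n_up
    axis = n_lo + n_up
    axis = axis / np.linalg.norm(axis)
    angles = []
    for b_lo, b_up in zip(lo, up):
        v1 = glycosidic_vector(b_lo)
        v2 = glycosidic_vector(b_up)
        p1 = v1 - np.dot(v1, axis) * axis
        p2 = v2 - np.dot(v2, axis) * axis
        n1, n2 = np.linalg.norm(p1), np.linalg.norm(p2)
        if n1 < 1e-12 or n2 < 1e-12:
            raise ValueError("glycosidic vector parallel to the stacking axis")
        cosang = np.dot(p1, p2) / (n1 * n2)
        angles.append(float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))))
    rise = float(abs(np.dot(pts_up.mean(axis=0) - pts_lo.mean(axis=0), axis)))
    rms = tuple(planarity(assembly, k) for k in (lower_layer, upper_layer))
    return StackGeometry(
        layer_indices=(lower_layer, upper_layer),
        ta=float(np.mean(angles)),
        rise=rise,
        planarity_rms=rms,
    )


# ---------------------------------------------------------------------------
# ion bonds
# ---------------------------------------------------------------------------


def ion_bonds(assembly: Assembly) -> list:
    """Distances from each ion to guanine O6 oxygens within 4.0 A.

    ``in_plane`` is true when the ion's axial offset from the nearest layer's
    best-fit plane is below 0.5 A.
    """
    if not assembly.ions:
        raise ValueError("assembly has no ions")
    out = []
    layer_planes = []
    for layer in assembly.layers:
        pts = np.vstack([b.positions() for b in layer])
        layer_planes.append((pts.mean(axis=0), _best_fit_normal(pts)))
    o6 = [
        a.position
        for b in assembly.bases()
        if b.identity == "G"
        for a in b.atoms
        if a.name == "O6"
    ]
    for idx, ion in enumerate(assembly.ions):
        dists = sorted(
            float(np.linalg.norm(ion.position - p))
            for p in o6
            if np.linalg.norm(ion.position - p) <= _ION_DISTANCE_CAP
        )
        offset = min(abs(float(np.dot(ion.position - c, n))) for c, n in layer_planes)
        out.append(
            IonBondSet(
                ion_index=idx,
                species=ion.species,
                distances=tuple(dists),
                in_plane=offset < _IN_PLANE_OFFSET,
            )
        )
    return out
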