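"""Idealized nucleobase assemblies: templates, pairs, triads, tetrads, stacks.

Backbone-free model building for duplex, triplex and quadruplex motifs. The
sugar/phosphate backbone of each nucleoside is replaced by a single hydrogen
on the glycosidic nitrogen (N9 for purines, N1 for pyrimidines), so a base is
a small planar molecule and a model structure is a set of rigidly placed
bases, optionally with monovalent ions.

Conventions (right-handed Cartesian, Angstrom):
    * a base template lies in the xy-plane, glycosidic anchor at the origin,
      glycosidic substituent H along -y;
    * layers of a built stack are bottom-to-top along +z;
    * rotations are counterclockwise viewed from +z.

Pairing places the second base in the plane of the first so that the
requested edge's donor-H...acceptor contacts are linear with an ideal
H...acceptor distance of 1.90 A (least-squares over the in-plane rigid
motions, both parities).  Since a planar base is achiral, an in-plane
reflection is the same physical operation as flipping the base over about an
in-plane axis; the ``flipped`` flag of reversed-Hoogsteen ("r") variants
selects that other parity branch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Sequence

import numpy as np

__all__ = [
    "AtomSite",
    "BaseTemplate",
    "PlacedBase",
    "Ion",
    "Assembly",
    "load_template",
    "build_pair",
    "build_triad",
    "build_tetrad",
    "build_stack",
    "flip_base",
    "IDEAL_HBL",
    "ION_SPECIES",
]

IDEAL_HBL = 1.90  # target H...acceptor distance when placing a pair, A
ION_SPECIES = ("Li+", "Na+", "K+")

# ---------------------------------------------------------------------------
# atom-level chemistry tables
# ---------------------------------------------------------------------------

# hydrogen-bond acceptor heavy atoms per base identity
_ACCEPTORS = {
    "A": ("N1", "N3", "N7"),
    "G": ("N3", "N7", "O6"),
    "C": ("N3", "O2"),
    "C+": ("O2",),  # N3 is protonated, no longer an acceptor
    "T": ("O2", "O4"),
}

# donor hydrogens (name of H atom) per base identity
_DONOR_HS = {
    "A": ("H61", "H62"),
    "G": ("H1", "H21", "H22"),
    "C": ("H41", "H42"),
    "C+": ("H41", "H42", "H3"),
    "T": ("H3",),
}

_CARBONYL_O = {"O2", "O4", "O6"}
_RING_ATOMS = {
    "A": ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9"),
    "G": ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9"),
    "C": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "T": ("N1", "C2", "N3", "C4", "C5", "C6"),
}

# Watson-Crick and Hoogsteen edge heavy atoms (for edge classification)
WC_EDGE = {
    "A": ("N1", "N6"),
    "G": ("N1", "N2", "O6"),
    "C": ("N3", "N4", "O2"),
    "C+": ("N3", "N4", "O2"),
    "T": ("N3", "O4", "O2"),
}
HOOGSTEEN_EDGE = {"A": ("N7", "N6"), "G": ("N7", "O6")}

# Hydrogen-bond specs per pairing: (donor_base, donor_heavy, acceptor_base,
# acceptor_heavy), with base index 0/1 in the order of the key.  Watson-Crick
# keys are ordered as printed in the component-energy tables; Hoogsteen keys
# are (third_base, purine).
_WC_BONDS = {
    ("G", "C"): [(0, "N1", 1, "N3"), (0, "N2", 1, "O2"), (1, "N4", 0, "O6")],
    ("A", "T"): [(0, "N6", 1, "O4"), (1, "N3", 0, "N1")],
    ("G", "T"): [(0, "N1", 1, "O2"), (1, "N3", 0, "O6")],
    ("G", "G"): [(0, "N1", 1, "O6"), (1, "N1", 0, "O6")],
    ("C", "T"): [(0, "N4", 1, "O2"), (1, "N3", 0, "N3")],
    ("T", "T"): [(0, "N3", 1, "O2"), (1, "N3", 0, "O2")],
    ("A", "G"): [(0, "N6", 1, "O6"), (1, "N1", 0, "N1")],
    ("A", "C"): [(0, "N6", 1, "N3"), (1, "N4", 0, "N1")],
    ("A", "A"): [(0, "N6", 1, "N1"), (1, "N6", 0, "N1")],
    ("C", "C"): [(0, "N4", 1, "N3")],
}
_HG_BONDS = {
    ("T", "A"): [(0, "N3", 1, "N7"), (1, "N6", 0, "O4")],
    ("C+", "G"): [(0, "N3", 1, "N7"), (0, "N4", 1, "O6")],
    ("G", "G"): [(0, "N1", 1, "O6"), (0, "N2", 1, "N7")],
    ("A", "A"): [(0, "N6", 1, "N7"), (1, "N6", 0, "N7")],
}
# Reversed-Hoogsteen ("r") variants: the flipped third base presents the same
# donors but reaches the other acceptor of the purine edge (O2 instead of O4
# for T; N7/O6 swapped for C+ and G).
_HG_BONDS_FLIPPED = {
    ("T", "A"): [(0, "N3", 1, "N7"), (1, "N6", 0, "O2")],
    ("C+", "G"): [(0, "N4", 1, "N7"), (0, "N3", 1, "O6")],
    ("G", "G"): [(0, "N1", 1, "N7"), (0, "N2", 1, "O6")],
    ("A", "A"): [(0, "N6", 1, "N7"), (1, "N6", 0, "N7")],
}

# Parity convention: each template has a fixed ring-winding sense in its
# standard frame, so coplanar placement of the second base is either the
# proper-rotation branch (same winding) or the reflected branch (opposite
# winding; for a planar molecule an in-plane reflection is the physical
# flip about an in-plane axis).  A Watson-Crick pair joins bases of opposite
# winding (antiparallel strands); a Hoogsteen pair in a parallel triplex
# joins bases of equal winding.  ``flipped`` toggles the branch.
_DEFAULT_PARITY = {"watson_crick": -1.0, "hoogsteen": 1.0}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AtomSite:
    """One atom of a base: PDB-style name, element and position with role tags."""

    name: str
    element: str
    position: np.ndarray
    roles: frozenset = frozenset()

    def moved(self, position: np.ndarray) -> "AtomSite":
        return replace(self, position=np.asarray(position, float))


@dataclass(frozen=True)
class BaseTemplate:
    """Idealized geometry of one nucleobase variant in the standard frame."""

    identity: str  # A | T | G | C
    protonated: bool
    backbone_stripped: bool
    atoms: tuple

    @property
    def key(self) -> str:
        """Identity key including protonation, e.g. 'C+'."""
        return self.identity + ("+" if self.protonated else "")

    def atom(self, name: str) -> AtomSite:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"{self.key} has no atom {name!r}")

    @property
    def anchor_name(self) -> str:
        return "N9" if self.identity in ("A", "G") else "N1"

    @property
    def substituent_name(self) -> str:
        return "H9" if self.identity in ("A", "G") else "H1"

    @property
    def donor_hydrogens(self) -> tuple:
        return _DONOR_HS[self.key]

    @property
    def acceptor_atoms(self) -> tuple:
        return _ACCEPTORS[self.key]

    def hydrogens_of(self, heavy: str) -> list:
        """Donor hydrogens bonded to the given heavy atom (by name pattern)."""
        out = []
        for h in _DONOR_HS[self.key]:
            if h[1] == heavy[1]:  # H1<->N1, H21/H22<->N2, H41<->N4, ...
                out.append(h)
        return out


@dataclass
class PlacedBase:
    """A base with concrete coordinates inside an assembly."""

    template: BaseTemplate
    atoms: list
    flipped: bool = False
    chain: str = ""
    seqid: int = 0

    @property
    def identity(self) -> str:
        return self.template.identity

    @property
    def key(self) -> str:
        return self.template.key

    def atom(self, name: str) -> AtomSite:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"{self.key} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "PlacedBase":
        R = np.asarray(R, float)
        t = np.asarray(t, float)
        return PlacedBase(
            template=self.template,
            atoms=[a.moved(R @ a.position + t) for a in self.atoms],
            flipped=self.flipped,
            chain=self.chain,
            seqid=self.seqid,
        )


@dataclass
class Ion:
    species: str
    position: np.ndarray


@dataclass
class Assembly:
    """Layers of placed bases plus optional ions.

    ``layers`` is ordered bottom-to-top along +z for built assemblies.
    ``metadata`` records construction parameters (rise, twist) when built.
    """

    layers: list
    ions: list = field(default_factory=list)
    provenance: str = "built"
    metadata: dict = field(default_factory=dict)

    def bases(self) -> list:
        return [b for layer in self.layers for b in layer]

    def all_positions(self) -> np.ndarray:
        pts = [b.positions() for b in self.bases()]
        if self.ions:
            pts.append(np.array([i.position for i in self.ions]))
        return np.vstack(pts)

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "Assembly":
        R = np.asarray(R, float)
        t = np.asarray(t, float)
        return Assembly(
            layers=[[b.transformed(R, t) for b in layer] for layer in self.layers],
            ions=[Ion(i.species, R @ i.position + t) for i in self.ions],
            provenance=self.provenance,
            metadata=dict(self.metadata),
        )


# ---------------------------------------------------------------------------
# template loading
# ---------------------------------------------------------------------------

_TEMPLATE_CACHE: dict = {}


def _roles_for(key: str, name: str, element: str) -> frozenset:
    ident = key[0]
    roles = set()
    if name in _RING_ATOMS.get(ident, ()):
        roles.add("ring")
    if name in _ACCEPTORS[key]:
        roles.add("hbond_acceptor")
    if name in _DONOR_HS[key]:
        roles.add("hbond_donor")
    if name in _CARBONYL_O and element == "O":
        roles.add("carbonyl_oxygen")
    anchor = "N9" if ident in ("A", "G") else "N1"
    if name == anchor:
        roles.add("glycosidic_anchor")
    if name == "H" + anchor[1]:
        roles.add("glycosidic_substituent")
    return frozenset(roles)


def _read_template_file() -> dict:
    data = {}
    text = resources.files("dnastack.data").joinpath("base_templates.tsv").read_text()
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("base\t"):
            continue
        base, name, element, x, y, z = line.split("\t")
        data.setdefault(base, []).append(
            AtomSite(
                name=name,
                element=element,
                position=np.array([float(x), float(y), float(z)]),
                roles=_roles_for(base, name, element),
            )
        )
    return data


def load_template(identity: str, protonated: bool = False, backbone_stripped: bool = True) -> BaseTemplate:
    """Return the idealized template for one nucleobase variant.

    ``protonated`` is valid only for cytosine (the C+ of C+.G-C triads);
    ``backbone_stripped`` templates carry a hydrogen in place of C1'.
    """
    if identity not in ("A", "T", "G", "C"):
        raise ValueError(f"unknown base identity {identity!r}")
    if protonated and identity != "C":
        raise ValueError("protonated templates exist only for cytosine")
    if not backbone_stripped:
        raise ValueError("only backbone-stripped templates are bundled")
    key = identity + ("+" if protonated else "")
    if key not in _TEMPLATE_CACHE:
        data = _read_template_file()
        _TEMPLATE_CACHE.update(
            {
                k: BaseTemplate(
                    identity=k[0],
                    protonated=k.endswith("+"),
                    backbone_stripped=True,
                    atoms=tuple(v),
                )
                for k, v in data.items()
            }
        )
    return _TEMPLATE_CACHE[key]


def template_from_key(key: str) -> BaseTemplate:
    return load_template(key[0], protonated=key.endswith("+"))


# ---------------------------------------------------------------------------
# placement engine
# ---------------------------------------------------------------------------


def _flip_matrix() -> np.ndarray:
    # 180 deg rotation about the template's glycosidic (y) axis
    return np.diag([-1.0, 1.0, -1.0])


def flip_base(base: PlacedBase) -> PlacedBase:
    """Rotate a placed base 180 deg about its own glycosidic vector axis."""
    anchor = base.atom(base.template.anchor_name).position
    sub = base.atom(base.template.substituent_name).position
    axis = sub - anchor
    axis = axis / np.linalg.norm(axis)
    # Rodrigues for theta = pi: R = 2 aa^T - I
    R = 2.0 * np.outer(axis, axis) - np.eye(3)
    out = base.transformed(R, anchor - R @ anchor)
    out.flipped = not base.flipped
    return out


def _placed_from_template(tpl: BaseTemplate) -> PlacedBase:
    return PlacedBase(template=tpl, atoms=list(tpl.atoms))


def _neighbor_centroid(base: PlacedBase, heavy: str) -> np.ndarray:
    """Centroid of covalent heavy-atom neighbors of ``heavy`` (distance < 1.7 A)."""
    p = base.atom(heavy).position
    nbrs = [
        a.position
        for a in base.atoms
        if a.name != heavy and a.element != "H" and np.linalg.norm(a.position - p) < 1.7
    ]
    if not nbrs:
        raise ValueError(f"no covalent neighbors found for {heavy}")
    return np.mean(nbrs, axis=0)


def _kabsch2d(moving: np.ndarray, target: np.ndarray) -> tuple:
    """Proper 2D rotation + translation minimizing |R m + t - g|^2."""
    mc, gc = moving.mean(axis=0), target.mean(axis=0)
    M = (target - gc).T @ (moving - mc)
    U, _, Vt = np.linalg.svd(M)
    d = np.sign(np.linalg.det(U @ Vt))
    R = U @ np.diag([1.0, d]) @ Vt
    t = gc - R @ mc
    rss = float(np.sum((moving @ R.T + t - target) ** 2))
    return R, t, rss


def _bond_correspondences(
    fixed: PlacedBase, moving: PlacedBase, bonds: Sequence, h_choice: dict
) -> tuple:
    """Build correspondence points for a bond list.

    ``bonds`` entries are (donor_idx, donor_heavy, acceptor_idx, acceptor_heavy)
    with 0 = fixed base, 1 = moving base.  ``h_choice`` maps (base_idx, heavy)
    to the selected donor hydrogen name.

    Returns (moving template points, initial fixed-frame targets, updaters)
    where each updater recomputes the target of one point from the current
    placement of the moving base (used to make donor-on-moving-base bonds
    linear without prescribing the acceptor lone-pair direction, which is
    ill-defined for carbonyl oxygens).
    """
    mov_pts, tgt_pts, updaters = [], [], []
    for di, dheavy, ai, aheavy in bonds:
        if di == 0:  # donor fixed, acceptor on the moving base
            hname = h_choice[(0, dheavy)]
            hpos = fixed.atom(hname).position
            dpos = fixed.atom(dheavy).position
            u = hpos - dpos
            u /= np.linalg.norm(u)
            acc_target = hpos + IDEAL_HBL * u
            acc_tpl = moving.atom(aheavy).position
            mov_pts.append(acc_tpl)
            tgt_pts.append(acc_target)
            updaters.append(None)
            if not aheavy.startswith("O"):
                # ring-N acceptor: lone pair antiparallel to the bond
                nbc_tpl = _neighbor_centroid(moving, aheavy)
                d_nb = np.linalg.norm(acc_tpl - nbc_tpl)
                mov_pts.append(nbc_tpl)
                tgt_pts.append(acc_target + d_nb * u)
                updaters.append(None)
        else:  # donor on the moving base, acceptor fixed
            apos = fixed.atom(aheavy).position
            v = apos - _neighbor_centroid(fixed, aheavy)
            v /= np.linalg.norm(v)
            hname = h_choice[(1, dheavy)]
            h_tpl = moving.atom(hname).position
            d_tpl = moving.atom(dheavy).position
            dDH = np.linalg.norm(h_tpl - d_tpl)
            i0 = len(mov_pts)
            mov_pts += [h_tpl, d_tpl]
            # initial guess: along the acceptor's neighbor-centroid axis
            tgt_pts += [apos + IDEAL_HBL * v, apos + (IDEAL_HBL + dDH) * v]

            def make_updater(i0, apos, d_tpl_idx_pos, dDH):
                def update(targets, place):
                    d_now = place(d_tpl_idx_pos)
                    w = apos - d_now
                    w /= np.linalg.norm(w)
                    targets[i0] = apos - IDEAL_HBL * w
                    targets[i0 + 1] = apos - (IDEAL_HBL + dDH) * w

                return update

            updaters.append(make_updater(i0, apos, d_tpl, dDH))
            updaters.append(None)
    return np.array(mov_pts), np.array(tgt_pts), [u for u in updaters if u]


def _h_choices(fixed: PlacedBase, moving: PlacedBase, bonds: Sequence) -> list:
    """All combinations of donor-hydrogen selections for amino donors."""
    keys, options = [], []
    for di, dheavy, _, _ in bonds:
        base = fixed if di == 0 else moving
        hs = base.template.hydrogens_of(dheavy)
        if not hs:
            raise ValueError(f"{base.key} has no donor hydrogen on {dheavy}")
        keys.append((di, dheavy))
        options.append(hs)
    combos = [{}]
    for k, opts in zip(keys, options):
        combos = [{**c, k: h} for c in combos for h in opts]
    return combos


def _fit_moving_base(fixed: PlacedBase, moving_tpl: PlacedBase, bonds, parity: float) -> tuple:
    """Best in-plane placement of ``moving_tpl`` against ``fixed`` for one parity."""
    S = np.diag([parity, 1.0, parity])  # in-plane reflection (= physical flip)
    mirrored = moving_tpl.transformed(S, np.zeros(3))
    best = None
    for h_choice in _h_choices(fixed, mirrored, bonds):
        mov, tgt, updaters = _bond_correspondences(fixed, mirrored, bonds, h_choice)
        R2, t2, rss = _kabsch2d(mov[:, :2], tgt[:, :2])
        for _ in range(30):  # linearize donor-on-moving bonds iteratively
            if not updaters:
                break

            def place(p, R2=R2, t2=t2):
                return np.array([*(R2 @ p[:2] + t2), 0.0])

            for upd in updaters:
                upd(tgt, place)
            R2, t2, rss = _kabsch2d(mov[:, :2], tgt[:, :2])
        if best is None or rss < best[2]:
            best = (R2, t2, rss, h_choice)
    R2, t2, rss, h_choice = best
    R = np.eye(3)
    R[:2, :2] = R2
    t = np.array([t2[0], t2[1], 0.0])
    placed = mirrored.transformed(R, t)
    placed.flipped = parity < 0 and not moving_tpl.flipped
    return placed, rss


def _pair_bond_spec(key1: str, key2: str, edge: str, flipped: bool = False) -> tuple:
    if edge == "watson_crick":
        table = _WC_BONDS
    else:
        table = _HG_BONDS_FLIPPED if flipped else _HG_BONDS
    k1 = key1 if key1 in ("C+",) else key1[0]
    k2 = key2 if key2 in ("C+",) else key2[0]
    if (k1, k2) in table:
        return table[(k1, k2)], False
    if (k2, k1) in table:
        # swap base roles in the bond list
        swapped = [(1 - di, dh, 1 - ai, ah) for di, dh, ai, ah in table[(k2, k1)]]
        return swapped, True
    raise ValueError(f"no donor/acceptor complementarity for {k1}/{k2} on {edge} edge")


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------


def build_pair(
    template1: BaseTemplate,
    template2: BaseTemplate,
    edge: str = "watson_crick",
    flipped_second: bool = False,
) -> Assembly:
    """Place two bases coplanar with donors facing acceptors across ``edge``.

    The first base sits in its standard frame; the second is fitted by
    least squares so every specified hydrogen bond is linear at 1.90 A.
    ``flipped_second`` turns the second base over about its glycosidic axis
    first (the reversed-Hoogsteen "r" construction).
    """
    if edge not in ("watson_crick", "hoogsteen"):
        raise ValueError(f"unknown edge {edge!r}")
    bonds, _ = _pair_bond_spec(template1.key, template2.key, edge, flipped_second)
    fixed = _placed_from_template(template1)
    moving = _placed_from_template(template2)
    parity = _DEFAULT_PARITY[edge] * (-1.0 if flipped_second else 1.0)
    placed2, _ = _fit_moving_base(fixed, moving, bonds, parity)
    placed2.flipped = flipped_second
    fixed.chain, placed2.chain = "A", "B"
    return Assembly(layers=[[fixed, placed2]], provenance="built", metadata={"edge": edge})


def build_triad(pair_assembly: Assembly, third_template: BaseTemplate, flipped: bool = False) -> Assembly:
    """Add a third base at the Hoogsteen edge of the pair's purine.

    Supported triads: C+.G-C, T.A-T, G.G-C, A.A-T and their flipped
    ("r") variants.
    """
    if len(pair_assembly.layers) != 1 or len(pair_assembly.layers[0]) != 2:
        raise ValueError("triad construction needs a single two-base layer")
    layer = pair_assembly.layers[0]
    purines = [b for b in layer if b.identity in ("A", "G")]
    if not purines:
        raise ValueError("pair has no purine with a Hoogsteen edge")
    purine = purines[0]
    key = (third_template.key if third_template.key == "C+" else third_template.identity, purine.identity)
    if key not in _HG_BONDS:
        raise ValueError(f"unsupported triad: no Hoogsteen complementarity for {key[0]} on {key[1]}")
    # bond specs are keyed (third, purine); here the purine is the fixed base
    bonds = [
        (1 - di, dh, 1 - ai, ah)
        for di, dh, ai, ah in (_HG_BONDS_FLIPPED if flipped else _HG_BONDS)[key]
    ]
    moving = _placed_from_template(third_template)
    parity = _DEFAULT_PARITY["hoogsteen"] * (-1.0 if flipped else 1.0)
    placed3, _ = _fit_moving_base(purine, moving, bonds, parity)
    placed3.flipped = flipped
    placed3.chain = "C"
    meta = dict(pair_assembly.metadata)
    meta["triad_third"] = ("r" if flipped else "") + third_template.key
    return Assembly(
        layers=[[layer[0], layer[1], placed3]],
        ions=list(pair_assembly.ions),
        provenance="built",
        metadata=meta,
    )


def build_tetrad(ion_species: str | None = None, out_of_plane: float = 0.0) -> Assembly:
    """Four guanines in C4-cyclic Hoogsteen arrangement, optional central ion.

    Each guanine donates N1-H/N2-H to the next guanine's O6/N7.  The cycle
    center is found by least squares: the second guanine is constrained to be
    an exact 90 deg rotation of the first, so the four Hoogsteen bond sets are
    identical by construction.  The ion sits on the C4 axis, in-plane (z = 0)
    by default, or displaced by ``out_of_plane`` along +z.
    """
    if ion_species is not None and ion_species not in ION_SPECIES:
        raise ValueError(f"unsupported ion species {ion_species!r}")
    g = load_template("G")
    fixed = _placed_from_template(g)
    bonds = _HG_BONDS[("G", "G")]
    # the neighbor guanine is an exact 90 deg copy of the first: solve only
    # the cycle center (the donation cycle closes in one rotation sense only,
    # which depends on the template winding -- try both)
    best = None
    for theta in (math.pi / 2.0, -math.pi / 2.0):
        R2 = np.array(
            [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
        )
        for h_choice in _h_choices(fixed, fixed, bonds):
            mov, tgt, _updaters = _bond_correspondences(fixed, fixed, bonds, h_choice)
            # point p maps to R (p - c) + c ; minimize |R p + (I-R) c - t|^2 over c
            A = np.eye(2) - R2
            b = np.mean(tgt[:, :2] - mov[:, :2] @ R2.T, axis=0)
            c = np.linalg.solve(A, b)
            rss = float(np.sum((mov[:, :2] @ R2.T + (A @ c) - tgt[:, :2]) ** 2))
            if best is None or rss < best[2]:
                best = (c, theta, rss)
    c2, theta, _ = best
    center = np.array([c2[0], c2[1], 0.0])
    # place the four guanines by successive 90 deg rotations about the center
    bases = []
    for k, chain in enumerate("ABCD"):
        ang = k * theta
        Rk = np.array(
            [
                [math.cos(ang), -math.sin(ang), 0.0],
                [math.sin(ang), math.cos(ang), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        b = fixed.transformed(Rk, center - Rk @ center)
        b.chain = chain
        bases.append(b)
    assembly = Assembly(
        layers=[bases],
        provenance="built",
        metadata={"kind": "tetrad", "ion_in_plane": out_of_plane == 0.0},
    )
    # recenter: C4 axis through the origin
    assembly = assembly.transformed(np.eye(3), -center)
    if ion_species is not None:
        assembly.ions.append(Ion(ion_species, np.array([0.0, 0.0, float(out_of_plane)])))
    return assembly


def build_stack(
    layer_assemblies: Sequence[Assembly],
    rise: float = 3.4,
    twist: float = 36.0,
    ion_species: str | None = None,
) -> Assembly:
    """Stack single-layer assemblies at the given rise and twist.

    Layer k is rotated by k * twist (deg, counterclockwise from +z) about the
    vertical axis through its in-plane centroid and translated to z = k * rise.
    With ``ion_species`` a single ion is placed on the axis midway between the
    first two layers (the out-of-plane quadruplex arrangement); per-layer ions
    of the inputs are kept where they are.
    """
    if not layer_assemblies:
        raise ValueError("empty layer list")
    if rise <= 0:
        raise ValueError("rise must be positive")
    if ion_species is not None and ion_species not in ION_SPECIES:
        raise ValueError(f"unsupported ion species {ion_species!r}")
    layers, ions = [], []
    for k, asm in enumerate(layer_assemblies):
        if len(asm.layers) != 1:
            raise ValueError("build_stack expects single-layer assemblies")
        pts = np.vstack([b.positions() for b in asm.layers[0]])
        centroid = pts.mean(axis=0)
        ang = math.radians(k * twist)
        Rk = np.array(
            [
                [math.cos(ang), -math.sin(ang), 0.0],
                [math.sin(ang), math.cos(ang), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        # center in-plane, rotate, lift to k * rise
        t = np.array([0.0, 0.0, k * rise])
        shift = -np.array([centroid[0], centroid[1], centroid[2]])
        placed_layer = []
        for b in asm.layers[0]:
            bb = b.transformed(np.eye(3), shift).transformed(Rk, t)
            bb.seqid = k + 1
            placed_layer.append(bb)
        layers.append(placed_layer)
        for i in asm.ions:
            ions.append(Ion(i.species, Rk @ (i.position + shift) + t))
    if ion_species is not None:
        ions.append(Ion(ion_species, np.array([0.0, 0.0, rise / 2.0])))
    return Assembly(
        layers=layers,
        ions=ions,
        provenance="built",
        metadata={"rise": float(rise), "twist": float(twist)},
    )
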