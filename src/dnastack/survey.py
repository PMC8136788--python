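"""Survey of experimental DNA structures in PDB format.

Parses helical DNA structures (X-ray or multi-model NMR), applies the
inclusion rules of a typical-helix survey — pure-DNA structures only, no
protein/PNA/RNA complexes, no nucleobase analogs — and pools hydrogen bond
lengths, glycosidic vector angles and twist angles over all included pairs,
steps and NMR models.  The pooled means are the experimental reference
against which backbone-free model values are compared; the comparison is
summarized as a stress diagnosis (under/overrotation for twist, tensile/
compressive for bond lengths).

X-ray structures carry no hydrogens; donor hydrogens are rebuilt at
idealized in-plane positions from the donor nitrogen's heavy-atom
neighbors, so X-ray and NMR data are measured identically.

Nothing here downloads anything: accession files are user-supplied paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

from .geometry import Assembly, AtomSite, Ion, PlacedBase, load_template
from .metrics import (
    HBondCriteria,
    compute_ta,
    detect_hbonds,
    ion_bonds,
    pair_geometry,
)

__all__ = [
    "SurveyRecord",
    "SurveySummary",
    "write_pdb",
    "parse_structure",
    "rebuild_hydrogens",
    "apply_inclusion_rules",
    "infer_layers",
    "survey",
    "diagnose_stress",
]

_STANDARD_DNA = {"DA": "A", "DT": "T", "DG": "G", "DC": "C"}
_ION_RESNAMES = {"LI": "Li+", "NA": "Na+", "K": "K+"}
_AMINO3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
_RNA_RESNAMES = {"A", "U", "G", "C", "RA", "RU", "RG", "RC"}

# default stress tolerances
_TA_TOL = 2.0  # deg
_HBL_TOL = 0.05  # A


# ---------------------------------------------------------------------------
# PDB writing
# ---------------------------------------------------------------------------


def write_pdb(assemblies, accession: str = "MODL") -> str:
    """Serialize one assembly (or a list, one MODEL each) to PDB text.

    Bases become ATOM records (residue DA/DT/DG/DC, layer index as residue
    number); ions become HETATM records.
    """
    if isinstance(assemblies, Assembly):
        assemblies = [assemblies]
    st = gemmi.Structure()
    st.name = accession
    for asm in assemblies:
        model = gemmi.Model(str(len(st) + 1))
        chains = {}
        for li, layer in enumerate(asm.layers):
            for bi, base in enumerate(layer):
                cname = base.chain or "ABCDEFGH"[bi % 8]
                chain = chains.setdefault(cname, gemmi.Chain(cname))
                res = gemmi.Residue()
                res.name = {"A": "DA", "T": "DT", "G": "DG", "C": "DC"}[base.identity]
                res.seqid = gemmi.SeqId(base.seqid or li + 1, " ")
                for a in base.atoms:
                    atom = gemmi.Atom()
                    atom.name = a.name
                    atom.element = gemmi.Element(a.element)
                    atom.pos = gemmi.Position(*a.position)
                    res.add_atom(atom)
                chain.add_residue(res)
        if asm.ions:
            ichain = chains.setdefault("I", gemmi.Chain("I"))
            for k, ion in enumerate(asm.ions):
                res = gemmi.Residue()
                res.name = ion.species.rstrip("+").upper()
                res.seqid = gemmi.SeqId(k + 1, " ")
                res.het_flag = "H"
                atom = gemmi.Atom()
                atom.name = ion.species.rstrip("+").upper()
                atom.element = gemmi.Element(ion.species.rstrip("+"))
                atom.pos = gemmi.Position(*ion.position)
                res.add_atom(atom)
                ichain.add_residue(res)
        for chain in chains.values():
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string()


# ---------------------------------------------------------------------------
# PDB parsing
# ---------------------------------------------------------------------------


@dataclass
class SurveyRecord:
    """One experimental structure: parsed models plus survey bookkeeping."""

    accession: str
    method: str  # xray | nmr (nmr when multi-model)
    assemblies: list
    structure_class: str  # duplex | triplex | quadruplex | other
    foreign_chains: list = field(default_factory=list)
    analog_residues: list = field(default_factory=list)
    excluded: bool = False
    exclusion_reason: str | None = None

    @property
    def model_count(self) -> int:
        return len(self.assemblies)


def parse_structure(pdb_text: str, accession: str = "UNKNOWN") -> SurveyRecord:
    """Parse PDB text into one assembly per MODEL.

    Standard DNA residues (DA/DT/DG/DC) map onto the bundled templates (an
    extra H3 on DC marks the protonated variant); monovalent ions are
    captured; non-nucleic chains are retained only as exclusion evidence.
    """
    st = gemmi.read_pdb_string(pdb_text)
    foreign, analogs = [], []
    assemblies = []
    for model in st:
        bases, ions = [], []
        for chain in model:
            for res in chain:
                if res.name in _STANDARD_DNA:
                    bases.append(_base_from_residue(res, chain.name))
                elif res.name in _ION_RESNAMES:
                    pos = np.array(list(res[0].pos.tolist()))
                    ions.append(Ion(_ION_RESNAMES[res.name], pos))
                elif res.name == "HOH":
                    continue
                elif res.name in _AMINO3:
                    foreign.append((chain.name, res.name, "protein"))
                elif res.name in _RNA_RESNAMES:
                    foreign.append((chain.name, res.name, "rna"))
                else:
                    analogs.append((chain.name, res.name))
        if not bases:
            raise ValueError("no nucleic residues in PDB input")
        asm = Assembly(
            layers=_layers_from_seqids(bases),
            ions=ions,
            provenance="parsed",
            metadata={"accession": accession},
        )
        assemblies.append(asm)
    method = "nmr" if len(assemblies) > 1 else "xray"
    record = SurveyRecord(
        accession=accession,
        method=method,
        assemblies=assemblies,
        structure_class=_classify(assemblies[0]),
        foreign_chains=sorted(set(foreign)),
        analog_residues=sorted(set(analogs)),
    )
    return record


def _base_from_residue(res: "gemmi.Residue", chain_name: str) -> PlacedBase:
    identity = _STANDARD_DNA[res.name]
    protonated = identity == "C" and any(a.name == "H3" for a in res)
    tpl = load_template(identity, protonated=protonated)
    tpl_names = {a.name: a for a in tpl.atoms}
    atoms = []
    for a in res:
        roles = tpl_names[a.name].roles if a.name in tpl_names else frozenset()
        atoms.append(
            AtomSite(
                name=a.name,
                element=a.element.name,
                position=np.array(list(a.pos.tolist())),
                roles=roles,
            )
        )
    return PlacedBase(
        template=tpl, atoms=atoms, chain=chain_name, seqid=res.seqid.num
    )


def _layers_from_seqids(bases: list) -> list:
    by_seq = {}
    for b in bases:
        by_seq.setdefault(b.seqid, []).append(b)
    return [sorted(by_seq[s], key=lambda b: b.chain) for s in sorted(by_seq)]


def _classify(assembly: Assembly) -> str:
    sizes = {len(layer) for layer in assembly.layers}
    idents = {b.identity for b in assembly.bases()}
    if sizes == {4} and idents == {"G"}:
        return "quadruplex"
    if sizes == {3}:
        return "triplex"
    if sizes == {2}:
        return "duplex"
    return "other"


# ---------------------------------------------------------------------------
# hydrogen rebuilding (X-ray structures carry none)
# ---------------------------------------------------------------------------


def rebuild_hydrogens(base: PlacedBase) -> PlacedBase:
    """Add missing donor hydrogens at idealized in-plane positions.

    Ring N-H: along the external bisector of the two ring neighbors.
    Amino N-H2: trigonal, +-120 deg from the single heavy neighbor within
    the base plane.  Bond length 1.01 A.  Present hydrogens are kept.
    """
    pts = base.positions()
    c = pts.mean(axis=0)
    _, _, Vt = np.linalg.svd(pts - c)
    normal = Vt[2]
    new_atoms = list(base.atoms)
    have = {a.name for a in base.atoms}
    for hname in base.template.donor_hydrogens:
        if hname in have:
            continue
        heavy = "N" + hname[1]
        if heavy not in {a.name for a in base.atoms}:
            continue
        hp = base.atom(heavy).position
        nbrs = [
            a.position
            for a in base.atoms
            if a.element != "H"
            and a.name != heavy
            and np.linalg.norm(a.position - hp) < 1.7
        ]
        if not nbrs:
            continue
        if len(nbrs) >= 2:  # ring N-H: external bisector
            d = hp - np.mean(nbrs, axis=0)
            d = d - np.dot(d, normal) * normal
            d /= np.linalg.norm(d)
            new_atoms.append(AtomSite(hname, "H", hp + 1.01 * d, frozenset({"hbond_donor"})))
        else:  # amino N-H2: trigonal sp2, C-N-H = 120 deg, in-plane
            u = hp - nbrs[0]  # C -> N direction, extended
            u = u - np.dot(u, normal) * normal
            u /= np.linalg.norm(u)
            w = np.cross(normal, u)
            sign = 1.0 if hname.endswith("1") else -1.0
            d = 0.5 * u + sign * (np.sqrt(3.0) / 2.0) * w
            new_atoms.append(AtomSite(hname, "H", hp + 1.01 * d, frozenset({"hbond_donor"})))
    return PlacedBase(
        template=base.template,
        atoms=new_atoms,
        flipped=base.flipped,
        chain=base.chain,
        seqid=base.seqid,
    )


def _with_hydrogens(assembly: Assembly) -> Assembly:
    return Assembly(
        layers=[[rebuild_hydrogens(b) for b in layer] for layer in assembly.layers],
        ions=assembly.ions,
        provenance=assembly.provenance,
        metadata=assembly.metadata,
    )


# ---------------------------------------------------------------------------
# inclusion rules
# ---------------------------------------------------------------------------


def apply_inclusion_rules(records: list) -> list:
    """Flag records that a typical-helix survey must exclude.

    Protein/PNA/RNA-containing complexes and structures with non-standard
    nucleobase residues are excluded with machine-readable reasons.
    """
    for rec in records:
        if any(kind == "protein" for _, _, kind in rec.foreign_chains):
            rec.excluded, rec.exclusion_reason = True, "protein_complex"
        elif any(kind == "rna" for _, _, kind in rec.foreign_chains):
            rec.excluded, rec.exclusion_reason = True, "rna_hybrid"
        elif rec.analog_residues:
            rec.excluded, rec.exclusion_reason = True, "base_analog"
        else:
            rec.excluded, rec.exclusion_reason = False, None
    return records


# ---------------------------------------------------------------------------
# layer inference and pooled survey
# ---------------------------------------------------------------------------


def infer_layers(assembly: Assembly, criteria: HBondCriteria = HBondCriteria()) -> Assembly:
    """Regroup bases into layers by hydrogen-bond connectivity.

    Bases joined by >= 1 inter-base hydrogen bond form one layer (pair,
    triad or tetrad); layers are ordered by centroid along the dominant
    stacking direction.  Useful for parsed structures whose residue
    numbering does not encode layers.
    """
    flat = Assembly(layers=[assembly.bases()], ions=assembly.ions)
    bonds = detect_hbonds(flat, 0, criteria)
    n = len(flat.layers[0])
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for b in bonds:
        ri, rj = find(b.donor_base), find(b.acceptor_base)
        if ri != rj:
            parent[ri] = rj
    groups = {}
    for i, base in enumerate(flat.layers[0]):
        groups.setdefault(find(i), []).append(base)
    cents = {k: np.vstack([b.positions() for b in g]).mean(axis=0) for k, g in groups.items()}
    all_c = np.array(list(cents.values()))
    axis = np.array([0.0, 0.0, 1.0])
    if len(all_c) > 1:
        _, _, Vt = np.linalg.svd(all_c - all_c.mean(axis=0))
        axis = Vt[0]
    order = sorted(groups, key=lambda k: float(np.dot(cents[k], axis)))
    return Assembly(
        layers=[sorted(groups[k], key=lambda b: b.chain) for k in order],
        ions=assembly.ions,
        provenance=assembly.provenance,
        metadata=assembly.metadata,
    )


@dataclass
class SurveySummary:
    structure_class: str
    pairing_category: str  # watson_crick | hoogsteen | tetrad
    mean_hbl: float | None
    mean_gva: float | None
    mean_ta: float | None
    mean_nh_n: float | None
    mean_nh_o: float | None
    mean_ion_o: float | None
    n_pairs: int
    n_steps: int
    internal_only: bool = False
    metadata: dict = field(default_factory=dict)


def _category(pg, layer_size: int) -> str:
    if layer_size >= 4:
        return "tetrad"
    if pg.edge in ("hoogsteen", "reversed_hoogsteen"):
        return "hoogsteen"
    if pg.edge == "watson_crick":
        return "watson_crick"
    return "watson_crick" if layer_size == 2 else "hoogsteen"


def survey(
    records: list,
    structure_class: str,
    criteria: HBondCriteria = HBondCriteria(),
    internal_only: bool = False,
) -> dict:
    """Pooled metric means over all included records of one class.

    Metrics from every base pair, stacking step and NMR model are pooled,
    then averaged (models weigh equally; the mean is invariant to model
    order).  ``internal_only`` drops the first and last layer of each
    structure to exclude fraying termini.  Returns
    ``{pairing_category: SurveySummary}``.
    """
    pools: dict = {}
    n_steps = 0
    ta_pool = []
    for rec in records:
        if rec.excluded or rec.structure_class != structure_class:
            continue
        for asm in rec.assemblies:
            asm = infer_layers(_with_hydrogens(asm), criteria)
            lo, hi = 0, len(asm.layers)
            if internal_only and len(asm.layers) > 2:
                lo, hi = 1, len(asm.layers) - 1
            for li in range(lo, hi):
                layer = asm.layers[li]
                for i in range(len(layer)):
                    for j in range(i + 1, len(layer)):
                        pg = pair_geometry(asm, li, i, j, criteria)
                        if not pg.bonds:
                            continue
                        cat = _category(pg, len(layer))
                        pool = pools.setdefault(
                            cat, {"hbl": [], "gva": [], "nh_n": [], "nh_o": []}
                        )
                        pool["hbl"].append(pg.mean_hbl)
                        pool["gva"].append(pg.gva)
                        for b in pg.bonds:
                            if b.bond_class == "NH-N":
                                pool["nh_n"].append(b.hbl)
                            elif b.bond_class == "NH-O":
                                pool["nh_o"].append(b.hbl)
            for li in range(lo, hi - 1):
                if len(asm.layers[li]) == len(asm.layers[li + 1]):
                    ta_pool.append(compute_ta(asm, li, li + 1).ta)
                    n_steps += 1
            if asm.ions:
                ion_pool = pools.setdefault(
                    "tetrad" if structure_class == "quadruplex" else "watson_crick",
                    {"hbl": [], "gva": [], "nh_n": [], "nh_o": []},
                )
                ion_pool.setdefault("ion_o", [])
                for ibs in ion_bonds(asm):
                    ion_pool["ion_o"].extend(ibs.distances)
    if not pools and not ta_pool:
        raise ValueError(f"no included records of class {structure_class!r}")
    out = {}
    for cat, pool in pools.items():
        out[cat] = SurveySummary(
            structure_class=structure_class,
            pairing_category=cat,
            mean_hbl=_mean(pool["hbl"]),
            mean_gva=_mean(pool["gva"]),
            mean_ta=_mean(ta_pool),
            mean_nh_n=_mean(pool["nh_n"]),
            mean_nh_o=_mean(pool["nh_o"]),
            mean_ion_o=_mean(pool.get("ion_o", [])),
            n_pairs=len(pool["hbl"]),
            n_steps=n_steps,
            internal_only=internal_only,
            metadata={"nmr_models": "averaged"},
        )
    return out


def _mean(xs):
    return float(np.mean(xs)) if xs else None


# ---------------------------------------------------------------------------
# stress diagnosis
# ---------------------------------------------------------------------------


def diagnose_stress(model_value: float, survey_value: float, kind: str, tol: float | None = None) -> str:
    """Compare a backbone-free model value against the experimental mean.

    TA: a model twist below the survey mean means the relaxed layers
    underrotate (torsional stress would build when a backbone is added);
    above means overrotation.  HBL: model bonds shorter than experiment mean
    the pair would be stretched by the backbone (tensile stress); longer
    bonds mean it would be squeezed (compressive stress).
    """
    if kind == "TA":
        tol = _TA_TOL if tol is None else tol
        if model_value < survey_value - tol:
            return "underrotated"
        if model_value > survey_value + tol:
            return "overrotated"
        return "neutral"
    if kind == "HBL":
        tol = _HBL_TOL if tol is None else tol
        if model_value < survey_value - tol:
            return "tensile"
        if model_value > survey_value + tol:
            return "compressive"
        return "neutral"
    raise ValueError(f"unknown stress kind {kind!r}")
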