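"""Synthetic structures and energy ledgers with known ground truth.

Every pipeline stage is testable offline: the generator builds idealized
assemblies at stated rise/twist/HBL, perturbs coordinates with isotropic
Gaussian noise, writes them in PDB format for the survey module, and
fabricates mock energy-record suites around the bundled component-energy
fixture.  The noise model is deliberately the simplest that supports
recovery tests — independent Gaussian displacement per atom and additive
Gaussian error per energy — and is not a physical error model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energy import FixtureTable, RecordSet
from .geometry import (
    Assembly,
    Ion,
    PlacedBase,
    build_pair,
    build_stack,
    build_tetrad,
    load_template,
)
from .qm import mock_backend
from .survey import write_pdb

__all__ = [
    "SyntheticSpec",
    "perturb_assembly",
    "build_reference_assembly",
    "generate_survey_pool",
    "generate_ledger_suite",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth parameters of a synthetic structure pool."""

    structure_class: str = "duplex"  # duplex | triplex | quadruplex
    rise: float = 3.4  # A
    twist: float = 36.0  # deg
    hbl: float = 1.90  # A (construction target)
    n_layers: int = 2
    coordinate_sigma: float = 0.0  # A
    energy_sigma: float = 0.0  # kcal/mol
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.coordinate_sigma < 0 or self.energy_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


def perturb_assembly(assembly: Assembly, sigma: float, seed: int) -> Assembly:
    """Isotropic Gaussian displacement of every atom (and ion), seeded."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    layers = []
    for layer in assembly.layers:
        new_layer = []
        for b in layer:
            atoms = [
                a.moved(a.position + rng.normal(0.0, sigma, size=3)) if sigma > 0 else a
                for a in b.atoms
            ]
            new_layer.append(
                PlacedBase(
                    template=b.template,
                    atoms=atoms,
                    flipped=b.flipped,
                    chain=b.chain,
                    seqid=b.seqid,
                )
            )
        layers.append(new_layer)
    ions = [
        Ion(i.species, i.position + (rng.normal(0.0, sigma, size=3) if sigma > 0 else 0.0))
        for i in assembly.ions
    ]
    return Assembly(
        layers=layers, ions=ions, provenance="perturbed", metadata=dict(assembly.metadata)
    )


def build_reference_assembly(spec: SyntheticSpec) -> Assembly:
    """Noise-free structure of the requested class at the true parameters."""
    if spec.structure_class == "duplex":
        mk = lambda: build_pair(load_template("G"), load_template("C"))
    elif spec.structure_class == "triplex":
        from .geometry import build_triad

        def mk():
            at = build_pair(load_template("A"), load_template("T"))
            return build_triad(at, load_template("T"))

    elif spec.structure_class == "quadruplex":
        mk = lambda: build_tetrad(None)
    else:
        raise ValueError(f"unknown structure class {spec.structure_class!r}")
    layers = [mk() for _ in range(spec.n_layers)]
    ion = "K+" if spec.structure_class == "quadruplex" else None
    return build_stack(layers, rise=spec.rise, twist=spec.twist, ion_species=ion)


def generate_survey_pool(spec: SyntheticSpec) -> list:
    """``n_replicates`` perturbed copies, each serialized as PDB text.

    Replicate k is perturbed with a child seed derived from ``spec.seed``,
    so the pool is fully deterministic.
    """
    ref = build_reference_assembly(spec)
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_replicates)
    out = []
    for k, ss in enumerate(seeds):
        asm = perturb_assembly(ref, spec.coordinate_sigma, int(ss.generate_state(1)[0] % 2**31))
        out.append(write_pdb(asm, accession=f"SYN{k:04d}"))
    return out


def generate_ledger_suite(
    fixture: FixtureTable, energy_sigma: float = 0.0, seed: int = 0
) -> dict:
    """Mock record sets for every fixture structure: id -> RecordSet.

    At zero noise each ledger operation reproduces its fixture row exactly;
    otherwise components carry seeded additive Gaussian errors.
    """
    seeds = np.random.SeedSequence(seed).spawn(len(fixture.ids()))
    out = {}
    for sid, ss in zip(fixture.ids(), seeds):
        out[sid] = mock_backend(
            sid, fixture, noise_sigma=energy_sigma, seed=int(ss.generate_state(1)[0] % 2**31)
        )
    return out
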