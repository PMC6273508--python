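"""Seedable generators of toy molecules and synthetic descriptor datasets.

Everything here is deterministic per seed so that the geometric stack and the
modeling stack can both be exercised without any external data.  Molecule
families give controllably distinct shapes (fused rings vs chains vs stars);
dataset generators emit descriptor tables directly, with planted structure
whose indices are returned for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem
from scipy.spatial.transform import Rotation

from .descriptor import BRSVector, DescriptorTable
from .molio import TypedMolecule, assign_feature_types, generate_conformers, _mol_from_rdkit

FAMILIES = ("rigid_ring", "chain", "star", "random_druglike")

_RIGID_RINGS = [
    "c1ccc2ccccc2c1",            # naphthalene
    "c1ccc2cc3ccccc3cc2c1",      # anthracene
    "c1ccc2[nH]ccc2c1",          # indole
    "c1ccc2ncccc2c1",            # quinoline
    "c1ccc2occc2c1",             # benzofuran
    "c1ccc2sccc2c1",             # benzothiophene
]

_DRUGLIKE = [
    "CC(=O)Oc1ccccc1C(=O)O",           # aspirin-like
    "CC(=O)Nc1ccc(O)cc1",              # acetanilide phenol
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",      # arylpropionic acid
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",      # xanthine
    "NC(=[NH2+])c1ccccc1",             # amidinium
    "OC(=O)c1ccccc1O",                 # salicylate
    "NCCc1ccc(O)c(O)c1",               # catecholamine
    "CN1CCC(CC1)c1ccccc1",             # piperidine aryl
]

_CHAIN_ATOMS = ["C", "C", "C", "C", "O", "N"]
_STAR_BRANCHES = ["C", "CC", "O", "N", "CO"]


@dataclass
class FixtureSpec:
    """Parameters for toy-molecule generation."""

    seed: int = 0
    family: str = "random_druglike"

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family: {self.family}")


@dataclass
class DatasetSpec:
    """Parameters for synthetic descriptor datasets.

    Decoy rows are Beta-distributed around ~0.45; active rows get a +shift on
    ``m_informative`` of the ``k`` dimensions plus Gaussian noise, clipped to
    [0, 1] — mimicking the mid-range concentration of real profiles.
    """

    seed: int = 0
    n_active: int = 100
    n_decoy: int = 400
    k: int = 300
    m_informative: int = 15
    shift: float = 0.25
    noise: float = 0.05


def _family_smiles(family: str, rng: np.random.Generator) -> str:
    if family == "rigid_ring":
        return _RIGID_RINGS[rng.integers(len(_RIGID_RINGS))]
    if family == "random_druglike":
        return _DRUGLIKE[rng.integers(len(_DRUGLIKE))]
    if family == "chain":
        length = int(rng.integers(5, 9))
        symbols = ["C"] + [
            _CHAIN_ATOMS[rng.integers(len(_CHAIN_ATOMS))] for _ in range(length - 2)
        ] + ["C"]
        return "".join(symbols)
    # star: quaternary-like center with 4 branches
    branches = [
        _STAR_BRANCHES[rng.integers(len(_STAR_BRANCHES))] for _ in range(3)
    ]
    return "C(" + ")(".join(branches) + ")C"


def make_toy_molecule(spec: FixtureSpec) -> TypedMolecule:
    """Deterministic toy molecule: valid 3D geometry, typed features, one
    embedded conformer."""
    rng = np.random.default_rng(spec.seed)
    smiles = _family_smiles(spec.family, rng)
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:  # families above always parse
        raise RuntimeError(f"internal fixture SMILES failed: {smiles}")
    rdmol = Chem.AddHs(rdmol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(spec.seed)
    if AllChem.EmbedMolecule(rdmol, params) != 0:
        raise RuntimeError(f"fixture embedding failed for {smiles}")
    AllChem.MMFFOptimizeMolecule(rdmol, maxIters=500)
    mol = _mol_from_rdkit(rdmol, f"{spec.family}-{spec.seed}")
    return assign_feature_types(mol)


def make_toy_pool(
    n: int, seed: int = 0, families: tuple = FAMILIES
) -> list[TypedMolecule]:
    """n single-conformer toy molecules cycling through the families, with
    unique ids — suitable as a template pool."""
    pool = []
    for i in range(n):
        family = families[i % len(families)]
        mol = make_toy_molecule(FixtureSpec(seed=seed * 10007 + i, family=family))
        mol.id = f"{mol.id}-p{i}"
        pool.append(mol)
    return pool


def random_rigid_copy(mol: TypedMolecule, seed: int = 0) -> TypedMolecule:
    """Copy with one uniform random rotation + translation in [-10, 10]^3
    applied to every conformer (and atom positions)."""
    rng = np.random.default_rng(seed)
    rot = Rotation.random(rng=rng)
    trans = rng.uniform(-10.0, 10.0, size=3)
    atoms = [
        type(a)(a.element, rot.apply(a.position) + trans, a.radius, a.features)
        for a in mol.atoms
    ]
    conformers = [rot.apply(c) + trans for c in mol.conformers]
    return TypedMolecule(
        id=f"{mol.id}-rigidcopy{seed}",
        atoms=atoms,
        conformers=conformers,
        rdmol=mol.rdmol,
    )


def make_classification_dataset(
    spec: DatasetSpec,
) -> tuple[DescriptorTable, np.ndarray, np.ndarray]:
    """Synthetic descriptor table with planted class signal.

    Returns (table, labels, informative_dims); labels are 1 for actives.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_active + spec.n_decoy
    # Beta(4.05, 4.95): mean 0.45, values well inside [0, 1]
    X = rng.beta(4.05, 4.95, size=(n, spec.k))
    informative = np.sort(rng.choice(spec.k, size=spec.m_informative, replace=False))
    labels = np.concatenate(
        [np.ones(spec.n_active, dtype=int), np.zeros(spec.n_decoy, dtype=int)]
    )
    X[: spec.n_active, informative] += spec.shift
    X[: spec.n_active] += rng.normal(0.0, spec.noise, size=(spec.n_active, spec.k))
    X = np.clip(X, 0.0, 1.0)
    template_ids = [f"T{i:03d}" for i in range(spec.k)]
    rows = [
        BRSVector(f"{'act' if labels[i] else 'dec'}{i:04d}", X[i]) for i in range(n)
    ]
    table = DescriptorTable(
        fingerprint=f"synthetic:seed={spec.seed}:k={spec.k}",
        template_ids=template_ids,
        rows=rows,
    )
    return table, labels, informative


@dataclass
class SelectivitySpec:
    """Parameters for the synthetic subtype-selectivity dataset."""

    seed: int = 0
    n: int = 400
    k: int = 300
    m_linked: int = 10
    selective_fraction: float = 0.4  # split evenly between the two tails
    coefficient: float = 0.06
    noise: float = 0.02


def make_selectivity_dataset(
    spec: SelectivitySpec,
) -> tuple[pd.DataFrame, DescriptorTable, np.ndarray]:
    """Activity table (id, pKi_A, pKi_B) plus a descriptor table whose rows
    depend linearly on SR through ``m_linked`` dimensions, so regression
    recovery is possible.  Returns (activities, table, linked_dims)."""
    rng = np.random.default_rng(spec.seed)
    half = spec.selective_fraction / 2.0
    comp = rng.choice([-1, 0, 1], size=spec.n, p=[half, 1.0 - spec.selective_fraction, half])
    sr = np.where(
        comp == 0,
        rng.uniform(-1.25, 1.25, size=spec.n),
        comp * (1.3 + rng.exponential(0.8, size=spec.n)),
    )
    pki_b = rng.normal(7.0, 0.7, size=spec.n)
    pki_a = pki_b + sr

    X = rng.beta(4.05, 4.95, size=(spec.n, spec.k))
    linked = np.sort(rng.choice(spec.k, size=spec.m_linked, replace=False))
    signs = rng.choice([-1.0, 1.0], size=spec.m_linked)
    X[:, linked] += spec.coefficient * sr[:, None] * signs[None, :]
    X += rng.normal(0.0, spec.noise, size=X.shape)
    X = np.clip(X, 0.0, 1.0)

    ids = [f"cmpd{i:04d}" for i in range(spec.n)]
    activities = pd.DataFrame({"id": ids, "pKi_A": pki_a, "pKi_B": pki_b})
    table = DescriptorTable(
        fingerprint=f"synthetic-sel:seed={spec.seed}:k={spec.k}",
        template_ids=[f"T{i:03d}" for i in range(spec.k)],
        rows=[BRSVector(ids[i], X[i]) for i in range(spec.n)],
    )
    return activities, table, linked
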