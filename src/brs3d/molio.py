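"""Molecule I/O, pharmacophore feature typing, and conformer generation.

Structures are carried around as :class:`TypedMolecule`: a light container of
atoms (element, vdW radius, feature flags) plus one or more conformer
coordinate sets.  An RDKit ``Mol`` is kept alongside when available so that
substructure typing, conformer embedding, and SDF writing can reuse it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, rdMolAlign

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

FEATURE_NAMES = ("hydrophobic", "donor", "acceptor", "positive", "negative")


def _load_data_yaml(name: str) -> dict:
    with resources.files("brs3d.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


def load_vdw_radii(path: str | Path | None = None) -> dict[str, float]:
    """Van der Waals radius table; ``default`` key is the fallback radius."""
    if path is None:
        return _load_data_yaml("vdw_radii.yaml")
    with open(path) as fh:
        return yaml.safe_load(fh)


def load_feature_rules(path: str | Path | None = None) -> dict[str, list[str]]:
    """Feature-typing rules: feature name -> list of SMARTS patterns."""
    if path is None:
        return _load_data_yaml("feature_rules.yaml")
    with open(path) as fh:
        return yaml.safe_load(fh)


_VDW = load_vdw_radii()


def vdw_radius(element: str) -> float:
    return float(_VDW.get(element, _VDW["default"]))


@dataclass
class Atom:
    """One atom: element symbol, position (Angstrom), vdW radius, feature flags."""

    element: str
    position: np.ndarray
    radius: float
    features: frozenset[str] = frozenset()

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.radius <= 0:
            raise ValueError(f"radius must be positive, got {self.radius}")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be finite")


@dataclass
class TypedMolecule:
    """A molecule with typed atoms and zero or more conformer coordinate sets.

    ``conformers`` holds (n_atoms, 3) arrays in Angstrom; conformer 0 is the
    reference geometry.  ``rdmol`` (optional) retains the underlying RDKit
    molecule for typing/embedding; it is never required by the shape stack.
    """

    id: str
    atoms: list[Atom]
    conformers: list[np.ndarray] = field(default_factory=list)
    rdmol: Chem.Mol | None = None
    unprofiled: bool = False

    def __post_init__(self):
        if not self.atoms:
            raise ValueError("TypedMolecule needs at least one atom")
        self.conformers = [np.asarray(c, dtype=float) for c in self.conformers]
        for c in self.conformers:
            if c.shape != (self.n_atoms, 3):
                raise ValueError(
                    f"conformer shape {c.shape} != ({self.n_atoms}, 3)"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def heavy_indices(self) -> np.ndarray:
        return np.array(
            [i for i, a in enumerate(self.atoms) if a.element != "H"], dtype=int
        )

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]


# ---------------------------------------------------------------------------
# reading / writing


def _mol_from_rdkit(rdmol: Chem.Mol, mol_id: str) -> TypedMolecule:
    rdmol = Chem.AddHs(rdmol, addCoords=rdmol.GetNumConformers() > 0)
    atoms = []
    conf = rdmol.GetConformer() if rdmol.GetNumConformers() else None
    for i, a in enumerate(rdmol.GetAtoms()):
        pos = np.array(conf.GetAtomPosition(i)) if conf is not None else np.zeros(3)
        atoms.append(Atom(a.GetSymbol(), pos, vdw_radius(a.GetSymbol())))
    conformers = []
    if conf is not None:
        conformers.append(np.array(conf.GetPositions(), dtype=float))
    return TypedMolecule(id=mol_id, atoms=atoms, conformers=conformers, rdmol=rdmol)


def _record_id(rdmol: Chem.Mol, stem: str, index: int) -> str:
    name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else ""
    return name.strip() or f"{stem}_{index}"


def _iter_mol2_blocks(text: str):
    marker = "@<TRIPOS>MOLECULE"
    parts = text.split(marker)
    for part in parts[1:]:
        yield marker + part


def read_molecules(
    path: str | Path, fmt: str | None = None
) -> list[TypedMolecule]:
    """Read molecules from an SDF, MOL2, or SMILES file.

    SMILES files contain one record per line: ``SMILES<whitespace>id``; their
    molecules carry no conformers until :func:`generate_conformers` runs.
    Unparsable individual records are skipped with a logged warning; an
    unreadable file raises.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such molecule file: {path}")
    if fmt is None:
        fmt = {".sdf": "sdf", ".mol2": "mol2", ".smi": "smiles"}.get(
            path.suffix.lower(), "sdf"
        )
    stem = path.stem
    mols: list[TypedMolecule] = []
    skipped = 0

    if fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
        for i, rdmol in enumerate(supplier):
            if rdmol is None:
                skipped += 1
                logger.warning("skipping unparsable SDF record %d in %s", i, path)
                continue
            mols.append(_mol_from_rdkit(rdmol, _record_id(rdmol, stem, i)))
    elif fmt == "mol2":
        text = path.read_text()
        for i, block in enumerate(_iter_mol2_blocks(text)):
            rdmol = Chem.MolFromMol2Block(block, removeHs=False, sanitize=True)
            if rdmol is None:
                skipped += 1
                logger.warning("skipping unparsable MOL2 record %d in %s", i, path)
                continue
            mols.append(_mol_from_rdkit(rdmol, _record_id(rdmol, stem, i)))
    elif fmt == "smiles":
        for i, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split(None, 1)
            rdmol = Chem.MolFromSmiles(fields[0])
            if rdmol is None:
                skipped += 1
                logger.warning("skipping unparsable SMILES line %d in %s", i + 1, path)
                continue
            mol_id = fields[1].strip() if len(fields) > 1 else f"{stem}_{i}"
            rdmol = Chem.AddHs(rdmol)
            atoms = [
                Atom(a.GetSymbol(), np.zeros(3), vdw_radius(a.GetSymbol()))
                for a in rdmol.GetAtoms()
            ]
            mols.append(TypedMolecule(id=mol_id, atoms=atoms, rdmol=rdmol))
    else:
        raise ValueError(f"unknown format: {fmt}")

    if skipped:
        logger.warning("%s: skipped %d unparsable record(s)", path, skipped)
    return mols


def write_sdf(
    mols: list[TypedMolecule], path: str | Path, conformer: int = 0
) -> None:
    """Write one conformer per molecule to an SDF (V2000) file."""
    writer = Chem.SDWriter(str(path))
    try:
        for mol in mols:
            rdmol = mol.rdmol
            if rdmol is None:
                rw = Chem.RWMol()
                for a in mol.atoms:
                    rw.AddAtom(Chem.Atom(a.element))
                rdmol = rw.GetMol()
            rdmol = Chem.Mol(rdmol)
            rdmol.RemoveAllConformers()
            conf = Chem.Conformer(mol.n_atoms)
            coords = mol.conformers[conformer]
            for i in range(mol.n_atoms):
                conf.SetAtomPosition(i, coords[i].tolist())
            rdmol.AddConformer(conf, assignId=True)
            rdmol.SetProp("_Name", mol.id)
            writer.write(rdmol)
    finally:
        writer.close()


# ---------------------------------------------------------------------------
# feature typing


def assign_feature_types(
    mol: TypedMolecule, rules: dict[str, list[str]] | None = None
) -> TypedMolecule:
    """Populate per-atom pharmacophore feature flags from SMARTS rules.

    Typing depends only on topology and formal charges, never on conformers.
    Atoms matching no rule simply get an empty feature set.
    """
    if mol.rdmol is None:
        raise ValueError(f"{mol.id}: feature typing needs the RDKit molecule")
    if rules is None:
        rules = load_feature_rules()
    flags: dict[int, set[str]] = {i: set() for i in range(mol.n_atoms)}
    for feature, patterns in rules.items():
        for smarts in patterns:
            patt = Chem.MolFromSmarts(smarts)
            if patt is None:
                raise ValueError(f"bad SMARTS for {feature!r}: {smarts!r}")
            for match in mol.rdmol.GetSubstructMatches(patt):
                for idx in match:
                    if idx < mol.n_atoms:
                        flags[idx].add(feature)
    atoms = [
        Atom(a.element, a.position, a.radius, frozenset(flags[i]))
        for i, a in enumerate(mol.atoms)
    ]
    return TypedMolecule(
        id=mol.id,
        atoms=atoms,
        conformers=[c.copy() for c in mol.conformers],
        rdmol=mol.rdmol,
        unprofiled=mol.unprofiled,
    )


# ---------------------------------------------------------------------------
# conformers


def _heavy_rms(rdmol: Chem.Mol, ci: int, cj: int) -> float:
    probe = Chem.RemoveHs(Chem.Mol(rdmol))
    return rdMolAlign.GetBestRMS(probe, probe, prbId=ci, refId=cj)


def generate_conformers(
    mol: TypedMolecule,
    max_confs: int = 50,
    rmsd_prune: float = 0.5,
    seed: int = 42,
) -> TypedMolecule:
    """Embed up to ``max_confs`` conformers (ETKDG), minimize (MMFF94), and
    prune so retained conformers differ by >= ``rmsd_prune`` heavy-atom RMSD.

    Deterministic for a fixed seed.  On embedding failure the molecule is
    returned flagged ``unprofiled`` rather than dropped.
    """
    if mol.rdmol is None:
        raise ValueError(f"{mol.id}: conformer generation needs the RDKit molecule")
    rdmol = Chem.Mol(mol.rdmol)
    rdmol.RemoveAllConformers()
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    ids = list(AllChem.EmbedMultipleConfs(rdmol, numConfs=int(max_confs), params=params))
    if not ids:
        logger.warning("%s: conformer embedding failed; flagged unprofiled", mol.id)
        out = TypedMolecule(
            id=mol.id, atoms=list(mol.atoms), conformers=[], rdmol=mol.rdmol
        )
        out.unprofiled = True
        return out

    energies = []
    results = AllChem.MMFFOptimizeMoleculeConfs(rdmol, maxIters=500)
    for cid, (converged, energy) in zip(ids, results):
        energies.append((energy if np.isfinite(energy) else np.inf, cid))
    energies.sort()

    kept: list[int] = []
    for _, cid in energies:
        if all(_heavy_rms(rdmol, cid, kid) >= rmsd_prune for kid in kept):
            kept.append(cid)

    conformers = [
        np.array(rdmol.GetConformer(cid).GetPositions(), dtype=float) for cid in kept
    ]
    # keep only the retained conformers on the RDKit side, renumbered 0..n-1
    pruned = Chem.Mol(rdmol)
    pruned.RemoveAllConformers()
    for cid in kept:
        pruned.AddConformer(Chem.Conformer(rdmol.GetConformer(cid)), assignId=True)
    return TypedMolecule(
        id=mol.id, atoms=list(mol.atoms), conformers=conformers, rdmol=pruned
    )
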