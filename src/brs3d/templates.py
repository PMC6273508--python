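"""Diverse rigid-template library construction.

Pipeline: rigid-rigid self-similarity matrix over a ligand pool, Pearson-row
distance between matrix rows, greedy max-min (maximum dissimilarity) selection
of k centers.  The whole module is deterministic — no RNG anywhere.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import molio
from .molio import TypedMolecule
from .shapesim import DEFAULT_W_SHAPE, GaussianShape, make_shape, rigid_align


@dataclass
class SimilarityMatrix:
    """Symmetric [0,1] rigid-rigid similarity matrix with unit diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id count")

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(self.ids) + "\n")
            for mol_id, row in zip(self.ids, self.values):
                fh.write(mol_id + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "SimilarityMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
            rows = [
                [float(v) for v in line.rstrip("\n").split("\t")[1:]] for line in fh
            ]
        return cls(ids=header, values=np.array(rows))


@dataclass
class TemplateLibrary:
    """Ordered set of k rigid template shapes; order defines descriptor index."""

    k: int
    ids: list[str]
    shapes: list[GaussianShape]
    molecules: list[TypedMolecule]
    w_shape: float = DEFAULT_W_SHAPE
    build_metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("template ids must be unique")
        if not (len(self.ids) == len(self.shapes) == self.k):
            raise ValueError("library size mismatch")

    @property
    def fingerprint(self) -> str:
        return f"{self.build_metadata.get('pool_hash', 'unknown')}:k={self.k}"

    def save(self, path: str | Path) -> None:
        """Persist as SDF of template conformers + plain-text sidecar."""
        path = Path(path)
        molio.write_sdf(self.molecules, path)
        with open(path.with_suffix(".meta"), "w") as fh:
            fh.write(f"k={self.k}\n")
            fh.write(f"w_shape={self.w_shape!r}\n")
            for key, val in sorted(self.build_metadata.items()):
                fh.write(f"{key}={val}\n")

    @classmethod
    def load(cls, path: str | Path) -> "TemplateLibrary":
        path = Path(path)
        mols = [molio.assign_feature_types(m) for m in molio.read_molecules(path, "sdf")]
        meta: dict = {}
        meta_path = path.with_suffix(".meta")
        if meta_path.exists():
            for line in meta_path.read_text().splitlines():
                key, _, val = line.partition("=")
                meta[key] = val
        w_shape = float(meta.pop("w_shape", DEFAULT_W_SHAPE))
        meta.pop("k", None)
        return cls(
            k=len(mols),
            ids=[m.id for m in mols],
            shapes=[make_shape(m, 0) for m in mols],
            molecules=mols,
            w_shape=w_shape,
            build_metadata=meta,
        )


def pool_hash(pool: list[TypedMolecule]) -> str:
    """Stable hash of pool ids + rounded reference-conformer coordinates."""
    digest = hashlib.sha256()
    for mol in pool:
        digest.update(mol.id.encode())
        if mol.conformers:
            digest.update(np.round(mol.conformers[0], 4).tobytes())
    return digest.hexdigest()[:16]


def self_similarity_matrix(
    pool: list[TypedMolecule],
    w_shape: float = DEFAULT_W_SHAPE,
    **align_kwargs,
) -> SimilarityMatrix:
    """All-pairs rigid-rigid combined scores, symmetrized by max, diagonal 1.

    Every pool molecule must carry exactly one conformer (the frozen bioactive
    geometry); alignment of j onto i and i onto j are both computed because an
    optimizer-based scorer need not be exactly symmetric.
    """
    if len(pool) < 2:
        raise ValueError("pool must contain at least 2 molecules")
    for mol in pool:
        if len(mol.conformers) != 1:
            raise ValueError(
                f"{mol.id}: template pool molecules need exactly 1 conformer, "
                f"got {len(mol.conformers)}"
            )
    shapes = [make_shape(m, 0) for m in pool]
    n = len(pool)
    S = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            S[i, j] = rigid_align(
                shapes[j], shapes[i], w_shape=w_shape, **align_kwargs
            ).combined_score
    S = np.maximum(S, S.T)
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(ids=[m.id for m in pool], values=S)


def pearson_distance(row_i: np.ndarray, row_j: np.ndarray) -> float:
    """One minus Pearson correlation; zero-variance rows fall back to d = 1."""
    row_i = np.asarray(row_i, dtype=float)
    row_j = np.asarray(row_j, dtype=float)
    if row_i.shape != row_j.shape:
        raise ValueError(f"length mismatch: {row_i.shape} vs {row_j.shape}")
    if row_i.size < 3:
        raise ValueError("rows must have length >= 3")
    if np.std(row_i) == 0 or np.std(row_j) == 0:
        return 1.0
    return float(1.0 - np.corrcoef(row_i, row_j)[0, 1])


def row_distance_matrix(sim: SimilarityMatrix) -> np.ndarray:
    """Pairwise Pearson-row distances between full similarity-matrix rows."""
    n = len(sim.ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pearson_distance(sim.values[i], sim.values[j])
    return D


def maxmin_select(D: np.ndarray, k: int) -> list[int]:
    """Greedy maximum-dissimilarity center selection.

    First center: index with maximal total distance to all others (ties to the
    lowest index).  Each subsequent center maximizes the minimum distance to
    the already-chosen set.  Purely deterministic.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds pool size {n}")
    first = int(np.argmax(D.sum(axis=1)))  # argmax takes the lowest index on ties
    selected = [first]
    min_dist = D[first].copy()
    while len(selected) < k:
        min_dist[selected] = -np.inf
        nxt = int(np.argmax(min_dist))
        selected.append(nxt)
        min_dist = np.minimum(min_dist, D[nxt])
    return selected


def build_template_library(
    pool: list[TypedMolecule],
    k: int = 300,
    w_shape: float = DEFAULT_W_SHAPE,
    **align_kwargs,
) -> TemplateLibrary:
    """Self-similarity -> Pearson row distance -> max-min centers -> library."""
    if k > len(pool):
        raise ValueError(f"k={k} exceeds pool size {len(pool)}")
    sim = self_similarity_matrix(pool, w_shape=w_shape, **align_kwargs)
    D = row_distance_matrix(sim)
    centers = maxmin_select(D, k)
    mols = [pool[i] for i in centers]
    return TemplateLibrary(
        k=k,
        ids=[m.id for m in mols],
        shapes=[make_shape(m, 0) for m in mols],
        molecules=mols,
        w_shape=w_shape,
        build_metadata={
            "distance": "one_minus_pearson",
            "selection": "greedy_maxmin",
            "tie_rule": "lowest_index",
            "symmetrization": "max",
            "pool_hash": pool_hash(pool),
            "pool_size": len(pool),
        },
    )
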