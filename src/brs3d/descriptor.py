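"""Similarity-profile descriptor computation and persistence.

A molecule's profile is the length-k vector of maximum combined scores from
flexibly superimposing it onto each rigid template, index-aligned with the
template library order.  Batch profiling caches one small JSON file per
molecule under a directory keyed by the library fingerprint, so runs are
resumable and trivially parallel.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from joblib import Parallel, delayed

from .molio import TypedMolecule
from .shapesim import flexible_superimpose
from .templates import TemplateLibrary

logger = logging.getLogger(__name__)


@dataclass
class BRSVector:
    """One molecule's length-k similarity profile."""

    molecule_id: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class DescriptorTable:
    """Profiles for a set of molecules against one fixed library."""

    fingerprint: str
    template_ids: list[str]
    rows: list[BRSVector] = field(default_factory=list)
    missing: list[str] = field(default_factory=list)

    @property
    def ids(self) -> list[str]:
        return [r.molecule_id for r in self.rows]

    @property
    def matrix(self) -> np.ndarray:
        return np.array([r.values for r in self.rows])


def compute_brs3d(
    query: TypedMolecule,
    library: TemplateLibrary,
    top_n: int = 10,
    **align_kwargs,
) -> BRSVector:
    """Profile one molecule: element i = max combined score against template i."""
    if not query.conformers:
        raise ValueError(f"unprofiled molecule: {query.id} has no conformers")
    values = np.empty(library.k)
    for i, template in enumerate(library.shapes):
        results = flexible_superimpose(
            query, template, top_n=top_n, w_shape=library.w_shape, **align_kwargs
        )
        values[i] = results[0].combined_score
    return BRSVector(molecule_id=query.id, values=values)


def _cache_file(cache_path: Path, mol_id: str) -> Path:
    return cache_path / f"{mol_id}.json"


def _load_cached(cache_path: Path, mol_id: str) -> np.ndarray | None:
    f = _cache_file(cache_path, mol_id)
    if f.exists():
        return np.array(json.loads(f.read_text())["values"])
    return None


def batch_profile(
    mols: list[TypedMolecule],
    library: TemplateLibrary,
    cache_path: str | Path | None = None,
    top_n: int = 10,
    n_jobs: int = 1,
    **align_kwargs,
) -> DescriptorTable:
    """Profile many molecules; only missing rows are computed.

    The cache directory stores the library fingerprint; reusing it with a
    different library is refused.  Parallel execution (``n_jobs``) gives
    results identical to serial.  Molecules without conformers are recorded
    under ``table.missing`` — never zero-filled.
    """
    cache = None
    if cache_path is not None:
        cache = Path(cache_path)
        cache.mkdir(parents=True, exist_ok=True)
        fp_file = cache / "fingerprint.txt"
        if fp_file.exists():
            cached_fp = fp_file.read_text().strip()
            if cached_fp != library.fingerprint:
                raise ValueError(
                    f"cache at {cache} was built for library {cached_fp!r}, "
                    f"not {library.fingerprint!r}; refusing to mix"
                )
        else:
            fp_file.write_text(library.fingerprint + "\n")

    table = DescriptorTable(
        fingerprint=library.fingerprint, template_ids=list(library.ids)
    )
    todo: list[TypedMolecule] = []
    cached_rows: dict[str, np.ndarray] = {}
    for mol in mols:
        if mol.unprofiled or not mol.conformers:
            logger.warning("%s: no conformers; row flagged missing", mol.id)
            table.missing.append(mol.id)
            continue
        hit = _load_cached(cache, mol.id) if cache is not None else None
        if hit is not None:
            cached_rows[mol.id] = hit
        else:
            todo.append(mol)

    computed = Parallel(n_jobs=n_jobs)(
        delayed(compute_brs3d)(mol, library, top_n, **align_kwargs) for mol in todo
    )
    new_rows = {vec.molecule_id: vec.values for vec in computed}
    if cache is not None:
        for mol_id, values in new_rows.items():
            _cache_file(cache, mol_id).write_text(
                json.dumps({"values": values.tolist()})
            )

    for mol in mols:
        if mol.id in cached_rows:
            table.rows.append(BRSVector(mol.id, cached_rows[mol.id]))
        elif mol.id in new_rows:
            table.rows.append(BRSVector(mol.id, new_rows[mol.id]))
    return table


def write_table(table: DescriptorTable, path: str | Path) -> None:
    """Tab-separated table: first column molecule id, then one column per
    template, full float precision (round-trip exact)."""
    with open(path, "w") as fh:
        fh.write(f"# library={table.fingerprint}\n")
        fh.write("molecule_id\t" + "\t".join(table.template_ids) + "\n")
        for row in table.rows:
            fh.write(
                row.molecule_id
                + "\t"
                + "\t".join(repr(float(v)) for v in row.values)
                + "\n"
            )


def read_table(path: str | Path) -> DescriptorTable:
    path = Path(path)
    fingerprint = "unknown"
    with open(path) as fh:
        lines = fh.read().splitlines()
    idx = 0
    if lines and lines[0].startswith("# library="):
        fingerprint = lines[0].split("=", 1)[1]
        idx = 1
    header = lines[idx].split("\t")
    template_ids = header[1:]
    table = DescriptorTable(fingerprint=fingerprint, template_ids=template_ids)
    for lineno, line in enumerate(lines[idx + 1 :], start=idx + 2):
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != len(template_ids) + 1:
            raise ValueError(
                f"{path}:{lineno}: expected {len(template_ids) + 1} fields, "
                f"got {len(fields)}"
            )
        table.rows.append(BRSVector(fields[0], np.array([float(v) for v in fields[1:]])))
    return table
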