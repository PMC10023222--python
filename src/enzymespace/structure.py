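"""PDB structure I/O with a per-residue quality score in the B-factor column.

Structural models carry a residue-wise quality score (TopScore convention:
0–1, lower is better) in the B-factor column of the PDB file.  Reading
enforces that convention: every atom of a residue must carry the same
B-factor; deviations are averaged with a warning.  AlphaFold-style models
(pLDDT in 0–100, higher is better) can be rescaled on input to the single
internal convention via ``1 - pLDDT/100``.

Parsing and serialization are delegated to biotite's fixed-column PDB
reader/writer; this module owns the residue/chain object model, the score
convention and the validity checks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import biotite.structure as bst
from biotite.structure.io import pdb as bpdb

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "StructureModel",
    "read_pdb",
    "write_pdb",
    "residue_scores",
    "EmptyStructureError",
    "PDBParseError",
]

logger = logging.getLogger(__name__)

SCORE_CONVENTIONS = ("topscore", "plddt")

# Maximum magnitudes representable in the fixed PDB columns (8.3 / 6.2)
_COORD_MAX, _COORD_MIN = 9999.999, -999.999
_BFACTOR_MAX = 999.99


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be parsed."""


class EmptyStructureError(PDBParseError):
    """Raised when a PDB file contains no atoms."""


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,):
            raise ValueError(f"atom {self.name}: coordinate must be length 3")
        if not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: non-finite coordinate")


@dataclass
class Residue:
    """One residue (or HETATM group) with its per-residue quality score."""

    name: str
    number: int
    chain_id: str
    atoms: list[Atom] = field(default_factory=list)
    score: float = 0.0
    icode: str = ""
    hetero: bool = False

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"residue {self.name} {self.number}: no atoms")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Atom | None:
        return self.atom("CA")

    @property
    def label(self) -> str:
        return f"{self.chain_id}:{self.number}{self.icode}"

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms])

    def heavy_coords(self) -> np.ndarray:
        pts = [a.coord for a in self.atoms if a.element != "H"]
        return np.array(pts) if pts else np.empty((0, 3))


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class StructureModel:
    """Chains of ordered residues, plus HETATM groups kept as ligands."""

    chains: list[Chain] = field(default_factory=list)
    ligands: list[Residue] = field(default_factory=list)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r}")

    def residues(self) -> Iterator[Residue]:
        """All polymer residues in chain/residue order."""
        for c in self.chains:
            yield from c.residues

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    def find_residue(self, chain_id: str, number: int, icode: str = "") -> Residue:
        for r in self.chain(chain_id).residues:
            if r.number == number and r.icode == icode:
                return r
        raise KeyError(f"no residue {chain_id}:{number}{icode}")


def _score_from_bfactor(raw: float, convention: str) -> float:
    if convention == "topscore":
        return raw
    if convention == "plddt":
        return 1.0 - raw / 100.0
    raise ValueError(f"unknown score convention {convention!r}; use one of {SCORE_CONVENTIONS}")


def read_pdb(path: str | Path, score_convention: str = "topscore") -> StructureModel:
    """Read a PDB file into a :class:`StructureModel`.

    The B-factor column is interpreted as the per-residue quality score
    under ``score_convention``; mixed B-factors within a residue are
    averaged with a warning.  Only the first MODEL of multi-model files is
    read; for alternate locations the highest-occupancy atom is kept.
    Insertion codes are preserved.
    """
    if score_convention not in SCORE_CONVENTIONS:
        raise ValueError(
            f"unknown score convention {score_convention!r}; use one of {SCORE_CONVENTIONS}"
        )
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise EmptyStructureError(f"{path}: empty file")
    # Light pre-validation so parse errors carry line numbers.
    n_atom_lines = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            n_atom_lines += 1
            try:
                for lo, hi in ((30, 38), (38, 46), (46, 54), (60, 66)):
                    float(line[lo:hi])
            except ValueError:
                raise PDBParseError(f"{path}: unparsable ATOM/HETATM record at line {lineno}")
    if n_atom_lines == 0:
        raise EmptyStructureError(f"{path}: no ATOM or HETATM records")

    pdb_file = bpdb.PDBFile.read(str(path))
    try:
        atoms = bpdb.get_structure(
            pdb_file, model=1, altloc="occupancy", extra_fields=["b_factor", "occupancy"]
        )
    except Exception as exc:  # biotite raises several parse exception types
        raise PDBParseError(f"{path}: {exc}") from exc
    if atoms.array_length() == 0:
        raise EmptyStructureError(f"{path}: no atoms parsed")
    return model_from_atom_array(atoms, score_convention=score_convention, origin=str(path))


def model_from_atom_array(
    atoms: bst.AtomArray, score_convention: str = "topscore", origin: str = "<array>"
) -> StructureModel:
    """Group a biotite AtomArray into the residue/chain object model."""
    model = StructureModel()
    chain_index: dict[str, Chain] = {}
    starts = bst.get_residue_starts(atoms)
    boundaries = list(starts) + [atoms.array_length()]
    for lo, hi in zip(boundaries[:-1], boundaries[1:]):
        sub = atoms[lo:hi]
        b = np.asarray(sub.b_factor, dtype=float)
        if not np.allclose(b, b[0], atol=5e-3):
            logger.warning(
                "%s: residue %s %d has mixed B-factors; using the mean",
                origin,
                sub.res_name[0],
                int(sub.res_id[0]),
            )
        score = _score_from_bfactor(float(np.mean(b)), score_convention)
        res = Residue(
            name=str(sub.res_name[0]),
            number=int(sub.res_id[0]),
            chain_id=str(sub.chain_id[0]),
            icode=str(sub.ins_code[0]).strip(),
            hetero=bool(sub.hetero[0]),
            score=score,
            atoms=[
                Atom(
                    name=str(sub.atom_name[k]),
                    element=str(sub.element[k]),
                    coord=np.array(sub.coord[k], dtype=float),
                    occupancy=float(sub.occupancy[k]),
                )
                for k in range(sub.array_length())
            ],
        )
        if res.hetero:
            model.ligands.append(res)
        else:
            chain = chain_index.get(res.chain_id)
            if chain is None:
                chain = Chain(id=res.chain_id)
                chain_index[res.chain_id] = chain
                model.chains.append(chain)
            chain.residues.append(res)
    return model


def _to_atom_array(model: StructureModel, score_convention: str = "topscore") -> bst.AtomArray:
    records: list[tuple[Residue, bool]] = [(r, False) for r in model.residues()]
    records += [(r, True) for r in model.ligands]
    n = sum(len(r.atoms) for r, _ in records)
    arr = bst.AtomArray(n)
    arr.add_annotation("b_factor", dtype=float)
    arr.add_annotation("occupancy", dtype=float)
    i = 0
    for res, het in records:
        if score_convention == "topscore":
            b = res.score
        else:
            b = 100.0 * (1.0 - res.score)
        for atom in res.atoms:
            arr.chain_id[i] = res.chain_id
            arr.res_id[i] = res.number
            arr.ins_code[i] = res.icode
            arr.res_name[i] = res.name
            arr.hetero[i] = het
            arr.atom_name[i] = atom.name
            arr.element[i] = atom.element
            arr.coord[i] = atom.coord
            arr.b_factor[i] = b
            arr.occupancy[i] = atom.occupancy
            i += 1
    return arr


def write_pdb(model: StructureModel, path: str | Path, score_convention: str = "topscore") -> None:
    """Write a model as fixed-column PDB (coords %.3f, B-factor %.2f).

    The per-residue score is placed in the B-factor column so that
    ``read_pdb(write_pdb(m))`` preserves residue count, atom names,
    coordinates and scores at format precision.
    """
    for res in list(model.residues()) + list(model.ligands):
        for atom in res.atoms:
            if np.any(atom.coord > _COORD_MAX) or np.any(atom.coord < _COORD_MIN):
                raise ValueError(
                    f"residue {res.label} atom {atom.name}: coordinate "
                    f"{atom.coord} overflows fixed PDB columns"
                )
        if not 0 <= res.score <= _BFACTOR_MAX:
            raise ValueError(f"residue {res.label}: score {res.score} outside B-factor columns")
    arr = _to_atom_array(model, score_convention)
    pdb_file = bpdb.PDBFile()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bpdb.set_structure(pdb_file, arr)
    pdb_file.write(str(path))


def residue_scores(model: StructureModel) -> dict[str, list[float]]:
    """Per-chain ordered per-residue score sequences."""
    return {c.id: [r.score for r in c.residues] for c in model.chains}
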