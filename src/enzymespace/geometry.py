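"""Per-residue geometric descriptors: SASA, exposure, contacts, secondary structure.

These descriptors feed the terminal-disorder trimming criteria and the
model-quality analyses:

* solvent accessible surface area (SASA) by the Shrake–Rupley rolling-probe
  point-sampling algorithm;
* relative SASA, normalized by the residue type's theoretical maximum
  (Tien et al. 2013 "theoretical" column);
* contact density, the number of spatial neighbors of a residue under a
  pinned Cβ/8 Å/sequence-separation ≥ 3 convention;
* secondary-structure labels {H, E, C} from Cα geometry (P-SEA-style
  distance/angle windows, via biotite's assigner), which works on models
  lacking full backbones.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree
import biotite.structure as bst

from .structure import Residue, StructureModel

__all__ = [
    "SasaParams",
    "ContactParams",
    "ResidueDescriptors",
    "sphere_points",
    "sasa_from_spheres",
    "sasa_shrake_rupley",
    "relative_sasa",
    "contact_densities",
    "contact_density",
    "assign_secondary_structure",
    "compute_descriptors",
    "MAX_SASA_TIEN_2013",
    "VDW_RADII",
]

logger = logging.getLogger(__name__)

# Van der Waals radii by element (Å); unknown elements fall back to carbon
# with a warning unless strict mode is on.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
}
FALLBACK_RADIUS = 1.70

# Theoretical maximum SASA per residue type (Tien et al. 2013), Å².
MAX_SASA_TIEN_2013: dict[str, float] = {
    "ALA": 129.0,
    "ARG": 274.0,
    "ASN": 195.0,
    "ASP": 193.0,
    "CYS": 167.0,
    "GLN": 225.0,
    "GLU": 223.0,
    "GLY": 104.0,
    "HIS": 224.0,
    "ILE": 197.0,
    "LEU": 201.0,
    "LYS": 236.0,
    "MET": 224.0,
    "PHE": 240.0,
    "PRO": 159.0,
    "SER": 155.0,
    "THR": 172.0,
    "TRP": 285.0,
    "TYR": 263.0,
    "VAL": 174.0,
}


@dataclass(frozen=True)
class SasaParams:
    probe_radius: float = 1.4
    sphere_points: int = 960
    radii: Mapping[str, float] = field(default_factory=lambda: dict(VDW_RADII))
    strict: bool = False

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be positive")
        if self.sphere_points < 92:
            raise ValueError("sphere_points must be >= 92")

    def radius_of(self, element: str, context: str = "") -> float:
        el = element.strip().upper()
        if el in self.radii:
            return self.radii[el]
        if self.strict:
            raise KeyError(f"no van der Waals radius for element {element!r} ({context})")
        logger.warning(
            "no vdW radius for element %r (%s); using %.2f Å", element, context, FALLBACK_RADIUS
        )
        return FALLBACK_RADIUS


@dataclass(frozen=True)
class ContactParams:
    """Contact convention: Cβ atoms (Cα for Gly) within ``cutoff``, at least
    ``min_separation`` apart in sequence."""

    cutoff: float = 8.0
    min_separation: int = 3


@dataclass
class ResidueDescriptors:
    sasa: float
    relative_sasa: float
    contact_density: int
    ss_label: str  # one of H, E, C

    def __post_init__(self) -> None:
        if self.sasa < 0:
            raise ValueError("sasa must be >= 0")
        if self.ss_label not in ("H", "E", "C"):
            raise ValueError(f"bad secondary structure label {self.ss_label!r}")


def sphere_points(n: int) -> np.ndarray:
    """``n`` quasi-uniform points on the unit sphere (golden-spiral lattice)."""
    k = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0))  # golden angle
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    theta = phi * k
    return np.column_stack((r * np.cos(theta), r * np.sin(theta), z))


def sasa_from_spheres(
    coords: np.ndarray, radii: np.ndarray, params: SasaParams = SasaParams()
) -> np.ndarray:
    """Shrake–Rupley SASA for arbitrary spheres.

    For each atom, test points are placed quasi-uniformly on its
    solvent-expanded sphere (radius + probe); the accessible fraction is the
    share of points lying inside no neighbor's expanded sphere, scaled by
    the expanded sphere's area 4π(r+p)².
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(coords)
    if n == 0:
        return np.zeros(0)
    expanded = radii + params.probe_radius
    unit = sphere_points(params.sphere_points)
    tree = cKDTree(coords)
    max_exp = expanded.max()
    out = np.zeros(n)
    for i in range(n):
        pts = coords[i] + expanded[i] * unit
        neighbors = [j for j in tree.query_ball_point(coords[i], expanded[i] + max_exp) if j != i]
        accessible = np.ones(len(pts), dtype=bool)
        for j in neighbors:
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            accessible &= d2 >= expanded[j] ** 2
        out[i] = accessible.mean() * 4.0 * math.pi * expanded[i] ** 2
    return out


def sasa_shrake_rupley(
    model: StructureModel,
    params: SasaParams = SasaParams(),
    include_ligands: bool = False,
) -> tuple[dict[str, float], list[tuple[str, str, float]]]:
    """Per-residue and per-atom SASA of a model.

    Returns ``(residue_sasa, atom_sasa)`` where ``residue_sasa`` maps the
    residue label (``chain:number``) to the sum over its atoms, and
    ``atom_sasa`` lists ``(residue_label, atom_name, sasa)``.  Ligand atoms
    occlude the protein surface; their own areas are reported only when
    ``include_ligands`` is set.
    """
    residues = list(model.residues())
    entries: list[tuple[Residue, bool]] = [(r, True) for r in residues]
    entries += [(r, include_ligands) for r in model.ligands]
    coords, radii, owner = [], [], []
    for res, reported in entries:
        for atom in res.atoms:
            coords.append(atom.coord)
            radii.append(params.radius_of(atom.element, context=f"{res.label} {atom.name}"))
            owner.append((res, atom.name, reported))
    areas = sasa_from_spheres(np.array(coords), np.array(radii), params)
    residue_sasa: dict[str, float] = {}
    atom_sasa: list[tuple[str, str, float]] = []
    for (res, atom_name, reported), area in zip(owner, areas):
        if not reported:
            continue
        residue_sasa[res.label] = residue_sasa.get(res.label, 0.0) + float(area)
        atom_sasa.append((res.label, atom_name, float(area)))
    return residue_sasa, atom_sasa


def relative_sasa(
    residue_sasa: float,
    residue_type: str,
    max_sasa: Mapping[str, float] = MAX_SASA_TIEN_2013,
) -> float:
    """SASA normalized by the residue type's maximum attainable SASA.

    May exceed 1 for terminal residues, which expose more surface than the
    Gly-X-Gly reference context behind the normalization table.
    """
    key = residue_type.strip().upper()
    if key not in max_sasa:
        raise KeyError(f"no maximum-SASA reference for residue type {residue_type!r}")
    if residue_sasa < 0:
        raise ValueError("residue_sasa must be >= 0")
    return residue_sasa / max_sasa[key]


def _contact_anchor(res: Residue) -> np.ndarray | None:
    atom = res.atom("CB")
    if atom is None or res.name == "GLY":
        atom = res.ca
    return None if atom is None else atom.coord


def contact_densities(
    model: StructureModel, params: ContactParams = ContactParams()
) -> dict[str, int]:
    """Contact density for every polymer residue, keyed by residue label.

    Within a chain, pairs closer than ``min_separation`` in sequence are
    excluded; across chains every pair is eligible.  The contribution is
    symmetric: i counts j exactly when j counts i.
    """
    anchors: list[tuple[str, int, np.ndarray]] = []  # (chain, position, coord)
    labels: list[str] = []
    for chain in model.chains:
        for pos, res in enumerate(chain.residues):
            coord = _contact_anchor(res)
            if coord is not None:
                anchors.append((chain.id, pos, coord))
                labels.append(res.label)
    counts = {label: 0 for label in labels}
    if not anchors:
        return counts
    coords = np.array([a[2] for a in anchors])
    tree = cKDTree(coords)
    for i, j in tree.query_pairs(params.cutoff):
        ci, pi, _ = anchors[i]
        cj, pj, _ = anchors[j]
        if ci == cj and abs(pi - pj) < params.min_separation:
            continue
        counts[labels[i]] += 1
        counts[labels[j]] += 1
    return counts


def contact_density(
    model: StructureModel,
    chain_id: str,
    number: int,
    params: ContactParams = ContactParams(),
) -> int:
    """Contact density of a single residue (by chain and residue number)."""
    res = model.find_residue(chain_id, number)
    return contact_densities(model, params)[res.label]


def assign_secondary_structure(model: StructureModel) -> dict[str, list[str]]:
    """Per-residue secondary structure labels {H, E, C} from Cα geometry.

    Uses P-SEA-style Cα distance/angle windows (biotite's assigner).
    Residues without a Cα, chains too short for the windows, and
    non-standard residues are labelled C.
    """
    out: dict[str, list[str]] = {}
    mapping = {"a": "H", "b": "E", "c": "C"}
    for chain in model.chains:
        labels = ["C"] * len(chain.residues)
        with_ca = [(k, r) for k, r in enumerate(chain.residues) if r.ca is not None]
        for k, r in enumerate(chain.residues):
            if r.ca is None:
                logger.warning("residue %s lacks CA; labelled C", r.label)
        if len(with_ca) >= 5:
            arr = bst.AtomArray(len(with_ca))
            for idx, (k, res) in enumerate(with_ca):
                arr.chain_id[idx] = chain.id
                arr.res_id[idx] = idx + 1  # positional numbering for the assigner
                arr.res_name[idx] = res.name
                arr.atom_name[idx] = "CA"
                arr.element[idx] = "C"
                arr.coord[idx] = res.ca.coord
            try:
                sse = bst.annotate_sse(arr)
            except Exception:
                sse = np.array(["c"] * len(with_ca))
            amino = bst.filter_amino_acids(arr)
            pos = 0
            for idx, (k, _res) in enumerate(with_ca):
                if amino[idx] and pos < len(sse):
                    labels[k] = mapping.get(str(sse[pos]), "C")
                    pos += 1
        out[chain.id] = labels
    return out


def compute_descriptors(
    model: StructureModel,
    sasa_params: SasaParams = SasaParams(),
    contact_params: ContactParams = ContactParams(),
    max_sasa: Mapping[str, float] = MAX_SASA_TIEN_2013,
) -> dict[str, ResidueDescriptors]:
    """All per-residue descriptors of a model, keyed by residue label."""
    residue_sasa, _ = sasa_shrake_rupley(model, sasa_params)
    contacts = contact_densities(model, contact_params)
    ss = assign_secondary_structure(model)
    out: dict[str, ResidueDescriptors] = {}
    for chain in model.chains:
        for k, res in enumerate(chain.residues):
            sasa = residue_sasa.get(res.label, 0.0)
            try:
                rel = relative_sasa(sasa, res.name, max_sasa)
            except KeyError:
                logger.warning("residue %s: unknown type for relative SASA; set 0", res.label)
                rel = 0.0
            out[res.label] = ResidueDescriptors(
                sasa=sasa,
                relative_sasa=rel,
                contact_density=contacts.get(res.label, 0),
                ss_label=ss[chain.id][k],
            )
    return out
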