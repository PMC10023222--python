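"""Synthetic sequence families and structures with controlled properties.

Everything the toolkit consumes can be generated here deterministically:

* sequence families mutated from a common ancestor at a controlled
  identity, with EC labels attached — for the clustering stage;
* structural models built from ideal backbone torsions (helix φ=−57°/
  ψ=−47°, strand φ=−120°/ψ=+120°, randomized coil) with a per-segment
  quality-score profile written to the B-factor column — for the
  descriptor, trimming and quality stages;
* toy pocket geometries (an enclosed cavity, an open cleft, a flat
  surface) with a ligand and a binding site — for the buriedness stage,
  plus a two-chain template-assembly variant for the noncomplete pathway.

Generators are pure functions of their seed: the same seed and recipe give
byte-identical output files.  Side chains are reduced to an ideal Cβ; the
geometry is intentionally idealized — identity, topology and exposure are
what the consumers measure, not physical realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .binding_site import BindingSite, TemplateAssembly
from .ec import EnzymeRecord, parse_ec
from .structure import Atom, Chain, Residue, StructureModel

__all__ = [
    "Segment",
    "make_sequence_family",
    "make_structure",
    "make_pocket_model",
    "make_template_assembly",
    "make_study_set",
    "place_atom",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Ideal backbone geometry (lengths Å, angles deg)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8

TORSIONS = {"helix": (-57.0, -47.0), "strand": (-120.0, 120.0)}


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray, length: float, angle: float, torsion: float) -> np.ndarray:
    """Natural-extension-reference-frame placement of atom d.

    Returns the point at ``length`` from c, with bond angle b-c-d of
    ``angle`` degrees and torsion a-b-c-d of ``torsion`` degrees.
    """
    ang = math.radians(angle)
    tor = math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -length * math.cos(ang),
            length * math.sin(ang) * math.cos(tor),
            length * math.sin(ang) * math.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


@dataclass(frozen=True)
class Segment:
    """A stretch of one secondary-structure kind with a quality score.

    ``score`` is the per-residue B-factor value written for the segment
    (TopScore convention, 0–1 lower is better); a sequence of per-residue
    values of the segment's length is also accepted.
    """

    kind: str  # helix | strand | coil
    length: int
    score: float | tuple[float, ...] = 0.1

    def __post_init__(self) -> None:
        if self.kind not in ("helix", "strand", "coil"):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.length < 1:
            raise ValueError("segment length must be >= 1")
        if not isinstance(self.score, float | int) and len(self.score) != self.length:
            raise ValueError("per-residue score profile must match segment length")

    def scores(self) -> list[float]:
        if isinstance(self.score, float | int):
            return [float(self.score)] * self.length
        return [float(s) for s in self.score]


def _segment_torsions(segments: Sequence[Segment], rng: np.random.Generator) -> list[tuple[float, float]]:
    torsions: list[tuple[float, float]] = []
    for seg in segments:
        for _ in range(seg.length):
            if seg.kind in TORSIONS:
                torsions.append(TORSIONS[seg.kind])
            else:
                # sterically plausible but incoherent: consecutive residues
                # almost never satisfy the same helix/strand window
                phi = float(rng.uniform(-160.0, -50.0))
                psi = float(rng.uniform(-180.0, 180.0))
                torsions.append((phi, psi))
    return torsions


def _build_backbone(torsions: Sequence[tuple[float, float]]) -> list[dict[str, np.ndarray]]:
    n_res = len(torsions)
    coords: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = math.radians(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = coords[i - 1]
        psi_prev = torsions[i - 1][1]
        n_i = place_atom(prev["N"], prev["CA"], prev["C"], BOND_C_N, ANGLE_CA_C_N, psi_prev)
        ca_i = place_atom(prev["CA"], prev["C"], n_i, BOND_N_CA, ANGLE_C_N_CA, 180.0)
        phi_i = torsions[i][0]
        c_i = place_atom(prev["C"], n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi_i)
        coords.append({"N": n_i, "CA": ca_i, "C": c_i})
    # carbonyl O and ideal Cβ
    for i, res in enumerate(coords):
        psi = torsions[i][1]
        res["O"] = place_atom(res["N"], res["CA"], res["C"], BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
        b = res["CA"] - res["N"]
        c = res["C"] - res["CA"]
        a = np.cross(b, c)
        res["CB"] = -0.58273431 * a + 0.56802827 * b - 0.54067466 * c + res["CA"]
    return coords


def _has_clash(coords: Sequence[dict[str, np.ndarray]], min_dist: float = 1.5) -> bool:
    pts = np.array([res[name] for res in coords for name in ("N", "CA", "C")])
    owner = np.repeat(np.arange(len(coords)), 3)
    from scipy.spatial import cKDTree

    tree = cKDTree(pts)
    for i, j in tree.query_pairs(min_dist):
        if abs(int(owner[i]) - int(owner[j])) >= 2:
            return True
    return False


def make_structure(
    segments: Sequence[Segment],
    seed: int = 0,
    chain_id: str = "A",
    sequence: str | None = None,
    max_retries: int = 50,
) -> StructureModel:
    """Build a single-chain model from ideal per-segment torsions.

    Helix and strand segments use ideal φ/ψ; coil segments draw randomized
    torsions from the seed and are regenerated (up to ``max_retries``) if
    the backbone self-clashes below 1.5 Å.  Each residue gets N, CA, C, O
    and an ideal tetrahedral CB (except Gly), and its segment's score in
    the B-factor column.  ``sequence`` gives one-letter residue types
    (default poly-alanine).
    """
    segments = list(segments)
    n_res = sum(s.length for s in segments)
    rng = np.random.default_rng(seed)
    coords = None
    for _attempt in range(max_retries):
        torsions = _segment_torsions(segments, rng)
        candidate = _build_backbone(torsions)
        if not _has_clash(candidate):
            coords = candidate
            break
    if coords is None:
        raise RuntimeError(f"could not build a clash-free backbone in {max_retries} attempts")

    one_to_three = {
        "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
        "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
        "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
        "W": "TRP", "Y": "TYR",
    }
    if sequence is None:
        sequence = "A" * n_res
    if len(sequence) != n_res:
        raise ValueError("sequence length must match total segment length")

    scores = [s for seg in segments for s in seg.scores()]
    chain = Chain(id=chain_id)
    for i in range(n_res):
        res_name = one_to_three[sequence[i]]
        atoms = [
            Atom("N", "N", coords[i]["N"]),
            Atom("CA", "C", coords[i]["CA"]),
            Atom("C", "C", coords[i]["C"]),
            Atom("O", "O", coords[i]["O"]),
        ]
        if res_name != "GLY":
            atoms.append(Atom("CB", "C", coords[i]["CB"]))
        chain.residues.append(
            Residue(name=res_name, number=i + 1, chain_id=chain_id, atoms=atoms, score=scores[i])
        )
    return StructureModel(chains=[chain])


def make_sequence_family(
    seed: int,
    n: int,
    target_identity: float,
    ec_labels: Sequence[str] | str,
    length: int = 200,
    accession_prefix: str = "SYN",
    organism: str = "synthetic construct",
    tolerance: float = 0.05,
    max_resample: int = 200,
) -> list[EnzymeRecord]:
    """A family of ``n`` sequences at a controlled identity to an ancestor.

    Each member mutates every ancestor site independently with probability
    ``1 - target_identity`` (to a uniformly drawn different residue) and is
    resampled until its realized identity to the ancestor lies within
    ``tolerance`` of the target.  ``ec_labels`` may be one EC string for
    the whole family or one per member; a ';'-separated entry attaches
    several EC numbers to that member.
    """
    if n < 1:
        raise ValueError("family size must be >= 1")
    if not 0 < target_identity <= 1:
        raise ValueError("target_identity must be in (0, 1]")
    if length * tolerance < 1:
        raise ValueError(
            f"identity tolerance {tolerance} is below the attainable resolution 1/{length}"
        )
    if isinstance(ec_labels, str):
        ec_labels = [ec_labels] * n
    if len(ec_labels) != n:
        raise ValueError("need one EC label entry per member")

    rng = np.random.default_rng(seed)
    alphabet = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    ancestor = rng.choice(alphabet, size=length)
    rate = 1.0 - target_identity

    records: list[EnzymeRecord] = []
    for i in range(n):
        for _ in range(max_resample):
            seq = ancestor.copy()
            mutate = rng.random(length) < rate
            if mutate.any():
                # draw a *different* residue at each mutated site
                offsets = rng.integers(1, len(alphabet), size=int(mutate.sum()))
                idx_old = np.searchsorted(alphabet, seq[mutate])
                seq[mutate] = alphabet[(idx_old + offsets) % len(alphabet)]
            realized = float((seq == ancestor).mean())
            if abs(realized - target_identity) <= tolerance:
                break
        else:
            raise RuntimeError("could not realize the target identity; length too short?")
        ecs = tuple(parse_ec(tok) for tok in str(ec_labels[i]).split(";"))
        records.append(
            EnzymeRecord(
                accession=f"{accession_prefix}{i:03d}",
                sequence=seq.tobytes().decode(),
                ec_numbers=ecs,
                organism=organism,
                keywords=("synthetic",),
            )
        )
    return records


def _lattice_box(lo: np.ndarray, hi: np.ndarray, spacing: float) -> np.ndarray:
    axes = [np.arange(lo[k], hi[k] + spacing / 2, spacing) for k in range(3)]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)


def _pseudo_chain(points: np.ndarray, chain_id: str = "A", score: float = 0.1) -> Chain:
    chain = Chain(id=chain_id)
    for i, pt in enumerate(points):
        chain.residues.append(
            Residue(
                name="ALA",
                number=i + 1,
                chain_id=chain_id,
                atoms=[Atom("CA", "C", np.asarray(pt, dtype=float))],
                score=score,
            )
        )
    return chain


def make_pocket_model(
    depth_mode: str, seed: int = 0
) -> tuple[StructureModel, Residue, BindingSite]:
    """A toy pocket: (model, ligand group, binding site).

    ``enclosed`` carves a cavity in the middle of a solid atom lattice (the
    ligand sits inside, fully surrounded); ``cleft`` carves a hemispherical
    depression into the top face of a slab; ``flat`` rests the ligand on an
    intact flat face.  By construction the three modes produce high,
    intermediate and near-zero mean degrees of buriedness.
    """
    if depth_mode not in ("enclosed", "cleft", "flat"):
        raise ValueError("depth_mode must be enclosed, cleft or flat")
    spacing = 1.4
    if depth_mode == "enclosed":
        pts = _lattice_box(np.array([-7.0] * 3), np.array([7.0] * 3), spacing)
        pts = pts[np.linalg.norm(pts, axis=1) > 4.2]  # carve central cavity
        ligand_center = np.zeros(3)
    else:
        pts = _lattice_box(np.array([-8.0, -8.0, -6.0]), np.array([8.0, 8.0, 0.0]), spacing)
        if depth_mode == "cleft":
            pts = pts[np.linalg.norm(pts - np.array([0.0, 0.0, 0.6]), axis=1) > 4.2]
            ligand_center = np.array([0.0, 0.0, -1.2])
        else:
            ligand_center = np.array([0.0, 0.0, 2.6])

    model = StructureModel(chains=[_pseudo_chain(pts)])
    ligand = Residue(
        name="LIG",
        number=9001,
        chain_id="L",
        hetero=True,
        atoms=[Atom("C1", "C", ligand_center)],
        score=0.0,
    )
    model.ligands.append(ligand)

    from .binding_site import site_from_ligand

    site = site_from_ligand(model, ligand, cutoff=4.6)
    return model, ligand, site


def make_template_assembly(
    model: StructureModel,
    site: BindingSite,
    with_partner: bool,
    partner_offset: float = 4.0,
) -> TemplateAssembly:
    """Template assembly for a pocket model: chain A mirrors the model.

    With ``with_partner``, a small second chain (B) is placed hovering
    ``partner_offset`` Å above the site centroid — the unmodeled
    complementary surface recorded by the template's stoichiometry.
    """
    chain_a = Chain(id="A")
    for res in model.residues():
        chain_a.residues.append(
            Residue(
                name=res.name,
                number=res.number,
                chain_id="A",
                atoms=[Atom(a.name, a.element, a.coord.copy()) for a in res.atoms],
                score=res.score,
            )
        )
    chains = [chain_a]
    if with_partner:
        site_pts = np.vstack([r.coords() for r in site.residue_objects(model)])
        centroid = site_pts.mean(axis=0)
        top = site_pts[:, 2].max()
        anchor = np.array([centroid[0], centroid[1], top + partner_offset])
        offsets = _lattice_box(np.array([-2.0, -2.0, 0.0]), np.array([2.0, 2.0, 2.0]), 2.0)
        chains.append(_pseudo_chain(offsets + anchor, chain_id="B"))
    template = StructureModel(chains=chains)
    alignment = {(res.chain_id, res.number): ("A", res.number) for res in model.residues()}
    return TemplateAssembly(structure=template, alignment=alignment)


def make_study_set(seed: int = 0) -> dict:
    """A complete synthetic study: families, annotations, models, scores.

    Emulates the inputs of a structural coverage map at desk scale: five
    sequence families (within-family ancestor identity 0.85, between-family
    sequences unrelated) labelled across EC classes, one member carrying
    two EC numbers from different subsub-classes, a structural model with a
    disordered N-tail for the representative of the first family, and raw
    TopScore-convention model scores plus template identities for every
    representative.
    """
    rng = np.random.default_rng(seed)
    specs = [
        ("GTP", 8, "3.6.5.2"),
        ("ADH", 6, "1.1.1.1"),
        ("ACT", 5, "2.3.1.12"),
        ("PEP", 4, "3.4.21.1"),
        ("LIG", 2, "6.3.2.1"),
    ]
    records: list[EnzymeRecord] = []
    for k, (prefix, n, ec) in enumerate(specs):
        labels: list[str] = [ec] * n
        if prefix == "GTP":
            labels[3] = "3.6.5.2;3.6.1.1"  # one bifunctional member
        records.extend(
            make_sequence_family(
                seed=int(rng.integers(0, 2**31 - 1)),
                n=n,
                target_identity=0.85,
                ec_labels=labels,
                length=120 + 10 * k,
                accession_prefix=prefix,
            )
        )
    # a trimmable model: disordered N-tail (high score) + confident helix body
    tail_scores = tuple(float(s) for s in rng.uniform(0.7, 0.9, size=12))
    structure = make_structure(
        [Segment("coil", 12, tail_scores), Segment("helix", 30, 0.1)],
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    raw_topscore = {
        f"{prefix}{0:03d}": round(float(rng.uniform(0.05, 0.55)), 3) for prefix, _, _ in specs
    }
    template_identity = {
        acc: round(float(rng.uniform(0.35, 0.95)), 3) for acc in raw_topscore
    }
    return {
        "records": records,
        "structure": structure,
        "raw_topscore": raw_topscore,
        "template_identity": template_identity,
    }
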