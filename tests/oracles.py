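"""Independent oracles: small, slow re-derivations used only by the tests."""

from __future__ import annotations

import math
import statistics

import numpy as np


def mc_sasa(coords, radii, probe=1.4, n_samples=40000, seed=0):
    """Monte-Carlo SASA: random points on each expanded sphere, rejection
    against all other expanded spheres."""
    rng = np.random.default_rng(seed)
    coords = np.asarray(coords, float)
    expanded = np.asarray(radii, float) + probe
    out = np.zeros(len(coords))
    for i in range(len(coords)):
        v = rng.normal(size=(n_samples, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = coords[i] + expanded[i] * v
        free = np.ones(n_samples, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            free &= np.linalg.norm(pts - coords[j], axis=1) >= expanded[j]
        out[i] = free.mean() * 4 * math.pi * expanded[i] ** 2
    return out


def two_sphere_cap_sasa(R: float, d: float) -> float:
    """Analytic SASA of one of two equal expanded spheres (radius R) at
    center distance d < 2R: full sphere minus the buried spherical cap."""
    cap_height = R - d / 2.0
    return 4 * math.pi * R * R - 2 * math.pi * R * cap_height


def biopython_global_score(a: str, b: str, match=1, mismatch=0, open_=-5, extend=-1):
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = open_
    aligner.extend_gap_score = extend
    return aligner.score(a, b)


def biopython_identity(a: str, b: str) -> float:
    """Identity (stripped terminal-gap denominator) from a Biopython global
    alignment under the package's scoring."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    aln = aligner.align(a, b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    start, end = 0, len(ga)
    while start < end and (set(ga[:start + 1]) <= {"-"} or set(gb[:start + 1]) <= {"-"}):
        start += 1
    while end > start and (set(ga[end - 1:]) <= {"-"} or set(gb[end - 1:]) <= {"-"}):
        end -= 1
    ga, gb = ga[start:end], gb[start:end]
    matches = sum(1 for x, y in zip(ga, gb) if x == y and x != "-")
    return matches / len(ga) if ga else 0.0


def greedy_oracle(records, identity_matrix, cutoff=0.30):
    """Brute-force greedy clustering from a precomputed identity matrix.

    ``identity_matrix`` maps frozenset({acc_a, acc_b}) -> identity.
    Returns a list of (representative, set_of_members).
    """
    order = sorted(records, key=lambda r: (-len(r.sequence), r.accession))
    clusters: list[tuple[str, set]] = []
    for rec in order:
        for k, (rep, members) in enumerate(clusters):
            ident = 1.0 if rec.accession == rep else identity_matrix[frozenset((rec.accession, rep))]
            if ident >= cutoff:
                members.add(rec.accession)
                break
        else:
            clusters.append((rec.accession, {rec.accession}))
    return clusters


def trim_criteria_oracle(
    region_len: int,
    terminal: str,
    ss_element_lengths: list[int],
    rel_sasas: list[float],
    contacts: list[int],
) -> bool:
    """Hand-coded restatement of the five removal criteria.

    (i) >= 10 residues; (ii) no intersecting helix/strand element longer
    than 5; (iii) lower-median relative SASA strictly > 0.40; (iv)
    lower-median contact count strictly < 4; (v) terminal region only.
    """
    c1 = region_len >= 10
    c2 = all(n <= 5 for n in ss_element_lengths)
    c3 = statistics.median_low(sorted(rel_sasas)) > 0.40
    c4 = statistics.median_low(sorted(contacts)) < 4
    c5 = terminal in ("N", "C")
    return c1 and c2 and c3 and c4 and c5


def ray_march_dob(point, directions, atom_coords, atom_radii, scan_range=10.0):
    """Scalar per-atom ray/sphere scan for one grid point (independent of
    the vectorized implementation)."""
    dob = 0
    for d in directions:
        blocked = []
        for sign in (1.0, -1.0):
            direction = sign * np.asarray(d, float)
            hit = False
            for c, r in zip(atom_coords, atom_radii):
                rel = np.asarray(c, float) - np.asarray(point, float)
                t_mid = float(np.dot(rel, direction))
                d2 = float(np.dot(rel, rel)) - t_mid * t_mid
                disc = r * r - d2
                if disc < 0:
                    continue
                t_enter = t_mid - math.sqrt(disc)
                if 0 < t_enter <= scan_range:
                    hit = True
                    break
            blocked.append(hit)
        if blocked[0] and blocked[1]:
            dob += 1
    return dob
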