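"""Identity-based greedy sequence clustering with functional-purity splitting.

A desk-scale clusterer in the CD-HIT tradition: sequences are sorted
longest-first and each joins the first cluster whose representative it
matches at or above the identity cutoff (default 30%), otherwise it founds
a new cluster.  Clusters mixing several EC subsub-classes are then split so
that every cluster is pure in its three-level EC function, guaranteeing a
representative per subsub-class.

Identity is computed from a global (Needleman–Wunsch, affine-gap) alignment
as identical aligned pairs divided by alignment columns after stripping
terminal-gap columns.  The aligner uses a deterministic traceback
(diagonal > gap-in-second > gap-in-first) so results are reproducible
byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .ec import EnzymeRecord

__all__ = [
    "ClusteringParams",
    "SequenceCluster",
    "align_global",
    "global_identity",
    "greedy_cluster",
    "select_representative",
    "split_by_subsubclass",
    "write_clusters_tsv",
    "read_clusters_tsv",
]

logger = logging.getLogger(__name__)

UNCLASSIFIED = "unclassified"

_NEG_INF = float("-inf")


@dataclass(frozen=True)
class ClusteringParams:
    """Clustering cutoff and alignment scoring.

    Gap of length L is scored ``gap_open + (L - 1) * gap_extend``.
    """

    identity_cutoff: float = 0.30
    match: int = 1
    mismatch: int = 0
    gap_open: int = -5
    gap_extend: int = -1

    def __post_init__(self) -> None:
        if not 0 < self.identity_cutoff <= 1:
            raise ValueError("identity_cutoff must be in (0, 1]")


@dataclass
class SequenceCluster:
    """A homologous cluster: representative plus members with identities.

    The representative is a member of its own cluster at identity 1.0.
    After subsub-class splitting, ``subsub_class`` holds the single
    three-level EC key shared by all members (or ``"unclassified"``).
    """

    representative: str
    members: dict[str, float] = field(default_factory=dict)
    subsub_class: str | None = None

    @property
    def accessions(self) -> list[str]:
        return list(self.members)

    def __len__(self) -> int:
        return len(self.members)


def align_global(
    seq_a: str, seq_b: str, params: ClusteringParams = ClusteringParams()
) -> tuple[float, str, str]:
    """Global affine-gap alignment (Gotoh); returns (score, gapped_a, gapped_b).

    Traceback ties are broken deterministically: match/mismatch state is
    preferred over a gap in ``seq_b``, which is preferred over a gap in
    ``seq_a``.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align empty sequence")
    n, m = len(seq_a), len(seq_b)
    go, ge = float(params.gap_open), float(params.gap_extend)

    # State matrices: M ends in aligned pair, X in gap consuming seq_a,
    # Y in gap consuming seq_b.
    M = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = go + (i - 1) * ge
    for j in range(1, m + 1):
        Y[0][j] = go + (j - 1) * ge

    for i in range(1, n + 1):
        ai = seq_a[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        for j in range(1, m + 1):
            s = params.match if ai == seq_b[j - 1] else params.mismatch
            Mi[j] = s + max(Mp[j - 1], Xp[j - 1], Yp[j - 1])
            Xi[j] = max(Mp[j] + go, Xp[j] + ge, Yp[j] + go)
            Yi[j] = max(Mi[j - 1] + go, Xi[j - 1] + go, Yi[j - 1] + ge)

    # Deterministic traceback, state preference M > X > Y.
    i, j = n, m
    finals = {"M": M[i][j], "X": X[i][j], "Y": Y[i][j]}
    score = max(finals.values())
    state = next(k for k in "MXY" if finals[k] == score)
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            out_a.append(seq_a[i - 1])
            out_b.append(seq_b[j - 1])
            s = params.match if seq_a[i - 1] == seq_b[j - 1] else params.mismatch
            target = M[i][j] - s
            i, j = i - 1, j - 1
            prev = {"M": M[i][j], "X": X[i][j], "Y": Y[i][j]}
        elif state == "X":
            out_a.append(seq_a[i - 1])
            out_b.append("-")
            target = X[i][j]
            i -= 1
            prev = {"M": M[i][j] + go, "X": X[i][j] + ge, "Y": Y[i][j] + go}
        else:
            out_a.append("-")
            out_b.append(seq_b[j - 1])
            target = Y[i][j]
            j -= 1
            prev = {"M": M[i][j] + go, "X": X[i][j] + go, "Y": Y[i][j] + ge}
        if i == 0 and j == 0:
            break
        if j == 0:
            state = "X"
        elif i == 0:
            state = "Y"
        else:
            state = next(k for k in "MXY" if prev[k] == target)
    return score, "".join(reversed(out_a)), "".join(reversed(out_b))


def _strip_terminal_gap_columns(gapped_a: str, gapped_b: str) -> tuple[str, str]:
    start, end = 0, len(gapped_a)
    while start < end and (gapped_a[start] == "-" or gapped_b[start] == "-"):
        # only strip while inside a *terminal* gap run of one sequence
        if gapped_a[start] == "-" and set(gapped_a[:start]) <= {"-"}:
            start += 1
        elif gapped_b[start] == "-" and set(gapped_b[:start]) <= {"-"}:
            start += 1
        else:
            break
    while end > start and (gapped_a[end - 1] == "-" or gapped_b[end - 1] == "-"):
        if gapped_a[end - 1] == "-" and set(gapped_a[end:]) <= {"-"}:
            end -= 1
        elif gapped_b[end - 1] == "-" and set(gapped_b[end:]) <= {"-"}:
            end -= 1
        else:
            break
    return gapped_a[start:end], gapped_b[start:end]


def global_identity(
    seq_a: str, seq_b: str, params: ClusteringParams = ClusteringParams()
) -> float:
    """Fractional identity of the optimal global alignment of two sequences.

    Identity = identical aligned pairs / alignment columns, after terminal
    gap columns are stripped.  Symmetric in its arguments.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot compute identity of an empty sequence")
    if seq_a == seq_b:
        return 1.0
    # Symmetry by convention: align the (longer, shorter) pair.
    if (len(seq_a), seq_a) < (len(seq_b), seq_b):
        seq_a, seq_b = seq_b, seq_a
    _, ga, gb = align_global(seq_a, seq_b, params)
    ga, gb = _strip_terminal_gap_columns(ga, gb)
    if not ga:
        return 0.0
    matches = sum(1 for x, y in zip(ga, gb) if x == y and x != "-")
    return matches / len(ga)


def _clustering_order(records: Sequence[EnzymeRecord]) -> list[EnzymeRecord]:
    return sorted(records, key=lambda r: (-len(r.sequence), r.accession))


def greedy_cluster(
    records: Sequence[EnzymeRecord],
    params: ClusteringParams = ClusteringParams(),
) -> list[SequenceCluster]:
    """Greedy longest-first clustering against cluster representatives.

    Records are processed by descending sequence length (accession as the
    tie-break); each joins the first existing cluster whose representative
    it matches at ``identity_cutoff`` or better, else founds a new cluster.
    Deterministic for fixed input.
    """
    if not records:
        raise ValueError("greedy_cluster requires at least one record")
    by_acc = {r.accession: r for r in records}
    if len(by_acc) != len(records):
        raise ValueError("duplicate accessions in record set")
    clusters: list[SequenceCluster] = []
    for record in _clustering_order(records):
        placed = False
        for cluster in clusters:
            ident = global_identity(
                record.sequence, by_acc[cluster.representative].sequence, params
            )
            if ident >= params.identity_cutoff:
                cluster.members[record.accession] = ident
                placed = True
                break
        if not placed:
            clusters.append(
                SequenceCluster(
                    representative=record.accession,
                    members={record.accession: 1.0},
                )
            )
    return clusters


def select_representative(
    members: Sequence[str],
    records: Mapping[str, EnzymeRecord],
    params: ClusteringParams = ClusteringParams(),
) -> str:
    """Centroid representative: member maximizing mean identity to co-members.

    Ties go to the longer sequence, then the lexicographically smallest
    accession.  A singleton is its own representative.
    """
    if not members:
        raise ValueError("cannot select a representative from no members")
    members = list(members)
    if len(members) == 1:
        return members[0]
    idents = {m: [] for m in members}
    for i, a in enumerate(members):
        for b in members[i + 1 :]:
            ident = global_identity(records[a].sequence, records[b].sequence, params)
            idents[a].append(ident)
            idents[b].append(ident)
    return min(
        members,
        key=lambda m: (
            -sum(idents[m]) / len(idents[m]),
            -len(records[m].sequence),
            m,
        ),
    )


def _is_pure(cluster: SequenceCluster, records: Mapping[str, EnzymeRecord]) -> bool:
    keysets = [set(records[m].subsub_keys()) for m in cluster.members]
    union = set().union(*keysets) if keysets else set()
    return len(union) == 1 and all(ks == union for ks in keysets)


def split_by_subsubclass(
    cluster: SequenceCluster,
    records: Mapping[str, EnzymeRecord],
    params: ClusteringParams = ClusteringParams(),
) -> list[SequenceCluster]:
    """Split a cluster so every output cluster is subsub-class pure.

    Members are partitioned by the three-level EC key; a member carrying
    several EC numbers appears in every matching partition, so each
    subsub-class function keeps a representative.  Members with only
    wildcard subsub levels go to a dedicated ``"unclassified"`` partition.
    An already-pure cluster is returned unchanged (with its key filled in).
    """
    if _is_pure(cluster, records):
        key = records[next(iter(cluster.members))].subsub_keys()[0]
        cluster.subsub_class = key
        return [cluster]

    partitions: dict[str, list[str]] = {}
    for member in cluster.members:
        keys = records[member].subsub_keys()
        if not keys:
            logger.warning(
                "member %s has only wildcard subsub-class; routed to %r",
                member,
                UNCLASSIFIED,
            )
            partitions.setdefault(UNCLASSIFIED, []).append(member)
        else:
            for key in keys:
                partitions.setdefault(key, []).append(member)

    result: list[SequenceCluster] = []
    keys = sorted(k for k in partitions if k != UNCLASSIFIED)
    if UNCLASSIFIED in partitions:
        keys.append(UNCLASSIFIED)
    for key in keys:
        members = partitions[key]
        rep = select_representative(members, records, params)
        new = SequenceCluster(representative=rep, subsub_class=key)
        for m in members:
            new.members[m] = (
                1.0
                if m == rep
                else global_identity(records[m].sequence, records[rep].sequence, params)
            )
        result.append(new)
    return result


def split_all(
    clusters: Iterable[SequenceCluster],
    records: Mapping[str, EnzymeRecord],
    params: ClusteringParams = ClusteringParams(),
) -> list[SequenceCluster]:
    """Apply :func:`split_by_subsubclass` to every cluster, keeping order."""
    out: list[SequenceCluster] = []
    for cluster in clusters:
        out.extend(split_by_subsubclass(cluster, records, params))
    return out


def write_clusters_tsv(
    clusters: Sequence[SequenceCluster],
    path: str | Path,
    sidecar: str | Path | None = None,
) -> None:
    """Write clusters as ``representative<TAB>member`` rows.

    Members within a cluster are listed representative first, then
    lexicographically; a JSON sidecar stores identities and subsub keys.
    """
    with open(path, "w", newline="\n") as handle:
        for cluster in clusters:
            rep = cluster.representative
            ordered = [rep] + sorted(m for m in cluster.members if m != rep)
            for member in ordered:
                handle.write(f"{rep}\t{member}\n")
    if sidecar is not None:
        payload = [
            {
                "representative": c.representative,
                "subsub_class": c.subsub_class,
                "members": {m: round(c.members[m], 6) for m in sorted(c.members)},
            }
            for c in clusters
        ]
        with open(sidecar, "w") as handle:
            json.dump(payload, handle, indent=1, sort_keys=True)
            handle.write("\n")


def read_clusters_tsv(path: str | Path) -> list[SequenceCluster]:
    """Read a ``representative<TAB>member`` TSV (MMseqs2 createtsv dialect).

    Identities are not stored in the TSV and are left at 0.0 except the
    representative's own 1.0; use the JSON sidecar for exact values.
    """
    clusters: dict[str, SequenceCluster] = {}
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            rep, member = line.split("\t")
            cluster = clusters.setdefault(
                rep, SequenceCluster(representative=rep, members={rep: 1.0})
            )
            cluster.members.setdefault(member, 1.0 if member == rep else 0.0)
    return list(clusters.values())
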