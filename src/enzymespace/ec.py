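"""Enzyme Commission (EC) hierarchy: numbers, annotated records, count trees.

EC numbers have four levels — main class, subclass, subsub-class and the
serial designation of the specific enzyme function (e.g. ``3.6.5.2``, the
small monomeric GTPase: a hydrolase acting on acid anhydrides, specifically
on GTP).  The first three levels form the *subsub-class key* (``3.6.5``),
the unit of functional purity used by the clustering stage.  Deeper levels
may be wildcards (``-``) and the fourth level may carry a preliminary
``n``-designation (``3.5.1.n3``).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ECNumber",
    "EnzymeRecord",
    "ECTree",
    "ECTreeNode",
    "parse_ec",
    "load_annotations",
    "build_ec_tree",
    "read_fasta",
]

logger = logging.getLogger(__name__)

WILDCARD = "-"

# 20 canonical amino acids plus X for unknown
SEQUENCE_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

_PRELIM_RE = re.compile(r"^n\d+$")


class ECParseError(ValueError):
    """Raised for a malformed EC number string."""


@dataclass(frozen=True, order=True)
class ECNumber:
    """A four-level EC classification code.

    ``main`` is an integer 1–7 (oxidoreductases … translocases); ``sub``
    and ``subsub`` are integers or the wildcard ``"-"``; ``designation``
    is an integer token, the wildcard, or a preliminary ``n<int>`` form.
    A wildcard at one level forces wildcards at all deeper levels.
    """

    main: int
    sub: str = WILDCARD
    subsub: str = WILDCARD
    designation: str = WILDCARD

    def __post_init__(self) -> None:
        if not isinstance(self.main, int) or not 1 <= self.main <= 7:
            raise ECParseError(f"EC main class must be an integer 1-7, got {self.main!r}")
        levels = [self.sub, self.subsub, self.designation]
        seen_wildcard = False
        for name, tok in zip(("sub", "subsub", "designation"), levels):
            if tok == WILDCARD:
                seen_wildcard = True
                continue
            if seen_wildcard:
                raise ECParseError(
                    f"EC level {name!r}={tok!r} is concrete below a wildcard level"
                )
            if name == "designation":
                if not (tok.isdigit() or _PRELIM_RE.match(tok)):
                    raise ECParseError(f"malformed EC designation token {tok!r}")
            elif not tok.isdigit():
                raise ECParseError(f"malformed EC {name} token {tok!r}")

    def __str__(self) -> str:
        return f"{self.main}.{self.sub}.{self.subsub}.{self.designation}"

    @property
    def levels(self) -> tuple[str, str, str, str]:
        return (str(self.main), self.sub, self.subsub, self.designation)

    def prefix(self, depth: int) -> str:
        """Dot-joined prefix at ``depth`` levels (1–4)."""
        if not 1 <= depth <= 4:
            raise ValueError("depth must be 1-4")
        return ".".join(self.levels[:depth])

    def depth(self) -> int:
        """Number of leading concrete (non-wildcard) levels."""
        d = 1
        for tok in (self.sub, self.subsub, self.designation):
            if tok == WILDCARD:
                break
            d += 1
        return d

    def has_subsub(self) -> bool:
        return self.sub != WILDCARD and self.subsub != WILDCARD

    def subsub_key(self) -> str:
        """Three-level prefix, e.g. ``"3.6.5"``.

        Defined only when levels 1–3 are all concrete.
        """
        if not self.has_subsub():
            raise ValueError(f"subsub_key undefined for {self}: wildcard in levels 1-3")
        return self.prefix(3)


def parse_ec(text: str) -> ECNumber:
    """Parse a dot-separated EC string into an :class:`ECNumber`.

    Missing trailing levels become wildcards: ``"3.6"`` parses the same as
    ``"3.6.-.-"``.  Preliminary designations (``n3``) are accepted at the
    fourth level.

    >>> parse_ec("3.6.5.2").main
    3
    """
    tokens = [t.strip() for t in str(text).strip().split(".")]
    if not 1 <= len(tokens) <= 4:
        raise ECParseError(f"EC string {text!r} must have 1-4 dot-separated tokens")
    tokens += [WILDCARD] * (4 - len(tokens))
    main_tok = tokens[0]
    if not main_tok.isdigit():
        raise ECParseError(f"malformed EC main-class token {main_tok!r} in {text!r}")
    try:
        return ECNumber(int(main_tok), tokens[1], tokens[2], tokens[3])
    except ECParseError as exc:
        raise ECParseError(f"{exc} in {text!r}") from None


@dataclass
class EnzymeRecord:
    """One annotated enzyme sequence (one metadata-CSV row).

    ``accession`` is a UniProt-style identifier, unique within a record
    set; ``sequence`` uses the 20 canonical letters plus ``X``.
    """

    accession: str
    sequence: str
    ec_numbers: tuple[ECNumber, ...]
    organism: str = ""
    keywords: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be nonempty")
        if len(self.sequence) < 1:
            raise ValueError(f"{self.accession}: sequence must be nonempty")
        bad = set(self.sequence) - SEQUENCE_ALPHABET
        if bad:
            raise ValueError(
                f"{self.accession}: sequence contains disallowed characters {sorted(bad)}"
            )
        self.ec_numbers = tuple(self.ec_numbers)
        self.keywords = tuple(self.keywords)

    def subsub_keys(self) -> tuple[str, ...]:
        """Distinct subsub-class keys of this record, in first-seen order."""
        seen: dict[str, None] = {}
        for ec in self.ec_numbers:
            if ec.has_subsub():
                seen.setdefault(ec.subsub_key())
        return tuple(seen)


@dataclass
class ECTreeNode:
    prefix: str
    level: int
    count: int = 0
    attached: int = 0  # records attached exactly at this level (wildcard tails)
    children: dict[str, "ECTreeNode"] = field(default_factory=dict)

    def walk(self) -> Iterable["ECTreeNode"]:
        yield self
        for child in self.children.values():
            yield from child.walk()


@dataclass
class ECTree:
    """Count tree over the four EC levels.

    Every node's ``count`` equals the sum of its children's counts plus the
    records attached exactly at that node (records whose EC is wildcard
    below it).  A record with k EC labels contributes k attachments.
    """

    roots: dict[str, ECTreeNode] = field(default_factory=dict)

    def node(self, prefix: str) -> ECTreeNode:
        tokens = prefix.split(".")
        table = self.roots
        node = None
        for depth in range(1, len(tokens) + 1):
            key = ".".join(tokens[:depth])
            if key not in table:
                raise KeyError(f"no EC tree node {key!r}")
            node = table[key]
            table = node.children
        assert node is not None
        return node

    def nodes(self) -> Iterable[ECTreeNode]:
        for root in self.roots.values():
            yield from root.walk()

    @property
    def total(self) -> int:
        return sum(r.count for r in self.roots.values())


def build_ec_tree(records: Iterable[EnzymeRecord]) -> ECTree:
    """Aggregate record counts over the EC hierarchy.

    Each EC label of each record is attached at its deepest concrete level
    and increments the count of every ancestor node, so a record carrying
    two EC numbers is counted once under each.  An empty record set yields
    an empty tree.
    """
    tree = ECTree()
    for record in records:
        for ec in record.ec_numbers:
            depth = ec.depth()
            table = tree.roots
            for level in range(1, depth + 1):
                key = ec.prefix(level)
                node = table.setdefault(key, ECTreeNode(prefix=key, level=level))
                node.count += 1
                if level == depth:
                    node.attached += 1
                table = node.children
    return tree


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an accession→sequence mapping.

    The accession is the first whitespace-delimited token of the header.
    """
    sequences: dict[str, str] = {}
    name: str | None = None
    parts: list[str] = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    sequences[name] = "".join(parts)
                name = line[1:].split()[0]
                parts = []
            elif line:
                parts.append(line.strip())
    if name is not None:
        sequences[name] = "".join(parts)
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as handle:
        for name, seq in sequences.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def save_records(records: Sequence[EnzymeRecord], path: str | Path) -> None:
    """Serialize records to JSON (accession, sequence, ec, organism, keywords)."""
    import json

    payload = [
        {
            "accession": r.accession,
            "sequence": r.sequence,
            "ec": ";".join(str(e) for e in r.ec_numbers),
            "organism": r.organism,
            "keywords": list(r.keywords),
        }
        for r in records
    ]
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=1)
        handle.write("\n")


def load_records(path: str | Path) -> list[EnzymeRecord]:
    """Load records saved by :func:`save_records`."""
    import json

    with open(path) as handle:
        payload = json.load(handle)
    return [
        EnzymeRecord(
            accession=item["accession"],
            sequence=item["sequence"],
            ec_numbers=tuple(parse_ec(t) for t in item["ec"].split(";") if t),
            organism=item.get("organism", ""),
            keywords=tuple(item.get("keywords", ())),
        )
        for item in payload
    ]


class AnnotationSchemaError(ValueError):
    """Raised when the annotation table violates the expected schema."""


def load_annotations(
    table: str | Path | pd.DataFrame,
    fasta: str | Path | Mapping[str, str] | None = None,
) -> list[EnzymeRecord]:
    """Load an annotation table (CSV/TSV) into :class:`EnzymeRecord` objects.

    Required columns: ``accession``, ``ec`` and either ``sequence`` or a
    companion FASTA keyed by accession.  Multi-EC cells are split on ``;``.
    Rows lacking any EC annotation are skipped with a logged warning;
    duplicate accessions are an error.
    """
    if isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        sep = "\t" if str(table).endswith((".tsv", ".tab")) else ","
        df = pd.read_csv(table, sep=sep, dtype=str, keep_default_na=False)

    required = {"accession", "ec"}
    missing = required - set(df.columns)
    if missing:
        raise AnnotationSchemaError(f"annotation table missing columns: {sorted(missing)}")
    if "sequence" not in df.columns and fasta is None:
        raise AnnotationSchemaError(
            "annotation table has no 'sequence' column and no companion FASTA given"
        )

    seq_map: Mapping[str, str] | None = None
    if fasta is not None:
        seq_map = fasta if isinstance(fasta, Mapping) else read_fasta(fasta)

    dupes = df["accession"][df["accession"].duplicated()].tolist()
    if dupes:
        raise AnnotationSchemaError(f"duplicate accessions: {sorted(set(dupes))}")

    records: list[EnzymeRecord] = []
    n_skipped = 0
    for row in df.itertuples(index=False):
        data = row._asdict()
        acc = data["accession"].strip()
        ec_cell = data.get("ec", "").strip()
        ec_tokens = [t.strip() for t in ec_cell.split(";") if t.strip()]
        if not ec_tokens:
            n_skipped += 1
            logger.warning("row %r has no EC annotation; skipped", acc)
            continue
        ecs = tuple(parse_ec(tok) for tok in ec_tokens)
        if "sequence" in data and data["sequence"].strip():
            seq = data["sequence"].strip().upper()
        elif seq_map is not None and acc in seq_map:
            seq = seq_map[acc].upper()
        else:
            raise AnnotationSchemaError(f"no sequence for accession {acc!r}")
        keywords = tuple(
            k.strip() for k in data.get("keywords", "").split(";") if k.strip()
        )
        records.append(
            EnzymeRecord(
                accession=acc,
                sequence=seq,
                ec_numbers=ecs,
                organism=data.get("organism", "").strip(),
                keywords=keywords,
            )
        )
    if n_skipped:
        logger.warning("skipped %d rows without EC annotation", n_skipped)
    return records
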