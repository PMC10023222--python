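"""Aggregation into the treemap node table and the per-accession metadata CSV.

The two interaction surfaces of a structural coverage map:

* a treemap over the EC hierarchy, where each node's *size* is the number
  of cluster representatives under that EC prefix and its *color* the mean
  harmonized quality score of the scored representatives;
* a flat metadata CSV with one row per (record, cluster membership) for
  large-scale programmatic use.

The treemap HTML export is a small self-contained inline-SVG document with
a slice-and-dice layout; the node table itself is also exportable as JSON.
"""

from __future__ import annotations

import csv
import html
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .cluster import SequenceCluster, UNCLASSIFIED
from .ec import EnzymeRecord
from .quality import quality_class

__all__ = [
    "TreemapNode",
    "MetadataRow",
    "build_treemap",
    "build_metadata_rows",
    "export_metadata_csv",
    "load_metadata_csv",
    "export_treemap_html",
    "treemap_to_json",
    "METADATA_COLUMNS",
]

logger = logging.getLogger(__name__)

METADATA_COLUMNS = (
    "accession",
    "representative",
    "subsub_class",
    "ec",
    "organism",
    "keywords",
    "identity_to_representative",
    "topscore",
    "plddt",
    "qmean6",
    "quality_class",
)


@dataclass
class TreemapNode:
    """EC-hierarchy node: size = representative count, color = mean score."""

    prefix: str
    level: int  # 0 for the synthetic root, 1-4 for EC levels
    size: int = 0
    n_scored: int = 0
    score_sum: float = 0.0
    children: dict[str, "TreemapNode"] = field(default_factory=dict)

    @property
    def color(self) -> float | None:
        """Mean harmonized score of scored representatives, or None."""
        return self.score_sum / self.n_scored if self.n_scored else None

    def walk(self) -> Iterable["TreemapNode"]:
        yield self
        for child in self.children.values():
            yield from child.walk()

    def to_dict(self) -> dict:
        return {
            "prefix": self.prefix,
            "level": self.level,
            "size": self.size,
            "n_scored": self.n_scored,
            "color": self.color,
            "children": [
                c.to_dict()
                for c in sorted(self.children.values(), key=lambda c: (-c.size, c.prefix))
            ],
        }


def _leaf_ecs(cluster: SequenceCluster, record: EnzymeRecord) -> list[str]:
    """Designation-level EC strings of a representative under its cluster key."""
    out = []
    for ec in record.ec_numbers:
        if ec.has_subsub() and ec.subsub_key() == cluster.subsub_class:
            out.append(str(ec))
    return out


def build_treemap(
    records: Mapping[str, EnzymeRecord],
    clusters: Sequence[SequenceCluster],
    scores: Mapping[str, float] | None = None,
) -> TreemapNode:
    """Aggregate post-split clusters into the treemap node tree.

    One leaf per designation-level EC node; sizes count representatives
    (a multi-EC representative contributes to each leaf it represents);
    representatives without a scored model contribute to size but not to
    color.  ``scores`` maps representative accessions to harmonized 0–1
    higher-is-better values.  Unclassified clusters carry no EC and are
    not drawn.
    """
    scores = scores or {}
    clustered = {m for c in clusters for m in c.members}
    stray = set(scores) - clustered
    if stray:
        raise ValueError(f"scores reference unclustered records: {sorted(stray)}")

    root = TreemapNode(prefix="EC", level=0)
    for cluster in clusters:
        if cluster.subsub_class in (None, UNCLASSIFIED):
            continue
        rep = cluster.representative
        record = records[rep]
        score = scores.get(rep)
        for ec_str in _leaf_ecs(cluster, record):
            tokens = ec_str.split(".")
            node = root
            for level in range(5):
                node.size += 1
                if score is not None:
                    node.n_scored += 1
                    node.score_sum += score
                if level < 4:
                    key = ".".join(tokens[: level + 1])
                    node = node.children.setdefault(key, TreemapNode(prefix=key, level=level + 1))
    return root


@dataclass
class MetadataRow:
    """One metadata-CSV row: a record's membership in one pure cluster."""

    accession: str
    representative: str
    subsub_class: str
    ec: str  # ';'-joined EC strings
    organism: str
    keywords: str  # ';'-joined
    identity_to_representative: float
    topscore: float | None = None  # harmonized (1 - TopScore)
    plddt: float | None = None  # harmonized (pLDDT / 100)
    qmean6: float | None = None
    quality_class: str = ""


def build_metadata_rows(
    records: Mapping[str, EnzymeRecord],
    clusters: Sequence[SequenceCluster],
    harmonized: Mapping[str, Mapping[str, float]] | None = None,
    raw_topscore: Mapping[str, float] | None = None,
) -> list[MetadataRow]:
    """Flatten records × cluster memberships into metadata rows.

    ``harmonized`` maps score source → accession → harmonized value;
    ``raw_topscore`` (native 0–1, lower better) drives the quality class.
    Rows are ordered by EC (subsub key) then accession.
    """
    harmonized = harmonized or {}
    raw_topscore = raw_topscore or {}
    rows: list[MetadataRow] = []
    for cluster in clusters:
        for member, identity in cluster.members.items():
            record = records[member]
            raw = raw_topscore.get(member)
            rows.append(
                MetadataRow(
                    accession=member,
                    representative=cluster.representative,
                    subsub_class=cluster.subsub_class or "",
                    ec=";".join(str(e) for e in record.ec_numbers),
                    organism=record.organism,
                    keywords=";".join(record.keywords),
                    identity_to_representative=round(identity, 4),
                    topscore=harmonized.get("topscore", {}).get(member),
                    plddt=harmonized.get("plddt", {}).get(member),
                    qmean6=harmonized.get("qmean6", {}).get(member),
                    quality_class=quality_class(raw) if raw is not None else "",
                )
            )
    rows.sort(key=lambda r: (r.subsub_class, r.ec, r.accession))
    return rows


def _fmt(value: float | None) -> str:
    return "" if value is None else f"{value:.4f}"


def export_metadata_csv(rows: Sequence[MetadataRow], path: str | Path) -> None:
    """Write metadata rows as RFC-4180 CSV with the documented column order.

    Output is UTF-8 and byte-deterministic for fixed input; fields with
    commas or quotes are quoted, so the file round-trips losslessly.
    """
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, quoting=csv.QUOTE_MINIMAL, lineterminator="\n")
        writer.writerow(METADATA_COLUMNS)
        for row in rows:
            writer.writerow(
                [
                    row.accession,
                    row.representative,
                    row.subsub_class,
                    row.ec,
                    row.organism,
                    row.keywords,
                    f"{row.identity_to_representative:.4f}",
                    _fmt(row.topscore),
                    _fmt(row.plddt),
                    _fmt(row.qmean6),
                    row.quality_class,
                ]
            )


def load_metadata_csv(path: str | Path) -> list[MetadataRow]:
    """Read a metadata CSV written by :func:`export_metadata_csv`."""
    rows: list[MetadataRow] = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if tuple(reader.fieldnames or ()) != METADATA_COLUMNS:
            raise ValueError(f"unexpected metadata CSV columns: {reader.fieldnames}")
        for rec in reader:
            rows.append(
                MetadataRow(
                    accession=rec["accession"],
                    representative=rec["representative"],
                    subsub_class=rec["subsub_class"],
                    ec=rec["ec"],
                    organism=rec["organism"],
                    keywords=rec["keywords"],
                    identity_to_representative=float(rec["identity_to_representative"]),
                    topscore=float(rec["topscore"]) if rec["topscore"] else None,
                    plddt=float(rec["plddt"]) if rec["plddt"] else None,
                    qmean6=float(rec["qmean6"]) if rec["qmean6"] else None,
                    quality_class=rec["quality_class"],
                )
            )
    return rows


def treemap_to_json(root: TreemapNode, path: str | Path) -> None:
    with open(path, "w") as handle:
        json.dump(root.to_dict(), handle, indent=1)
        handle.write("\n")


def _color_hex(score: float | None) -> str:
    """Map a harmonized 0–1 score to a red→blue ramp; gray when unscored."""
    if score is None:
        return "#b0b0b0"
    s = min(1.0, max(0.0, score))
    r = round(220 * (1 - s) + 30 * s)
    g = 60
    b = round(30 * (1 - s) + 220 * s)
    return f"#{r:02x}{g:02x}{b:02x}"


def _layout(node: TreemapNode, x: float, y: float, w: float, h: float, out: list[dict]) -> None:
    out.append(
        {
            "prefix": node.prefix,
            "level": node.level,
            "size": node.size,
            "color": node.color,
            "x": round(x, 2),
            "y": round(y, 2),
            "w": round(w, 2),
            "h": round(h, 2),
            "leaf": not node.children,
        }
    )
    if not node.children or node.size == 0:
        return
    children = sorted(node.children.values(), key=lambda c: (-c.size, c.prefix))
    pad = 1.0 if node.level < 2 else 0.0
    horizontal = node.level % 2 == 0  # alternate split direction per level
    offset = 0.0
    for child in children:
        frac = child.size / node.size
        if horizontal:
            cw = w * frac
            _layout(child, x + offset + pad, y + pad, max(cw - 2 * pad, 0.1), max(h - 2 * pad, 0.1), out)
            offset += cw
        else:
            ch = h * frac
            _layout(child, x + pad, y + offset + pad, max(w - 2 * pad, 0.1), max(ch - 2 * pad, 0.1), out)
            offset += ch


def export_treemap_html(root: TreemapNode, path: str | Path, width: int = 900, height: int = 600) -> None:
    """Write a self-contained HTML treemap (inline SVG, no dependencies).

    Rectangle area is proportional to representative count; fill color
    encodes the mean harmonized score.  The node table is embedded as JSON
    in a ``<script id="treemap-data">`` block so the document doubles as a
    machine-readable export.
    """
    if root.size == 0:
        raise ValueError("cannot export an empty treemap")
    boxes: list[dict] = []
    _layout(root, 0.0, 0.0, float(width), float(height), boxes)
    rects = []
    for box in boxes:
        if box["level"] == 0:
            continue
        tooltip = f"{box['prefix']}: {box['size']} representatives"
        if box["color"] is not None:
            tooltip += f", mean score {box['color']:.3f}"
        rects.append(
            f'<rect x="{box["x"]}" y="{box["y"]}" width="{box["w"]}" height="{box["h"]}" '
            f'fill="{_color_hex(box["color"])}" fill-opacity="{0.25 if not box["leaf"] else 0.9}" '
            f'stroke="#333" stroke-width="0.5"><title>{html.escape(tooltip)}</title></rect>'
        )
        if box["leaf"] and box["w"] > 30 and box["h"] > 12:
            rects.append(
                f'<text x="{box["x"] + 2}" y="{box["y"] + 11}" font-size="9" fill="#fff">'
                f"{html.escape(box['prefix'])}</text>"
            )
    payload = json.dumps(root.to_dict())
    doc = (
        "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
        "<title>Enzyme space coverage treemap</title></head><body>\n"
        f"<h1>Structural coverage of enzyme space ({root.size} representative attachments)</h1>\n"
        f'<svg width="{width}" height="{height}" xmlns="http://www.w3.org/2000/svg">\n'
        + "\n".join(rects)
        + "\n</svg>\n"
        f'<script type="application/json" id="treemap-data">{payload}</script>\n'
        "</body></html>\n"
    )
    Path(path).write_text(doc, encoding="utf-8")
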