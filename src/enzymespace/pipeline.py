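"""End-to-end coverage pipeline: records → clusters → quality → exports."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

from .cluster import ClusteringParams, greedy_cluster, split_all, write_clusters_tsv
from .coverage import (
    build_metadata_rows,
    build_treemap,
    export_metadata_csv,
    treemap_to_json,
)
from .ec import EnzymeRecord
from .quality import harmonize_score
from .structure import StructureModel, write_pdb
from .trimming import TrimCriteria, trim_structure

__all__ = ["run_coverage_pipeline"]


def run_coverage_pipeline(
    records: Sequence[EnzymeRecord],
    out_dir: str | Path,
    raw_topscore: Mapping[str, float] | None = None,
    structure: StructureModel | None = None,
    params: ClusteringParams = ClusteringParams(),
    criteria: TrimCriteria = TrimCriteria(),
) -> dict:
    """Cluster, split, score, (optionally) trim, and export a coverage map.

    Writes ``clusters.tsv`` (+JSON sidecar), ``metadata.csv`` and
    ``treemap.json`` to ``out_dir`` (``trimmed.pdb`` too when a structure
    is given) and returns the in-memory artifacts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    by_acc = {r.accession: r for r in records}

    clusters = split_all(greedy_cluster(records, params), by_acc, params)
    write_clusters_tsv(clusters, out / "clusters.tsv", out / "clusters.json")

    raw_topscore = dict(raw_topscore or {})
    harmonized = {
        "topscore": {acc: harmonize_score("topscore", v).value for acc, v in raw_topscore.items()}
    }
    rep_scores = {
        c.representative: harmonized["topscore"][c.representative]
        for c in clusters
        if c.representative in harmonized["topscore"]
    }

    root = build_treemap(by_acc, clusters, rep_scores)
    treemap_to_json(root, out / "treemap.json")

    rows = build_metadata_rows(by_acc, clusters, harmonized, raw_topscore)
    export_metadata_csv(rows, out / "metadata.csv")

    result = {"clusters": clusters, "treemap": root, "metadata": rows}
    if structure is not None:
        trimmed, reports = trim_structure(structure, criteria)
        write_pdb(trimmed, out / "trimmed.pdb")
        result["trimmed"] = trimmed
        result["trim_reports"] = reports
    return result
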