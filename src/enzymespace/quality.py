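"""Model-quality harmonization, banding, and residue-score analyses.

Three model sources score structures on different scales: TopScore (0–1,
lower is better), pLDDT (0–100, higher is better) and QMEAN6 (~0–1, higher
is better).  Harmonization maps all three onto a single 0–1 higher-is-
better scale — ``1 - TopScore``, ``pLDDT/100`` and QMEAN6 clamped to
[0, 1] — so that values close to 1 always indicate high quality.

Quality bands follow the TopScore convention: high quality below 0.2, good
quality in [0.2, 0.4), low at or above 0.4.  Banding can optionally be
cumulative, where "good" includes the high-quality models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .binding_site import BindingSite
from .structure import StructureModel

__all__ = [
    "QualityThresholds",
    "HarmonizedScore",
    "ScoreSummary",
    "harmonize_score",
    "quality_class",
    "group_scores_by_ss",
    "scores_by_distance_from_site",
    "bin_models_by_template_identity",
    "SCORE_SOURCES",
]

logger = logging.getLogger(__name__)

SCORE_SOURCES = ("topscore", "plddt", "qmean6")


@dataclass(frozen=True)
class QualityThresholds:
    """TopScore band edges: high below 0.2, good below 0.4, low otherwise."""

    high_below: float = 0.2
    good_below: float = 0.4

    def __post_init__(self) -> None:
        if not 0 < self.high_below < self.good_below < 1:
            raise ValueError("thresholds must satisfy 0 < high_below < good_below < 1")


@dataclass(frozen=True)
class HarmonizedScore:
    """A quality value on the common 0–1 higher-is-better scale."""

    value: float
    source: str

    def __post_init__(self) -> None:
        if self.source not in SCORE_SOURCES:
            raise ValueError(f"unknown score source {self.source!r}")
        if not 0 <= self.value <= 1:
            raise ValueError("harmonized value must lie in [0, 1]")


def harmonize_score(source: str, raw_value: float) -> HarmonizedScore:
    """Map a native score onto the common 0–1 higher-is-better scale.

    topscore → 1 − raw; plddt → raw/100; qmean6 → clamp(raw, 0, 1).
    Out-of-range TopScore or pLDDT values are an error (QMEAN6 variants can
    stray outside [0, 1] and are clamped).
    """
    if source == "topscore":
        if not 0 <= raw_value <= 1:
            raise ValueError(f"TopScore {raw_value} outside [0, 1]")
        return HarmonizedScore(1.0 - raw_value, source)
    if source == "plddt":
        if not 0 <= raw_value <= 100:
            raise ValueError(f"pLDDT {raw_value} outside [0, 100]")
        return HarmonizedScore(raw_value / 100.0, source)
    if source == "qmean6":
        return HarmonizedScore(min(1.0, max(0.0, raw_value)), source)
    raise ValueError(f"unknown score source {source!r}; use one of {SCORE_SOURCES}")


def quality_class(
    topscore_value: float,
    thresholds: QualityThresholds = QualityThresholds(),
    cumulative: bool = False,
) -> str:
    """Band a TopScore value: high (<0.2), good ([0.2, 0.4)), low (≥0.4).

    With ``cumulative=True``, high-quality values are reported as "good"
    too (the nested counting where good includes high): the return value is
    then "good" for everything below the good threshold.
    """
    if not 0 <= topscore_value <= 1:
        raise ValueError(f"TopScore {topscore_value} outside [0, 1]")
    if topscore_value < thresholds.high_below:
        return "good" if cumulative else "high"
    if topscore_value < thresholds.good_below:
        return "good"
    return "low"


@dataclass(frozen=True)
class ScoreSummary:
    count: int
    mean: float
    median: float

    @classmethod
    def of(cls, values: Sequence[float]) -> "ScoreSummary":
        if not values:
            return cls(0, float("nan"), float("nan"))
        arr = np.asarray(values, dtype=float)
        return cls(len(arr), float(arr.mean()), float(np.median(arr)))


def group_scores_by_ss(
    model: StructureModel, ss_labels: Mapping[str, Sequence[str]]
) -> dict[str, list[float]]:
    """Partition per-residue scores by secondary structure {H, E, C}.

    ``ss_labels`` maps chain id to labels aligned with the chain's
    residues.  Every residue lands in exactly one group.
    """
    groups: dict[str, list[float]] = {"H": [], "E": [], "C": []}
    for chain in model.chains:
        labels = ss_labels[chain.id]
        if len(labels) != len(chain.residues):
            raise ValueError(f"labels for chain {chain.id!r} misaligned with residues")
        for res, label in zip(chain.residues, labels):
            groups[label].append(res.score)
    return groups


def scores_by_distance_from_site(
    model: StructureModel,
    site: BindingSite,
    bin_width: float = 2.0,
) -> dict[int, dict]:
    """Bin per-residue scores by distance from the binding site.

    A residue's distance is the minimum heavy-atom distance to any site
    residue (site residues themselves are at 0).  Residues fall into bins
    ``[k*w, (k+1)*w)``; each bin reports count, median and quartiles.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    site.validate(model)
    site_keys = set(site.residues)
    site_pts = np.vstack([r.heavy_coords() for r in site.residue_objects(model)])

    from scipy.spatial import cKDTree

    tree = cKDTree(site_pts)
    binned: dict[int, list[float]] = {}
    for res in model.residues():
        if (res.chain_id, res.number) in site_keys:
            dist = 0.0
        else:
            pts = res.heavy_coords()
            dist = float(tree.query(pts, k=1)[0].min()) if len(pts) else float("inf")
        k = int(dist // bin_width)
        binned.setdefault(k, []).append(res.score)
    out: dict[int, dict] = {}
    for k in sorted(binned):
        vals = np.asarray(binned[k], dtype=float)
        out[k] = {
            "range": (k * bin_width, (k + 1) * bin_width),
            "count": len(vals),
            "median": float(np.median(vals)),
            "q1": float(np.percentile(vals, 25)),
            "q3": float(np.percentile(vals, 75)),
        }
    return out


def bin_models_by_template_identity(
    model_scores: Mapping[str, float],
    identities: Mapping[str, float],
    bin_edges: Sequence[float] = (0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
) -> dict[str, dict]:
    """Partition model TopScores by template sequence identity bins.

    ``identities`` maps model id to the identity (fraction) of the template
    used to build it; models are expected above the 30% modelling cutoff
    (lower values only warn).  Bins are ``[edge_k, edge_k+1)``, with the
    final bin closed on the right.  Each bin reports count, median and full
    range of the scores.
    """
    edges = list(bin_edges)
    if sorted(edges) != edges or len(edges) < 2:
        raise ValueError("bin_edges must be increasing with at least two edges")
    missing = set(model_scores) - set(identities)
    if missing:
        raise ValueError(f"no template identity for models: {sorted(missing)}")
    bins: dict[str, list[float]] = {
        f"[{edges[k]:.2f},{edges[k + 1]:.2f})": [] for k in range(len(edges) - 1)
    }
    labels = list(bins)
    for model_id, score in model_scores.items():
        ident = identities[model_id]
        if not 0 <= ident <= 1:
            raise ValueError(f"identity {ident} for {model_id!r} outside [0, 1]")
        if ident < edges[0]:
            logger.warning("model %s: template identity %.2f below %.2f", model_id, ident, edges[0])
            continue
        if ident > edges[-1]:
            continue
        k = min(int(np.searchsorted(edges, ident, side="right")) - 1, len(labels) - 1)
        bins[labels[k]].append(score)
    out: dict[str, dict] = {}
    for label, vals in bins.items():
        if vals:
            arr = np.asarray(vals, dtype=float)
            out[label] = {
                "count": len(arr),
                "median": float(np.median(arr)),
                "min": float(arr.min()),
                "max": float(arr.max()),
            }
        else:
            out[label] = {"count": 0, "median": float("nan"), "min": float("nan"), "max": float("nan")}
    return out
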