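"""Five-criterion removal of unmodeled terminal regions from structural models.

Multi-domain enzyme models often carry long low-confidence tails where
template information was missing for a noncatalytic domain.  A candidate
region is removed only if it satisfies all five criteria:

(i)   it is at least ten residues long;
(ii)  it contains no residues of a secondary-structure element (α-helix or
      β-strand) longer than five residues;
(iii) its median relative solvent accessible surface area is larger than 0.40;
(iv)  its median contact density is smaller than four contacts;
(v)   it lies at the N- or C-terminus — internal loops stay within the
      modeled domain(s).

"Unmodeled" is operationalized as a contiguous run of low-confidence
residues (per-residue score at or above a threshold, default 0.6 on the
0–1 lower-is-better scale) or an explicit caller-supplied residue mask.
Medians use the lower median for even-sized regions so criterion
boundaries are exact.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Collection, Mapping, Sequence

from .geometry import ContactParams, ResidueDescriptors, SasaParams, compute_descriptors
from .structure import StructureModel

__all__ = [
    "Region",
    "TrimCriteria",
    "CriteriaReport",
    "detect_unmodeled_regions",
    "evaluate_region",
    "trim_structure",
    "lower_median",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Region:
    """A contiguous residue run, by position within its chain (inclusive)."""

    chain_id: str
    start: int
    end: int
    terminal: str  # one of "N", "C", "internal"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start must be <= end")
        if self.terminal not in ("N", "C", "internal"):
            raise ValueError(f"bad terminal tag {self.terminal!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TrimCriteria:
    min_length: int = 10
    max_ss_element: int = 5
    min_median_rel_sasa: float = 0.40
    max_median_contacts: int = 4
    terminal_only: bool = True

    def __post_init__(self) -> None:
        for name in ("min_length", "max_ss_element", "min_median_rel_sasa", "max_median_contacts"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CriteriaReport:
    """Verdict of the five criteria for one candidate region."""

    region: Region
    length_ok: bool
    ss_ok: bool
    sasa_ok: bool
    contacts_ok: bool
    terminal_ok: bool
    median_rel_sasa: float
    median_contacts: float
    longest_ss_element: int
    refused: bool = False  # removal vetoed to avoid deleting an entire chain

    @property
    def removable(self) -> bool:
        return (
            self.length_ok
            and self.ss_ok
            and self.sasa_ok
            and self.contacts_ok
            and self.terminal_ok
        )

    def criteria(self) -> tuple[bool, bool, bool, bool, bool]:
        return (self.length_ok, self.ss_ok, self.sasa_ok, self.contacts_ok, self.terminal_ok)

    def to_dict(self) -> dict:
        return {
            "chain": self.region.chain_id,
            "start": self.region.start,
            "end": self.region.end,
            "terminal": self.region.terminal,
            "length_ok": self.length_ok,
            "ss_ok": self.ss_ok,
            "sasa_ok": self.sasa_ok,
            "contacts_ok": self.contacts_ok,
            "terminal_ok": self.terminal_ok,
            "median_rel_sasa": self.median_rel_sasa,
            "median_contacts": self.median_contacts,
            "longest_ss_element": self.longest_ss_element,
            "removable": self.removable,
            "refused": self.refused,
        }


def lower_median(values: Sequence[float]) -> float:
    """Lower median: element at index (n-1)//2 of the sorted values."""
    if not values:
        raise ValueError("median of empty sequence")
    return sorted(values)[(len(values) - 1) // 2]


def _runs(flags: Sequence[bool]) -> list[tuple[int, int]]:
    runs: list[tuple[int, int]] = []
    start = None
    for k, f in enumerate(flags):
        if f and start is None:
            start = k
        elif not f and start is not None:
            runs.append((start, k - 1))
            start = None
    if start is not None:
        runs.append((start, len(flags) - 1))
    return runs


def _tag_terminal(start: int, end: int, n: int) -> str:
    if start == 0:
        return "N"
    if end == n - 1:
        return "C"
    return "internal"


def detect_unmodeled_regions(
    model: StructureModel,
    disorder_threshold: float = 0.6,
    mask: Collection[str] | Mapping[str, Sequence[bool]] | None = None,
) -> list[Region]:
    """Find candidate unmodeled regions.

    Without a mask: maximal contiguous runs of residues whose score is at
    or above ``disorder_threshold`` (scores are lower-is-better, so high
    score means low confidence).  With a mask (a set of residue labels or a
    per-chain boolean sequence), exactly the mask's runs are returned.
    Each region is tagged N/C/internal.
    """
    if mask is None and not 0 < disorder_threshold < 1:
        raise ValueError("disorder_threshold must be in (0, 1)")
    regions: list[Region] = []
    for chain in model.chains:
        n = len(chain.residues)
        if mask is None:
            flags = [r.score >= disorder_threshold for r in chain.residues]
        elif isinstance(mask, Mapping):
            flags = list(mask.get(chain.id, [False] * n))
            if len(flags) != n:
                raise ValueError(f"mask for chain {chain.id!r} has wrong length")
        else:
            flags = [r.label in mask for r in chain.residues]
        for start, end in _runs(flags):
            regions.append(Region(chain.id, start, end, _tag_terminal(start, end, n)))
    return regions


def _ss_elements(labels: Sequence[str]) -> list[tuple[int, int, str]]:
    """Maximal runs of identical H or E labels as (start, end, label)."""
    elements: list[tuple[int, int, str]] = []
    start = 0
    for k in range(1, len(labels) + 1):
        if k == len(labels) or labels[k] != labels[start]:
            if labels[start] in ("H", "E"):
                elements.append((start, k - 1, labels[start]))
            start = k
    return elements


def evaluate_region(
    region: Region,
    model: StructureModel,
    descriptors: Mapping[str, ResidueDescriptors],
    criteria: TrimCriteria = TrimCriteria(),
) -> CriteriaReport:
    """Apply the five criteria to one candidate region.

    Criterion boundaries follow the printed inequalities exactly: length
    ≥ 10 passes, an intersecting secondary-structure element of length > 5
    fails, median relative SASA must exceed 0.40 strictly, median contacts
    must be below 4 strictly, and only terminal regions qualify.
    """
    chain = model.chain(region.chain_id)
    if region.end >= len(chain.residues):
        raise ValueError(f"region {region} outside chain {region.chain_id}")
    residues = chain.residues[region.start : region.end + 1]
    desc = [descriptors[r.label] for r in residues]

    labels = [descriptors[r.label].ss_label for r in chain.residues]
    longest = 0
    for s, e, _lab in _ss_elements(labels):
        if s <= region.end and e >= region.start:  # element intersects region
            longest = max(longest, e - s + 1)

    med_sasa = lower_median([d.relative_sasa for d in desc])
    med_contacts = lower_median([float(d.contact_density) for d in desc])
    return CriteriaReport(
        region=region,
        length_ok=len(region) >= criteria.min_length,
        ss_ok=longest <= criteria.max_ss_element,
        sasa_ok=med_sasa > criteria.min_median_rel_sasa,
        contacts_ok=med_contacts < criteria.max_median_contacts,
        terminal_ok=(not criteria.terminal_only) or region.terminal in ("N", "C"),
        median_rel_sasa=med_sasa,
        median_contacts=med_contacts,
        longest_ss_element=longest,
    )


def trim_structure(
    model: StructureModel,
    criteria: TrimCriteria = TrimCriteria(),
    mode: str = "single",
    disorder_threshold: float = 0.6,
    mask: Collection[str] | Mapping[str, Sequence[bool]] | None = None,
    sasa_params: SasaParams = SasaParams(),
    contact_params: ContactParams = ContactParams(),
) -> tuple[StructureModel, list[CriteriaReport]]:
    """Detect, evaluate, and delete removable terminal regions.

    ``mode="single"`` makes one pass; ``mode="iterate"`` repeats until no
    terminal region is removable (a formerly internal run adjacent to a
    removed tail may become terminal).  Deleting an entire chain is refused
    and reported.  Retained residues keep their numbering.  The input model
    is not modified.
    """
    if mode not in ("single", "iterate"):
        raise ValueError("mode must be 'single' or 'iterate'")
    work = copy.deepcopy(model)
    reports: list[CriteriaReport] = []
    for _round in range(100 if mode == "iterate" else 1):
        descriptors = compute_descriptors(work, sasa_params, contact_params)
        regions = detect_unmodeled_regions(work, disorder_threshold, mask)
        round_reports = [evaluate_region(r, work, descriptors, criteria) for r in regions]

        # Veto removals that would empty a chain.
        for chain in work.chains:
            doomed = [
                rep
                for rep in round_reports
                if rep.removable and rep.region.chain_id == chain.id
            ]
            if doomed and sum(len(rep.region) for rep in doomed) >= len(chain.residues):
                for rep in doomed:
                    rep.refused = True
                logger.warning(
                    "refusing to trim chain %s: removal would delete every residue", chain.id
                )

        reports.extend(round_reports)
        removable = [rep for rep in round_reports if rep.removable and not rep.refused]
        if not removable:
            break
        # Delete from the back so earlier regions' indices stay valid.
        for rep in sorted(removable, key=lambda r: -r.region.start):
            chain = work.chain(rep.region.chain_id)
            del chain.residues[rep.region.start : rep.region.end + 1]
        if mode == "single":
            break
        mask = None  # a caller mask is positional; it is consumed by the first pass
    return work, reports
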