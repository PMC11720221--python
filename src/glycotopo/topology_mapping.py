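"""Classify glycosylation sites against annotated membrane topology.

A site is ``in_tm`` when it falls inside a TM segment (inclusive ends; a site
on a segment's first or last residue is in the membrane), ``interface`` when
its sequence distance to the nearest TM segment is between 1 and the window
``w``, and ``extramembrane`` otherwise. A site whose own listed topological
domain does not contain its position is flagged ``annotation_mismatch``; that
flag takes precedence over distance-based labels.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, NamedTuple, Optional

from .io_annotations import (
    GlycanClass,
    GlycoSite,
    TopologyAnnotation,
    TopoSegment,
)

__all__ = [
    "LocationLabel",
    "SiteLocation",
    "ClassificationResult",
    "DEFAULT_INTERFACE_WINDOW",
    "locate_site",
    "classify_all",
    "site_multiplicity",
]

#: default interface window in sequence positions (CLI-configurable)
DEFAULT_INTERFACE_WINDOW = 3


class LocationLabel(str, Enum):
    IN_TM = "in_tm"
    INTERFACE = "interface"
    EXTRAMEMBRANE = "extramembrane"
    ANNOTATION_MISMATCH = "annotation_mismatch"


@dataclass(frozen=True)
class SiteLocation:
    """Annotation-level classification outcome for one site.

    ``nearest_tm_distance`` is 0 for in_tm sites, the minimum sequence distance
    to a TM segment otherwise, and None when the annotation has no TM segment.
    ``segment`` is the containing TM segment for in_tm sites and the nearest
    TM segment for interface sites.
    """

    site: GlycoSite
    label: LocationLabel
    nearest_tm_distance: Optional[int]
    segment: Optional[TopoSegment] = None

    def __post_init__(self) -> None:
        if self.label is LocationLabel.IN_TM and self.nearest_tm_distance != 0:
            raise ValueError("in_tm requires nearest_tm_distance == 0")
        if (
            self.label is LocationLabel.INTERFACE
            and (self.nearest_tm_distance is None or self.nearest_tm_distance < 1)
        ):
            raise ValueError("interface requires nearest_tm_distance >= 1")


class ClassificationResult(NamedTuple):
    locations: list[SiteLocation]
    unmapped: list[GlycoSite]


def locate_site(
    site: GlycoSite,
    topo: TopologyAnnotation,
    w: int = DEFAULT_INTERFACE_WINDOW,
) -> SiteLocation:
    """Classify one site against one protein's topology annotation.

    Ties between equally distant TM segments are broken toward the
    lower-numbered segment.
    """
    if w < 0:
        raise ValueError(f"interface window must be >= 0, got {w}")
    if topo.sequence_length is not None and site.position > topo.sequence_length:
        raise ValueError(
            f"{site.accession}: position {site.position} exceeds sequence length "
            f"{topo.sequence_length}"
        )

    nearest: Optional[TopoSegment] = None
    nearest_dist: Optional[int] = None
    for seg in topo.tm_segments:  # already sorted by start
        d = seg.distance_to(site.position)
        if nearest_dist is None or d < nearest_dist:
            nearest, nearest_dist = seg, d

    # consistency of the site's own listed domain wins over geometry
    if site.listed_domain is not None:
        lo, hi = site.listed_domain
        if not lo <= site.position <= hi:
            return SiteLocation(site, LocationLabel.ANNOTATION_MISMATCH, nearest_dist, nearest)

    if nearest_dist == 0:
        return SiteLocation(site, LocationLabel.IN_TM, 0, nearest)
    if nearest_dist is not None and nearest_dist <= w:
        return SiteLocation(site, LocationLabel.INTERFACE, nearest_dist, nearest)
    return SiteLocation(site, LocationLabel.EXTRAMEMBRANE, nearest_dist, None)


def classify_all(
    sites: Iterable[GlycoSite],
    topologies: Mapping[str, TopologyAnnotation],
    w: int = DEFAULT_INTERFACE_WINDOW,
) -> ClassificationResult:
    """Classify every site; sites whose accession lacks a topology annotation
    are itemized as unmapped rather than raising."""
    locations: list[SiteLocation] = []
    unmapped: list[GlycoSite] = []
    for site in sites:
        topo = topologies.get(site.accession)
        if topo is None:
            unmapped.append(site)
        else:
            locations.append(locate_site(site, topo, w))
    return ClassificationResult(locations, unmapped)


def site_multiplicity(
    locations: Iterable[SiteLocation],
    glycan_class: Optional[GlycanClass] = None,
) -> tuple[dict[str, int], dict[int, int]]:
    """Count in_tm sites per protein and histogram proteins by site count.

    Returns ``(per_accession, histogram)`` where histogram maps a multiplicity
    to the number of proteins with exactly that many in_tm sites. Σ over the
    histogram of (multiplicity × proteins) equals the number of counted sites.
    """
    per_accession: Counter[str] = Counter()
    for loc in locations:
        if loc.label is not LocationLabel.IN_TM:
            continue
        if glycan_class is not None and loc.site.glycan_class is not glycan_class:
            continue
        per_accession[loc.site.accession] += 1
    histogram = Counter(per_accession.values())
    return dict(per_accession), dict(histogram)
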