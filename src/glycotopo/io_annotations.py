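"""Tabular I/O for glycosylation-site tables, topology tables and predictor profiles.

All tables are UTF-8, tab-separated, with a named header row. Sequence
coordinates are 1-based with inclusive range ends throughout (UniProt-style
``248-256``); both hyphen and en-dash range separators are accepted on input.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "GlycanClass",
    "SiteStatus",
    "SegmentClass",
    "GlycoSite",
    "TopoSegment",
    "TopologyAnnotation",
    "PredictionProfile",
    "SchemaError",
    "RowError",
    "TableError",
    "ValidationError",
    "read_site_table",
    "write_site_table",
    "read_topology_table",
    "write_topology_table",
    "read_prediction_profiles",
    "write_prediction_profiles",
    "write_classification_table",
    "read_classification_table",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: residue-label alphabet for per-residue topology predictions
PROFILE_ALPHABET = set("MIOU")

_RANGE_RE = re.compile(r"^\s*(\d+)\s*[-–—]\s*(\d+)\s*$")


class GlycanClass(str, Enum):
    """Category of glycan attached at a site."""

    O_GLCNAC = "O-GlcNAc"
    O_LINKED_OTHER = "O-linked-other"
    N_LINKED = "N-linked"
    UNREPORTED = "unreported"


class SiteStatus(str, Enum):
    REPORTED = "reported"
    PREDICTED = "predicted"


class SegmentClass(str, Enum):
    TM_HELIX = "tm_helix"
    TM_STRAND = "tm_strand"
    NON_TM = "non_tm"

    @property
    def is_tm(self) -> bool:
        return self is not SegmentClass.NON_TM


class SchemaError(ValueError):
    """A required column is absent from a table header."""


class ValidationError(ValueError):
    """A record violates a structural invariant."""


@dataclass
class RowError:
    """One malformed data row, identified by its 1-based line number."""

    line: int
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"line {self.line}: {self.message}"


class TableError(ValueError):
    """Aggregate of row-level failures raised when parsing strictly."""

    def __init__(self, path: str | Path, errors: Sequence[RowError]):
        self.errors = list(errors)
        detail = "; ".join(str(e) for e in self.errors)
        super().__init__(f"{path}: {len(self.errors)} bad row(s): {detail}")


@dataclass(frozen=True)
class GlycoSite:
    """A single glycosylation site on a protein sequence.

    ``listed_domain`` is the site's own topological-domain range as stated by
    the source table (used for annotation-consistency checks); ``structure``
    names the coordinate source given for the protein (a 4-character PDB code,
    a predicted-model identifier, or empty).
    """

    accession: str
    position: int
    residue: str
    glycan_class: GlycanClass
    status: SiteStatus
    evidence: tuple[str, ...] = ()
    listed_domain: Optional[tuple[int, int]] = None
    domain_description: str = ""
    structure: str = ""
    glycan_in_structure: Optional[bool] = None
    protein_name: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(
                f"{self.accession}: position must be >= 1, got {self.position}"
            )
        if self.residue not in AMINO_ACIDS:
            raise ValidationError(
                f"{self.accession}:{self.position}: residue {self.residue!r} is not "
                "a one-letter amino-acid code"
            )
        if self.glycan_class is GlycanClass.N_LINKED and self.residue != "N":
            raise ValidationError(
                f"{self.accession}:{self.position}: N-linked site must be Asn (N), "
                f"got {self.residue}"
            )
        if (
            self.glycan_class in (GlycanClass.O_GLCNAC, GlycanClass.O_LINKED_OTHER)
            and self.residue not in ("S", "T")
        ):
            raise ValidationError(
                f"{self.accession}:{self.position}: O-linked site must be Ser/Thr, "
                f"got {self.residue}"
            )

    @property
    def key(self) -> tuple[str, int, GlycanClass]:
        """Identity used for deduplication across evidence rows."""
        return (self.accession, self.position, self.glycan_class)


@dataclass(frozen=True, order=True)
class TopoSegment:
    """One annotated topology segment, 1-based inclusive."""

    start: int
    end: int
    seg_class: SegmentClass = SegmentClass.TM_HELIX
    description: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"segment start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValidationError(f"segment start must be >= 1, got {self.start}")

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end

    def distance_to(self, position: int) -> int:
        """Sequence distance from ``position`` to the segment (0 if inside)."""
        if position < self.start:
            return self.start - position
        if position > self.end:
            return position - self.end
        return 0


@dataclass(frozen=True)
class TopologyAnnotation:
    """Ordered, non-overlapping topology segments for one protein."""

    accession: str
    segments: tuple[TopoSegment, ...] = ()
    sequence_length: Optional[int] = None

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.segments, key=lambda s: (s.start, s.end)))
        object.__setattr__(self, "segments", ordered)
        for a, b in zip(ordered, ordered[1:]):
            if b.start <= a.end:
                raise ValidationError(
                    f"{self.accession}: overlapping segments "
                    f"[{a.start},{a.end}] and [{b.start},{b.end}]"
                )
        if self.sequence_length is not None:
            for seg in ordered:
                if seg.end > self.sequence_length:
                    raise ValidationError(
                        f"{self.accession}: segment end {seg.end} exceeds sequence "
                        f"length {self.sequence_length}"
                    )

    @property
    def tm_segments(self) -> tuple[TopoSegment, ...]:
        return tuple(s for s in self.segments if s.seg_class.is_tm)


@dataclass(frozen=True)
class PredictionProfile:
    """Per-residue topology labels from one external predictor.

    Labels: M (membrane), I (inside), O (outside), U (unknown).
    ``supports_strands`` is False for predictors that cannot call TM strands.
    """

    predictor_name: str
    labels: str
    supports_strands: bool = True

    def __post_init__(self) -> None:
        bad = set(self.labels) - PROFILE_ALPHABET
        if bad:
            raise ValidationError(
                f"profile {self.predictor_name!r}: illegal label(s) "
                f"{sorted(bad)!r}; alphabet is M/I/O/U"
            )

    def __len__(self) -> int:
        return len(self.labels)

    def label_at(self, position: int) -> str:
        """1-based lookup."""
        if not 1 <= position <= len(self.labels):
            raise IndexError(
                f"position {position} outside profile {self.predictor_name!r} "
                f"(length {len(self.labels)})"
            )
        return self.labels[position - 1]


# ---------------------------------------------------------------------------
# parsing helpers
# ---------------------------------------------------------------------------

def parse_range(text: str) -> tuple[int, int]:
    """Parse ``"248-256"`` / ``"248–256"`` into an inclusive (start, end) pair."""
    m = _RANGE_RE.match(text)
    if m is None:
        raise ValueError(f"not a residue range: {text!r}")
    return int(m.group(1)), int(m.group(2))


def _require_columns(path: Path, fieldnames: Sequence[str] | None, required: Iterable[str]) -> None:
    have = set(fieldnames or ())
    missing = [c for c in required if c not in have]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def _split_evidence(text: str) -> tuple[str, ...]:
    parts = re.split(r"[;,/]", text)
    return tuple(p.strip() for p in parts if p.strip())


_SITE_COLUMNS = ("accession", "position", "residue", "glycan_class", "status", "evidence")


def read_site_table(
    path: str | Path,
    *,
    errors: Optional[list[RowError]] = None,
) -> list[GlycoSite]:
    """Read a glycosylation-site table.

    Required columns: accession, position, residue, glycan_class, status,
    evidence. Optional: domain_start, domain_end, domain_description,
    structure, glycan_in_structure, protein_name.

    Rows repeating (accession, position, glycan_class) are merged, with their
    evidence lists concatenated. If ``errors`` is given, malformed rows are
    appended to it and skipped; otherwise a :class:`TableError` listing every
    bad row (with line numbers) is raised.
    """
    path = Path(path)
    collected: list[RowError] = []
    sites: dict[tuple, GlycoSite] = {}
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        _require_columns(path, reader.fieldnames, _SITE_COLUMNS)
        for lineno, row in enumerate(reader, start=2):
            try:
                site = _site_from_row(row)
            except (ValueError, KeyError) as exc:
                collected.append(RowError(lineno, str(exc)))
                continue
            if site.key in sites:
                prev = sites[site.key]
                merged_ev = prev.evidence + tuple(
                    e for e in site.evidence if e not in prev.evidence
                )
                sites[site.key] = replace(prev, evidence=merged_ev)
            else:
                sites[site.key] = site
    if collected:
        if errors is None:
            raise TableError(path, collected)
        errors.extend(collected)
    return list(sites.values())


def _site_from_row(row: Mapping[str, str]) -> GlycoSite:
    pos_text = (row["position"] or "").strip()
    try:
        position = int(pos_text)
    except ValueError:
        raise ValueError(f"non-integer position {pos_text!r}") from None
    listed: Optional[tuple[int, int]] = None
    ds, de = (row.get("domain_start") or "").strip(), (row.get("domain_end") or "").strip()
    if ds and de:
        listed = (int(ds), int(de))
    gis_text = (row.get("glycan_in_structure") or "").strip().lower()
    gis = {"yes": True, "no": False}.get(gis_text) if gis_text else None
    return GlycoSite(
        accession=row["accession"].strip(),
        position=position,
        residue=row["residue"].strip(),
        glycan_class=GlycanClass((row["glycan_class"] or "").strip()),
        status=SiteStatus((row["status"] or "").strip()),
        evidence=_split_evidence(row.get("evidence") or ""),
        listed_domain=listed,
        domain_description=(row.get("domain_description") or "").strip(),
        structure=(row.get("structure") or "").strip(),
        glycan_in_structure=gis,
        protein_name=(row.get("protein_name") or "").strip(),
    )


_SITE_OUT_COLUMNS = _SITE_COLUMNS + (
    "domain_start",
    "domain_end",
    "domain_description",
    "structure",
    "glycan_in_structure",
    "protein_name",
)


def write_site_table(sites: Iterable[GlycoSite], path: str | Path) -> None:
    """Write sites as TSV with a stable column order (round-trips read_site_table)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_SITE_OUT_COLUMNS)
        for s in sites:
            ds, de = (s.listed_domain or ("", ""))
            gis = "" if s.glycan_in_structure is None else ("yes" if s.glycan_in_structure else "no")
            writer.writerow(
                [
                    s.accession,
                    s.position,
                    s.residue,
                    s.glycan_class.value,
                    s.status.value,
                    ";".join(s.evidence),
                    ds,
                    de,
                    s.domain_description,
                    s.structure,
                    gis,
                    s.protein_name,
                ]
            )


_TOPO_COLUMNS = ("accession", "start", "end", "seg_class")


def read_topology_table(path: str | Path) -> dict[str, TopologyAnnotation]:
    """Read topology segments grouped per accession, sorted and overlap-checked.

    Required columns: accession, start, end, seg_class; optional: description,
    sequence_length. Overlapping segments for one accession raise
    :class:`ValidationError` naming both segments.
    """
    path = Path(path)
    segments: dict[str, list[TopoSegment]] = {}
    lengths: dict[str, int] = {}
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        _require_columns(path, reader.fieldnames, _TOPO_COLUMNS)
        for lineno, row in enumerate(reader, start=2):
            try:
                acc = row["accession"].strip()
                seg = TopoSegment(
                    start=int(row["start"]),
                    end=int(row["end"]),
                    seg_class=SegmentClass(row["seg_class"].strip()),
                    description=(row.get("description") or "").strip(),
                )
            except ValueError as exc:
                raise TableError(path, [RowError(lineno, str(exc))]) from exc
            segments.setdefault(acc, []).append(seg)
            sl = (row.get("sequence_length") or "").strip()
            if sl:
                lengths[acc] = int(sl)
    return {
        acc: TopologyAnnotation(acc, tuple(segs), lengths.get(acc))
        for acc, segs in segments.items()
    }


def write_topology_table(annotations: Mapping[str, TopologyAnnotation], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TOPO_COLUMNS + ("description", "sequence_length"))
        for acc in sorted(annotations):
            ann = annotations[acc]
            for seg in ann.segments:
                writer.writerow(
                    [acc, seg.start, seg.end, seg.seg_class.value, seg.description,
                     ann.sequence_length if ann.sequence_length is not None else ""]
                )


def read_prediction_profiles(path: str | Path) -> list[PredictionProfile]:
    """Read predictor profiles (columns: predictor, labels; optional supports_strands).

    All profiles in one file must share a common label length; a mismatch
    raises :class:`ValidationError` naming the offending predictors.
    """
    path = Path(path)
    profiles: list[PredictionProfile] = []
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        _require_columns(path, reader.fieldnames, ("predictor", "labels"))
        for row in reader:
            ss = (row.get("supports_strands") or "true").strip().lower()
            profiles.append(
                PredictionProfile(
                    predictor_name=row["predictor"].strip(),
                    labels=row["labels"].strip(),
                    supports_strands=ss not in ("false", "no", "0"),
                )
            )
    if profiles:
        ref = profiles[0]
        for p in profiles[1:]:
            if len(p) != len(ref):
                raise ValidationError(
                    f"profile length mismatch: {ref.predictor_name!r} has "
                    f"{len(ref)} labels but {p.predictor_name!r} has {len(p)}"
                )
    return profiles


def write_prediction_profiles(profiles: Iterable[PredictionProfile], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["predictor", "supports_strands", "labels"])
        for p in profiles:
            writer.writerow([p.predictor_name, "true" if p.supports_strands else "false", p.labels])


# ---------------------------------------------------------------------------
# classification output table (site + location label)
# ---------------------------------------------------------------------------

_CLASSIFICATION_COLUMNS = _SITE_OUT_COLUMNS + (
    "label",
    "nearest_tm_distance",
    "segment_start",
    "segment_end",
    "segment_class",
)


def write_classification_table(records, path: str | Path) -> None:
    """Write SiteLocation records as TSV; bit-exact across runs on equal input."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_CLASSIFICATION_COLUMNS)
        for loc in records:
            s = loc.site
            ds, de = (s.listed_domain or ("", ""))
            gis = "" if s.glycan_in_structure is None else ("yes" if s.glycan_in_structure else "no")
            seg = loc.segment
            writer.writerow(
                [
                    s.accession,
                    s.position,
                    s.residue,
                    s.glycan_class.value,
                    s.status.value,
                    ";".join(s.evidence),
                    ds,
                    de,
                    s.domain_description,
                    s.structure,
                    gis,
                    s.protein_name,
                    loc.label.value,
                    "" if loc.nearest_tm_distance is None else loc.nearest_tm_distance,
                    seg.start if seg else "",
                    seg.end if seg else "",
                    seg.seg_class.value if seg else "",
                ]
            )


def read_classification_table(path: str | Path):
    """Read back a classification table written by :func:`write_classification_table`."""
    from .topology_mapping import LocationLabel, SiteLocation

    path = Path(path)
    records = []
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        _require_columns(path, reader.fieldnames, _SITE_COLUMNS + ("label",))
        for row in reader:
            site = _site_from_row(row)
            seg = None
            if (row.get("segment_start") or "").strip():
                seg = TopoSegment(
                    int(row["segment_start"]),
                    int(row["segment_end"]),
                    SegmentClass(row["segment_class"]),
                )
            dist_text = (row.get("nearest_tm_distance") or "").strip()
            records.append(
                SiteLocation(
                    site=site,
                    label=LocationLabel(row["label"]),
                    nearest_tm_distance=int(dist_text) if dist_text else None,
                    segment=seg,
                )
            )
    return records
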