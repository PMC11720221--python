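"""Headline summaries over classification and verdict tables.

Counts are stratified: reported and predicted sites are never mixed, protein
identity is keyed on accession (a protein carrying both O- and N-sites is
counted once in the union), and structure availability is triaged into
experimental PDB entry / predicted model / none.
"""

from __future__ import annotations

import csv
import json
import re
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .io_annotations import GlycanClass, GlycoSite, SiteStatus
from .topology_mapping import LocationLabel, SiteLocation, site_multiplicity
from .structure_validation import StructureVerdict, Verdict

__all__ = [
    "SummaryCounts",
    "StructureSource",
    "classify_structure_source",
    "triage_structures",
    "summarize",
    "render_report",
]

_PDB_CODE_RE = re.compile(r"^[0-9][A-Za-z0-9]{3}$")

#: verdicts that contradict the annotation-level expectation
EXCEPTION_VERDICTS = frozenset(
    {
        Verdict.RELOCATED_EXTRAMEMBRANE,
        Verdict.ON_TM_HELIX,
        Verdict.RESIDUE_MISMATCH,
        Verdict.GLYCAN_ABSENT,
        Verdict.OUTSIDE_MEMBRANE,
    }
)


class StructureSource:
    PDB = "pdb"
    MODEL = "model"
    NONE = "none"


def classify_structure_source(text: str) -> str:
    """Triage a structure-source string: 4-character experimental PDB code,
    predicted-model identifier (AF-...), or nothing."""
    text = (text or "").strip()
    if not text or text == "-":
        return StructureSource.NONE
    first = re.split(r"[,;\s]+", text)[0]
    if first.upper().startswith("AF-"):
        return StructureSource.MODEL
    if _PDB_CODE_RE.match(first):
        return StructureSource.PDB
    return StructureSource.NONE


def triage_structures(sites: Iterable[GlycoSite]) -> dict[str, str]:
    """Best structure source per accession (pdb beats model beats none)."""
    rank = {StructureSource.PDB: 2, StructureSource.MODEL: 1, StructureSource.NONE: 0}
    best: dict[str, str] = {}
    for site in sites:
        source = classify_structure_source(site.structure)
        current = best.get(site.accession)
        if current is None or rank[source] > rank[current]:
            best[site.accession] = source
    return best


@dataclass
class SummaryCounts:
    """The pipeline's headline counts, reported/predicted strata separate."""

    n_proteins_reported_tm: int = 0
    n_sites_O_tm: int = 0
    n_sites_N_tm: int = 0
    n_proteins_O: int = 0
    n_proteins_N: int = 0
    multiplicity_histogram: dict[int, int] = field(default_factory=dict)
    n_predicted_tm_sites: int = 0
    n_interface_O_proteins: int = 0
    n_interface_N_proteins: int = 0
    n_structures_pdb: int = 0
    n_structures_model: int = 0
    n_structures_none: int = 0

    def validate(self) -> None:
        if self.n_proteins_reported_tm > self.n_proteins_O + self.n_proteins_N:
            raise ValueError("union count exceeds sum of strata")
        n_hist_sites = sum(k * v for k, v in self.multiplicity_histogram.items())
        if self.multiplicity_histogram and n_hist_sites != self.n_sites_O_tm:
            raise ValueError(
                f"multiplicity histogram covers {n_hist_sites} sites, "
                f"expected {self.n_sites_O_tm}"
            )


def summarize(
    locations: Sequence[SiteLocation],
    interface_O_sites: Sequence[GlycoSite] = (),
    interface_N_sites: Sequence[GlycoSite] = (),
    verdicts: Sequence[StructureVerdict] = (),
) -> SummaryCounts:
    """Aggregate classified TM-site locations plus the interface-expectation
    strata into :class:`SummaryCounts`.

    ``locations`` are the classifications of the TM-site table;
    ``interface_*_sites`` are the site lists expected at the membrane
    interface (counted by distinct accession). Structure triage is taken from
    the sites' structure-source strings, over reported-stratum proteins.
    """
    counts = SummaryCounts()

    def _is_o(site: GlycoSite) -> bool:
        return site.glycan_class in (GlycanClass.O_GLCNAC, GlycanClass.O_LINKED_OTHER)

    reported_tm = [
        loc
        for loc in locations
        if loc.label is LocationLabel.IN_TM and loc.site.status is SiteStatus.REPORTED
    ]
    o_tm = [loc for loc in reported_tm if loc.site.glycan_class is GlycanClass.O_GLCNAC]
    n_tm = [loc for loc in reported_tm if loc.site.glycan_class is GlycanClass.N_LINKED]
    counts.n_sites_O_tm = len(o_tm)
    counts.n_sites_N_tm = len(n_tm)
    o_accessions = {loc.site.accession for loc in o_tm}
    n_accessions = {loc.site.accession for loc in n_tm}
    counts.n_proteins_O = len(o_accessions)
    counts.n_proteins_N = len(n_accessions)
    counts.n_proteins_reported_tm = len(o_accessions | n_accessions)
    _, histogram = site_multiplicity(reported_tm, GlycanClass.O_GLCNAC)
    counts.multiplicity_histogram = dict(sorted(histogram.items()))
    counts.n_predicted_tm_sites = sum(
        1
        for loc in locations
        if loc.label is LocationLabel.IN_TM and loc.site.status is SiteStatus.PREDICTED
    )
    counts.n_interface_O_proteins = len({s.accession for s in interface_O_sites})
    counts.n_interface_N_proteins = len({s.accession for s in interface_N_sites})

    reported_sites = [
        loc.site for loc in locations if loc.site.status is SiteStatus.REPORTED
    ]
    triage = triage_structures(reported_sites)
    tally = Counter(triage.values())
    counts.n_structures_pdb = tally.get(StructureSource.PDB, 0)
    counts.n_structures_model = tally.get(StructureSource.MODEL, 0)
    counts.n_structures_none = tally.get(StructureSource.NONE, 0)

    counts.validate()
    return counts


def render_report(
    counts: SummaryCounts,
    verdicts: Sequence[StructureVerdict],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write summary.json, summary.tsv and exceptions.tsv with stable ordering;
    output is byte-identical across runs on identical input."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "summary_json": out_dir / "summary.json",
        "summary_tsv": out_dir / "summary.tsv",
        "exceptions_tsv": out_dir / "exceptions.tsv",
    }

    payload = asdict(counts)
    payload["multiplicity_histogram"] = {
        str(k): v for k, v in sorted(counts.multiplicity_histogram.items())
    }
    paths["summary_json"].write_text(
        json.dumps(payload, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )

    with paths["summary_tsv"].open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["metric", "value"])
        for key, value in sorted(payload.items()):
            if isinstance(value, dict):
                for k, v in value.items():
                    writer.writerow([f"{key}[{k}]", v])
            else:
                writer.writerow([key, value])

    exceptions = sorted(
        (v for v in verdicts if v.verdict in EXCEPTION_VERDICTS),
        key=lambda v: (v.site.accession, v.site.position),
    )
    with paths["exceptions_tsv"].open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["accession", "position", "residue", "verdict", "glycan_found",
             "orientation", "slab_class", "mapped_position"]
        )
        for v in exceptions:
            writer.writerow(
                [
                    v.site.accession,
                    v.site.position,
                    v.site.residue,
                    v.verdict.value,
                    "yes" if v.glycan_found else "no",
                    v.orientation.value,
                    v.slab_class.value if v.slab_class else "",
                    v.mapped_position if v.mapped_position is not None else "",
                ]
            )
    return paths
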