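"""Multi-predictor topology consensus at glycosylation sites.

Aggregates per-residue membrane/non-membrane calls from several predictor
profiles into vote counts, fractions and majority labels, and flags sites
where the consensus disagrees with a reference annotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

from .io_annotations import (
    GlycoSite,
    PredictionProfile,
    SegmentClass,
    TopologyAnnotation,
)

__all__ = [
    "MajorityLabel",
    "ConsensusRecord",
    "AgreementRow",
    "tally_votes",
    "agreement_report",
]


class MajorityLabel(str, Enum):
    TM = "tm"
    NON_TM = "non_tm"
    TIE = "tie"


@dataclass(frozen=True)
class ConsensusRecord:
    """Vote summary at one sequence position."""

    position: int
    tm_votes: int
    total_votes: int
    majority_label: MajorityLabel

    def __post_init__(self) -> None:
        if not 0 <= self.tm_votes <= self.total_votes:
            raise ValueError(
                f"tm_votes {self.tm_votes} outside [0, {self.total_votes}]"
            )

    @property
    def fraction(self) -> float:
        return self.tm_votes / self.total_votes if self.total_votes else 0.0


def _eligible(
    profiles: Iterable[PredictionProfile], seg_class: Optional[SegmentClass]
) -> list[PredictionProfile]:
    # strand-blind predictors abstain over TM-strand segments
    if seg_class is SegmentClass.TM_STRAND:
        return [p for p in profiles if p.supports_strands]
    return list(profiles)


def tally_votes(
    profiles: Sequence[PredictionProfile],
    position: int,
    *,
    reference_is_tm: Optional[bool] = None,
    count_reference_vote: bool = True,
    seg_class: Optional[SegmentClass] = None,
) -> ConsensusRecord:
    """Count membrane votes at a 1-based position across predictor profiles.

    ``reference_is_tm``, when given and ``count_reference_vote`` is on, adds
    the reference annotation as one extra vote. Majority is by strict
    majority; exact splits report ``tie``. A position outside any profile
    raises IndexError naming that profile.
    """
    eligible = _eligible(profiles, seg_class)
    tm_votes = 0
    total = 0
    for profile in eligible:
        label = profile.label_at(position)  # raises IndexError naming profile
        if label == "U":
            continue
        total += 1
        if label == "M":
            tm_votes += 1
    if reference_is_tm is not None and count_reference_vote:
        total += 1
        if reference_is_tm:
            tm_votes += 1
    if tm_votes * 2 > total:
        majority = MajorityLabel.TM
    elif tm_votes * 2 < total:
        majority = MajorityLabel.NON_TM
    else:
        majority = MajorityLabel.TIE
    return ConsensusRecord(position, tm_votes, total, majority)


@dataclass(frozen=True)
class AgreementRow:
    """One site's consensus record next to its reference topology label."""

    site: GlycoSite
    record: ConsensusRecord
    reference_is_tm: bool
    flagged: bool


def agreement_report(
    profiles: Sequence[PredictionProfile],
    sites: Iterable[GlycoSite],
    reference: TopologyAnnotation,
    *,
    count_reference_vote: bool = True,
) -> list[AgreementRow]:
    """One row per site; rows where the predictor majority disagrees with the
    reference annotation are flagged."""
    rows: list[AgreementRow] = []
    for site in sites:
        seg_class = None
        ref_tm = False
        for seg in reference.tm_segments:
            if site.position in seg:
                ref_tm = True
                seg_class = seg.seg_class
                break
        record = tally_votes(
            profiles,
            site.position,
            reference_is_tm=ref_tm,
            count_reference_vote=count_reference_vote,
            seg_class=seg_class,
        )
        majority_tm = record.majority_label is MajorityLabel.TM
        flagged = record.majority_label is MajorityLabel.TIE or majority_tm != ref_tm
        rows.append(AgreementRow(site, record, ref_tm, flagged))
    return rows
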