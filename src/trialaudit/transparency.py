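"""Transparency indicators: trial-documentation access and data sharing.

These are pure tabulations of annotator-extracted fields — whether the full
protocol and the statistical analysis plan could be accessed (and where),
and how the data-sharing (availability) statement classifies: willing to
share, not willing, or no statement at all, with the sharing modalities
(access location, time frame, researcher-only restriction, other
restrictions) recorded for willing trials.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .model import Location, SharingStatement, TransparencyInfo, TrialRecord

__all__ = ["TransparencyIndicators", "summarize_transparency"]


@dataclass(frozen=True)
class TransparencyIndicators:
    protocol_available: bool
    protocol_location: Location
    protocol_complete: Optional[bool]
    protocol_in_english: Optional[bool]
    sap_available: bool
    sharing_statement: SharingStatement
    statement_location: Location
    access_location_given: Optional[bool]
    timeframe_given: Optional[bool]
    researchers_only: Optional[bool]
    other_restrictions: Optional[bool]
    registry_publication_consistent: Optional[bool]


def summarize_transparency(record: TrialRecord) -> TransparencyIndicators:
    """Flatten one record's transparency fields into the indicator tuple.

    Sharing sub-flags (access location, time frame, restrictions) are
    emitted only when a statement exists; with no statement they are absent
    rather than false. Registry/publication consistency applies only when
    the statement appears in both places.
    """
    tr: TransparencyInfo = record.transparency
    has_statement = tr.sharing_statement is not SharingStatement.NO_STATEMENT
    return TransparencyIndicators(
        protocol_available=tr.protocol_available,
        protocol_location=tr.protocol_location,
        protocol_complete=tr.protocol_complete if tr.protocol_available else None,
        protocol_in_english=tr.protocol_in_english if tr.protocol_available else None,
        sap_available=tr.sap_available,
        sharing_statement=tr.sharing_statement,
        statement_location=tr.statement_location,
        access_location_given=tr.access_location_given if has_statement else None,
        timeframe_given=tr.timeframe_given if has_statement else None,
        researchers_only=tr.researchers_only if has_statement else None,
        other_restrictions=tr.other_restrictions if has_statement else None,
        registry_publication_consistent=(
            tr.registry_publication_consistent
            if tr.statement_location is Location.BOTH
            else None
        ),
    )
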