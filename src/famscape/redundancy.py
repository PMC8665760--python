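"""Greedy identity/coverage redundancy filtering (nr90/nr70-style reduction).

Longest-first greedy scheme: records are visited by decreasing length (id as
tie-break); a record is retained unless some already-retained record aligns
to it with identity above the ceiling AND coverage at or above the floor, in
which case it is mapped to the first such retained record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import AlignParams, sw_align
from .records import SequenceRecord


@dataclass
class FilterResult:
    retained: list[str]
    representative_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.retained) & set(self.representative_of):
            raise ValueError("retained and discarded sets overlap")


def is_redundant_pair(aln, max_identity: float, min_coverage: float) -> bool:
    return aln.identity > max_identity and aln.coverage >= min_coverage


def filter_redundant(
    records: list[SequenceRecord],
    max_identity: float = 0.9,
    min_coverage: float = 0.7,
    params: AlignParams | None = None,
) -> FilterResult:
    """Reduce a record set to at most ``max_identity`` pairwise identity.

    The defaults (0.9 identity, 0.7 coverage) are the map-construction
    settings; 0.7 identity is the deeper reduction used for very large
    families. Deterministic: length-descending order with lexicographic id
    tie-break. Empty input yields an empty result.
    """
    if not 0 < max_identity <= 1 or not 0 < min_coverage <= 1:
        raise ValueError("thresholds must be in (0, 1]")
    params = params or AlignParams()
    order = sorted(records, key=lambda r: (-len(r), r.id))
    retained: list[SequenceRecord] = []
    result = FilterResult(retained=[])
    for rec in order:
        rep = None
        for kept in retained:
            aln = sw_align(kept.seq, rec.seq, params)
            if is_redundant_pair(aln, max_identity, min_coverage):
                rep = kept
                break
        if rep is None:
            retained.append(rec)
            result.retained.append(rec.id)
        else:
            result.representative_of[rec.id] = rep.id
    return result
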