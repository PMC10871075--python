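"""Post-processing of CNV calls and disorder-region screening.

Stages, in pipeline order: merge nearby same-direction calls (gap strictly
below 200 kb by default), optionally combine two callers' sets by union,
filter on marker count / length / confidence (all strictly greater-than, as
is conventional for these thresholds), then match the surviving calls
against a disorder-region database.  A disorder is "detected" when the
union of direction-matching overlap covers at least ``min_fraction`` of the
region (any positive overlap by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .signal_io import CNVCall, DisorderRegion, chrom_sort_rank

__all__ = [
    "ScreenResult",
    "merge_adjacent_calls",
    "filter_calls",
    "combine_callsets",
    "detected_fraction",
    "match_disorders",
]

MERGE_GAP_DEFAULT = 200_000
MIN_SNPS_DEFAULT = 10
MIN_LENGTH_DEFAULT = 50_000
MIN_CONF_DEFAULT = 50.0
MIN_FRACTION_DEFAULT = 1e-9  # any positive overlap


@dataclass(frozen=True)
class ScreenResult:
    """Per-sample, per-disorder screening verdict."""

    sample_id: str
    disorder: str
    matched_calls: tuple[CNVCall, ...]
    detected_fraction: float
    status: str  # "detected" | "normal" | "qc_failed"


def _check_single_sample(calls: Sequence[CNVCall]) -> None:
    ids = {c.sample_id for c in calls}
    if len(ids) > 1:
        raise ValueError(f"calls from multiple samples: {sorted(ids)}")


def _sorted_calls(calls: Iterable[CNVCall]) -> list[CNVCall]:
    return sorted(calls, key=lambda c: (chrom_sort_rank(c.chrom), c.start, c.end))


def merge_adjacent_calls(calls: Sequence[CNVCall], max_gap: int = MERGE_GAP_DEFAULT) -> list[CNVCall]:
    """Merge consecutive same-chromosome, same-direction calls whose gap
    (intervening bases, next.start - prev.end - 1) is strictly below
    ``max_gap``.

    The merged call spans the union, sums marker counts and confidences
    (additive log-likelihood rationale), and takes the copy number of the
    longer constituent.  The operation is idempotent.
    """
    _check_single_sample(calls)
    merged: list[CNVCall] = []
    for c in _sorted_calls(calls):
        prev = merged[-1] if merged else None
        if (
            prev is not None
            and prev.chrom == c.chrom
            and prev.direction == c.direction
            and c.start - prev.end - 1 < max_gap
        ):
            longer = prev if prev.length >= c.length else c
            merged[-1] = CNVCall(
                sample_id=prev.sample_id,
                chrom=prev.chrom,
                start=min(prev.start, c.start),
                end=max(prev.end, c.end),
                cn=longer.cn,
                n_snps=prev.n_snps + c.n_snps,
                confidence=prev.confidence + c.confidence,
                caller=prev.caller if prev.caller == c.caller else "merged",
            )
        else:
            merged.append(c)
    return merged


def filter_calls(
    calls: Sequence[CNVCall],
    min_snps: int = MIN_SNPS_DEFAULT,
    min_length: int = MIN_LENGTH_DEFAULT,
    min_conf: float = MIN_CONF_DEFAULT,
) -> list[CNVCall]:
    """Keep calls with n_snps > min_snps AND length > min_length AND
    confidence > min_conf (all strict)."""
    return [
        c
        for c in calls
        if c.n_snps > min_snps and c.length > min_length and c.confidence > min_conf
    ]


def combine_callsets(calls_a: Sequence[CNVCall], calls_b: Sequence[CNVCall]) -> list[CNVCall]:
    """Union of two callers' sets for one sample (reduces false negatives).

    Overlapping same-direction calls collapse to their span union with
    confidence = max (caller scales are not commensurable) and caller tag
    "both" when the constituents came from different callers.
    Opposite-direction overlaps are kept separately.
    """
    pool = list(calls_a) + list(calls_b)
    if not pool:
        return []
    _check_single_sample(pool)
    out: list[CNVCall] = []
    for c in _sorted_calls(pool):
        prev = out[-1] if out else None
        if (
            prev is not None
            and prev.chrom == c.chrom
            and prev.direction == c.direction
            and c.start <= prev.end
        ):
            longer = prev if prev.length >= c.length else c
            out[-1] = CNVCall(
                sample_id=prev.sample_id,
                chrom=prev.chrom,
                start=min(prev.start, c.start),
                end=max(prev.end, c.end),
                cn=longer.cn,
                n_snps=max(prev.n_snps, c.n_snps),
                confidence=max(prev.confidence, c.confidence),
                caller=prev.caller if prev.caller == c.caller else "both",
            )
        else:
            out.append(c)
    return out


def _union_length(intervals: list[tuple[int, int]]) -> int:
    """Total length of a union of 1-based inclusive intervals."""
    if not intervals:
        return 0
    intervals.sort()
    total = 0
    cur_s, cur_e = intervals[0]
    for s, e in intervals[1:]:
        if s > cur_e + 1:
            total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    return total + (cur_e - cur_s + 1)


def detected_fraction(calls: Sequence[CNVCall], region: DisorderRegion) -> float:
    """Union length of (call ∩ region) over direction-matching calls,
    divided by the region length (1-based inclusive)."""
    clipped = [
        (max(c.start, region.start), min(c.end, region.end))
        for c in calls
        if c.chrom == region.chrom
        and c.direction == region.direction
        and c.start <= region.end
        and c.end >= region.start
    ]
    return _union_length(clipped) / region.length


def match_disorders(
    calls: Sequence[CNVCall],
    db: Sequence[DisorderRegion],
    min_fraction: float = MIN_FRACTION_DEFAULT,
    sample_id: str | None = None,
) -> list[ScreenResult]:
    """One ScreenResult per disorder region.

    A call counts toward a region when direction matches (cn<2 <-> del,
    cn>2 <-> dup) and, when the region specifies an expected copy number,
    the call's cn equals it.  Status is "detected" iff the detected fraction
    reaches ``min_fraction``.
    """
    if sample_id is None:
        sample_id = calls[0].sample_id if calls else "unknown"
    results = []
    for region in db:
        candidates = [
            c
            for c in calls
            if c.chrom == region.chrom
            and c.direction == region.direction
            and (region.expected_cn is None or c.cn == region.expected_cn)
            and c.start <= region.end
            and c.end >= region.start
        ]
        frac = detected_fraction(candidates, region)
        results.append(
            ScreenResult(
                sample_id=sample_id,
                disorder=region.name,
                matched_calls=tuple(candidates),
                detected_fraction=frac,
                status="detected" if frac >= min_fraction else "normal",
            )
        )
    return results
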