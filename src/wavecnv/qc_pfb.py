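"""Sample quality control and population-B-allele-frequency computation.

QC is applied per sample: a sample passes when its genotype call rate is at
least ``call_rate_min`` (default 0.98, inclusive) and the standard deviation
of its autosomal LRR is at most ``lrr_sd_max`` (default 0.2, inclusive).
Standard deviations use ddof=1 throughout the package.

The PFB (population frequency of the B allele) is the per-marker mean of
non-missing BAF across a cohort, clamped into [0.01, 0.99] so the exported
table is usable by external CNV callers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .signal_io import MarkerMap, SignalSample

__all__ = ["QCError", "QCReport", "sample_qc", "compute_pfb", "marker_call_rates"]

CALL_RATE_MIN_DEFAULT = 0.98
LRR_SD_MAX_DEFAULT = 0.2
PFB_CLAMP = (0.01, 0.99)


class QCError(ValueError):
    """Raised when QC statistics cannot be computed at all."""


@dataclass(frozen=True)
class QCReport:
    sample_id: str
    call_rate: float
    lrr_sd: float
    passed: bool


def sample_qc(
    sample: SignalSample,
    markers: MarkerMap,
    call_rate_min: float = CALL_RATE_MIN_DEFAULT,
    lrr_sd_max: float = LRR_SD_MAX_DEFAULT,
) -> QCReport:
    """Per-sample QC report.

    Call rate counts markers with a non-missing BAF and, when a genotype
    column is present, a genotype other than NC.  LRR SD is computed over
    non-missing autosomal LRR (ddof=1); a sample with no usable LRR at all
    raises :class:`QCError`.
    """
    if len(sample) != len(markers):
        raise ValueError("sample and marker map lengths differ")
    called = np.isfinite(sample.baf)
    if sample.genotype is not None:
        called &= sample.genotype != "NC"
    call_rate = float(called.mean()) if len(sample) else 0.0

    auto = markers.autosome_mask
    lrr = sample.lrr[auto & np.isfinite(sample.lrr)]
    if lrr.size == 0:
        raise QCError(f"{sample.sample_id}: no non-missing autosomal LRR values")
    lrr_sd = float(np.std(lrr, ddof=1)) if lrr.size > 1 else 0.0

    passed = call_rate >= call_rate_min and lrr_sd <= lrr_sd_max
    return QCReport(sample.sample_id, call_rate, lrr_sd, passed)


def compute_pfb(samples: Sequence[SignalSample]) -> np.ndarray:
    """Per-marker mean of non-missing BAF across samples, clamped to [0.01, 0.99].

    Markers with no observation in any sample get 0.5.
    """
    if len(samples) == 0:
        raise ValueError("compute_pfb requires at least one sample")
    n = len(samples[0])
    total = np.zeros(n)
    count = np.zeros(n)
    for s in samples:
        if len(s) != n:
            raise ValueError("samples have inconsistent marker counts")
        present = np.isfinite(s.baf)
        total[present] += s.baf[present]
        count[present] += 1
    pfb = np.full(n, 0.5)
    seen = count > 0
    pfb[seen] = total[seen] / count[seen]
    return np.clip(pfb, *PFB_CLAMP)


def marker_call_rates(samples: Sequence[SignalSample]) -> np.ndarray:
    """Across-sample per-marker call rate (optional marker-level filter)."""
    if len(samples) == 0:
        raise ValueError("requires at least one sample")
    n = len(samples[0])
    called = np.zeros(n)
    for s in samples:
        ok = np.isfinite(s.baf)
        if s.genotype is not None:
            ok &= s.genotype != "NC"
        called += ok
    return called / len(samples)
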