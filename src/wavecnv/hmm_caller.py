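"""Distance-aware HMM segmentation of (corrected) LRR into copy-number calls.

States are copy numbers {0,1,2,3,4}.  The LRR emission for state s is
Gaussian(lrr_mean[s], lrr_sd[s]); an optional BAF term adds a genotype
mixture whose components sit at the allelic fractions achievable at that
copy number (e.g. {0, 1/3, 2/3, 1} for CN3), weighted binomially by the
marker's population B-allele frequency, each component a Gaussian truncated
to [0, 1]; CN0 has no genotype and uses a uniform BAF density.

Transitions depend on the physical distance d to the previous marker:

    a(s -> t | d) = rho(d) * [s == t] + (1 - rho(d)) * prior[t],
    rho(d) = exp(-d / decay_distance)

so nearby markers strongly share state while distant markers relax toward
the stationary prior.  Chromosome boundaries reset to the prior.  Viterbi
ties are broken toward CN2, then the smaller copy number.

Runs of equal non-diploid state become calls whose confidence is the summed
per-marker emission log-likelihood advantage over CN2 (natural log).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import binom, norm

from .signal_io import CNVCall, MarkerMap

__all__ = [
    "HMMParams",
    "emission_loglik",
    "emission_matrix",
    "viterbi_path",
    "viterbi_chromosome",
    "segment_calls",
    "call_cnvs",
]

STATES = (0, 1, 2, 3, 4)
# canonical SNP-array per-state emission parameters; configurable, not fitted
LRR_MEAN_DEFAULT = (-3.0, -0.66, 0.0, 0.40, 0.68)
LRR_SD_DEFAULT = (1.0, 0.28, 0.16, 0.21, 0.19)
PRIOR_DEFAULT = (0.00125, 0.00125, 0.995, 0.00125, 0.00125)

# Viterbi tie preference: CN2 first, then smaller copy number
_PREF = np.array([2, 0, 1, 3, 4])


@dataclass
class HMMParams:
    lrr_mean: tuple[float, ...] = LRR_MEAN_DEFAULT
    lrr_sd: tuple[float, ...] = LRR_SD_DEFAULT
    prior: tuple[float, ...] = PRIOR_DEFAULT
    decay_distance: float = 100_000.0
    use_baf: bool = False
    baf_sd: float = 0.03

    def __post_init__(self) -> None:
        if len(self.lrr_mean) != 5 or len(self.lrr_sd) != 5 or len(self.prior) != 5:
            raise ValueError("per-state parameters must have length 5")
        if min(self.lrr_sd) <= 0:
            raise ValueError("lrr_sd must be positive")
        if abs(sum(self.prior) - 1.0) > 1e-12:
            raise ValueError("prior must sum to 1")
        if self.decay_distance <= 0:
            raise ValueError("decay_distance must be positive")
        if self.baf_sd <= 0:
            raise ValueError("baf_sd must be positive")


def _baf_mixture_loglik(baf: np.ndarray, pfb: np.ndarray, cn: int, sd: float) -> np.ndarray:
    """Log-density of the genotype mixture at copy number ``cn`` (vectorized)."""
    if cn == 0:
        return np.zeros_like(baf)  # uniform on [0, 1]
    centers = np.arange(cn + 1) / cn
    comps = []
    for j, c in enumerate(centers):
        w = binom.logpmf(j, cn, pfb)
        trunc = np.log(norm.cdf((1.0 - c) / sd) - norm.cdf((0.0 - c) / sd))
        comps.append(w + norm.logpdf(baf, loc=c, scale=sd) - trunc)
    return logsumexp(np.stack(comps), axis=0)


def emission_matrix(
    mlrr: np.ndarray,
    baf: np.ndarray | None,
    pfb: np.ndarray | None,
    params: HMMParams,
) -> np.ndarray:
    """(n_markers, 5) emission log-likelihoods; missing observations add 0."""
    mlrr = np.asarray(mlrr, dtype=float)
    n = mlrr.shape[0]
    out = np.zeros((n, 5))
    present = np.isfinite(mlrr)
    for s in STATES:
        mu, sd = params.lrr_mean[s], params.lrr_sd[s]
        out[present, s] += norm.logpdf(mlrr[present], loc=mu, scale=sd)
    if params.use_baf and baf is not None:
        baf = np.asarray(baf, dtype=float)
        pfb_arr = np.full(n, 0.5) if pfb is None else np.asarray(pfb, dtype=float)
        bp = np.isfinite(baf)
        for s in STATES:
            out[bp, s] += _baf_mixture_loglik(baf[bp], pfb_arr[bp], s, params.baf_sd)
    return out


def emission_loglik(
    mlrr_value: float,
    baf_value: float | None,
    pfb_value: float | None,
    state: int,
    params: HMMParams,
) -> float:
    """Scalar emission log-likelihood for one marker and one state."""
    if state not in STATES:
        raise ValueError(f"unknown state {state}")
    m = emission_matrix(
        np.array([mlrr_value if mlrr_value is not None else np.nan]),
        None if baf_value is None else np.array([baf_value]),
        None if pfb_value is None else np.array([pfb_value]),
        params,
    )
    return float(m[0, state])


def viterbi_chromosome(
    emissions: np.ndarray,
    positions: np.ndarray,
    params: HMMParams,
) -> tuple[np.ndarray, float]:
    """MAP state path for one chromosome; returns (path, log-probability)."""
    n = emissions.shape[0]
    if n == 0:
        raise ValueError("empty chromosome")
    log_prior = np.log(np.asarray(params.prior, dtype=float))
    positions = np.asarray(positions, dtype=float)
    rho = np.exp(-np.diff(positions) / params.decay_distance)

    V = log_prior + emissions[0]
    back = np.zeros((n, 5), dtype=np.int8)
    eye = np.eye(5)
    prior_row = np.asarray(params.prior, dtype=float)[None, :]
    for t in range(1, n):
        A = rho[t - 1] * eye + (1.0 - rho[t - 1]) * np.repeat(prior_row, 5, axis=0)
        with np.errstate(divide="ignore"):
            M = V[:, None] + np.log(A)
        # predecessor argmax; first max in preference order wins ties
        bi = _PREF[np.argmax(M[_PREF, :], axis=0)]
        V = M[bi, np.arange(5)] + emissions[t]
        back[t] = bi
    last = int(_PREF[np.argmax(V[_PREF])])
    logp = float(V[last])
    path = np.empty(n, dtype=np.int8)
    path[-1] = last
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path, logp


def viterbi_path(
    emissions: np.ndarray,
    markers: MarkerMap,
    params: HMMParams,
) -> tuple[np.ndarray, float]:
    """Genome-wide MAP path; chromosome boundaries reset to the prior."""
    if emissions.shape[0] != len(markers):
        raise ValueError("emissions and marker map lengths differ")
    path = np.empty(len(markers), dtype=np.int8)
    total = 0.0
    for _, sl in markers.chrom_slices():
        p, lp = viterbi_chromosome(emissions[sl], markers.position[sl], params)
        path[sl] = p
        total += lp
    return path, total


def segment_calls(
    path: np.ndarray,
    markers: MarkerMap,
    emissions: np.ndarray,
    sample_id: str,
    caller: str = "wavecnv-hmm",
) -> list[CNVCall]:
    """Maximal runs of equal non-CN2 state, confined to one chromosome each.

    Confidence = sum over the run of (emission loglik at the called state
    minus emission loglik at CN2).
    """
    calls: list[CNVCall] = []
    for chrom, sl in markers.chrom_slices():
        sub = path[sl]
        pos = markers.position[sl]
        emis = emissions[sl]
        i = 0
        while i < len(sub):
            if sub[i] == 2:
                i += 1
                continue
            j = i
            while j + 1 < len(sub) and sub[j + 1] == sub[i]:
                j += 1
            state = int(sub[i])
            conf = float(np.sum(emis[i : j + 1, state] - emis[i : j + 1, 2]))
            calls.append(
                CNVCall(
                    sample_id=sample_id,
                    chrom=chrom,
                    start=int(pos[i]),
                    end=int(pos[j]),
                    cn=state,
                    n_snps=j - i + 1,
                    confidence=conf,
                    caller=caller,
                )
            )
            i = j + 1
    return calls


def call_cnvs(
    lrr: np.ndarray,
    markers: MarkerMap,
    sample_id: str,
    params: HMMParams | None = None,
    baf: np.ndarray | None = None,
    pfb: np.ndarray | None = None,
    caller: str = "wavecnv-hmm",
) -> list[CNVCall]:
    """Emission matrix -> Viterbi -> segmentation in one step."""
    params = params or HMMParams()
    emis = emission_matrix(lrr, baf, pfb, params)
    path, _ = viterbi_path(emis, markers, params)
    return segment_calls(path, markers, emis, sample_id, caller=caller)
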