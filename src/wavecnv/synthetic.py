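"""Synthetic SNP-array cohort generator with planted wave archetypes.

The generator emulates the structure the wave-correction method exploits:
a small number of genome-wide smooth baseline patterns ("archetypes")
shared by groups of samples, each sample expressing its archetype with a
private amplitude factor (Normal(1, amplitude_jitter)), plus marker-level
Gaussian LRR noise, genotype-driven BAF, and optionally injected CNV
segments with recorded ground truth.

Waves are sums of a few sinusoids with chromosome-scale periods (3-20 Mb),
rescaled per chromosome so the peak absolute value equals the configured
amplitude; archetypes are regenerated until all pairwise correlations stay
below 0.5 so the planted cluster structure is identifiable.  The default
genome is scaled down (22 chromosomes x 10 Mb x 500 markers) so the whole
pipeline runs in seconds; real-genome dimensions are configuration options.
Population B-allele frequencies are drawn once per cohort (not per sample)
so PFB recovery is testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .hmm_caller import LRR_MEAN_DEFAULT
from .signal_io import MarkerMap, SignalSample, normalize_chrom

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SimulatedCohort",
    "make_marker_map",
    "make_wave_archetypes",
    "simulate_sample",
    "simulate_cohort",
]

# LRR offset per copy-number state; CN2 sits at 0 by construction
STATE_MEANS = {0: LRR_MEAN_DEFAULT[0], 1: LRR_MEAN_DEFAULT[1], 2: 0.0,
               3: LRR_MEAN_DEFAULT[3], 4: LRR_MEAN_DEFAULT[4]}


@dataclass(frozen=True)
class SimulationConfig:
    n_chromosomes: int = 22
    chromosome_length: int = 10_000_000
    markers_per_chromosome: int = 500
    n_archetypes: int = 6
    wave_amplitude: float = 0.2
    amplitude_jitter: float = 0.1
    lrr_noise_sd: float = 0.15
    baf_noise_sd: float = 0.03
    harmonics: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_archetypes < 1:
            raise ValueError("n_archetypes must be >= 1")
        for name in ("n_chromosomes", "chromosome_length", "markers_per_chromosome",
                     "harmonics"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if min(self.wave_amplitude, self.lrr_noise_sd, self.baf_noise_sd) < 0:
            raise ValueError("amplitudes and noise SDs must be non-negative")


@dataclass(frozen=True)
class SyntheticTruth:
    sample_id: str
    archetype_id: int
    amplitude_factor: float
    cnvs: tuple[tuple[str, int, int, int], ...]  # (chrom, start, end, cn)


@dataclass
class SimulatedCohort:
    markers: MarkerMap
    samples: list[SignalSample]
    truths: list[SyntheticTruth]
    popfreq: np.ndarray  # cohort-fixed per-marker population B-allele frequency
    archetypes: np.ndarray  # (n_archetypes, n_markers)
    config: SimulationConfig


def make_marker_map(config: SimulationConfig, rng: np.random.Generator | None = None) -> MarkerMap:
    """Uniformly placed (without replacement), sorted markers per chromosome."""
    if config.markers_per_chromosome > config.chromosome_length:
        raise ValueError("more markers than base pairs")
    rng = rng or np.random.default_rng(config.seed)
    ids, chroms, positions = [], [], []
    for c in range(1, config.n_chromosomes + 1):
        pos = rng.choice(config.chromosome_length, size=config.markers_per_chromosome,
                         replace=False) + 1
        pos.sort()
        for j, p in enumerate(pos):
            ids.append(f"snp_{c}_{j}")
            chroms.append(str(c))
            positions.append(int(p))
    return MarkerMap(np.array(ids, dtype=object), np.array(chroms, dtype=object),
                     np.array(positions, dtype=np.int64))


def _one_archetype(markers: MarkerMap, config: SimulationConfig,
                   rng: np.random.Generator) -> np.ndarray:
    w = np.zeros(len(markers))
    for _, sl in markers.chrom_slices():
        pos = markers.position[sl].astype(float)
        chrom_w = np.zeros(len(pos))
        for _ in range(config.harmonics):
            period = rng.uniform(3e6, 20e6)
            phase = rng.uniform(0, 2 * np.pi)
            amp = rng.uniform(0.5, 1.0)
            chrom_w += amp * np.sin(2 * np.pi * pos / period + phase)
        peak = np.abs(chrom_w).max()
        if peak > 0:
            chrom_w *= config.wave_amplitude / peak
        w[sl] = chrom_w
    return w


def make_wave_archetypes(markers: MarkerMap, config: SimulationConfig,
                         rng: np.random.Generator | None = None,
                         max_attempts: int = 100) -> np.ndarray:
    """(n_archetypes, n_markers) wave values, pairwise correlation < 0.5."""
    rng = rng or np.random.default_rng(config.seed)
    arch = np.vstack([_one_archetype(markers, config, rng)
                      for _ in range(config.n_archetypes)])
    if config.n_archetypes == 1 or config.wave_amplitude == 0:
        return arch
    attempts = 0
    while True:
        corr = np.corrcoef(arch)
        np.fill_diagonal(corr, 0.0)
        bad = np.flatnonzero((np.abs(corr) >= 0.5).any(axis=1))
        if len(bad) == 0:
            return arch
        if attempts >= max_attempts:
            raise RuntimeError("could not decorrelate archetypes in 100 attempts")
        arch[bad[0]] = _one_archetype(markers, config, rng)
        attempts += 1


def _genotype_label(b_count: int, cn: int) -> str:
    if cn != 2:
        return "NC"
    return ("AA", "AB", "BB")[b_count]


def simulate_sample(
    markers: MarkerMap,
    archetype: np.ndarray,
    config: SimulationConfig,
    popfreq: np.ndarray,
    cnvs: Sequence[tuple[str, int, int, int]] = (),
    rng: np.random.Generator | None = None,
    sample_id: str = "S0000",
    archetype_id: int = 0,
) -> tuple[SignalSample, SyntheticTruth]:
    """One sample: lrr = state offset + amplitude * wave + noise; BAF from
    the genotype mixture of the local copy-number state."""
    rng = rng or np.random.default_rng(0)
    n = len(markers)
    state = np.full(n, 2, dtype=int)
    for chrom, start, end, cn in cnvs:
        if start < 1 or end > config.chromosome_length or start > end:
            raise ValueError(f"CNV interval {chrom}:{start}-{end} outside chromosome")
        sel = (markers.chrom == normalize_chrom(chrom)) & (markers.position >= start) & (markers.position <= end)
        state[sel] = cn

    s = 1.0 + config.amplitude_jitter * rng.standard_normal()
    mu = np.array([STATE_MEANS[c] for c in state])
    lrr = mu + s * archetype + config.lrr_noise_sd * rng.standard_normal(n)

    baf = np.empty(n)
    genotype = np.empty(n, dtype=object)
    b_counts = np.zeros(n, dtype=int)
    for cn in np.unique(state):
        sel = state == cn
        if cn == 0:
            baf[sel] = rng.uniform(0, 1, sel.sum())
            genotype[sel] = "NC"
            continue
        counts = rng.binomial(cn, popfreq[sel])
        b_counts[sel] = counts
        baf[sel] = counts / cn + config.baf_noise_sd * rng.standard_normal(sel.sum())
        genotype[sel] = [_genotype_label(b, cn) for b in counts]
    baf = np.clip(baf, 0.0, 1.0)

    sample = SignalSample(sample_id=sample_id, lrr=lrr, baf=baf, genotype=genotype)
    truth = SyntheticTruth(
        sample_id=sample_id,
        archetype_id=archetype_id,
        amplitude_factor=float(s),
        cnvs=tuple((str(c), int(st), int(en), int(cn)) for c, st, en, cn in cnvs),
    )
    return sample, truth


def simulate_cohort(
    config: SimulationConfig,
    per_archetype_n: int,
    cnv_spec: Mapping[int, Sequence[tuple[str, int, int, int]]] | None = None,
) -> SimulatedCohort:
    """A full cohort: per archetype, ``per_archetype_n`` samples, in archetype
    blocks; ``cnv_spec`` maps global sample index -> CNV intervals to inject.
    Fully reproducible from ``config.seed``."""
    cnv_spec = cnv_spec or {}
    ss = np.random.SeedSequence(config.seed)
    map_ss, arch_ss, pfb_ss, sample_ss = ss.spawn(4)
    markers = make_marker_map(config, np.random.default_rng(map_ss))
    archetypes = make_wave_archetypes(markers, config, np.random.default_rng(arch_ss))
    popfreq = np.random.default_rng(pfb_ss).uniform(0.05, 0.95, len(markers))

    samples: list[SignalSample] = []
    truths: list[SyntheticTruth] = []
    child_seeds = sample_ss.spawn(config.n_archetypes * per_archetype_n)
    idx = 0
    for a in range(config.n_archetypes):
        for _ in range(per_archetype_n):
            sample, truth = simulate_sample(
                markers,
                archetypes[a],
                config,
                popfreq,
                cnvs=cnv_spec.get(idx, ()),
                rng=np.random.default_rng(child_seeds[idx]),
                sample_id=f"S{idx:04d}",
                archetype_id=a,
            )
            samples.append(sample)
            truths.append(truth)
            idx += 1
    return SimulatedCohort(markers, samples, truths, popfreq, archetypes, config)
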