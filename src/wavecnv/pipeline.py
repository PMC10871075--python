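"""End-to-end screening pipeline: QC -> correct -> call -> post-process -> match.

The pipeline is a pure composition of the stage functions; running it is
equivalent to applying the stages by hand, and two runs with identical
configuration and inputs produce byte-identical reports.  Samples failing
QC are reported with status ``qc_failed`` and emit no calls.
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Sequence

from . import __version__
from .hmm_caller import HMMParams, call_cnvs
from .postprocess import (
    MERGE_GAP_DEFAULT,
    MIN_CONF_DEFAULT,
    MIN_FRACTION_DEFAULT,
    MIN_LENGTH_DEFAULT,
    MIN_SNPS_DEFAULT,
    ScreenResult,
    combine_callsets,
    filter_calls,
    match_disorders,
    merge_adjacent_calls,
)
from .qc_pfb import CALL_RATE_MIN_DEFAULT, LRR_SD_MAX_DEFAULT, sample_qc
from .signal_io import (
    DisorderRegion,
    load_reference_model,
    read_cnv_calls,
    read_disorder_db,
    read_pfb_table,
    read_signal_table,
)
from .wave_correction import KNN_K_DEFAULT, correct_sample

__all__ = ["PipelineConfig", "run_screen_pipeline", "screen_one_sample", "write_report"]

log = logging.getLogger("wavecnv")


@dataclass
class PipelineConfig:
    model_path: str
    signals: list[str]  # signal-table paths
    disorder_db_path: str
    out_dir: str
    pfb_path: str | None = None
    calls2_path: str | None = None  # external rawcnv set for two-caller union
    call_rate_min: float = CALL_RATE_MIN_DEFAULT
    lrr_sd_max: float = LRR_SD_MAX_DEFAULT
    merge_gap: int = MERGE_GAP_DEFAULT
    min_snps: int = MIN_SNPS_DEFAULT
    min_length: int = MIN_LENGTH_DEFAULT
    min_conf: float = MIN_CONF_DEFAULT
    min_fraction: float = MIN_FRACTION_DEFAULT
    knn_k: int = KNN_K_DEFAULT
    hmm: HMMParams = field(default_factory=HMMParams)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        raw = tomllib.loads(Path(path).read_text())
        hmm = HMMParams(**raw.pop("hmm", {}))
        sig = raw.pop("signals")
        if isinstance(sig, str):
            sig = sorted(str(p) for p in Path(sig).glob("*.txt"))
        return cls(signals=list(sig), hmm=hmm, **raw)


def screen_one_sample(
    sample,
    markers,
    model,
    db: Sequence[DisorderRegion],
    config: PipelineConfig,
    pfb=None,
    external_calls=None,
) -> tuple[list[ScreenResult], list]:
    """Screen one already-loaded sample; returns (results, filtered calls)."""
    qc = sample_qc(sample, markers, config.call_rate_min, config.lrr_sd_max)
    if not qc.passed:
        return (
            [ScreenResult(sample.sample_id, "*", (), 0.0, "qc_failed")],
            [],
        )
    corrected = correct_sample(sample, model, knn_k=config.knn_k)
    calls = call_cnvs(
        corrected.mlrr,
        model.markers,
        sample.sample_id,
        params=config.hmm,
        baf=corrected.baf,
        pfb=pfb,
    )
    calls = merge_adjacent_calls(calls, max_gap=config.merge_gap)
    if external_calls:
        ext = merge_adjacent_calls(
            [c for c in external_calls if c.sample_id == sample.sample_id],
            max_gap=config.merge_gap,
        )
        calls = combine_callsets(calls, ext)
    calls = filter_calls(calls, config.min_snps, config.min_length, config.min_conf)
    results = match_disorders(calls, db, config.min_fraction, sample_id=sample.sample_id)
    return results, calls


def write_report(results: Sequence[ScreenResult], stream: IO[str]) -> None:
    stream.write("sample_id\tdisorder\tstatus\tdetected_fraction\tn_matched_calls\n")
    for r in results:
        stream.write(
            f"{r.sample_id}\t{r.disorder}\t{r.status}\t"
            f"{r.detected_fraction:.6f}\t{len(r.matched_calls)}\n"
        )


def run_screen_pipeline(config: PipelineConfig) -> tuple[list[ScreenResult], dict]:
    """Run the full screen over every configured signal file.

    Writes ``report.tsv`` and ``manifest.json`` into the output directory and
    returns the per-sample results plus the manifest.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    model = load_reference_model(config.model_path)
    with open(config.disorder_db_path) as fh:
        db = read_disorder_db(fh)
    external = None
    if config.calls2_path:
        with open(config.calls2_path) as fh:
            external = read_cnv_calls(fh)

    all_results: list[ScreenResult] = []
    for path in config.signals:
        with open(path) as fh:
            markers, sample = read_signal_table(fh)
        if len(markers) != len(model.markers):
            raise ValueError(f"{path}: marker count differs from the model")
        pfb = None
        if config.pfb_path:
            with open(config.pfb_path) as fh:
                pfb = read_pfb_table(fh, markers)
        results, _ = screen_one_sample(
            sample, markers, model, db, config, pfb=pfb, external_calls=external
        )
        log.info("screened %s: %d result rows", sample.sample_id, len(results))
        all_results.extend(results)

    with open(out / "report.tsv", "w") as fh:
        write_report(all_results, fh)
    manifest = {
        "package_version": __version__,
        "model_version": model.version,
        "model_k": int(model.k),
        "seed": config.seed,
        "thresholds": {
            "call_rate_min": config.call_rate_min,
            "lrr_sd_max": config.lrr_sd_max,
            "merge_gap": config.merge_gap,
            "min_snps": config.min_snps,
            "min_length": config.min_length,
            "min_conf": config.min_conf,
            "min_fraction": config.min_fraction,
        },
        "n_samples": len(config.signals),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return all_results, manifest
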