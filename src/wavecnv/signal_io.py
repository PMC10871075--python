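"""Readers and writers for the on-disk formats used throughout the package.

All genomic coordinates are 1-based inclusive internally; BED output is the
only 0-based half-open surface.  Chromosome labels are normalized by stripping
a leading ``chr``; autosomes "1".."22" plus "X"/"Y" are accepted, but sex
chromosomes are excluded from wave features downstream.

Formats:

* signal table -- tab-delimited GenomeStudio/PennCNV-style export with columns
  ``Name``, ``Chr``, ``Position``, ``<sample>.Log R Ratio``,
  ``<sample>.B Allele Freq`` and optionally ``<sample>.GType``; one sample per
  file; missing values serialized as ``NaN``.
* PFB table -- ``Name``, ``Chr``, ``Position``, ``PFB``.
* rawcnv -- the one-call-per-line dialect popularized by PennCNV.
* disorder database -- TSV with ``name``, ``chrom``, ``start``, ``end``,
  ``direction`` and optional ``expected_cn``.
* reference model archive -- a directory with one JSON metadata document plus
  TSV matrices (see :func:`save_reference_model`).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "MarkerMap",
    "SignalSample",
    "CNVCall",
    "DisorderRegion",
    "read_signal_table",
    "write_signal_table",
    "read_pfb_table",
    "write_pfb_table",
    "read_cnv_calls",
    "write_cnv_calls",
    "read_disorder_db",
    "write_disorder_db",
    "write_calls_bed",
    "read_calls_bed",
]


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


_AUTOSOMES = tuple(str(i) for i in range(1, 23))
_CHROM_RANK = {c: i for i, c in enumerate(_AUTOSOMES + ("X", "Y"))}
_GENOTYPES = ("AA", "AB", "BB", "NC")


def normalize_chrom(label: str) -> str:
    """Strip a leading ``chr`` and validate against 1..22, X, Y."""
    c = str(label).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c.lower() in ("x", "y"):
        c = c.upper()
    if c not in _CHROM_RANK:
        raise FormatError(f"unrecognized chromosome label: {label!r}")
    return c


def chrom_sort_rank(chrom: str) -> int:
    return _CHROM_RANK[chrom]


def is_autosome(chrom: str) -> bool:
    return chrom in _AUTOSOMES


@dataclass
class MarkerMap:
    """Ordered marker coordinates; the spatial backbone of the pipeline.

    Markers are sorted ascending by (chromosome, position); marker ids are
    unique; positions are 1-based and >= 1.
    """

    marker_id: np.ndarray
    chrom: np.ndarray
    position: np.ndarray

    def __post_init__(self) -> None:
        self.marker_id = np.asarray(self.marker_id, dtype=object)
        self.chrom = np.asarray([normalize_chrom(c) for c in self.chrom], dtype=object)
        self.position = np.asarray(self.position, dtype=np.int64)
        if not (len(self.marker_id) == len(self.chrom) == len(self.position)):
            raise ValueError("marker map field lengths differ")
        if len(self.marker_id) != len(set(self.marker_id)):
            raise FormatError("duplicate marker_id in marker map")
        if len(self.position) and self.position.min() < 1:
            raise ValueError("positions must be >= 1")
        ranks = np.array([_CHROM_RANK[c] for c in self.chrom])
        order = np.lexsort((self.position, ranks))
        if not np.array_equal(order, np.arange(len(order))):
            raise ValueError("marker map must be sorted by (chrom, position)")

    def __len__(self) -> int:
        return len(self.marker_id)

    @property
    def autosome_mask(self) -> np.ndarray:
        return np.array([is_autosome(c) for c in self.chrom], dtype=bool)

    def chrom_slices(self) -> list[tuple[str, slice]]:
        """Contiguous (chromosome, slice) runs in map order."""
        out: list[tuple[str, slice]] = []
        if len(self) == 0:
            return out
        start = 0
        for i in range(1, len(self) + 1):
            if i == len(self) or self.chrom[i] != self.chrom[start]:
                out.append((self.chrom[start], slice(start, i)))
                start = i
        return out


@dataclass
class SignalSample:
    """Per-marker LRR/BAF (and optional genotype) for one sample."""

    sample_id: str
    lrr: np.ndarray
    baf: np.ndarray
    genotype: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lrr = np.asarray(self.lrr, dtype=float)
        self.baf = np.asarray(self.baf, dtype=float)
        if self.lrr.shape != self.baf.shape:
            raise ValueError("lrr and baf lengths differ")
        present = np.isfinite(self.baf)
        if present.any() and ((self.baf[present] < 0) | (self.baf[present] > 1)).any():
            raise ValueError("baf outside [0, 1]")
        if self.genotype is not None:
            self.genotype = np.asarray(self.genotype, dtype=object)
            if self.genotype.shape != self.lrr.shape:
                raise ValueError("genotype length differs from lrr")

    def __len__(self) -> int:
        return len(self.lrr)


@dataclass(frozen=True)
class CNVCall:
    """A contiguous non-diploid segment; the unit of all post-processing."""

    sample_id: str
    chrom: str
    start: int
    end: int
    cn: int
    n_snps: int
    confidence: float
    caller: str = "wavecnv-hmm"

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.cn == 2:
            raise ValueError("a CNV call cannot have cn=2")
        if self.cn not in (0, 1, 3, 4):
            raise ValueError(f"copy number {self.cn} outside {{0,1,3,4}}")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def direction(self) -> str:
        return "del" if self.cn < 2 else "dup"


@dataclass(frozen=True)
class DisorderRegion:
    """One row of the disorder-region database."""

    name: str
    chrom: str
    start: int
    end: int
    direction: str
    expected_cn: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.end < self.start:
            raise FormatError(f"{self.name}: end {self.end} < start {self.start}")
        if self.direction not in ("del", "dup"):
            raise FormatError(f"{self.name}: direction {self.direction!r} not del/dup")
        if self.expected_cn is not None:
            if self.direction == "del" and self.expected_cn >= 2:
                raise FormatError(f"{self.name}: expected_cn inconsistent with del")
            if self.direction == "dup" and self.expected_cn <= 2:
                raise FormatError(f"{self.name}: expected_cn inconsistent with dup")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# signal tables


def _find_column(columns: Sequence[str], wanted: tuple[str, ...]) -> str:
    lowered = {c.lower(): c for c in columns}
    for w in wanted:
        if w in lowered:
            return lowered[w]
    raise FormatError(f"missing required column (one of {wanted})")


def read_signal_table(stream: IO[str] | str) -> tuple[MarkerMap, SignalSample]:
    """Read a one-sample signal table; returns the map and the aligned signal.

    Rows are re-sorted by (chrom, position) with signal values following their
    marker; unparseable LRR/BAF values become missing (NaN).
    """
    df = pd.read_csv(stream, sep="\t", dtype=str)
    name_col = _find_column(df.columns, ("name", "snp name"))
    chr_col = _find_column(df.columns, ("chr", "chrom", "chromosome"))
    pos_col = _find_column(df.columns, ("position", "pos"))
    lrr_cols = [c for c in df.columns if c.lower().endswith("log r ratio")]
    baf_cols = [c for c in df.columns if c.lower().endswith("b allele freq")]
    if not lrr_cols or not baf_cols:
        raise FormatError("missing Log R Ratio / B Allele Freq column")
    lrr_col, baf_col = lrr_cols[0], baf_cols[0]
    sample_id = lrr_col[: -len(".Log R Ratio")] if "." in lrr_col else "sample"
    gt_cols = [c for c in df.columns if c.lower().endswith("gtype")]

    pos_num = pd.to_numeric(df[pos_col], errors="coerce")
    if pos_num.isna().any() or (pos_num % 1 != 0).any():
        raise FormatError("non-integer marker position")
    chroms = [normalize_chrom(c) for c in df[chr_col]]
    ranks = np.array([_CHROM_RANK[c] for c in chroms])
    order = np.lexsort((pos_num.to_numpy(), ranks))
    lrr = _parse_floats(df[lrr_col])[order]
    baf = _parse_floats(df[baf_col])[order]
    baf[~np.isnan(baf) & ((baf < 0) | (baf > 1))] = np.nan
    genotype = None
    if gt_cols:
        genotype = df[gt_cols[0]].fillna("NC").str.upper().to_numpy(dtype=object)[order]
        genotype = np.array([g if g in _GENOTYPES else "NC" for g in genotype], dtype=object)

    markers = MarkerMap(
        marker_id=df[name_col].to_numpy(dtype=object)[order],
        chrom=np.array(chroms, dtype=object)[order],
        position=pos_num.to_numpy(dtype=np.int64)[order],
    )
    sample = SignalSample(sample_id=sample_id, lrr=lrr, baf=baf, genotype=genotype)
    return markers, sample


def write_signal_table(markers: MarkerMap, sample: SignalSample, stream: IO[str]) -> None:
    if len(markers) != len(sample):
        raise ValueError("marker map and sample lengths differ")
    sid = sample.sample_id
    cols = ["Name", "Chr", "Position", f"{sid}.Log R Ratio", f"{sid}.B Allele Freq"]
    if sample.genotype is not None:
        cols.append(f"{sid}.GType")
    stream.write("\t".join(cols) + "\n")
    for i in range(len(markers)):
        row = [
            str(markers.marker_id[i]),
            markers.chrom[i],
            str(int(markers.position[i])),
            _fmt(sample.lrr[i]),
            _fmt(sample.baf[i]),
        ]
        if sample.genotype is not None:
            row.append(str(sample.genotype[i]))
        stream.write("\t".join(row) + "\n")


def _fmt(x: float) -> str:
    return "NaN" if not np.isfinite(x) else repr(float(x))


def _parse_floats(series: pd.Series) -> np.ndarray:
    """Exact (round-trip) float parsing; anything unparseable is missing."""
    out = np.full(len(series), np.nan)
    for i, v in enumerate(series):
        try:
            out[i] = float(v)
        except (TypeError, ValueError):
            pass
    return out


# ---------------------------------------------------------------------------
# PFB tables


def write_pfb_table(markers: MarkerMap, pfb: np.ndarray, stream: IO[str]) -> None:
    if len(markers) != len(pfb):
        raise ValueError("marker map and pfb lengths differ")
    stream.write("Name\tChr\tPosition\tPFB\n")
    for i in range(len(markers)):
        stream.write(
            f"{markers.marker_id[i]}\t{markers.chrom[i]}\t{int(markers.position[i])}\t{_fmt(pfb[i])}\n"
        )


def read_pfb_table(stream: IO[str] | str, markers: MarkerMap | None = None) -> np.ndarray:
    """Read a PFB table; if *markers* is given, align by marker_id to the map."""
    df = pd.read_csv(stream, sep="\t", dtype=str)
    name_col = _find_column(df.columns, ("name", "snp name"))
    pfb_col = _find_column(df.columns, ("pfb",))
    values = pd.to_numeric(df[pfb_col], errors="coerce").to_numpy(dtype=float)
    if markers is None:
        return values
    by_id = dict(zip(df[name_col], values))
    out = np.full(len(markers), 0.5)
    for i, mid in enumerate(markers.marker_id):
        if mid in by_id and np.isfinite(by_id[mid]):
            out[i] = by_id[mid]
    return np.clip(out, 0.01, 0.99)


# ---------------------------------------------------------------------------
# rawcnv call files

_REGION_RE = re.compile(r"^(?:chr)?([0-9XYxy]+):(\d+)-(\d+)$")


def read_cnv_calls(stream: IO[str] | str, sample_id: str | None = None) -> list[CNVCall]:
    """Parse a rawcnv-dialect call file.

    ``length`` fields may contain thousands separators (ignored); a missing
    ``conf`` field yields confidence 0.  A declared cn=2 is an invariant
    violation and raises.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    calls: list[CNVCall] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) < 5:
            raise FormatError(f"line {lineno}: too few fields")
        m = _REGION_RE.match(fields[0])
        if not m:
            raise FormatError(f"line {lineno}: malformed region {fields[0]!r}")
        chrom, start, end = m.group(1), int(m.group(2)), int(m.group(3))
        kv: dict[str, str] = {}
        positional: list[str] = []
        for f in fields[1:]:
            if "=" in f:
                key, _, val = f.partition("=")
                if "," in key:  # "state2,cn=1"
                    key = key.split(",")[-1]
                kv[key.lower()] = val
            else:
                positional.append(f)
        if "numsnp" not in kv or "cn" not in kv:
            raise FormatError(f"line {lineno}: missing numsnp= or cn= field")
        cn = int(kv["cn"])
        if cn == 2:
            raise FormatError(f"line {lineno}: cn=2 is not a CNV")
        sid = sample_id if sample_id is not None else (positional[0] if positional else "unknown")
        try:
            calls.append(
                CNVCall(
                    sample_id=sid,
                    chrom=chrom,
                    start=start,
                    end=end,
                    cn=cn,
                    n_snps=int(kv["numsnp"]),
                    confidence=float(kv.get("conf", 0.0)),
                    caller="import",
                )
            )
        except ValueError as exc:
            raise FormatError(f"line {lineno}: {exc}") from exc
    return calls


def write_cnv_calls(calls: Iterable[CNVCall], stream: IO[str]) -> None:
    for c in calls:
        state = {0: 1, 1: 2, 3: 5, 4: 6}[c.cn]  # conventional state numbering
        stream.write(
            f"chr{c.chrom}:{c.start}-{c.end} numsnp={c.n_snps} "
            f"length={c.length:,} state{state},cn={c.cn} {c.sample_id} "
            f"startsnp=. endsnp=. conf={c.confidence:g}\n"
        )


# ---------------------------------------------------------------------------
# disorder database


def read_disorder_db(stream: IO[str] | str) -> list[DisorderRegion]:
    df = pd.read_csv(stream, sep="\t", dtype=str)
    for col in ("name", "chrom", "start", "end", "direction"):
        if col not in [c.lower() for c in df.columns]:
            raise FormatError(f"disorder DB missing column {col!r}")
    df.columns = [c.lower() for c in df.columns]
    regions = []
    for _, row in df.iterrows():
        expected = None
        if "expected_cn" in df.columns and pd.notna(row.get("expected_cn")):
            expected = int(row["expected_cn"])
        regions.append(
            DisorderRegion(
                name=str(row["name"]),
                chrom=str(row["chrom"]),
                start=int(row["start"]),
                end=int(row["end"]),
                direction=str(row["direction"]),
                expected_cn=expected,
            )
        )
    return regions


def write_disorder_db(regions: Iterable[DisorderRegion], stream: IO[str]) -> None:
    stream.write("name\tchrom\tstart\tend\tdirection\texpected_cn\n")
    for r in regions:
        exp = "" if r.expected_cn is None else str(r.expected_cn)
        stream.write(f"{r.name}\t{r.chrom}\t{r.start}\t{r.end}\t{r.direction}\t{exp}\n")


# ---------------------------------------------------------------------------
# BED


def write_calls_bed(calls: Iterable[CNVCall], stream: IO[str]) -> None:
    """BED (0-based half-open): start-1, end; name cn=<cn>; score clipped to [0,1000]."""
    for c in calls:
        score = min(max(c.confidence, 0.0), 1000.0)
        stream.write(f"chr{c.chrom}\t{c.start - 1}\t{c.end}\tcn={c.cn}\t{score:g}\n")


def read_calls_bed(stream: IO[str] | str, sample_id: str = "bed") -> list[CNVCall]:
    """Inverse of :func:`write_calls_bed` for the interval content only."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    calls = []
    for line in stream:
        line = line.strip()
        if not line:
            continue
        chrom, start0, end, name, score = line.split("\t")[:5]
        cn = int(name.split("=")[1])
        calls.append(
            CNVCall(
                sample_id=sample_id,
                chrom=chrom,
                start=int(start0) + 1,
                end=int(end),
                cn=cn,
                n_snps=1,
                confidence=float(score),
                caller="bed",
            )
        )
    return calls


# ---------------------------------------------------------------------------
# reference model archive (JSON metadata + TSV matrices in one directory)


def save_reference_model(model, path) -> None:
    """Serialize a ReferenceModel to a directory archive.

    Layout: ``meta.json`` (k, bin size, seeds, version, cluster sizes),
    ``bins.tsv`` (scheme + informative mask), ``markers.tsv``,
    ``marker_stats.tsv`` (per-cluster mean/sd columns), ``centroids.tsv``,
    ``reference_features.tsv`` (per-sample label + features) and
    ``selection_curve.tsv``.
    """
    import json
    from pathlib import Path

    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    meta = {
        "version": model.version,
        "k": int(model.k),
        "bin_size": int(model.bin_scheme.bin_size),
        "sd_floor": float(model.sd_floor),
        "seed": int(model.seed),
        "cluster_sizes": [int(x) for x in model.cluster_sizes],
    }
    (p / "meta.json").write_text(json.dumps(meta, indent=1))

    scheme = model.bin_scheme
    mask = scheme.informative_mask
    bins = pd.DataFrame(
        {
            "chrom": scheme.chrom,
            "start": scheme.start,
            "end": scheme.end,
            "informative": (mask.astype(int) if mask is not None else 0),
        }
    )
    bins.to_csv(p / "bins.tsv", sep="\t", index=False)

    m = model.markers
    pd.DataFrame(
        {"marker_id": m.marker_id, "chrom": m.chrom, "position": m.position}
    ).to_csv(p / "markers.tsv", sep="\t", index=False)

    stats = {}
    for c in range(model.k):
        stats[f"mean_{c}"] = model.marker_mean[c]
        stats[f"sd_{c}"] = model.marker_sd[c]
    pd.DataFrame(stats).to_csv(p / "marker_stats.tsv", sep="\t", index=False,
                               float_format="%.17g")

    pd.DataFrame(model.centroids).to_csv(p / "centroids.tsv", sep="\t",
                                         index=False, float_format="%.17g")

    if model.reference_features is not None:
        feat = pd.DataFrame(model.reference_features)
        feat.insert(0, "label", model.reference_labels)
        feat.insert(0, "sample_id", model.reference_sample_ids)
        feat.to_csv(p / "reference_features.tsv", sep="\t", index=False,
                    float_format="%.17g")

    if model.selection_curve is not None:
        pd.DataFrame(
            {"k": model.selection_curve.k_values, "score": model.selection_curve.scores}
        ).to_csv(p / "selection_curve.tsv", sep="\t", index=False,
                 float_format="%.17g")


def load_reference_model(path):
    """Inverse of :func:`save_reference_model`."""
    import json
    from pathlib import Path

    from .wave_reference import BinScheme, KSelectionCurve, ReferenceModel

    p = Path(path)
    meta = json.loads((p / "meta.json").read_text())
    bins = pd.read_csv(p / "bins.tsv", sep="\t", dtype={"chrom": str})
    scheme = BinScheme(
        bin_size=int(meta["bin_size"]),
        chrom=bins["chrom"].to_numpy(dtype=object),
        start=bins["start"].to_numpy(np.int64),
        end=bins["end"].to_numpy(np.int64),
        informative_mask=bins["informative"].to_numpy(bool),
    )
    mdf = pd.read_csv(p / "markers.tsv", sep="\t", dtype={"chrom": str})
    markers = MarkerMap(
        marker_id=mdf["marker_id"].to_numpy(dtype=object),
        chrom=mdf["chrom"].to_numpy(dtype=object),
        position=mdf["position"].to_numpy(np.int64),
    )
    k = int(meta["k"])
    stats = pd.read_csv(p / "marker_stats.tsv", sep="\t")
    marker_mean = np.vstack([stats[f"mean_{c}"].to_numpy(float) for c in range(k)])
    marker_sd = np.vstack([stats[f"sd_{c}"].to_numpy(float) for c in range(k)])
    centroids = pd.read_csv(p / "centroids.tsv", sep="\t").to_numpy(float)

    features = labels = None
    sample_ids: list[str] = []
    fpath = p / "reference_features.tsv"
    if fpath.exists():
        feat = pd.read_csv(fpath, sep="\t")
        sample_ids = feat["sample_id"].astype(str).tolist()
        labels = feat["label"].to_numpy(np.int64)
        features = feat.drop(columns=["sample_id", "label"]).to_numpy(float)

    curve = None
    cpath = p / "selection_curve.tsv"
    if cpath.exists():
        cdf = pd.read_csv(cpath, sep="\t")
        curve = KSelectionCurve(cdf["k"].to_numpy(np.int64), cdf["score"].to_numpy(float))

    return ReferenceModel(
        k=k,
        bin_scheme=scheme,
        markers=markers,
        centroids=centroids,
        cluster_sizes=np.array(meta["cluster_sizes"], dtype=np.int64),
        marker_mean=marker_mean,
        marker_sd=marker_sd,
        sd_floor=float(meta["sd_floor"]),
        seed=int(meta["seed"]),
        version=str(meta["version"]),
        reference_features=features,
        reference_labels=labels,
        reference_sample_ids=sample_ids,
        selection_curve=curve,
    )
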