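"""Shared data model, file I/O, configuration and logging.

The package works on SNP-array "final report"-like tables: one row per
probe with a genotype call, a B-allele frequency (BAF) and a log R ratio
(LRR).  Coordinates are 1-based inclusive everywhere in memory; BED output
is 0-based half-open.  Chromosomes are labelled ``1``..``22`` and ``X``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("mosaicscan")
if not logger.handlers:  # stderr handler, level adjustable by callers/CLI
    _h = logging.StreamHandler()
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.WARNING)

#: canonical chromosome ordering used for sorting and per-chromosome scans
CHROMOSOMES: tuple[str, ...] = tuple(str(c) for c in range(1, 23)) + ("X",)
AUTOSOMES: tuple[str, ...] = tuple(str(c) for c in range(1, 23))

_CHROM_RANK = {c: i for i, c in enumerate(CHROMOSOMES)}

GENOTYPES = ("AA", "AB", "BB", "NC")

PROBE_COLUMNS = ["sample_id", "chrom", "pos", "genotype", "baf", "lrr"]


def chrom_rank(chrom: str) -> int:
    """Sort rank of a chromosome label (1..22 then X)."""
    try:
        return _CHROM_RANK[str(chrom)]
    except KeyError:
        raise ValueError(f"unknown chromosome label: {chrom!r}") from None


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Tunable parameters of the detection and filtering pipeline.

    Defaults mirror the published analysis: events are retained at >= 2 Mb
    after merging fragments within 1 Mb, segments need >= 75 heterozygous
    probes, and trio events must show a median upper-band BAF in
    [0.51, 0.70).
    """

    min_event_size_bp: int = 2_000_000
    merge_gap_bp: int = 1_000_000
    min_seg_probes: int = 75
    #: score threshold in null standard errors for the single-sample
    #: segmentation statistic (analogue of MAD's T, on a different statistic)
    seg_score_threshold: float = 6.0
    trio_median_baf_min: float = 0.51
    trio_median_baf_max: float = 0.70
    lrr_gain_min: float = 0.04
    lrr_loss_max: float = -0.04
    constitutive_bdev_min: float = 0.15
    constitutive_lrr_min: float = 0.20
    #: BAF interval used to pick heterozygous probes when genotype calls
    #: are unavailable; with calls present, AB probes define the het set
    het_band: tuple[float, float] = (0.15, 0.85)
    rng_seed: int = 0

    # trio detector (signed-deviation run test) parameters
    trio_score_threshold: float = 6.0
    trio_min_sites: int = 25
    sign_consistency_min: float = 0.90
    sign_window: int = 10

    # BAF peak-calling parameters (filtering cascade)
    kde_bandwidth: float = 0.02
    peak_symmetry_tol: float = 0.03
    peak_separation_min: float = 0.04
    roh_het_density_ratio: float = 0.10
    contamination_min_peaks: int = 3
    contamination_chrom_fraction: float = 0.80

    def __post_init__(self) -> None:
        if not (0.5 < self.trio_median_baf_min < self.trio_median_baf_max <= 1.0):
            raise ValueError(
                "require 0.5 < trio_median_baf_min < trio_median_baf_max <= 1"
            )
        if self.min_event_size_bp <= 0:
            raise ValueError("min_event_size_bp must be positive")
        if self.min_seg_probes < 2:
            raise ValueError("min_seg_probes must be >= 2")
        if self.seg_score_threshold <= 0 or self.trio_score_threshold <= 0:
            raise ValueError("score thresholds must be positive")
        lo, hi = self.het_band
        if not (0.0 <= lo < 0.5 < hi <= 1.0):
            raise ValueError("het_band must straddle 0.5 within [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from a flat-key YAML file (missing keys -> defaults)."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "het_band" in raw:
            raw["het_band"] = tuple(raw["het_band"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> Path:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        data["het_band"] = list(self.het_band)
        path = Path(path)
        path.write_text(yaml.safe_dump(data, sort_keys=False))
        return path

    def with_overrides(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbeRecord:
    """One SNP probe measurement for one sample."""

    chromosome: str
    position: int
    genotype: str
    baf: float
    lrr: float

    def __post_init__(self) -> None:
        chrom_rank(self.chromosome)
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}")
        if not (0.0 <= self.baf <= 1.0) or np.isnan(self.baf):
            raise ValueError(f"baf must lie in [0, 1], got {self.baf}")


@dataclass
class SampleArray:
    """Per-sample probe table plus QC flags.

    ``probes`` is a DataFrame with columns chrom, pos, genotype, baf, lrr,
    sorted by (chromosome, position).  ``qc`` carries at least
    ``het_baf_sd`` and ``contamination_flag``; a flagged sample is excluded
    from event calling but never silently dropped from reports.
    """

    sample_id: str
    role: str = "singleton"  # child | mother | father | singleton
    probes: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=PROBE_COLUMNS[1:]))
    qc: dict = field(default_factory=dict)
    sex: str = "F"

    def __post_init__(self) -> None:
        if self.role not in ("child", "mother", "father", "singleton"):
            raise ValueError(f"bad role {self.role!r}")

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    def het_mask(self, het_band: tuple[float, float] = (0.15, 0.85)) -> np.ndarray:
        """Boolean mask of heterozygous probes.

        Uses the AB genotype call when calls are present; falls back to the
        BAF het band for call-free data.  NC probes are never heterozygous.
        """
        gt = self.probes["genotype"].to_numpy()
        if (gt == "AB").any():
            return gt == "AB"
        baf = self.probes["baf"].to_numpy()
        return (gt != "NC") & (baf >= het_band[0]) & (baf <= het_band[1])

    def chromosomes(self) -> list[str]:
        seen = self.probes["chrom"].unique().tolist()
        return sorted(seen, key=chrom_rank)


@dataclass
class TrioArray:
    """Child, mother and father arrays sharing an identical probe map."""

    child: SampleArray
    mother: SampleArray
    father: SampleArray

    def __post_init__(self) -> None:
        c, m, f = self.child.probes, self.mother.probes, self.father.probes
        if not (len(c) == len(m) == len(f)):
            raise ValueError("trio members must share an identical probe map")
        for other, who in ((m, "mother"), (f, "father")):
            if not (
                c["chrom"].to_numpy() == other["chrom"].to_numpy()
            ).all() or not (c["pos"].to_numpy() == other["pos"].to_numpy()).all():
                raise ValueError(f"probe map of {who} differs from child")

    @property
    def members(self) -> tuple[SampleArray, SampleArray, SampleArray]:
        return self.child, self.mother, self.father


@dataclass
class CandidateSegment:
    """A genomic interval with BAF/LRR summaries emitted by a detector."""

    chromosome: str
    start: int
    end: int
    n_probes: int
    b_deviation: float
    mean_lrr: float
    median_upper_baf: float = float("nan")
    source: str = "single_sample"  # or "trio"
    event_type: str | None = None  # loss | gain | loh | unknown
    parental_excess: str | None = None  # trio detections: paternal | maternal

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError("coordinates are 1-based")

    @property
    def size_bp(self) -> int:
        return self.end - self.start + 1


@dataclass
class MosaicEvent:
    """A filtered, classified mosaic event."""

    sample_id: str
    chromosome: str
    start: int
    end: int
    n_probes: int
    b_deviation: float
    mean_lrr: float
    event_type: str  # loss | gain | loh | gw_upd
    clonality: float
    parental_origin: str = "unknown"  # maternal | paternal | unknown
    median_upper_baf: float = float("nan")
    source: str = "single_sample"
    filter_trail: list[tuple[str, bool]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.event_type not in ("loss", "gain", "loh", "gw_upd", "unknown"):
            raise ValueError(f"bad event_type {self.event_type!r}")
        if not (0.0 <= self.clonality <= 1.0) and not np.isnan(self.clonality):
            raise ValueError("clonality must lie in [0, 1]")

    @property
    def size_bp(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# probe-table I/O
# ---------------------------------------------------------------------------

def read_probe_table(path: str | Path) -> SampleArray:
    """Read a tab-separated final-report-like probe table into a SampleArray.

    Expects header columns ``sample_id chrom pos genotype baf lrr``.
    Probes with missing BAF are dropped; missing LRR is tolerated (NaN).
    Unsorted input is sorted with a logged notice; malformed rows raise a
    parse error naming the offending line.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", dtype={"chrom": str, "genotype": str, "sample_id": str}
        )
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"{path}: cannot parse probe table: {exc}") from exc
    missing = set(PROBE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")

    # per-row validation with line numbers (header is line 1)
    pos = pd.to_numeric(df["pos"], errors="coerce")
    baf = pd.to_numeric(df["baf"], errors="coerce")
    bad_pos = pos.isna() | (pos < 1)
    if bad_pos.any():
        line = int(np.flatnonzero(bad_pos.to_numpy())[0]) + 2
        raise ValueError(f"{path}, line {line}: bad position {df['pos'].iloc[line - 2]!r}")
    bad_gt = ~df["genotype"].isin(GENOTYPES)
    if bad_gt.any():
        line = int(np.flatnonzero(bad_gt.to_numpy())[0]) + 2
        raise ValueError(f"{path}, line {line}: bad genotype {df['genotype'].iloc[line - 2]!r}")
    bad_chrom = ~df["chrom"].isin(CHROMOSOMES)
    if bad_chrom.any():
        line = int(np.flatnonzero(bad_chrom.to_numpy())[0]) + 2
        raise ValueError(f"{path}, line {line}: bad chromosome {df['chrom'].iloc[line - 2]!r}")
    out_of_range = baf.notna() & ((baf < 0) | (baf > 1))
    if out_of_range.any():
        line = int(np.flatnonzero(out_of_range.to_numpy())[0]) + 2
        raise ValueError(f"{path}, line {line}: baf {df['baf'].iloc[line - 2]!r} outside [0, 1]")

    df = df.assign(pos=pos.astype(np.int64), baf=baf, lrr=pd.to_numeric(df["lrr"], errors="coerce"))
    n_drop = int(df["baf"].isna().sum())
    if n_drop:
        logger.info("%s: dropping %d probes with missing BAF", path, n_drop)
        df = df[df["baf"].notna()]

    ids = df["sample_id"].unique()
    if len(ids) != 1:
        raise ValueError(f"{path}: expected exactly one sample_id, found {list(ids)}")

    rank = df["chrom"].map(_CHROM_RANK).to_numpy()
    order = np.lexsort((df["pos"].to_numpy(), rank))
    if not (order == np.arange(len(df))).all():
        logger.info("%s: input not sorted by (chromosome, position); sorting", path)
        df = df.iloc[order]
    probes = df[["chrom", "pos", "genotype", "baf", "lrr"]].reset_index(drop=True)
    sample = SampleArray(sample_id=str(ids[0]), probes=probes)
    sample.qc = compute_sample_qc(sample)
    return sample


def write_probe_table(sample: SampleArray, path: str | Path) -> Path:
    path = Path(path)
    df = sample.probes.copy()
    df.insert(0, "sample_id", sample.sample_id)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def read_pedigree(path: str | Path) -> pd.DataFrame:
    """Read a trio manifest: TSV with family_id, child, mother, father, sex."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"family_id", "child", "mother", "father", "sex"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"{path}: pedigree missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# event I/O (BED-compatible, extended columns)
# ---------------------------------------------------------------------------

_EVENT_COLUMNS = [
    "chrom", "start", "end", "sample_id", "event_type", "b_deviation",
    "clonality", "parental_origin", "n_probes", "mean_lrr",
    "median_upper_baf", "source", "filter_trail",
]


def _trail_to_str(trail: Sequence[tuple[str, bool]]) -> str:
    return ";".join(f"{name}:{int(ok)}" for name, ok in trail)


def _trail_from_str(s: str) -> list[tuple[str, bool]]:
    if not s or s != s:  # empty or NaN
        return []
    out = []
    for part in str(s).split(";"):
        name, _, ok = part.rpartition(":")
        out.append((name, bool(int(ok))))
    return out


def write_events(events: Iterable[MosaicEvent], path: str | Path) -> Path:
    """Write events as a BED-compatible TSV (0-based half-open intervals).

    Extended columns carry type, B-deviation, clonality, origin and the
    filter trail.  Overlapping identical events are written as-is.  The file
    round-trips losslessly through :func:`read_events`.
    """
    path = Path(path)
    rows = []
    for ev in events:
        rows.append({
            "chrom": ev.chromosome,
            "start": ev.start - 1,  # 1-based inclusive -> 0-based half-open
            "end": ev.end,
            "sample_id": ev.sample_id,
            "event_type": ev.event_type,
            "b_deviation": repr(float(ev.b_deviation)),
            "clonality": repr(float(ev.clonality)),
            "parental_origin": ev.parental_origin,
            "n_probes": ev.n_probes,
            "mean_lrr": repr(float(ev.mean_lrr)),
            "median_upper_baf": repr(float(ev.median_upper_baf)),
            "source": ev.source,
            "filter_trail": _trail_to_str(ev.filter_trail),
        })
    pd.DataFrame(rows, columns=_EVENT_COLUMNS).to_csv(path, sep="\t", index=False)
    return path


def read_events(path: str | Path) -> list[MosaicEvent]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "filter_trail": str})
    events = []
    for _, r in df.iterrows():
        events.append(MosaicEvent(
            sample_id=str(r["sample_id"]),
            chromosome=str(r["chrom"]),
            start=int(r["start"]) + 1,
            end=int(r["end"]),
            n_probes=int(r["n_probes"]),
            b_deviation=float(r["b_deviation"]),
            mean_lrr=float(r["mean_lrr"]),
            event_type=str(r["event_type"]),
            clonality=float(r["clonality"]),
            parental_origin=str(r["parental_origin"]),
            median_upper_baf=float(r["median_upper_baf"]),
            source=str(r["source"]),
            filter_trail=_trail_from_str(r.get("filter_trail", "")),
        ))
    return events


_CAND_COLUMNS = [
    "chrom", "start", "end", "n_probes", "b_deviation", "mean_lrr",
    "median_upper_baf", "source", "event_type", "parental_excess",
]


def write_candidates(segments: Iterable[CandidateSegment], path: str | Path) -> Path:
    """Write candidate segments (pre-filtering) as a BED-compatible TSV."""
    path = Path(path)
    rows = [{
        "chrom": s.chromosome, "start": s.start - 1, "end": s.end,
        "n_probes": s.n_probes, "b_deviation": repr(float(s.b_deviation)),
        "mean_lrr": repr(float(s.mean_lrr)),
        "median_upper_baf": repr(float(s.median_upper_baf)),
        "source": s.source, "event_type": s.event_type or "",
        "parental_excess": s.parental_excess or "",
    } for s in segments]
    pd.DataFrame(rows, columns=_CAND_COLUMNS).to_csv(path, sep="\t", index=False)
    return path


def read_candidates(path: str | Path) -> list[CandidateSegment]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = []
    for _, r in df.iterrows():
        out.append(CandidateSegment(
            chromosome=str(r["chrom"]), start=int(r["start"]) + 1, end=int(r["end"]),
            n_probes=int(r["n_probes"]), b_deviation=float(r["b_deviation"]),
            mean_lrr=float(r["mean_lrr"]), median_upper_baf=float(r["median_upper_baf"]),
            source=str(r["source"]),
            event_type=str(r["event_type"]) if pd.notna(r["event_type"]) and r["event_type"] else None,
            parental_excess=str(r["parental_excess"]) if pd.notna(r["parental_excess"]) and r["parental_excess"] else None,
        ))
    return out


# ---------------------------------------------------------------------------
# sample QC
# ---------------------------------------------------------------------------

def compute_sample_qc(sample: SampleArray, config: PipelineConfig | None = None) -> dict:
    """Standard deviation of heterozygous BAFs plus a contamination flag.

    A large ``het_baf_sd`` never excludes a sample on its own — real
    (especially genome-wide) mosaicism inflates it.  Samples with fewer
    than 100 AB probes get ``insufficient=True`` but are still processed.
    Contamination flagging (multi-band het BAF skew on most autosomes)
    delegates to :func:`mosaicscan.filter_single.flag_contamination`.
    """
    config = config or PipelineConfig()
    ab = sample.probes.loc[sample.probes["genotype"] == "AB", "baf"].to_numpy()
    qc: dict = {"n_het_probes": int(ab.size)}
    if ab.size < 100:
        qc["het_baf_sd"] = float(np.std(ab)) if ab.size else float("nan")
        qc["insufficient"] = True
        qc["contamination_flag"] = False
        return qc
    qc["het_baf_sd"] = float(np.std(ab))
    qc["insufficient"] = False
    from .filter_single import flag_contamination  # local import avoids a cycle

    qc["contamination_flag"] = bool(flag_contamination(sample, config))
    return qc
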