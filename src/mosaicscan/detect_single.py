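"""Single-sample detection of candidate mosaic segments.

A mosaic event skews the BAF of heterozygous probes away from 0.5 into two
symmetric bands, so the detector scans the folded deviation series
|BAF - 0.5| over heterozygous probes with a multi-scale interval scan
statistic, and emits segments whose mean deviation exceeds the sample's
genome-wide null by ``seg_score_threshold`` standard errors over at least
``min_seg_probes`` het probes.  The null BAF scale is estimated
robustly (median absolute deviation of the signed deviations genome-wide),
so the events themselves do not inflate it.  Mean LRR over all probes in
the interval then classifies each segment as loss, gain or copy-neutral
LOH.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._segmentation import robust_sigma, scan_intervals
from .core_io import CandidateSegment, PipelineConfig, SampleArray, logger

_FOLD_MEAN = math.sqrt(2 / math.pi)  # E|N(0,1)|
_FOLD_SD = math.sqrt(1 - 2 / math.pi)  # SD|N(0,1)|


@dataclass
class SegmentationParams:
    """Knobs of the changepoint scan (analogues of MAD's MinSegLen / T)."""

    min_seg_probes: int = 75
    seg_score_threshold: float = 6.0
    het_band: tuple[float, float] = (0.15, 0.85)

    @classmethod
    def from_config(cls, config: PipelineConfig) -> "SegmentationParams":
        return cls(config.min_seg_probes, config.seg_score_threshold, config.het_band)


def baf_deviation_signal(
    sample: SampleArray, het_band: tuple[float, float] = (0.15, 0.85)
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-probe |BAF - 0.5| over heterozygous probes, plus a density track.

    Returns ``(signal, density)``: ``signal`` has one row per het probe
    (chrom, pos, dev); ``density`` one row per chromosome with the het and
    total probe counts (non-het probes contribute to density only).
    """
    het = sample.het_mask(het_band)
    probes = sample.probes
    signal = pd.DataFrame({
        "chrom": probes["chrom"].to_numpy()[het],
        "pos": probes["pos"].to_numpy()[het],
        "dev": np.abs(probes["baf"].to_numpy()[het] - 0.5),
    })
    density = (
        pd.DataFrame({"chrom": probes["chrom"], "het": het})
        .groupby("chrom", sort=False)
        .agg(n_het=("het", "sum"), n_total=("het", "size"))
        .reset_index()
    )
    return signal, density


def null_baf_sigma(signal: pd.DataFrame) -> float:
    """Robust per-sample BAF noise scale from the genome-wide het signal.

    The folded deviations are reflected about zero so the MAD-based scale
    estimate sees the symmetric null; a minority of event probes barely
    moves the median.
    """
    return robust_sigma(_signed(signal))


def _signed(signal: pd.DataFrame) -> np.ndarray:
    dev = signal["dev"].to_numpy()
    return np.concatenate([dev, -dev])


def _interval_summaries(
    sample: SampleArray, chromosome: str, start: int, end: int,
    het_band: tuple[float, float],
) -> tuple[float, float, float, int]:
    """(mean_lrr, lrr_missing_frac, median_upper_baf, n_all_probes)."""
    p = sample.probes
    m = (p["chrom"] == chromosome) & (p["pos"] >= start) & (p["pos"] <= end)
    lrr = p.loc[m, "lrr"].to_numpy()
    n_all = int(m.sum())
    missing = float(np.isnan(lrr).mean()) if n_all else 1.0
    mean_lrr = float(np.nanmean(lrr)) if n_all and missing < 1.0 else float("nan")
    het = sample.het_mask(het_band) & m.to_numpy()
    baf = p["baf"].to_numpy()[het]
    upper = baf[baf > 0.5]
    med_upper = float(np.median(upper)) if upper.size else float("nan")
    return mean_lrr, missing, med_upper, n_all


def segment_baf(
    positions: np.ndarray,
    dev: np.ndarray,
    sigma_baf: float,
    params: SegmentationParams,
    chromosome: str,
) -> list[tuple[int, int, int, int, float]]:
    """Changepoint segmentation of one chromosome's deviation series.

    Returns emitted segments as ``(start_bp, end_bp, i, j, mean_dev)``
    tuples with het-probe index range [i, j).  A segment is emitted when
    its mean deviation exceeds the folded-normal null mean by
    ``seg_score_threshold`` null standard errors and spans at least
    ``min_seg_probes`` het probes.
    """
    n = dev.size
    if n < params.min_seg_probes:
        logger.info("chromosome %s: only %d het probes; no calls", chromosome, n)
        return []
    null_mean = sigma_baf * _FOLD_MEAN
    null_sd = sigma_baf * _FOLD_SD
    hits = scan_intervals(
        dev - null_mean, sigma=null_sd, threshold=params.seg_score_threshold,
        min_size=params.min_seg_probes, two_sided=False,
    )
    out = []
    for i, j, _score in hits:
        mean_dev = float(dev[i:j].mean())
        # breakpoint between het probes maps to the midpoint of their positions
        start = int(positions[i]) if i == 0 else (int(positions[i - 1]) + int(positions[i])) // 2
        end = int(positions[j - 1]) if j == n else (int(positions[j - 1]) + int(positions[j])) // 2
        out.append((start, end, i, j, mean_dev))
    return out


def classify_segment(segment: CandidateSegment, config: PipelineConfig | None = None) -> str:
    """Loss / gain / LOH call from the segment's mean LRR."""
    config = config or PipelineConfig()
    if np.isnan(segment.mean_lrr):
        return "unknown"
    if segment.mean_lrr <= config.lrr_loss_max:
        return "loss"
    if segment.mean_lrr >= config.lrr_gain_min:
        return "gain"
    return "loh"


def candidate_from_interval(
    sample: SampleArray,
    chromosome: str,
    start: int,
    end: int,
    config: PipelineConfig | None = None,
    source: str = "single_sample",
) -> CandidateSegment:
    """Summarize an arbitrary interval of a sample as a candidate segment.

    Useful for re-scoring externally supplied intervals (and for building
    synthetic raw-candidate mixes): B deviation over het probes, mean LRR
    over all probes, median upper-band BAF, and the LRR type call.
    """
    config = config or PipelineConfig()
    p = sample.probes
    m = (p["chrom"] == chromosome) & (p["pos"] >= start) & (p["pos"] <= end)
    het = sample.het_mask(config.het_band) & m.to_numpy()
    dev = np.abs(p["baf"].to_numpy()[het] - 0.5)
    mean_lrr, missing, med_upper, _ = _interval_summaries(
        sample, chromosome, start, end, config.het_band
    )
    seg = CandidateSegment(
        chromosome=chromosome, start=start, end=end, n_probes=int(het.sum()),
        b_deviation=float(dev.mean()) if dev.size else 0.0,
        mean_lrr=mean_lrr, median_upper_baf=med_upper, source=source,
    )
    seg.event_type = "unknown" if missing > 0.5 else classify_segment(seg, config)
    return seg


def detect_sample(
    sample: SampleArray, config: PipelineConfig | None = None
) -> list[CandidateSegment]:
    """Run the deviation scan over every chromosome of one sample.

    Chromosome X is skipped for males (single-copy BAF is uninterpretable).
    Returns classified candidate segments, pre-filtering; segments never
    overlap within a chromosome (the changepoint partition is disjoint).
    """
    config = config or PipelineConfig()
    params = SegmentationParams.from_config(config)
    signal, _ = baf_deviation_signal(sample, config.het_band)
    sigma = robust_sigma(_signed(signal))
    if not np.isfinite(sigma) or sigma <= 0:
        logger.warning("%s: degenerate BAF noise estimate; no calls", sample.sample_id)
        return []
    segments: list[CandidateSegment] = []
    for chrom in sample.chromosomes():
        if chrom == "X" and sample.sex == "M":
            continue
        sig_c = signal[signal["chrom"] == chrom]
        raw = segment_baf(
            sig_c["pos"].to_numpy(), sig_c["dev"].to_numpy(), sigma, params, chrom
        )
        for start, end, i, j, mean_dev in raw:
            mean_lrr, missing, med_upper, _ = _interval_summaries(
                sample, chrom, start, end, config.het_band
            )
            seg = CandidateSegment(
                chromosome=chrom, start=start, end=end, n_probes=j - i,
                b_deviation=mean_dev, mean_lrr=mean_lrr,
                median_upper_baf=med_upper, source="single_sample",
            )
            if missing > 0.5:
                seg.event_type = "unknown"  # flagged for manual review
                logger.warning(
                    "%s %s:%d-%d: %.0f%% of LRR missing; type unknown",
                    sample.sample_id, chrom, start, end, 100 * missing,
                )
            else:
                seg.event_type = classify_segment(seg, config)
            segments.append(seg)
    return segments
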