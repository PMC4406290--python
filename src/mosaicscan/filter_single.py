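"""Filtering cascade turning raw candidate segments into curatable events.

Raw BAF-deviation segmentation over-calls heavily; the dominant artefact
classes are hypersegmented fragments of one real event, inherited runs of
homozygosity (ROH) mistaken for mosaic LOH, skewed unimodal het-BAF bands
(calibration artefacts), constitutive duplications whose extreme B
deviation mimics very-high-clonality mosaicism, and contaminated samples
with multi-band BAF skew on every chromosome.  The cascade applies, in
order: fragment merging (within ``merge_gap_bp``, same type), the >= 2 Mb
size rule, BAF peak-class calling (bimodal mosaic vs unimodal skew vs
ROH), and the constitutive-duplication exclusion; contamination is a
sample-level veto.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._segmentation import kde_peaks
from .core_io import AUTOSOMES, CandidateSegment, PipelineConfig, SampleArray

DROP_REASONS = (
    "merged_fragment", "too_small", "roh", "unimodal_skew",
    "constitutive_dup", "contaminated_sample",
)


@dataclass
class FilterOutcome:
    segment: CandidateSegment
    verdict: str  # retain | drop
    reason: str | None = None

    def __post_init__(self) -> None:
        if self.verdict not in ("retain", "drop"):
            raise ValueError(f"bad verdict {self.verdict!r}")
        if self.verdict == "drop" and self.reason not in DROP_REASONS:
            raise ValueError(f"bad drop reason {self.reason!r}")


# ---------------------------------------------------------------------------
# individual filters
# ---------------------------------------------------------------------------

def _merge_with_provenance(
    segments: list[CandidateSegment], merge_gap_bp: int
) -> tuple[list[CandidateSegment], list[list[CandidateSegment]]]:
    """Merge same-chromosome, same-type segments separated by <= merge_gap_bp.

    Returns the merged list plus, aligned with it, the fragment groups each
    merged segment came from.  Merged B deviation and mean LRR are
    probe-count-weighted means of the fragments.
    """
    order = sorted(
        range(len(segments)),
        key=lambda i: (segments[i].chromosome, segments[i].start, segments[i].end),
    )
    merged: list[CandidateSegment] = []
    groups: list[list[CandidateSegment]] = []
    for idx in order:
        seg = segments[idx]
        if merged:
            prev = merged[-1]
            if (
                prev.chromosome == seg.chromosome
                and prev.event_type == seg.event_type
                and seg.start - prev.end <= merge_gap_bp
            ):
                n = prev.n_probes + seg.n_probes
                w_prev, w_seg = prev.n_probes / n, seg.n_probes / n
                med_vals = [
                    (m, w) for m, w in (
                        (prev.median_upper_baf, w_prev), (seg.median_upper_baf, w_seg)
                    ) if np.isfinite(m)
                ]
                merged[-1] = CandidateSegment(
                    chromosome=prev.chromosome,
                    start=prev.start,
                    end=max(prev.end, seg.end),
                    n_probes=n,
                    b_deviation=w_prev * prev.b_deviation + w_seg * seg.b_deviation,
                    mean_lrr=w_prev * prev.mean_lrr + w_seg * seg.mean_lrr,
                    median_upper_baf=(
                        sum(m * w for m, w in med_vals) / sum(w for _, w in med_vals)
                        if med_vals else float("nan")
                    ),
                    source=prev.source,
                    event_type=prev.event_type,
                    parental_excess=prev.parental_excess,
                )
                groups[-1].append(seg)
                continue
        merged.append(seg)
        groups.append([seg])
    return merged, groups


def merge_segments(
    segments: list[CandidateSegment], merge_gap_bp: int = 1_000_000
) -> list[CandidateSegment]:
    """Gap-bounded merging of hypersegmented fragments (idempotent)."""
    merged, _ = _merge_with_provenance(segments, merge_gap_bp)
    return merged


def size_filter(
    segments: list[CandidateSegment], min_event_size_bp: int = 2_000_000
) -> list[FilterOutcome]:
    """Retain segments of at least ``min_event_size_bp`` (inclusive)."""
    return [
        FilterOutcome(s, "retain") if s.size_bp >= min_event_size_bp
        else FilterOutcome(s, "drop", "too_small")
        for s in segments
    ]


def peak_call_baf(
    baf_values: np.ndarray,
    config: PipelineConfig | None = None,
    het_density: float | None = None,
    genome_het_density: float | None = None,
) -> str:
    """Classify a segment's het BAF distribution.

    ``roh`` when the het-probe density in the segment falls below
    ``roh_het_density_ratio`` of the sample's genome-wide het density;
    otherwise kernel-density peaks on [0, 1] decide: exactly two modes
    placed symmetrically about 0.5 (midpoint within ``peak_symmetry_tol``,
    separation >= ``peak_separation_min``) is a bimodal mosaic; anything
    else is a skewed unimodal artefact (the conservative drop for segments
    with too few values at normal het density).
    """
    config = config or PipelineConfig()
    if (
        het_density is not None and genome_het_density is not None
        and genome_het_density > 0
        and het_density < config.roh_het_density_ratio * genome_het_density
    ):
        return "roh"
    baf_values = np.asarray(baf_values, dtype=float)
    if baf_values.size < 20:
        return "unimodal_skew"
    peaks = kde_peaks(baf_values, bandwidth=config.kde_bandwidth)
    if len(peaks) == 2:
        mid = (peaks[0] + peaks[1]) / 2
        sep = abs(peaks[1] - peaks[0])
        if abs(mid - 0.5) <= config.peak_symmetry_tol and sep >= config.peak_separation_min:
            return "bimodal_mosaic"
    return "unimodal_skew"


def flag_constitutive_duplication(
    segment: CandidateSegment, config: PipelineConfig | None = None
) -> bool:
    """True when a gain looks constitutive rather than mosaic.

    A three-copy duplication present in all cells puts het bands at 1/3 and
    2/3 (B deviation ~1/6) with a full-amplitude LRR shift; gains with
    ``b_deviation >= constitutive_bdev_min`` and
    ``mean_lrr >= constitutive_lrr_min`` are excluded.  Mosaic duplications
    of very high clonality are inevitably also caught — a documented
    trade-off of the exclusion.
    """
    config = config or PipelineConfig()
    if segment.event_type != "gain":
        return False
    return (
        segment.b_deviation >= config.constitutive_bdev_min
        and np.isfinite(segment.mean_lrr)
        and segment.mean_lrr >= config.constitutive_lrr_min
    )


def flag_contamination(
    sample: SampleArray, config: PipelineConfig | None = None
) -> bool:
    """Multi-band het BAF skew on nearly all autosomes flags contamination.

    DNA from a second individual splits every BAF cluster into dosage
    mixtures, producing >= 3 kernel-density modes inside the het band on
    every chromosome; a single large mosaic event skews only its own
    chromosome and is not flagged.
    """
    config = config or PipelineConfig()
    lo, hi = config.het_band
    p = sample.probes
    autosomes = [c for c in sample.chromosomes() if c in AUTOSOMES]
    if not autosomes:
        return False
    n_multi = 0
    for chrom in autosomes:
        m = (p["chrom"] == chrom) & (p["genotype"] != "NC")
        baf = p.loc[m, "baf"].to_numpy()
        band = baf[(baf >= lo) & (baf <= hi)]
        if band.size < 30:
            continue
        peaks = kde_peaks(band, bandwidth=config.kde_bandwidth, lo=lo, hi=hi)
        if len(peaks) >= config.contamination_min_peaks:
            n_multi += 1
    return n_multi >= config.contamination_chrom_fraction * len(autosomes)


# ---------------------------------------------------------------------------
# cascade
# ---------------------------------------------------------------------------

def _segment_het_values(
    sample: SampleArray, seg: CandidateSegment, config: PipelineConfig
) -> tuple[np.ndarray, float]:
    p = sample.probes
    m = (p["chrom"] == seg.chromosome) & (p["pos"] >= seg.start) & (p["pos"] <= seg.end)
    het = sample.het_mask(config.het_band) & m.to_numpy()
    n_total = int(m.sum())
    density = het.sum() / n_total if n_total else 0.0
    return p["baf"].to_numpy()[het], density


def run_filter_cascade(
    segments: list[CandidateSegment],
    sample: SampleArray,
    config: PipelineConfig | None = None,
) -> tuple[list[CandidateSegment], list[FilterOutcome]]:
    """Apply the full cascade: merge -> size -> peak class -> constitutive.

    Contamination is checked first at sample level and vetoes every
    segment.  Every input segment appears in exactly one outcome; the
    survivors carry a ``filter_trail`` attribute listing each filter they
    passed.  Re-running the cascade on its own survivors changes nothing.
    """
    config = config or PipelineConfig()
    outcomes: list[FilterOutcome] = []

    contaminated = sample.qc.get("contamination_flag")
    if contaminated is None:
        contaminated = flag_contamination(sample, config)
    if contaminated:
        return [], [FilterOutcome(s, "drop", "contaminated_sample") for s in segments]

    merged, groups = _merge_with_provenance(segments, config.merge_gap_bp)
    for grp in groups:
        for frag in grp[1:]:
            outcomes.append(FilterOutcome(frag, "drop", "merged_fragment"))

    het = sample.het_mask(config.het_band)
    genome_density = het.mean() if len(het) else 0.0

    survivors: list[CandidateSegment] = []
    for seg, grp in zip(merged, groups):
        trail: list[tuple[str, bool]] = [("merge", True)]
        if seg.size_bp < config.min_event_size_bp:
            outcomes.append(FilterOutcome(seg if len(grp) == 1 else grp[0], "drop", "too_small"))
            continue
        trail.append(("size", True))
        values, density = _segment_het_values(sample, seg, config)
        klass = peak_call_baf(values, config, density, genome_density)
        if klass != "bimodal_mosaic":
            reason = "roh" if klass == "roh" else "unimodal_skew"
            outcomes.append(FilterOutcome(seg if len(grp) == 1 else grp[0], "drop", reason))
            continue
        trail.append(("peak_call", True))
        if flag_constitutive_duplication(seg, config):
            outcomes.append(FilterOutcome(seg if len(grp) == 1 else grp[0], "drop", "constitutive_dup"))
            continue
        trail.append(("constitutive_dup", True))
        seg.filter_trail = trail  # type: ignore[attr-defined]
        survivors.append(seg)
        outcomes.append(FilterOutcome(seg if len(grp) == 1 else grp[0], "retain"))
    return survivors, outcomes
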