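"""Trio-phased detection of low-clonality mosaic segments in the child.

Parental genotypes orient the child's BAF deviations: at sites where the
deviation direction is determined by which parent contributed which
allele, deviations caused by a real haplotype-level event all point the
same way (toward the haplotype in excess), whereas noise is symmetric.
Averaging the *signed* deviation therefore accumulates signal linearly in
the B deviation d, while the single-sample folded statistic grows only
like d^2/sigma for d below the noise floor — this is where trio detection
gains sensitivity.  A run of consistently signed deviation yields both the
event call and its parental attribution.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._segmentation import robust_sigma, scan_intervals
from .core_io import CandidateSegment, PipelineConfig, TrioArray, logger
from .detect_single import _interval_summaries, classify_segment

CONFIG_CLASSES = (
    "father_het_mother_hom", "mother_het_father_hom", "obligate_het",
    "both_hom_same", "both_het", "mendelian_inconsistent",
)

_HOM = ("AA", "BB")


def phase_informative_sites(trio: TrioArray) -> pd.DataFrame:
    """Classify every probe by its configuration of parental genotypes.

    Returns a DataFrame with columns chrom, pos, config_class, child_baf,
    child_genotype, signed_dev and hom_lift.  ``signed_dev`` is the child
    BAF deviation oriented so that positive means excess of the PATERNAL
    allele; it is defined only where the orientation is determinate (child
    heterozygous with at least one homozygous parent, or obligate-het
    sites).  ``hom_lift`` is min(BAF, 1 - BAF) at homozygous child probes
    (how far a homozygous cluster is pulled off 0/1 — the signature of a
    second cell line contributing the missing allele).  Mendelian
    inconsistencies are classified as such and excluded from the signal
    but remain countable.
    """
    c, m, f = trio.child.probes, trio.mother.probes, trio.father.probes
    gc = c["genotype"].to_numpy()
    gm = m["genotype"].to_numpy()
    gf = f["genotype"].to_numpy()
    baf = c["baf"].to_numpy()
    n = len(c)

    klass = np.full(n, "both_het", dtype=object)
    f_het = gf == "AB"
    m_het = gm == "AB"
    f_hom = np.isin(gf, _HOM)
    m_hom = np.isin(gm, _HOM)
    klass[f_het & m_hom] = "father_het_mother_hom"
    klass[m_het & f_hom] = "mother_het_father_hom"
    klass[f_hom & m_hom & (gf == gm)] = "both_hom_same"
    klass[f_hom & m_hom & (gf != gm)] = "obligate_het"
    nc = (gc == "NC") | (gf == "NC") | (gm == "NC")

    # Mendelian check: child alleles must be producible from the parents
    def _alleles(g):
        return {"AA": (0, 0), "AB": (0, 1), "BB": (1, 1)}.get(g)

    viol = np.zeros(n, dtype=bool)
    dose_c = np.select([gc == "AA", gc == "AB", gc == "BB"], [0, 1, 2], default=-1)
    min_f = np.select([gf == "AA", gf == "AB", gf == "BB"], [0, 0, 1], default=0)
    max_f = np.select([gf == "AA", gf == "AB", gf == "BB"], [0, 1, 1], default=1)
    min_m = np.select([gm == "AA", gm == "AB", gm == "BB"], [0, 0, 1], default=0)
    max_m = np.select([gm == "AA", gm == "AB", gm == "BB"], [0, 1, 1], default=1)
    ok = (dose_c >= min_f + min_m) & (dose_c <= max_f + max_m) & (dose_c >= 0)
    viol[~ok & ~nc] = True
    klass[viol] = "mendelian_inconsistent"
    klass[nc] = "both_het"  # uncallable; excluded from signal either way

    # orientation: +1 where the B allele is paternal, -1 where maternal
    orient = np.zeros(n)
    det = ~viol & ~nc
    m_is_aa = gm == "AA"
    f_is_aa = gf == "AA"
    c_het = gc == "AB"
    idx = det & (klass == "father_het_mother_hom") & c_het
    orient[idx] = np.where(m_is_aa[idx], 1.0, -1.0)  # pat allele differs from hom mother
    idx = det & (klass == "mother_het_father_hom") & c_het
    orient[idx] = np.where(f_is_aa[idx], -1.0, 1.0)  # mat allele differs from hom father
    idx = det & (klass == "obligate_het")
    orient[idx] = np.where(f_is_aa[idx], -1.0, 1.0)  # father's allele is A -> B maternal

    signed = np.where(orient != 0, orient * (baf - 0.5), np.nan)
    hom_lift = np.where(np.isin(gc, _HOM) & det, np.minimum(baf, 1 - baf), np.nan)

    return pd.DataFrame({
        "chrom": c["chrom"].to_numpy(),
        "pos": c["pos"].to_numpy(),
        "config_class": klass,
        "child_genotype": gc,
        "child_baf": baf,
        "signed_dev": signed,
        "hom_lift": hom_lift,
    })


def _windowed_sign_consistency(values: np.ndarray, window: int) -> float:
    """Fraction of non-overlapping windows whose mean shares the majority sign.

    Windowed means rather than raw sites: at low clonality the per-site
    sign is noise-dominated even for a perfectly haplotype-consistent
    event, while short local averages recover the common direction.
    """
    if values.size == 0:
        return 0.0
    n_win = max(1, values.size // window)
    means = np.array([w.mean() for w in np.array_split(values, n_win)])
    pos = (means > 0).sum()
    return max(pos, means.size - pos) / means.size


def detect_trio_events(
    trio: TrioArray, config: PipelineConfig | None = None
) -> list[CandidateSegment]:
    """Signed-deviation run test over the informative sites of a trio.

    Emits a segment when the run's |mean signed deviation| exceeds the
    genome-wide null by ``trio_score_threshold`` standard errors over at
    least ``trio_min_sites`` informative sites, with windowed sign
    consistency >= ``sign_consistency_min``.  Positive runs are paternal
    excess, negative maternal.  The symmetric-null construction makes the
    test invariant to global BAF mis-calibration that widens both
    directions equally.
    """
    config = config or PipelineConfig()
    sites = phase_informative_sites(trio)
    det = sites[np.isfinite(sites["signed_dev"])]
    if det.empty:
        logger.warning("no determinate informative sites; no trio calls")
        return []
    sigma = robust_sigma(det["signed_dev"].to_numpy())
    if not np.isfinite(sigma) or sigma <= 0:
        return []
    segments: list[CandidateSegment] = []
    for chrom in pd.unique(det["chrom"]):
        if chrom == "X" and trio.child.sex == "M":
            continue
        d_c = det[det["chrom"] == chrom]
        vals = d_c["signed_dev"].to_numpy()
        pos = d_c["pos"].to_numpy()
        n = vals.size
        if n < config.trio_min_sites:
            continue
        hits = scan_intervals(
            vals, sigma=sigma, threshold=config.trio_score_threshold,
            min_size=config.trio_min_sites, two_sided=True,
        )
        for i, j, _score in hits:
            m = j - i
            mean = float(vals[i:j].mean())
            if _windowed_sign_consistency(vals[i:j], config.sign_window) < config.sign_consistency_min:
                continue
            start = int(pos[i]) if i == 0 else (int(pos[i - 1]) + int(pos[i])) // 2
            end = int(pos[j - 1]) if j == n else (int(pos[j - 1]) + int(pos[j])) // 2
            mean_lrr, missing, med_upper, _ = _interval_summaries(
                trio.child, chrom, start, end, config.het_band
            )
            seg = CandidateSegment(
                chromosome=str(chrom), start=start, end=end, n_probes=m,
                b_deviation=abs(mean), mean_lrr=mean_lrr,
                median_upper_baf=med_upper, source="trio",
                parental_excess="paternal" if mean > 0 else "maternal",
            )
            seg.event_type = "unknown" if missing > 0.5 else classify_segment(seg, config)
            segments.append(seg)
    return segments


def _parent_signature(
    parent, seg: CandidateSegment, config: PipelineConfig
) -> tuple[float, float]:
    """(het b-deviation, mean LRR) of a parent over the event interval."""
    p = parent.probes
    m = (p["chrom"] == seg.chromosome) & (p["pos"] >= seg.start) & (p["pos"] <= seg.end)
    het = parent.het_mask(config.het_band) & m.to_numpy()
    baf = p["baf"].to_numpy()[het]
    bdev = float(np.abs(baf - 0.5).mean()) if baf.size else 0.0
    lrr = p.loc[m, "lrr"].to_numpy()
    mean_lrr = float(np.nanmean(lrr)) if m.any() and not np.all(np.isnan(lrr)) else 0.0
    return bdev, mean_lrr


def is_inherited(
    seg: CandidateSegment, trio: TrioArray, config: PipelineConfig | None = None
) -> bool:
    """True when a parent shows the same BAF/LRR signature over the region.

    A constitutive CNV in a parent reproduces the child's band structure
    (e.g. het bands at 1/3 and 2/3 for a duplication) with a full LRR
    shift; a mosaic event arising post-zygotically in the child does not.
    """
    config = config or PipelineConfig()
    for parent in (trio.mother, trio.father):
        bdev, lrr = _parent_signature(parent, seg, config)
        if bdev >= max(0.10, 0.5 * seg.b_deviation) or abs(lrr) >= config.constitutive_lrr_min:
            return True
    return False


def filter_trio_events(
    events: list[CandidateSegment],
    trio: TrioArray,
    config: PipelineConfig | None = None,
) -> list[CandidateSegment]:
    """Trio-specific filters: size, median upper-band BAF window, inheritance.

    Retains events of at least ``min_event_size_bp`` whose median
    upper-band BAF lies in [``trio_median_baf_min``,
    ``trio_median_baf_max``) — an undefined median (no skewed band, the
    spurious "NA or 0.50" mode) or one at/above 0.70 (constitutive-looking)
    drops the event — and which no parent carries constitutively.  Gains
    whose B deviation and LRR sit at the constitutive three-copy level are
    dropped even without a carrier parent: they cluster with inherited
    duplications, not with mosaic events.
    """
    from .filter_single import flag_constitutive_duplication

    config = config or PipelineConfig()
    kept = []
    for seg in events:
        if seg.size_bp < config.min_event_size_bp:
            continue
        mub = seg.median_upper_baf
        if not np.isfinite(mub):
            continue
        if not (config.trio_median_baf_min <= mub < config.trio_median_baf_max):
            continue
        if is_inherited(seg, trio, config):
            continue
        if flag_constitutive_duplication(seg, config):
            continue
        kept.append(seg)
    return kept
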