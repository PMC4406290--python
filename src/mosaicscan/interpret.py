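"""Clonality estimation, parental origin, and the genome-wide UPD scan.

The B deviation d of an event — the mean displacement of the heterozygous
BAF bands from 0.5 — is an algebraic function of the aberrant cell
fraction p (clonality), fixed by allele-dosage accounting in a two-line
mixture:

    LOH  (copy-neutral):  d = p / 2              p = 2 d
    loss (one copy):      d = p / (2 (2 - p))    p = 4 d / (1 + 2 d)
    gain (three copies):  d = p / (2 (2 + p))    p = 4 d / (1 - 2 d)

All three transforms are strictly increasing in p; the gain transform
saturates at d = 1/6 (the constitutive three-copy band), so a gain with
d >= 1/6 is not interpretable as mosaic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import CandidateSegment, MosaicEvent, PipelineConfig, TrioArray
from .detect_trio import phase_informative_sites

_VALID_RANGE = {"loh": 0.5, "loss": 0.5, "gain": 1.0 / 6.0, "gw_upd": 0.5}


def bdev_from_clonality(p: float, event_type: str) -> float:
    """Forward transform p -> d for one event type."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"clonality must lie in [0, 1], got {p}")
    if event_type == "loh":
        return p / 2
    if event_type == "loss":
        return p / (2 * (2 - p))
    if event_type == "gain":
        return p / (2 * (2 + p))
    raise ValueError(f"no clonality transform for event_type {event_type!r}")


def estimate_clonality(d: float, event_type: str) -> float:
    """Inverse transform d -> p for one event type.

    Raises for d outside the valid range; for gains beyond d = 1/6 the
    error suggests a constitutive duplication, which is what such a B
    deviation means.
    """
    hi = _VALID_RANGE.get(event_type)
    if hi is None:
        raise ValueError(f"no clonality transform for event_type {event_type!r}")
    if not (0.0 <= d <= hi):
        extra = (
            " (d >= 1/6 indicates a constitutive duplication, not mosaicism)"
            if event_type == "gain" else ""
        )
        raise ValueError(f"b_deviation {d} outside [0, {hi:.4g}] for {event_type}{extra}")
    if event_type == "loh":
        return 2 * d
    if event_type == "loss":
        return 4 * d / (1 + 2 * d)
    return 4 * d / (1 - 2 * d)  # gain


def clonality_roundtrip(p: float, event_type: str) -> float:
    """p -> d -> p consistency check (identity to numerical precision)."""
    return estimate_clonality(bdev_from_clonality(p, event_type), event_type)


def apply_loss_transform_to_gw_upd(d: float) -> float:
    """Loss-transform clonality 4d/(1+2d) for a genome-wide UPD deviation.

    Curated tabulations of genome-wide UPD report clonality through the
    loss transform of the event's B deviation; the scan's own
    model-consistent estimate (2d on obligate-het sites) is reported
    alongside in :class:`GwUpdReport`.
    """
    if not (0.0 <= d <= 0.5):
        raise ValueError(f"b_deviation {d} outside [0, 0.5]")
    return 4 * d / (1 + 2 * d)


# ---------------------------------------------------------------------------
# parental origin
# ---------------------------------------------------------------------------

def parental_origin(
    event: MosaicEvent | CandidateSegment,
    trio: TrioArray | None,
    config: PipelineConfig | None = None,
    min_sites: int = 20,
    majority: float = 0.80,
) -> str:
    """Majority vote of signed deviations over the event region.

    For losses and LOH, paternal-allele excess means the maternal material
    was lost (maternal origin of the event); for gains, paternal excess
    means the duplicated haplotype is paternal.  Returns ``unknown``
    without a trio, below ``min_sites`` determinate sites, or below the
    ``majority`` sign threshold.
    """
    if trio is None:
        return "unknown"
    sites = phase_informative_sites(trio)
    m = (
        (sites["chrom"] == event.chromosome)
        & (sites["pos"] >= event.start)
        & (sites["pos"] <= event.end)
        & np.isfinite(sites["signed_dev"])
    )
    dev = sites.loc[m, "signed_dev"].to_numpy()
    if dev.size < min_sites:
        return "unknown"
    pos_frac = (dev > 0).mean()
    if max(pos_frac, 1 - pos_frac) < majority:
        return "unknown"
    paternal_excess = pos_frac > 0.5
    etype = getattr(event, "event_type", None)
    if etype == "gain":
        return "paternal" if paternal_excess else "maternal"
    # loss / loh: the parent in excess is the one NOT lost
    return "maternal" if paternal_excess else "paternal"


# ---------------------------------------------------------------------------
# genome-wide UPD / chimerism scan
# ---------------------------------------------------------------------------

@dataclass
class GwUpdReport:
    """Genome-wide stratification of child BAF by parental-genotype class."""

    call: str  # gw_upd_chimera | none
    affected_parent: str  # paternal | maternal | none
    fraction_estimate: float  # 2 * mean obligate-het deviation
    b_deviation: float  # mean |obligate-het signed deviation|
    clonality_loss_transform: float  # 4d/(1+2d), for tabulation parity
    n_chromosomes_aberrant: int
    n_chromosomes: int
    class_stats: pd.DataFrame = field(repr=False, default=None)


def genome_wide_upd_scan(
    trio: TrioArray,
    config: PipelineConfig | None = None,
    z_threshold: float = 5.0,
    chrom_z_threshold: float = 4.0,
    min_obligate_per_chrom: int = 10,
) -> GwUpdReport:
    """Scan a trio for a genome-wide uniparental cell line (chimerism).

    An androgenetic line (two paternal haplotypes, no maternal) at
    fraction p signs itself in two strata: obligate-het sites (parents
    homozygous for different alleles) skew toward the paternal allele by
    p/2, and homozygous child probes at father-het sites are pulled off
    0/1 by p/2 (the paternal line contributes the allele the embryonic
    line lacks) while mother-het sites show no such hom-probe lift.  The
    call requires the oriented obligate-het skew on a majority of
    chromosomes plus the hom-probe lift confined to the affected parent's
    het class.  ``fraction_estimate`` is 2 * (mean obligate-het deviation).
    """
    config = config or PipelineConfig()
    sites = phase_informative_sites(trio)

    obl = sites[(sites["config_class"] == "obligate_het") & np.isfinite(sites["signed_dev"])]
    class_rows = []
    for klass in ("father_het_mother_hom", "mother_het_father_hom", "obligate_het", "both_hom_same"):
        sub = sites[sites["config_class"] == klass]
        lift = sub["hom_lift"].to_numpy()
        lift = lift[np.isfinite(lift)]
        sdev = sub["signed_dev"].to_numpy()
        sdev = sdev[np.isfinite(sdev)]
        class_rows.append({
            "config_class": klass,
            "n_sites": len(sub),
            "mean_signed_dev": sdev.mean() if sdev.size else np.nan,
            "mean_hom_lift": lift.mean() if lift.size else np.nan,
            "n_hom": lift.size,
            "se_hom_lift": lift.std(ddof=1) / np.sqrt(lift.size) if lift.size > 1 else np.nan,
        })
    stats = pd.DataFrame(class_rows).set_index("config_class")

    empty = GwUpdReport(
        call="none", affected_parent="none", fraction_estimate=0.0,
        b_deviation=0.0, clonality_loss_transform=0.0,
        n_chromosomes_aberrant=0, n_chromosomes=0, class_stats=stats,
    )
    if len(obl) < 50:
        return empty

    mean_dev = float(obl["signed_dev"].mean())
    d = abs(mean_dev)
    orientation = "paternal" if mean_dev > 0 else "maternal"

    # (b) oriented obligate-het skew on a majority of chromosomes
    n_aber = n_chrom = 0
    for chrom, grp in obl.groupby("chrom"):
        v = grp["signed_dev"].to_numpy()
        if v.size < min_obligate_per_chrom:
            continue
        n_chrom += 1
        z = v.mean() / (v.std(ddof=1) / np.sqrt(v.size))
        if abs(z) >= chrom_z_threshold and np.sign(v.mean()) == np.sign(mean_dev):
            n_aber += 1
    majority = n_chrom > 0 and n_aber > n_chrom / 2

    # (a) hom-probe lift confined to the affected parent's het class
    het_class = f"{'father' if orientation == 'paternal' else 'mother'}_het_{'mother' if orientation == 'paternal' else 'father'}_hom"
    other_class = f"{'mother' if orientation == 'paternal' else 'father'}_het_{'father' if orientation == 'paternal' else 'mother'}_hom"
    base = stats.loc["both_hom_same"]

    def lift_z(row) -> float:
        if not np.isfinite(row["mean_hom_lift"]) or not np.isfinite(row["se_hom_lift"]):
            return 0.0
        se = np.hypot(row["se_hom_lift"], base["se_hom_lift"] if np.isfinite(base["se_hom_lift"]) else 0.0)
        return (row["mean_hom_lift"] - base["mean_hom_lift"]) / se if se > 0 else 0.0

    affected_lift = lift_z(stats.loc[het_class])
    other_lift = lift_z(stats.loc[other_class])
    confined = affected_lift >= z_threshold and other_lift < z_threshold

    if majority and confined:
        return GwUpdReport(
            call="gw_upd_chimera", affected_parent=orientation,
            fraction_estimate=2 * d, b_deviation=d,
            clonality_loss_transform=apply_loss_transform_to_gw_upd(d),
            n_chromosomes_aberrant=n_aber, n_chromosomes=n_chrom,
            class_stats=stats,
        )
    empty.n_chromosomes_aberrant = n_aber
    empty.n_chromosomes = n_chrom
    return empty
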