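"""Synthetic trio SNP-array generator with known injected mosaic events.

Emulates Illumina-style genotyping arrays: ~680 k assayed positions across
the autosomes and X, heterozygous-BAF noise of SD ~0.02-0.06, and mosaic
loss / gain / copy-neutral LOH events rendered as allele-dosage mixtures of
a normal and an aberrant cell line at a given clonality.  Constitutive
duplications, runs of homozygosity, sample contamination and
androgenetic (genome-wide paternal UPD) chimerism are also representable,
since these are the error modes and edge cases the detection cascade must
separate from true mosaicism.

All randomness flows from a single seed; equal seeds give identical data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    AUTOSOMES,
    SampleArray,
    TrioArray,
    chrom_rank,
    compute_sample_qc,
)

#: GRCh37 chromosome lengths (bp), autosomes + X
GRCH37_LENGTHS: dict[str, int] = {
    "1": 249_250_621, "2": 243_199_373, "3": 198_022_430, "4": 191_154_276,
    "5": 180_915_260, "6": 171_115_067, "7": 159_138_663, "8": 146_364_022,
    "9": 141_213_431, "10": 135_534_747, "11": 135_006_516, "12": 133_851_895,
    "13": 115_169_878, "14": 107_349_540, "15": 102_531_392, "16": 90_354_753,
    "17": 81_195_210, "18": 78_077_248, "19": 59_128_983, "20": 63_025_520,
    "21": 48_129_895, "22": 51_304_566, "X": 155_270_560,
}

MOSAIC_TYPES = ("loss", "gain", "loh", "gw_upd")
EVENT_TYPES = MOSAIC_TYPES + ("constitutive_dup", "roh")


@dataclass(frozen=True)
class EventSpec:
    """One injected abnormality.

    ``clonality`` is the aberrant cell fraction p (ignored for
    constitutive_dup / roh, which are present in all cells).
    ``affected_parent`` names the parental haplotype acted on: for losses
    and LOH it is the haplotype *lost* from the aberrant line, for gains
    and constitutive duplications the haplotype duplicated.  A gain with
    ``third_haplotype=True`` duplicates a haplotype foreign to the diploid
    line instead.  ``target`` selects the trio member carrying the event.
    """

    chromosome: str
    start: int
    end: int
    event_type: str
    clonality: float | None = None
    affected_parent: str = "maternal"
    third_haplotype: bool = False
    target: str = "child"

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event_type {self.event_type!r}")
        if self.event_type in MOSAIC_TYPES:
            if self.clonality is None or not (0.0 < self.clonality <= 1.0):
                raise ValueError("mosaic events need clonality in (0, 1]")
        elif self.clonality is not None:
            raise ValueError(f"{self.event_type} events carry no clonality")
        if self.affected_parent not in ("maternal", "paternal"):
            raise ValueError("affected_parent must be maternal or paternal")
        if self.start > self.end or self.start < 1:
            raise ValueError("bad event interval")


@dataclass
class NoiseModel:
    """Array noise magnitudes.

    Defaults represent a clean Illumina-style array; the noisiest sample
    retained in curated analyses of this kind (het BAF SD 0.06) is
    representable by raising ``het_baf_sd``.  ``lrr_attenuation`` scales
    the ideal log2 copy-ratio means, since real arrays compress LRR.
    """

    het_baf_sd: float = 0.03
    hom_baf_sd: float = 0.01
    lrr_sd: float = 0.18
    contamination_fraction: float = 0.0
    lrr_attenuation: float = 1.0
    nc_rate: float = 0.0

    def __post_init__(self) -> None:
        if min(self.het_baf_sd, self.hom_baf_sd, self.lrr_sd) <= 0:
            raise ValueError("noise SDs must be positive")
        if not (0.0 <= self.contamination_fraction <= 0.5):
            raise ValueError("contamination_fraction must lie in [0, 0.5]")


# ---------------------------------------------------------------------------
# probe map and genotypes
# ---------------------------------------------------------------------------

def simulate_probe_map(
    n_probes: int,
    genome: dict[str, int] | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Random probe map: positions uniform per chromosome ∝ length.

    Returns a DataFrame with columns chrom, pos, freq (B-allele population
    frequency, uniform on [0.05, 0.95]), sorted by (chromosome, position).
    """
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    genome = genome or GRCH37_LENGTHS
    total = sum(genome.values())
    if n_probes > total:
        raise ValueError(f"n_probes {n_probes} exceeds genome length {total}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    chroms = sorted(genome, key=chrom_rank)
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    counts = rng.multinomial(n_probes, lengths / lengths.sum())
    frames = []
    for c, n_c, length in zip(chroms, counts, lengths.astype(int)):
        if n_c == 0:
            continue
        if n_c > length:
            raise ValueError(f"chromosome {c}: {n_c} probes exceed length {length}")
        pos = np.unique(rng.integers(1, length + 1, size=n_c))
        while pos.size < n_c:  # top up collisions (rare at real densities)
            extra = rng.integers(1, length + 1, size=n_c - pos.size)
            pos = np.unique(np.concatenate([pos, extra]))
        frames.append(pd.DataFrame({
            "chrom": c, "pos": pos, "freq": rng.uniform(0.05, 0.95, size=n_c),
        }))
    return pd.concat(frames, ignore_index=True)


@dataclass
class TrioGenotypes:
    """Phased ground-truth genotypes for one trio on a shared probe map."""

    probe_map: pd.DataFrame
    father_haps: np.ndarray  # (2, n) 0/1 B-allele indicators
    mother_haps: np.ndarray
    child_pat: np.ndarray  # (n,) allele transmitted by the father
    child_mat: np.ndarray

    @property
    def child_dosage(self) -> np.ndarray:
        return self.child_pat + self.child_mat


def _transmit(
    haps: np.ndarray, probe_map: pd.DataFrame, genome_lengths: dict[str, int],
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete: per chromosome, >=1 crossover placed uniformly plus
    Poisson extras at rate 1 per 100 Mb."""
    chrom = probe_map["chrom"].to_numpy()
    pos = probe_map["pos"].to_numpy()
    out = np.empty(len(probe_map), dtype=np.int8)
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        length = genome_lengths.get(str(c), int(pos[idx].max()) + 1)
        n_xo = 1 + rng.poisson(length / 1e8)
        xo = np.sort(rng.integers(1, length + 1, size=n_xo))
        start_hap = int(rng.integers(0, 2))
        hap_idx = (start_hap + np.searchsorted(xo, pos[idx], side="right")) % 2
        out[idx] = haps[hap_idx, idx]
    return out


def simulate_trio_genotypes(
    probe_map: pd.DataFrame,
    seed: int | np.random.Generator = 0,
    genome: dict[str, int] | None = None,
) -> TrioGenotypes:
    """Parents under Hardy-Weinberg; child by meiosis with recombination.

    Mendelian consistency holds by construction; phase is retained as
    ground truth for the trio detector and parental-origin tests.
    """
    if "freq" not in probe_map.columns:
        raise ValueError("probe map must carry allele frequencies (freq column)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    genome = genome or GRCH37_LENGTHS
    f = probe_map["freq"].to_numpy()
    n = len(probe_map)
    father = (rng.random((2, n)) < f).astype(np.int8)
    mother = (rng.random((2, n)) < f).astype(np.int8)
    child_pat = _transmit(father, probe_map, genome, rng)
    child_mat = _transmit(mother, probe_map, genome, rng)
    return TrioGenotypes(probe_map, father, mother, child_pat, child_mat)


def simulate_phased_sample(
    probe_map: pd.DataFrame, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Phased haplotype pair for a singleton (no parents), HWE."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    f = probe_map["freq"].to_numpy()
    pat = (rng.random(f.size) < f).astype(np.int8)
    mat = (rng.random(f.size) < f).astype(np.int8)
    return pat, mat


# ---------------------------------------------------------------------------
# expected BAF levels (closed forms)
# ---------------------------------------------------------------------------

def expected_baf_levels(
    genotype: str, event_type: str, p: float, allele_affected: str = "B"
) -> tuple[float, ...]:
    """Closed-form mixture means of the BAF for one genotype under an event.

    Heterozygous AB probes: loss of the B-bearing haplotype gives
    (1-p)/(2-p); a gain of it gives (1+p)/(2+p); LOH toward B gives
    (1+p)/2.  A/B exchange mirrors the level about 0.5.  Homozygous probes
    stay at 0 or 1 (dosage reweighting does not move an allele fraction of
    0/1).
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError("clonality p must lie in [0, 1]")
    if allele_affected not in ("A", "B"):
        raise ValueError("allele_affected must be A or B")
    if genotype in ("AA", "BB"):
        return (0.0,) if genotype == "AA" else (1.0,)
    if genotype != "AB":
        raise ValueError(f"bad genotype {genotype!r}")
    # levels with the B-bearing haplotype affected; A/B exchange mirrors
    if event_type == "loss":
        level = (1 - p) / (2 - p)  # B haplotype lost
    elif event_type == "gain":
        level = (1 + p) / (2 + p)  # B haplotype duplicated
    elif event_type in ("loh", "gw_upd"):
        level = (1 + p) / 2  # copy-neutral replacement toward B
    elif event_type == "constitutive_dup":
        level = 2.0 / 3.0
    else:
        raise ValueError(f"unknown event_type {event_type!r}")
    if allele_affected == "A":
        level = 1 - level
    return (level,)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _truncated_normal(
    mean: np.ndarray, sd: np.ndarray, rng: np.random.Generator,
    lo: float = 0.0, hi: float = 1.0, max_iter: int = 12,
) -> np.ndarray:
    """Vectorized truncated-normal draws by rejection (clip as last resort)."""
    out = rng.normal(mean, sd)
    bad = (out < lo) | (out > hi)
    it = 0
    while bad.any() and it < max_iter:
        out[bad] = rng.normal(np.asarray(mean)[bad] if np.ndim(mean) else mean,
                              np.asarray(sd)[bad] if np.ndim(sd) else sd)
        bad = (out < lo) | (out > hi)
        it += 1
    return np.clip(out, lo, hi)


def _event_mask(probe_map: pd.DataFrame, ev: EventSpec) -> np.ndarray:
    return (
        (probe_map["chrom"].to_numpy() == ev.chromosome)
        & (probe_map["pos"].to_numpy() >= ev.start)
        & (probe_map["pos"].to_numpy() <= ev.end)
    )


def _check_non_conflicting(probe_map: pd.DataFrame, events: Sequence[EventSpec]) -> None:
    masks = [(_event_mask(probe_map, ev), ev) for ev in events]
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            if masks[i][1].target == masks[j][1].target and (
                masks[i][0] & masks[j][0]
            ).any():
                raise ValueError(
                    f"overlapping conflicting events: {masks[i][1]} / {masks[j][1]}"
                )


def render_sample(
    probe_map: pd.DataFrame,
    pat: np.ndarray,
    mat: np.ndarray,
    events: Sequence[EventSpec] = (),
    noise: NoiseModel | None = None,
    seed: int | np.random.Generator = 0,
    sample_id: str = "S1",
    role: str = "singleton",
    father_haps: np.ndarray | None = None,
    mother_haps: np.ndarray | None = None,
) -> SampleArray:
    """Render one member's probe table from phased alleles plus events.

    BAF is a truncated normal around the allele-dosage mixture mean; LRR is
    normal around the ideal log2 copy ratio of the mixture (times the
    attenuation factor).  Genotype calls are the constitutive genotypes:
    array callers cluster against constitutive cluster positions, so a
    mosaic shift moves BAF but not the call (ROH tracts, which are
    constitutive, do re-call as homozygous).
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    _check_non_conflicting(probe_map, events)

    pat = pat.astype(np.int16).copy()
    mat = mat.astype(np.int16).copy()
    n = len(probe_map)
    lrr_mean = np.zeros(n)

    # constitutive modifications first (they change the genotype itself)
    for ev in events:
        m = _event_mask(probe_map, ev)
        if ev.event_type == "roh":
            mat[m] = pat[m]  # inherited identical-by-descent tract
        elif ev.event_type == "constitutive_dup":
            lrr_mean[m] = np.log2(3 / 2) * noise.lrr_attenuation

    dosage = (pat + mat).astype(np.int16)
    num = dosage.astype(float)  # B copies per average cell
    den = np.full(n, 2.0)  # total copies per average cell

    for ev in events:
        m = _event_mask(probe_map, ev)
        p = ev.clonality or 0.0
        parent_allele = pat if ev.affected_parent == "paternal" else mat
        if ev.event_type == "loss":
            kept = mat if ev.affected_parent == "paternal" else pat
            num[m] = (1 - p) * dosage[m] + p * kept[m]
            den[m] = 2 - p
            lrr_mean[m] = np.log2((2 - p) / 2) * noise.lrr_attenuation
        elif ev.event_type == "gain":
            if ev.third_haplotype:
                extra = (rng.random(int(m.sum())) < probe_map["freq"].to_numpy()[m]).astype(float)
            else:
                extra = parent_allele[m].astype(float)
            num[m] = (1 - p) * dosage[m] + p * (dosage[m] + extra)
            den[m] = 2 + p
            lrr_mean[m] = np.log2((2 + p) / 2) * noise.lrr_attenuation
        elif ev.event_type == "loh":
            kept = mat if ev.affected_parent == "paternal" else pat
            num[m] = (1 - p) * dosage[m] + p * 2 * kept[m]
        elif ev.event_type == "gw_upd":
            if father_haps is None and mother_haps is None:
                raise ValueError("gw_upd rendering needs parental haplotypes")
            haps = father_haps if ev.affected_parent == "paternal" else mother_haps
            if haps is None:
                raise ValueError(f"gw_upd needs {ev.affected_parent} haplotypes")
            num[m] = (1 - p) * dosage[m] + p * (haps[0, m] + haps[1, m])
        elif ev.event_type == "constitutive_dup":
            num[m] = dosage[m] + parent_allele[m]
            den[m] = 3.0

    baf_mean = num / den
    c = noise.contamination_fraction
    if c > 0:
        g_c = rng.binomial(2, probe_map["freq"].to_numpy())
        baf_mean = ((1 - c) * num + c * g_c) / ((1 - c) * den + 2 * c)

    genotype = np.array(["AA", "AB", "BB"], dtype=object)[dosage]
    if noise.nc_rate > 0:
        genotype[rng.random(n) < noise.nc_rate] = "NC"
    sd = np.where(genotype == "AB", noise.het_baf_sd, noise.hom_baf_sd)
    baf = _truncated_normal(baf_mean, sd, rng)
    lrr = rng.normal(lrr_mean, noise.lrr_sd)

    probes = pd.DataFrame({
        "chrom": probe_map["chrom"].to_numpy(),
        "pos": probe_map["pos"].to_numpy(),
        "genotype": genotype,
        "baf": baf,
        "lrr": lrr,
    })
    sample = SampleArray(sample_id=sample_id, role=role, probes=probes)
    sample.qc = compute_sample_qc(sample)
    return sample


def render_trio(
    genotypes: TrioGenotypes,
    events: Sequence[EventSpec] = (),
    noise: NoiseModel | None = None,
    seed: int | np.random.Generator = 0,
    family_id: str = "F1",
) -> TrioArray:
    """Render all three members; events apply to their ``target`` member."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    gm = genotypes

    def member_events(target: str) -> list[EventSpec]:
        return [ev for ev in events if ev.target == target]

    child = render_sample(
        gm.probe_map, gm.child_pat, gm.child_mat, member_events("child"), noise,
        rng, sample_id=f"{family_id}-child", role="child",
        father_haps=gm.father_haps, mother_haps=gm.mother_haps,
    )
    mother = render_sample(
        gm.probe_map, gm.mother_haps[0], gm.mother_haps[1], member_events("mother"),
        noise, rng, sample_id=f"{family_id}-mother", role="mother",
    )
    father = render_sample(
        gm.probe_map, gm.father_haps[0], gm.father_haps[1], member_events("father"),
        noise, rng, sample_id=f"{family_id}-father", role="father",
    )
    return TrioArray(child=child, mother=mother, father=father)


def inject_unimodal_skew(
    sample: SampleArray, chromosome: str, start: int, end: int, shift: float = 0.05
) -> SampleArray:
    """Shift the het BAF mode in a region to a single off-centre band.

    Emulates the calibration artefact class ("skewed unimodal BAF
    deviations") that the filtering cascade must reject.
    """
    p = sample.probes
    m = (
        (p["chrom"] == chromosome) & (p["pos"] >= start) & (p["pos"] <= end)
        & (p["genotype"] == "AB")
    )
    sample.probes.loc[m, "baf"] = np.clip(p.loc[m, "baf"] + shift, 0.0, 1.0)
    return sample


def simulate_candidate_mix(
    seed: int | np.random.Generator = 0,
    n_probes: int = 20_000,
    noise: NoiseModel | None = None,
    true_event_type: str = "loss",
    true_clonality: float = 0.44,
) -> tuple[SampleArray, list[tuple[int, int, str]], tuple[int, int]]:
    """One sample emulating the raw output of an over-calling segmenter.

    Raw BAF segmentation over-calls roughly 10:1; per true event the raw
    candidate list carries the event hypersegmented into three nearby
    fragments, six ROH tracts mistaken for copy-neutral events, and one
    skewed-unimodal artefact.  Returns ``(sample, candidates, truth)``
    where ``candidates`` are (start, end, label) intervals on chromosome 1
    (labels: fragment / roh / unimodal) and ``truth`` the true event span.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    noise = noise or NoiseModel()
    genome = {"1": 160_000_000}
    pm = simulate_probe_map(n_probes, genome, rng)
    pat, mat = simulate_phased_sample(pm, rng)
    Mb = 1_000_000
    true_span = (10 * Mb, 20 * Mb)
    events = [EventSpec("1", true_span[0], true_span[1], true_event_type,
                        clonality=true_clonality)]
    roh_spans = [(s * Mb, (s + 4) * Mb) for s in (30, 42, 54, 66, 78, 90)]
    events += [EventSpec("1", s, e, "roh") for s, e in roh_spans]
    sample = render_sample(pm, pat, mat, events, noise, rng)
    uni_span = (130 * Mb, 135 * Mb)
    inject_unimodal_skew(sample, "1", *uni_span, shift=0.05)
    # the true event reaches the candidate list as three nearby fragments
    s0, e0 = true_span
    frags = [(s0, s0 + 4 * Mb), (s0 + 4 * Mb + 500_000, s0 + 7 * Mb),
             (s0 + 7 * Mb + 400_000, e0)]
    candidates = [(s, e, "fragment") for s, e in frags]
    candidates += [(s, e, "roh") for s, e in roh_spans]
    candidates.append((*uni_span, "unimodal"))
    return sample, candidates, true_span


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def default_event_sampler(
    rng: np.random.Generator, genome: dict[str, int] | None = None
) -> EventSpec:
    """One random mosaic event of the character seen in curated calls:
    2-90 Mb, clonality 0.2-0.7, type weighted toward copy-number gains."""
    genome = genome or GRCH37_LENGTHS
    chroms = [c for c in genome if c in AUTOSOMES]
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    chrom = str(rng.choice(chroms, p=lengths / lengths.sum()))
    size = int(rng.uniform(2e6, min(90e6, genome[chrom] * 0.9)))
    start = int(rng.integers(1, genome[chrom] - size))
    etype = str(rng.choice(["gain", "loss", "loh"], p=[0.5, 0.25, 0.25]))
    return EventSpec(
        chromosome=chrom, start=start, end=start + size - 1, event_type=etype,
        clonality=float(rng.uniform(0.2, 0.7)),
        affected_parent=str(rng.choice(["maternal", "paternal"])),
    )


def simulate_cohort(
    n_cases: int,
    n_controls: int,
    case_event_rate: float,
    control_event_rate: float,
    event_sampler: Callable[[np.random.Generator], EventSpec] | None = None,
    seed: int = 0,
    n_probes: int | None = None,
    genome: dict[str, int] | None = None,
    noise: NoiseModel | None = None,
    render: bool = False,
) -> tuple[pd.DataFrame, list[SampleArray] | None]:
    """Bernoulli event assignment per sample plus ground truth.

    Returns ``(truth, samples)``: one truth row per sample (group, event
    presence, and the event's specification when present).  Probe arrays
    are rendered only when ``render=True`` (sized by ``n_probes``), since
    burden statistics need only the ground-truth counts.
    """
    for rate in (case_event_rate, control_event_rate):
        if not (0.0 <= rate <= 1.0):
            raise ValueError("event rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    sampler = event_sampler or default_event_sampler
    genome = genome or GRCH37_LENGTHS
    rows = []
    specs: list[EventSpec | None] = []
    for group, n_grp, rate in (("case", n_cases, case_event_rate),
                               ("control", n_controls, control_event_rate)):
        has = rng.random(n_grp) < rate
        for i in range(n_grp):
            sid = f"{group}{i:05d}"
            if has[i]:
                try:
                    ev = sampler(rng, genome)  # type: ignore[call-arg]
                except TypeError:
                    ev = sampler(rng)
                rows.append({
                    "sample_id": sid, "group": group, "has_event": True,
                    "event_type": ev.event_type, "chrom": ev.chromosome,
                    "start": ev.start, "end": ev.end, "clonality": ev.clonality,
                })
                specs.append(ev)
            else:
                rows.append({
                    "sample_id": sid, "group": group, "has_event": False,
                    "event_type": None, "chrom": None, "start": None,
                    "end": None, "clonality": None,
                })
                specs.append(None)
    truth = pd.DataFrame(rows)
    samples = None
    if render:
        if n_probes is None:
            raise ValueError("render=True needs n_probes")
        probe_map = simulate_probe_map(n_probes, genome, rng)
        samples = []
        for row, ev in zip(rows, specs):
            pat, mat = simulate_phased_sample(probe_map, rng)
            samples.append(render_sample(
                probe_map, pat, mat, [ev] if ev else [], noise, rng,
                sample_id=row["sample_id"],
            ))
    return truth, samples
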