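# Methods

## Problem and model

A mosaic structural abnormality — a deletion, duplication, or copy-neutral
loss of heterozygosity (LOH) present in a fraction *p* of cells (the
*clonality*) — changes the allele dosage seen by an SNP genotyping array.
At a heterozygous (AB) probe, the B-allele frequency (BAF) moves from 0.5
into two symmetric bands; at homozygous probes it stays at 0/1 (an allele
fraction of 0 or 1 is invariant under dosage reweighting).  The mean
displacement of the heterozygous bands is the **B deviation**
*d* = mean |BAF − 0.5|.  Accounting B copies over total copies in a
two-line mixture gives the type-specific transforms

| type | d(p) | p(d) | valid d |
|------|------|------|---------|
| LOH (copy-neutral) | p/2 | 2d | [0, 0.5] |
| loss (1 copy in aberrant line) | p/(2(2−p)) | 4d/(1+2d) | [0, 0.5] |
| gain (3 copies) | p/(2(2+p)) | 4d/(1−2d) | [0, 1/6] |

All three are strictly increasing in *p*; the gain transform saturates at
d = 1/6, the constitutive three-copy het band (1/3, 2/3) — a gain with
d ≥ 1/6 is constitutive, not mosaic.  The log R ratio (LRR, log2 total
intensity) separates the types: negative for loss, positive for gain,
≈ 0 for LOH, with ideal means log2((2∓p)/2).

Genome-wide uniparental disomy (androgenetic chimerism) is modelled as a
second cell line carrying both of one parent's haplotypes and none of the
other's.  Its clonality is reported two ways: the model-consistent
estimate 2·(mean obligate-heterozygote deviation), and the loss-transform
value 4d/(1+2d), which is how curated tabulations of such events print
clonality; for the same *d* the two differ (e.g. d = 0.0477 → 0.095 vs
0.174), so both are emitted.

## Single-sample detection

The detector scores the folded deviation series |BAF − 0.5| over
heterozygous probes.  Heterozygosity is taken from the AB genotype call
when calls are present (the BAF band [0.15, 0.85] is only a fallback for
call-free data): at high clonality the het bands leave any fixed BAF band,
and band-restricted selection would make 90 %-clonality losses invisible.

The per-sample BAF noise scale σ is estimated robustly: the folded
deviations are reflected about zero and σ = 1.4826·MAD, so a minority of
event probes cannot inflate the null.  Under the null the folded series
has mean σ√(2/π) and SD σ√(1−2/π).

Candidate intervals come from a **multi-scale interval scan**: for window
length *w* and start *s*, score(s, w) = Σ(x − null mean)/(σ_fold √w) in
null standard errors; windows on a geometric scale grid (ratio 1.4, step
w/4) seed candidates, each seed's boundaries are refined by exact
coordinate-wise search, and non-overlapping intervals with score ≥
`seg_score_threshold` (default 6.0) over ≥ `min_seg_probes` (default 75)
het probes are accepted best-first.  Plain recursive binary segmentation
was evaluated and rejected: a short interior bump barely moves the means
of the two halves of a whole chromosome (a 5 Mb event worth 8.6 SE
produced a first-split CUSUM of 2.2).

The threshold 6.0 was set by power algebra: at het SD 0.03 and 1 probe /
4 kb, a clonality-0.10 loss of 2 Mb scores ≈ 6.5 SE and of 5 Mb ≈ 10 SE,
while the genome-wide maximum null window score is ≈ 3–4.5, so pure-noise
chromosomes call nothing in ≫ 99 % of runs.  Boundaries between het
probes map to the midpoint of their positions (floored).  Classification:
mean LRR over *all* probes in the interval, thresholds ±0.04
(`lrr_loss_max` / `lrr_gain_min`); > 50 % missing LRR flags the segment
`unknown` for manual review.  Chromosome X is processed like an autosome
for females and skipped for males (single-copy BAF is uninterpretable).

## Filtering cascade

Raw segmentation over-calls heavily; the cascade applies, in order:

1. **Merge** — same-chromosome, same-type segments with gaps ≤ 1 Mb are
   merged (hypersegmentation repair); merged d and LRR are
   probe-count-weighted means of the fragments.  Idempotent.
2. **Size** — retain ≥ 2 Mb (inclusive; "at least 2 Mb" is the event
   definition), applied after merging.
3. **BAF peak class** — Gaussian KDE (absolute bandwidth 0.02, grid step
   0.002, peak prominence ≥ 5 % of the maximum) over the segment's het
   BAF values.  Exactly two modes symmetric about 0.5 (midpoint within
   0.03, separation ≥ 0.04) → mosaic; ROH when the segment's het-probe
   density is < 10 % of the sample's genome-wide het density; anything
   else (including < 20 values at normal density) is a skewed-unimodal
   artefact and is dropped.  The KDE parameters are design choices set to
   separate the three classes at het SD ≤ 0.06; all are config-exposed.
   A consequence of the bimodality requirement: events whose bands
   overlap into one mode (clonality ≲ 0.2 at SD 0.03) do not survive the
   cascade — consistent with the lowest curated single-sample clonality
   of ≈ 0.23.
4. **Constitutive-duplication exclusion** — gains with d ≥ 0.15 and mean
   LRR ≥ 0.20 are dropped: these sit at the constitutive three-copy level
   (d = 1/6).  Fixed thresholds stand in for clustering against an
   inherited-duplication reference set, which the package does not ship;
   the known cost is that mosaic duplications of very high clonality are
   also removed.

**Contamination** is a sample-level veto checked first: DNA from a second
individual splits every BAF cluster into dosage mixtures, so a sample is
flagged when ≥ 80 % of its autosomes individually show ≥ 3 KDE modes
inside the het band.  A single large event skews one chromosome only and
is never flagged.  Large het-BAF SD alone never excludes a sample
(genome-wide mosaicism inflates it; the QC value is reported, not acted
on).

Every input segment receives exactly one outcome (retain, or drop with
reason: merged_fragment / too_small / roh / unimodal_skew /
constitutive_dup / contaminated_sample); survivors carry the ordered
filter trail, the package's stand-in for manual curation provenance.

## Trio-phased detection

Parental genotypes orient the child's deviations.  Sites are classed by
the parental configuration (father-het/mother-hom, mother-het/father-hom,
obligate-het — parents homozygous for different alleles — both-hom-same,
both-het, Mendelian-inconsistent).  Where the orientation is determinate
(child AB with ≥ 1 homozygous parent, or obligate-het), the signed
deviation is oriented so positive = paternal-allele excess.  A real
haplotype-level event gives a consistently signed run of mean |d|;
noise is symmetric.  This accumulates signal ∝ d per site where the
single-sample folded statistic grows only ∝ d²/σ for d below the noise
floor — the source of the trio detector's low-clonality advantage.

The same interval scan (two-sided) runs on the signed series with its own
threshold (`trio_score_threshold` 6.0 SE, `trio_min_sites` 25, null σ
from the MAD of the genome-wide signed deviations).  Accepted runs must
pass **windowed sign consistency**: ≥ 90 % of non-overlapping 10-site
windows share the majority sign.  Windows rather than raw sites: at low
clonality the per-site sign is noise-dominated (P(correct sign) =
Φ(d/σ) < 0.9 exactly in the regime the detector exists for), while short
local means recover the common direction; the construction also makes the
detector invariant to calibration errors that widen both BAF directions
symmetrically.  Positive runs are paternal excess, negative maternal.

Trio-specific filters then require size ≥ 2 Mb; median upper-band BAF in
[0.51, 0.70) — an undefined median (no skewed band) or one at ≥ 0.70
(constitutive-looking) drops the event; no carrier parent (a parent
showing the same interval with het B deviation ≥ max(0.10, d_child/2) or
|LRR| ≥ 0.20 marks the event inherited); and the constitutive-duplication
exclusion, since a de novo constitutive duplication (upper band 2/3)
would otherwise slip the window.

`run_trio` unions single-sample and trio calls, deduplicating at ≥ 50 %
reciprocal overlap with single-sample precedence (their B deviation feeds
the clonality transforms directly), annotates parental origin, and always
runs the genome-wide UPD scan.

## Parental origin and the genome-wide UPD scan

Origin is a majority vote of signed deviations over the event region
(≥ 20 determinate sites, ≥ 80 % majority, else `unknown`): for loss/LOH,
paternal excess means the maternal material was lost (maternal origin);
for gains, paternal excess means a paternal duplication.

The genome-wide scan stratifies child BAF by parental-genotype class.  An
androgenetic line signs itself twice: obligate-het sites skew toward the
paternal allele by p/2, and homozygous child probes at *father-het* sites
are pulled off 0/1 by p/2 (the aberrant line, carrying both paternal
haplotypes, is AB wherever the father is) while *mother-het* sites show
no hom-probe lift.  The call requires (a) the hom-probe lift significant
(z ≥ 5 vs the both-hom-same baseline) in the affected parent's het class
and not the other's, and (b) the oriented obligate-het skew (|z| ≥ 4)
on a majority of chromosomes with ≥ 10 obligate sites, plus ≥ 50
obligate sites genome-wide.  A single large event fails the majority
rule.  The maternal (gynogenetic) mirror image is handled symmetrically.
When the scan fires, chromosome-wide copy-neutral trio calls are absorbed
into the one genome-wide event.

## Burden statistics

2×2 tables are (cases with event, cases without; controls with, without).
The odds ratio is the plain cross-product (a·d)/(b·c) with no continuity
correction; a zero "without" cell raises an error offering the
Haldane–Anscombe +0.5 correction as an explicit opt-in.  Fisher tests are
exact conditional hypergeometric tails: one-sided P[X ≥ a]; two-sided by
the minimum-likelihood convention (sum of point probabilities ≤ observed,
with a 1+1e−12 tie guard) — the convention of R's `fisher.test` and
scipy.  Meta-analysis: pooled-counts Fisher, and an exact stratified
(CMH-style) test of T = Σaᵢ against the convolution of the per-stratum
hypergeometric nulls, reported with the Mantel–Haenszel common OR.  The
test suite verifies both tails against brute-force enumeration over all
fixed-margin tables (total ≤ 60) computed from binomial coefficients.

## Synthetic-data generator

The simulator is the study-conditions definition, not a convenience:
Illumina-style probe maps (positions uniform per chromosome ∝ GRCh37
length, default scale ≈ 680 k probes genome-wide ≈ 1 / 4.5 kb; B-allele
frequencies uniform on [0.05, 0.95]); parents under Hardy–Weinberg;
children by meiosis with one obligate crossover per chromosome plus
Poisson extras at 1 per 100 Mb (the simplest model that makes
haplotype-run methods meaningful); phase retained as ground truth.  BAF
is a truncated normal (rejection-sampled) around the allele-dosage
mixture mean; default noise het SD 0.03, hom SD 0.01, LRR SD 0.18 — set
so that the detection sensitivity window (loss/LOH ≈ 10–90 % of cells,
gains ≈ 20–80 %) is achievable, since the source arrays' empirical noise
is not published; the documented noisy-sample case (het SD 0.06) is a
parameter away.  LRR means are ideal log2 copy ratios times an
attenuation factor (default 1.0) because real arrays compress LRR.
Genotype calls are the constitutive genotypes (callers cluster against
constitutive cluster positions; ROH tracts, being constitutive, re-call
homozygous).  Contamination mixes an unrelated Hardy–Weinberg genotype
vector at fraction c, splitting the het band into bands at 0.5 ± c/2 and
hom-adjacent bands — the multi-band genome-wide signature the
contamination flag keys on.  Gains can duplicate a transmitted haplotype
or a foreign ("third") haplotype; third-haplotype gains are rendered but
trio detection of them is explicitly not promised (the signed-deviation
signal they generate is not haplotype-consistent).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: linkage disequilibrium, array-specific probe
intensity bias and GC waves, genotype-calling error inside mosaic
regions, cell-line artefacts, and probe-level exclusion by population CNV
frequency (an optional probe-exclusion mask input is the only hook).

## Problem sizes used by tests and the acceptance script

Simulated chromosomes are 30–160 Mb with 1 probe / 4 kb (8 kb for the
sparser-chip trio comparison), 5–10 Mb events, 10–200 replicates per
property — sizes chosen so each suite runs in minutes while every rate
being asserted has binomial noise well inside its margin.  The paired
trio-vs-single comparison runs at het SD 0.06 and 8 kb spacing, i.e. the
noisy-sample / sparser-chip corner where phase information genuinely
matters; at the clean-array defaults both detectors find clonality-0.15
events of 5 Mb and the comparison is uninformative.

## Known limitations

* Clonality estimates inherit the noise-inflation bias of mean |BAF−0.5|
  (E|N(d,σ)| > d for d ≲ σ); at the curated-event range (d ≥ 0.05,
  σ = 0.03) the bias is < 0.01 in d and no de-biasing is applied.
* The constitutive-duplication exclusion removes mosaic gains of very
  high clonality by construction.
* The cascade's bimodality requirement removes sub-~0.2-clonality events
  from the *single-sample* product; they remain reachable via the trio
  path.
* One printed two-sided comparison against an external clinical series is
  not reproducible from printed counts; the paper-check report flags it
  (`expected_mismatch`) rather than matching it.
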