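"""Case-control enrichment statistics for mosaic event burdens.

Exact Fisher tests on 2x2 tables (conditional hypergeometric tails),
cross-product odds ratios, frequency estimates, and stratified
meta-analysis (pooled-counts Fisher and an exact
Cochran-Mantel-Haenszel-style test by convolution of the per-stratum
hypergeometric null distributions).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

_TWO_SIDED_SLACK = 1 + 1e-12  # guard against ties lost to rounding


class ZeroCellError(ValueError):
    """A zero 'without-event' cell makes the cross-product OR undefined."""


@dataclass(frozen=True)
class CohortCounts:
    """2x2 table: (cases with / without, controls with / without)."""

    cases_with_event: int
    cases_without: int
    controls_with_event: int
    controls_without: int

    def __post_init__(self) -> None:
        if min(self.cases_with_event, self.cases_without,
               self.controls_with_event, self.controls_without) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_cases == 0 or self.n_controls == 0:
            raise ValueError("both margins must be positive")

    @property
    def n_cases(self) -> int:
        return self.cases_with_event + self.cases_without

    @property
    def n_controls(self) -> int:
        return self.controls_with_event + self.controls_without

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.cases_with_event, self.cases_without,
                self.controls_with_event, self.controls_without)


def odds_ratio(counts: CohortCounts, haldane: bool = False) -> float:
    """Cross-product odds ratio (a d)/(b c), no continuity correction.

    A zero in either 'without' cell raises :class:`ZeroCellError`; passing
    ``haldane=True`` opts in to the Haldane-Anscombe +0.5 correction
    instead (also applied when a zero 'with' cell would give OR = 0).
    """
    a, b, c, d = counts.as_tuple()
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        return (a * d) / (b * c)
    if b == 0 or c == 0:
        raise ZeroCellError(
            "zero cell makes the odds ratio undefined; pass haldane=True to "
            "apply the Haldane-Anscombe +0.5 correction explicitly"
        )
    return (a * d) / (b * c)


def hypergeom_tails(N: int, K: int, n1: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact tail p-values for every admissible cell value of a 2x2 table.

    For fixed margins (total N, K with-event, n1 in the first row) returns
    ``(support, one_sided, two_sided)``: the admissible values a of the
    top-left cell, the upper-tail P[X >= a], and the minimum-likelihood
    two-sided p (sum of point probabilities not exceeding that of a).
    """
    support = np.arange(max(0, K + n1 - N), min(K, n1) + 1)
    pmf = hypergeom.pmf(support, N, K, n1)
    one_sided = np.minimum(np.cumsum(pmf[::-1])[::-1], 1.0)
    # two_sided[i] = sum of pmf values <= pmf[i] (with a tie guard)
    two_sided = (pmf[None, :] <= pmf[:, None] * _TWO_SIDED_SLACK) @ pmf
    return support, one_sided, np.minimum(two_sided, 1.0)


def fisher_exact(counts: CohortCounts, sidedness: str = "one_sided_greater") -> float:
    """Exact conditional p-value for a 2x2 table.

    With all margins fixed, the cases-with-event cell is hypergeometric.
    ``one_sided_greater`` is the upper tail P[X >= a]; ``two_sided`` sums
    the probabilities of every table whose point probability does not
    exceed the observed one (the minimum-likelihood convention).
    """
    a, b, c, d = counts.as_tuple()
    N = a + b + c + d
    K = a + c  # total with event
    n1 = a + b  # cases margin
    if sidedness == "one_sided_greater":
        return float(hypergeom.sf(a - 1, N, K, n1))
    if sidedness == "two_sided":
        support, _, two_sided = hypergeom_tails(N, K, n1)
        return float(two_sided[np.searchsorted(support, a)])
    raise ValueError(f"bad sidedness {sidedness!r}")


def frequency(events: int, n: int, decimals: int | None = 2) -> float:
    """Event frequency as a percentage (100 * events / n)."""
    if n <= 0:
        raise ValueError("n must be positive")
    pct = 100.0 * events / n
    return round(pct, decimals) if decimals is not None else pct


# ---------------------------------------------------------------------------
# meta-analysis
# ---------------------------------------------------------------------------

def _pool(counts_list: Sequence[CohortCounts]) -> CohortCounts:
    arr = np.array([c.as_tuple() for c in counts_list]).sum(axis=0)
    return CohortCounts(*map(int, arr))


def mantel_haenszel_or(counts_list: Sequence[CohortCounts]) -> float:
    """Mantel-Haenszel common odds ratio across strata."""
    num = den = 0.0
    for cc in counts_list:
        a, b, c, d = cc.as_tuple()
        n = a + b + c + d
        num += a * d / n
        den += b * c / n
    if den == 0:
        raise ZeroCellError("Mantel-Haenszel denominator is zero")
    return num / den


def meta_pooled(
    counts_list: Sequence[CohortCounts],
    method: str = "pooled_fisher",
    sidedness: str = "one_sided_greater",
) -> dict:
    """Stratified meta-analysis p-value.

    ``pooled_fisher`` collapses the strata and applies the exact Fisher
    test; ``cmh`` keeps strata fixed and tests T = sum of
    cases-with-event cells against its exact null (the convolution of the
    per-stratum hypergeometric distributions), with the Mantel-Haenszel
    common OR reported alongside.
    """
    counts_list = list(counts_list)
    if len(counts_list) < 1:
        raise ValueError("need at least one stratum")
    if method == "pooled_fisher":
        pooled = _pool(counts_list)
        return {
            "method": "pooled_fisher",
            "p_value": fisher_exact(pooled, sidedness),
            "pooled_counts": pooled.as_tuple(),
        }
    if method != "cmh":
        raise ValueError(f"bad method {method!r}")
    # exact CMH: convolve hypergeometric pmfs of each stratum
    dist = np.array([1.0])
    offset = 0
    t_obs = 0
    for cc in counts_list:
        a, b, c, d = cc.as_tuple()
        N, K, n1 = a + b + c + d, a + c, a + b
        lo, hi = max(0, K + n1 - N), min(K, n1)
        pmf = hypergeom.pmf(np.arange(lo, hi + 1), N, K, n1)
        dist = np.convolve(dist, pmf)
        offset += lo
        t_obs += a
    support = np.arange(offset, offset + dist.size)
    if sidedness == "one_sided_greater":
        p = float(dist[support >= t_obs].sum())
    elif sidedness == "two_sided":
        p_obs = float(dist[support == t_obs][0]) if (support == t_obs).any() else 0.0
        p = float(dist[dist <= p_obs * _TWO_SIDED_SLACK].sum())
    else:
        raise ValueError(f"bad sidedness {sidedness!r}")
    try:
        or_mh = mantel_haenszel_or(counts_list)
    except ZeroCellError:
        or_mh = float("nan")
    return {"method": "cmh", "p_value": min(p, 1.0), "or_mh": or_mh}


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def _event_types(events) -> pd.Series:
    if isinstance(events, pd.DataFrame):
        return events["event_type"].astype(str)
    return pd.Series([ev.event_type for ev in events], dtype=str)


def burden_report(
    case_events,
    n_cases: int,
    control_events,
    n_controls: int,
    haldane: bool = False,
) -> dict:
    """Frequencies, OR and exact p-values, overall and per event type.

    ``case_events`` / ``control_events`` are event collections (lists of
    MosaicEvent or DataFrames with an ``event_type`` column); each sample
    is counted at most once per table (an individual either carries
    mosaicism or not).  With zero control events the OR is reported only
    through the explicit Haldane correction path (``haldane=True``),
    otherwise as None.
    """
    ct_case = _event_types(case_events)
    ct_ctrl = _event_types(control_events)

    def table(n_case_ev: int, n_ctrl_ev: int) -> dict:
        cc = CohortCounts(n_case_ev, n_cases - n_case_ev, n_ctrl_ev, n_controls - n_ctrl_ev)
        try:
            or_ = odds_ratio(cc, haldane=haldane)
        except ZeroCellError:
            or_ = None
        return {
            "counts": cc.as_tuple(),
            "case_frequency_pct": frequency(n_case_ev, n_cases),
            "control_frequency_pct": frequency(n_ctrl_ev, n_controls),
            "odds_ratio": or_,
            "p_one_sided": fisher_exact(cc, "one_sided_greater"),
            "p_two_sided": fisher_exact(cc, "two_sided"),
        }

    report = {"overall": table(len(ct_case), len(ct_ctrl)), "by_type": {}}
    for etype in sorted(set(ct_case) | set(ct_ctrl)):
        report["by_type"][etype] = table(
            int((ct_case == etype).sum()), int((ct_ctrl == etype).sum())
        )
    return report
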