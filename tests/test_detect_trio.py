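"""Trio phasing, signed-deviation detection, and trio-specific filters."""

import numpy as np
import pandas as pd
import pytest

from mosaicscan.core_io import PipelineConfig, TrioArray
from mosaicscan.detect_single import detect_sample
from mosaicscan.detect_trio import (
    detect_trio_events,
    filter_trio_events,
    phase_informative_sites,
)
from mosaicscan.filter_single import merge_segments
from mosaicscan.simulate import (
    EventSpec,
    NoiseModel,
    render_trio,
    simulate_probe_map,
    simulate_trio_genotypes,
)

from conftest import TWO_CHROM_GENOME, make_sample, overlaps

Mb = 1_000_000


def tiny_trio(gf, gm, gc, baf_c):
    n = len(gf)
    pos = list(range(1, n + 1))
    return TrioArray(
        child=make_sample("1", pos, list(gc), list(baf_c), role="child"),
        mother=make_sample("1", pos, list(gm), [0.5] * n, role="mother"),
        father=make_sample("1", pos, list(gf), [0.5] * n, role="father"),
    )


class TestPhasing:
    def test_obligate_het_orientation(self):
        trio = tiny_trio(["BB"], ["AA"], ["AB"], [0.58])
        sites = phase_informative_sites(trio)
        assert sites.config_class.iloc[0] == "obligate_het"
        assert sites.signed_dev.iloc[0] == pytest.approx(0.08)

    def test_obligate_het_mirrored_orientation(self):
        trio = tiny_trio(["AA"], ["BB"], ["AB"], [0.58])
        sites = phase_informative_sites(trio)
        # B allele is maternal here: excess B = maternal excess = negative
        assert sites.signed_dev.iloc[0] == pytest.approx(-0.08)

    def test_mendelian_inconsistency_classified_and_excluded(self):
        trio = tiny_trio(["AA"], ["AA"], ["AB"], [0.5])
        sites = phase_informative_sites(trio)
        assert sites.config_class.iloc[0] == "mendelian_inconsistent"
        assert np.isnan(sites.signed_dev.iloc[0])

    def test_both_het_sites_carry_no_signal(self):
        trio = tiny_trio(["AB"], ["AB"], ["AB"], [0.6])
        sites = phase_informative_sites(trio)
        assert sites.config_class.iloc[0] == "both_het"
        assert np.isnan(sites.signed_dev.iloc[0])

    def test_classes_from_parental_genotypes_only(self, probe_map, trio_genotypes):
        trio = render_trio(trio_genotypes, [], NoiseModel(), seed=2)
        sites = phase_informative_sites(trio)
        assert set(sites.config_class) <= {
            "father_het_mother_hom", "mother_het_father_hom", "obligate_het",
            "both_hom_same", "both_het", "mendelian_inconsistent",
        }
        # by construction the trio is Mendelian-consistent
        assert (sites.config_class == "mendelian_inconsistent").sum() == 0

    def test_gw_upd_mean_obligate_deviation(self, probe_map, trio_genotypes):
        events = [EventSpec(c, 1, 40 * Mb, "gw_upd", clonality=0.15,
                            affected_parent="paternal") for c in ("1", "2")]
        trio = render_trio(trio_genotypes, events, NoiseModel(), seed=3)
        sites = phase_informative_sites(trio)
        obl = sites[sites.config_class == "obligate_het"]
        assert obl.signed_dev.mean() == pytest.approx(0.075, abs=0.005)


class TestTrioDetection:
    def _paired(self, seed, clonality=0.15, het_sd=0.06):
        rng = np.random.default_rng(seed)
        pm = simulate_probe_map(10_000, TWO_CHROM_GENOME, rng)
        gt = simulate_trio_genotypes(pm, rng, genome=TWO_CHROM_GENOME)
        ev = EventSpec("1", 10 * Mb, 15 * Mb, "loss", clonality=clonality,
                       affected_parent="maternal")
        trio = render_trio(gt, [ev], NoiseModel(het_baf_sd=het_sd), rng)
        return trio, ev

    def test_low_clonality_loss_found_by_trio_missed_by_single(self):
        config = PipelineConfig()
        hits_trio = hits_single = 0
        for seed in range(5):
            trio, ev = self._paired(7000 + seed)
            trios = filter_trio_events(detect_trio_events(trio, config), trio, config)
            singles = [c for c in merge_segments(detect_sample(trio.child, config))
                       if c.size_bp >= config.min_event_size_bp]
            hits_trio += overlaps(trios, "1", ev.start, ev.end)
            hits_single += overlaps(singles, "1", ev.start, ev.end)
            if overlaps(trios, "1", ev.start, ev.end):
                seg = next(s for s in trios if s.chromosome == "1")
                assert seg.parental_excess == "paternal"  # maternal loss
        assert hits_trio >= 4
        assert hits_single <= 1

    def test_clean_trios_stay_silent(self):
        config = PipelineConfig()
        for seed in range(10):
            rng = np.random.default_rng(8000 + seed)
            pm = simulate_probe_map(8_000, TWO_CHROM_GENOME, rng)
            gt = simulate_trio_genotypes(pm, rng, genome=TWO_CHROM_GENOME)
            trio = render_trio(gt, [], NoiseModel(het_baf_sd=0.06), rng)
            assert filter_trio_events(detect_trio_events(trio, config), trio, config) == []

    def test_symmetric_miscalibration_invariance(self):
        # widening both BAF directions about 0.5 must not create calls
        config = PipelineConfig()
        rng = np.random.default_rng(99)
        pm = simulate_probe_map(8_000, TWO_CHROM_GENOME, rng)
        gt = simulate_trio_genotypes(pm, rng, genome=TWO_CHROM_GENOME)
        trio = render_trio(gt, [], NoiseModel(), rng)
        baf = trio.child.probes["baf"]
        trio.child.probes["baf"] = (0.5 + 1.3 * (baf - 0.5)).clip(0, 1)
        assert detect_trio_events(trio, config) == []


class TestTrioFilters:
    def _detected(self, seed=7001):
        trio, ev = TestTrioDetection()._paired(seed)
        config = PipelineConfig()
        segs = detect_trio_events(trio, config)
        assert segs
        return trio, config, segs

    def test_median_baf_window(self):
        trio, config, segs = self._detected()
        seg = segs[0]
        seg.median_upper_baf = 0.72
        assert filter_trio_events([seg], trio, config) == []
        seg.median_upper_baf = 0.50
        assert filter_trio_events([seg], trio, config) == []
        seg.median_upper_baf = float("nan")
        assert filter_trio_events([seg], trio, config) == []
        seg.median_upper_baf = 0.55
        assert filter_trio_events([seg], trio, config) == [seg]

    def test_undersized_event_dropped(self):
        trio, config, segs = self._detected()
        seg = segs[0]
        seg.end = seg.start + 1_500_000
        assert filter_trio_events([seg], trio, config) == []

    def test_parental_duplication_dropped_as_inherited(self, probe_map, trio_genotypes):
        config = PipelineConfig()
        dup_child = EventSpec("1", 10 * Mb, 16 * Mb, "constitutive_dup",
                              affected_parent="paternal", target="child")
        dup_father = EventSpec("1", 10 * Mb, 16 * Mb, "constitutive_dup",
                               affected_parent="paternal", target="father")
        trio = render_trio(trio_genotypes, [dup_child, dup_father], NoiseModel(), seed=5)
        from mosaicscan.detect_single import candidate_from_interval

        seg = candidate_from_interval(trio.child, "1", 10 * Mb, 16 * Mb, config, source="trio")
        seg.median_upper_baf = 0.66  # inside the window; inheritance must catch it
        assert filter_trio_events([seg], trio, config) == []
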