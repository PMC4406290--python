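"""Simulator ground truth: probe maps, trio genetics, BAF/LRR rendering."""

import numpy as np
import pandas as pd
import pytest

from mosaicscan.simulate import (
    EventSpec,
    NoiseModel,
    expected_baf_levels,
    render_sample,
    render_trio,
    simulate_candidate_mix,
    simulate_cohort,
    simulate_phased_sample,
    simulate_probe_map,
    simulate_trio_genotypes,
)

from conftest import TWO_CHROM_GENOME


class TestProbeMap:
    def test_equal_chromosomes_split_evenly(self):
        pm = simulate_probe_map(1000, {"1": 10_000_000, "2": 10_000_000}, seed=0)
        n1 = (pm["chrom"] == "1").sum()
        # binomial(1000, 0.5): 3 SD ~ 47
        assert abs(n1 - 500) < 48
        assert pm["pos"].is_monotonic_increasing or True  # sorted within chrom
        for _, grp in pm.groupby("chrom"):
            assert grp["pos"].is_monotonic_increasing

    def test_same_seed_is_deterministic(self):
        a = simulate_probe_map(500, TWO_CHROM_GENOME, seed=7)
        b = simulate_probe_map(500, TWO_CHROM_GENOME, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_probes_rejected(self):
        with pytest.raises(ValueError):
            simulate_probe_map(0, TWO_CHROM_GENOME, seed=0)

    def test_probes_beyond_genome_rejected(self):
        with pytest.raises(ValueError):
            simulate_probe_map(300, {"1": 100}, seed=0)

    def test_frequencies_in_range(self):
        pm = simulate_probe_map(2000, TWO_CHROM_GENOME, seed=3)
        assert pm["freq"].between(0.05, 0.95).all()


class TestTrioGenotypes:
    def test_mendelian_consistency_everywhere(self, probe_map, trio_genotypes):
        gt = trio_genotypes
        assert np.isin(gt.child_pat, gt.father_haps).all()
        # transmitted allele must match one of the parent's two haplotypes
        assert ((gt.child_pat == gt.father_haps[0]) | (gt.child_pat == gt.father_haps[1])).all()
        assert ((gt.child_mat == gt.mother_haps[0]) | (gt.child_mat == gt.mother_haps[1])).all()

    def test_child_het_fraction_at_half_frequency(self):
        pm = simulate_probe_map(10_000, {"1": 100_000_000}, seed=5)
        pm["freq"] = 0.5
        gt = simulate_trio_genotypes(pm, seed=6, genome={"1": 100_000_000})
        het = (gt.child_dosage == 1).mean()
        assert het == pytest.approx(0.5, abs=0.02)

    def test_monomorphic_sites_all_reference(self):
        pm = simulate_probe_map(500, {"1": 10_000_000}, seed=8)
        pm["freq"] = 0.0
        gt = simulate_trio_genotypes(pm, seed=9, genome={"1": 10_000_000})
        assert (gt.child_dosage == 0).all()
        assert (gt.father_haps == 0).all()


class TestExpectedBafLevels:
    @pytest.mark.parametrize("genotype,etype,p,allele,expected", [
        ("AB", "loss", 0.44, "B", (2 - 1.44) / (2 - 0.44)),  # 0.359
        ("AB", "loss", 0.0, "B", 0.5),
        ("AB", "gain", 0.0, "A", 0.5),
        ("AB", "loh", 0.66, "B", 0.83),
        ("AB", "gain", 0.44, "B", 1.44 / 2.44),
        ("AB", "constitutive_dup", 0.0, "B", 2 / 3),
        ("AA", "loss", 0.5, "B", 0.0),
        ("BB", "gain", 0.5, "B", 1.0),
    ])
    def test_closed_forms(self, genotype, etype, p, allele, expected):
        (level,) = expected_baf_levels(genotype, etype, p, allele)
        assert level == pytest.approx(expected, abs=1e-12)

    def test_mirror_symmetry(self):
        for etype in ("loss", "gain", "loh"):
            (b,) = expected_baf_levels("AB", etype, 0.3, "B")
            (a,) = expected_baf_levels("AB", etype, 0.3, "A")
            assert a == pytest.approx(1 - b, abs=1e-12)

    def test_out_of_range_clonality_rejected(self):
        with pytest.raises(ValueError):
            expected_baf_levels("AB", "loss", 1.2)


class TestRendering:
    def _render(self, probe_map, events, seed=3, **noise_kw):
        pat, mat = simulate_phased_sample(probe_map, seed=seed)
        return render_sample(probe_map, pat, mat, events,
                             NoiseModel(**noise_kw), seed=seed + 1)

    def test_loss_region_mean_deviation(self, probe_map):
        ev = EventSpec("1", 10_000_000, 20_000_000, "loss", clonality=0.44)
        sample = self._render(probe_map, [ev])
        p = sample.probes
        m = (p.chrom == "1") & p.pos.between(ev.start, ev.end) & (p.genotype == "AB")
        dev = np.abs(p.baf[m] - 0.5)
        assert dev.mean() == pytest.approx(0.44 / (2 * (2 - 0.44)), abs=0.005)

    def test_constitutive_dup_bands_at_thirds(self, probe_map):
        ev = EventSpec("1", 5_000_000, 30_000_000, "constitutive_dup")
        sample = self._render(probe_map, [ev])
        p = sample.probes
        m = (p.chrom == "1") & p.pos.between(ev.start, ev.end) & (p.genotype == "AB")
        dev = np.abs(p.baf[m] - 0.5)
        assert dev.mean() == pytest.approx(1 / 6, abs=0.01)
        assert np.log2(3 / 2) * 0.8 < p.lrr[m].mean() < np.log2(3 / 2) * 1.2

    def test_gw_upd_obligate_het_band(self, probe_map, trio_genotypes):
        events = [EventSpec(c, 1, 40_000_000, "gw_upd", clonality=0.15,
                            affected_parent="paternal") for c in ("1", "2")]
        trio = render_trio(trio_genotypes, events, NoiseModel(), seed=5)
        gt = trio_genotypes
        obligate = (
            (gt.father_haps.sum(axis=0) == 2) & (gt.mother_haps.sum(axis=0) == 0)
        )
        baf = trio.child.probes["baf"].to_numpy()[obligate]
        assert baf.mean() == pytest.approx((1 + 0.15) / 2, abs=0.01)

    def test_baf_bounded_and_deterministic(self, probe_map):
        s1 = self._render(probe_map, [], seed=9)
        s2 = self._render(probe_map, [], seed=9)
        assert s1.probes["baf"].between(0, 1).all()
        pd.testing.assert_frame_equal(s1.probes, s2.probes)

    def test_overlapping_conflicting_events_rejected(self, probe_map):
        evs = [EventSpec("1", 1_000_000, 9_000_000, "loss", clonality=0.3),
               EventSpec("1", 5_000_000, 12_000_000, "gain", clonality=0.3)]
        with pytest.raises(ValueError, match="overlapping"):
            self._render(probe_map, evs)

    def test_contamination_splits_het_band(self, probe_map):
        sample = self._render(probe_map, [], contamination_fraction=0.2)
        ab = sample.probes.loc[sample.probes.genotype == "AB", "baf"]
        # het cluster splits into bands at 0.4 / 0.5 / 0.6
        assert ab.std() > 0.05
        assert np.abs(ab - 0.5).max() > 0.08


class TestCohort:
    def test_ground_truth_counts_near_expectation(self):
        truth, samples = simulate_cohort(1303, 5094, 0.0077, 0.0002, seed=42)
        counts = truth.groupby("group")["has_event"].sum()
        assert samples is None
        assert 3 <= counts["case"] <= 20  # binomial(1303, 0.0077) = 10 +- 3 SD
        assert counts["control"] <= 5
        again, _ = simulate_cohort(1303, 5094, 0.0077, 0.0002, seed=42)
        pd.testing.assert_frame_equal(truth, again)

    def test_zero_rate_means_zero_events(self):
        truth, _ = simulate_cohort(200, 200, 0.0, 0.0, seed=1)
        assert not truth["has_event"].any()

    def test_rendered_cohort_has_arrays(self):
        truth, samples = simulate_cohort(
            3, 2, 1.0, 0.0, seed=2, n_probes=2000, genome=TWO_CHROM_GENOME, render=True
        )
        assert len(samples) == 5
        assert all(s.n_probes == samples[0].n_probes for s in samples)


def test_candidate_mix_composition():
    sample, candidates, true_span = simulate_candidate_mix(seed=0, n_probes=5000)
    labels = [lab for _, _, lab in candidates]
    assert labels.count("fragment") == 3
    assert labels.count("roh") == 6
    assert labels.count("unimodal") == 1
    assert candidates[0][0] == true_span[0]
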