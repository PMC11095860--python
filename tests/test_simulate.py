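"""Synthetic-cohort generator: planting guarantees, determinism, and
parameter recovery through the production callers."""

import dataclasses

import numpy as np
import pytest
from scipy import stats as sps

from icipair.acquired import summarize
from icipair.lineage import EventKey
from icipair.simulate import (
    SimConfig,
    SpatialConfig,
    default_gene_panel,
    simulate_cells,
    simulate_cohort,
    simulate_segments,
)
from icipair.spatial import engagement_fraction

STK11_FS = EventKey("STK11", "indel", "p.K78fs")


def tiny_config(**overrides):
    defaults = dict(
        n_patients=10,
        acquired_event_freqs={STK11_FS: 1.0},
        baseline_event_freqs={EventKey("KRAS", "SNV", "p.G12C"): 0.5},
        biallelic_freqs={},
        private_event_rate=1.0,
        spatial=None,
        hscore_n_patients=0,
        segment_noise_sd=0.0,
        seed=11,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


class TestConfigValidation:
    def test_therapy_mix_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SimConfig(therapy_mix={"ICI-mono": 0.5})

    def test_empty_therapy_mix_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(therapy_mix={})

    def test_probability_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            tiny_config(acquired_event_freqs={STK11_FS: 1.5})

    def test_purity_range_must_be_in_unit_interval(self):
        with pytest.raises(ValueError):
            SimConfig(purity_range=(0.0, 0.9))

    def test_engagement_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            SpatialConfig(target_engagement=1.2)


class TestPlanting:
    def test_probability_one_event_in_every_post_no_pre(self):
        cases, truth = simulate_cohort(tiny_config())
        for case in cases:
            assert STK11_FS in case.post.variant_keys
            assert STK11_FS not in case.pre.variant_keys
            assert str(STK11_FS) in truth.planted_acquired[case.patient_id]

    def test_probability_zero_plants_nothing(self):
        cases, truth = simulate_cohort(tiny_config(acquired_event_freqs={STK11_FS: 0.0}))
        assert all(not v for v in truth.planted_acquired.values())
        for case in cases:
            assert case.pre.variant_keys == case.post.variant_keys

    def test_baseline_events_in_both_samples(self):
        cases, truth = simulate_cohort(tiny_config())
        for case in cases:
            for text in truth.planted_baseline[case.patient_id]:
                key = EventKey.parse(text)
                assert key in case.pre.variant_keys
                assert key in case.post.variant_keys

    def test_planted_fraction_within_binomial_ci(self):
        """n=500 at the STK11 acquired-mutation rate: the planted count
        must sit inside the exact (Clopper-Pearson) 95% CI of 0.089."""
        freq = 0.089
        config = tiny_config(n_patients=500, acquired_event_freqs={STK11_FS: freq},
                             seed=202401)
        cases, _ = simulate_cohort(config)
        k = sum(STK11_FS in c.post.variant_keys for c in cases)
        lo, hi = sps.binomtest(k, 500).proportion_ci(0.95, method="exact")
        assert lo <= freq <= hi


class TestDeterminism:
    def test_same_seed_identical_cohort(self):
        config = SimConfig(n_patients=8, seed=99,
                           spatial=SpatialConfig(), spatial_n_patients=2)
        cases_a, truth_a = simulate_cohort(config)
        cases_b, truth_b = simulate_cohort(dataclasses.replace(config))
        assert truth_a.to_json() == truth_b.to_json()
        for a, b in zip(cases_a, cases_b):
            assert a.pre.variant_keys == b.pre.variant_keys
            assert a.post.variant_keys == b.post.variant_keys
            assert [s.log2_ratio for s in truth_a.segments[a.pre.sample_id]] == [
                s.log2_ratio for s in truth_b.segments[b.pre.sample_id]
            ]
        for sid in truth_a.cell_frames:
            assert truth_a.cell_frames[sid].cells.equals(truth_b.cell_frames[sid].cells)

    def test_different_seed_differs(self):
        a, _ = simulate_cohort(tiny_config(acquired_event_freqs={STK11_FS: 0.5}, seed=1))
        b, _ = simulate_cohort(tiny_config(acquired_event_freqs={STK11_FS: 0.5}, seed=2))
        assert any(
            x.post.variant_keys != y.post.variant_keys for x, y in zip(a, b)
        )


class TestSimulateSegments:
    def test_diploid_gives_zero_log2(self):
        panel = default_gene_panel()
        segs = simulate_segments({g: 2.0 for g in panel["gene"]}, 0.63, 0.0, panel)
        assert all(s.log2_ratio == pytest.approx(0.0, abs=1e-15) for s in segs)

    def test_hand_inverted_log2_for_acn6(self):
        panel = default_gene_panel().head(1)
        gene = panel["gene"].iloc[0]
        segs = simulate_segments({gene: 6.0}, 0.5, 0.0, panel)
        gene_seg = [s for s in segs if s.start == panel["start"].iloc[0]][0]
        assert gene_seg.log2_ratio == pytest.approx(1.0)

    def test_zero_acn_at_full_purity_infeasible(self):
        panel = default_gene_panel().head(1)
        with pytest.raises(ValueError):
            simulate_segments({panel["gene"].iloc[0]: 0.0}, 1.0, 0.0, panel)

    def test_segments_non_overlapping_and_sorted(self):
        panel = default_gene_panel()
        segs = simulate_segments({g: 2.0 for g in panel["gene"]}, 0.5, 0.0, panel)
        by_chrom = {}
        for s in segs:
            by_chrom.setdefault(s.chrom, []).append(s)
        for chrom_segs in by_chrom.values():
            for a, b in zip(chrom_segs, chrom_segs[1:]):
                assert a.end < b.start


class TestSimulateCells:
    def test_poisson_count_within_interval(self):
        config = SpatialConfig(area_mm2=1.0, density={"tumor": 100.0},
                               target_engagement=0.0)
        frame, _ = simulate_cells(config, seed=4)
        lo, hi = sps.poisson(100.0).ppf([0.005, 0.995])
        assert lo <= len(frame.cells) <= hi

    def test_target_engagement_zero_exact(self):
        config = SpatialConfig(target_engagement=0.0)
        frame, truth = simulate_cells(config, seed=5)
        measured = engagement_fraction(frame)
        assert truth["engagement"] == 0.0
        assert measured.fraction == 0.0

    def test_target_engagement_one_exact(self):
        config = SpatialConfig(target_engagement=1.0)
        frame, truth = simulate_cells(config, seed=6)
        measured = engagement_fraction(frame)
        assert truth["engagement"] == 1.0
        assert measured.fraction == 1.0

    @pytest.mark.parametrize("target", [0.1, 0.3, 0.62])
    def test_realized_engagement_matches_truth_exactly(self, target):
        config = SpatialConfig(target_engagement=target)
        frame, truth = simulate_cells(config, seed=7)
        measured = engagement_fraction(frame)
        assert measured.fraction == truth["engagement"]
        n = measured.n_pdl1
        assert truth["engagement"] == round(target * n) / n

    def test_thomas_process_runs(self):
        config = SpatialConfig(process="thomas", target_engagement=0.2)
        frame, truth = simulate_cells(config, seed=8)
        assert engagement_fraction(frame).fraction == truth["engagement"]

    def test_coordinates_rounded_to_two_decimals(self):
        frame, _ = simulate_cells(SpatialConfig(), seed=9)
        xy = frame.cells[["x", "y"]].to_numpy()
        assert np.allclose(xy, np.round(xy, 2))


class TestRecoveryThroughCallers:
    def test_acquired_frequencies_recovered_joint_ci(self):
        """summarize() on a 500-patient cohort recovers every planted
        acquired frequency: each configured rate lies inside the
        Sidak-adjusted exact binomial CI of its called count (family
        coverage 95% across all planted events)."""
        config = SimConfig(n_patients=500, spatial=None, hscore_n_patients=0,
                           private_event_rate=0.0, seed=314159)
        cases, truth = simulate_cohort(config)
        summary = summarize(cases)
        table = summary["gene_table"].set_index(["gene", "finding_type"])

        finding_for = {"loss": "heterozygous-loss", "deletion": "homozygous-deletion",
                       "amplification": "amplification"}
        events = dict(config.acquired_event_freqs)
        level = 0.95 ** (1.0 / len(events))  # Sidak per-event confidence
        deletion_freq = {
            e.gene: f for e, f in events.items()
            if e.event_class == "CNA" and e.detail == "deletion"
        }
        n = config.n_patients
        for event, freq in events.items():
            if event.event_class == "CNA":
                key = (event.gene, finding_for[event.detail])
            else:
                key = (event.gene, "mutation")
            k = int(table.loc[key, "n_patients"]) if key in table.index else 0
            lo, hi = sps.binomtest(k, n).proportion_ci(level, method="exact")
            # biallelic planting adds to the per-gene rate for knob genes
            extra = config.biallelic_freqs.get(event.gene, 0.0)
            if event.event_class == "CNA" and event.detail == "loss":
                expected = 1.0 - (1.0 - freq) * (1.0 - extra)
                # a concurrent homozygous deletion supersedes the loss
                expected *= 1.0 - deletion_freq.get(event.gene, 0.0)
            elif event.event_class != "CNA" and event.gene in config.biallelic_freqs:
                expected = 1.0 - (1.0 - freq) * (1.0 - extra)
            else:
                expected = freq
            assert lo <= expected <= hi, (event, k / n, expected)

    def test_true_acn_recovered_exactly_at_zero_noise(self):
        config = SimConfig(n_patients=12, segment_noise_sd=0.0, spatial=None,
                           hscore_n_patients=0, seed=77)
        cases, truth = simulate_cohort(config)
        for case in cases:
            for profile in (case.pre, case.post):
                called = {c.gene: c.acn_raw for c in profile.acn_calls}
                for gene, acn in truth.true_acn[profile.sample_id].items():
                    assert called[gene] == pytest.approx(acn, abs=1e-9)

    def test_hscore_shift_reflected_in_medians(self):
        config = SimConfig(n_patients=40, spatial=None, hscore_n_patients=40,
                           hscore_noise_sd=5.0, seed=21)
        _, truth = simulate_cohort(config)
        pre = np.array([v[0] for v in truth.hscores.values()])
        post = np.array([v[1] for v in truth.hscores.values()])
        # shift -70 with clipping at 300: median change within noise of -70
        assert np.median(post - pre) == pytest.approx(-70.0, abs=15.0)
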