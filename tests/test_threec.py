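"""3C interaction profiles, distance-decay background, loop calling."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from loop3c.errors import (
    InsufficientDataError,
    InvalidInputError,
    InvalidStandardsError,
    MissingNormalizerError,
    UnmappedAssayError,
)
from loop3c.simulate import load_preset, simulate_3c_plates
from loop3c.threec import (
    InteractionPoint,
    InteractionProfile,
    build_profile,
    call_loops,
    combine_profiles,
    fit_background,
    fold_enrichments,
    interaction_frequency,
    library_concentration,
)


class TestInteractionFrequency:
    def test_equal_cq_gives_unit_frequency(self):
        p = interaction_frequency([25.0, 25.0], [25.0])
        assert p.rel_frequency == pytest.approx(1.0)
        assert p.n == 2

    def test_three_cycles_later_is_one_eighth(self):
        p = interaction_frequency([28.0], [25.0])
        assert p.rel_frequency == pytest.approx(0.125)

    def test_missing_normalizer_rejected(self):
        with pytest.raises(MissingNormalizerError):
            interaction_frequency([25.0], [])

    def test_replicate_sd_recorded(self):
        p = interaction_frequency([24.0, 25.0, 26.0], [25.0])
        assert p.sd > 0
        assert p.n == 3


class TestBuildProfile:
    def test_seven_anchor_plate_gives_ordered_seven_point_profile(
        self, pc3m_scenario, pc3m_locus
    ):
        plates = simulate_3c_plates(pc3m_scenario, pc3m_locus, seed=3)
        prof = build_profile(
            plates.plate, pc3m_locus.locus, plates.library_id, pc3m_locus.anchor_map
        )
        assert len(prof.points) == 7
        d = [p.tss_distance_kb for p in prof.points]
        assert d == sorted(d)
        assert all(p.n == pc3m_scenario.replicates for p in prof.points)

    def test_empty_plate_rejected(self, pc3m_locus):
        with pytest.raises(InvalidInputError):
            build_profile(
                pd.DataFrame(columns=["sample", "assay", "replicate", "cq"]),
                pc3m_locus.locus,
                "lib",
                pc3m_locus.anchor_map,
            )

    def test_unmapped_assay_rejected_by_name(self, pc3m_scenario, pc3m_locus):
        plates = simulate_3c_plates(pc3m_scenario, pc3m_locus, seed=3)
        plate = plates.plate.copy()
        plate.loc[plate.index[-1], "assay"] = "mystery_assay"
        with pytest.raises(UnmappedAssayError, match="mystery_assay"):
            build_profile(plate, pc3m_locus.locus, plates.library_id, pc3m_locus.anchor_map)

    def test_global_cq_shift_leaves_profile_unchanged(self, pc3m_scenario, pc3m_locus):
        plates = simulate_3c_plates(pc3m_scenario, pc3m_locus, seed=9)
        prof1 = build_profile(
            plates.plate, pc3m_locus.locus, plates.library_id, pc3m_locus.anchor_map
        )
        shifted = plates.plate.copy()
        shifted["cq"] = shifted["cq"] + 3.21
        prof2 = build_profile(
            shifted, pc3m_locus.locus, plates.library_id, pc3m_locus.anchor_map
        )
        for a, b in zip(prof1.points, prof2.points):
            assert b.rel_frequency == pytest.approx(a.rel_frequency, rel=1e-12)

    def test_two_libraries_concord_on_log_scale(self, pc3m_scenario, pc3m_locus):
        profs = []
        for seed in (101, 202):
            plates = simulate_3c_plates(pc3m_scenario, pc3m_locus, seed=seed)
            profs.append(
                build_profile(
                    plates.plate, pc3m_locus.locus, plates.library_id, pc3m_locus.anchor_map
                )
            )
        ratios = [
            math.log(a.rel_frequency / b.rel_frequency)
            for a, b in zip(profs[0].points, profs[1].points)
        ]
        assert abs(np.mean(ratios)) < 0.3
        combined = combine_profiles(profs)
        assert len(combined.points) == 7


def _profile_on_curve(a=2.0, b=1.2, dists=(-80.0, -60.0, -30.0, -7.0, 45.0, 70.0, 120.0)):
    points = [
        InteractionPoint(
            fragment_id=i,
            tss_distance_kb=d,
            rel_frequency=a * abs(d) ** -b,
            sd=0.0,
            n=3,
        )
        for i, d in enumerate(sorted(dists))
    ]
    return InteractionProfile(points=points, bait_fragment_id=999)


class TestFitBackground:
    def test_noiseless_powerlaw_recovered_exactly(self):
        bg = fit_background(_profile_on_curve(a=2.0, b=1.2))
        assert bg.b == pytest.approx(1.2, abs=1e-9)
        assert math.exp(bg.log_a) == pytest.approx(2.0, rel=1e-9)
        assert bg.excluded_fragments == ()

    def test_background_positive_everywhere(self):
        bg = fit_background(_profile_on_curve())
        for d in (0.5, 5.0, 50.0, 500.0):
            assert bg.predict(d) > 0
            assert bg.predict(-d) == bg.predict(d)

    def test_too_few_points_rejected(self):
        prof = InteractionProfile(
            points=[
                InteractionPoint(i, d, 1.0, 0.0, 1)
                for i, d in enumerate([-10.0, 5.0, 20.0])
            ],
            bait_fragment_id=99,
        )
        with pytest.raises(InsufficientDataError):
            fit_background(prof)

    def test_rising_signal_falls_back_to_flat_background(self):
        points = [
            InteractionPoint(i, d, 0.1 * abs(d) ** 0.8, 0.0, 1)
            for i, d in enumerate([-80.0, -40.0, -10.0, 40.0, 90.0])
        ]
        bg = fit_background(InteractionProfile(points=points, bait_fragment_id=99))
        assert bg.flat
        assert bg.predict(10.0) == bg.predict(100.0)

    def test_loops_excluded_from_pc3m_fit(self, pc3m_scenario, pc3m_locus):
        """Iterative exclusion removes the planted loops from the background
        in at least 90% of seeds."""
        loop_ids = {
            pc3m_locus.fragment_for_anchor(-63.2),
            pc3m_locus.fragment_for_anchor(48.4),
        }
        hits = 0
        n_seeds = 100
        for seed in range(1, n_seeds + 1):
            plates = simulate_3c_plates(pc3m_scenario, pc3m_locus, seed=seed)
            prof = build_profile(
                plates.plate, pc3m_locus.locus, plates.library_id, pc3m_locus.anchor_map
            )
            bg = fit_background(prof)
            hits += loop_ids <= set(bg.excluded_fragments)
        assert hits >= 0.9 * n_seeds

    def test_no_exclusions_on_loopless_profiles(self, fibroblast_scenario, fibroblast_locus):
        clean = 0
        n_seeds = 100
        for seed in range(1, n_seeds + 1):
            plates = simulate_3c_plates(fibroblast_scenario, fibroblast_locus, seed=seed)
            prof = build_profile(
                plates.plate,
                fibroblast_locus.locus,
                plates.library_id,
                fibroblast_locus.anchor_map,
            )
            if not fit_background(prof).excluded_fragments:
                clean += 1
        assert clean >= 0.9 * n_seeds

    def test_decay_exponent_recovered_within_ten_percent(
        self, fibroblast_scenario, fibroblast_locus
    ):
        bs = []
        for seed in range(1, 21):
            plates = simulate_3c_plates(fibroblast_scenario, fibroblast_locus, seed=seed)
            prof = build_profile(
                plates.plate,
                fibroblast_locus.locus,
                plates.library_id,
                fibroblast_locus.anchor_map,
            )
            bs.append(fit_background(prof).b)
        truth = fibroblast_scenario.decay.b
        assert np.mean(bs) == pytest.approx(truth, rel=0.10)


class TestFoldsAndCalls:
    def test_signal_equal_to_background_gives_unit_folds(self):
        prof = _profile_on_curve(a=3.0, b=0.9)
        bg = fit_background(prof)
        calls = fold_enrichments(prof, bg)
        for c in calls:
            assert c.fold_over_background == pytest.approx(1.0, rel=1e-9)
        called = call_loops(calls)
        assert not any(c.is_peak for c in called)

    def test_proximal_reference_is_nearest_fragment_when_window_empty(self):
        prof = _profile_on_curve()
        bg = fit_background(prof)
        calls = fold_enrichments(prof, bg, proximal_window_kb=4.0)
        proximal = min(prof.points, key=lambda p: abs(p.tss_distance_kb))
        assert all(c.proximal_fragment_id == proximal.fragment_id for c in calls)
        assert prof.point(proximal.fragment_id)  # proximal itself has fold 1
        prox_call = [c for c in calls if c.fragment_id == proximal.fragment_id][0]
        assert prox_call.fold_over_proximal == pytest.approx(1.0)

    def test_noiseless_pc3m_recovers_loop_folds_exactly(self, pc3m_scenario, pc3m_locus):
        scn = replace(pc3m_scenario, cq_noise_sd_3c=0.0)
        plates = simulate_3c_plates(scn, pc3m_locus, seed=1)
        prof = build_profile(
            plates.plate, pc3m_locus.locus, plates.library_id, pc3m_locus.anchor_map
        )
        bg = fit_background(prof)
        calls = {c.fragment_id: c for c in fold_enrichments(prof, bg)}
        f63 = calls[pc3m_locus.fragment_for_anchor(-63.2)]
        f48 = calls[pc3m_locus.fragment_for_anchor(48.4)]
        assert f63.fold_over_background == pytest.approx(9.0, rel=1e-9)
        assert f48.fold_over_background == pytest.approx(6.0, rel=1e-9)

    def test_loop_caller_sensitivity_on_pc3m_seeds(self, pc3m_scenario, pc3m_locus):
        """Both planted loops recovered in >= 95% of 200 seeds."""
        loop_ids = {
            pc3m_locus.fragment_for_anchor(-63.2),
            pc3m_locus.fragment_for_anchor(48.4),
        }
        hits = 0
        n_seeds = 200
        for seed in range(1, n_seeds + 1):
            plates = simulate_3c_plates(pc3m_scenario, pc3m_locus, seed=seed)
            prof = build_profile(
                plates.plate, pc3m_locus.locus, plates.library_id, pc3m_locus.anchor_map
            )
            calls = call_loops(fold_enrichments(prof, fit_background(prof)))
            if {c.fragment_id for c in calls if c.is_peak} == loop_ids:
                hits += 1
        assert hits >= 0.95 * n_seeds


class TestLibraryConcentration:
    def test_exact_dilution_series_interpolates(self):
        est = library_concentration(21.66095, [(100.0, 20.0), (10.0, 23.3219)])
        assert est.ng == pytest.approx(31.6228, rel=1e-4)
        assert not est.extrapolated

    def test_unknown_at_standard_returns_standard(self):
        est = library_concentration(20.0, [(100.0, 20.0), (10.0, 23.3219)])
        assert est.ng == pytest.approx(100.0, rel=1e-9)

    def test_out_of_range_flagged_as_extrapolated(self):
        est = library_concentration(25.0, [(100.0, 20.0), (10.0, 23.3219)])
        assert est.extrapolated

    def test_equal_standards_rejected(self):
        with pytest.raises(InvalidStandardsError):
            library_concentration(21.0, [(50.0, 20.0), (50.0, 21.0)])
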