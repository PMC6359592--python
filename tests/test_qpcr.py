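"""Cq arithmetic: relative quantities, digestion QC, ddCt expression."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from loop3c.errors import InsufficientReplicatesError, InvalidInputError
from loop3c.qpcr import (
    TWO_TIER_STAR_THRESHOLDS,
    delta_delta_ct,
    digestion_efficiency,
    expression_results,
    qc_digestion,
    relative_quantity,
    significance_stars,
)
from loop3c.simulate import load_preset, simulate_expression_plates


class TestRelativeQuantity:
    @pytest.mark.parametrize(
        "cq, eff, expected",
        [
            (0.0, 1.0, 1.0),
            (1.0, 1.0, 0.5),
            (10.0, 0.9, 1.9**-10),
        ],
    )
    def test_closed_form(self, cq, eff, expected):
        assert relative_quantity(cq, eff) == pytest.approx(expected, rel=1e-12)

    def test_monotone_decreasing_in_cq(self):
        qs = [relative_quantity(cq, 0.95) for cq in np.linspace(0, 40, 30)]
        assert all(b < a for a, b in zip(qs, qs[1:]))

    @pytest.mark.parametrize("eff", [0.0, -0.5, 1.5])
    def test_invalid_efficiency_rejected(self, eff):
        with pytest.raises(InvalidInputError):
            relative_quantity(20.0, eff)


class TestDigestionEfficiency:
    @pytest.mark.parametrize(
        "ddcq, expected",
        [(0.0, 0.0), (1.0, 50.0), (math.log2(10.0), 90.0)],
    )
    def test_closed_form(self, ddcq, expected):
        eff = digestion_efficiency(24.0 + ddcq, 24.0, 24.0, 24.0)
        assert eff == pytest.approx(expected, abs=1e-9)

    def test_monotone_increasing_in_ddcq(self):
        effs = [
            digestion_efficiency(24.0 + d, 24.0, 24.0, 24.0)
            for d in np.linspace(-2, 8, 40)
        ]
        assert all(b > a for a, b in zip(effs, effs[1:]))
        assert max(effs) <= 100.0

    def test_library_qc_pass_and_fail(self):
        assert qc_digestion({"s1": 90.0, "s2": 92.0, "s3": 88.0}, 85.0).passed
        report = qc_digestion({"s1": 90.0, "s2": 80.0}, 85.0)
        assert not report.passed
        assert report.failing_sites == ("s2",)

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidInputError):
            qc_digestion({}, 85.0)


class TestSignificanceStars:
    @pytest.mark.parametrize(
        "p, stars",
        [(0.0005, "***"), (0.005, "**"), (0.03, "*"), (0.05, "ns"), (0.2, "ns")],
    )
    def test_three_tier_scheme(self, p, stars):
        assert significance_stars(p) == stars

    def test_two_tier_scheme(self):
        assert significance_stars(0.01, TWO_TIER_STAR_THRESHOLDS) == "*"
        assert significance_stars(0.0005, TWO_TIER_STAR_THRESHOLDS) == "**"

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            significance_stars(1.5)


def _plate(rows):
    return pd.DataFrame(rows, columns=["sample", "assay", "replicate", "cq"])


def _noiseless_plate(fold, n=3):
    """Test and calibrator samples where the target differs by log2(fold)."""
    rows = []
    for rep in range(1, n + 1):
        rows += [
            ("cal", "T", rep, 26.0),
            ("cal", "R", rep, 20.0),
            ("test", "T", rep, 26.0 - math.log2(fold)),
            ("test", "R", rep, 20.0),
        ]
    return _plate(rows)


class TestDeltaDeltaCt:
    def test_equal_delta_cq_gives_fold_one(self):
        r = delta_delta_ct(_noiseless_plate(1.0), "T", "R", "test", "cal")
        assert r.fold_change == pytest.approx(1.0, rel=1e-12)

    def test_two_doublings_gives_fold_four(self):
        r = delta_delta_ct(_noiseless_plate(4.0), "T", "R", "test", "cal")
        assert r.fold_change == pytest.approx(4.0, rel=1e-12)
        assert r.delta_delta_cq == pytest.approx(-2.0, abs=1e-12)

    def test_ci_brackets_fold_and_stars_match_p(self):
        rng = np.random.default_rng(7)
        plate = _noiseless_plate(4.0)
        plate["cq"] = plate["cq"] + rng.normal(0, 0.1, len(plate))
        r = delta_delta_ct(plate, "T", "R", "test", "cal")
        assert r.ci_low <= r.fold_change <= r.ci_high
        assert r.stars == significance_stars(r.p_value)

    def test_global_cq_shift_leaves_fold_unchanged(self):
        rng = np.random.default_rng(11)
        plate = _noiseless_plate(3.0)
        plate["cq"] = plate["cq"] + rng.normal(0, 0.2, len(plate))
        r1 = delta_delta_ct(plate, "T", "R", "test", "cal")
        shifted = plate.copy()
        shifted["cq"] = shifted["cq"] + 5.4321
        r2 = delta_delta_ct(shifted, "T", "R", "test", "cal")
        assert r2.fold_change == pytest.approx(r1.fold_change, rel=1e-12)

    def test_missing_sample_rejected(self):
        with pytest.raises(InvalidInputError):
            delta_delta_ct(_noiseless_plate(2.0), "T", "R", "absent", "cal")

    def test_single_replicate_rejected(self):
        plate = _plate(
            [("cal", "T", 1, 26.0), ("cal", "R", 1, 20.0),
             ("test", "T", 1, 25.0), ("test", "R", 1, 20.0)]
        )
        with pytest.raises(InsufficientReplicatesError):
            delta_delta_ct(plate, "T", "R", "test", "cal")

    def test_geometric_mean_reference_mode(self):
        plate = pd.concat(
            [
                _noiseless_plate(4.0),
                _plate(
                    [("cal", "R2", rep, 22.0) for rep in (1, 2, 3)]
                    + [("test", "R2", rep, 22.0) for rep in (1, 2, 3)]
                ),
            ],
            ignore_index=True,
        )
        (r,) = expression_results(
            plate, "T", ["R", "R2"], ["test"], "cal", combine_references=True
        )
        assert r.reference_gene == "R+R2"
        assert r.fold_change == pytest.approx(4.0, rel=1e-12)


class TestGeneratorRoundTrip:
    def test_noiseless_plates_recover_folds_exactly(self):
        scn = replace(load_preset("pc3m"), cq_noise_sd_expression=0.0)
        plate, truth = simulate_expression_plates(scn, seed=5)
        for _, row in truth.iterrows():
            r = delta_delta_ct(
                plate, "PTBP3", row["reference_gene"], row["sample"], "fibroblast"
            )
            assert r.fold_change == pytest.approx(row["true_fold"], rel=1e-9)

    def test_null_fold_scenario_reports_ns(self):
        scn = load_preset("null")
        ns = 0
        n_seeds = 50
        for seed in range(1, n_seeds + 1):
            plate, _ = simulate_expression_plates(scn, seed=seed)
            r = delta_delta_ct(plate, "PTBP3", "GAPDH", "null_sample", "fibroblast")
            ns += r.stars == "ns"
        assert ns >= 0.9 * n_seeds
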