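import numpy as np
import pandas as pd
import pytest

import lesionmap as lm
from lesionmap.damage import CalibrationError, reconstruct_table


class TestPercentDamage:
    def test_containment_and_disjoint(self, grid64):
        region = lm.sphere_roi((-20, 0, 0), 8.0, grid64)
        superset = lm.sphere_roi((-20, 0, 0), 14.0, grid64).mask
        far = lm.sphere_roi((30, 20, 20), 8.0, grid64).mask
        assert lm.percent_damage(superset, region) == 100.0
        assert lm.percent_damage(far, region) == 0.0

    def test_exact_half(self, grid16):
        region_data = np.zeros(grid16.shape, bool)
        region_data[0, 0, :8] = True
        lesion_data = np.zeros(grid16.shape, bool)
        lesion_data[0, 0, :4] = True
        region = lm.Region("r", lm.BinaryVolume(grid16, region_data))
        assert lm.percent_damage(lm.BinaryVolume(grid16, lesion_data), region) == 50.0

    def test_empty_region_rejected(self, grid16):
        empty = lm.Region("e", lm.BinaryVolume(grid16, np.zeros(grid16.shape, bool)))
        lesion = lm.BinaryVolume(grid16, np.ones(grid16.shape, bool))
        with pytest.raises(ValueError):
            lm.percent_damage(lesion, empty)

    def test_monotone_under_lesion_growth(self, grid64, rng):
        region = lm.sphere_roi((-20, 0, 0), 10.0, grid64)
        small = lm.sphere_roi((-24, 2, 0), 6.0, grid64).mask
        big = lm.BinaryVolume(grid64, small.data | lm.sphere_roi((-20, 0, 0), 9.0, grid64).mask.data)
        assert lm.percent_damage(big, region) >= lm.percent_damage(small, region)


class TestBinarize:
    def test_inclusive_threshold(self):
        out = lm.binarize_damage([80.0, 79.9, 100.0, 0.0], 80.0)
        assert out.tolist() == [True, False, True, False]

    def test_threshold_100_requires_complete_destruction(self):
        assert lm.binarize_damage([99.9, 100.0], 100.0).tolist() == [False, True]

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            lm.binarize_damage([50.0], 0.0)


class TestRegionSetPositive:
    def _profile(self):
        rows = []
        # partitions: both, smg-only, pop-only, neither
        data = {
            "p_both": (90.0, 85.0), "p_smg": (90.0, 10.0),
            "p_pop": (10.0, 95.0), "p_none": (10.0, 20.0),
        }
        for pid, (smg, pop) in data.items():
            rows.append({"patient": pid, "region": "smg", "percent_damage": smg})
            rows.append({"patient": pid, "region": "pop", "percent_damage": pop})
        return lm.DamageProfile(pd.DataFrame(rows))

    def test_disjunction_over_regions(self):
        profile = self._profile()
        pos = lm.region_set_positive(
            profile, ["smg", "pop"], {"smg": 80.0, "pop": 80.0},
            ["p_both", "p_smg", "p_pop", "p_none"],
        )
        assert pos.tolist() == [True, True, True, False]

    def test_partition_counts_sum_to_positive_total(self):
        profile = self._profile()
        ids = ["p_both", "p_smg", "p_pop", "p_none"]
        thr = {"smg": 80.0, "pop": 80.0}
        smg = lm.binarize_damage(profile.percent("smg", ids), 80.0)
        pop = lm.binarize_damage(profile.percent("pop", ids), 80.0)
        any_pos = lm.region_set_positive(profile, ["smg", "pop"], thr, ids)
        both = (smg & pop).sum()
        smg_only = (smg & ~pop).sum()
        pop_only = (pop & ~smg).sum()
        assert both + smg_only + pop_only == any_pos.sum()


class TestClassificationReport:
    def test_published_accuracy_of_seed_spheres(self):
        # 40/54 impaired with damage, 21/100 impaired without
        rep = lm.classification_report(
            [True] * 54 + [False] * 100,
            [True] * 40 + [False] * 14 + [True] * 21 + [False] * 79,
            80.0,
        )
        assert round(rep.odds_ratio, 1) == 10.7
        assert round(rep.ppv) == 74
        assert round(rep.npv) == 79

    def test_published_accuracy_of_guided_regions(self):
        rep = lm.classification_report(
            [True] * 54 + [False] * 100,
            [True] * 46 + [False] * 8 + [True] * 15 + [False] * 85,
        )
        assert round(rep.odds_ratio, 1) == 32.6

    def test_zero_cell_gives_undefined_odds_ratio(self):
        rep = lm.classification_report([True, True, False, False],
                                       [True, True, True, False])
        assert rep.table.b == 0
        assert rep.odds_ratio is None
        assert rep.table.odds_ratio(haldane=True) > 0

    def test_odds_identity_on_random_tables(self, rng):
        for _ in range(200):
            a, b, c, d = rng.integers(1, 40, 4)
            rep = lm.ClassificationReport(80.0, lm.ContingencyTable2x2(a, b, c, d))
            ppv_odds = rep.ppv / (100.0 - rep.ppv)
            npv_odds = rep.npv / (100.0 - rep.npv)
            assert rep.odds_ratio == pytest.approx(ppv_odds * npv_odds, abs=1e-9)

    def test_label_swap_inverts_odds_ratio(self, rng):
        pos = rng.random(60) < 0.4
        imp = rng.random(60) < 0.5
        r1 = lm.classification_report(pos, imp)
        r2 = lm.classification_report(pos, ~imp)
        if r1.odds_ratio and r2.odds_ratio:
            assert r2.odds_ratio == pytest.approx(1.0 / r1.odds_ratio)

    def test_prevalence_invariance_of_sens_spec_only(self):
        pos = np.array([True] * 10 + [False] * 10)
        imp = np.array([True] * 8 + [False] * 2 + [True] * 3 + [False] * 7)
        base = lm.classification_report(pos, imp)
        # duplicate every negative patient: prevalence drops
        pos2 = np.concatenate([pos, pos[~imp]])
        imp2 = np.concatenate([imp, imp[~imp]])
        shifted = lm.classification_report(pos2, imp2)
        assert shifted.sensitivity == pytest.approx(base.sensitivity)
        assert shifted.specificity == pytest.approx(base.specificity)
        assert shifted.ppv != pytest.approx(base.ppv)
        assert shifted.npv != pytest.approx(base.npv)


class TestCalibration:
    def test_picks_highest_odds_ratio(self, rng):
        pct = np.concatenate([rng.uniform(80, 100, 30), rng.uniform(0, 75, 50)])
        impaired = np.concatenate([rng.random(30) < 0.9, rng.random(50) < 0.1])
        thr, reports = lm.calibrate_threshold(pct, impaired)
        best = reports[thr].odds_ratio
        for rep in reports.values():
            if rep.odds_ratio is not None:
                assert best >= rep.odds_ratio

    def test_undefined_or_ranks_below_defined(self):
        # at threshold 100 nobody is positive among the spared -> zero cell
        pct = np.array([100.0, 100.0, 85.0, 85.0, 50.0, 40.0, 30.0, 20.0])
        imp = np.array([True, True, True, False, False, False, True, False])
        thr, reports = lm.calibrate_threshold(pct, imp, grid=(80.0, 100.0))
        assert reports[100.0].odds_ratio is None
        assert thr == 80.0

    def test_tie_breaks_to_higher_threshold(self):
        # thresholds 70 and 80 classify identically here
        pct = np.array([90.0, 90.0, 60.0, 60.0, 10.0, 10.0])
        imp = np.array([True, False, True, False, True, False])
        thr, reports = lm.calibrate_threshold(pct, imp, grid=(70.0, 80.0))
        assert reports[70.0].table == reports[80.0].table
        assert thr == 80.0

    def test_all_undefined_is_failure_with_reports(self):
        pct = np.array([90.0, 90.0, 10.0, 10.0])
        imp = np.array([True, True, False, False])  # perfect separation
        with pytest.raises(CalibrationError) as exc:
            lm.calibrate_threshold(pct, imp, grid=(80.0,))
        assert 80.0 in exc.value.reports

    def test_needs_two_patients_per_class(self):
        with pytest.raises(ValueError):
            lm.calibrate_threshold([90.0, 10.0], [True, False])


class TestReconstruction:
    def test_validation_sample_guided_regions(self):
        # n=108, 40 impaired; printed PPV 64, NPV 94, Sens 93, Spec 69
        t = reconstruct_table(108, 64, 94, 93, 69, n_impaired=40)
        assert (t.a, t.b, t.c, t.d) == (37, 21, 3, 47)
        assert round(t.odds_ratio(), 1) == 27.6

    def test_discovery_sample_guided_plus_vlsm(self):
        # n=154, 61 impaired; printed PPV 83, NPV 91, Sens 87, Spec 88
        t = reconstruct_table(154, 83, 91, 87, 88, n_impaired=61)
        assert (t.a, t.b, t.c, t.d) == (53, 11, 8, 82)
        assert round(t.odds_ratio(), 1) == 49.4

    def test_no_match_raises(self):
        with pytest.raises(ValueError):
            reconstruct_table(10, 99, 99, 1, 1)


class TestProfileIO:
    def test_csv_round_trip(self, tmp_path):
        rows = pd.DataFrame(
            {"patient": ["p1", "p1"], "region": ["a", "b"], "percent_damage": [50.0, 75.0]}
        )
        profile = lm.DamageProfile(rows)
        path = tmp_path / "damage.csv"
        profile.to_csv(path)
        back = lm.DamageProfile.from_csv(path)
        assert back.percent("b", ["p1"]).tolist() == [75.0]

    def test_out_of_range_rejected(self):
        rows = pd.DataFrame({"patient": ["x"], "region": ["r"], "percent_damage": [105.0]})
        with pytest.raises(ValueError):
            lm.DamageProfile(rows)
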