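import numpy as np
import pandas as pd
import pytest

from rilimet import (SimConfig, cross_tissue_corr, differential_screen,
                     intersect_tissues, normalize, qc_filter,
                     run_panel_cascade, select_panel, simulate_cohort,
                     trajectories, triage_evaluate, triage_map,
                     union_differential, vip_screen)
from rilimet.stats import DiffResult

from conftest import make_table


def _diff_from_sets(sig, universe):
    frame = pd.DataFrame(
        {"statistic": 1.0, "p": [0.001 if m in sig else 0.9
                                 for m in universe],
         "q": [0.01 if m in sig else 0.9 for m in universe],
         "log2fc": 1.0, "direction": 1,
         "significant": [m in sig for m in universe]},
        index=pd.Index(universe, name="metabolite_id"))
    return DiffResult(contrast="synthetic", frame=frame)


class TestSetStages:
    def test_union_over_days(self):
        u = ["A", "B", "C", "D"]
        res = union_differential([_diff_from_sets({"A", "B"}, u),
                                  _diff_from_sets({"B", "C"}, u)])
        assert res == {"A", "B", "C"}

    def test_single_day_identity(self):
        u = ["A", "B"]
        assert union_differential([_diff_from_sets({"A"}, u)]) == {"A"}

    def test_intersection(self):
        assert intersect_tissues({"A", "B", "C"}, {"B", "C", "D"}) == \
            {"B", "C"}

    def test_disjoint_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="empty"):
            assert intersect_tissues({"A"}, {"B"}) == set()


def _normalized(cohort):
    lf, _ = qc_filter(cohort.lung)
    lung = normalize(lf, "is_weight")
    plasma = {}
    for d, t in cohort.plasma_by_day.items():
        tf, _ = qc_filter(t)
        plasma[d] = normalize(tf, "is")
    return lung, plasma


class TestVipScreen:
    def test_threshold_zero_keeps_all(self, cohort):
        lung, plasma = _normalized(cohort)
        cand = cohort.planted_ids[:6]
        panel = vip_screen(cand, lung, plasma[5], threshold=0.0)
        assert set(panel.members) == set(cand)

    def test_single_candidate_rejected(self, cohort):
        lung, plasma = _normalized(cohort)
        with pytest.raises(ValueError):
            vip_screen(cohort.planted_ids[:1], lung, plasma[5])

    def test_planted_marker_retained_among_decoys(self):
        kept = 0
        n_seeds = 10
        for seed in range(n_seeds):
            c = simulate_cohort(SimConfig(seed=seed, n_metabolites=40,
                                          n_planted_markers=6))
            lung, plasma = _normalized(c)
            decoys = [m for m in lung.measured_ids
                      if m not in c.planted_ids][:15]
            cand = ["urea"] + decoys
            panel = vip_screen(cand, lung, plasma[5])
            if "urea" in panel.members:
                kept += 1
        assert kept >= 9


class TestCrossTissueCorr:
    def test_perfect_linear_r_one(self, small_cohort):
        lung, plasma = _normalized(small_cohort)
        m = lung.measured_ids[0]
        # construct plasma column = 2 x lung column on matched animals
        sl = lung.samples.loc[lung.study_mask()]
        sp = plasma[5].samples.loc[plasma[5].study_mask()]
        lung_by_animal = lung.abundance.loc[sl.index, m] \
            .set_axis(sl["animal_id"])
        plasma[5].abundance.loc[sp.index, m] = \
            (2.0 * lung_by_animal.reindex(sp["animal_id"])).to_numpy()
        corr = cross_tissue_corr(lung, plasma[5], [m])
        assert corr[m][0] == pytest.approx(1.0)

    def test_r_matches_hand_formula(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 9.0])
        y = np.array([2.0, 1.0, 5.0, 3.0, 8.0])
        lung = make_table({"m": x}, tissue="lung")
        plasma = make_table({"m": y}, tissue="plasma")
        corr = cross_tissue_corr(lung, plasma, ["m"])
        cx, cy = x - x.mean(), y - y.mean()
        r_hand = (cx @ cy) / np.sqrt((cx @ cx) * (cy @ cy))
        assert corr["m"][0] == pytest.approx(r_hand, abs=1e-12)

    def test_too_few_matched_animals_rejected(self):
        lung = make_table({"m": [1.0, 2.0]}, tissue="lung")
        plasma = make_table({"m": [1.0, 2.0]}, tissue="plasma")
        with pytest.raises(ValueError, match="3 animals"):
            cross_tissue_corr(lung, plasma, ["m"])


class TestSelectPanel:
    def test_vip_tie_breaks_lexically_and_filtration(self, cohort):
        lung, plasma = _normalized(cohort)
        cand = sorted(cohort.planted_ids[:8])
        screened = vip_screen(cand, lung, plasma[5], threshold=0.0)
        corr = cross_tissue_corr(lung, plasma[5], screened.members)
        final = select_panel(screened, corr, plasma[5], k=5)
        assert final.stage == "final"
        assert len(final.members) == 5
        assert set(final.members) <= set(screened.members)
        vips = final.frame["vip_final"].to_numpy()
        assert (np.diff(vips) <= 1e-12).all()

    def test_k_exceeding_survivors_rejected(self, cohort):
        lung, plasma = _normalized(cohort)
        screened = vip_screen(cohort.planted_ids[:4], lung, plasma[5],
                              threshold=0.0)
        corr = cross_tissue_corr(lung, plasma[5], screened.members)
        with pytest.raises(ValueError, match="exceeds"):
            select_panel(screened, corr, plasma[5], k=10)


class TestTriage:
    def test_dose_class_bijection(self):
        assert triage_map(35.0) == "Severe"
        assert triage_map(0.0) == "Control"
        assert triage_map(10) == "Mild"
        assert triage_map(20) == "Moderate"
        with pytest.raises(ValueError):
            triage_map(15.0)

    def test_confusion_row_sums_equal_class_counts(self, cohort):
        _, plasma = _normalized(cohort)
        res = triage_evaluate(plasma[5], cohort.planted_ids[:7], seed=0)
        counts = res.per_sample["true_class"].value_counts()
        for c in res.classes:
            assert res.confusion.loc[c].sum() == counts[c]
        assert res.overall_accuracy == pytest.approx(
            np.trace(res.confusion.to_numpy())
            / res.confusion.to_numpy().sum())

    def test_perfectly_separable_classes_all_correct(self):
        """Effects large enough that every pair of adjacent dose groups
        is >= 5 residual-SD apart per marker give perfect LOO triage."""
        cfg = SimConfig(seed=2, amplitude_sd=20.0, residual_sd_log=0.05,
                        animal_sd_log=0.0, missing_rate=0.0,
                        n_metabolites=40, n_planted_markers=7)
        c = simulate_cohort(cfg)
        _, plasma = _normalized(c)
        # a centered 4-class indicator block has rank 3, so 3 latent
        # components fully determine the class geometry
        res = triage_evaluate(plasma[5], c.planted_ids, n_components=3,
                              seed=0)
        assert all(v == 1.0 for v in res.per_class_accuracy.values())

    def test_null_cohort_shows_no_spurious_skill(self):
        """With no planted effects LOO accuracy must not exceed chance
        (LOO is pessimistic under the null, so only the upper bound is
        informative)."""
        accs = []
        for seed in range(8):
            cfg = SimConfig(seed=seed, n_metabolites=40,
                            n_planted_markers=6, amplitude_sd=0.0)
            c = simulate_cohort(cfg)
            _, plasma = _normalized(c)
            res = triage_evaluate(plasma[5], c.lung.measured_ids[:6],
                                  seed=seed)
            accs.append(res.overall_accuracy)
        se = np.sqrt(0.25 * 0.75 / (8 * 39))
        assert np.mean(accs) <= 0.25 + 2 * se

    def test_fitted_scheme_bounds_loo(self, cohort):
        _, plasma = _normalized(cohort)
        loo = triage_evaluate(plasma[5], cohort.planted_ids[:7], seed=0)
        fit = triage_evaluate(plasma[5], cohort.planted_ids[:7],
                              cv="fitted", seed=0)
        assert fit.cv_scheme == "fitted"
        assert fit.overall_accuracy >= loo.overall_accuracy - 1e-9

    def test_day5_beats_day1_with_onset_effects(self, cohort):
        _, plasma = _normalized(cohort)
        r1 = triage_evaluate(plasma[1], cohort.planted_ids[:7], seed=0)
        r5 = triage_evaluate(plasma[5], cohort.planted_ids[:7], seed=0)
        assert r5.overall_accuracy >= r1.overall_accuracy


class TestPanelRecovery:
    def test_cascade_is_filtration_and_recovers_markers(self):
        c = simulate_cohort(SimConfig(seed=4, n_metabolites=40,
                                      n_planted_markers=7))
        lung, plasma = _normalized(c)
        lung_diff = differential_screen(lung, test="anova")
        plasma_diffs = [differential_screen(t) for t in plasma.values()]
        panel = run_panel_cascade(lung_diff, plasma_diffs, lung, plasma[5])
        assert panel.stage == "final"
        inter = intersect_tissues(set(lung_diff.significant_ids),
                                  union_differential(plasma_diffs))
        assert set(panel.members) <= inter
        planted_found = set(panel.members) & set(c.planted_ids)
        assert len(planted_found) >= min(5, len(panel.members))


class TestTrajectories:
    def test_identical_groups_give_unit_ratios(self):
        days = {}
        for d in (1, 2, 3, 5):
            rng = np.random.default_rng(d)
            vals = np.concatenate([np.full(5, 10.0), np.full(5, 10.0)])
            days[d] = make_table({"m": vals},
                                 dose=[0.0] * 5 + [10.0] * 5, day=float(d))
        out = trajectories(days, ["m"], {})
        row = out.frame.loc[("m", 10.0)]
        for d in (1, 2, 3, 5):
            assert row[f"ratio_d{d}"] == pytest.approx(1.0)
        assert not row["monotone_2_to_5"]
        assert row["first_significant_day"] is None
        assert row["direction"] == 0

    def test_ratio_invariant_to_column_rescaling(self, small_cohort):
        _, plasma = _normalized(small_cohort)
        m = plasma[5].measured_ids[0]
        out1 = trajectories(plasma, [m], {})
        plasma2 = {d: t.copy() for d, t in plasma.items()}
        for t in plasma2.values():
            t.abundance[m] *= 17.0
        out2 = trajectories(plasma2, [m], {})
        pd.testing.assert_frame_equal(out1.frame, out2.frame)

    def test_onset_and_monotonicity_recovered(self):
        """AC5:0 responds only at 35 Gy from day 2: with enough animals
        the control-vs-35-Gy screen finds it from day 2 onward and its
        35-Gy ratio trajectory is monotone after onset."""
        hits_mono = hits_day = 0
        n_seeds = 10
        for seed in range(n_seeds):
            c = simulate_cohort(SimConfig(
                seed=seed, n_per_dose=(25, 25, 25, 25),
                n_metabolites=40, n_planted_markers=6))
            _, plasma = _normalized(c)
            diffs = {d: differential_screen(t, case_doses=(35.0,))
                     for d, t in plasma.items()}
            out = trajectories(plasma, ["AC5:0"], diffs)
            row = out.frame.loc[("AC5:0", 35.0)]
            if row["monotone_2_to_5"]:
                hits_mono += 1
            if row["first_significant_day"] == 2:
                hits_day += 1
        assert hits_mono >= 0.7 * n_seeds
        assert hits_day >= 0.7 * n_seeds
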