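"""Baseline normalization, paired t, thresholds, concentration curves."""

import math

import numpy as np
import pytest
from scipy import stats

from ehtlab import synthetic
from ehtlab.dose_response import (BASELINE, DoseResponseExperiment,
                                  build_concentration_response,
                                  normalize_to_baseline, paired_t_test,
                                  threshold_concentration)
from ehtlab.simulate import (simulate_calcium_experiment,
                             simulate_dose_response_experiment)
from ehtlab.twitch import RecordingSummary


def _summary(force=61.0, rvel=270.0, cvel=380.0, bpm=30.0, intervals=None,
             well="w1"):
    s = RecordingSummary(n_twitches=30, well_id=well)
    s.mean_force = force
    s.mean_relaxation_velocity = rvel
    s.mean_contraction_velocity = cvel
    s.frequency_bpm = bpm
    s.frequency_hz = bpm / 60.0
    s.frequency_defined = True
    s.beat_intervals = np.asarray(intervals if intervals is not None
                                  else np.full(29, 2.0))
    return s


def _experiment(effect_by_conc, ladder=(1.0, 3.0, 10.0), n_wells=4,
                idr_by_conc=None):
    """Hand-built experiment: per-well values with known multipliers."""
    rng = np.random.default_rng(0)
    summaries = {}
    for w in range(n_wells):
        well = f"w{w + 1}"
        base_rvel = 270.0 + 5.0 * w
        base_intervals = (2.0 + 0.01 * rng.standard_normal(29)
                          if idr_by_conc is not None else None)
        summaries[(well, BASELINE)] = _summary(rvel=base_rvel, well=well,
                                               intervals=base_intervals)
        for conc in ladder:
            mult = effect_by_conc.get(conc, 1.0)
            jitter = 1.0 + 0.001 * rng.standard_normal()
            intervals = None
            if idr_by_conc is not None:
                spread = idr_by_conc.get(conc, 0.01)
                intervals = 2.0 + spread * rng.standard_normal(29)
            summaries[(well, conc)] = _summary(rvel=base_rvel * mult * jitter,
                                               intervals=intervals, well=well)
    return DoseResponseExperiment(compound="test", ladder=list(ladder),
                                  summaries=summaries)


class TestNormalizeToBaseline:
    def test_baseline_rows_are_exactly_100(self):
        exp = _experiment({1.0: 0.9, 3.0: 0.8, 10.0: 0.6})
        table = normalize_to_baseline(exp)
        for well in exp.wells:
            assert table.loc[(well, BASELINE)].eq(100.0).all()

    def test_percent_definition(self):
        summaries = {
            ("w1", BASELINE): _summary(rvel=100.0),
            ("w1", 5.0): _summary(rvel=70.0),
            ("w2", BASELINE): _summary(rvel=200.0),
            ("w2", 5.0): _summary(rvel=150.0),
        }
        exp = DoseResponseExperiment("x", [5.0], summaries)
        table = normalize_to_baseline(exp)
        assert table.loc[("w1", 5.0), "relaxation_velocity"] == pytest.approx(70.0)
        assert table.loc[("w2", 5.0), "relaxation_velocity"] == pytest.approx(75.0)

    def test_zero_baseline_flagged_undefined(self):
        summaries = {
            ("w1", BASELINE): _summary(force=0.0),
            ("w1", 5.0): _summary(force=10.0),
            ("w2", BASELINE): _summary(),
            ("w2", 5.0): _summary(),
        }
        exp = DoseResponseExperiment("x", [5.0], summaries)
        table = normalize_to_baseline(exp)
        assert math.isnan(table.loc[("w1", 5.0), "force"])

    def test_normalization_is_idempotent(self):
        exp = _experiment({1.0: 0.9, 3.0: 0.8, 10.0: 0.6})
        t1 = normalize_to_baseline(exp)
        # re-normalizing the percent table: divide by the 100 baseline rows
        renorm = t1 / t1.xs(BASELINE, level="condition") * 100.0
        assert np.allclose(renorm.to_numpy(), t1.to_numpy(), equal_nan=True)

    def test_simulated_ladder_is_monotone_in_relaxation_velocity(self):
        exp = simulate_dose_response_experiment(
            synthetic.DRUG_MODELS["e4031_like"], [1, 5, 25, 125], seed=3,
            noise_sd=0.0)
        table = normalize_to_baseline(exp)
        per_conc = (table.reset_index()
                    .query("condition != @BASELINE")
                    .groupby("condition")["relaxation_velocity"].mean())
        vals = per_conc.loc[[1, 5, 25, 125]].to_numpy()
        assert np.all(np.diff(vals) < 0)

    def test_missing_baseline_rejected(self):
        with pytest.raises(ValueError):
            DoseResponseExperiment("x", [5.0], {("w1", 5.0): _summary()})

    def test_non_increasing_ladder_rejected(self):
        with pytest.raises(ValueError):
            DoseResponseExperiment("x", [5.0, 5.0],
                                   {("w1", BASELINE): _summary()})


class TestPairedT:
    def test_identical_samples_give_p_one(self):
        t, p = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_hand_computed_differences(self):
        # diffs {-1,-2,-3,-2}: mean -2, sd sqrt(2/3), t = -2/(sd/2) = -4.899
        base = [10.0, 10.0, 10.0, 10.0]
        treat = [9.0, 8.0, 7.0, 8.0]
        t, p = paired_t_test(base, treat)
        assert t == pytest.approx(-4.898979, rel=1e-6)
        assert p == pytest.approx(2 * stats.t.sf(4.898979, df=3), rel=1e-6)
        # cross-check against the independent library implementation
        ref = stats.ttest_rel(treat, base)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_sign_flip_antisymmetry(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=6), rng.normal(size=6)
        t1, p1 = paired_t_test(a, b)
        t2, p2 = paired_t_test(b, a)
        assert t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(p1)

    def test_zero_variance_nonzero_mean(self):
        t, p = paired_t_test([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
        assert math.isinf(t) and p == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0, 2.0], [1.0])


class TestThreshold:
    def test_no_effect_compound_has_no_threshold(self):
        exp = _experiment({}, idr_by_conc={})
        assert threshold_concentration(exp, "relaxation_velocity",
                                       "t").threshold is None
        assert threshold_concentration(exp,
                                       procedure="mannwhitney").threshold is None

    def test_clear_effect_thresholds_at_onset(self):
        exp = _experiment({1.0: 1.0, 3.0: 0.8, 10.0: 0.6})
        thr = threshold_concentration(exp, "relaxation_velocity", "t")
        assert thr.threshold == 3.0

    def test_isolated_significance_is_not_a_threshold(self):
        # effect at the middle concentration only: non-monotone, ignored
        exp = _experiment({1.0: 1.0, 3.0: 0.6, 10.0: 1.0})
        thr = threshold_concentration(exp, "relaxation_velocity", "t")
        assert thr.threshold is None
        assert thr.p_values[3.0] < 0.05

    def test_degenerate_alpha_thresholds_at_first_concentration(self):
        exp = _experiment({1.0: 0.95, 3.0: 0.8, 10.0: 0.6})
        thr = threshold_concentration(exp, "relaxation_velocity", "t",
                                      alpha=1.0)
        assert thr.threshold == 1.0

    def test_scatter_threshold_via_mannwhitney(self):
        exp = _experiment({}, idr_by_conc={1.0: 0.01, 3.0: 0.4, 10.0: 0.5})
        thr = threshold_concentration(exp, procedure="mannwhitney")
        assert thr.threshold == 3.0
        assert thr.parameter == "idr"

    def test_insufficient_replicates_rejected(self):
        exp = _experiment({}, n_wells=1)
        with pytest.raises(ValueError):
            threshold_concentration(exp)

    def test_simulated_drug_threshold_at_or_below_effect_step(self):
        # relaxation IC50 placed at ladder step 3 of [1, 5, 25, 125, 625]
        model = synthetic.DrugEffectModel(
            compound="probe", ic50_relax=25.0, ic50_force=2500.0,
            scatter_onset=2500.0, max_reduction=0.4)
        hits = 0
        seeds = range(10)
        for seed in seeds:
            exp = simulate_dose_response_experiment(
                model, [1, 5, 25, 125, 625], seed=seed)
            thr = threshold_concentration(exp, "relaxation_velocity", "t")
            hits += thr.threshold is not None and thr.threshold <= 25.0
        assert hits >= 0.9 * len(seeds)

    def test_weakening_the_drug_never_lowers_the_threshold(self):
        ladder = [1, 5, 25, 125, 625]
        medians = []
        for ic50 in (5.0, 125.0):
            thresholds = []
            for seed in range(20):
                model = synthetic.DrugEffectModel(
                    compound="probe", ic50_relax=ic50, ic50_force=1e5,
                    scatter_onset=1e5, max_reduction=0.4)
                exp = simulate_dose_response_experiment(model, ladder,
                                                        seed=seed)
                thr = threshold_concentration(exp, "relaxation_velocity", "t")
                thresholds.append(thr.threshold if thr.threshold is not None
                                  else float("inf"))
            medians.append(np.median(thresholds))
        assert medians[1] >= medians[0]

    def test_negative_control_false_threshold_rate(self):
        # 20 no-effect experiments; bound 1 - (1-alpha)^5 + 0.05
        model = synthetic.DRUG_MODELS["inactive_control"]
        false_t = false_mw = 0
        n = 20
        for seed in range(n):
            exp = simulate_dose_response_experiment(model, [1, 3, 10, 30, 100],
                                                    seed=100 + seed)
            false_t += threshold_concentration(
                exp, "relaxation_velocity", "t").threshold is not None
            false_mw += threshold_concentration(
                exp, procedure="mannwhitney").threshold is not None
        bound = 1 - (1 - 0.05) ** 5 + 0.05
        assert false_t / n <= bound
        assert false_mw / n <= bound


class TestConcentrationResponse:
    def test_calcium_series_reproduces_force_drop_and_plateau(self):
        exp = simulate_calcium_experiment(levels=(0.2, 1.8, 2.2, 3.0),
                                          n_wells=4, seed=1)
        table = build_concentration_response(exp).set_index("condition")
        low = table.loc[0.2, "force_mean"]
        base = table.loc[1.8, "force_mean"]
        assert low / base == pytest.approx(0.10, abs=0.03)
        hi1, hi2 = table.loc[2.2, "force_mean"], table.loc[3.0, "force_mean"]
        assert abs(hi1 - hi2) / hi2 <= 0.05

    def test_single_level_gives_one_ladder_row(self):
        summaries = {("w1", BASELINE): _summary(), ("w1", 2.2): _summary(),
                     ("w2", BASELINE): _summary(), ("w2", 2.2): _summary()}
        exp = DoseResponseExperiment("calcium", [2.2], summaries)
        table = build_concentration_response(exp)
        assert list(table["condition"]) == [BASELINE, 2.2]

    def test_missing_level_left_as_gap(self):
        summaries = {("w1", BASELINE): _summary(), ("w1", 3.0): _summary(),
                     ("w2", BASELINE): _summary(), ("w2", 3.0): _summary()}
        exp = DoseResponseExperiment("calcium", [1.0, 3.0], summaries)
        table = build_concentration_response(exp)
        assert 1.0 not in set(table["condition"])
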