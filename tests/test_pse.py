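"""PSE estimation from reversal levels and illusion-magnitude summaries."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import illusim as il
from illusim.pse import IncompleteDesignError, PSEEstimationError
from illusim.staircase import TrialRecord


def cell_records(levels_responses, staircase_id="shadow0_ascending",
                 shadow=0, direction="ascending", start_index=0):
    """Build a consistent trial log for one staircase from its response run."""
    return [
        TrialRecord(
            subject_id="s01", block=0.0, staircase_id=staircase_id,
            shadow=shadow, direction=direction, trial_index=start_index + i,
            comparative_level=lv, standard_side="left", response=resp,
            reversal=False,
        )
        for i, (lv, resp) in enumerate(levels_responses)
    ]


def threshold_run(direction, threshold=100.0, config=None):
    """Deterministic threshold-observer run of one staircase, as a log."""
    config = config or il.StaircaseConfig()
    obs = il.ThresholdObserver("s01", threshold)
    from illusim.staircase import StaircaseState

    shadow = 0
    state = StaircaseState.start(shadow, direction, config)
    out = []
    while not state.terminated:
        lv = state.current_level
        resp = obs.respond(shadow, 0.0, lv, None)
        il.update_staircase(state, resp, config)
        out.append((lv, resp))
    return cell_records(
        out, staircase_id=f"shadow{shadow}_{direction}", direction=direction
    )


class TestEstimatePse:
    def test_alternating_reversals_average_to_midpoint(self):
        config = il.StaircaseConfig()
        recs = threshold_run("ascending")
        # reindex the descending run so trial indices do not collide
        desc = [
            dataclasses.replace(r, trial_index=r.trial_index + 1000)
            for r in threshold_run("descending")
        ]
        pse = il.estimate_pse(recs + desc, config)
        assert pse == pytest.approx(100.5)

    def test_bracketing_reversals_average_to_threshold_midpoint(self):
        """Threshold between grid levels: reversals alternate 104/103."""
        config = il.StaircaseConfig()
        recs = threshold_run("ascending", threshold=103.5, config=config)
        reversals = [103.0, 104.0]
        pse = il.estimate_pse(recs, config)
        assert pse == pytest.approx(np.mean(reversals)) == 103.5

    def test_pooled_and_per_staircase_agree_for_balanced_counts(self):
        config = il.StaircaseConfig()
        recs = threshold_run("ascending")
        desc = [
            dataclasses.replace(r, trial_index=r.trial_index + 1000)
            for r in threshold_run("descending")
        ]
        pooled = il.estimate_pse(recs + desc, config, pooling="pooled")
        per = il.estimate_pse(recs + desc, config, pooling="per_staircase")
        assert pooled == pytest.approx(per)

    def test_empty_cell_raises(self):
        with pytest.raises(PSEEstimationError):
            il.estimate_pse([], il.StaircaseConfig())


class TestPseTable:
    def test_experiment_shaped_log_yields_200_rows(self):
        pop = il.sample_population(il.PopulationSpec(n_subjects=20, seed=0))
        angles = [-60.0, -30.0, 0.0, 30.0, 60.0]
        config = il.StaircaseConfig()
        trials = il.run_experiment(pop, angles, config, seed=3)
        table = il.pse_table(trials, config)
        assert len(table.frame) == 200
        assert table.n_subjects == 20 and table.n_angles == 5
        assert table.frame["pse"].between(92, 108).all()

    def test_row_order_permutation_leaves_table_unchanged(self):
        pop = il.sample_population(il.PopulationSpec(n_subjects=3, seed=1))
        config = il.StaircaseConfig()
        trials = il.run_experiment(pop, [0.0, 30.0], config, seed=5)
        frame = trials.to_frame()
        shuffled = frame.sample(frac=1.0, random_state=9)
        a = il.pse_table(frame, config).frame
        b = il.pse_table(shuffled, config).frame
        pd.testing.assert_frame_equal(a, b)

    def test_standard_side_metadata_is_ignored(self):
        pop = il.sample_population(il.PopulationSpec(n_subjects=3, seed=1))
        config = il.StaircaseConfig()
        trials = il.run_experiment(pop, [0.0], config, seed=5)
        frame = trials.to_frame()
        flipped = frame.assign(
            standard_side=frame["standard_side"].map(
                {"left": "right", "right": "left"}
            )
        )
        pd.testing.assert_frame_equal(
            il.pse_table(frame, config).frame,
            il.pse_table(flipped, config).frame,
        )

    def test_missing_cells_raise_structural_error(self):
        pop = il.sample_population(il.PopulationSpec(n_subjects=3, seed=1))
        config = il.StaircaseConfig()
        trials = il.run_experiment(pop, [0.0, 30.0], config, seed=5)
        frame = trials.to_frame()
        # drop one whole cell
        mask = ~(
            (frame.subject_id == "s01")
            & (frame.shadow == 1)
            & (frame.block == 0.0)
        )
        with pytest.raises(IncompleteDesignError):
            il.pse_table(frame[mask], config)

    def test_fast_path_matches_replayed_log(self):
        """Record-free simulation equals pse_table(run_experiment(...))."""
        pop = il.sample_population(il.PopulationSpec(n_subjects=4, seed=6))
        config = il.StaircaseConfig()
        angles = [0.0, 30.0]
        via_log = il.pse_table(
            il.run_experiment(pop, angles, config, seed=77), config
        )
        direct = il.simulate_pse_table(pop, angles, config, seed=77)
        pd.testing.assert_frame_equal(via_log.frame, direct.frame)

    def test_zero_noise_recovery_within_one_step(self):
        """Known 3.0 shift, no noise: every subject recovered within 1%."""
        spec = il.PopulationSpec(
            n_subjects=4, baseline_pse_sd=0.0, shadow_shift_mean=3.0,
            shadow_shift_sd=0.0, slope=0.5, lapse_rate=0.0,
        )
        pop = il.sample_population(spec)
        table = il.simulate_pse_table(
            pop, [0.0], il.StaircaseConfig(), seed=13
        )
        wide = table.to_wide()
        diffs = wide[:, 1, 0] - wide[:, 0, 0]
        assert np.all(np.abs(diffs - 3.0) <= 1.0)


class TestIllusionMagnitude:
    def test_identical_shadow_conditions_give_zero(self):
        wide = np.tile(
            np.linspace(99, 101, 10)[:, None, None], (1, 2, 5)
        )
        table = il.PSETable.from_wide(wide, angles=[-60, -30, 0, 30, 60])
        summary = il.illusion_magnitude(table)
        assert summary.grand_mean == 0.0
        assert (summary.per_angle["mean"] == 0.0).all()

    def test_constant_offset_recovered_exactly(self):
        rng = np.random.default_rng(0)
        base = rng.normal(100, 1, size=(10, 1, 5))
        wide = np.concatenate([base, base + 2.0], axis=1)
        table = il.PSETable.from_wide(wide, angles=[-60, -30, 0, 30, 60])
        summary = il.illusion_magnitude(table)
        assert summary.grand_mean == pytest.approx(2.0)
        assert summary.grand_sd == pytest.approx(0.0)

    def test_estimator_precision_improves_with_more_reversals(self):
        """SD of the PSE estimate is non-increasing in the reversal count."""
        spec = il.PopulationSpec(
            n_subjects=2, baseline_pse_sd=0.0, shadow_shift_mean=0.0,
            shadow_shift_sd=0.0, slope=2.0, lapse_rate=0.0,
        )
        pop = il.sample_population(spec)
        sds = []
        for criterion in (2, 8):
            config = il.StaircaseConfig(reversal_criterion=criterion)
            estimates = [
                il.simulate_pse_table(pop, [0.0], config, seed=s)
                .frame["pse"]
                .to_numpy()
                for s in range(60)
            ]
            sds.append(np.std(np.concatenate(estimates)))
        assert sds[1] <= sds[0]
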