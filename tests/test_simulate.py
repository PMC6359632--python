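"""Synthetic spectral-count generator and recovery scoring."""

import numpy as np
import pandas as pd
import pytest

from nsafde import (
    Call,
    DEPCall,
    DifferentialExpression,
    SimConfig,
    Tier,
    evaluate_recovery,
    read_sim_config,
    simulate_counts,
)


def fit_sim(matrix):
    return DifferentialExpression(matrix, "ref", "cmp").fit()


class TestGenerator:
    def test_same_seed_identical(self):
        cfg = SimConfig(n_proteins=50, n_dep=5, seed=7, depth=5000)
        m1, t1 = simulate_counts(cfg)
        m2, t2 = simulate_counts(cfg)
        pd.testing.assert_frame_equal(m1.counts, m2.counts)
        assert t1 == t2

    def test_different_seed_differs(self):
        m1, _ = simulate_counts(SimConfig(n_proteins=50, seed=1, depth=5000))
        m2, _ = simulate_counts(SimConfig(n_proteins=50, seed=2, depth=5000))
        assert not m1.counts.equals(m2.counts)

    def test_shape_and_design(self):
        cfg = SimConfig(n_proteins=40, n_replicates=3, depth=4000, seed=0)
        m, truth = simulate_counts(cfg)
        assert len(m.accessions) == 40
        assert m.run_ids == ["ref_1", "ref_2", "ref_3", "cmp_1", "cmp_2", "cmp_3"]
        assert len(truth.accessions) == 40
        assert sum(truth.is_dep) == 0

    def test_truth_marks_n_dep(self):
        _, truth = simulate_counts(SimConfig(n_proteins=60, n_dep=12, seed=3, depth=6000))
        assert sum(truth.is_dep) == 12
        assert all(f == 10.0 for f, d in zip(truth.true_fold, truth.is_dep) if d)

    def test_run_totals_concentrate_around_depth(self):
        m, _ = simulate_counts(SimConfig(n_proteins=200, depth=10_000, seed=11))
        totals = m.counts.sum(axis=0)
        assert (np.abs(totals - 10_000) / 10_000 < 0.05).all()

    def test_detection_floor_zeroes_small_counts(self):
        m, _ = simulate_counts(
            SimConfig(n_proteins=200, depth=2000, detection_floor=3, seed=5)
        )
        x = m.counts.to_numpy()
        assert ((x == 0) | (x >= 3)).all()

    def test_dispersion_inflates_variance(self):
        lam_runs = []
        for dispersion in (0.0, 1.0):
            m, _ = simulate_counts(
                SimConfig(n_proteins=100, depth=50_000, dispersion=dispersion,
                          n_replicates=3, detection_floor=0, seed=21)
            )
            lam_runs.append(m.counts.var(axis=1).mean())
        assert lam_runs[1] > 5 * lam_runs[0]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_proteins=10, n_dep=11)
        with pytest.raises(ValueError):
            SimConfig(fold_changes=(0.0,))
        with pytest.raises(ValueError):
            SimConfig(dispersion=-1)

    def test_null_mean_ratio_near_one(self):
        """No planted effect: NSAF ratios scatter around 1."""
        m, _ = simulate_counts(SimConfig(n_proteins=200, n_dep=0, depth=10_000, seed=13))
        res = fit_sim(m)
        ratios = res.calls["nsaf_ratio"]
        finite = ratios[np.isfinite(ratios) & (ratios > 0)]
        assert 0.8 < finite.mean() < 1.25


class TestRecovery:
    def test_perfect_calls(self):
        _, truth = simulate_counts(SimConfig(n_proteins=10, n_dep=3, seed=1, depth=2000))
        calls = [
            DEPCall(acc, 1.0, 10.0 if dep else 1.0, Tier.VERY_LOW, Tier.LOW, Tier.LOW,
                    10.0 if dep else 1.0, 0.0,
                    Call.OVEREXPRESSED if dep else Call.NOT_SIGNIFICANT)
            for acc, dep in zip(truth.accessions, truth.is_dep)
        ]
        sens, fdp, confusion = evaluate_recovery(calls, truth)
        assert (sens, fdp) == (1.0, 0.0)
        assert confusion["true_calls"].sum() == 3

    def test_zero_calls_convention(self):
        _, truth = simulate_counts(SimConfig(n_proteins=10, n_dep=3, seed=1, depth=2000))
        calls = [
            DEPCall(acc, 1.0, 1.0, Tier.LOW, Tier.LOW, Tier.LOW, 1.0, 1.0,
                    Call.NOT_SIGNIFICANT)
            for acc in truth.accessions
        ]
        sens, fdp, _ = evaluate_recovery(calls, truth)
        assert (sens, fdp) == (0.0, 0.0)

    def test_call_everything(self):
        _, truth = simulate_counts(SimConfig(n_proteins=20, n_dep=5, seed=2, depth=2000))
        calls = [
            DEPCall(acc, 1.0, 10.0, Tier.LOW, Tier.MEDIUM, Tier.MEDIUM, 10.0, 0.0,
                    Call.OVEREXPRESSED)
            for acc in truth.accessions
        ]
        sens, fdp, _ = evaluate_recovery(calls, truth)
        assert sens == 1.0
        assert fdp == pytest.approx((20 - 5) / 20)

    def test_wrong_direction_not_recovered(self):
        _, truth = simulate_counts(SimConfig(n_proteins=10, n_dep=2, seed=3, depth=2000))
        calls = [
            DEPCall(acc, 10.0, 1.0, Tier.LOW, Tier.LOW, Tier.LOW, 0.1, 0.0,
                    Call.UNDEREXPRESSED if dep else Call.NOT_SIGNIFICANT)
            for acc, dep in zip(truth.accessions, truth.is_dep)
        ]
        sens, fdp, _ = evaluate_recovery(calls, truth)
        assert sens == 0.0  # planted folds are 10 (up); UE calls don't count
        assert fdp == 1.0

    def test_sensitivity_monotone_in_fold(self):
        """Averaged over seeds, stronger planted folds are never harder to
        recover."""
        mean_sens = []
        for fold in (2.0, 5.0, 10.0):
            sens = []
            for seed in (101, 102, 103):
                cfg = SimConfig(n_proteins=150, n_dep=15, fold_changes=(fold,),
                                depth=20_000, seed=seed)
                m, truth = simulate_counts(cfg)
                s, _, _ = evaluate_recovery(fit_sim(m).call_records, truth)
                sens.append(s)
            mean_sens.append(np.mean(sens))
        assert mean_sens[0] <= mean_sens[1] + 1e-9 <= mean_sens[2] + 2e-9


class TestConfigFile:
    def test_round_trip(self, tmp_path):
        p = tmp_path / "sim.cfg"
        p.write_text(
            "# comment\nn_proteins = 40\nn_dep = 4\nfold_changes = 10, 0.1\n"
            "depth = 8000\nseed = 9\n"
        )
        cfg = read_sim_config(p)
        assert cfg.n_proteins == 40
        assert cfg.fold_changes == (10.0, 0.1)
        assert cfg.seed == 9
        assert read_sim_config(p, seed=4).seed == 4

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "sim.cfg"
        p.write_text("bogus = 1\n")
        with pytest.raises(ValueError, match="unknown simulation parameter"):
            read_sim_config(p)
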