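"""Synthetic count generator: determinism, statistical structure, probes."""

import numpy as np
import pandas as pd
import pytest

from craci.calibration import fit_calibration_table
from craci.sitecall_ncrna import NcrnaCallConfig, call_sites_ncrna, is_multi_u
from craci.simdata import (
    SimConfig,
    choose_sites,
    make_probe_reference,
    simulate_calibration_series,
    simulate_counts,
    write_simulation,
)


class TestSimulateCounts:
    def test_seed_determinism(self):
        cfg = SimConfig(seed=42, n_refs=2, ref_length=200, n_true_sites=4)
        r1, r2 = simulate_counts(cfg), simulate_counts(cfg)
        assert r1.reference == r2.reference
        for key in r1.tables:
            pd.testing.assert_frame_equal(r1.tables[key], r2.tables[key])
        pd.testing.assert_frame_equal(r1.truth, r2.truth)

    def test_different_seeds_differ(self):
        a = simulate_counts(SimConfig(seed=1, n_true_sites=2))
        b = simulate_counts(SimConfig(seed=2, n_true_sites=2))
        assert a.reference != b.reference

    def test_background_ratios_near_intercept(self):
        # f = 0 everywhere: observed ratios should sit within 3 binomial SEs
        # of b for the vast majority of sites
        cfg = SimConfig(seed=3, n_refs=4, ref_length=1000, depth=10000,
                        n_true_sites=0, default_b=0.05)
        result = simulate_counts(cfg)
        df = result.tables[("treated", 1)]
        ratios = df["n_C"] / (df["n_C"] + df["n_T"])
        se = np.sqrt(0.05 * 0.95 / 10000)
        frac_within = np.mean(np.abs(ratios - 0.05) <= 3 * se)
        assert frac_within >= 0.99

    def test_saturated_site_clips_to_one(self):
        cfg = SimConfig(seed=4, n_refs=1, ref_length=300, depth=5000,
                        default_A=0.96, default_b=0.04, n_true_sites=1,
                        true_fraction_range=(1.0, 1.0))
        result = simulate_counts(cfg)
        site = result.truth.iloc[0]
        df = result.tables[("treated", 1)]
        row = df[(df.ref_id == site.ref_id) & (df.pos == site.pos)].iloc[0]
        assert row.n_C / (row.n_C + row.n_T) == 1.0  # y = clip(0.96+0.04) = 1

    def test_inputs_and_ivt_carry_no_signal(self):
        cfg = SimConfig(seed=5, depth=2000, n_true_sites=5,
                        true_fraction_range=(0.8, 0.9))
        result = simulate_counts(cfg)
        truth_keys = set(zip(result.truth.ref_id, result.truth.pos))
        for cond in ("input1", "input2", "ivt"):
            df = result.tables[(cond, 1)]
            planted = df[[(r, p) in truth_keys for r, p in zip(df.ref_id, df.pos)]]
            ratios = planted["n_C"] / (planted["n_C"] + planted["n_T"])
            assert (ratios < 0.15).all()

    def test_planted_non_t_site_rejected(self):
        cfg = SimConfig(seed=6, n_refs=1, ref_length=100)
        ref = simulate_counts(SimConfig(seed=6, n_refs=1, ref_length=100,
                                        n_true_sites=0)).reference["ref001"]
        non_t = next(i + 1 for i, c in enumerate(ref) if c != "T")
        with pytest.raises(ValueError, match="not a reference T"):
            simulate_counts(SimConfig(seed=6, n_refs=1, ref_length=100,
                                      truth=[("ref001", non_t, 0.5)]))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(default_A=0.0)
        with pytest.raises(ValueError):
            SimConfig(default_b=0.5)
        with pytest.raises(ValueError):
            SimConfig(truth=[("ref001", 5, 1.5)])

    def test_write_simulation_roundtrip(self, tmp_path):
        from craci.io_formats import read_count_table, records_to_frame

        cfg = SimConfig(seed=7, n_refs=1, ref_length=150, n_true_sites=2)
        result = simulate_counts(cfg)
        paths = write_simulation(result, tmp_path / "sim")
        assert paths["reference"].exists() and paths["truth"].exists()
        back = records_to_frame(read_count_table(paths["treated_rep1"]))
        pd.testing.assert_frame_equal(
            back, result.tables[("treated", 1)], check_dtype=False)


class TestChooseSites:
    def test_multi_u_share_planted_in_multi_u_contexts(self):
        ref = simulate_counts(SimConfig(seed=8, n_refs=2, ref_length=500,
                                        n_true_sites=0)).reference
        sites = choose_sites(ref, 10, (0.3, 0.9), seed=8, multi_u_fraction=0.4)
        flags = [is_multi_u(_motif(ref, r, p)) for r, p, _ in sites]
        assert sum(flags) == 4 and len(sites) == 10

    def test_fractions_within_requested_range(self):
        ref = simulate_counts(SimConfig(seed=9, n_refs=1, ref_length=400,
                                        n_true_sites=0)).reference
        sites = choose_sites(ref, 8, (0.3, 0.5), seed=9)
        assert all(0.3 <= f <= 0.5 for _, _, f in sites)


def _motif(ref, ref_id, pos):
    from craci.io_formats import motif_at

    return motif_at(ref[ref_id], pos)


class TestCalibrationSeries:
    def test_six_points_per_motif_by_default(self):
        points = simulate_calibration_series(motifs=["AATAA", "CCTCC"], seed=1)
        assert len(points) == 12
        levels = sorted({p.d_fraction_true for p in points})
        assert levels == [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]

    def test_analytic_mode_lies_exactly_on_line(self):
        points = simulate_calibration_series(motifs=["AATAA"], depth=None,
                                             default_A=0.9, default_b=0.05)
        for p in points:
            assert p.ratio_observed == pytest.approx(0.9 * p.d_fraction_true + 0.05)

    def test_seed_determinism(self):
        a = simulate_calibration_series(motifs=["AATAA"], seed=11)
        b = simulate_calibration_series(motifs=["AATAA"], seed=11)
        assert a == b

    def test_empty_levels_rejected(self):
        with pytest.raises(ValueError):
            simulate_calibration_series(motifs=["AATAA"], levels=())


class TestProbeReference:
    def test_layout(self):
        probe = make_probe_reference("GATAG")
        assert len(probe) == 35
        assert probe[15:20] == "GATAG"      # 1-based positions 16-20
        assert probe[17] == "T"             # central T at position 18
        assert "T" not in probe[:15] and "T" not in probe[20:]

    def test_invalid_motif_rejected(self):
        with pytest.raises(ValueError):
            make_probe_reference("GATA")


class TestEndToEndRecovery:
    def test_planted_ncrna_sites_recovered_without_false_positives(self, flat_background, unit_curves):
        """Planted high-fraction sites are called; background T sites are not."""
        n_ok = 0
        n_runs = 12
        for seed in range(n_runs):
            cfg = SimConfig(seed=seed, n_refs=5, ref_length=1600, depth=500,
                            n_true_sites=20, true_fraction_range=(0.3, 0.9),
                            replicates={"treated": 2, "input1": 1, "input2": 1})
            result = simulate_counts(cfg)
            treated = pd.concat([result.tables[("treated", 1)], result.tables[("treated", 2)]])
            calls = call_sites_ncrna(treated, result.tables[("input1", 1)],
                                     result.tables[("input2", 1)],
                                     unit_curves, flat_background, result.reference)
            called = {c.site for c in calls if c.called}
            truth_all = set(zip(result.truth.ref_id, result.truth.pos))
            truth_single_u = {
                (r, p) for r, p, mu in
                zip(result.truth.ref_id, result.truth.pos, result.truth.multi_u) if not mu}
            if called == truth_single_u and not (called - truth_all):
                n_ok += 1
        assert n_ok >= 0.95 * n_runs

    def test_multi_u_planted_sites_never_called(self, flat_background, unit_curves):
        cfg = SimConfig(seed=77, n_refs=4, ref_length=1200, depth=800,
                        n_true_sites=12, true_fraction_range=(0.5, 0.9),
                        multi_u_fraction=0.5)
        result = simulate_counts(cfg)
        treated = pd.concat([result.tables[("treated", 1)], result.tables[("treated", 2)]])
        calls = call_sites_ncrna(treated, result.tables[("input1", 1)],
                                 result.tables[("input2", 1)],
                                 unit_curves, flat_background, result.reference)
        called = {c.site for c in calls if c.called}
        multi_u_truth = {
            (r, p) for r, p, mu in
            zip(result.truth.ref_id, result.truth.pos, result.truth.multi_u) if mu}
        assert not (called & multi_u_truth)

    def test_stoichiometry_recovery_rmse(self, flat_background, unit_curves):
        """Estimated D fractions track planted truth to RMSE <= 0.05 at depth 1000."""
        fractions = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9]
        errors = []
        for seed in range(5):
            base = simulate_counts(SimConfig(seed=seed + 100, n_refs=3,
                                             ref_length=900, n_true_sites=0))
            sites = choose_sites(base.reference, len(fractions), (0.5, 0.5),
                                 seed=seed + 100)
            truth = [(r, p, f) for (r, p, _), f in zip(sites, fractions)]
            cfg = SimConfig(seed=seed + 100, n_refs=3, ref_length=900,
                            depth=1000, truth=truth)
            result = simulate_counts(cfg)
            calls = call_sites_ncrna(result.tables[("treated", 1)],
                                     result.tables[("input1", 1)],
                                     result.tables[("input2", 1)],
                                     unit_curves, flat_background, result.reference)
            by_site = {c.site: c for c in calls}
            for r, p, f in truth:
                est = by_site[(r, p)].d_fraction
                errors.append(est - f)
        rmse = float(np.sqrt(np.mean(np.square(errors))))
        assert rmse <= 0.05
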