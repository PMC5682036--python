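"""Synthetic-study generator: determinism, construction oracles, and
parameter-recovery properties at study scale."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from erpstates.behavior import dprime, score_responses
from erpstates.microstate import MicrostateModel, backfit, gmd
from erpstates.simulate import (
    DEFAULT_DPRIME,
    SimulationSpec,
    cell_erp,
    default_design,
    default_timeline,
    generate_montage,
    generate_templates,
    resolve_noise_sd,
    simulate_behavior,
    simulate_study,
    simulate_study_evoked,
    true_durations,
)


class TestMontageGeneration:
    def test_16_channels_on_the_sphere(self):
        m = generate_montage(16, seed=0)
        radii = np.linalg.norm(m.positions, axis=1)
        assert np.abs(radii - 90.0).max() < 1e-6

    def test_quasi_uniform_coverage_204(self):
        """Nearest-neighbour spacing (brute-force pairwise distances) is even."""
        m = generate_montage(204, seed=0)
        d = squareform(pdist(m.positions))
        np.fill_diagonal(d, np.inf)
        nn = d.min(axis=1)
        assert nn.std() / nn.mean() < 0.5

    def test_same_seed_identical(self):
        a = generate_montage(64, seed=5)
        b = generate_montage(64, seed=5)
        assert np.array_equal(a.positions, b.positions)

    def test_too_few_channels_rejected(self):
        with pytest.raises(ValueError):
            generate_montage(8, seed=0)


class TestTemplateGeneration:
    def test_maps_are_average_referenced_unit_gfp(self, templates):
        assert np.abs(templates.mean(axis=1)).max() < 1e-9
        assert np.abs(np.sqrt((templates**2).mean(axis=1)) - 1.0).max() < 1e-9

    def test_pairwise_dissimilarity(self, templates):
        """|r| < 0.9 between any two maps implies GMD > 0.63 (brute force)."""
        k = templates.shape[0]
        for i in range(k):
            for j in range(i + 1, k):
                r = np.corrcoef(templates[i], templates[j])[0, 1]
                assert abs(r) < 0.9
                assert gmd(templates[i], templates[j]) > 0.63

    def test_same_seed_identical(self, montage, grid, head):
        a, _ = generate_templates(3, montage, grid, head, seed=9)
        b, _ = generate_templates(3, montage, grid, head, seed=9)
        assert np.array_equal(a, b)


class TestStudySimulation:
    def test_noiseless_trials_equal_cell_erp(self, templates):
        design = default_design()
        design = type(design)(design.groups, design.conditions, {g: 2 for g in design.groups})
        spec = SimulationSpec(design=design, noise_sd=0.0, n_trials=3, subject_jitter_sd=0.0)
        epochs, _ = simulate_study(spec, templates, seed=0)
        es = epochs[0]
        erp = cell_erp(spec, templates, (es.group, es.condition))
        assert np.allclose(es.data, erp[None])

    def test_noiseless_grand_mean_backfit_recovers_label_sequence(self, templates):
        spec = SimulationSpec(noise_sd=0.0, subject_jitter_sd=0.0)
        model = MicrostateModel(maps=templates)
        cell = ("Expert", "Tapp")
        erp = cell_erp(spec, templates, cell)
        from erpstates.types import Evoked

        ev = Evoked(data=erp, sfreq=spec.sfreq, t0_index=spec.t0_index)
        seq = backfit(model, ev, window=(0.0, 750.0))
        t_ms = seq.times
        expected = np.full(len(t_ms), -1)
        for m, t0, t1 in spec.timeline[cell]:
            expected[(t_ms >= t0) & (t_ms < t1)] = m
        assert np.array_equal(seq.labels, expected)

    def test_durations_sum_to_window_length(self, design):
        spec = SimulationSpec()
        for cell, dur in ((c, true_durations(spec, c)) for c in spec.timeline):
            assert sum(dur.values()) == pytest.approx(184.0)

    def test_duration_recovery_within_two_frames_at_snr_half(self, templates):
        """Back-fitting noisy subject ERPs recovers the per-cell mean durations
        within ±8 ms (2 frames at 250 Hz) at single-trial SNR 0.5, n=20."""
        design = default_design()
        design = type(design)(design.groups, design.conditions, {g: 20 for g in design.groups})
        spec = SimulationSpec(design=design, target_snr=0.5)
        evokeds, truth = simulate_study_evoked(spec, templates, seed=21)
        model = MicrostateModel(maps=templates)
        from erpstates.microstate import duration_table

        table = duration_table(model, evokeds, window=(295.0, 480.0))
        for g in design.groups:
            for c in design.conditions:
                true = truth.durations[(g, c)]
                sub = table[(table.group == g) & (table.condition == c)]
                for m in range(3, 7):
                    rec = sub[sub["map"] == m]["duration_ms"].mean()
                    assert rec == pytest.approx(true[m], abs=8.0), (g, c, m)

    def test_timeline_outside_epoch_rejected(self):
        tl = default_timeline(default_design())
        tl[("Expert", "R")] = [(0, 0.0, 800.0)]
        with pytest.raises(ValueError):
            SimulationSpec(timeline=tl)

    def test_evoked_level_matches_trial_level_statistics(self, templates):
        """The evoked-level shortcut has the same mean and √n-scaled noise."""
        design = default_design()
        design = type(design)(design.groups, design.conditions, {g: 2 for g in design.groups})
        spec = SimulationSpec(design=design, n_trials=50, subject_jitter_sd=0.0)
        sd = resolve_noise_sd(spec, templates)
        evokeds, _ = simulate_study_evoked(spec, templates, seed=4)
        erp = cell_erp(spec, templates, (evokeds[0].group, evokeds[0].condition))
        resid = evokeds[0].data - (erp - erp.mean(axis=0, keepdims=True))
        # residual sd ≈ noise_sd/√n_trials (baseline correction adds a little)
        assert resid.std() == pytest.approx(sd / np.sqrt(50), rel=0.25)


class TestBehaviorSimulation:
    def test_zero_sensitivity_gives_half_rates(self):
        design = default_design()
        dp = {(g, c): 0.0 for g in design.groups for c in ("Tsub", "Tapp")}
        trials = simulate_behavior(design, dp, n_trials_per_condition=400, subject_sd=0.0, seed=0)
        p_no = (trials["response"] == "NO").mean()
        assert p_no == pytest.approx(0.5, abs=0.02)

    def test_recovers_dprime_two(self):
        design = default_design()
        dp = {(g, c): 2.0 for g in design.groups for c in ("Tsub", "Tapp")}
        trials = simulate_behavior(
            design, dp, n_trials_per_condition=10_000, subject_sd=0.0, seed=1
        )
        table = score_responses(trials, design)
        rec = table[["dprime_Tsub", "dprime_Tapp"]].to_numpy().mean()
        assert rec == pytest.approx(2.0, abs=0.1)

    def test_same_seed_identical(self):
        design = default_design()
        a = simulate_behavior(design, seed=3)
        b = simulate_behavior(design, seed=3)
        assert a.equals(b)

    def test_cell_dprime_recovery_and_ordering(self):
        """Generator → scorer round trip: cell means near target, expertise and
        transgression orderings reproduced (averaged over seeds)."""
        design = default_design()
        devs = {cell: [] for cell in DEFAULT_DPRIME}
        order_ok = 0
        seeds = range(10)
        for s in seeds:
            trials = simulate_behavior(design, seed=100 + s)
            table = score_responses(trials, design)
            means = table.groupby("group")[["dprime_Tsub", "dprime_Tapp"]].mean()
            for (g, c), target in DEFAULT_DPRIME.items():
                devs[(g, c)].append(means.loc[g, f"dprime_{c}"] - target)
            ok = True
            for c in ("Tsub", "Tapp"):
                col = means[f"dprime_{c}"]
                ok &= col["Expert"] > col["Amateur"] > col["Nonmusician"]
            for g in ("Nonmusician", "Amateur"):
                ok &= means.loc[g, "dprime_Tapp"] > means.loc[g, "dprime_Tsub"]
            order_ok += ok
        for cell, dev in devs.items():
            assert abs(np.mean(dev)) <= 0.15, (cell, np.mean(dev))
        assert order_ok >= 0.95 * len(list(seeds))
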