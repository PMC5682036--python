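"""Topographic measures, segmentation, model-order selection, back-fitting,
durations and their nonparametric statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from erpstates.microstate import (
    MicrostateModel,
    backfit,
    choose_k,
    duration_table,
    duration_tests,
    durations,
    explained_variance,
    gfp,
    gmd,
    segment,
    segmentation_criteria,
)
from erpstates.simulate import SimulationSpec, default_design, simulate_study_evoked
from erpstates.types import Evoked, StudyDesign


def _orthogonal_templates(k, n_ch, seed=0):
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(n_ch, k)))
    maps = q.T - q.T.mean(axis=1, keepdims=True)
    return maps / np.sqrt((maps**2).mean(axis=1, keepdims=True))


def _evoked_from_frames(frames, sfreq=250.0):
    return Evoked(data=frames, sfreq=sfreq, t0_index=0)


class TestGfp:
    def test_two_channel_closed_form(self):
        assert gfp(np.array([1.0, -1.0])) == pytest.approx(1.0)

    def test_constant_map_is_zero(self):
        assert gfp(np.full(32, 7.7)) == 0.0

    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=204)
        brute = np.sqrt(np.mean((v - v.mean()) ** 2))
        assert abs(gfp(v) - brute) < 1e-12


class TestGmd:
    def test_identical_maps(self):
        v = np.random.default_rng(1).normal(size=64)
        assert gmd(v, v) == pytest.approx(0.0, abs=1e-12)

    def test_polarity_reversal_is_two(self):
        v = np.random.default_rng(2).normal(size=64)
        assert gmd(v, -v) == pytest.approx(2.0, abs=1e-12)

    def test_identity_with_spatial_correlation(self):
        """GMD² = 2(1−r) on 1,000 random map pairs to 1e-10."""
        rng = np.random.default_rng(3)
        for _ in range(1000):
            u, v = rng.normal(size=(2, 32))
            r = np.corrcoef(u, v)[0, 1]
            assert abs(gmd(u, v) ** 2 - 2 * (1 - r)) < 1e-10

    def test_flat_map_rejected(self):
        with pytest.raises(ValueError):
            gmd(np.ones(8), np.arange(8.0))


class TestSegmentation:
    def _alternating_cells(self, k=4, n_ch=32, reps=10, frames_per=8):
        maps = _orthogonal_templates(k, n_ch)
        frames = np.concatenate(
            [np.tile(maps[i % k][:, None], (1, frames_per)) for i in range(k * reps)],
            axis=1,
        ) * 2.5
        return maps, {("G", "R"): _evoked_from_frames(frames)}

    def test_noiseless_orthogonal_templates_fully_recovered(self):
        maps, cells = self._alternating_cells()
        model, seqs = segment(cells, 4, n_restarts=10, min_frames=1, window=(0.0, 1280.0), seed=0)
        assert model.gev == pytest.approx(1.0, abs=1e-12)
        corr = np.abs(np.corrcoef(np.vstack([model.maps, maps]))[:4, 4:])
        assert np.allclose(np.sort(corr.max(axis=0)), 1.0, atol=1e-9)

    def test_recovers_study_templates(self, cells, templates):
        """Maps fitted on the 9 grand means match ground truth with |r| > 0.95."""
        model, _ = segment(cells, 7, n_restarts=30, seed=11)
        corr = np.abs(np.corrcoef(np.vstack([model.maps, templates]))[:7, 7:])
        best = corr.max(axis=0)
        assert (best > 0.95).all()
        # a one-to-one matching exists
        assert len(set(corr.argmax(axis=0))) == 7

    def test_no_segment_shorter_than_min_frames(self, cells):
        model, seqs = segment(cells, 7, n_restarts=30, min_frames=7, seed=12)
        for seq in seqs.values():
            run = 1
            for a, b in zip(seq.labels[:-1], seq.labels[1:]):
                if a == b:
                    run += 1
                else:
                    assert run >= 7 or a < 0
                    run = 1

    def test_gev_non_decreasing_in_k(self, cells):
        gevs = []
        for k in (3, 5, 7):
            model, _ = segment(cells, k, n_restarts=20, seed=13)
            gevs.append(model.gev)
        assert gevs == sorted(gevs)


class TestExplainedVariance:
    def test_perfect_template_data_is_one(self):
        maps = _orthogonal_templates(3, 16)
        frames = np.repeat(maps.T, 5, axis=1) * 4.0
        labels = np.repeat(np.arange(3), 5)
        model = MicrostateModel(maps=maps)
        assert explained_variance(model, frames, labels) == pytest.approx(1.0, abs=1e-12)

    def test_all_unlabeled_is_zero(self):
        maps = _orthogonal_templates(3, 16)
        frames = np.repeat(maps.T, 5, axis=1)
        model = MicrostateModel(maps=maps)
        assert explained_variance(model, frames, np.full(15, -1)) == 0.0

    def test_matches_frame_by_frame_brute_force(self):
        rng = np.random.default_rng(4)
        maps = _orthogonal_templates(4, 24, seed=5)
        frames = rng.normal(size=(24, 40))
        labels = rng.integers(0, 4, size=40)
        model = MicrostateModel(maps=maps)
        num = den = 0.0
        for t in range(40):
            f = frames[:, t] - frames[:, t].mean()
            g2 = (f**2).mean()
            r = np.corrcoef(f, maps[labels[t]])[0, 1]
            num += g2 * r**2
            den += g2
        assert abs(explained_variance(model, frames, labels) - num / den) < 1e-12


class TestModelOrderSelection:
    def test_noiseless_five_template_data_selects_five(self):
        maps = _orthogonal_templates(5, 64, seed=6)
        frames = np.concatenate(
            [np.tile(maps[i % 5][:, None], (1, 10)) for i in range(20)], axis=1
        ) * 3.0
        rng = np.random.default_rng(7)
        frames = frames + rng.normal(scale=1e-3, size=frames.shape)
        cells = {("G", "R"): _evoked_from_frames(frames)}
        crit, _ = segmentation_criteria(
            cells, range(2, 10), window=(0.0, 800.0), n_restarts=15, min_frames=1, seed=8
        )
        k_opt, tab = choose_k(crit)
        assert k_opt == 5

    def test_kl_zero_at_range_endpoints(self, cells):
        crit, _ = segmentation_criteria(cells, range(4, 9), n_restarts=10, seed=9)
        _, tab = choose_k(crit)
        assert tab["kl"].iloc[0] == 0.0
        assert tab["kl"].iloc[-1] == 0.0

    def test_cv_decreases_with_k_on_pure_noise(self):
        """The CV criterion must keep falling on structureless data (its
        overfitting penalty is weak when k ≪ channels); checked on 50 seeds."""
        for s in range(50):
            rng = np.random.default_rng(200 + s)
            frames = rng.normal(size=(204, 60))
            cells = {("G", "R"): _evoked_from_frames(frames)}
            crit, _ = segmentation_criteria(
                cells, range(2, 6), window=(0.0, 240.0), n_restarts=5, min_frames=1, seed=s
            )
            cv = crit["cv"].to_numpy()
            assert (np.diff(cv) < 0).all()

    def test_too_short_k_range_rejected(self, cells):
        crit, _ = segmentation_criteria(cells, range(4, 7), n_restarts=5, seed=10)
        with pytest.raises(ValueError):
            choose_k(crit)


class TestBackfit:
    def test_template_data_fully_labeled(self, templates):
        model = MicrostateModel(maps=templates)
        frames = np.tile(templates[3][:, None], (1, 238)) * 2.0
        ev = Evoked(data=frames, sfreq=250.0, t0_index=50)
        seq = backfit(model, ev, window=(295.0, 480.0))
        assert (seq.labels == 3).all()
        assert durations(seq, 7)[3] == pytest.approx(184.0)

    def test_zero_evoked_unlabeled(self, templates):
        model = MicrostateModel(maps=templates)
        ev = Evoked(data=np.zeros((204, 238)), sfreq=250.0, t0_index=50)
        seq = backfit(model, ev, window=(295.0, 480.0))
        assert (seq.labels == -1).all()


class TestDurations:
    def _seq(self, labels):
        from erpstates.microstate import LabelSequence

        return LabelSequence(labels=np.asarray(labels), sfreq=250.0, t0_index=-74)

    def test_window_has_46_frames_summing_to_184_ms(self):
        seq = self._seq(np.zeros(46, int))
        total = sum(durations(seq, 2).values())
        assert total == pytest.approx(184.0)

    def test_single_map_takes_all(self):
        d = durations(self._seq(np.full(46, 1)), 3)
        assert d[1] == pytest.approx(184.0)
        assert d[0] == d[2] == 0.0

    def test_alternating_maps_split_evenly(self):
        labels = np.tile([0, 1], 23)
        d = durations(self._seq(labels), 2)
        assert d[0] == d[1] == pytest.approx(92.0)

    def test_conservation_on_study_backfits(self, study, templates):
        """Labeled + unlabeled time equals the window length for every
        subject × condition."""
        _, evokeds, _ = study
        model = MicrostateModel(maps=templates)
        table = duration_table(model, evokeds[:30], window=(295.0, 480.0))
        sums = table.groupby(["subject_id", "condition"])["duration_ms"].sum()
        assert np.allclose(sums.to_numpy(), 184.0)


class TestDurationTests:
    def _table(self, groups_values, map_idx=3, condition="R"):
        rows = []
        for g, values in groups_values.items():
            for i, v in enumerate(values):
                rows.append(
                    {
                        "subject_id": f"{g}{i}",
                        "group": g,
                        "condition": condition,
                        "map": map_idx,
                        "duration_ms": v,
                    }
                )
        return pd.DataFrame(rows)

    def _design(self):
        return StudyDesign(["A", "B", "C"], ["R", "T"], {"A": 3, "B": 3, "C": 3})

    def test_identical_groups_h_zero(self):
        tab = self._table({"A": [5, 5, 5], "B": [5, 5, 5], "C": [5, 5, 5]})
        tab2 = tab.copy()
        tab2["condition"] = "T"
        out = duration_tests(pd.concat([tab, tab2]), self._design(), maps=[3])
        kw = [r for r in out if r["statistic"] == "KruskalWallis-H"]
        assert all(r["value"] == 0.0 and r["p"] == 1.0 for r in kw)

    def test_separated_groups_match_rank_brute_force(self):
        """H for {1,2,3},{4,5,6},{7,8,9} equals the hand-computed 7.2 and the
        gatekept Mann-Whitney contrasts report U = 0 for ordered pairs."""
        tab = self._table({"A": [1, 2, 3], "B": [4, 5, 6], "C": [7, 8, 9]})
        tab2 = tab.copy()
        tab2["condition"] = "T"
        out = duration_tests(pd.concat([tab, tab2]), self._design(), maps=[3])
        kw = [r for r in out if r["statistic"] == "KruskalWallis-H"][0]
        # brute force: H = 12/(N(N+1)) Σ n_i (R̄_i − (N+1)/2)² with ranks 1…9
        assert kw["value"] == pytest.approx(7.2, abs=1e-10)
        mwu = [r for r in out if r["statistic"] == "MannWhitney-U"]
        assert mwu, "significant omnibus must release the pairwise tests"
        assert all("gatekept" in r["correction"] for r in mwu)
        first = [r for r in mwu if r["effect"].endswith("A vs B")][0]
        # enumeration oracle: all 3 values of A precede B, so U(A<B) = 0
        assert first["value"] == 0.0

    def test_mwu_exact_one_sided_p_for_complete_separation(self):
        """U = 0 for {1,2,3} vs {4,5,6}; exact one-sided p = 1/C(6,3) = 0.05."""
        u, p = stats.mannwhitneyu([1, 2, 3], [4, 5, 6], alternative="less", method="exact")
        assert u == 0.0
        assert p == pytest.approx(0.05, abs=1e-12)
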