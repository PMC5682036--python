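"""Behavioral scoring, signal-detection d′, and the expertise × transgression ANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from erpstates.behavior import dprime, dprime_anova, group_contrasts, score_responses
from erpstates.simulate import default_design, simulate_behavior
from erpstates.types import StudyDesign


def _trials(responses_by_cond, subject="s1", group="G"):
    rows = []
    for cond, responses in responses_by_cond.items():
        for r in responses:
            rows.append(
                {"subject_id": subject, "group": group, "condition": cond, "response": r}
            )
    return pd.DataFrame(rows)


def _design(n=2):
    return StudyDesign(
        ["Nonmusician", "Amateur", "Expert"],
        ["R", "Tsub", "Tapp"],
        {"Nonmusician": n, "Amateur": n, "Expert": n},
    )


class TestScoring:
    def test_all_yes_responder(self):
        t = _trials({c: ["YES"] * 10 for c in ("R", "Tsub", "Tapp")})
        tab = score_responses(t, _design())
        assert tab.loc[0, "pc_R"] == 1.0
        assert tab.loc[0, "pc_Tsub"] == 0.0
        assert tab.loc[0, "pc_Tapp"] == 0.0

    def test_all_no_responder(self):
        t = _trials({c: ["NO"] * 10 for c in ("R", "Tsub", "Tapp")})
        tab = score_responses(t, _design())
        assert tab.loc[0, "pc_R"] == 0.0
        assert tab.loc[0, "pc_Tsub"] == 1.0

    def test_coin_flip_near_half(self):
        rng = np.random.default_rng(0)
        t = _trials(
            {
                c: np.where(rng.random(90) < 0.5, "YES", "NO").tolist()
                for c in ("R", "Tsub", "Tapp")
            }
        )
        tab = score_responses(t, _design())
        for c in ("R", "Tsub", "Tapp"):
            # binomial: sd of percent correct at n=90 is ≈ 5.3%, allow ±11
            assert abs(tab.loc[0, f"pc_{c}"] - 0.5) < 0.11

    def test_unknown_condition_rejected(self):
        t = _trials({"R": ["YES"], "Weird": ["NO"]})
        with pytest.raises(ValueError, match="unknown"):
            score_responses(t, _design())


class TestDprime:
    def test_equal_rates_give_zero(self):
        assert dprime(45, 90, 45, 90) == pytest.approx(0.0, abs=1e-12)

    def test_textbook_rates(self):
        # H=0.9, FA=0.1: d′ = z(0.9) − z(0.1) = 2·1.28155 (quantile oracle)
        assert dprime(81, 90, 9, 90) == pytest.approx(2.5631, abs=1e-4)

    def test_more_false_alarms_than_hits_is_negative(self):
        assert dprime(10, 90, 30, 90) < 0

    def test_extreme_rates_corrected_to_finite(self):
        d = dprime(90, 90, 0, 90)
        assert np.isfinite(d)
        expected = stats.norm.ppf(1 - 1 / 180) - stats.norm.ppf(1 / 180)
        assert d == pytest.approx(expected, abs=1e-12)

    def test_interior_rates_exactly_uncorrected(self):
        d = dprime(60, 90, 20, 90)
        assert d == pytest.approx(
            stats.norm.ppf(60 / 90) - stats.norm.ppf(20 / 90), abs=1e-12
        )

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            dprime(0, 0, 0, 10)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        h1=st.integers(0, 89),
        fa=st.integers(0, 90),
    )
    def test_monotone_in_hits_and_false_alarms(self, h1, fa):
        assert dprime(h1 + 1, 90, fa, 90) > dprime(h1, 90, fa, 90)
        if fa < 90:
            assert dprime(h1, 90, fa + 1, 90) < dprime(h1, 90, fa, 90)


class TestDprimeAnova:
    def _table(self, dsub, dapp, groups):
        return pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(len(groups))],
                "group": groups,
                "dprime_Tsub": dsub,
                "dprime_Tapp": dapp,
            }
        )

    def test_zero_effect_gives_zero_f(self):
        groups = ["Nonmusician"] * 2 + ["Amateur"] * 2 + ["Expert"] * 2
        tab = self._table([1.0] * 6, [1.0] * 6, groups)
        out = dprime_anova(tab, _design())
        assert all(r["value"] == 0.0 for r in out)

    def test_toy_design_matches_brute_force(self):
        from .test_anova import brute_force_mixed

        groups = ["Nonmusician"] * 2 + ["Amateur"] * 2 + ["Expert"] * 2
        dsub = [0.3, 0.6, 1.4, 1.7, 3.5, 3.9]
        dapp = [1.5, 1.8, 3.4, 3.9, 4.0, 4.4]
        tab = self._table(dsub, dapp, groups)
        out = dprime_anova(tab, _design())
        y = np.column_stack([dsub, dapp])
        brute = brute_force_mixed(y, groups)
        by_label = {r["effect"]: r for r in out}
        assert by_label["Expertise"]["value"] == pytest.approx(brute["A"][0], abs=1e-8)
        assert by_label["Transgression"]["value"] == pytest.approx(brute["B"][0], abs=1e-8)
        assert by_label["Expertise x Transgression"]["value"] == pytest.approx(
            brute["AB"][0], abs=1e-8
        )
        assert by_label["Expertise"]["effect_size"] == pytest.approx(brute["A"][1], abs=1e-8)

    def test_study_scale_main_effects_significant(self):
        """At the generator's default effect sizes both main effects must come
        out significant (checked on a handful of fixed seeds)."""
        design = default_design()
        for seed in range(5):
            trials = simulate_behavior(design, seed=300 + seed)
            table = score_responses(trials, design)
            out = {r["effect"]: r for r in dprime_anova(table, design)}
            assert out["Expertise"]["p"] < 0.05
            assert out["Transgression"]["p"] < 0.05

    def test_missing_dprime_rejected(self):
        groups = ["Nonmusician"] * 2 + ["Amateur"] * 2 + ["Expert"] * 2
        tab = self._table([1.0] * 6, [np.nan] * 6, groups)
        with pytest.raises(ValueError):
            dprime_anova(tab, _design())


class TestGroupContrasts:
    def test_identical_groups_all_corrected_p_one(self):
        groups = ["Nonmusician"] * 3 + ["Amateur"] * 3 + ["Expert"] * 3
        tab = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(9)],
                "group": groups,
                "dprime_Tsub": [1.0] * 9,
                "dprime_Tapp": [2.0] * 9,
            }
        )
        out = group_contrasts(tab, _design(3))
        for rec in out:
            if "paired" not in rec["effect"]:
                assert rec["p"] == 1.0

    def test_constant_paired_difference_hits_degenerate_branch(self, caplog):
        groups = ["Nonmusician"] * 3 + ["Amateur"] * 3 + ["Expert"] * 3
        tab = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(9)],
                "group": groups,
                "dprime_Tsub": [1.0, 1.5, 2.0] * 3,
                "dprime_Tapp": [2.0, 2.5, 3.0] * 3,  # differences all exactly 1
            }
        )
        with caplog.at_level("WARNING", logger="erpstates"):
            out = group_contrasts(tab, _design(3))
        paired = [r for r in out if "paired" in r["effect"]]
        assert paired and all(r["p"] == 1.0 and r["value"] == 0.0 for r in paired)
        assert "degenerate" in caplog.text

    def test_independent_t_matches_direct_formula(self):
        rng = np.random.default_rng(1)
        groups = ["Nonmusician"] * 4 + ["Amateur"] * 4 + ["Expert"] * 4
        dsub = rng.normal(size=12) + np.repeat([0, 1, 3], 4)
        dapp = rng.normal(size=12) + np.repeat([1, 3, 4], 4)
        tab = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(12)],
                "group": groups,
                "dprime_Tsub": dsub,
                "dprime_Tapp": dapp,
            }
        )
        out = group_contrasts(tab, _design(4))
        rec = [r for r in out if r["effect"] == "Tsub|Nonmusician vs Amateur"][0]
        xa, xb = dsub[:4], dsub[4:8]
        # brute-force pooled-variance t
        sp2 = (((xa - xa.mean()) ** 2).sum() + ((xb - xb.mean()) ** 2).sum()) / 6
        t_ref = (xa.mean() - xb.mean()) / np.sqrt(sp2 * (1 / 4 + 1 / 4))
        assert rec["value"] == pytest.approx(t_ref, abs=1e-10)
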