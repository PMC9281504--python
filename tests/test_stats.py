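"""Statistical layer: transforms, tests, effect sizes, ANOVA vs oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pushrim import (
    ParameterPanel,
    bonferroni,
    classify_effect_size,
    cohens_d_pooled,
    log_transform,
    paired_t,
    partial_eta_squared,
    rm_anova_2x2,
    shapiro_wilk,
)
from pushrim.errors import DegenerateDataError
from pushrim.stats import rm_anova_2x2_batch


def brute_force_anova(y):
    """Independent oracle: explicit cell-mean SS decomposition, 2x2 within."""
    n = y.shape[0]
    grand = y.mean()
    subj = y.mean(axis=(1, 2))
    out = {}
    for eff, axis in (("condition", 1), ("side", 2)):
        lvl = y.mean(axis=tuple({0, 1, 2} - {axis}))
        ss = 2 * n * np.sum((lvl - grand) ** 2)
        sub_eff = y.mean(axis=3 - axis)
        ss_err = 2 * np.sum(
            (sub_eff - subj[:, None] - lvl[None, :] + grand) ** 2
        )
        out[eff] = (ss, ss_err)
    a = y.mean(axis=(0, 2))
    b = y.mean(axis=(0, 1))
    ab = y.mean(axis=0)
    ss_ab = n * np.sum((ab - a[:, None] - b[None, :] + grand) ** 2)
    as_ = y.mean(axis=2)
    bs = y.mean(axis=1)
    resid = (
        y
        - as_[:, :, None]
        - bs[:, None, :]
        - ab[None]
        + a[None, :, None]
        + b[None, None, :]
        + subj[:, None, None]
        - grand
    )
    out["interaction"] = (ss_ab, np.sum(resid**2))
    return out


class TestLogTransform:
    def test_inverse_of_exp(self):
        np.testing.assert_allclose(log_transform([np.exp(2.5)]), [2.5])

    def test_zero_rejected_with_name(self):
        with pytest.raises(ValueError, match="pt"):
            log_transform([1.0, 0.0], parameter="pt")

    def test_monotone(self):
        x = np.array([0.3, 1.0, 2.0, 10.0])
        assert np.all(np.diff(log_transform(x)) > 0)


class TestShapiroWilk:
    def test_constant_vector_degenerate(self):
        with pytest.raises(DegenerateDataError):
            shapiro_wilk([5.0] * 10)

    def test_skewed_reference_sample(self):
        """Right-skewed fixed sample: W ~ 0.79, normality rejected."""
        x = [148, 154, 158, 160, 161, 162, 166, 170, 182, 195, 236]
        w, p = shapiro_wilk(x)
        assert w == pytest.approx(0.789, abs=0.005)
        assert p < 0.05

    def test_size_limits(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])

    def test_type_one_error_rate(self):
        """Gaussian samples of n=16: ~5% rejections at alpha = 0.05."""
        rng = np.random.default_rng(11)
        rejections = sum(
            shapiro_wilk(rng.normal(size=16))[1] < 0.05 for _ in range(2000)
        )
        assert 0.035 <= rejections / 2000 <= 0.065


class TestPairedT:
    def test_hand_computed_example(self):
        x1 = np.array([10.0, 11.0, 12.0, 13.0])
        x0 = x1 + np.array([1.0, 2.0, 3.0, 4.0])
        t, dof, p = paired_t(x0, x1)
        assert t == pytest.approx(2.5 / (np.std([1, 2, 3, 4], ddof=1) / 2))
        assert t == pytest.approx(3.873, abs=1e-3)
        assert dof == 3

    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(2)
        x0, x1 = rng.normal(size=(2, 12))
        t1, _, p1 = paired_t(x0, x1)
        t2, _, p2 = paired_t(x1, x0)
        assert t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(p1)

    def test_identical_inputs_degenerate(self):
        with pytest.raises(DegenerateDataError):
            paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


class TestCohensD:
    @pytest.mark.parametrize(
        "m0, s0, m1, s1, expected",
        [
            (117.77, 45.36, 86.53, 38.65, 0.741),
            (29.36, 6.93, 35.82, 10.94, 0.705),
        ],
    )
    def test_reference_rows(self, m0, s0, m1, s1, expected):
        assert cohens_d_pooled(m0, s0, m1, s1) == pytest.approx(
            expected, abs=5e-4
        )

    def test_equal_means_zero(self):
        assert cohens_d_pooled(5.0, 1.0, 5.0, 2.0) == 0.0

    @given(
        m0=st.floats(0.1, 100),
        s0=st.floats(0.1, 50),
        m1=st.floats(0.1, 100),
        s1=st.floats(0.1, 50),
        a=st.floats(0.01, 100),
    )
    @settings(max_examples=50, deadline=None)
    def test_symmetry_and_scale_invariance(self, m0, s0, m1, s1, a):
        d = cohens_d_pooled(m0, s0, m1, s1)
        assert cohens_d_pooled(m1, s1, m0, s0) == pytest.approx(d, rel=1e-12)
        assert cohens_d_pooled(a * m0, a * s0, a * m1, a * s1) == pytest.approx(
            d, rel=1e-9
        )

    def test_reference_sd_variant(self):
        assert cohens_d_pooled(10.0, 2.0, 8.0, 4.0, method="reference_sd") == 1.0

    def test_double_zero_sd_degenerate(self):
        with pytest.raises(DegenerateDataError):
            cohens_d_pooled(1.0, 0.0, 2.0, 0.0)


class TestEtaAndBonferroni:
    @pytest.mark.parametrize(
        "ss_e, ss_r, expected", [(1, 3, 0.25), (0, 5, 0.0), (5, 0, 1.0)]
    )
    def test_partial_eta(self, ss_e, ss_r, expected):
        assert partial_eta_squared(ss_e, ss_r) == pytest.approx(expected)

    def test_bonferroni(self):
        np.testing.assert_allclose(
            bonferroni([0.01, 0.4, 0.2], 5), [0.05, 1.0, 1.0]
        )
        np.testing.assert_allclose(bonferroni([0.3], 1), [0.3])

    @pytest.mark.parametrize(
        "value, kind, expected",
        [
            (0.741, "d", "moderate"),
            (0.148, "eta2p", "large"),
            (0.0, "d", "negligible"),
            (0.2, "d", "small"),
            (0.8, "d", "large"),
            (0.06, "eta2p", "medium"),
        ],
    )
    def test_classification(self, value, kind, expected):
        assert classify_effect_size(value, kind) == expected

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            classify_effect_size(0.5, "r")


class TestRmAnova:
    def test_no_within_subject_variation(self):
        y = np.repeat(
            np.arange(1.0, 9.0)[:, None, None], 4, axis=1
        ).reshape(8, 2, 2)
        res = rm_anova_2x2(ParameterPanel(y))
        for r in res:
            assert r.statistic == pytest.approx(0.0, abs=1e-12)
            assert r.effect_size == pytest.approx(0.0, abs=1e-12)

    def test_pure_condition_effect(self):
        rng = np.random.default_rng(4)
        base = rng.lognormal(3, 0.3, 6)
        y = np.empty((6, 2, 2))
        y[:, 0, :] = (base + 1.0)[:, None]
        y[:, 1, :] = base[:, None]
        res = {r.effect_name: r for r in rm_anova_2x2(ParameterPanel(y))}
        assert res["condition"].effect_size == pytest.approx(1.0)
        assert res["side"].statistic == pytest.approx(0.0, abs=1e-9)
        assert res["interaction"].statistic == pytest.approx(0.0, abs=1e-9)

    def test_matches_brute_force_oracle_random_panels(self):
        """F, dof, eta2p match the explicit SS decomposition to 1e-10."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(3, 20))
            y = rng.lognormal(2.0, 0.5, (n, 2, 2))
            oracle = brute_force_anova(y)
            for r in rm_anova_2x2(ParameterPanel(y)):
                ss_e, ss_err = oracle[r.effect_name]
                f_oracle = ss_e / (ss_err / (n - 1))
                assert r.statistic == pytest.approx(f_oracle, abs=1e-10, rel=1e-10)
                assert r.dof == (1.0, float(n - 1))
                assert r.effect_size == pytest.approx(
                    ss_e / (ss_e + ss_err), abs=1e-12
                )

    def test_f_equals_t_squared_on_marginals(self):
        """For 2-level factors, F equals the squared paired t on the
        factor's marginal means."""
        rng = np.random.default_rng(12)
        for _ in range(20):
            y = rng.lognormal(1.0, 0.4, (10, 2, 2))
            res = {r.effect_name: r for r in rm_anova_2x2(ParameterPanel(y))}
            for effect, axis in (("condition", 2), ("side", 1)):
                marg = y.mean(axis=axis)
                t, _, p = paired_t(marg[:, 0], marg[:, 1])
                assert res[effect].statistic == pytest.approx(t**2, abs=1e-9)
                assert res[effect].p_raw == pytest.approx(p, abs=1e-12)

    def test_matches_pingouin(self):
        """Cross-check against an independent reference implementation."""
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(21)
        y = rng.lognormal(3, 0.4, (9, 2, 2))
        rows = [
            dict(subj=i, cond=j, side=k, y=y[i, j, k])
            for i, j, k in itertools.product(range(9), range(2), range(2))
        ]
        aov = pg.rm_anova(
            data=pd.DataFrame(rows), dv="y", within=["cond", "side"],
            subject="subj", detailed=True, effsize="np2",
        ).set_index("Source")
        res = {r.effect_name: r for r in rm_anova_2x2(ParameterPanel(y))}
        for effect, source in (
            ("condition", "cond"),
            ("side", "side"),
            ("interaction", "cond * side"),
        ):
            assert res[effect].statistic == pytest.approx(
                float(aov.loc[source, "F"]), rel=1e-9
            )
            assert res[effect].effect_size == pytest.approx(
                float(aov.loc[source, "np2"]), rel=1e-9
            )

    def test_incomplete_panel_rejected(self):
        y = np.ones((4, 2, 2))
        y[1, 0, 1] = np.nan
        with pytest.raises(DegenerateDataError):
            ParameterPanel(y)

    def test_type_one_error_calibration(self):
        """Null lognormal panels, n=16: each effect rejects at ~5%."""
        rng = np.random.default_rng(123)
        y = rng.lognormal(3.0, 0.4, (2000, 16, 2, 2))
        res = rm_anova_2x2_batch(y)
        for effect in ("condition", "side", "interaction"):
            rate = float(np.mean(res[effect]["p"] < 0.05))
            assert 0.035 <= rate <= 0.065


class TestPanelFromLong:
    def test_round_trip(self):
        rng = np.random.default_rng(9)
        y = rng.lognormal(0, 1, (5, 2, 2))
        rows = []
        conds = ["with_racket", "without_racket"]
        sides = ["dominant", "non_dominant"]
        for i, j, k in itertools.product(range(5), range(2), range(2)):
            rows.append(
                dict(
                    participant=f"S{i}", condition=conds[j], side=sides[k],
                    parameter="pt", value=y[i, j, k],
                )
            )
        panel = ParameterPanel.from_long(pd.DataFrame(rows), "pt")
        np.testing.assert_allclose(panel.values, y)

    def test_missing_cell_detected(self):
        rows = [
            dict(participant="S0", condition="with_racket", side="dominant",
                 parameter="pt", value=1.0),
            dict(participant="S1", condition="with_racket", side="dominant",
                 parameter="pt", value=2.0),
        ]
        with pytest.raises(DegenerateDataError):
            ParameterPanel.from_long(pd.DataFrame(rows), "pt")
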