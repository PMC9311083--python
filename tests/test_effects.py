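"""Effect-size oracles, direction conventions and exclusion accounting."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sexplas.effects import (
    all_pairwise_contrasts,
    compute_effects,
    direction_convention,
    hedges_d_value,
    lncvr_value,
)
from tests.conftest import make_group


def brute_force_d(m1, sd1, n1, m2, sd2, n2):
    """Independent spelling of the Hedges' d arithmetic."""
    df = n1 + n2 - 2
    sp = math.sqrt(((n1 - 1) * sd1 * sd1 + (n2 - 1) * sd2 * sd2) / df)
    d = (1 - 3 / (4 * df - 1)) * (m1 - m2) / sp
    return d, (n1 + n2) / (n1 * n2) + d * d / (2 * df)


class TestHedgesD:
    def test_identical_groups_give_zero(self):
        for n in (3, 10, 50):
            d, v = hedges_d_value(5.0, 1.0, n, 5.0, 2.0, n)
            assert d == 0.0
            assert v == pytest.approx(2 / n)

    def test_hand_worked_example(self):
        # m_cold=10, m_warm=8, sd=2, n=10 per group: J(18 df) * 1
        d, v = hedges_d_value(10, 2, 10, 8, 2, 10)
        assert d == pytest.approx((1 - 3 / 71) * 1.0, abs=1e-12)
        assert d == pytest.approx(0.9577464788732395, abs=1e-12)

    @given(
        m1=st.floats(-50, 50), m2=st.floats(-50, 50),
        sd1=st.floats(0.1, 9), sd2=st.floats(0.1, 9),
        n1=st.integers(3, 80), n2=st.integers(3, 80),
    )
    @settings(max_examples=200, derandomize=True)
    def test_matches_independent_arithmetic(self, m1, m2, sd1, sd2, n1, n2):
        got = hedges_d_value(m1, sd1, n1, m2, sd2, n2)
        want = brute_force_d(m1, sd1, n1, m2, sd2, n2)
        assert got[0] == pytest.approx(want[0], abs=1e-12)
        assert got[1] == pytest.approx(want[1], abs=1e-12)

    @given(
        m1=st.floats(-50, 50), m2=st.floats(-50, 50),
        sd1=st.floats(0.1, 9), sd2=st.floats(0.1, 9),
        n1=st.integers(3, 80), n2=st.integers(3, 80),
        c=st.floats(0.01, 100),
    )
    @settings(max_examples=100, derandomize=True)
    def test_swap_antisymmetry_and_scale_invariance(self, m1, m2, sd1, sd2, n1, n2, c):
        d_ab, v_ab = hedges_d_value(m1, sd1, n1, m2, sd2, n2)
        d_ba, v_ba = hedges_d_value(m2, sd2, n2, m1, sd1, n1)
        assert d_ba == pytest.approx(-d_ab, abs=1e-12)
        # the d-free part of V is invariant under the swap
        assert v_ba - d_ba**2 / (2 * (n1 + n2 - 2)) == pytest.approx(
            v_ab - d_ab**2 / (2 * (n1 + n2 - 2)), abs=1e-12
        )
        d_scaled, _ = hedges_d_value(c * m1, c * sd1, n1, c * m2, c * sd2, n2)
        assert d_scaled == pytest.approx(d_ab, rel=1e-9)

    def test_estimates_true_effect_with_small_bias(self, rng):
        """Computed d converges on the generating standardised difference."""
        delta, n, reps = 1.0, 100, 10_000
        x1 = rng.normal(delta, 1.0, (reps, n))
        x2 = rng.normal(0.0, 1.0, (reps, n))
        ds = [
            hedges_d_value(a.mean(), a.std(ddof=1), n, b.mean(), b.std(ddof=1), n)[0]
            for a, b in zip(x1, x2)
        ]
        assert np.mean(ds) == pytest.approx(delta, rel=0.02)


class TestLnCVR:
    def test_equal_cvs_equal_n_give_zero(self):
        val, _ = lncvr_value(10, 2, 15, 20, 4, 15)
        assert val == pytest.approx(0.0, abs=1e-15)

    def test_hand_worked_example(self):
        # CV ratio 2 with equal n: corrections cancel
        val, v = lncvr_value(100, 20, 20, 100, 10, 20)
        assert val == pytest.approx(math.log(2), abs=1e-12)
        expected_v = (
            20**2 / (20 * 100**2) + 1 / 38 + 10**2 / (20 * 100**2) + 1 / 38
        )
        assert v == pytest.approx(expected_v, abs=1e-12)

    def test_small_sample_correction_with_unequal_n(self):
        val, _ = lncvr_value(100, 20, 11, 100, 10, 21)
        assert val == pytest.approx(math.log(2) + 1 / 20 - 1 / 40, abs=1e-12)

    @given(
        m1=st.floats(1, 50), m2=st.floats(1, 50),
        sd1=st.floats(0.1, 9), sd2=st.floats(0.1, 9),
        n1=st.integers(3, 80), n2=st.integers(3, 80),
    )
    @settings(max_examples=100, derandomize=True)
    def test_antisymmetry(self, m1, m2, sd1, sd2, n1, n2):
        ab, _ = lncvr_value(m1, sd1, n1, m2, sd2, n2)
        ba, _ = lncvr_value(m2, sd2, n2, m1, sd1, n1)
        assert ab == pytest.approx(-ba, abs=1e-12)

    def test_zero_mean_rejected(self):
        with pytest.raises(ZeroDivisionError):
            lncvr_value(0.0, 1, 10, 5, 1, 10)


class TestDirectionConvention:
    cold = {"temperature": 18.0}
    warm = {"temperature": 25.0}

    @pytest.mark.parametrize("trait", ["development_time", "longevity", "size", "survival"])
    def test_cold_minuend_classes(self, trait):
        minu, subt = direction_convention(trait, self.cold, self.warm)
        assert minu["temperature"] == 18.0

    @pytest.mark.parametrize("trait", ["cold_resistance", "heat_resistance", "gene_expression"])
    def test_warm_minuend_classes(self, trait):
        minu, subt = direction_convention(trait, self.cold, self.warm)
        assert minu["temperature"] == 25.0

    def test_equal_temperatures_unorderable(self):
        with pytest.raises(ValueError, match="orderable"):
            direction_convention("longevity", self.cold, dict(self.cold))

    def test_override_orders_duration_manipulations(self):
        a, b = {"temperature": None, "id": "a"}, {"temperature": None, "id": "b"}
        minu, _ = direction_convention("longevity", a, b, override="a_colder")
        assert minu["id"] == "a"
        minu, _ = direction_convention("heat_resistance", a, b, override="a_colder")
        assert minu["id"] == "b"


class TestPairwiseContrasts:
    def _experiment(self, levels, sexes=("F", "M"), sd=2.0, **kw):
        rows = []
        for i, temp in enumerate(levels):
            for sex in sexes:
                rows.append(
                    make_group("s1", "e1", f"L{i}", sex, 10 + i, sd, 10, temp, **kw)
                )
        return pd.DataFrame(rows)

    @pytest.mark.parametrize("n_levels, n_pairs", [(2, 1), (3, 3), (4, 6)])
    def test_contrast_counts(self, n_levels, n_pairs):
        exp = self._experiment([18 + 2 * i for i in range(n_levels)])
        eff, exc = all_pairwise_contrasts(exp)
        d = [e for e in eff if e.kind == "hedges_d"]
        assert len(d) == 2 * n_pairs  # per sex
        assert len([e for e in eff if e.kind == "lncvr_treatment"]) == 2 * n_pairs
        assert len([e for e in eff if e.kind == "lncvr_sex"]) == n_levels
        assert not exc

    def test_zero_sd_excluded_per_sex(self):
        exp = self._experiment([18, 22, 26])
        # males at L0 have sd 0: kills 2 of the 3 male contrasts
        exp.loc[(exp["treatment_level_id"] == "L0") & (exp["sex"] == "M"), "sd"] = 0.0
        eff, exc = all_pairwise_contrasts(exp)
        d = [e for e in eff if e.kind == "hedges_d"]
        assert len([e for e in d if e.sex == "F"]) == 3
        assert len([e for e in d if e.sex == "M"]) == 1
        assert {x.reason for x in exc} == {"zero_sd"}

    def test_small_pooled_n_excluded(self):
        exp = self._experiment([18, 25])
        exp["n"] = 2
        eff, exc = all_pairwise_contrasts(exp)
        assert not [e for e in eff if e.kind == "hedges_d"]
        assert all(x.reason == "small_pooled_n" for x in exc)

    def test_longevity_longer_when_cold_gives_positive_d(self):
        rows = [
            make_group("s", "e", "cold", sex, 10, 2, 10, 18.0)
            for sex in ("F", "M")
        ] + [
            make_group("s", "e", "warm", sex, 8, 2, 10, 28.0)
            for sex in ("F", "M")
        ]
        eff, _ = all_pairwise_contrasts(pd.DataFrame(rows))
        for e in eff:
            if e.kind == "hedges_d":
                assert e.value > 0

    def test_lncvr_sex_positive_when_males_more_variable(self):
        rows = [
            make_group("s", "e", "L1", "F", 10, 1, 10, 18.0),
            make_group("s", "e", "L1", "M", 10, 2, 10, 18.0),
            make_group("s", "e", "L2", "F", 12, 1, 10, 25.0),
            make_group("s", "e", "L2", "M", 12, 2, 10, 25.0),
        ]
        eff, _ = all_pairwise_contrasts(pd.DataFrame(rows))
        sex_effects = [e for e in eff if e.kind == "lncvr_sex"]
        assert sex_effects and all(e.value > 0 for e in sex_effects)


class TestComputeEffects:
    def test_accounting_balances(self, small_synth):
        eff, exc = compute_effects(small_synth.data)
        # every attempted contrast is either an effect or a coded exclusion
        n_exp = small_synth.data.groupby(["study_id", "experiment_id"]).ngroups
        # 2 levels per experiment: 2 d + 2 lncvr_treatment + 2 lncvr_sex each
        assert len(eff) + len(exc) == 6 * n_exp
        if len(exc):
            assert set(exc["reason"]) <= {"zero_sd", "small_pooled_n", "zero_mean",
                                          "unorderable_levels"}

    def test_unorderable_without_override_excluded(self):
        rows = [
            make_group("s", "e", "short", sex, 10, 2, 10, None)
            for sex in ("F", "M")
        ] + [
            make_group("s", "e", "long", sex, 8, 2, 10, None)
            for sex in ("F", "M")
        ]
        eff, exc = compute_effects(pd.DataFrame(rows))
        kinds = set(eff["kind"]) if len(eff) else set()
        assert "hedges_d" not in kinds
        assert (exc["reason"] == "unorderable_levels").sum() == 4
        # lncvr_sex needs no ordering and survives
        assert (eff["kind"] == "lncvr_sex").sum() == 2
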