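import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from poretrace.analytics import (
    SectionModelParams,
    VesiclePopulationRecord,
    loglog_scaling_fit,
    mann_whitney_u,
    ratio_vs_size,
    section_model_pore_radius,
)


class TestSectionModel:
    def test_zero_probability_gives_closed_pore(self):
        assert section_model_pore_radius(150e-9, 0.0, 0.25) == 0.0

    def test_boundary_gives_vesicle_radius(self):
        assert section_model_pore_radius(150e-9, 1.0, 0.25) == \
            pytest.approx(150e-9, rel=1e-12)

    def test_reference_value(self):
        # R_ves 150 nm, p_e 0.01, k_d 0.25 -> 2*150*sqrt(0.0025) = 15 nm
        assert section_model_pore_radius(150e-9, 0.01, 0.25) == \
            pytest.approx(15e-9, rel=1e-12)

    def test_unphysical_product_rejected(self):
        with pytest.raises(ValueError):
            section_model_pore_radius(150e-9, 0.9, 0.5)
        with pytest.raises(ValueError):
            SectionModelParams(p_e=1.5, k_d=0.2)

    @given(st.floats(1e-4, 0.25), st.floats(0.01, 1.0))
    def test_pore_area_never_exceeds_contact_area(self, p_e, k_d):
        if p_e * k_d > 0.25:
            return
        params = SectionModelParams(p_e=p_e, k_d=k_d)
        r_ves = 150e-9
        assert params.max_pore_area(r_ves) <= params.contact_area(r_ves)

    def test_record_requires_pore_smaller_than_vesicle(self):
        with pytest.raises(ValueError):
            VesiclePopulationRecord(r_ves=100e-9, r_p_max=150e-9,
                                    t_expa=1e-3, t_rise=1e-3, group="vesicle")


class TestLogLogScaling:
    def test_exact_power_law(self):
        rv = np.array([50, 100, 200, 400]) * 1e-9
        rp = 0.1 * rv ** 1.7 / (1e-9 ** 0.7)
        df = pd.DataFrame({"rves_m": rv, "rpmax_m": rp})
        slope, intercept, r = loglog_scaling_fit(df)
        assert slope == pytest.approx(1.7, rel=1e-9)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_two_points_exact_line(self):
        df = pd.DataFrame({"rves_m": [1e-7, 2e-7], "rpmax_m": [1e-8, 4e-8]})
        slope, intercept, r = loglog_scaling_fit(df)
        assert slope == pytest.approx(2.0, rel=1e-9)
        assert abs(r) == pytest.approx(1.0, abs=1e-12)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(2)
        rv = 10 ** rng.uniform(-7.3, -6.4, 40)
        rp = 10 ** (1.2 * np.log10(rv) + 0.9 + rng.normal(0, 0.05, 40))
        df = pd.DataFrame({"rves_m": rv, "rpmax_m": rp})
        s1, i1, r1 = loglog_scaling_fit(df)
        df2 = pd.DataFrame({"rves_m": 10 * rv, "rpmax_m": rp})
        s2, i2, r2 = loglog_scaling_fit(df2)
        assert s2 == pytest.approx(s1, rel=1e-9)
        assert i2 == pytest.approx(i1 - s1, rel=1e-6)
        assert r2 == pytest.approx(r1, rel=1e-9)

    def test_zero_variance_rejected(self):
        df = pd.DataFrame({"rves_m": [1e-7, 1e-7], "rpmax_m": [1e-8, 2e-8]})
        with pytest.raises(ValueError):
            loglog_scaling_fit(df)


class TestRatioVsSize:
    def test_constant_product_gives_constant_ratio(self):
        rv = np.linspace(50e-9, 400e-9, 20)
        rp = 2 * rv * np.sqrt(0.0025)
        df = pd.DataFrame({"rves_m": rv, "rpmax_m": rp})
        pairs = ratio_vs_size(df)
        assert np.allclose(pairs[:, 1], 2 * np.sqrt(0.0025))

    def test_empty_input(self):
        assert ratio_vs_size(pd.DataFrame({"rves_m": [], "rpmax_m": []})).size == 0

    def test_superlinear_scaling_gives_increasing_ratio(self):
        # a log-log slope > 1 implies the relative pore size grows with
        # vesicle size (Spearman trend > 0 on a synthetic population)
        rng = np.random.default_rng(7)
        rv = 10 ** rng.uniform(-7.2, -6.5, 100)
        rp = 10 ** (3.43 * np.log10(rv) + 15.26 + rng.normal(0, 0.08, 100))
        keep = rp < rv
        df = pd.DataFrame({"rves_m": rv[keep], "rpmax_m": rp[keep]})
        pairs = ratio_vs_size(df)
        rho = stats.spearmanr(pairs[:, 0], pairs[:, 1]).statistic
        assert rho > 0.5


class TestMannWhitney:
    def test_identical_groups_p_one(self):
        u, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert u == pytest.approx(4.5)
        assert p == 1.0

    def test_complete_separation_small_n(self):
        # {1,2,3} vs {4,5,6}: U=0, exact two-tailed p = 2/20 = 0.1
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_large_shift_minimal_p(self):
        a = [1.0, 2.0, 3.5, 4.0, 5.1]
        u, p = mann_whitney_u(a, [x + 1000 for x in a])
        assert u == 0.0
        assert p == pytest.approx(2 / 252, rel=1e-9)  # 2/C(10,5)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_scipy_exact_without_ties(self, seed):
        rng = np.random.default_rng(seed)
        n_a, n_b = rng.integers(2, 9, 2)
        a = rng.normal(0, 1, n_a)
        b = rng.normal(0.5, 1, n_b)
        u, p = mann_whitney_u(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert u == pytest.approx(float(ref.statistic))
        assert p == pytest.approx(float(ref.pvalue), rel=1e-9)

    def test_enumeration_handles_ties(self):
        # brute-force oracle computed inline for a tied sample
        a, b = np.array([1.0, 2.0, 2.0]), np.array([2.0, 3.0])
        u_obs, p = mann_whitney_u(a, b)
        pooled = np.concatenate([a, b])
        us = []
        for comb in itertools.combinations(range(5), 3):
            sel = np.zeros(5, bool)
            sel[list(comb)] = True
            x, y = pooled[sel], pooled[~sel]
            us.append(np.sum(x[:, None] > y[None, :])
                      + 0.5 * np.sum(x[:, None] == y[None, :]))
        us = np.array(us)
        expect = min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))
        assert p == pytest.approx(expect)

    def test_large_n_uses_tie_corrected_normal(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 5, 40).astype(float)
        b = rng.integers(1, 6, 35).astype(float)
        u, p = mann_whitney_u(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic")
        assert p == pytest.approx(float(ref.pvalue), rel=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])
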