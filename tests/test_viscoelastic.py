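"""Prony-series relaxation: evaluation, fitting, long-term modulus, statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thyromech import (
    LoadingMode,
    PronyParams,
    UniaxialRecord,
    fit_prony,
    long_term_modulus,
    prony_eval,
    relaxation_summary_stats,
)
from thyromech.datasets import RELAXATION_STRESS_REPLICATES
from thyromech.viscoelastic import RelaxationSummary


def relaxation_record(params, t, eps0=0.25, noise=None):
    sigma = eps0 * np.asarray(prony_eval(params, t))
    if noise is not None:
        sigma = sigma * (1.0 + noise)
    return UniaxialRecord(mode=LoadingMode.RELAXATION, time_s=t,
                          stress_MPa=sigma, hold_strain=eps0)


class TestPronyEval:
    def test_instantaneous_modulus_is_total_sum(self, prony_reference):
        assert prony_eval(prony_reference, 0.0) == pytest.approx(3.49)
        assert prony_reference.instantaneous == pytest.approx(3.49)

    def test_long_time_limit_is_equilibrium(self, prony_reference):
        assert prony_eval(prony_reference, 1e9) == pytest.approx(0.51, rel=1e-9)

    def test_single_term_closed_form(self):
        p = PronyParams(moduli=(1.0,), taus=(1.0,), equilibrium=0.0)
        assert prony_eval(p, 1.0) == pytest.approx(np.exp(-1.0))

    def test_negative_time_rejected(self, prony_reference):
        with pytest.raises(ValueError):
            prony_eval(prony_reference, -1.0)

    @given(t1=st.floats(0.0, 5e3), t2=st.floats(0.0, 5e3))
    @settings(deadline=None)
    def test_strictly_decreasing_for_positive_moduli(self, prony_reference, t1, t2):
        lo, hi = sorted((t1, t2))
        if hi - lo > 1e-6 * (1.0 + hi):  # below this the decay is sub-ulp
            assert prony_eval(prony_reference, hi) < prony_eval(prony_reference, lo)

    def test_total_relaxation_equals_sum_of_moduli(self, prony_reference):
        drop = prony_eval(prony_reference, 0.0) - prony_reference.equilibrium
        assert drop == pytest.approx(sum(prony_reference.moduli))

    def test_three_stage_shape(self, prony_reference):
        """Initial decay rate dominates the end-of-hold rate by >= 10x:
        stiff response, transient relaxation, then near-steady state."""
        h, t_end = 1e-3, 1000.0
        rate0 = abs(prony_eval(prony_reference, h) - prony_eval(prony_reference, 0.0)) / h
        rate1 = abs(
            prony_eval(prony_reference, t_end) - prony_eval(prony_reference, t_end - h)
        ) / h
        assert rate0 >= 10.0 * rate1


class TestLongTermModulus:
    def test_from_published_replicate_mean(self):
        assert long_term_modulus(
            residual_stress=3.693e-3, hold_strain=0.25
        ) == pytest.approx(1.477e-2, rel=1e-3)

    def test_zero_residual_stress(self):
        assert long_term_modulus(residual_stress=0.0, hold_strain=0.25) == 0.0

    def test_linearity_in_residual_stress(self):
        a = long_term_modulus(residual_stress=1e-3, hold_strain=0.25)
        b = long_term_modulus(residual_stress=2e-3, hold_strain=0.25)
        assert b == pytest.approx(2.0 * a)

    def test_zero_strain_rejected(self):
        with pytest.raises(ValueError):
            long_term_modulus(residual_stress=1e-3, hold_strain=0.0)


class TestFitProny:
    def test_noiseless_two_term_recovery(self):
        truth = PronyParams(moduli=(1.0, 0.5), taus=(5.0, 80.0), equilibrium=0.2)
        t = np.arange(0.0, 500.0, 0.2)
        params, report = fit_prony(relaxation_record(truth, t), n_terms=2)
        assert report.success
        np.testing.assert_allclose(params.moduli, truth.moduli, rtol=0.005)
        np.testing.assert_allclose(params.taus, truth.taus, rtol=0.005)
        assert params.equilibrium == pytest.approx(truth.equilibrium, rel=0.005)

    def test_constant_stress_degenerates_to_equilibrium(self):
        t = np.arange(0.0, 100.0, 0.5)
        rec = UniaxialRecord(mode=LoadingMode.RELAXATION, time_s=t,
                             stress_MPa=np.full_like(t, 5e-3), hold_strain=0.25)
        params, _ = fit_prony(rec, n_terms=2)
        assert params.equilibrium == pytest.approx(5e-3 / 0.25, rel=1e-6)
        assert all(e < 1e-8 for e in params.moduli)

    def test_residual_norm_non_increasing_in_terms(self, prony_reference):
        rng = np.random.default_rng(3)
        t = np.arange(0.0, 2000.0, 1.0)
        rec = relaxation_record(prony_reference, t,
                                noise=0.01 * rng.standard_normal(len(t)))
        rss = [fit_prony(rec, n_terms=n)[1].rss for n in (1, 2, 3)]
        assert rss[1] <= rss[0] + 1e-12
        assert rss[2] <= rss[1] + 1e-12

    def test_terms_sorted_by_relaxation_time(self, prony_reference):
        t = np.arange(0.0, 3000.0, 1.0)
        params, _ = fit_prony(relaxation_record(prony_reference, t), n_terms=3)
        assert list(params.taus) == sorted(params.taus)


class TestRelaxationStats:
    def test_reproduces_published_stress_statistics(self):
        summaries = [
            RelaxationSummary(initial_stress_MPa=s0, final_stress_MPa=s1,
                              hold_strain=0.25, hold_duration_s=1000.0)
            for s0, s1 in zip(RELAXATION_STRESS_REPLICATES["initial"],
                              RELAXATION_STRESS_REPLICATES["final"])
        ]
        stats = relaxation_summary_stats(summaries)
        assert stats["initial_stress_MPa"].mean == pytest.approx(2.433e-2, rel=1e-3)
        assert stats["initial_stress_MPa"].variance == pytest.approx(2.39e-5, rel=5e-3)
        assert stats["final_stress_MPa"].mean == pytest.approx(3.693e-3, rel=1e-3)
        assert stats["final_stress_MPa"].variance == pytest.approx(1.84e-7, rel=5e-3)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            PronyParams(moduli=(1.0,), taus=(-1.0,), equilibrium=0.1)
        with pytest.raises(ValueError):
            PronyParams(moduli=(1.0, 1.0), taus=(10.0, 1.0), equilibrium=0.1)
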