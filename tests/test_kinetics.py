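"""Forward-model tests: closed forms, oracles, conservation, pulse modes."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from csflux.kinetics import (
    AcquisitionParams,
    ExchangeParams,
    PoolState,
    closed_form_labelled,
    equilibrium_fractions,
    propagate_discrete_pulses,
    propagate_full,
    propagate_labelled,
    simulate_thermal,
    thermal_half_time,
    _full_rate_matrix,
    _labelled_rate_matrix,
)

FIG2A = ExchangeParams(k_fwd=0.0057, k_rev=0.0, T1_out=8.9, T1_in=1.2)
ACQ10 = AcquisitionParams(flip_angle=10.0, rep_time=1.0, n_samples=40)
UNIT_DOSE = PoolState(labelled_out=1.0)


# --- labelled-pool continuous model -----------------------------------------


def test_intracellular_maximum_and_scaling_factor():
    """The intracellular labelled signal peaks at ~4.757e-3 near t = 2.59 s,
    so scaling its maximum to 1.0 requires a ~210-fold factor."""
    t = np.linspace(0.0, 40.0, 8001)[1:]
    tc = propagate_labelled(FIG2A, ACQ10, UNIT_DOSE, t)
    peak = tc.in_signal.max()
    t_peak = tc.times[tc.in_signal.argmax()]
    assert peak == pytest.approx(4.757e-3, rel=1e-3)
    assert t_peak == pytest.approx(2.59, abs=0.01)
    assert round(1.0 / peak, -1) == 210


def test_decoupled_compartments_decay_analytically():
    """With no influx and an empty cell, the inside stays empty and the
    outside decays mono-exponentially at 1/T1_out - ln(cos a)/t_R."""
    params = ExchangeParams(k_fwd=0.0, k_rev=0.0, T1_out=8.9, T1_in=1.2)
    t = np.linspace(0.0, 30.0, 61)[1:]
    tc = propagate_labelled(params, ACQ10, UNIT_DOSE, t)
    rate = 1.0 / 8.9 - ACQ10.pulse_loss_rate
    np.testing.assert_allclose(tc.out_signal, np.exp(-rate * t), rtol=1e-12)
    assert np.all(tc.in_signal == 0.0)


def test_labelled_signal_vanishes_at_long_times():
    tc = propagate_labelled(FIG2A, ACQ10, UNIT_DOSE, [500.0])
    assert tc.out_signal[0] < 1e-12 and tc.in_signal[0] < 1e-12


@pytest.mark.parametrize(
    "bad_init", [{"labelled_out": -0.1}, {"labelled_in": math.nan}]
)
def test_invalid_initial_amounts_rejected(bad_init):
    with pytest.raises(ValueError):
        PoolState(**bad_init)


def test_nonfinite_parameters_rejected():
    with pytest.raises(ValueError):
        ExchangeParams(k_fwd=math.nan)
    with pytest.raises(ValueError):
        ExchangeParams(k_fwd=0.01, T1_out=0.0)


def test_times_must_increase():
    with pytest.raises(ValueError, match="strictly increasing"):
        propagate_labelled(FIG2A, ACQ10, UNIT_DOSE, [0.0, 1.0, 1.0])


# --- closed-form oracle ------------------------------------------------------


def test_closed_form_identity_at_time_zero():
    init = PoolState(labelled_out=0.7, labelled_in=0.2)
    assert closed_form_labelled(FIG2A, ACQ10, init, 0.0) == (0.7, 0.2)


def test_closed_form_diagonal_limit():
    """With no exchange each pool decays independently at 1/T1 - ln(cos a)/t_R."""
    params = ExchangeParams(k_fwd=0.0, k_rev=0.0, T1_out=5.0, T1_in=2.0)
    init = PoolState(labelled_out=0.8, labelled_in=0.3)
    out, inn = closed_form_labelled(params, ACQ10, init, 3.0)
    p = ACQ10.pulse_loss_rate
    assert out == pytest.approx(0.8 * math.exp((-1 / 5.0 + p) * 3.0), rel=1e-12)
    assert inn == pytest.approx(0.3 * math.exp((-1 / 2.0 + p) * 3.0), rel=1e-12)


def test_propagator_matches_expm_oracle_at_5s():
    tc = propagate_labelled(FIG2A, ACQ10, UNIT_DOSE, [5.0])
    out, inn = closed_form_labelled(FIG2A, ACQ10, UNIT_DOSE, 5.0)
    assert tc.out_signal[0] == pytest.approx(out, rel=1e-8)
    assert tc.in_signal[0] == pytest.approx(inn, rel=1e-8)


@given(
    k1=st.floats(0.0, 0.5),
    km1=st.floats(0.0, 0.5),
    t1o=st.floats(0.5, 50.0),
    t1i=st.floats(0.5, 50.0),
    alpha=st.floats(0.0, 45.0),
    t=st.floats(0.0, 100.0),
)
def test_propagator_equals_matrix_exponential_everywhere(k1, km1, t1o, t1i, alpha, t):
    """Property: the hand-derived 2x2 closed form agrees with scipy's expm to
    relative 1e-8 across randomized parameter sets (incl. near-degenerate)."""
    params = ExchangeParams(k_fwd=k1, k_rev=km1, T1_out=t1o, T1_in=t1i)
    acq = AcquisitionParams(flip_angle=alpha, rep_time=1.0, n_samples=2)
    init = PoolState(labelled_out=0.6, labelled_in=0.4)
    tc = propagate_labelled(params, acq, init, [t] if t > 0 else [1e-9])
    out, inn = closed_form_labelled(params, acq, init, tc.times[0])
    scale = max(out, inn, 1e-300)
    assert abs(tc.out_signal[0] - out) <= 1e-8 * scale + 1e-300
    assert abs(tc.in_signal[0] - inn) <= 1e-8 * scale + 1e-300


@given(
    k1=st.floats(0.0, 0.3),
    km1=st.floats(0.0, 0.3),
    t1o=st.floats(0.5, 50.0),
    t1i=st.floats(0.5, 50.0),
    alpha=st.floats(1.0, 45.0),
)
def test_nonnegativity_and_monotone_total_decay(k1, km1, t1o, t1i, alpha):
    """Positivity of the linear positive system and strict decay of the total
    labelled signal whenever relaxation or pulse losses act."""
    params = ExchangeParams(k_fwd=k1, k_rev=km1, T1_out=t1o, T1_in=t1i)
    acq = AcquisitionParams(flip_angle=alpha, rep_time=1.0, n_samples=2)
    t = np.linspace(0.0, 60.0, 121)[1:]
    tc = propagate_labelled(params, acq, PoolState(labelled_out=0.9, labelled_in=0.1), t)
    assert np.all(tc.out_signal >= 0.0) and np.all(tc.in_signal >= 0.0)
    total = tc.out_signal + tc.in_signal
    assert np.all(np.diff(total) < 0.0)


# --- four-pool model ---------------------------------------------------------


@pytest.mark.parametrize(
    "params",
    [
        FIG2A,
        ExchangeParams(k_fwd=0.0057, k_rev=0.0121, T1_out=8.9, T1_in=1.2),
        ExchangeParams(k_fwd=0.05, k_rev=0.08, T1_out=2.0, T1_in=0.7),
    ],
)
def test_four_pool_mass_conservation(params):
    """Relaxation and pulse losses only move label to the unlabelled pools:
    the four-pool total is conserved to better than 1e-9 of the dose."""
    t = np.linspace(0.0, 120.0, 241)[1:]
    full = propagate_full(params, ACQ10, UNIT_DOSE, t)
    assert np.max(np.abs(full.total - 1.0)) < 1e-9


def test_four_pool_matches_stiff_integrator():
    """Cross-check of the matrix-exponential propagation against LSODA."""
    params = ExchangeParams(k_fwd=0.0057, k_rev=0.0121, T1_out=8.9, T1_in=1.2)
    t = np.linspace(0.0, 40.0, 41)[1:]
    full = propagate_full(params, ACQ10, UNIT_DOSE, t)
    M = _full_rate_matrix(params, ACQ10.pulse_loss_rate)
    sol = solve_ivp(
        lambda _, y: M @ y,
        (0.0, 40.0),
        [1.0, 0.0, 0.0, 0.0],
        t_eval=t,
        method="LSODA",
        rtol=1e-8,
        atol=1e-10,
    )
    stacked = np.stack(
        [full.labelled_out, full.labelled_in, full.unlabelled_out, full.unlabelled_in]
    )
    np.testing.assert_allclose(stacked, sol.y, rtol=1e-6, atol=1e-10)


def test_total_pool_dwarfs_labelled_pool_at_40s():
    """By the end of a hyperpolarized time course the chemically transported
    (total) intracellular pool exceeds the still-labelled one >100-fold."""
    full = propagate_full(FIG2A, ACQ10, UNIT_DOSE, np.arange(1.0, 41.0))
    assert full.total_in[-1] / full.labelled_in[-1] > 100.0


def test_back_reaction_invisible_in_labelled_signal():
    """Adding the efflux constant inferred from long time courses changes the
    labelled extracellular decay by <1e-3 of the dose over 40 s (the
    'superimposed' curves), checked against a fine-step explicit integrator."""
    t = np.arange(1.0, 41.0)
    base = propagate_labelled(FIG2A, ACQ10, UNIT_DOSE, t)
    rev = ExchangeParams(k_fwd=0.0057, k_rev=0.0121, T1_out=8.9, T1_in=1.2)
    with_rev = propagate_labelled(rev, ACQ10, UNIT_DOSE, t)
    assert np.max(np.abs(base.out_signal - with_rev.out_signal)) < 1e-3
    A = _labelled_rate_matrix(rev, ACQ10.pulse_loss_rate)
    sol = solve_ivp(
        lambda _, y: A @ y, (0.0, 40.0), [1.0, 0.0], t_eval=t, method="RK45",
        rtol=1e-6, atol=1e-12,
    )
    np.testing.assert_allclose(with_rev.out_signal, sol.y[0], rtol=1e-5)


# --- discrete pulses ----------------------------------------------------------


def test_zero_flip_angle_equals_pulse_free_evolution():
    acq = AcquisitionParams(flip_angle=0.0, rep_time=1.0, n_samples=20, pulse_mode="discrete")
    t = np.arange(20.0)
    disc = propagate_discrete_pulses(FIG2A, acq, UNIT_DOSE, t)
    cont = propagate_labelled(
        FIG2A,
        AcquisitionParams(flip_angle=0.0, rep_time=1.0, n_samples=20),
        UNIT_DOSE,
        t[1:],
    )
    np.testing.assert_allclose(disc.out_signal[1:], cont.out_signal, rtol=1e-12)


def test_pure_geometric_attenuation_without_relaxation():
    """A single pool with no relaxation or exchange loses exactly cos(a) per pulse."""
    params = ExchangeParams(k_fwd=0.0, k_rev=0.0)
    acq = AcquisitionParams(flip_angle=25.0, rep_time=2.0, n_samples=10, pulse_mode="discrete")
    t = np.arange(10.0) * 2.0
    disc = propagate_discrete_pulses(params, acq, UNIT_DOSE, t)
    np.testing.assert_allclose(
        disc.out_signal, np.cos(np.radians(25.0)) ** np.arange(10), rtol=1e-12
    )


def test_discrete_and_continuous_sampling_agree_at_pulse_grid():
    """At pre-pulse sampling instants the discrete-pulse model and the
    ln(cos a)/t_R continuous approximation agree within 1% (in fact exactly:
    the scalar per-pulse loss commutes with the exchange matrix)."""
    t = np.arange(40.0)
    acq_d = AcquisitionParams(flip_angle=10.0, rep_time=1.0, n_samples=40, pulse_mode="discrete")
    disc = propagate_discrete_pulses(FIG2A, acq_d, UNIT_DOSE, t)
    cont = propagate_labelled(FIG2A, ACQ10, UNIT_DOSE, t)
    rel_out = np.abs(disc.out_signal - cont.out_signal) / cont.out_signal
    rel_in = np.abs(disc.in_signal[1:] - cont.in_signal[1:]) / cont.in_signal[1:]
    assert rel_out.max() < 0.01 and rel_in.max() < 0.01
    assert rel_out.max() < 1e-12  # the agreement is exact in this convention


def test_discrete_pulses_reject_off_grid_times():
    acq = AcquisitionParams(flip_angle=10.0, rep_time=1.0, n_samples=5, pulse_mode="discrete")
    with pytest.raises(ValueError, match="multiples of rep_time"):
        propagate_discrete_pulses(FIG2A, acq, UNIT_DOSE, [0.0, 0.5, 1.0])


def test_pulse_mode_mismatch_rejected():
    with pytest.raises(ValueError):
        propagate_discrete_pulses(FIG2A, ACQ10, UNIT_DOSE, [0.0, 1.0])
    acq_d = AcquisitionParams(pulse_mode="discrete")
    with pytest.raises(ValueError):
        propagate_labelled(FIG2A, acq_d, UNIT_DOSE, [1.0])


# --- thermal exchange ---------------------------------------------------------


def test_thermal_equilibrium_matches_rate_ratio():
    """k_fwd 0.0043, k_rev 0.0091 give a 67.9% extracellular share at
    equilibrium — the 68:32 split also seen in the aqueous volume ratio."""
    out_eq, in_eq = equilibrium_fractions(0.0043, 0.0091)
    assert out_eq == pytest.approx(0.679, abs=5e-4)
    tc = simulate_thermal(0.0043, 0.0091, (1.0, 0.0), np.arange(20.0, 1801.0, 20.0))
    assert tc.out_signal[-1] == pytest.approx(out_eq, abs=1e-6)
    np.testing.assert_allclose(tc.out_signal + tc.in_signal, 1.0, atol=1e-12)


def test_thermal_half_time_closed_form():
    t_half = thermal_half_time(0.0043, 0.0091)
    assert t_half == pytest.approx(51.7, abs=0.05)
    tc = simulate_thermal(0.0043, 0.0091, (1.0, 0.0), [t_half])
    out_eq, _ = equilibrium_fractions(0.0043, 0.0091)
    # halfway between the initial and equilibrium extracellular fractions
    assert tc.out_signal[0] == pytest.approx(out_eq + 0.5 * (1.0 - out_eq), rel=1e-9)


def test_symmetric_rates_equilibrate_to_half():
    for init in [(1.0, 0.0), (0.25, 0.75)]:
        tc = simulate_thermal(0.02, 0.02, init, [2000.0])
        assert tc.out_signal[0] == pytest.approx(0.5, abs=1e-8)


def test_frozen_system_is_valid_and_constant():
    tc = simulate_thermal(0.0, 0.0, (0.3, 0.7), np.arange(0.0, 100.0, 10.0))
    assert np.all(tc.out_signal == 0.3) and np.all(tc.in_signal == 0.7)
    with pytest.raises(ValueError):
        equilibrium_fractions(0.0, 0.0)


def test_thermal_init_fractions_must_sum_to_one():
    with pytest.raises(ValueError, match="sum to 1"):
        simulate_thermal(0.01, 0.01, (0.6, 0.6), [1.0])


def test_labelled_dynamics_reduce_to_thermal_without_losses():
    """With a zero flip angle and infinite T1s the labelled system is pure
    exchange and must reproduce the thermal model exactly."""
    params = ExchangeParams(k_fwd=0.0043, k_rev=0.0091)
    acq = AcquisitionParams(flip_angle=0.0, rep_time=1.0, n_samples=2)
    t = np.arange(10.0, 1210.0, 50.0)
    labelled = propagate_labelled(params, acq, UNIT_DOSE, t)
    thermal = simulate_thermal(0.0043, 0.0091, (1.0, 0.0), t)
    np.testing.assert_allclose(labelled.out_signal, thermal.out_signal, rtol=1e-10)
    np.testing.assert_allclose(labelled.in_signal, thermal.in_signal, rtol=1e-10)
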