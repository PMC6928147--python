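"""Two-site membrane exchange kinetics of hyperpolarized and thermal ion pools.

The physical system is a suspension of cells exchanging a monovalent cation
(here ``133Cs+``) across the plasma membrane::

    out  --k_fwd-->  in
    out  <--k_rev--  in

In a dissolution-DNP (dDNP) experiment the injected ions carry hyperpolarized
("labelled") longitudinal magnetization, which is consumed irreversibly by
longitudinal relaxation (time constants ``T1_out`` and ``T1_in``) and by the
radio-frequency sampling pulses (flip angle ``alpha`` every ``rep_time``
seconds).  The labelled amounts ``L_o(t)``, ``L_i(t)`` obey the linear system

    dL_o/dt = -L_o/T1_out + ln(cos a) L_o / t_R - k_fwd L_o + k_rev L_i
    dL_i/dt = -L_i/T1_in  + ln(cos a) L_i / t_R + k_fwd L_o - k_rev L_i

where ``ln(cos a)/t_R`` is the continuous approximation to the pulse losses.
Relaxed ("unlabelled") ions are chemically identical and keep exchanging; the
four-pool system (labelled + unlabelled, out + in) conserves total chemical
amount exactly.  Thermal (non-hyperpolarized) time courses obey the pure
exchange system with conserved pair sums.

All systems here are linear with constant coefficients, so propagation is by
matrix exponentials: a hand-derived closed form for the 2x2 labelled system
(the workhorse inside fitting loops) and :func:`scipy.linalg.expm` elsewhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.linalg import expm

__all__ = [
    "ExchangeParams",
    "AcquisitionParams",
    "PoolState",
    "TimeCourse",
    "PoolTimeCourse",
    "propagate_labelled",
    "propagate_full",
    "closed_form_labelled",
    "propagate_discrete_pulses",
    "simulate_thermal",
    "equilibrium_fractions",
    "thermal_half_time",
]


def _check_nonneg_finite(name: str, value: float, allow_inf: bool = False) -> float:
    value = float(value)
    if math.isnan(value) or (math.isinf(value) and not allow_inf):
        raise ValueError(f"{name} must be finite, got {value!r}")
    if value < 0:
        raise ValueError(f"{name} must be non-negative, got {value!r}")
    return value


@dataclass(frozen=True)
class ExchangeParams:
    """Rate constants and relaxation times of the two-site system.

    Parameters
    ----------
    k_fwd : float
        Influx (out -> in) first-order rate constant, 1/s.
    k_rev : float
        Efflux (in -> out) rate constant, 1/s.
    T1_out, T1_in : float
        Longitudinal relaxation times outside/inside the cell, s.  May be
        ``math.inf`` to disable relaxation (limits testing).
    """

    k_fwd: float
    k_rev: float = 0.0
    T1_out: float = math.inf
    T1_in: float = math.inf

    def __post_init__(self) -> None:
        _check_nonneg_finite("k_fwd", self.k_fwd)
        _check_nonneg_finite("k_rev", self.k_rev)
        for name in ("T1_out", "T1_in"):
            v = _check_nonneg_finite(name, getattr(self, name), allow_inf=True)
            if v == 0:
                raise ValueError(f"{name} must be positive, got 0")

    @property
    def r1_out(self) -> float:
        """Relaxation rate 1/T1_out (0 for infinite T1)."""
        return 0.0 if math.isinf(self.T1_out) else 1.0 / self.T1_out

    @property
    def r1_in(self) -> float:
        return 0.0 if math.isinf(self.T1_in) else 1.0 / self.T1_in


@dataclass(frozen=True)
class AcquisitionParams:
    """RF sampling scheme of the NMR time course.

    ``flip_angle`` (degrees) is the nutation angle of each read pulse,
    ``rep_time`` (s) the inter-pulse interval, ``n_samples`` the number of
    acquired spectra.  ``pulse_mode`` selects between the continuous
    ``ln(cos a)/t_R`` loss approximation and explicit discrete pulses.
    ``dead_time`` (s) is an optional injection-to-first-spectrum delay; the
    time origin is the first acquired spectrum.
    """

    flip_angle: float = 10.0
    rep_time: float = 1.0
    n_samples: int = 40
    pulse_mode: Literal["continuous", "discrete"] = "continuous"
    dead_time: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.flip_angle < 90):
            raise ValueError(f"flip_angle must be in [0, 90) degrees, got {self.flip_angle}")
        if not (self.rep_time > 0 and math.isfinite(self.rep_time)):
            raise ValueError(f"rep_time must be positive and finite, got {self.rep_time}")
        if self.n_samples < 2:
            raise ValueError(f"n_samples must be >= 2, got {self.n_samples}")
        if self.pulse_mode not in ("continuous", "discrete"):
            raise ValueError(f"unknown pulse_mode {self.pulse_mode!r}")
        _check_nonneg_finite("dead_time", self.dead_time)

    @property
    def cos_alpha(self) -> float:
        return math.cos(math.radians(self.flip_angle))

    @property
    def pulse_loss_rate(self) -> float:
        """ln(cos a)/t_R, the (non-positive) continuous pulse-loss rate, 1/s."""
        return math.log(self.cos_alpha) / self.rep_time

    def sample_times(self) -> np.ndarray:
        """Default acquisition grid: n_samples instants spaced by rep_time from 0."""
        return np.arange(self.n_samples) * self.rep_time


@dataclass(frozen=True)
class PoolState:
    """Amounts in each pool at one instant, in normalized signal units."""

    labelled_out: float = 0.0
    labelled_in: float = 0.0
    unlabelled_out: float = 0.0
    unlabelled_in: float = 0.0

    def __post_init__(self) -> None:
        for name in ("labelled_out", "labelled_in", "unlabelled_out", "unlabelled_in"):
            _check_nonneg_finite(name, getattr(self, name))

    @property
    def total(self) -> float:
        return self.labelled_out + self.labelled_in + self.unlabelled_out + self.unlabelled_in


def _validate_times(times) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < 1:
        raise ValueError("times must be a non-empty 1-D array")
    if not np.all(np.isfinite(t)):
        raise ValueError("times must be finite")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        i = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
        raise ValueError(f"times must be strictly increasing (violation at index {i})")
    return t


@dataclass(frozen=True)
class TimeCourse:
    """Sampled per-compartment signal trajectories.

    ``kind`` is ``"dnp"`` for hyperpolarized (labelled-pool) data and
    ``"thermal"`` for conventional-acquisition data.  ``meta`` carries
    provenance (generating truth for synthetic data, normalization applied).
    """

    times: np.ndarray
    out_signal: np.ndarray
    in_signal: np.ndarray
    kind: Literal["dnp", "thermal"] = "dnp"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = _validate_times(self.times)
        out = np.asarray(self.out_signal, dtype=float)
        inn = np.asarray(self.in_signal, dtype=float)
        if out.shape != t.shape or inn.shape != t.shape:
            raise ValueError("out_signal and in_signal must match times in length")
        if not (np.all(np.isfinite(out)) and np.all(np.isfinite(inn))):
            raise ValueError("signals must be finite")
        if self.kind not in ("dnp", "thermal"):
            raise ValueError(f"unknown kind {self.kind!r}")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "out_signal", out)
        object.__setattr__(self, "in_signal", inn)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class PoolTimeCourse:
    """All four pools (labelled/unlabelled x out/in) on a common time grid."""

    times: np.ndarray
    labelled_out: np.ndarray
    labelled_in: np.ndarray
    unlabelled_out: np.ndarray
    unlabelled_in: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def total_out(self) -> np.ndarray:
        return self.labelled_out + self.unlabelled_out

    @property
    def total_in(self) -> np.ndarray:
        return self.labelled_in + self.unlabelled_in

    @property
    def total(self) -> np.ndarray:
        return self.total_out + self.total_in


def _labelled_rate_matrix(params: ExchangeParams, pulse_rate: float) -> np.ndarray:
    """2x2 generator of the labelled (out, in) subsystem."""
    return np.array(
        [
            [-params.r1_out + pulse_rate - params.k_fwd, params.k_rev],
            [params.k_fwd, -params.r1_in + pulse_rate - params.k_rev],
        ]
    )


def _expm2_apply(A: np.ndarray, times: np.ndarray, y0: np.ndarray) -> np.ndarray:
    """exp(A t) @ y0 for a real 2x2 matrix with b*c >= 0, vectorized over t.

    Uses the uniform closed form
    ``exp(A t) = E_c(t) I + E_s(t) (A - mu I)`` with ``mu = tr(A)/2``,
    ``delta = sqrt(((a-d)/2)^2 + b c)``, ``E_c = (e^{l1 t} + e^{l2 t})/2`` and
    ``E_s = (e^{l1 t} - e^{l2 t})/(2 delta)`` (``l1,2 = mu +- delta``), which
    remains exact and numerically stable as ``delta -> 0`` (repeated
    eigenvalue) via a series switch.  Returns array of shape (len(times), 2).
    """
    a, b = A[0]
    c, d = A[1]
    t = np.asarray(times, dtype=float)
    y0 = np.asarray(y0, dtype=float)
    if b == 0.0 or c == 0.0:
        # triangular system: each diagonal mode is exact, and the coupling
        # term uses expm1 to avoid cancellation when the eigenvalues are far
        # apart (the fast-decaying pool would otherwise lose all precision)
        ea = np.exp(a * t)
        ed = np.exp(d * t)
        gap = abs(a - d)
        if gap == 0.0:
            g = t * ea
        else:
            g = -np.exp(max(a, d) * t) * np.expm1(-gap * t) / gap
        out = ea * y0[0] + b * y0[1] * g
        inn = ed * y0[1] + c * y0[0] * g
        return np.stack([out, inn], axis=-1)
    mu = 0.5 * (a + d)
    disc = (0.5 * (a - d)) ** 2 + b * c
    # b*c >= 0 for a positive exchange system, so eigenvalues are real
    delta = math.sqrt(max(disc, 0.0))
    e1 = np.exp((mu + delta) * t)
    e2 = np.exp((mu - delta) * t)
    ec = 0.5 * (e1 + e2)
    x = delta * t
    small = x < 1e-6
    with np.errstate(divide="ignore", invalid="ignore"):
        es = np.where(small, t * np.exp(mu * t) * (1.0 + x * x / 6.0),
                      (e1 - e2) / (2.0 * delta if delta > 0 else 1.0))
    shifted = A @ y0 - mu * y0  # (A - mu I) y0
    out = ec * y0[0] + es * shifted[0]
    inn = ec * y0[1] + es * shifted[1]
    return np.stack([out, inn], axis=-1)


def propagate_labelled(
    params: ExchangeParams,
    acq: AcquisitionParams,
    init: PoolState,
    times,
) -> TimeCourse:
    """Propagate the hyperpolarized (labelled) pools under the continuous model.

    Solves the 2x2 linear system with relaxation, continuous pulse-loss and
    exchange terms, exactly, via the closed-form matrix exponential.
    """
    if acq.pulse_mode != "continuous":
        raise ValueError("propagate_labelled requires pulse_mode='continuous'")
    t = _validate_times(times)
    A = _labelled_rate_matrix(params, acq.pulse_loss_rate)
    y = _expm2_apply(A, t, np.array([init.labelled_out, init.labelled_in]))
    return TimeCourse(
        times=t,
        out_signal=np.maximum(y[:, 0], 0.0),
        in_signal=np.maximum(y[:, 1], 0.0),
        kind="dnp",
        meta={"model": "labelled-continuous", "params": params, "acq": acq},
    )


def closed_form_labelled(
    params: ExchangeParams,
    acq: AcquisitionParams,
    init: PoolState,
    t: float,
) -> tuple[float, float]:
    """Labelled pool pair at time ``t`` via :func:`scipy.linalg.expm`.

    Independent of the closed-form path in :func:`propagate_labelled`; serves
    as its oracle in tests.  Handles a degenerate (repeated-eigenvalue) rate
    matrix by construction.
    """
    if acq.pulse_mode != "continuous":
        raise ValueError("closed_form_labelled requires pulse_mode='continuous'")
    t = float(t)
    if not (t >= 0 and math.isfinite(t)):
        raise ValueError(f"t must be finite and non-negative, got {t}")
    A = _labelled_rate_matrix(params, acq.pulse_loss_rate)
    y = expm(A * t) @ np.array([init.labelled_out, init.labelled_in])
    return float(y[0]), float(y[1])


def _full_rate_matrix(params: ExchangeParams, pulse_rate: float) -> np.ndarray:
    """4x4 generator in pool order (l_out, l_in, u_out, u_in).

    Relaxation and pulse losses move labelled amounts into the matching
    unlabelled pool; exchange acts identically on both populations.  Columns
    sum to zero, so total chemical amount is conserved exactly.
    """
    r_o, r_i = params.r1_out, params.r1_in
    k1, km1 = params.k_fwd, params.k_rev
    p = pulse_rate  # <= 0
    return np.array(
        [
            [-r_o + p - k1, km1, 0.0, 0.0],
            [k1, -r_i + p - km1, 0.0, 0.0],
            [r_o - p, 0.0, -k1, km1],
            [0.0, r_i - p, k1, -km1],
        ]
    )


def propagate_full(
    params: ExchangeParams,
    acq: AcquisitionParams,
    init: PoolState,
    times,
) -> PoolTimeCourse:
    """Propagate all four pools (labelled + unlabelled, out + in).

    The unlabelled pools gain exactly what the labelled pools lose to
    relaxation and pulse sampling, so the four-pool total is constant.  The
    system is linear; propagation steps with exact matrix exponentials
    between successive output instants.
    """
    if acq.pulse_mode != "continuous":
        raise ValueError("propagate_full requires pulse_mode='continuous'")
    t = _validate_times(times)
    M = _full_rate_matrix(params, acq.pulse_loss_rate)
    y = np.array([init.labelled_out, init.labelled_in, init.unlabelled_out, init.unlabelled_in])
    out = np.empty((t.size, 4))
    prev = 0.0
    cache: dict[float, np.ndarray] = {}
    for j, tj in enumerate(t):
        dt = tj - prev
        if dt > 0:
            P = cache.get(dt)
            if P is None:
                P = expm(M * dt)
                cache[dt] = P
            y = P @ y
        out[j] = y
        prev = tj
    return PoolTimeCourse(
        times=t,
        labelled_out=out[:, 0],
        labelled_in=out[:, 1],
        unlabelled_out=out[:, 2],
        unlabelled_in=out[:, 3],
        meta={"model": "full-continuous", "params": params, "acq": acq},
    )


def propagate_discrete_pulses(
    params: ExchangeParams,
    acq: AcquisitionParams,
    init: PoolState,
    times,
) -> TimeCourse:
    """Labelled pools with explicit discrete read pulses.

    Between pulses the exchange/relaxation ODEs run *without* the
    ``ln(cos a)/t_R`` term; at each pulse both labelled pools are multiplied
    by ``cos a`` (longitudinal magnetization surviving the read pulse).  The
    reported signal at each pulse instant is the pre-pulse longitudinal
    amount (the ``sin a`` detection factor is absorbed into normalization).
    ``times`` must be non-negative integer multiples of ``rep_time``.
    """
    if acq.pulse_mode != "discrete":
        raise ValueError("propagate_discrete_pulses requires pulse_mode='discrete'")
    t = _validate_times(times)
    n = np.rint(t / acq.rep_time)
    if not np.allclose(t, n * acq.rep_time, rtol=0.0, atol=1e-9 * acq.rep_time):
        bad = int(np.argmax(np.abs(t - n * acq.rep_time)))
        raise ValueError(
            f"times must be multiples of rep_time={acq.rep_time}; offending value {t[bad]}"
        )
    n = n.astype(int)
    A0 = _labelled_rate_matrix(params, 0.0)
    step = expm(A0 * acq.rep_time)
    cos_a = acq.cos_alpha
    wanted = {int(k): j for j, k in enumerate(n)}
    y = np.array([init.labelled_out, init.labelled_in])
    out = np.empty((t.size, 2))
    for pulse in range(int(n[-1]) + 1):
        if pulse in wanted:
            out[wanted[pulse]] = y  # pre-pulse longitudinal amounts
        y = step @ (cos_a * y)
    return TimeCourse(
        times=t,
        out_signal=out[:, 0],
        in_signal=out[:, 1],
        kind="dnp",
        meta={"model": "labelled-discrete", "params": params, "acq": acq},
    )


def simulate_thermal(k_fwd: float, k_rev: float, init_fractions, times) -> TimeCourse:
    """Thermal (Boltzmann-polarization) exchange time course.

    Pure two-site exchange of conserved amounts::

        d out/dt = -k_fwd out + k_rev in,      out + in = 1

    Thermal polarization regenerates between scans and each acquired pair is
    normalized to sum 1, so no relaxation or pulse-loss terms appear.  The
    solution is the closed-form mono-exponential approach to the equilibrium
    fractions ``(k_rev, k_fwd)/(k_fwd + k_rev)`` with rate ``k_fwd + k_rev``.
    """
    k1 = _check_nonneg_finite("k_fwd", k_fwd)
    km1 = _check_nonneg_finite("k_rev", k_rev)
    f = np.asarray(init_fractions, dtype=float)
    if f.shape != (2,):
        raise ValueError("init_fractions must be a pair (out, in)")
    if np.any(f < 0):
        raise ValueError("init_fractions must be non-negative")
    if abs(f.sum() - 1.0) > 1e-8:
        raise ValueError(f"init_fractions must sum to 1, got {f.sum()}")
    t = _validate_times(times)
    ktot = k1 + km1
    if ktot == 0:
        out = np.full_like(t, f[0])  # frozen system: valid, not an error
    else:
        out_eq = km1 / ktot
        out = out_eq + (f[0] - out_eq) * np.exp(-ktot * t)
    return TimeCourse(
        times=t,
        out_signal=out,
        in_signal=1.0 - out,
        kind="thermal",
        meta={"model": "thermal", "k_fwd": k1, "k_rev": km1},
    )


def equilibrium_fractions(k_fwd: float, k_rev: float) -> tuple[float, float]:
    """Equilibrium (out, in) fractions of the thermal exchange, (k_rev, k_fwd)/sum."""
    k1 = _check_nonneg_finite("k_fwd", k_fwd)
    km1 = _check_nonneg_finite("k_rev", k_rev)
    ktot = k1 + km1
    if ktot == 0:
        raise ValueError("equilibrium undefined for k_fwd = k_rev = 0 (frozen system)")
    return km1 / ktot, k1 / ktot


def thermal_half_time(k_fwd: float, k_rev: float) -> float:
    """Half-time of the approach to exchange equilibrium, ln(2)/(k_fwd + k_rev), s."""
    ktot = _check_nonneg_finite("k_fwd", k_fwd) + _check_nonneg_finite("k_rev", k_rev)
    if ktot == 0:
        return math.inf
    return math.log(2.0) / ktot
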