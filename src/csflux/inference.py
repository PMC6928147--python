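"""Parameter estimation from peak-integral time courses.

Two fitting routes, matching how the two experiment types are analysed:

* hyperpolarized (dDNP) courses — affine-invariant ensemble MCMC over
  ``(T1_out, T1_in, k_fwd, amplitude, noise_sd)`` with the efflux constant
  fixed at zero (the extent of reaction over ~40 s is far below 1%, so the
  back-reaction is unidentifiable and its omission is harmless);
* thermal courses — deterministic nonlinear least squares over
  ``(k_fwd, k_rev)`` with asymptotic standard errors from the Jacobian.

Priors are independent log-uniform within broad bounds: every parameter is a
positive scale parameter potentially spanning decades, and at realistic
signal-to-noise the posterior for the well-identified parameters is
prior-insensitive.  Sampling is done in log space.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .kinetics import (
    AcquisitionParams,
    ExchangeParams,
    PoolState,
    TimeCourse,
    _expm2_apply,
    _labelled_rate_matrix,
    propagate_discrete_pulses,
    simulate_thermal,
)

__all__ = [
    "PriorSpec",
    "MCMCConfig",
    "PosteriorSummary",
    "FitResult",
    "PredictiveEnvelope",
    "normalize_timecourse",
    "fit_dnp_mcmc",
    "fit_thermal_nls",
    "posterior_predictive",
    "DNP_PARAM_NAMES",
]

DNP_PARAM_NAMES = ("T1_out", "T1_in", "k_fwd", "amplitude", "noise_sd")

_DEFAULT_BOUNDS = {
    "T1_out": (0.1, 100.0),
    "T1_in": (0.1, 100.0),
    "k_fwd": (1e-5, 1.0),
    "amplitude": (0.01, 100.0),
    "noise_sd": (1e-6, 1.0),
}


@dataclass(frozen=True)
class PriorSpec:
    """Independent log-uniform priors within per-parameter bounds."""

    bounds: dict = field(default_factory=lambda: dict(_DEFAULT_BOUNDS))
    family: str = "log_uniform"

    def __post_init__(self) -> None:
        if self.family != "log_uniform":
            raise ValueError(f"unsupported prior family {self.family!r}")
        for name, (lo, hi) in self.bounds.items():
            if not (0 < lo < hi and math.isfinite(lo) and math.isfinite(hi)):
                raise ValueError(
                    f"prior bounds for {name} must satisfy 0 < lower < upper < inf, got {(lo, hi)}"
                )

    def log_bounds(self, names) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([math.log(self.bounds[n][0]) for n in names])
        hi = np.array([math.log(self.bounds[n][1]) for n in names])
        return lo, hi


@dataclass(frozen=True)
class MCMCConfig:
    """Ensemble-sampler settings.  Defaults suit the 5-parameter dDNP posterior."""

    n_walkers: int = 40
    n_steps: int = 50000
    burn_frac: float = 0.5
    seed: int = 0
    pulse_mode: str = "continuous"
    channels: str = "both"  # "both" or "out" (withhold the intracellular channel)
    rhat_threshold: float = 1.05
    max_init_retries: int = 100

    def __post_init__(self) -> None:
        if self.n_walkers < 2 * len(DNP_PARAM_NAMES):
            raise ValueError("n_walkers must be at least twice the parameter count")
        if not (0 < self.burn_frac < 1):
            raise ValueError("burn_frac must lie in (0, 1)")
        if self.channels not in ("both", "out"):
            raise ValueError(f"channels must be 'both' or 'out', got {self.channels!r}")
        if self.pulse_mode not in ("continuous", "discrete"):
            raise ValueError(f"unknown pulse_mode {self.pulse_mode!r}")


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior moments, credible intervals and convergence diagnostics.

    ``samples`` holds the post-burn-in draws in natural (not log) parameter
    space, shape (n_draws, n_params) with columns ordered as
    ``param_names``.  ``converged`` is False when any split-R-hat exceeds
    the configured threshold; results are still returned (fail loudly via
    the flag, never silently).
    """

    param_names: tuple
    mean: dict
    sd: dict
    ci95: dict
    rhat: dict
    ess: dict
    converged: bool
    samples: np.ndarray
    n_chains: int
    n_steps: int
    burn_in: int
    seed: int
    meta: dict = field(default_factory=dict)


@dataclass(frozen=True)
class FitResult:
    """Point estimates with asymptotic standard errors from least squares."""

    estimates: dict
    stderr: dict
    rss: float
    converged: bool
    n_obs: int
    message: str = ""


@dataclass(frozen=True)
class PredictiveEnvelope:
    """Median and central 95% posterior-predictive band per channel."""

    times: np.ndarray
    out_median: np.ndarray
    out_lo: np.ndarray
    out_hi: np.ndarray
    in_median: np.ndarray
    in_lo: np.ndarray
    in_hi: np.ndarray
    include_noise: bool


def normalize_timecourse(
    raw: TimeCourse, mode: str, drop_first: bool = False
) -> TimeCourse:
    """Normalize peak integrals for fitting.

    ``"thermal_pair_sum"`` rescales each (out, in) pair to sum 1
    (conservation-of-mass normalization).  ``"dnp_first_out"`` divides both
    channels by the reference extracellular integral — the first point, or
    the second when ``drop_first`` is set (the first spectrum is prone to an
    incomplete-mixing artifact and is then discarded).
    """
    if len(raw) < 3:
        raise ValueError("time course must have at least 3 points to normalize")
    t, out, inn = raw.times, raw.out_signal, raw.in_signal
    if drop_first:
        t, out, inn = t[1:], out[1:], inn[1:]
    if mode == "thermal_pair_sum":
        s = out + inn
        if np.any(s <= 0):
            i = int(np.flatnonzero(s <= 0)[0])
            raise ValueError(
                f"pair sum non-positive at point {i} (t={t[i]} s): cannot normalize"
            )
        out, inn = out / s, inn / s
    elif mode == "dnp_first_out":
        ref = out[0]
        if ref <= 0:
            raise ValueError(
                f"reference extracellular integral at t={t[0]} s is non-positive ({ref}): "
                "cannot normalize"
            )
        out, inn = out / ref, inn / ref
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    meta = dict(raw.meta)
    meta["normalization"] = {"mode": mode, "drop_first": drop_first}
    return TimeCourse(times=t, out_signal=out, in_signal=inn, kind=raw.kind, meta=meta)


def _dnp_model(
    T1_out: float,
    T1_in: float,
    k_fwd: float,
    amplitude: float,
    times: np.ndarray,
    acq: AcquisitionParams,
    pulse_mode: str = "continuous",
) -> tuple[np.ndarray, np.ndarray]:
    """Labelled-pool trajectories for unit zero-trans dose scaled by amplitude."""
    if pulse_mode == "discrete":
        params = ExchangeParams(k_fwd=k_fwd, k_rev=0.0, T1_out=T1_out, T1_in=T1_in)
        acq_d = replace(acq, pulse_mode="discrete")
        tc = propagate_discrete_pulses(
            params, acq_d, PoolState(labelled_out=1.0), times + acq.dead_time
        )
        return amplitude * tc.out_signal, amplitude * tc.in_signal
    # fast path: closed-form 2x2 exponential, no dataclass validation overhead
    p = math.log(math.cos(math.radians(acq.flip_angle))) / acq.rep_time
    A = np.array(
        [[-1.0 / T1_out + p - k_fwd, 0.0], [k_fwd, -1.0 / T1_in + p]]
    )
    y = _expm2_apply(A, times + acq.dead_time, np.array([1.0, 0.0]))
    return amplitude * y[:, 0], amplitude * y[:, 1]


def _dnp_log_prob_factory(tc, acq, priors, config):
    """Vectorized log-posterior over walker batches, shape (n, 5) -> (n,).

    For the continuous pulse mode with the efflux constant pinned at zero
    the labelled system is triangular, so the trajectories have the
    two-exponential closed form evaluated here for all walkers at once
    (cross-checked against :func:`propagate_labelled` in the test suite).
    The discrete pulse mode falls back to the stepped propagator per walker.
    """
    names = DNP_PARAM_NAMES
    lo, hi = priors.log_bounds(names)
    times = tc.times + acq.dead_time
    data_out = tc.out_signal
    data_in = tc.in_signal
    use_in = config.channels == "both"
    n_obs = data_out.size * (2 if use_in else 1)
    const = -0.5 * n_obs * math.log(2.0 * math.pi)
    pulse = math.log(math.cos(math.radians(acq.flip_angle))) / acq.rep_time
    discrete = config.pulse_mode == "discrete"

    def log_prob(log_theta: np.ndarray) -> np.ndarray:
        lt = np.atleast_2d(log_theta)
        ok = np.all((lt >= lo) & (lt <= hi), axis=1)
        T1o, T1i, k1, amp, sd = np.exp(lt).T
        if discrete:
            mo = np.empty((lt.shape[0], times.size))
            mi = np.empty_like(mo)
            for r in range(lt.shape[0]):
                mo[r], mi[r] = _dnp_model(
                    T1o[r], T1i[r], k1[r], amp[r], tc.times, acq, "discrete"
                )
        else:
            lam_o = (-1.0 / T1o + pulse - k1)[:, None]
            lam_i = (-1.0 / T1i + pulse)[:, None]
            eo = np.exp(lam_o * times)
            gap = np.abs(lam_o - lam_i)
            safe = np.where(gap == 0.0, 1.0, gap)
            # (e^{lam_o t} - e^{lam_i t})/(lam_o - lam_i) via expm1, exact in
            # the degenerate limit and cancellation-free for disparate rates
            build = np.where(
                gap == 0.0,
                times * eo,
                -np.exp(np.maximum(lam_o, lam_i) * times) * np.expm1(-gap * times) / safe,
            )
            mo = amp[:, None] * eo
            mi = (amp * k1)[:, None] * build
        ss = np.sum((mo - data_out) ** 2, axis=1)
        if use_in:
            ss += np.sum((mi - data_in) ** 2, axis=1)
        ll = const - n_obs * np.log(sd) - 0.5 * ss / (sd * sd)
        ll = np.where(ok & np.isfinite(ll), ll, -np.inf)
        return ll if log_theta.ndim == 2 else float(ll[0])

    return log_prob, lo, hi, n_obs


def _dnp_start_point(tc, acq, priors, config) -> np.ndarray:
    """Rough maximum-likelihood start from a quick least-squares pass (log space)."""
    names = DNP_PARAM_NAMES
    lo, hi = priors.log_bounds(names)
    use_in = config.channels == "both"

    def resid(x):
        T1o, T1i, k1, amp = np.exp(x)
        mo, mi = _dnp_model(T1o, T1i, k1, amp, tc.times, acq, "continuous")
        r = mo - tc.out_signal
        if use_in:
            r = np.concatenate([r, mi - tc.in_signal])
        return r

    x0 = np.log([8.0, 2.0, 0.005, max(tc.out_signal[0], 0.05)])
    try:
        res = least_squares(resid, x0, bounds=(lo[:4], hi[:4]), method="trf", xtol=1e-12)
        x = res.x
        r = res.fun
    except Exception:  # fall back to the heuristic start
        x = x0
        r = resid(x0)
    sd0 = float(np.std(r))
    sd_lo, sd_hi = priors.bounds["noise_sd"]
    sd0 = min(max(sd0, sd_lo * 1.5), sd_hi / 1.5)
    start = np.append(x, math.log(sd0))
    eps = 1e-6
    return np.clip(start, lo + eps, hi - eps)


def fit_dnp_mcmc(
    tc: TimeCourse,
    acq: AcquisitionParams,
    priors: PriorSpec | None = None,
    config: MCMCConfig | None = None,
) -> PosteriorSummary:
    """Posterior sampling of the dDNP kinetic model.

    The likelihood is i.i.d. Gaussian on the residuals between the data and
    the labelled-pool forward model with free parameters ``T1_out``,
    ``T1_in``, ``k_fwd``, an overall ``amplitude`` (the initial labelled
    amount is not pinned to the artifact-prone first point) and the noise
    ``noise_sd``; the efflux constant is fixed at zero.  Convergence is
    assessed by split-R-hat over walkers; ``converged`` is False if any
    exceeds the threshold.
    """
    import emcee

    if tc.kind != "dnp":
        raise ValueError(f"fit_dnp_mcmc requires a dnp time course, got kind={tc.kind!r}")
    priors = priors or PriorSpec()
    config = config or MCMCConfig()
    log_prob, lo, hi, n_obs = _dnp_log_prob_factory(tc, acq, priors, config)
    ndim = len(DNP_PARAM_NAMES)
    rng = np.random.default_rng(config.seed)

    center = _dnp_start_point(tc, acq, priors, config)
    p0 = center + 1e-2 * rng.standard_normal((config.n_walkers, ndim))
    p0 = np.clip(p0, lo + 1e-9, hi - 1e-9)
    for i in range(config.n_walkers):
        retries = 0
        while not math.isfinite(log_prob(p0[i])):
            p0[i] = rng.uniform(lo, hi)
            retries += 1
            if retries > config.max_init_retries:
                raise RuntimeError(
                    "could not find a finite-likelihood start point within the priors"
                )

    # differential-evolution moves traverse the curved T1_in/k_fwd ridge far
    # better than the default stretch move on this posterior
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(
        config.n_walkers, ndim, log_prob, moves=moves, vectorize=True
    )
    sampler.random_state = np.random.RandomState(config.seed).get_state()
    sampler.run_mcmc(p0, config.n_steps, progress=False, skip_initial_state_check=True)

    burn = int(config.n_steps * config.burn_frac)
    chain = np.exp(sampler.get_chain()[burn:])  # (draws, walkers, ndim), natural space
    logp = sampler.get_log_prob()[burn:]  # (draws, walkers)
    flat = chain.reshape(-1, ndim)

    import arviz as az

    mean, sd, ci95, rhat, ess = {}, {}, {}, {}, {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, name in enumerate(DNP_PARAM_NAMES):
            draws = flat[:, i]
            mean[name] = float(draws.mean())
            sd[name] = float(draws.std(ddof=1))
            ci95[name] = (float(np.percentile(draws, 2.5)), float(np.percentile(draws, 97.5)))
            per_walker = chain[:, :, i].T  # (chains=walkers, draws)
            rhat[name] = float(az.rhat(per_walker))
            ess[name] = float(az.ess(per_walker))
    converged = all(r <= config.rhat_threshold for r in rhat.values())
    map_draw = flat[int(np.argmax(logp.reshape(-1)))]
    return PosteriorSummary(
        param_names=DNP_PARAM_NAMES,
        mean=mean,
        sd=sd,
        ci95=ci95,
        rhat=rhat,
        ess=ess,
        converged=converged,
        samples=flat,
        n_chains=config.n_walkers,
        n_steps=config.n_steps,
        burn_in=burn,
        seed=config.seed,
        meta={
            "acq": acq,
            "config": config,
            "priors": priors,
            "n_obs": n_obs,
            "map": dict(zip(DNP_PARAM_NAMES, map_draw)),
            "acceptance_fraction": float(np.mean(sampler.acceptance_fraction)),
        },
    )


def fit_thermal_nls(
    tc: TimeCourse,
    init_guess: tuple[float, float] = (0.005, 0.005),
    init_fractions: tuple[float, float] = (1.0, 0.0),
) -> FitResult:
    """Least-squares fit of the thermal exchange model to both channels jointly.

    Estimates ``(k_fwd, k_rev)`` with asymptotic standard errors from the
    Jacobian at the solution (``cov = s^2 (J^T J)^{-1}`` with
    ``s^2 = RSS / (m - p)``).  Non-convergence is flagged on the result, not
    raised.
    """
    if tc.kind != "thermal":
        raise ValueError(f"fit_thermal_nls requires a thermal time course, got {tc.kind!r}")
    times, data_out, data_in = tc.times, tc.out_signal, tc.in_signal

    def resid(k):
        model = simulate_thermal(k[0], k[1], init_fractions, times)
        return np.concatenate(
            [model.out_signal - data_out, model.in_signal - data_in]
        )

    x0 = np.maximum(np.asarray(init_guess, dtype=float), 1e-8)
    res = least_squares(resid, x0, bounds=(0.0, np.inf), method="trf", xtol=1e-14, ftol=1e-14)
    m, p = res.fun.size, 2
    rss = float(np.sum(res.fun**2))
    s2 = rss / max(m - p, 1)
    JTJ = res.jac.T @ res.jac
    try:
        cov = s2 * np.linalg.inv(JTJ)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return FitResult(
        estimates={"k_fwd": float(res.x[0]), "k_rev": float(res.x[1])},
        stderr={"k_fwd": float(se[0]), "k_rev": float(se[1])},
        rss=rss,
        converged=bool(res.success),
        n_obs=m,
        message=res.message,
    )


def posterior_predictive(
    tc: TimeCourse,
    summary: PosteriorSummary,
    n_draws: int = 200,
    seed: int = 0,
    include_noise: bool = True,
) -> PredictiveEnvelope:
    """Median and central 95% envelope of posterior model trajectories.

    With ``include_noise`` (default) each draw adds Gaussian observation
    noise at that draw's ``noise_sd``, giving the posterior-predictive band
    against which data coverage is meaningful; without it the band reflects
    trajectory (parameter) uncertainty only.
    """
    if n_draws > summary.samples.shape[0]:
        raise ValueError(
            f"n_draws={n_draws} exceeds the {summary.samples.shape[0]} stored draws"
        )
    acq: AcquisitionParams = summary.meta["acq"]
    pulse_mode = summary.meta["config"].pulse_mode if "config" in summary.meta else "continuous"
    rng = np.random.default_rng(seed)
    idx = rng.choice(summary.samples.shape[0], size=n_draws, replace=False)
    outs = np.empty((n_draws, tc.times.size))
    inns = np.empty((n_draws, tc.times.size))
    for j, i in enumerate(idx):
        T1o, T1i, k1, amp, sd = summary.samples[i]
        mo, mi = _dnp_model(T1o, T1i, k1, amp, tc.times, acq, pulse_mode)
        if include_noise:
            mo = mo + rng.normal(0.0, sd, mo.size)
            mi = mi + rng.normal(0.0, sd, mi.size)
        outs[j], inns[j] = mo, mi
    lo_q, hi_q = 2.5, 97.5
    return PredictiveEnvelope(
        times=tc.times,
        out_median=np.median(outs, axis=0),
        out_lo=np.percentile(outs, lo_q, axis=0),
        out_hi=np.percentile(outs, hi_q, axis=0),
        in_median=np.median(inns, axis=0),
        in_lo=np.percentile(inns, lo_q, axis=0),
        in_hi=np.percentile(inns, hi_q, axis=0),
        include_noise=include_noise,
    )
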