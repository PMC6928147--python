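"""Seeded synthetic dDNP and thermal time courses with known ground truth.

No raw peak-integral data accompany the experiments this package models, so
parameter-recovery validation rests on generated datasets that emulate their
statistical structure: ~40-point dDNP courses at 1 s spacing with the
intracellular peak well below 1% of the initial extracellular signal, and
long thermal courses (spectra every 10-20 s over hundreds of seconds) whose
pairs are normalized to sum 1.  Noise is additive Gaussian on the peak
integrals, identical for both peaks (receiver thermal noise is
peak-independent); negative noisy integrals are legitimate data and are not
clipped.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .kinetics import (
    AcquisitionParams,
    ExchangeParams,
    PoolState,
    TimeCourse,
    propagate_labelled,
    simulate_thermal,
)

__all__ = [
    "NoiseModel",
    "SyntheticDataset",
    "generate_dnp_dataset",
    "generate_thermal_dataset",
    "make_fixture_suite",
    "DEFAULT_DNP_NOISE_SD",
    "DEFAULT_THERMAL_NOISE_SD",
]

# Default noise levels, in normalized signal units (fractions of the initial
# extracellular integral for dDNP; of the pair sum for thermal).
DEFAULT_DNP_NOISE_SD = 0.005
DEFAULT_THERMAL_NOISE_SD = 0.01


@dataclass(frozen=True)
class NoiseModel:
    """Additive i.i.d. Gaussian noise on peak integrals, with a fixed seed."""

    sd: float
    seed: int
    kind: str = "gaussian_additive"

    def __post_init__(self) -> None:
        if not (self.sd >= 0 and math.isfinite(self.sd)):
            raise ValueError(f"noise sd must be finite and >= 0, got {self.sd}")
        if self.kind != "gaussian_additive":
            raise ValueError(f"unsupported noise kind {self.kind!r}")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class SyntheticDataset:
    """A generated time course together with the truth that produced it."""

    timecourse: TimeCourse
    truth: dict = field(default_factory=dict)


def generate_dnp_dataset(
    truth: ExchangeParams,
    acq: AcquisitionParams,
    dose: float = 1.0,
    noise: NoiseModel = NoiseModel(sd=DEFAULT_DNP_NOISE_SD, seed=0),
    first_point_artifact: float = 0.0,
) -> SyntheticDataset:
    """Noisy hyperpolarized time course at the acquisition pulse grid.

    The clean trajectories are the labelled-pool forward model evaluated at
    the ``n_samples`` pulse instants, starting from an initial extracellular
    labelled amount ``dose`` (zero-trans: nothing inside at t = 0).

    ``first_point_artifact`` optionally shrinks the first extracellular
    integral by the given fraction, mimicking the incomplete-mixing artifact
    seen in the first acquired spectrum, to exercise drop-first-point
    handling downstream.
    """
    if not (0 <= first_point_artifact < 1):
        raise ValueError("first_point_artifact must be in [0, 1)")
    if not (dose > 0 and math.isfinite(dose)):
        raise ValueError(f"dose must be positive and finite, got {dose}")
    times = acq.sample_times()
    clean = propagate_labelled(
        truth,
        dataclasses.replace(acq, pulse_mode="continuous"),
        PoolState(labelled_out=dose),
        times,
    )
    out = clean.out_signal.copy()
    out[0] *= 1.0 - first_point_artifact
    inn = clean.in_signal.copy()
    rng = noise.rng()
    out = out + rng.normal(0.0, noise.sd, out.size)
    inn = inn + rng.normal(0.0, noise.sd, inn.size)
    tc = TimeCourse(
        times=times,
        out_signal=out,
        in_signal=inn,
        kind="dnp",
        meta={"synthetic": True, "truth": truth, "acq": acq, "noise": noise, "dose": dose},
    )
    return SyntheticDataset(
        timecourse=tc,
        truth={
            "params": truth,
            "acq": acq,
            "noise": noise,
            "dose": dose,
            "first_point_artifact": first_point_artifact,
        },
    )


def generate_thermal_dataset(
    k_fwd: float,
    k_rev: float,
    schedule=None,
    init_fractions=(1.0, 0.0),
    noise: NoiseModel = NoiseModel(sd=DEFAULT_THERMAL_NOISE_SD, seed=0),
    renormalize: bool = True,
) -> SyntheticDataset:
    """Noisy thermal exchange time course.

    Default schedule is a spectrum every 20 s out to 1200 s (> 3 equilibrium
    half-times at the rate constants typical here).  With ``renormalize``
    each noisy pair is rescaled to sum exactly 1, mimicking the
    conservation-of-mass normalization applied to measured pairs.
    """
    if schedule is None:
        schedule = np.arange(0.0, 1201.0, 20.0)
    clean = simulate_thermal(k_fwd, k_rev, init_fractions, schedule)
    rng = noise.rng()
    out = clean.out_signal + rng.normal(0.0, noise.sd, clean.out_signal.size)
    inn = clean.in_signal + rng.normal(0.0, noise.sd, clean.in_signal.size)
    if renormalize:
        s = out + inn
        if np.any(s <= 0):
            raise ValueError("pair sum non-positive after noise; cannot renormalize")
        out, inn = out / s, inn / s
    tc = TimeCourse(
        times=np.asarray(schedule, dtype=float),
        out_signal=out,
        in_signal=inn,
        kind="thermal",
        meta={
            "synthetic": True,
            "k_fwd": k_fwd,
            "k_rev": k_rev,
            "noise": noise,
            "renormalized": renormalize,
        },
    )
    return SyntheticDataset(
        timecourse=tc,
        truth={
            "k_fwd": k_fwd,
            "k_rev": k_rev,
            "init_fractions": tuple(float(f) for f in init_fractions),
            "noise": noise,
            "renormalized": renormalize,
        },
    )


#: Canonical fixture definitions: representative experimental conditions
#: (initial Cs+ concentration / delivery method) with their fitted constants.
_FIXTURES = {
    "dnp_3p3mM": dict(kind="dnp", T1_out=8.9, T1_in=1.2, k_fwd=0.0057, seed_offset=1),
    "dnp_2p5mM": dict(kind="dnp", T1_out=9.6, T1_in=3.0, k_fwd=0.0024, seed_offset=2),
    "dnp_33mM": dict(kind="dnp", T1_out=13.6, T1_in=2.4, k_fwd=0.0008, seed_offset=3),
    "thermal_d4": dict(kind="thermal", k_fwd=0.0043, k_rev=0.0091, seed_offset=4),
    "thermal_direct": dict(kind="thermal", k_fwd=0.0043, k_rev=0.013, seed_offset=5),
}


def make_fixture_suite(out_dir, base_seed: int = 20191223) -> dict:
    """Write the canonical synthetic fixtures as CSVs plus a truth manifest.

    Five datasets: three dDNP courses spanning the observed range of influx
    constants (high-activator low dose, low-activator low dose, high dose
    with the smallest k_fwd) and two thermal courses (the two delivery
    methods, differing in the efflux constant).  Returns the manifest dict;
    files are deterministic given ``base_seed``.
    """
    from .io import write_timecourse  # deferred to avoid an import cycle

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"base_seed": int(base_seed), "datasets": {}}
    for name, defn in _FIXTURES.items():
        seed = int(base_seed) + defn["seed_offset"]
        if defn["kind"] == "dnp":
            params = ExchangeParams(
                k_fwd=defn["k_fwd"], k_rev=0.0, T1_out=defn["T1_out"], T1_in=defn["T1_in"]
            )
            acq = AcquisitionParams(flip_angle=10.0, rep_time=1.0, n_samples=40)
            ds = generate_dnp_dataset(
                params, acq, dose=1.0, noise=NoiseModel(sd=DEFAULT_DNP_NOISE_SD, seed=seed)
            )
            entry = {
                "kind": "dnp",
                "params": {
                    "k_fwd": params.k_fwd,
                    "k_rev": params.k_rev,
                    "T1_out": params.T1_out,
                    "T1_in": params.T1_in,
                },
                "acq": {
                    "flip_angle": acq.flip_angle,
                    "rep_time": acq.rep_time,
                    "n_samples": acq.n_samples,
                },
                "dose": 1.0,
                "noise": {"kind": "gaussian_additive", "sd": DEFAULT_DNP_NOISE_SD, "seed": seed},
            }
        else:
            ds = generate_thermal_dataset(
                defn["k_fwd"],
                defn["k_rev"],
                noise=NoiseModel(sd=DEFAULT_THERMAL_NOISE_SD, seed=seed),
            )
            entry = {
                "kind": "thermal",
                "params": {"k_fwd": defn["k_fwd"], "k_rev": defn["k_rev"]},
                "init_fractions": [1.0, 0.0],
                "renormalized": True,
                "noise": {
                    "kind": "gaussian_additive",
                    "sd": DEFAULT_THERMAL_NOISE_SD,
                    "seed": seed,
                },
            }
        path = out_dir / f"{name}.csv"
        write_timecourse(ds.timecourse, path)
        entry["file"] = path.name
        manifest["datasets"][name] = entry
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
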