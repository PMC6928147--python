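"""Biophysical quantities derived from fitted exchange rate constants.

Downstream arithmetic of a membrane-transport kinetic analysis: diffusional
permeability (P_d = k_rev * V_cell_water / A_cell), initial flux, Nernst and
Goldman membrane potentials, aqueous volume fractions of a cell suspension,
and per-channel ion turnover.  All functions return full precision; rounding
to reporting precision is left to callers.

Units: s^-1 for rate constants, fL for volumes, um^2 for areas, mM for
concentrations, cm/s for permeabilities, mV for potentials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "CellGeometry",
    "PhysicalConstants",
    "RBC_GEOMETRY",
    "permeability",
    "nernst_potential",
    "goldman_potential",
    "influx_flux",
    "mmol_per_min_to_umol_per_s",
    "ions_per_cell_and_channel",
    "aqueous_volume_fractions",
    "matched_efflux",
    "derive_table",
]

_FL_PER_UM2_TO_CM = 1e-4  # 1 fL / 1 um^2 = 1e-12 cm^3 / 1e-8 cm^2


@dataclass(frozen=True)
class CellGeometry:
    """Geometry of the cell; defaults are the normal human erythrocyte.

    ``water_volume`` is the osmotically active water volume (fL),
    ``cell_volume`` the isovolumic whole-cell volume (fL), ``surface_area``
    the membrane area (um^2) and ``water_fraction`` the intracellular
    aqueous volume fraction of a normo-volumic cell.
    """

    water_volume: float = 62.0
    surface_area: float = 143.0
    cell_volume: float = 86.0
    water_fraction: float = 0.717

    def __post_init__(self) -> None:
        for name in ("water_volume", "surface_area", "cell_volume", "water_fraction"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{name} must be positive and finite, got {v}")
        if self.water_volume > self.cell_volume:
            raise ValueError("water_volume cannot exceed cell_volume")
        if self.water_fraction > 1:
            raise ValueError("water_fraction must be <= 1")


@dataclass(frozen=True)
class PhysicalConstants:
    """Constants used in the electrochemical formulas.

    Faraday's constant is 96.5 kC/mol (as conventionally rounded in the
    membrane-potential literature this package follows) rather than the
    CODATA value, and Avogadro's number 6.022e23, so worked numbers match
    the standard printed arithmetic.
    """

    R: float = 8.314  # J / (mol K)
    F: float = 96.5e3  # C / mol
    T: float = 310.15  # K
    z: int = 1
    N_A: float = 6.022e23  # 1 / mol

    def __post_init__(self) -> None:
        if not (self.T > 0 and math.isfinite(self.T)):
            raise ValueError(f"temperature must be positive, got {self.T}")


RBC_GEOMETRY = CellGeometry()


def permeability(k_rev: float, geom: CellGeometry = RBC_GEOMETRY) -> float:
    """Diffusional permeability coefficient P_d = k_rev * V_water / A, in cm/s.

    ``k_rev`` is the first-order efflux rate constant (1/s); the cell water
    volume (fL) and membrane area (um^2) come from ``geom``.
    """
    if not (k_rev >= 0 and math.isfinite(k_rev)):
        raise ValueError(f"k_rev must be finite and >= 0, got {k_rev}")
    return k_rev * (geom.water_volume / geom.surface_area) * _FL_PER_UM2_TO_CM


def nernst_potential(
    conc_ratio_out_over_in: float, consts: PhysicalConstants = PhysicalConstants()
) -> float:
    """Nernst membrane potential (mV) from an out/in concentration ratio."""
    r = conc_ratio_out_over_in
    if not (r > 0 and math.isfinite(r)):
        raise ValueError(f"concentration ratio must be positive and finite, got {r}")
    return 1e3 * consts.R * consts.T / (consts.z * consts.F) * math.log(r)


def goldman_potential(
    P_cation: float,
    P_anion: float,
    cation_out: float,
    cation_in: float,
    anion_out: float,
    anion_in: float,
    consts: PhysicalConstants = PhysicalConstants(),
) -> float:
    """Goldman potential (mV) for one permeant cation and one permeant anion.

    Delta_psi = (R T / z F) ln[(P_cat [cat]_out + P_an [an]_in) /
    (P_cat [cat]_in + P_an [an]_out)].  With ``P_anion = 0`` this reduces
    exactly to the cation's Nernst potential.
    """
    for name, v in (("P_cation", P_cation), ("P_anion", P_anion)):
        if not (v >= 0 and math.isfinite(v)):
            raise ValueError(f"{name} must be finite and >= 0, got {v}")
    if P_cation == 0 and P_anion == 0:
        raise ValueError("at least one permeability must be positive")
    for name, v in (
        ("cation_out", cation_out),
        ("cation_in", cation_in),
        ("anion_out", anion_out),
        ("anion_in", anion_in),
    ):
        if not (v >= 0 and math.isfinite(v)):
            raise ValueError(f"{name} must be finite and >= 0, got {v}")
    num = P_cation * cation_out + P_anion * anion_in
    den = P_cation * cation_in + P_anion * anion_out
    if num <= 0 or den <= 0:
        raise ValueError("numerator and denominator of the Goldman ratio must be positive")
    return 1e3 * consts.R * consts.T / (consts.z * consts.F) * math.log(num / den)


def influx_flux(k_fwd: float, conc_out: float, haematocrit: float) -> float:
    """Initial influx, mmol (L cells)^-1 s^-1.

    ``k_fwd`` acts on the extracellular amount, so the flux into a unit
    volume of cells is k_fwd * [ion]_out / Ht with the extracellular
    concentration in mM and the haematocrit Ht in (0, 1).
    """
    if not (0 < haematocrit < 1):
        raise ValueError(f"haematocrit must lie in (0, 1), got {haematocrit}")
    if not (k_fwd >= 0 and math.isfinite(k_fwd)):
        raise ValueError(f"k_fwd must be finite and >= 0, got {k_fwd}")
    if not (conc_out >= 0 and math.isfinite(conc_out)):
        raise ValueError(f"conc_out must be finite and >= 0, got {conc_out}")
    return k_fwd * conc_out / haematocrit


def mmol_per_min_to_umol_per_s(flux_mmol_per_min: float) -> float:
    """Convert mmol (L cells)^-1 min^-1 to umol (L cells)^-1 s^-1."""
    return flux_mmol_per_min * 1e3 / 60.0


def ions_per_cell_and_channel(
    flux_umol_per_L_cells_s: float,
    geom: CellGeometry = RBC_GEOMETRY,
    channels_per_cell: float = 55.0,
    consts: PhysicalConstants = PhysicalConstants(),
) -> tuple[float, float]:
    """Per-cell and per-channel ion turnover from a volume-normalized flux.

    With ``cell_volume`` in fL there are 1/(V*1e-15) cells per litre of
    cells; the flux (umol per litre of cells per second) times Avogadro's
    number divided by that count gives ions per cell per second, and
    dividing by the channel copy number gives the single-channel turnover
    (the transport analogue of an enzyme's k_cat).
    """
    if not (flux_umol_per_L_cells_s >= 0 and math.isfinite(flux_umol_per_L_cells_s)):
        raise ValueError("flux must be finite and >= 0")
    if channels_per_cell < 1:
        raise ValueError(f"channels_per_cell must be >= 1, got {channels_per_cell}")
    cells_per_litre = 1.0 / (geom.cell_volume * 1e-15)
    per_cell = flux_umol_per_L_cells_s * 1e-6 * consts.N_A / cells_per_litre
    return per_cell, per_cell / channels_per_cell


def aqueous_volume_fractions(
    haematocrit: float, water_fraction: float = RBC_GEOMETRY.water_fraction
) -> tuple[float, float, tuple[float, float]]:
    """Aqueous volume fractions of a cell suspension.

    Returns ``(intracellular_water, extracellular, (out_pct, in_pct))``:
    the intracellular-water fraction Ht * water_fraction, the extracellular
    fraction 1 - Ht, and the two expressed as percentages of the total
    aqueous volume.  At exchange equilibrium with equal concentrations on
    both sides, the out:in signal ratio equals this aqueous volume ratio.
    """
    if not (0 <= haematocrit <= 1):
        raise ValueError(f"haematocrit must lie in [0, 1], got {haematocrit}")
    if not (0 < water_fraction <= 1):
        raise ValueError(f"water_fraction must lie in (0, 1], got {water_fraction}")
    intra = haematocrit * water_fraction
    extra = 1.0 - haematocrit
    total = intra + extra
    return intra, extra, (100.0 * extra / total, 100.0 * intra / total)


def matched_efflux(k_fwd: float, k_fwd_ref: float, k_rev_ref: float) -> float:
    """Efflux constant scaled to a new influx constant at a fixed k_rev/k_fwd ratio.

    Used to carry an efflux estimate from a long (thermal) experiment over to
    a short hyperpolarized one with a different fitted influx constant:
    k_rev = (k_fwd / k_fwd_ref) * k_rev_ref.
    """
    if k_fwd_ref <= 0:
        raise ValueError("k_fwd_ref must be positive")
    return (k_fwd / k_fwd_ref) * k_rev_ref


def derive_table(
    k_fwd: float,
    k_rev: float | None,
    composition: dict,
    geom: CellGeometry = RBC_GEOMETRY,
    consts: PhysicalConstants = PhysicalConstants(),
) -> dict:
    """Full derived-quantity table from fitted rate constants.

    ``composition`` may contain ``conc_out_mM``, ``haematocrit``,
    ``conc_ratio_out_in`` and ``channels_per_cell``; quantities whose inputs
    are absent are omitted from the result.
    """
    table: dict = {"k_fwd_per_s": k_fwd}
    if k_rev is not None:
        table["k_rev_per_s"] = k_rev
        table["permeability_cm_per_s"] = permeability(k_rev, geom)
        from .kinetics import equilibrium_fractions

        if k_fwd + k_rev > 0:
            out_eq, in_eq = equilibrium_fractions(k_fwd, k_rev)
            table["equilibrium_out_fraction"] = out_eq
            table["equilibrium_in_fraction"] = in_eq
    ht = composition.get("haematocrit")
    conc = composition.get("conc_out_mM")
    if ht is not None and conc is not None:
        flux = influx_flux(k_fwd, conc, ht)
        table["influx_mmol_per_L_cells_s"] = flux
        per_cell, per_channel = ions_per_cell_and_channel(
            flux * 1e3, geom, composition.get("channels_per_cell", 55.0), consts
        )
        table["ions_per_cell_per_s"] = per_cell
        table["ions_per_channel_per_s"] = per_channel
    if ht is not None:
        intra, extra, (out_pct, in_pct) = aqueous_volume_fractions(ht, geom.water_fraction)
        table["intracellular_water_fraction"] = intra
        table["extracellular_fraction"] = extra
        table["aqueous_out_pct"] = out_pct
        table["aqueous_in_pct"] = in_pct
    ratio = composition.get("conc_ratio_out_in")
    if ratio is not None:
        table["nernst_potential_mV"] = nernst_potential(ratio, consts)
    return table
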