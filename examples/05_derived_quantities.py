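"""Downstream biophysics from fitted rate constants.

Takes the thermal-fit rate constants and the sample composition and derives
membrane permeability, initial flux, membrane potential, aqueous volume
fractions and per-channel turnover — the quantities that turn first-order
rate constants into cell-biological statements.
"""

from csflux import (
    aqueous_volume_fractions,
    influx_flux,
    ions_per_cell_and_channel,
    matched_efflux,
    mmol_per_min_to_umol_per_s,
    nernst_potential,
    permeability,
)

k_fwd, k_rev = 0.0043, 0.0091  # thermal-fit estimates, /s

P = permeability(k_rev)
print(f"permeability P_d = k_rev * V_water/A = {P:.2g} cm/s")

flux = influx_flux(k_fwd, 16.7, 0.4)
print(f"initial influx  = {flux:.2g} mmol (L cells)^-1 s^-1 "
      "(k_fwd x 16.7 mM / Ht 0.4)")

intra, extra, (out_pct, in_pct) = aqueous_volume_fractions(0.4, 0.717)
print(f"aqueous volumes: intracellular water {intra:.3f}, extracellular {extra:.1f}"
      f" -> {out_pct:.0f}:{in_pct:.0f} out:in")

print(f"membrane potential at ratio 1.19:1 = {nernst_potential(1.19):+.1f} mV")

per_cell, per_channel = ions_per_cell_and_channel(30.0, channels_per_cell=55.0)
print(f"turnover: {per_cell:.2g} ions/cell/s; {per_channel:.2g} ions/channel/s "
      "through ~55 channel trimers")

print(f"efflux carried to the hyperpolarized condition: "
      f"{matched_efflux(0.0057, k_fwd, k_rev):.4g} /s")
print(f"(29 umol (L cells)^-1 s^-1 = {mmol_per_min_to_umol_per_s(1.74):.0f} "
      "from the earlier per-minute convention)")
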