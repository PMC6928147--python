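"""Forward simulation of a hyperpolarized ion-transport time course.

Propagates the labelled (hyperpolarized) and unlabelled (relaxed) pools of a
two-site membrane exchange system at reference red-blood-cell parameters:
T1_out 8.9 s, T1_in 1.2 s, influx 0.0057 /s, a 10 degree read pulse every
second.  Prints the intracellular signal maximum, the scaling needed to
bring it to full scale, and the labelled-vs-total pool sizes at 40 s.
"""

import numpy as np

from csflux import AcquisitionParams, ExchangeParams, PoolState, propagate_full

params = ExchangeParams(k_fwd=0.0057, k_rev=0.0, T1_out=8.9, T1_in=1.2)
acq = AcquisitionParams(flip_angle=10.0, rep_time=1.0, n_samples=40)
grid = np.linspace(0.0, 40.0, 4001)[1:]
pools = propagate_full(params, acq, PoolState(labelled_out=1.0), grid)

peak = pools.labelled_in.max()
t_peak = pools.times[pools.labelled_in.argmax()]
print(f"intracellular labelled maximum: {peak:.4g} at t = {t_peak:.2f} s")
print(f"scaling required to reach 1.0:  {1.0 / peak:.0f}-fold")
print(f"mass conservation error:        {np.abs(pools.total - 1.0).max():.2e}")
print(f"at t = 40 s: labelled_in = {pools.labelled_in[-1]:.3g}, "
      f"total_in = {pools.total_in[-1]:.3g} "
      f"({pools.total_in[-1] / pools.labelled_in[-1]:.0f}x larger)")
print()
print("The hyperpolarized signal reports only a tiny, decaying 'label' on the")
print("chemical flux: the total transported pool at 40 s dwarfs the labelled")
print("one because relaxation strips the label while transport continues.")
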