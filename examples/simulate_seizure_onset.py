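"""Seizure-onset simulation: logistic coupling growth to synchronization.

Integrates the 14-oscillator system over 2580 model-seconds while the
coupling K(t) rises logistically (a = 0.0065, C = 75) from K0 = 0.00718,
crossing the critical value near t = 1800.  Prints the coherence r(t) at a
few checkpoints and the band it settles into after lock-in.  Runtime is
about half a minute.
"""

import numpy as np

from kurasync import (
    CouplingSchedule,
    OscillatorEnsemble,
    SimulationConfig,
    coupling_crossing_time,
    critical_coupling,
    reconstruct_dynamic,
    simulate,
    table1_fixture,
)

components = table1_fixture()
ensemble = OscillatorEnsemble(components.frequencies_hz)
schedule = CouplingSchedule.logistic(a=0.0065, C=75.0, K0=0.00718)

kc = critical_coupling(ensemble).K_c
t_cross = coupling_crossing_time(schedule, kc)
print(f"K_c = {kc:.5f}; logistic K(t) crosses it at t = {t_cross:.1f} s")

result = simulate(ensemble, schedule, SimulationConfig(t_end=2580.0, output_rate=1.0))
for t_check in (500, 1000, 1500, 1800, 2100, 2580):
    i = int(t_check)
    print(f"  t = {t_check:>4d} s   K = {result.coupling[i]:7.3f}   r = {result.r[i]:.3f}")

window = result.t >= 2280.0
print(f"final 300 s: r in [{result.r[window].min():.3f}, {result.r[window].max():.3f}]")

signal = reconstruct_dynamic(components, result)
print(f"reconstructed S(t): {len(signal)} samples, "
      f"late-stage amplitude ~{np.ptp(signal.samples[window])/2:.2f} mV")
print("\nBefore the crossing r stays near the incoherent floor; once K(t)")
print("exceeds K_c the ensemble partially locks and r oscillates in a high")
print("band (one gamma oscillator keeps drifting, so r < 1).")
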