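"""DTW comparison: synchronized simulation vs a coherent oscillation.

Simulates the strongly coupled ensemble (constant K = 75 > K_c),
reconstructs its scalar signal, and aligns it against (a) a single large
cosine — the seizure-like regime the synchronized system should resemble —
and (b) white noise of the same length.  A warping path closer to the
diagonal (higher linearity R^2) means more similar temporal structure.
"""

import numpy as np

from kurasync import (
    CouplingSchedule,
    OscillatorEnsemble,
    SimulationConfig,
    dtw_align,
    generate_seizure_like,
    reconstruct_dynamic,
    simulate,
    table1_fixture,
)

components = table1_fixture()
result = simulate(
    OscillatorEnsemble(components.frequencies_hz),
    CouplingSchedule.constant(75.0),
    SimulationConfig(t_end=60.0, output_rate=20.0),
)
recon = reconstruct_dynamic(components, result)
late = result.t >= 30.0
sim = recon.samples[late] - recon.samples[late].mean()

psi_rate = np.polyfit(result.t[late], np.unwrap(result.psi[late]), 1)[0] / (2 * np.pi)
seizure = generate_seizure_like(np.std(sim) * np.sqrt(2), psi_rate,
                                sim.size / 20.0, 20.0).samples[: sim.size]
noise = np.random.default_rng(0).normal(0.0, np.std(sim), size=sim.size)

for name, ref in [("seizure-like cosine", seizure), ("white noise", noise)]:
    res = dtw_align(sim, ref)
    print(f"vs {name:<20} normalized_cost = {res.normalized_cost:7.4f}   "
          f"path linearity R^2 = {res.linearity_r2:.4f}")

print("\nThe synchronized reconstruction warps near-diagonally onto the")
print("coherent oscillation and much less cleanly onto noise: linear path")
print("growth is the diagnostic of similar signals.")
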