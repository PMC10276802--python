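"""Dyadic-band component selection from a basal EEG-like signal.

Generates a noisy 60-s, 300-Hz synthetic basal signal (a 14-cosine sum plus
white noise), computes its one-sided amplitude spectrum, and keeps the
largest-amplitude bin in each dyadic band of FFT bins.  With 9000 bins
there are exactly 14 bands, one per conventional brainwave range.
"""

from kurasync import SynthSpec, compute_amplitude_spectrum, generate_basal, select_components

signal = generate_basal(SynthSpec(seed=42))  # default noise: 10% of peak amplitude
spectrum = compute_amplitude_spectrum(signal)
print(f"{len(signal)} samples -> {spectrum.n_bins} positive-frequency bins "
      f"({spectrum.bin_width_hz:.5f} Hz apart)")

components = select_components(spectrum)
print(f"selected {len(components)} components, one per dyadic band:\n")
print(f"{'band':>4} {'bin':>5} {'freq (Hz)':>10} {'amp (mV)':>9}  brainwave")
for c in components:
    print(f"{c.band_index:>4} {c.bin_index:>5} {c.frequency_hz:>10.4f} "
          f"{c.amplitude:>9.5f}  {c.brainwave}")

print("\nEach row is one oscillator source: the amplitude/phase feed the")
print("cosine-sum reconstruction and the frequency becomes a natural")
print("frequency of the coupled phase model.")
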