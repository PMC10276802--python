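"""Synthetic EEG-like signals for exercising the full pipeline.

The basal-condition generator emulates a resting cortical recording as a
sum of cosines — by default the 14 published components spanning infra-low
delta through gamma, whose repeating-decimal frequencies are exact
multiples of 1/60 Hz and therefore sit exactly on the FFT bins of a 60-s
window — plus additive white Gaussian noise.  The seizure-like generator
produces the opposite regime: one large coherent oscillation, the
signature of a fully synchronized ensemble.

Neither generator attempts realistic EEG background spectra (1/f),
movement artifacts or multi-channel structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .reconstruct import reconstruct_static
from .signals import Signal
from .spectral import ComponentSet, read_components_tsv

__all__ = ["SynthSpec", "table1_fixture", "generate_basal", "generate_seizure_like"]

_FIXTURE_NAME = "table1_components.tsv"


def table1_fixture() -> ComponentSet:
    """The packaged 14-component basal-EEG decomposition.

    Amplitudes in mV, frequencies in Hz (repeating decimals stored as the
    exact bin rationals k/60), initial phases in degrees on disk, plus the
    conventional brainwave label of each component.
    """
    with resources.as_file(
        resources.files("kurasync.data").joinpath(_FIXTURE_NAME)
    ) as path:
        return read_components_tsv(path)


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for a basal-condition synthetic signal.

    Defaults follow the study conditions: 60 s at 300 Hz built from the
    packaged 14-component set.  ``noise_sd`` defaults to 10% of the largest
    component amplitude.
    """

    components: ComponentSet = field(default_factory=table1_fixture)
    duration_s: float = 60.0
    sample_rate_hz: float = 300.0
    noise_sd: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.sample_rate_hz <= 0:
            raise ValueError("duration and sample rate must be positive")
        sd = self.noise_sd
        if sd is None:
            amps = self.components.amplitudes
            sd = 0.1 * float(amps.max()) if amps.size else 0.0
            object.__setattr__(self, "noise_sd", sd)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def generate_basal(spec: SynthSpec) -> Signal:
    """Cosine-sum basal signal plus seeded white Gaussian noise."""
    clean = reconstruct_static(spec.components, spec.duration_s, spec.sample_rate_hz)
    samples = clean.samples
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        samples = samples + rng.normal(0.0, spec.noise_sd, size=samples.size)
    return Signal(samples, spec.sample_rate_hz)


def generate_seizure_like(
    amplitude: float,
    frequency_hz: float,
    duration_s: float,
    sample_rate_hz: float = 300.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Signal:
    """A single large coherent oscillation, optionally noisy.

    Emulates the synchronized regime in which the ensemble behaves as one
    giant oscillator; used as a comparison target for DTW diagnostics.
    """
    if duration_s <= 0 or sample_rate_hz <= 0:
        raise ValueError("duration and sample rate must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    n = int(round(duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    samples = amplitude * np.cos(2.0 * np.pi * frequency_hz * t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        samples = samples + rng.normal(0.0, noise_sd, size=n)
    return Signal(samples, sample_rate_hz)
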