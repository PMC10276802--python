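"""One-sided amplitude spectra and dyadic-band component selection.

The amplitude spectrum uses the cosine convention: a tone
``A*cos(2*pi*f*t + phi)`` sampled exactly on FFT bin ``k`` comes back with
``bin_amplitudes[k-1] == A`` and ``bin_phases[k-1] == phi``.  The DC term is
stored doubled (``dc_amplitude / 2`` equals the sample mean) so that the
reconstruction ``A0/2 + sum_m A_m cos(2*pi*f_m*t + phi_m)`` holds without
special cases.

Component selection keeps one candidate per dyadic band of bins,

    B_0 = {1},   B_n = {k : 2**(n-1) < k <= 2**n},  n = 1..n_max,

taking the bin of largest amplitude in each band (ties to the lowest bin).
A 60-s window at 300 Hz has 9000 positive-frequency bins and therefore
yields floor(log2(9000)) + 1 = 14 components, one representative for every
conventional brainwave band from infra-low delta up to gamma.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .signals import Signal

__all__ = [
    "AmplitudeSpectrum",
    "SpectralComponent",
    "ComponentSet",
    "compute_amplitude_spectrum",
    "select_components",
    "brainwave_band",
    "read_components_tsv",
    "write_components_tsv",
]

# Conventional EEG band edges in Hz (upper edge inclusive).
_BRAINWAVE_EDGES = [
    (0.5, "Infra-low delta"),
    (4.0, "Delta"),
    (8.0, "Theta"),
    (13.0, "Alpha"),
    (30.0, "Beta"),
    (float("inf"), "Gamma"),
]


def brainwave_band(frequency_hz: float) -> str:
    """Conventional EEG band label for a frequency (upper edges inclusive)."""
    for upper, label in _BRAINWAVE_EDGES:
        if frequency_hz <= upper:
            return label
    raise AssertionError("unreachable")


@dataclass(frozen=True)
class AmplitudeSpectrum:
    """One-sided amplitude spectrum of an ``M``-sample signal.

    ``bin_amplitudes[k-1]`` and ``bin_phases[k-1]`` describe bin
    ``k = 1..floor(M/2)`` at frequency ``k * bin_width_hz``.  For even ``M``
    the Nyquist bin amplitude is ``|X_k|/M`` (not doubled).
    """

    dc_amplitude: float
    bin_amplitudes: np.ndarray
    bin_phases: np.ndarray
    bin_width_hz: float
    source_length: int

    def __post_init__(self) -> None:
        amps = np.asarray(self.bin_amplitudes, dtype=float)
        phases = np.asarray(self.bin_phases, dtype=float)
        if amps.shape != phases.shape or amps.ndim != 1:
            raise ValueError("amplitude/phase arrays must be 1-D and matched")
        if amps.size != self.source_length // 2:
            raise ValueError("expected floor(M/2) positive-frequency bins")
        if np.any(amps < 0):
            raise ValueError("amplitudes must be non-negative")
        object.__setattr__(self, "bin_amplitudes", amps)
        object.__setattr__(self, "bin_phases", phases)

    @property
    def n_bins(self) -> int:
        return self.bin_amplitudes.size

    def bin_frequency(self, k: int) -> float:
        return k * self.bin_width_hz


@dataclass(frozen=True)
class SpectralComponent:
    """One selected oscillator source: amplitude (mV), frequency (Hz),
    initial phase (radians internally), its dyadic band and FFT bin."""

    amplitude: float
    frequency_hz: float
    phase_rad: float
    band_index: int
    bin_index: int
    brainwave: str = ""

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.bin_index < 1 or self.band_index < 0:
            raise ValueError("bin_index >= 1 and band_index >= 0 required")
        lo = 0 if self.band_index == 0 else 2 ** (self.band_index - 1)
        hi = 1 if self.band_index == 0 else 2**self.band_index
        if not (lo < self.bin_index <= hi):
            raise ValueError(
                f"bin {self.bin_index} outside dyadic band {self.band_index} ({lo}, {hi}]"
            )

    @property
    def phase_deg(self) -> float:
        return float(np.degrees(self.phase_rad))


@dataclass(frozen=True)
class ComponentSet:
    """Frequency-sorted selected components plus the DC amplitude."""

    components: tuple[SpectralComponent, ...]
    dc_amplitude: float
    source_length: int
    sample_rate_hz: float

    def __post_init__(self) -> None:
        comps = tuple(self.components)
        bands = [c.band_index for c in comps]
        if bands != list(range(len(comps))):
            raise ValueError("band indices must be consecutive from 0")
        freqs = [c.frequency_hz for c in comps]
        if any(f0 > f1 for f0, f1 in zip(freqs, freqs[1:])):
            raise ValueError("components must be sorted by ascending frequency")
        object.__setattr__(self, "components", comps)

    def __len__(self) -> int:
        return len(self.components)

    def __iter__(self):
        return iter(self.components)

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([c.amplitude for c in self.components])

    @property
    def frequencies_hz(self) -> np.ndarray:
        return np.array([c.frequency_hz for c in self.components])

    @property
    def phases_rad(self) -> np.ndarray:
        return np.array([c.phase_rad for c in self.components])

    def take_first(self, n: int) -> "ComponentSet":
        """Restrict to the ``n`` lowest-frequency components."""
        if not (1 <= n <= len(self)):
            raise ValueError(f"take_first needs 1 <= n <= {len(self)}, got {n}")
        return ComponentSet(self.components[:n], self.dc_amplitude,
                            self.source_length, self.sample_rate_hz)


def compute_amplitude_spectrum(signal: Signal) -> AmplitudeSpectrum:
    """One-sided amplitude spectrum of a signal under the cosine convention.

    Amplitudes are ``2|X_k|/M`` for ``k = 1..floor(M/2)`` (Nyquist bin of an
    even-length signal: ``|X_k|/M``), the DC entry is ``2|X_0|/M``, and
    phases are the complex arguments of ``X_k``, so an on-bin tone's
    amplitude and phase are recovered exactly.
    """
    x = signal.samples
    M = x.size
    X = np.fft.rfft(x)
    # DC kept signed (A0/2 must equal the sample mean for reconstruction);
    # a cosine at f=0 has no phase slot to carry the sign.
    dc = 2.0 * X[0].real / M
    # rfft returns floor(M/2)+1 coefficients; drop DC to index bins from 1.
    amps = 2.0 * np.abs(X[1:]) / M
    if M % 2 == 0:
        amps[-1] /= 2.0  # Nyquist bin appears once in the full spectrum
    phases = np.angle(X[1:])
    return AmplitudeSpectrum(
        dc_amplitude=float(dc),
        bin_amplitudes=amps,
        bin_phases=phases,
        bin_width_hz=signal.sample_rate_hz / M,
        source_length=M,
    )


def max_band_index(spectrum: AmplitudeSpectrum) -> int:
    """Largest usable dyadic band index, floor(log2(n_bins))."""
    return int(np.floor(np.log2(spectrum.n_bins)))


def select_components(
    spectrum: AmplitudeSpectrum, n_max: int | None = None
) -> ComponentSet:
    """Pick one component per dyadic band of FFT bins.

    Bands are ``B_0 = {1}`` and ``B_n = (2**(n-1), 2**n]``; bins above
    ``2**n_max`` are discarded.  The candidate of a band is its bin of
    maximum amplitude, ties broken toward the lowest bin.  ``n_max=None``
    selects every available band, giving ``floor(log2(floor(M/2))) + 1``
    components.
    """
    if spectrum.n_bins < 1:
        raise ValueError("spectrum has no positive-frequency bins")
    auto = max_band_index(spectrum)
    if n_max is None:
        n_max = auto
    elif n_max > auto:
        raise ValueError(
            f"n_max={n_max} exceeds floor(log2({spectrum.n_bins})) = {auto}"
        )
    elif n_max < 0:
        raise ValueError("n_max must be >= 0")
    comps = []
    for n in range(n_max + 1):
        lo = 1 if n == 0 else 2 ** (n - 1) + 1
        hi = 1 if n == 0 else 2**n
        band = spectrum.bin_amplitudes[lo - 1 : hi]
        if band.size == 0:  # cannot happen for n <= n_max
            raise RuntimeError(f"empty dyadic band {n}")
        k = lo + int(np.argmax(band))  # argmax takes the first (lowest) bin on ties
        freq = spectrum.bin_frequency(k)
        comps.append(
            SpectralComponent(
                amplitude=float(spectrum.bin_amplitudes[k - 1]),
                frequency_hz=freq,
                phase_rad=float(spectrum.bin_phases[k - 1]),
                band_index=n,
                bin_index=k,
                brainwave=brainwave_band(freq),
            )
        )
    return ComponentSet(
        components=tuple(comps),
        dc_amplitude=spectrum.dc_amplitude,
        source_length=spectrum.source_length,
        sample_rate_hz=spectrum.bin_width_hz * spectrum.source_length,
    )


_TSV_COLUMNS = ["index", "amplitude_mv", "frequency_hz", "initial_phase_deg",
                "band", "bin", "brainwave"]


def write_components_tsv(cs: ComponentSet, path: str | Path) -> None:
    """Serialize a component set as TSV (phases in degrees).

    Header comment lines carry the DC amplitude and source-window metadata
    needed to round-trip the set.
    """
    rows = [
        {
            "index": i,
            "amplitude_mv": c.amplitude,
            "frequency_hz": c.frequency_hz,
            "initial_phase_deg": c.phase_deg,
            "band": c.band_index,
            "bin": c.bin_index,
            "brainwave": c.brainwave,
        }
        for i, c in enumerate(cs.components)
    ]
    df = pd.DataFrame(rows, columns=_TSV_COLUMNS)
    with open(path, "w") as fh:
        fh.write(f"# dc_amplitude_mv={cs.dc_amplitude!r}\n")
        fh.write(f"# source_length={cs.source_length}\n")
        fh.write(f"# sample_rate_hz={cs.sample_rate_hz!r}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def read_components_tsv(path: str | Path) -> ComponentSet:
    """Read a component TSV written by :func:`write_components_tsv`.

    Frequencies are recomputed exactly as ``bin * sample_rate / M`` so that
    repeating-decimal frequencies (e.g. 119.93... Hz = 7196/60) stay on-bin.
    """
    meta: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        if line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = float(value)
        else:
            body.append(line)
    import io

    df = pd.read_csv(io.StringIO("".join(body)), sep="\t")
    missing = [c for c in _TSV_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    M = int(meta.get("source_length", 0))
    fs = meta.get("sample_rate_hz", 0.0)
    bin_width = fs / M if M > 0 and fs > 0 else None
    comps = []
    for _, row in df.iterrows():
        k = int(row["bin"])
        # same expression as AmplitudeSpectrum.bin_frequency: bit-exact round trip
        freq = k * bin_width if bin_width else float(row["frequency_hz"])
        comps.append(
            SpectralComponent(
                amplitude=float(row["amplitude_mv"]),
                frequency_hz=freq,
                phase_rad=float(np.radians(row["initial_phase_deg"])),
                band_index=int(row["band"]),
                bin_index=k,
                brainwave=str(row.get("brainwave", "")),
            )
        )
    return ComponentSet(
        components=tuple(comps),
        dc_amplitude=float(meta.get("dc_amplitude_mv", 0.0)),
        source_length=M,
        sample_rate_hz=fs,
    )
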