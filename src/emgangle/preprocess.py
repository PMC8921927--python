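"""Signal conditioning: gain, de-bias, FIR bandpass, and mains notch.

The acquisition chain amplifies the electrode signals 700x and rides them on
a 2.5 V DC offset, so conditioning subtracts the bias and restricts the
spectrum to the 20-200 Hz band where surface EMG carries most of its power,
with a 48-52 Hz band-stop against 50 Hz mains interference.  Both filters
are linear-phase FIRs; because analysis is offline they are applied
zero-phase (forward-backward) by default, which removes group delay at the
cost of squaring the magnitude response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signal_core import EmgRecording

__all__ = [
    "FilterSpec",
    "debias",
    "apply_gain",
    "design_bandpass",
    "design_notch",
    "apply_fir",
    "preprocess",
]


@dataclass(frozen=True)
class FilterSpec:
    """Conditioning parameters.

    ``gain`` records the acquisition amplification (the hardware applies it
    before the bias is added); the software chain does not re-apply it.
    """

    band_low: float = 20.0
    band_high: float = 200.0
    notch_low: float = 48.0
    notch_high: float = 52.0
    fir_taps: int = 256
    gain: float = 700.0
    bias_v: float = 2.5
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.band_low < self.band_high:
            raise ValueError("need 0 < band_low < band_high")
        if not self.band_low <= self.notch_low < self.notch_high <= self.band_high:
            raise ValueError("notch band must sit inside the passband")
        if self.fir_taps < 3:
            raise ValueError("fir_taps must be at least 3")
        if not self.gain > 0:
            raise ValueError("gain must be positive")

    def validate_rate(self, sample_rate: float) -> None:
        if not self.band_high < sample_rate / 2:
            raise ValueError(
                f"band_high={self.band_high} Hz violates Nyquist for "
                f"sample_rate={sample_rate} Hz"
            )


def debias(rec: EmgRecording, bias: float = 2.5) -> EmgRecording:
    """Subtract the acquisition DC offset (volts) from every sample."""
    if not np.isfinite(bias):
        raise ValueError("bias must be finite")
    return rec.with_samples(rec.samples - bias)


def apply_gain(rec: EmgRecording, gain: float) -> EmgRecording:
    """Scale every sample by a positive gain."""
    if not gain > 0:
        raise ValueError("gain must be positive")
    return rec.with_samples(rec.samples * gain)


def design_bandpass(spec: FilterSpec, sample_rate: float) -> np.ndarray:
    """Linear-phase FIR bandpass coefficients for *spec* at *sample_rate*."""
    spec.validate_rate(sample_rate)
    return sps.firwin(
        spec.fir_taps,
        [spec.band_low, spec.band_high],
        pass_zero=False,
        fs=sample_rate,
    )


#: Transition width (Hz) on each side of the notch stop band.
_NOTCH_TRANSITION_HZ = 4.0


def design_notch(spec: FilterSpec, sample_rate: float) -> np.ndarray:
    """Linear-phase FIR band-stop coefficients rejecting the mains band.

    Uses an equiripple (Parks-McClellan) design: a stop band this narrow
    (4 Hz) needs sharp 4 Hz transitions that a windowed design cannot reach
    at ~256 taps.  A band-stop FIR needs unit response at DC and Nyquist,
    which requires a type-I (odd-length) filter; an even ``fir_taps`` is
    rounded up by one.
    """
    nyq = sample_rate / 2
    lo_edge = spec.notch_low - _NOTCH_TRANSITION_HZ
    hi_edge = spec.notch_high + _NOTCH_TRANSITION_HZ
    if not (0 < lo_edge and hi_edge < nyq):
        raise ValueError("notch band (plus transitions) must lie inside (0, Nyquist)")
    taps = spec.fir_taps | 1
    return sps.remez(
        taps,
        [0.0, lo_edge, spec.notch_low, spec.notch_high, hi_edge, nyq],
        [1.0, 0.0, 1.0],
        weight=[1.0, 5.0, 1.0],
        fs=sample_rate,
    )


def apply_fir(
    rec: EmgRecording, coeffs: np.ndarray, zero_phase: bool = True
) -> EmgRecording:
    """Apply an FIR filter per channel, preserving channel order.

    Zero-phase mode runs the filter forward and backward with reflect
    padding of one filter length at each end; causal mode is a plain
    convolution with the same padding, so the output keeps the input length.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    n = rec.n_samples
    pad = len(coeffs)
    if n <= pad:
        raise ValueError(
            f"recording of {n} samples is shorter than the {pad}-tap filter"
        )
    if zero_phase:
        out = sps.filtfilt(coeffs, [1.0], rec.samples, axis=0, padtype="even", padlen=pad)
    else:
        padded = np.concatenate(
            [rec.samples[pad - 1 :: -1], rec.samples, rec.samples[: -pad - 1 : -1]],
            axis=0,
        )
        filtered = sps.lfilter(coeffs, [1.0], padded, axis=0)
        delay = (len(coeffs) - 1) // 2  # linear phase: integer group delay
        out = filtered[pad + delay : pad + delay + n]
    return rec.with_samples(np.ascontiguousarray(out))


def preprocess(
    rec: EmgRecording,
    spec: FilterSpec | None = None,
    chain_gain: float = 1.0,
) -> EmgRecording:
    """Full conditioning chain: de-bias, gain, bandpass, notch.

    ``chain_gain`` defaults to 1 because amplification happens in hardware;
    set it to ``spec.gain`` to emulate the acquisition amplifier on
    unamplified inputs.  The chain is deterministic and linear after the
    de-bias stage.
    """
    spec = spec or FilterSpec()
    spec.validate_rate(rec.sample_rate)
    out = debias(rec, spec.bias_v)
    if chain_gain != 1.0:
        out = apply_gain(out, chain_gain)
    out = apply_fir(out, design_bandpass(spec, rec.sample_rate), spec.zero_phase)
    out = apply_fir(out, design_notch(spec, rec.sample_rate), spec.zero_phase)
    return out
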