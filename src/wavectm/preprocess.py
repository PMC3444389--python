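"""ECG conditioning: resampling and zero-phase filtering.

The default pipeline brings any record to a 1024 Hz operating rate and then
applies, in order, a 0.5 Hz highpass (baseline wander), a 70 Hz lowpass
(high-frequency noise) and a 50 Hz notch (powerline interference), each as a
forward/backward (zero-phase) pass.  The wavelet analysis downstream assigns
the 4-8 Hz atrial band to a fixed dyadic scale only at 1024 Hz, so resampling
comes first.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .signal_io import ECGRecord

__all__ = ["FilterSpec", "resample_to", "apply_filter", "condition", "DEFAULTS"]

#: Default conditioning parameters (Hz except where noted).
DEFAULTS = {
    "target_fs": 1024.0,
    "hp_cutoff": 0.5,
    "lp_cutoff": 70.0,
    "notch_freq": 50.0,
    "notch_q": 35.0,
    "filter_order": 5,
}


@dataclass
class FilterSpec:
    """One filtering stage of the conditioning chain.

    kind : "highpass", "lowpass" or "notch"
    cutoff_hz : cutoff (highpass/lowpass) or center frequency (notch), Hz
    order_or_q : Butterworth order (highpass/lowpass) or notch quality factor
    zero_phase : apply forward/backward for zero net phase (default True)
    """

    kind: str
    cutoff_hz: float
    order_or_q: float
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        if self.kind not in {"highpass", "lowpass", "notch"}:
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if not 0.0 < self.cutoff_hz < fs / 2:
            raise ValueError(
                f"{self.kind} cutoff {self.cutoff_hz} Hz must lie strictly inside (0, {fs / 2}) Hz"
            )


def resample_to(record: ECGRecord, target_fs: float) -> ECGRecord:
    """Resample to ``target_fs`` by rational polyphase interpolation.

    The rate ratio must be rational with small terms (denominator of the
    reduced fraction <= 1000); a Kaiser-windowed anti-imaging/anti-alias
    lowpass is applied by the polyphase resampler.
    """
    if not target_fs > 0:
        raise ValueError("target_fs must be positive")
    if target_fs == record.fs:
        return record.evolve(record.samples, f"resample:{target_fs:g}Hz(identity)")
    ratio = Fraction(target_fs).limit_denominator(10**6) / Fraction(record.fs).limit_denominator(10**6)
    if ratio.denominator > 1000 or ratio.numerator > 10**6:
        raise ValueError(
            f"resampling ratio {target_fs}/{record.fs} is not a manageable rational number"
        )
    up, down = ratio.numerator, ratio.denominator
    out = sps.resample_poly(record.samples, up, down, window=("kaiser", 5.0))
    return record.evolve(out, f"resample:{target_fs:g}Hz", fs=target_fs)


def _design_sos(spec: FilterSpec, fs: float) -> np.ndarray:
    if spec.kind in {"highpass", "lowpass"}:
        return sps.butter(
            int(spec.order_or_q), spec.cutoff_hz, btype=spec.kind, fs=fs, output="sos"
        )
    b, a = sps.iirnotch(spec.cutoff_hz, spec.order_or_q, fs=fs)
    return sps.tf2sos(b, a)


def apply_filter(record: ECGRecord, spec: FilterSpec) -> ECGRecord:
    """Apply one filter stage; zero-phase stages run forward/backward.

    Edge transients are suppressed by odd reflection padding three filter
    lengths long; a record shorter than the padding raises ``ValueError``.
    """
    spec.validate(record.fs)
    sos = _design_sos(spec, record.fs)
    if spec.zero_phase:
        padlen = 3 * (2 * sos.shape[0] + 1)
        if len(record.samples) <= padlen:
            raise ValueError(
                f"record too short for zero-phase filtering: {len(record.samples)} samples, "
                f"need > {padlen}"
            )
        out = sps.sosfiltfilt(sos, record.samples, padlen=padlen)
    else:
        out = sps.sosfilt(sos, record.samples)
    return record.evolve(out, f"filter:{spec.kind}:{spec.cutoff_hz:g}Hz")


def condition(
    record: ECGRecord,
    target_fs: float = DEFAULTS["target_fs"],
    hp_cutoff: float = DEFAULTS["hp_cutoff"],
    lp_cutoff: float = DEFAULTS["lp_cutoff"],
    notch_freq: float = DEFAULTS["notch_freq"],
    notch_q: float = DEFAULTS["notch_q"],
    filter_order: int = DEFAULTS["filter_order"],
) -> ECGRecord:
    """Full conditioning chain: resample -> highpass -> lowpass -> notch.

    All filters are zero-phase.  The notch frequency is configurable for
    60 Hz mains regions; the default is 50 Hz.
    """
    rec = resample_to(record, target_fs)
    rec = apply_filter(rec, FilterSpec("highpass", hp_cutoff, filter_order))
    rec = apply_filter(rec, FilterSpec("lowpass", lp_cutoff, filter_order))
    rec = apply_filter(rec, FilterSpec("notch", notch_freq, notch_q))
    return rec
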