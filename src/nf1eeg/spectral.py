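"""Log spectral power: single-window Hann FFT, canonical bands, baseline ratio.

Conventions (config-exposed, fixed here for reproducibility):

* power scale: one-sided amplitude-compensated periodogram, so a
  unit-amplitude sinusoid contributes mean-square power 0.5 at its bin
  regardless of window length or zero-padding;
* log base 10, displayed as log10(uV^2);
* log is applied per epoch, then spectra are averaged over epochs
  (log-then-average, which is not the same as average-then-log);
* band bounds are inclusive at the stated integer frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal.windows import hann

from .core import BANDS, MID_FRONTAL, Epochs, window_slice

__all__ = [
    "PowerSpectrum",
    "BandPower",
    "compute_log_spectrum",
    "band_power",
    "task_specific_power",
    "band_table_gap",
]

_LOG_FLOOR = 1e-30


@dataclass
class PowerSpectrum:
    """Channels x frequencies log10 power averaged over epochs."""

    values: np.ndarray           # (n_channels, n_freqs) log10 power
    freqs: np.ndarray            # Hz, uniform grid
    resolution: float            # Hz
    window_ms: tuple[float, float]
    n_epochs: int
    condition: str | None
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.freqs = np.asarray(self.freqs, float)
        diffs = np.diff(self.freqs)
        if self.freqs.size > 1 and not np.allclose(diffs, self.resolution, atol=1e-9):
            raise ValueError("frequency grid must be uniform at the stated resolution")
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")

    def channel_values(self, label: str) -> np.ndarray:
        return self.values[self.channels.index(label)]


@dataclass
class BandPower:
    """Per-band mean log10 power over a channel set."""

    bands: dict
    values: dict
    channel_set: str
    condition: str | None
    adjusted: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.values[b] for b in self.bands])


def compute_log_spectrum(
    epochs: Epochs,
    window_ms: tuple[float, float] = (900.0, 1900.0),
    resolution: float = 1.0,
    condition: str | None = None,
    correct_only: bool = False,
) -> PowerSpectrum:
    """Hann-tapered FFT per epoch and channel, log10, averaged over epochs.

    The FFT length is rate/resolution; a window shorter than that is
    zero-padded (the 0.25 Hz grid of the alpha-peak analysis comes from the
    1900 ms epoch this way).  Rejected epochs never contribute.
    """
    lo, hi = window_ms
    if lo < epochs.window_ms[0] - 1e-9 or hi > epochs.window_ms[1] + 1e-9:
        raise ValueError(f"analysis window {window_ms} outside epoch {epochs.window_ms}")
    mask = epochs.valid_mask(condition, correct_only=correct_only)
    n_valid = int(mask.sum())
    if n_valid < 1:
        raise ValueError("no valid epochs to average")
    sl = window_slice(lo, hi, epochs.rate, anchor_ms=epochs.window_ms[0])
    seg = epochs.data[mask][:, :, sl]
    n = seg.shape[-1]
    n_fft = epochs.rate / resolution
    if abs(n_fft - round(n_fft)) > 1e-9:
        raise ValueError(f"resolution {resolution} Hz not commensurate with rate {epochs.rate}")
    n_fft = int(round(n_fft))
    if n_fft < n:
        raise ValueError(
            f"resolution {resolution} Hz implies {n_fft} samples, window has {n}"
        )
    taper = hann(n, sym=False)
    spec = np.fft.rfft(seg * taper, n=n_fft, axis=-1)
    # Amplitude-compensated one-sided power: unit sinusoid -> 0.5 at its bin.
    amp = 2.0 * np.abs(spec) / taper.sum()
    power = 0.5 * amp**2
    logp = np.log10(np.maximum(power, _LOG_FLOOR))
    values = logp.mean(axis=0)
    freqs = np.fft.rfftfreq(n_fft, 1.0 / epochs.rate)
    return PowerSpectrum(
        values=values,
        freqs=freqs,
        resolution=epochs.rate / n_fft,
        window_ms=window_ms,
        n_epochs=n_valid,
        condition=condition,
        channels=tuple(epochs.montage.labels),
    )


def band_power(
    spec: PowerSpectrum,
    channel_set: str = "all_scalp",
    montage=None,
    bands: dict = BANDS,
) -> BandPower:
    """Mean log power over in-band bins (inclusive bounds) and channels.

    ``channel_set`` is "all_scalp" (needs ``montage``), "mid_frontal"
    (Fz/F1/F2), or an explicit sequence of labels.
    """
    if channel_set == "all_scalp":
        if montage is None:
            raise ValueError("all_scalp channel set needs the montage")
        labels = montage.scalp_labels
        set_name = "all_scalp"
    elif channel_set == "mid_frontal":
        labels = MID_FRONTAL
        set_name = "mid_frontal"
    else:
        labels = tuple(channel_set)
        set_name = ",".join(labels)
    missing = [ch for ch in labels if ch not in spec.channels]
    if missing:
        raise KeyError(f"spectrum lacks channels {missing}")
    rows = [spec.channels.index(ch) for ch in labels]
    values = {}
    for name, (lo, hi) in bands.items():
        in_band = (spec.freqs >= lo - 1e-9) & (spec.freqs <= hi + 1e-9)
        if not in_band.any():
            raise ValueError(f"band {name} ({lo}-{hi} Hz) is empty on the grid")
        values[name] = float(spec.values[np.ix_(rows, np.flatnonzero(in_band))].mean())
    return BandPower(
        bands=dict(bands),
        values=values,
        channel_set=set_name,
        condition=spec.condition,
    )


def task_specific_power(task: BandPower, rest_open: BandPower) -> BandPower:
    """Task-specific (baseline-adjusted) power: log(task) - log(rest, eyes open).

    Sign is interpretable only as relative modulation; there is no
    pre-stimulus baseline to anchor the absolute level.
    """
    if task.bands != rest_open.bands:
        raise ValueError("band tables differ between task and rest")
    if task.channel_set != rest_open.channel_set:
        raise ValueError("channel sets differ between task and rest")
    if rest_open.condition not in (None, "eyes_open"):
        raise ValueError("baseline must be the eyes-open resting condition")
    values = {b: task.values[b] - rest_open.values[b] for b in task.bands}
    return replace(task, values=values, adjusted=True)


def band_table_gap(bands: dict = BANDS, lo: int = 1, hi: int = 100) -> list[int]:
    """Integer frequencies in [lo, hi] covered by no band (the notch region)."""
    uncovered = []
    for f in range(lo, hi + 1):
        if not any(b_lo <= f <= b_hi for b_lo, b_hi in bands.values()):
            uncovered.append(f)
    return uncovered
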