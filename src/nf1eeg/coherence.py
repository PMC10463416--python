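"""Frontoparietal theta inter-site phase clustering (ISPC).

Pipeline: Surface-Laplacian spatial filtering -> complex Morlet wavelet
(4 cycles) phase extraction at 4/5/6/7 Hz -> per-timepoint ISPC over trials
for each of the 27 mid-frontal-to-parietal channel pairs -> averaging in the
fixed order time window (900-1500 ms) -> frequencies -> channel pairs,
yielding one estimate per region pair (ML, MM, MR) and load.  Task estimates
are baseline-adjusted by subtracting the identically computed eyes-open
resting estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import fftconvolve

from .core import (
    MID_FRONTAL,
    PARIETAL_REGIONS,
    Epochs,
    window_slice,
)
from .spherical import surface_laplacian_operator

__all__ = [
    "PhaseSeries",
    "CoherenceEstimate",
    "surface_laplacian",
    "morlet_phase",
    "ispc_trials",
    "frontoparietal_ispc",
    "task_specific_coherence",
    "THETA_FREQS_HZ",
    "COHERENCE_WINDOW_MS",
]

THETA_FREQS_HZ = (4.0, 5.0, 6.0, 7.0)
COHERENCE_WINDOW_MS = (900.0, 1500.0)
N_CYCLES = 4.0
#: Wavelet truncation in Gaussian SDs; at 4 cycles this keeps the 4 Hz
#: half-support (~398 ms) inside the 400 ms guard band after 1500 ms.
TRUNC_SD = 2.5


@dataclass
class PhaseSeries:
    """Per-trial instantaneous phase (radians, wrapped to (-pi, pi])."""

    angles: np.ndarray          # (n_trials, n_times)
    freq_hz: float
    channel: str
    times_ms: np.ndarray

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, float)
        if self.angles.ndim != 2 or self.angles.shape[0] < 1:
            raise ValueError("angles must be trials x time with >= 1 trial")
        if np.any(self.angles <= -np.pi - 1e-12) or np.any(self.angles > np.pi + 1e-12):
            raise ValueError("phases must be wrapped to (-pi, pi]")

    @property
    def n_trials(self) -> int:
        return self.angles.shape[0]


@dataclass
class CoherenceEstimate:
    region_pair: str            # "ML" | "MM" | "MR"
    load: str                   # "1back" | "2back" | "rest"
    ispc: float
    n_trials: int
    adjusted: float | None = None
    rest_ispc: float | None = None
    provenance: dict | None = None

    def __post_init__(self) -> None:
        if not (0.0 - 1e-12 <= self.ispc <= 1.0 + 1e-12):
            raise ValueError("raw ISPC must lie in [0, 1]")
        if self.adjusted is not None and not (-1.0 - 1e-12 <= self.adjusted <= 1.0 + 1e-12):
            raise ValueError("adjusted ISPC must lie in [-1, 1]")
        if self.n_trials < 2:
            raise ValueError("ISPC needs at least 2 trials")


# --------------------------------------------------------------------------
# Surface Laplacian
# --------------------------------------------------------------------------


def surface_laplacian(
    epochs: Epochs, m: int = 4, n_terms: int = 10, reg: float = 1e-5
) -> Epochs:
    """Spherical-spline Surface Laplacian of the scalp channels.

    Linear in the input; attenuates spatially broad (volume-conducted)
    activity relative to focal sources.  Auxiliary channels pass through
    unchanged.
    """
    montage = epochs.montage
    scalp = montage.scalp_indices
    if scalp.size < 3:
        raise ValueError("surface Laplacian needs at least 3 scalp channels")
    L = surface_laplacian_operator(montage.positions[scalp], m=m, n_terms=n_terms, reg=reg)
    out = epochs.copy()
    out.data[:, scalp, :] = np.einsum("cg,egt->ect", L, epochs.data[:, scalp, :])
    return out


# --------------------------------------------------------------------------
# Morlet phase
# --------------------------------------------------------------------------


def _morlet_kernel(freq_hz: float, rate: float, n_cycles: float = N_CYCLES):
    sd_t = n_cycles / (2.0 * np.pi * freq_hz)
    half = int(round(TRUNC_SD * sd_t * rate))
    t = np.arange(-half, half + 1) / rate
    kernel = np.exp(2j * np.pi * freq_hz * t) * np.exp(-(t**2) / (2 * sd_t**2))
    return kernel / np.sqrt(np.sum(np.abs(kernel) ** 2)), half


def wavelet_half_support_s(freq_hz: float, rate: float, n_cycles: float = N_CYCLES) -> float:
    """Temporal half-support of the truncated wavelet in seconds."""
    return _morlet_kernel(freq_hz, rate, n_cycles)[1] / rate


def morlet_phase(
    epochs: Epochs,
    channel: str,
    freq_hz: float,
    condition: str | None = None,
    correct_only: bool = False,
    n_cycles: float = N_CYCLES,
) -> PhaseSeries:
    """Instantaneous phase via complex Morlet convolution (Gaussian-windowed
    complex exponential, ``n_cycles`` cycles, unit energy)."""
    if not (1.0 <= freq_hz <= epochs.rate / 2.0):
        raise ValueError(f"frequency {freq_hz} Hz outside 1-Nyquist")
    mask = epochs.valid_mask(condition, correct_only=correct_only)
    sig = epochs.data[mask, epochs.montage.index(channel), :]
    kernel, _ = _morlet_kernel(freq_hz, epochs.rate, n_cycles)
    conv = fftconvolve(sig, kernel[None, :], mode="same", axes=-1)
    return PhaseSeries(
        angles=np.angle(conv),
        freq_hz=freq_hz,
        channel=channel,
        times_ms=epochs.times_ms,
    )


# --------------------------------------------------------------------------
# ISPC
# --------------------------------------------------------------------------


def ispc_trials(x: PhaseSeries, y: PhaseSeries) -> np.ndarray:
    """Per-timepoint ISPC over trials: | n^-1 sum_t exp(i(phi_x - phi_y)) |."""
    if x.angles.shape != y.angles.shape:
        raise ValueError("phase series shapes differ")
    if x.freq_hz != y.freq_hz:
        raise ValueError("phase series frequencies differ")
    if x.angles.shape[0] < 2:
        raise ValueError("ISPC over trials needs n >= 2")
    return np.abs(np.mean(np.exp(1j * (x.angles - y.angles)), axis=0))


def frontoparietal_ispc(
    epochs: Epochs,
    load: str,
    window_ms: tuple[float, float] = COHERENCE_WINDOW_MS,
    freqs_hz=THETA_FREQS_HZ,
    n_cycles: float = N_CYCLES,
) -> dict[str, CoherenceEstimate]:
    """Region-pair theta ISPC for one load (or "rest" on eyes-open epochs).

    ISPC is computed for all 27 mid-frontal-to-parietal channel pairs and
    each frequency, then averaged in the fixed order: time window ->
    frequencies -> channel pairs within each parietal set.  Asserts that no
    wavelet half-support crosses the epoch end inside the window.
    """
    condition = "eyes_open" if load == "rest" else load
    correct_only = load != "rest"
    for ch in MID_FRONTAL + tuple(c for r in PARIETAL_REGIONS.values() for c in r):
        if ch not in epochs.montage.labels:
            raise KeyError(f"coherence region channel {ch} missing from montage")

    guard_s = (epochs.window_ms[1] - window_ms[1]) / 1000.0
    worst = max(wavelet_half_support_s(f, epochs.rate, n_cycles) for f in freqs_hz)
    if worst > guard_s + 1e-9:
        raise ValueError(
            f"wavelet half-support {worst * 1000:.0f} ms crosses the epoch end within "
            f"the {window_ms} ms window (guard {guard_s * 1000:.0f} ms)"
        )

    channels = MID_FRONTAL + tuple(c for r in PARIETAL_REGIONS.values() for c in r)
    phases = {
        (ch, f): morlet_phase(
            epochs, ch, f, condition=condition, correct_only=correct_only, n_cycles=n_cycles
        )
        for ch in channels
        for f in freqs_hz
    }
    n_trials = next(iter(phases.values())).n_trials
    sl = window_slice(*window_ms, epochs.rate, anchor_ms=epochs.window_ms[0])

    out: dict[str, CoherenceEstimate] = {}
    for pair_name, parietal in PARIETAL_REGIONS.items():
        per_pair = []
        for seed_ch in MID_FRONTAL:
            for par_ch in parietal:
                per_freq = []
                for f in freqs_hz:
                    series = ispc_trials(phases[(seed_ch, f)], phases[(par_ch, f)])
                    per_freq.append(series[sl].mean())      # time average first
                per_pair.append(np.mean(per_freq))          # then frequencies
        out[pair_name] = CoherenceEstimate(
            region_pair=pair_name,
            load=load,
            ispc=float(np.mean(per_pair)),                  # finally channel pairs
            n_trials=n_trials,
            provenance={
                "window_ms": tuple(window_ms),
                "freqs_hz": tuple(freqs_hz),
                "n_channel_pairs": len(per_pair),
                "n_total_pairs": len(MID_FRONTAL)
                * sum(len(r) for r in PARIETAL_REGIONS.values()),
                "n_cycles": n_cycles,
            },
        )
    return out


def task_specific_coherence(
    task: CoherenceEstimate, rest_open: CoherenceEstimate
) -> CoherenceEstimate:
    """Adjusted coherence: task ISPC minus the eyes-open resting ISPC.

    Raw components are retained for audit; the difference may be negative
    and is never clipped.
    """
    if task.region_pair != rest_open.region_pair:
        raise ValueError(
            f"region pair mismatch: {task.region_pair} vs {rest_open.region_pair}"
        )
    if rest_open.load != "rest":
        raise ValueError("baseline estimate must come from resting state")
    return replace(
        task,
        adjusted=float(task.ispc - rest_open.ispc),
        rest_ispc=rest_open.ispc,
    )
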