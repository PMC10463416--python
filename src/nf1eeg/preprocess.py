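"""Continuous-to-clean-epochs preprocessing.

Order of operations mirrors the analysis protocol: mastoid re-reference ->
filter chain (0.1 Hz high-pass, downsample to 256 Hz, profile low-pass,
48-52 Hz notch) -> epoching with per-epoch mean-centring -> ocular ICA ->
threshold rejection with bad-channel interpolation -> common-average
re-reference -> inclusion check (>= 15 valid epochs per condition).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal

from .core import (
    EPOCH_WINDOW_MS,
    Epochs,
    Montage,
    Recording,
    window_n_samples,
)
from .spherical import spline_interpolation_matrix
from .synthetic_eeg import blink_projection

logger = logging.getLogger(__name__)

__all__ = [
    "rereference",
    "filter_chain",
    "make_epochs",
    "ocular_ica",
    "reject_and_repair",
    "check_inclusion",
    "IcaModel",
    "InclusionReport",
    "AllChannelsBadError",
    "REJECTION_THRESHOLD_UV",
    "MIN_VALID_EPOCHS",
]

#: Amplitude rejection thresholds (uV) per analysis profile.
REJECTION_THRESHOLD_UV = {"rest": 200.0, "task": 120.0}

#: Minimum valid epochs per condition for a participant to be included.
MIN_VALID_EPOCHS = 15

TARGET_RATE = 256.0
LOW_PASS_HZ = {"rest": 200.0, "task": 120.0}
HIGH_PASS_HZ = 0.1
NOTCH_BAND_HZ = (46.0, 54.0)  # -6 dB edges bracketing the 48-52 Hz stop band


class AllChannelsBadError(RuntimeError):
    """Every scalp channel exceeded the bad-channel criterion."""


# --------------------------------------------------------------------------
# Re-referencing
# --------------------------------------------------------------------------


def rereference(obj: Recording | Epochs, mode: str):
    """Re-reference to averaged mastoids or to the common average.

    Mastoid mode subtracts (M1+M2)/2 from every channel.  Common-average
    mode subtracts the per-sample mean over scalp channels from the scalp
    channels (auxiliary channels are left untouched).
    """
    montage = obj.montage
    out = obj.copy()
    if mode == "averaged-mastoids":
        try:
            m1, m2 = montage.index("M1"), montage.index("M2")
        except KeyError as err:
            raise ValueError(f"mastoid re-reference needs M1 and M2: {err}") from None
        if isinstance(obj, Recording):
            ref = 0.5 * (out.data[m1] + out.data[m2])
            out.data -= ref[None, :]
        else:
            ref = 0.5 * (out.data[:, m1, :] + out.data[:, m2, :])
            out.data -= ref[:, None, :]
    elif mode == "common-average":
        scalp = montage.scalp_indices
        if scalp.size == 0:
            raise ValueError("common-average re-reference needs scalp channels")
        if isinstance(obj, Recording):
            ref = out.data[scalp].mean(axis=0)
            out.data[scalp] -= ref[None, :]
        else:
            ref = out.data[:, scalp, :].mean(axis=1)
            out.data[:, scalp, :] -= ref[:, None, :]
    else:
        raise ValueError(f"unknown re-reference mode {mode!r}")
    return out


# --------------------------------------------------------------------------
# Filtering
# --------------------------------------------------------------------------


@lru_cache(maxsize=16)
def _fir_kernel(kind: str, fs: float, lo: float, hi: float | None) -> np.ndarray:
    """Odd-length windowed-sinc FIR kernels (zero-phase when centre-applied)."""
    if kind == "highpass":
        # transition band of 2x the cutoff keeps the kernel manageable; the
        # -6 dB point of the windowed sinc sits at the cutoff itself
        numtaps = int(3.3 * fs / (2 * lo))
        numtaps += 1 - numtaps % 2
        return signal.firwin(numtaps, lo, pass_zero=False, fs=fs)
    if kind == "lowpass":
        trans = max(0.05 * lo, min(8.0, 0.95 * fs / 2 - lo))
        numtaps = int(3.3 * fs / trans)
        numtaps += 1 - numtaps % 2
        return signal.firwin(numtaps, lo, pass_zero=True, fs=fs)
    if kind == "bandstop":
        trans = 2.0
        numtaps = int(3.3 * fs / trans)
        numtaps += 1 - numtaps % 2
        return signal.firwin(numtaps, [lo, hi], pass_zero="bandstop", fs=fs)
    raise ValueError(kind)


def _apply_fir(data: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Zero-phase application of a symmetric FIR along the last axis."""
    d = (len(h) - 1) // 2
    pad = min(d, data.shape[-1] - 1)
    padded = np.pad(data, [(0, 0)] * (data.ndim - 1) + [(pad, pad)], mode="reflect")
    out = signal.fftconvolve(padded, h.reshape((1,) * (data.ndim - 1) + (-1,)), mode="same", axes=-1)
    return out[..., pad : pad + data.shape[-1]]


def filter_chain(rec: Recording, profile: str) -> Recording:
    """High-pass, downsample to 256 Hz, profile low-pass, 48-52 Hz notch.

    Stages run in that order; event sample indices are remapped to the new
    rate.  A low-pass edge above the post-downsample Nyquist (the resting
    profile's 200 Hz) is skipped — the decimator's anti-alias filter already
    bounds content at 128 Hz.
    """
    if profile not in LOW_PASS_HZ:
        raise ValueError(f"unknown filter profile {profile!r}")
    fs = rec.rate
    if fs < TARGET_RATE:
        raise ValueError(f"input rate {fs} Hz below the {TARGET_RATE} Hz target")
    factor = fs / TARGET_RATE
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(f"input rate {fs} Hz is not an integer multiple of {TARGET_RATE} Hz")
    factor = int(round(factor))

    data = _apply_fir(rec.data, _fir_kernel("highpass", fs, HIGH_PASS_HZ, None))
    if factor > 1:
        data = signal.resample_poly(data, up=1, down=factor, axis=-1)
    fs2 = TARGET_RATE

    lp = LOW_PASS_HZ[profile]
    if lp < 0.95 * fs2 / 2:
        data = _apply_fir(data, _fir_kernel("lowpass", fs2, lp, None))
    else:
        logger.info(
            "low-pass edge %.0f Hz above Nyquist at %.0f Hz; stage skipped", lp, fs2
        )
    data = _apply_fir(data, _fir_kernel("bandstop", fs2, *NOTCH_BAND_HZ))

    n_new = data.shape[-1]
    events = []
    for sample, code in rec.events:
        new = int(round(sample / factor))
        if 0 <= new < n_new:
            events.append((new, code))
    return Recording(data=data, rate=fs2, montage=rec.montage, events=events)


# --------------------------------------------------------------------------
# Epoching
# --------------------------------------------------------------------------


def _mean_center(data: np.ndarray) -> np.ndarray:
    return data - data.mean(axis=-1, keepdims=True)


_SEGMENT_CODES = {"rest_open": "eyes_open", "rest_closed": "eyes_closed"}
_BOUNDARY_CODES = {"rest_open", "rest_closed", "block_start_1back", "block_start_2back"}


def make_epochs(rec: Recording, scheme: str, window_ms=EPOCH_WINDOW_MS) -> Epochs:
    """Cut a filtered recording into mean-centred epochs.

    ``scheme='task'``: one epoch per stimulus onset (0-1900 ms), with target
    flags and response correctness (a response 0.15-1.9 s after a target is
    a hit; any response after a non-target is a false alarm; silence after a
    target is a miss).  ``scheme='rest-arbitrary'``: rest segments tiled
    into non-overlapping arbitrary epochs; eyes-open and eyes-closed epochs
    are carried in one container.
    """
    n_samp = window_n_samples(*window_ms, rec.rate)
    n_total = rec.n_samples
    chunks, conditions = [], []

    if scheme == "rest-arbitrary":
        events = sorted(rec.events)
        starts = [
            (s, _SEGMENT_CODES[code]) for s, code in events if code in _SEGMENT_CODES
        ]
        if not starts:
            raise ValueError("recording has no rest segment events")
        boundaries = sorted(s for s, code in events if code in _BOUNDARY_CODES)
        for seg_start, condition in starts:
            later = [b for b in boundaries if b > seg_start]
            seg_end = later[0] if later else n_total
            n_fit = (seg_end - seg_start) // n_samp
            if n_fit == 0:
                logger.warning(
                    "rest segment (%s) shorter than one %.0f ms epoch; skipped",
                    condition,
                    window_ms[1] - window_ms[0],
                )
                continue
            for k in range(n_fit):
                a = seg_start + k * n_samp
                chunks.append(rec.data[:, a : a + n_samp])
                conditions.append(condition)
        if not chunks:
            raise ValueError("no rest epochs could be formed")
        data = _mean_center(np.stack(chunks))
        return Epochs(
            data=data,
            rate=rec.rate,
            window_ms=window_ms,
            conditions=np.array(conditions, dtype=object),
            montage=rec.montage,
        )

    if scheme == "task":
        stim = [
            (s, code) for s, code in sorted(rec.events) if code.startswith("stim_")
        ]
        if not stim:
            raise ValueError("recording has no stimulus events")
        responses = np.array(
            sorted(s for s, code in rec.events if code == "response"), dtype=int
        )
        targets, correct = [], []
        min_rt = int(round(0.15 * rec.rate))
        for s, code in stim:
            if s + n_samp > n_total:
                logger.warning("stimulus at sample %d truncated by recording end; skipped", s)
                continue
            _, load, kind = code.split("_")
            chunks.append(rec.data[:, s : s + n_samp])
            conditions.append(load)
            is_target = kind == "target"
            targets.append(is_target)
            resp = responses[(responses >= s + min_rt) & (responses < s + n_samp)]
            responded = resp.size > 0
            correct.append(responded if is_target else not responded)
        data = _mean_center(np.stack(chunks))
        return Epochs(
            data=data,
            rate=rec.rate,
            window_ms=window_ms,
            conditions=np.array(conditions, dtype=object),
            montage=rec.montage,
            target=np.array(targets),
            correct=np.array(correct),
        )

    raise ValueError(f"unknown epoching scheme {scheme!r}")


# --------------------------------------------------------------------------
# Ocular ICA
# --------------------------------------------------------------------------


@dataclass
class IcaModel:
    """ICA decomposition over the scalp-channel subspace.

    ``unmixing`` maps used scalp channels to the 32 component time courses;
    ``mixing`` maps components back.  Correlation diagnostics and the
    flagged-component set record why components were removed.
    """

    unmixing: np.ndarray            # (n_components, n_used)
    mixing: np.ndarray              # (n_used, n_components)
    used_channels: tuple[str, ...]
    omitted_channels: tuple[str, ...]
    r_veog: np.ndarray
    r_heog: np.ndarray
    r_spatial: np.ndarray
    flagged: frozenset[int]

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]


def _uniquely_high(r: np.ndarray, floor: float = 0.3, n_mads: float = 4.0) -> np.ndarray:
    """Outlier rule for 'uniquely high' |correlations| among components:
    |r| above median + n_mads * MAD and above an absolute floor."""
    a = np.abs(r)
    med = np.median(a)
    mad = np.median(np.abs(a - med))
    return (a > med + n_mads * mad) & (a > floor)


def ocular_ica(
    epochs: Epochs,
    n_components: int = 32,
    omit: tuple[str, ...] = ("TP7",),
    blink_template: np.ndarray | None = None,
    seed: int = 0,
    temporal_floor: float = 0.3,
    spatial_floor: float = 0.7,
    max_iter: int = 200,
) -> tuple[IcaModel, Epochs]:
    """Remove ocular components from scalp channels.

    Components are extracted from scalp channels only (persistently noisy
    channels, TP7 by default, are temporarily omitted).  A component is
    flagged when its temporal correlation with VEOG/HEOG or its spatial
    correlation with the blink topography is uniquely high among the
    ``n_components`` components; the mixing transform less the flagged
    components is applied back, and per-epoch mean-centring is re-applied.
    """
    from mne.preprocessing import infomax

    montage = epochs.montage
    scalp = [
        montage.labels[i] for i in montage.scalp_indices if montage.labels[i] not in omit
    ]
    if len(scalp) < n_components:
        raise ValueError(
            f"{len(scalp)} usable scalp channels < {n_components} requested components"
        )
    idx = np.array([montage.index(ch) for ch in scalp])
    veog = epochs.data[:, montage.index("VEOG"), :].reshape(-1)
    heog = epochs.data[:, montage.index("HEOG"), :].reshape(-1)

    n_ep, _, n_samp = epochs.data.shape
    X = epochs.data[:, idx, :].transpose(1, 0, 2).reshape(len(idx), -1)
    means = X.mean(axis=1, keepdims=True)
    Xc = X - means
    n_obs = Xc.shape[1]

    # PCA whitening to n_components dimensions, then extended infomax.
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    if S[n_components - 1] <= S[0] * 1e-12:
        raise RuntimeError("scalp data rank below the requested component count")
    U, S = U[:, :n_components], S[:n_components]
    whiten = (np.sqrt(n_obs) / S)[:, None] * U.T           # (k, n_used)
    Z = whiten @ Xc
    W = infomax(Z.T, extended=True, rng=seed, max_iter=max_iter, verbose="error")  # (k, k)
    unmixing = W @ whiten
    sources = unmixing @ Xc
    mixing = np.linalg.pinv(unmixing)

    def _corr(a: np.ndarray, b: np.ndarray) -> float:
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            return 0.0
        return float(np.dot(a - a.mean(), b - b.mean()) / (len(a) * sa * sb))

    r_veog = np.array([_corr(src, veog) for src in sources])
    r_heog = np.array([_corr(src, heog) for src in sources])
    if blink_template is None:
        blink_template = blink_projection(montage)[idx]
    else:
        blink_template = np.asarray(blink_template, float)
        if blink_template.shape[0] == montage.n_channels:
            blink_template = blink_template[idx]
    r_spatial = np.array([_corr(mixing[:, k], blink_template) for k in range(n_components)])

    # Temporal EOG correlations are near zero for brain components, so a
    # low floor suffices; broad frontal oscillation topographies correlate
    # moderately (up to ~0.5) with the blink projection, hence the higher
    # spatial floor.
    flagged = (
        _uniquely_high(r_veog, temporal_floor)
        | _uniquely_high(r_heog, temporal_floor)
        | _uniquely_high(r_spatial, spatial_floor)
    )
    flagged_set = frozenset(int(k) for k in np.flatnonzero(flagged))

    cleaned = epochs.copy()
    if flagged_set:
        bad = sorted(flagged_set)
        removal = mixing[:, bad] @ sources[bad, :]
        Xclean = X - removal
        cleaned.data[:, idx, :] = Xclean.reshape(len(idx), n_ep, n_samp).transpose(1, 0, 2)
    cleaned.data = _mean_center(cleaned.data)

    model = IcaModel(
        unmixing=unmixing,
        mixing=mixing,
        used_channels=tuple(scalp),
        omitted_channels=tuple(omit),
        r_veog=r_veog,
        r_heog=r_heog,
        r_spatial=r_spatial,
        flagged=flagged_set,
    )
    return model, cleaned


# --------------------------------------------------------------------------
# Rejection and repair
# --------------------------------------------------------------------------


def reject_and_repair(
    epochs: Epochs,
    threshold_uv: float,
    bad_fraction: float = 0.2,
    spline_terms: int = 50,
) -> Epochs:
    """Two-pass amplitude rejection with bad-channel interpolation.

    Pass 1 rejects epochs whose absolute amplitude on any scalp channel
    exceeds the threshold.  Channels exceeding the threshold on more than
    ``bad_fraction`` of epochs are declared bad; rejection is re-run
    ignoring them, and the bad channels are reconstructed by
    spherical-spline interpolation from the remaining scalp channels.
    Idempotent: a second run with the same threshold changes nothing.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    montage = epochs.montage
    scalp = montage.scalp_indices
    peaks = np.abs(epochs.data[:, scalp, :]).max(axis=2)  # (n_epochs, n_scalp)

    over = peaks > threshold_uv
    frac = over.mean(axis=0)
    bad_local = np.flatnonzero(frac > bad_fraction)
    bad_labels = frozenset(montage.labels[scalp[j]] for j in bad_local) | epochs.bad_channels
    good_local = np.array(
        [j for j in range(len(scalp)) if montage.labels[scalp[j]] not in bad_labels]
    )
    if good_local.size == 0:
        raise AllChannelsBadError("all scalp channels marked bad")

    rejected = over[:, good_local].any(axis=1)

    out = epochs.copy()
    bad_idx = np.array([montage.index(ch) for ch in sorted(bad_labels)], dtype=int)
    if bad_idx.size:
        good_idx = scalp[good_local]
        M = spline_interpolation_matrix(
            montage.positions[good_idx], montage.positions[bad_idx], n_terms=spline_terms
        )
        out.data[:, bad_idx, :] = np.einsum("bg,egt->ebt", M, out.data[:, good_idx, :])
    out.rejected = epochs.rejected | rejected
    out.bad_channels = bad_labels
    return out


# --------------------------------------------------------------------------
# Inclusion check
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class InclusionReport:
    analysis: str                       # "rest" | "task"
    counts: dict
    included: bool
    reason: str = ""


def check_inclusion(
    epochs: Epochs, analysis: str, min_epochs: int = MIN_VALID_EPOCHS
) -> InclusionReport:
    """Per-participant inclusion verdict: >= ``min_epochs`` valid epochs in
    every condition of the analysis (task epochs must also be correct)."""
    if analysis == "rest":
        conditions = ("eyes_open", "eyes_closed")
        correct_only = False
    elif analysis == "task":
        conditions = ("1back", "2back")
        correct_only = True
    else:
        raise ValueError(f"unknown analysis {analysis!r}")
    counts = {
        c: int(epochs.valid_mask(c, correct_only=correct_only).sum()) for c in conditions
    }
    short = [c for c, n in counts.items() if n < min_epochs]
    if short:
        reason = ", ".join(f"{c}: {counts[c]} < {min_epochs}" for c in short)
        return InclusionReport(analysis, counts, False, reason)
    return InclusionReport(analysis, counts, True)
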