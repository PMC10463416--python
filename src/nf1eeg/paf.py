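"""Peak alpha frequency (PAF) at Pz after 1/f adjustment and smoothing.

The aperiodic background is modelled as a quadratic in log10 frequency,
fitted while omitting the loose alpha range (6.5-13.5 Hz) and the notch
region (48-52 Hz); the residual spectrum is Gaussian-smoothed and the PAF is
the arg-max of the residual in the loose alpha range.  Maxima at a range
boundary or on a monotone edge slope are flagged for review rather than
silently relocated; manual overrides are recorded in the estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .spectral import PowerSpectrum

__all__ = ["PafEstimate", "adjust_one_over_f", "estimate_paf", "ALPHA_RANGE_HZ"]

#: Loose alpha range for PAF determination (Hz, inclusive).
ALPHA_RANGE_HZ = (6.5, 13.5)

#: Default support of the aperiodic fit (Hz), excluding the omitted ranges.
FIT_RANGES_HZ = ((1.0, 40.0), (55.0, 100.0))

#: Ranges omitted from the aperiodic fit: loose alpha and the notch region.
OMIT_RANGES_HZ = (ALPHA_RANGE_HZ, (48.0, 52.0))


@dataclass
class PafEstimate:
    paf_hz: float
    channel: str
    condition: str | None
    flag: str                       # "clean" | "needs-review"
    review_note: str
    residual: np.ndarray            # 1/f-adjusted spectrum at the channel
    smoothed: np.ndarray            # Gaussian-smoothed residual
    freqs: np.ndarray
    override_applied: bool = False

    def __post_init__(self) -> None:
        lo, hi = ALPHA_RANGE_HZ
        if not (lo <= self.paf_hz <= hi):
            raise ValueError(f"PAF {self.paf_hz} Hz outside {ALPHA_RANGE_HZ}")


def _range_mask(freqs: np.ndarray, ranges) -> np.ndarray:
    mask = np.zeros_like(freqs, dtype=bool)
    for lo, hi in ranges:
        mask |= (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
    return mask


def adjust_one_over_f(
    spec: PowerSpectrum,
    fit_ranges=FIT_RANGES_HZ,
    omit_ranges=OMIT_RANGES_HZ,
) -> PowerSpectrum:
    """Residual spectrum after removing a quadratic-in-log10(f) background.

    The quadratic is fitted per channel to log power over ``fit_ranges``
    minus ``omit_ranges``; the residual is defined on the full grid.
    """
    freqs = spec.freqs
    fit_mask = _range_mask(freqs, fit_ranges) & ~_range_mask(freqs, omit_ranges)
    fit_mask &= freqs > 0
    if fit_mask.sum() < 3:
        raise ValueError("fewer than 3 usable bins for the aperiodic fit")
    logf_fit = np.log10(freqs[fit_mask])
    logf_all = np.log10(np.maximum(freqs, freqs[freqs > 0].min()))
    residual = np.empty_like(spec.values)
    for ch in range(spec.values.shape[0]):
        coeffs = np.polyfit(logf_fit, spec.values[ch, fit_mask], deg=2)
        residual[ch] = spec.values[ch] - np.polyval(coeffs, logf_all)
    return replace(spec, values=residual)


def estimate_paf(
    residual: PowerSpectrum,
    channel: str = "Pz",
    smooth_sd_bins: float = 2.0,
    alpha_range=ALPHA_RANGE_HZ,
    manual_override_hz: float | None = None,
) -> PafEstimate:
    """Arg-max of the smoothed residual in the loose alpha range.

    Smoothing uses a Gaussian kernel (SD in bins, truncated at +/-4 SD).
    The estimate is flagged ``needs-review`` when the maximum sits at a
    range boundary or when the smoothed residual is strictly monotone
    across the half-range containing it (an edge-slope maximum).  A manual
    override replaces the value and is recorded.
    """
    row = residual.channel_values(channel)
    smoothed = gaussian_filter1d(row, sigma=smooth_sd_bins, truncate=4.0)
    lo, hi = alpha_range
    in_range = (residual.freqs >= lo - 1e-9) & (residual.freqs <= hi + 1e-9)
    idx = np.flatnonzero(in_range)
    if idx.size < 3:
        raise ValueError("alpha range not covered by the frequency grid")
    seg = smoothed[idx]
    if np.ptp(seg) < 1e-12:
        raise ValueError("residual is flat across the alpha range; no peak")
    k = int(np.argmax(seg))
    paf = float(residual.freqs[idx[k]])

    flag, note = "clean", ""
    if k == 0 or k == idx.size - 1:
        flag, note = "needs-review", f"maximum at the {lo if k == 0 else hi} Hz boundary"
    else:
        # Edge-slope maxima: the half-range containing the maximum rises
        # strictly toward the range edge (ascending beta slope above the
        # midpoint, descending delta slope below it).
        mid = 0.5 * (lo + hi)
        if paf >= mid:
            half = seg[np.flatnonzero(residual.freqs[idx] >= mid)]
            monotone_to_edge = half.size > 1 and np.all(np.diff(half) > 0)
        else:
            half = seg[np.flatnonzero(residual.freqs[idx] <= mid)]
            monotone_to_edge = half.size > 1 and np.all(np.diff(half) < 0)
        if monotone_to_edge:
            flag, note = (
                "needs-review",
                "smoothed residual strictly monotone across the half-range "
                "containing the maximum (edge-slope peak)",
            )

    override = False
    if manual_override_hz is not None:
        paf = float(manual_override_hz)
        override = True
        note = (note + "; " if note else "") + f"manual override to {paf} Hz"
    return PafEstimate(
        paf_hz=paf,
        channel=channel,
        condition=residual.condition,
        flag=flag,
        review_note=note,
        residual=row,
        smoothed=smoothed,
        freqs=residual.freqs,
        override_applied=override,
    )
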