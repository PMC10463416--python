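"""Synthetic EEG cohorts with known ground truth.

Generates continuous 512 Hz recordings that emulate the study sessions the
analysis expects: 2.5 min eyes-open and 2.5 min eyes-closed rest followed by
a four-block visual n-back (1/2/2/1-back, 100 trials per block, 25 targets).
The signal model is

* a 1/f^chi background (independent per channel),
* per-band oscillations synthesized as narrowband-filtered noise (not pure
  sinusoids, so instantaneous phase is non-degenerate) with smooth scalp
  topographies and eyes-closed gain factors,
* NF1-like group offsets: added log10 band power (delta/theta) and a lowered
  alpha centre frequency,
* frontoparietal theta coupling with a von Mises phase-lag concentration,
* optional ocular artifacts: raised-cosine blinks projected onto frontal
  channels and square-wave saccades on HEOG.

Identical (config, seed) reproduces bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import hilbert
from scipy.special import i0, i1

from .core import (
    AUX_CHANNELS,
    BANDS,
    EPOCH_WINDOW_MS,
    MID_FRONTAL,
    PARIETAL_REGIONS,
    Epochs,
    Montage,
    Recording,
    window_n_samples,
)

__all__ = [
    "OscSpec",
    "CouplingSpec",
    "ArtifactSpec",
    "SubjectProfile",
    "SynthConfig",
    "CohortSubject",
    "generate_recording",
    "generate_group_cohort",
    "inject_artifacts",
    "generate_phase_locked_epochs",
    "blink_projection",
    "default_schedule",
]


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class OscSpec:
    """One band oscillation: centre (Hz), bandwidth (Hz), RMS amplitude (uV),
    scalp topography preset, and the eyes-closed power gain."""

    center_hz: float
    bandwidth_hz: float
    amplitude_uv: float
    topography: str = "uniform"
    closed_gain: float = 1.0

    def validate(self) -> None:
        if self.amplitude_uv < 0:
            raise ValueError("oscillation amplitude must be >= 0")
        if not (0.1 <= self.center_hz <= 100.0):
            raise ValueError("band centre must lie within 0.1-100 Hz")
        if self.closed_gain < 0:
            raise ValueError("closed gain must be >= 0")


@dataclass(frozen=True)
class CouplingSpec:
    """Frontoparietal theta coupling between the mid-frontal seed and one
    parietal region; kappa is the von Mises concentration of the per-trial
    phase lag (np.inf degenerates to a constant lag)."""

    region_pair: str = "MM"
    freq_hz: float = 5.0
    kappa: float = 1.0
    lag_rad: float = 0.7
    amplitude_uv: float = 2.0

    def validate(self) -> None:
        if self.region_pair not in PARIETAL_REGIONS:
            raise ValueError(f"unknown region pair {self.region_pair!r}")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.amplitude_uv < 0:
            raise ValueError("coupling amplitude must be >= 0")


@dataclass(frozen=True)
class ArtifactSpec:
    """Ocular artifact rates and shapes.

    Blinks: 300 ms raised-cosine positive deflections on VEOG with a frontal
    scalp projection decaying with distance from the eyes.  Saccades:
    square-wave deflections on HEOG with a weak lateralized scalp leak.
    """

    blink_rate_hz: float = 0.15
    blink_amp_uv: float = 300.0
    blink_dur_s: float = 0.3
    saccade_rate_hz: float = 0.08
    saccade_amp_uv: float = 60.0
    saccade_dur_s: float = 0.4

    def validate(self) -> None:
        if min(self.blink_rate_hz, self.saccade_rate_hz) < 0:
            raise ValueError("artifact rates must be >= 0")

    @property
    def any_active(self) -> bool:
        return (self.blink_rate_hz > 0 and self.blink_amp_uv != 0) or (
            self.saccade_rate_hz > 0 and self.saccade_amp_uv != 0
        )


def _default_bands() -> dict[str, OscSpec]:
    # Amplitudes / closed gains anchored to the control-group eyes-open vs
    # eyes-closed band-power pattern: low frequencies and alpha rise with
    # eyes closed, gamma falls.
    return {
        "delta": OscSpec(2.0, 2.0, 9.0, "frontal", closed_gain=1.5),
        "theta": OscSpec(5.5, 3.0, 8.0, "frontal_midline", closed_gain=2.2),
        "alpha": OscSpec(10.0, 2.0, 8.0, "posterior", closed_gain=8.0),
        "beta": OscSpec(20.0, 10.0, 2.5, "central", closed_gain=1.2),
        "low_gamma": OscSpec(38.0, 10.0, 1.2, "uniform", closed_gain=0.3),
        "high_gamma": OscSpec(75.0, 30.0, 1.0, "uniform", closed_gain=0.2),
    }


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject ground truth: group label, additive log10 band-power
    offsets, and the true alpha centre frequency (Hz)."""

    group: str = "CON"
    band_log_offsets: dict = field(default_factory=dict)
    alpha_center_hz: float = 10.0


@dataclass(frozen=True)
class SynthConfig:
    """Generator configuration; defaults encode the emulated study session."""

    seed: int = 0
    rate: float = 512.0
    chi: float = 1.0                       # background exponent: power ~ 1/f^chi
    background_uv: float = 2.5             # background RMS per channel (uV)
    bands: dict = field(default_factory=_default_bands)
    shared_fraction: float = 0.4           # variance fraction of the shared band source
    # NF1-like group offsets (added log10 power; alpha-peak shift in Hz),
    # anchored to the reported group means of the study design targeted here.
    group_log_offsets: dict = field(
        default_factory=lambda: {"delta": 0.4, "theta": 0.6}
    )
    paf_shift_hz: float = -1.3
    alpha_center_hz: float = 10.0
    subject_sd_log10: float = 0.3          # between-subject band-power SD
    subject_sd_paf_hz: float = 0.8         # between-subject alpha-centre SD
    coupling: tuple = (
        CouplingSpec("ML"),
        CouplingSpec("MM"),
        CouplingSpec("MR"),
    )
    artifacts: ArtifactSpec = field(default_factory=ArtifactSpec)
    # Session structure
    rest_open_s: float = 150.0
    rest_closed_s: float = 150.0
    blocks: tuple = ("1back", "2back", "2back", "1back")
    trials_per_block: int = 100
    targets_per_block: int = 25
    fixation_s: float = 2.0
    stim_s: float = 0.5
    jitter_s: float = 0.1                  # +/- jitter in 17 ms steps
    hit_rate: float = 0.95
    false_alarm_rate: float = 0.02
    rt_median_s: float = 0.601             # log-normal response-time median
    rt_sigma: float = 0.29

    def validate(self) -> None:
        for spec in self.bands.values():
            spec.validate()
        for c in self.coupling:
            c.validate()
        self.artifacts.validate()
        if self.rate <= 0:
            raise ValueError("rate must be positive")


def default_schedule(cfg: SynthConfig) -> list[tuple[str, object]]:
    """Session schedule: rest segments followed by the n-back blocks."""
    sched: list[tuple[str, object]] = []
    if cfg.rest_open_s > 0:
        sched.append(("rest_open", cfg.rest_open_s))
    if cfg.rest_closed_s > 0:
        sched.append(("rest_closed", cfg.rest_closed_s))
    for load in cfg.blocks:
        sched.append(("task", load))
    return sched


# --------------------------------------------------------------------------
# Noise primitives
# --------------------------------------------------------------------------


def _powerlaw_noise(rng: np.random.Generator, n_ch: int, n: int, chi: float, rate: float) -> np.ndarray:
    """Independent 1/f^chi noise per channel, unit RMS per channel."""
    white = rng.standard_normal((n_ch, n))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, 1.0 / rate)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-chi / 2.0)
    out = np.fft.irfft(spec * shape, n=n, axis=-1)
    rms = np.sqrt(np.mean(out**2, axis=-1, keepdims=True))
    rms[rms == 0] = 1.0
    return out / rms


def _narrowband_noise(
    rng: np.random.Generator, shape_ch: int, n: int, rate: float, center: float, bw: float
) -> np.ndarray:
    """Gaussian-spectrum narrowband noise, unit RMS, one row per channel."""
    white = rng.standard_normal((shape_ch, n))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, 1.0 / rate)
    sigma = max(bw / 2.0, 1.0 / (n / rate))  # at least one bin wide
    profile = np.exp(-0.5 * ((f - center) / sigma) ** 2)
    out = np.fft.irfft(spec * profile, n=n, axis=-1)
    rms = np.sqrt(np.mean(out**2, axis=-1, keepdims=True))
    rms[rms == 0] = 1.0
    return out / rms


def _phase_shift_narrowband(x: np.ndarray, lag_rad: float) -> np.ndarray:
    """Shift the phase of a narrowband signal by lag_rad via its analytic form."""
    analytic = hilbert(x)
    return np.real(analytic * np.exp(-1j * lag_rad))


def _topography(montage: Montage, preset: str) -> np.ndarray:
    """Per-channel oscillation weight; auxiliary channels get zero."""
    pos = montage.positions
    y = pos[:, 1]
    z = pos[:, 2]
    if preset == "uniform":
        w = np.ones(montage.n_channels)
    elif preset == "posterior":
        w = 0.3 + 0.7 * np.clip(-y, 0.0, None)
    elif preset == "frontal":
        w = 0.3 + 0.7 * np.clip(y, 0.0, None)
    elif preset == "frontal_midline":
        fz = pos[montage.index("Fz")] if "Fz" in montage.labels else np.array([0.0, 0.7, 0.7])
        d2 = np.sum((pos - fz) ** 2, axis=1)
        w = 0.2 + 0.8 * np.exp(-d2 / 0.5)
    elif preset == "central":
        w = 0.2 + 0.8 * np.clip(z, 0.0, None)
    else:
        raise ValueError(f"unknown topography preset {preset!r}")
    w = w.copy()
    w[~montage.is_scalp] = 0.0
    return w


def blink_projection(montage: Montage) -> np.ndarray:
    """Scalp projection of a blink: decays with distance from the eyes.

    By convention the VEOG weight is 1, so the blink amplitude parameter is
    the VEOG deflection in uV.
    """
    eye = np.array([0.0, 1.05, -0.15])
    d2 = np.sum((montage.positions - eye) ** 2, axis=1)
    proj = np.exp(-d2 / (2 * 0.35**2))
    proj[~montage.is_scalp] = 0.0
    proj[montage.index("VEOG")] = 1.0
    proj[montage.index("HEOG")] = 0.1
    return proj


# --------------------------------------------------------------------------
# Continuous recording
# --------------------------------------------------------------------------


def _kappa_to_plv(kappa: float) -> float:
    if np.isinf(kappa):
        return 1.0
    if kappa == 0:
        return 0.0
    return float(i1(kappa) / i0(kappa))


def _segment_signal(
    cfg: SynthConfig,
    montage: Montage,
    rng: np.random.Generator,
    n: int,
    eyes_closed: bool,
    profile: SubjectProfile,
) -> np.ndarray:
    """One segment of channels x samples signal (uV)."""
    n_ch = montage.n_channels
    freqs = np.fft.rfftfreq(n, 1.0 / cfg.rate)

    # 1/f^chi background on every channel (auxiliary channels at half scale).
    bg = _powerlaw_noise(rng, n_ch, n, cfg.chi, cfg.rate) * cfg.background_uv
    bg[~montage.is_scalp] *= 0.5
    data = bg

    # One white-noise spectrum drives the independent per-channel component
    # of every band: the Gaussian band profiles are nearly disjoint in
    # frequency, so the extracted band components are effectively
    # independent while costing a single noise draw + FFT pair per segment.
    # Profiles are normalized analytically to unit expected RMS (Parseval),
    # accumulated per channel, and realized with a single inverse FFT.
    osc_spec = np.fft.rfft(rng.standard_normal((n_ch, n)), axis=-1)
    bin_weight = np.full(freqs.shape, 2.0)
    bin_weight[0] = 1.0
    if n % 2 == 0:
        bin_weight[-1] = 1.0
    shared = np.sqrt(cfg.shared_fraction)
    indep = np.sqrt(1.0 - cfg.shared_fraction)
    prof_sum = np.zeros((n_ch, freqs.size))
    for name, spec in cfg.bands.items():
        amp = spec.amplitude_uv
        if amp == 0:
            continue
        center = spec.center_hz
        if name == "alpha":
            center = profile.alpha_center_hz
        gain = 1.0
        if eyes_closed:
            gain *= np.sqrt(spec.closed_gain)
        offset = profile.band_log_offsets.get(name, 0.0)
        gain *= 10.0 ** (offset / 2.0)
        w = _topography(montage, spec.topography)
        sigma = max(spec.bandwidth_hz / 2.0, 1.0 / (n / cfg.rate))
        prof = np.exp(-0.5 * ((freqs - center) / sigma) ** 2)
        prof /= np.sqrt(np.sum(bin_weight * prof**2) / n)  # unit expected RMS
        coef = w * amp * gain
        prof_sum += np.outer(coef * indep, prof)
        src = _narrowband_noise(rng, 1, n, cfg.rate, center, spec.bandwidth_hz)[0]
        data += (coef * shared)[:, None] * src
    data += np.fft.irfft(osc_spec * prof_sum, n=n, axis=-1)

    # Frontoparietal theta coupling: shared narrowband theta injected into the
    # mid-frontal seed and, phase-lagged and partially mixed with independent
    # theta, into the parietal target region.  The mixing ratio equals the von
    # Mises mean resultant I1(kappa)/I0(kappa), so the injected inter-site
    # phase clustering approximates that value.
    for c in profile_couplings(cfg, profile):
        if c.amplitude_uv == 0:
            continue
        src = _narrowband_noise(rng, 1, n, cfg.rate, c.freq_hz, 1.5)[0]
        lagged = _phase_shift_narrowband(src, c.lag_rad)
        rho = _kappa_to_plv(c.kappa)
        for ch in MID_FRONTAL:
            data[montage.index(ch)] += c.amplitude_uv * src
        for ch in PARIETAL_REGIONS[c.region_pair]:
            ind = _narrowband_noise(rng, 1, n, cfg.rate, c.freq_hz, 1.5)[0]
            data[montage.index(ch)] += c.amplitude_uv * (
                rho * lagged + np.sqrt(max(0.0, 1.0 - rho**2)) * ind
            )
    return data


def profile_couplings(cfg: SynthConfig, profile: SubjectProfile):
    return cfg.coupling


def _task_segment_events(
    cfg: SynthConfig, rng: np.random.Generator, load: str, start_sample: int
) -> tuple[list[tuple[int, str]], int]:
    """Events for one n-back block; returns (events, n_samples_in_block)."""
    rate = cfg.rate
    events: list[tuple[int, str]] = [(start_sample, f"block_start_{load}")]
    n_back = int(load[0])
    n_trials = cfg.trials_per_block
    eligible = np.arange(n_back, n_trials)
    targets = np.zeros(n_trials, dtype=bool)
    chosen = rng.choice(eligible, size=min(cfg.targets_per_block, eligible.size), replace=False)
    targets[chosen] = True

    t = 0.0
    steps = np.round(cfg.jitter_s / 0.017)
    for trial in range(n_trials):
        jitter = 0.017 * rng.integers(-steps, steps + 1)
        stim_t = t + cfg.fixation_s + jitter
        stim_sample = start_sample + int(round(stim_t * rate))
        kind = "target" if targets[trial] else "nontarget"
        events.append((stim_sample, f"stim_{load}_{kind}"))
        respond = (
            rng.random() < cfg.hit_rate if targets[trial] else rng.random() < cfg.false_alarm_rate
        )
        if respond:
            rt = np.exp(np.log(cfg.rt_median_s) + cfg.rt_sigma * rng.standard_normal())
            rt = float(np.clip(rt, 0.2, cfg.fixation_s + cfg.stim_s))
            events.append((stim_sample + int(round(rt * rate)), "response"))
        t = stim_t + cfg.stim_s  # next fixation starts after the stimulus
    # block length: last stimulus + stim + full epoch tail + short break
    n_block = int(round((t + EPOCH_WINDOW_MS[1] / 1000.0 + 0.5) * rate))
    return events, n_block


def generate_recording(
    cfg: SynthConfig,
    profile: SubjectProfile | None = None,
    schedule: list[tuple[str, object]] | None = None,
    montage: Montage | None = None,
    total_duration_s: float | None = None,
) -> Recording:
    """Simulate one continuous recording following ``schedule``.

    ``schedule`` entries are ("rest_open", seconds), ("rest_closed", seconds)
    or ("task", load) with load in {"1back", "2back"}.  Raises if the
    schedule does not fit inside ``total_duration_s`` (when given).
    """
    cfg.validate()
    if profile is None:
        profile = SubjectProfile(alpha_center_hz=cfg.alpha_center_hz)
    if montage is None:
        montage = Montage.standard()
    if schedule is None:
        schedule = default_schedule(cfg)

    rng = np.random.default_rng(cfg.seed)
    rate = cfg.rate
    pieces: list[np.ndarray] = []
    events: list[tuple[int, str]] = []
    cursor = 0
    for kind, arg in schedule:
        if kind in ("rest_open", "rest_closed"):
            n = int(round(float(arg) * rate))
            events.append((cursor, kind))
            seg = _segment_signal(cfg, montage, rng, n, kind == "rest_closed", profile)
        elif kind == "task":
            load = str(arg)
            if load not in ("1back", "2back"):
                raise ValueError(f"unknown task load {load!r}")
            seg_events, n = _task_segment_events(cfg, rng, load, cursor)
            events.extend(seg_events)
            seg = _segment_signal(cfg, montage, rng, n, False, profile)
        else:
            raise ValueError(f"unknown schedule entry {kind!r}")
        pieces.append(seg)
        cursor += n

    if total_duration_s is not None and cursor > total_duration_s * rate:
        raise ValueError(
            f"schedule needs {cursor / rate:.1f} s but only {total_duration_s:.1f} s requested"
        )
    data = np.concatenate(pieces, axis=1)
    events = [(s, c) for s, c in events if 0 <= s < data.shape[1]]
    return Recording(data=data, rate=rate, montage=montage, events=events)


# --------------------------------------------------------------------------
# Artifacts
# --------------------------------------------------------------------------


def inject_artifacts(rec: Recording, spec: ArtifactSpec, seed: int = 0) -> Recording:
    """Return a copy of ``rec`` with ocular artifacts added.

    The input recording is untouched and serves as the clean reference for
    scoring artifact removal.
    """
    spec.validate()
    out = rec.copy()
    if not spec.any_active:
        return out
    rng = np.random.default_rng(seed)
    rate = rec.rate
    n = rec.n_samples
    montage = rec.montage

    if spec.blink_rate_hz > 0 and spec.blink_amp_uv != 0:
        proj = blink_projection(montage)
        n_blinks = rng.poisson(spec.blink_rate_hz * n / rate)
        dur = int(round(spec.blink_dur_s * rate))
        template = 0.5 * (1 - np.cos(2 * np.pi * np.arange(dur) / dur))
        for start in np.sort(rng.integers(0, max(1, n - dur), size=n_blinks)):
            out.data[:, start : start + dur] += (
                spec.blink_amp_uv * proj[:, None] * template[None, :]
            )

    if spec.saccade_rate_hz > 0 and spec.saccade_amp_uv != 0:
        heog = montage.index("HEOG")
        x_lat = montage.positions[:, 0].copy()
        x_lat[~montage.is_scalp] = 0.0
        n_sacc = rng.poisson(spec.saccade_rate_hz * n / rate)
        dur = int(round(spec.saccade_dur_s * rate))
        for start in np.sort(rng.integers(0, max(1, n - dur), size=n_sacc)):
            sign = rng.choice([-1.0, 1.0])
            box = sign * spec.saccade_amp_uv
            out.data[heog, start : start + dur] += box
            out.data[:, start : start + dur] += 0.05 * box * x_lat[:, None]
    return out


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSubject:
    subject_id: str
    group: str
    age_years: float
    profile: SubjectProfile
    recording: Recording


def generate_group_cohort(
    cfg: SynthConfig,
    n_con: int,
    n_nf1: int,
    seed: int,
    schedule: list[tuple[str, object]] | None = None,
    apply_artifacts: bool | None = None,
) -> list[CohortSubject]:
    """Simulate a two-group cohort with deterministic per-subject seeds.

    NF1-like subjects receive the configured group offsets (added delta/theta
    log power, lowered alpha centre) on top of normally distributed
    between-subject variability.  ``apply_artifacts`` defaults to whether the
    config's artifact rates are non-zero.
    """
    if n_con < 1 or n_nf1 < 1:
        raise ValueError("need at least one subject per group")
    cfg.validate()
    if apply_artifacts is None:
        apply_artifacts = cfg.artifacts.any_active
    montage = Montage.standard()
    master = np.random.SeedSequence(seed)
    children = master.spawn(n_con + n_nf1)
    groups = ["CON"] * n_con + ["NF1"] * n_nf1
    subjects: list[CohortSubject] = []
    for i, (group, child) in enumerate(zip(groups, children)):
        rng = np.random.default_rng(child)
        offsets = {
            band: float(rng.normal(0.0, cfg.subject_sd_log10)) for band in cfg.bands
        }
        alpha_center = cfg.alpha_center_hz + float(rng.normal(0.0, cfg.subject_sd_paf_hz))
        if group == "NF1":
            for band, off in cfg.group_log_offsets.items():
                offsets[band] = offsets.get(band, 0.0) + off
            alpha_center += cfg.paf_shift_hz
        age = float(rng.uniform(11.0, 17.0))
        profile = SubjectProfile(
            group=group, band_log_offsets=offsets, alpha_center_hz=alpha_center
        )
        rec_seed = int(rng.integers(0, 2**31 - 1))
        art_seed = int(rng.integers(0, 2**31 - 1))
        rec = generate_recording(
            replace(cfg, seed=rec_seed), profile=profile, schedule=schedule, montage=montage
        )
        if apply_artifacts:
            rec = inject_artifacts(rec, cfg.artifacts, seed=art_seed)
        subjects.append(
            CohortSubject(
                subject_id=f"{group.lower()}{i:02d}",
                group=group,
                age_years=age,
                profile=profile,
                recording=rec,
            )
        )
    return subjects


# --------------------------------------------------------------------------
# Phase-locked epochs (ground truth for ISPC)
# --------------------------------------------------------------------------


def generate_phase_locked_epochs(
    n_trials: int,
    freq_hz: float,
    kappa: float,
    lag_rad: float,
    seed: int = 0,
    rate: float = 256.0,
    noise_uv: float = 0.05,
) -> Epochs:
    """Two-channel epochs whose per-trial phase difference at ``freq_hz`` is
    drawn von Mises(lag, kappa); kappa=inf gives a constant lag.
    """
    if n_trials < 2:
        raise ValueError("need at least 2 trials")
    rng = np.random.default_rng(seed)
    n_samp = window_n_samples(*EPOCH_WINDOW_MS, rate)
    t = np.arange(n_samp) / rate
    base = rng.uniform(0.0, 2 * np.pi, size=n_trials)
    if np.isinf(kappa):
        diff = np.full(n_trials, lag_rad)
    elif kappa == 0:
        diff = rng.uniform(-np.pi, np.pi, size=n_trials)
    else:
        diff = rng.vonmises(lag_rad, kappa, size=n_trials)
    x = np.cos(2 * np.pi * freq_hz * t[None, :] + base[:, None])
    y = np.cos(2 * np.pi * freq_hz * t[None, :] + base[:, None] - diff[:, None])
    data = np.stack([x, y], axis=1) + noise_uv * rng.standard_normal((n_trials, 2, n_samp))
    montage = Montage(
        labels=("chx", "chy"),
        positions=np.array([[0.0, 1.0, 0.0], [0.0, -1.0, 0.0]]),
        is_scalp=np.array([True, True]),
    )
    return Epochs(
        data=data,
        rate=rate,
        window_ms=EPOCH_WINDOW_MS,
        conditions=np.array(["1back"] * n_trials, dtype=object),
        montage=montage,
    )
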