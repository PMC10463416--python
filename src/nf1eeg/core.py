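"""Shared containers and study constants for the NF1 EEG pipeline.

The pipeline operates on three in-memory objects:

* :class:`Montage` — channel labels and unit-sphere scalp positions,
* :class:`Recording` — a continuous multichannel trace with an event stream,
* :class:`Epochs` — trials x channels x samples with condition labels,
  rejection state and bad-channel bookkeeping.

Band definitions, coherence regions and the event-code vocabulary live here
so that every stage agrees on them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np

# --------------------------------------------------------------------------
# Study constants
# --------------------------------------------------------------------------

#: Canonical frequency bands (Hz, inclusive bounds on the 1 Hz grid).
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 3.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 11.0),
    "beta": (12.0, 29.0),
    "low_gamma": (30.0, 47.0),
    "high_gamma": (53.0, 100.0),
}

#: Frontoparietal coherence regions (mid-frontal seed -> parietal targets).
MID_FRONTAL: tuple[str, ...] = ("F1", "Fz", "F2")
PARIETAL_REGIONS: dict[str, tuple[str, ...]] = {
    "ML": ("P3", "P5", "P7"),   # left-parietal
    "MM": ("P1", "Pz", "P2"),   # mid-parietal
    "MR": ("P4", "P6", "P8"),   # right-parietal
}
COHERENCE_CHANNELS: tuple[str, ...] = MID_FRONTAL + tuple(
    ch for region in PARIETAL_REGIONS.values() for ch in region
)

#: Auxiliary (non-scalp) channels recorded alongside the 64 scalp sites.
AUX_CHANNELS: tuple[str, ...] = ("HEOG", "VEOG", "M1", "M2")

#: Closed vocabulary of event codes carried by a Recording.
EVENT_CODES: frozenset[str] = frozenset(
    {
        "rest_open",
        "rest_closed",
        "block_start_1back",
        "block_start_2back",
        "stim_1back_target",
        "stim_1back_nontarget",
        "stim_2back_target",
        "stim_2back_nontarget",
        "response",
    }
)

#: Epoch condition vocabulary.
CONDITIONS: frozenset[str] = frozenset({"eyes_open", "eyes_closed", "1back", "2back"})

#: Epoch window (ms) shared by rest (arbitrary) and task (stimulus-locked).
EPOCH_WINDOW_MS: tuple[float, float] = (0.0, 1900.0)


def window_n_samples(start_ms: float, end_ms: float, rate: float) -> int:
    """Number of samples in the half-open window [start_ms, end_ms).

    Sample k sits at time k/rate; it belongs to the window when
    start <= k/rate < end.  At 256 Hz the 0-1900 ms epoch holds 487
    samples and the 900-1900 ms analysis slice exactly 256.
    """
    eps = 1e-9
    first = int(np.ceil(start_ms * rate / 1000.0 - eps))
    stop = int(np.ceil(end_ms * rate / 1000.0 - eps))
    return stop - first


def window_slice(start_ms: float, end_ms: float, rate: float, anchor_ms: float = 0.0) -> slice:
    """Sample slice for [start_ms, end_ms) relative to an epoch anchored at anchor_ms."""
    eps = 1e-9
    first = int(np.ceil((start_ms - anchor_ms) * rate / 1000.0 - eps))
    stop = int(np.ceil((end_ms - anchor_ms) * rate / 1000.0 - eps))
    return slice(first, stop)


# --------------------------------------------------------------------------
# Montage
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Montage:
    """Channel labels with 3-D positions; scalp sites lie on the unit sphere."""

    labels: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3)
    is_scalp: np.ndarray   # (n_channels,) bool

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        pos = np.asarray(self.positions, dtype=float)
        scalp = np.asarray(self.is_scalp, dtype=bool)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "is_scalp", scalp)
        if len(set(labels)) != len(labels):
            raise ValueError("montage labels must be unique")
        if pos.shape != (len(labels), 3):
            raise ValueError("positions must be (n_channels, 3)")
        if scalp.shape != (len(labels),):
            raise ValueError("is_scalp must be (n_channels,)")
        norms = np.linalg.norm(pos[scalp], axis=1)
        if scalp.any() and np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("scalp positions must have unit norm (within 1e-9)")

    # -- lookups ------------------------------------------------------------

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage") from None

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    @property
    def scalp_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_scalp)

    @property
    def scalp_labels(self) -> tuple[str, ...]:
        return tuple(self.labels[i] for i in self.scalp_indices)

    def require_channels(self, labels) -> None:
        missing = [ch for ch in labels if ch not in self.labels]
        if missing:
            raise KeyError(f"montage is missing required channels: {missing}")

    # -- construction / IO --------------------------------------------------

    @classmethod
    def standard(cls) -> "Montage":
        """64-channel 10-10 scalp montage (BioSemi layout) plus HEOG/VEOG/M1/M2.

        Scalp positions come from mne's template and are projected onto the
        unit sphere about the head origin.  Auxiliary channels carry nominal
        off-sphere positions and are flagged non-scalp.
        """
        import mne

        tmpl = mne.channels.make_standard_montage("biosemi64")
        ch_pos = tmpl.get_positions()["ch_pos"]
        labels = list(tmpl.ch_names)
        pos = np.array([ch_pos[name] for name in labels], dtype=float)
        pos /= np.linalg.norm(pos, axis=1, keepdims=True)
        aux_pos = {
            "HEOG": (1.1, 0.9, -0.3),
            "VEOG": (0.3, 1.1, -0.2),
            "M1": (-1.1, -0.2, -0.4),
            "M2": (1.1, -0.2, -0.4),
        }
        for name in AUX_CHANNELS:
            labels.append(name)
            pos = np.vstack([pos, np.asarray(aux_pos[name], dtype=float)])
        is_scalp = np.array([name not in AUX_CHANNELS for name in labels])
        montage = cls(tuple(labels), pos, is_scalp)
        montage.require_channels(COHERENCE_CHANNELS)
        return montage

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("label\tx\ty\tz\tis_scalp\n")
            for lab, p, s in zip(self.labels, self.positions, self.is_scalp):
                fh.write(f"{lab}\t{p[0]:.9f}\t{p[1]:.9f}\t{p[2]:.9f}\t{int(s)}\n")

    @classmethod
    def from_tsv(cls, path) -> "Montage":
        labels, pos, scalp = [], [], []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("label"):
                raise ValueError(f"{path}: not a montage TSV")
            for line in fh:
                lab, x, y, z, s = line.rstrip("\n").split("\t")
                labels.append(lab)
                pos.append((float(x), float(y), float(z)))
                scalp.append(bool(int(s)))
        return cls(tuple(labels), np.array(pos), np.array(scalp))


# --------------------------------------------------------------------------
# Recording
# --------------------------------------------------------------------------


@dataclass
class Recording:
    """Continuous multichannel EEG in microvolts with an event stream."""

    data: np.ndarray                     # (n_channels, n_samples), uV
    rate: float                          # samples / s
    montage: Montage
    events: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.data.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"data has {self.data.shape[0]} channels, montage {self.montage.n_channels}"
            )
        if not self.rate > 0:
            raise ValueError("rate must be positive")
        n = self.data.shape[1]
        for sample, code in self.events:
            if not 0 <= sample < n:
                raise ValueError(f"event sample {sample} outside recording of {n} samples")
            if code not in EVENT_CODES:
                raise ValueError(f"unknown event code {code!r}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.montage.index(label)]

    def copy(self) -> "Recording":
        return Recording(self.data.copy(), self.rate, self.montage, list(self.events))


# --------------------------------------------------------------------------
# Epochs
# --------------------------------------------------------------------------


@dataclass
class Epochs:
    """Epoched data: epochs x channels x samples, with per-epoch state.

    ``window_ms`` is half-open [start, end) relative to the epoch anchor
    (stimulus onset for task epochs, segment tiling point for rest).
    """

    data: np.ndarray                      # (n_epochs, n_channels, n_samples), uV
    rate: float
    window_ms: tuple[float, float]
    conditions: np.ndarray                # (n_epochs,) strings from CONDITIONS
    montage: Montage
    rejected: np.ndarray | None = None    # (n_epochs,) bool
    bad_channels: frozenset[str] = frozenset()
    target: np.ndarray | None = None      # task: target trial flags
    correct: np.ndarray | None = None     # task: response correctness

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be epochs x channels x samples")
        n_ep, n_ch, n_samp = self.data.shape
        if n_ch != self.montage.n_channels:
            raise ValueError("channel dimension does not match montage")
        expected = window_n_samples(*self.window_ms, self.rate)
        if n_samp != expected:
            raise ValueError(
                f"window {self.window_ms} at {self.rate} Hz implies {expected} samples, "
                f"data has {n_samp}"
            )
        self.conditions = np.asarray(self.conditions, dtype=object)
        if self.conditions.shape != (n_ep,):
            raise ValueError("conditions must have one label per epoch")
        bad = set(self.conditions) - CONDITIONS
        if bad:
            raise ValueError(f"unknown conditions: {sorted(bad)}")
        if self.rejected is None:
            self.rejected = np.zeros(n_ep, dtype=bool)
        self.rejected = np.asarray(self.rejected, dtype=bool)
        if self.rejected.shape != (n_ep,):
            raise ValueError("rejection mask length must equal epoch count")
        self.bad_channels = frozenset(self.bad_channels)
        for name in ("target", "correct"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=bool)
                if arr.shape != (n_ep,):
                    raise ValueError(f"{name} flags must have one entry per epoch")
                setattr(self, name, arr)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        start = self.window_ms[0]
        first = int(np.ceil(start * self.rate / 1000.0 - 1e-9))
        return (first + np.arange(self.n_samples)) * 1000.0 / self.rate

    def copy(self) -> "Epochs":
        return replace(
            self,
            data=self.data.copy(),
            conditions=self.conditions.copy(),
            rejected=self.rejected.copy(),
            target=None if self.target is None else self.target.copy(),
            correct=None if self.correct is None else self.correct.copy(),
        )

    def valid_mask(self, condition: str | None = None, correct_only: bool = False) -> np.ndarray:
        mask = ~self.rejected
        if condition is not None:
            mask &= self.conditions == condition
        if correct_only:
            if self.correct is None:
                raise ValueError("epochs carry no correctness flags")
            mask &= self.correct
        return mask

    def select(self, mask: np.ndarray) -> "Epochs":
        mask = np.asarray(mask, dtype=bool)
        return replace(
            self,
            data=self.data[mask],
            conditions=self.conditions[mask],
            rejected=self.rejected[mask],
            target=None if self.target is None else self.target[mask],
            correct=None if self.correct is None else self.correct[mask],
        )

    def concatenate(self, other: "Epochs") -> "Epochs":
        if other.rate != self.rate or other.window_ms != self.window_ms:
            raise ValueError("cannot concatenate epochs with different geometry")
        if other.montage.labels != self.montage.labels:
            raise ValueError("cannot concatenate epochs with different montages")

        def _cat_flags(a, b, n_a, n_b):
            if a is None and b is None:
                return None
            a = np.zeros(n_a, dtype=bool) if a is None else a
            b = np.zeros(n_b, dtype=bool) if b is None else b
            return np.concatenate([a, b])

        return replace(
            self,
            data=np.concatenate([self.data, other.data]),
            conditions=np.concatenate([self.conditions, other.conditions]),
            rejected=np.concatenate([self.rejected, other.rejected]),
            bad_channels=self.bad_channels | other.bad_channels,
            target=_cat_flags(self.target, other.target, self.n_epochs, other.n_epochs),
            correct=_cat_flags(self.correct, other.correct, self.n_epochs, other.n_epochs),
        )


def replace_fields(obj, **kw):
    """dataclasses.replace passthrough (convenience re-export)."""
    return dataclasses.replace(obj, **kw)
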