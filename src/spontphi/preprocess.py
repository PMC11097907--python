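"""Preprocessing chain from raw multichannel recordings to analysis-ready epochs.

The canonical chain for epidural rodent EEG is::

    rereference -> downsample -> bandpass -> epoch -> subsample

i.e. re-reference to a bipolar derivation, anti-aliased resampling to 500 Hz,
zero-phase 0.5-45 Hz fourth-order Butterworth filtering, cutting into 4 s
non-overlapping epochs (optionally time-locked to pre-stimulus windows), and
random subsampling of channels/epochs for a balanced analysis set.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "Recording",
    "EEGEpochs",
    "rereference",
    "bandpass",
    "downsample",
    "epoch",
    "subsample",
    "preprocess_pipeline",
    "flag_bad_channels",
    "read_delimited",
    "write_delimited",
    "read_edf",
    "save_epochs",
    "load_epochs",
]


@dataclass
class Recording:
    """Continuous multichannel recording.

    data : array, shape (n_channels, n_samples), microvolts
    rate : sampling rate in Hz
    """

    data: np.ndarray
    rate: float
    channel_labels: list[str] = field(default_factory=list)
    condition: str | None = None
    reference: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length mismatch")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.rate


@dataclass
class EEGEpochs:
    """Epoched multichannel recording; unit of all spontaneous measures.

    data : array, shape (n_epochs, n_channels, n_samples), microvolts
    """

    data: np.ndarray
    rate: float
    channel_labels: list[str] = field(default_factory=list)
    condition: str | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (epochs x channels x samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch data must be finite")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.data.shape[1] < 2:
            raise ValueError("need at least 2 channels")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.data.shape[1])]
        if len(self.channel_labels) != self.data.shape[1]:
            raise ValueError("channel_labels length mismatch")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


def rereference(raw: Recording, anode: str, cathode: str) -> Recording:
    """Subtract a bipolar derivation (anode - cathode) from every channel.

    The reference channels are retained; the recording is flagged with the
    derivation used. ``anode == cathode`` is the identity.
    """
    labels = raw.channel_labels
    for lab in (anode, cathode):
        if lab not in labels:
            raise KeyError(f"channel {lab!r} not found")
    ref = raw.data[labels.index(anode)] - raw.data[labels.index(cathode)]
    return replace(raw, data=raw.data - ref[None, :], reference=(anode, cathode))


def _butter_sos(low: float, high: float, order: int, rate: float):
    nyq = rate / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"invalid band ({low}, {high}) Hz at rate {rate} Hz")
    return signal.butter(order, [low, high], btype="bandpass", fs=rate, output="sos")


def bandpass(raw, low: float = 0.5, high: float = 45.0, order: int = 4,
             rate: float | None = None):
    """Zero-phase (forward-backward) Butterworth bandpass.

    Accepts a :class:`Recording` (rate taken from it) or a plain array with an
    explicit ``rate``. Forward-backward application doubles the effective
    attenuation and cancels phase distortion, which matters for the
    phase-based coalition measures downstream.
    """
    if isinstance(raw, Recording):
        sos = _butter_sos(low, high, order, raw.rate)
        return replace(raw, data=signal.sosfiltfilt(sos, raw.data, axis=-1))
    if rate is None:
        raise ValueError("rate required for plain-array input")
    sos = _butter_sos(low, high, order, rate)
    return signal.sosfiltfilt(sos, np.asarray(raw, dtype=float), axis=-1)


def downsample(raw: Recording, target: float) -> Recording:
    """Anti-aliased polyphase resampling to ``target`` Hz."""
    if target > raw.rate:
        raise ValueError("target rate exceeds original rate")
    if target == raw.rate:
        return raw
    frac = Fraction(target / raw.rate).limit_denominator(1000)
    data = signal.resample_poly(raw.data, frac.numerator, frac.denominator, axis=-1)
    return replace(raw, data=data, rate=target)


def epoch(raw: Recording, length: float = 4.0,
          stimulus_times: np.ndarray | None = None,
          window: tuple[float, float] = (-5.0, -1.0)) -> EEGEpochs:
    """Cut a recording into non-overlapping epochs of ``length`` seconds.

    Without stimulus times, consecutive non-overlapping windows are taken from
    the start and the trailing remainder is dropped. With a stimulus-time
    table (onsets in seconds), one epoch is taken from the stimulus-free
    ``window`` (relative seconds) preceding each stimulus; ``window`` must
    span exactly ``length`` seconds.
    """
    n_samp = int(round(length * raw.rate))
    if stimulus_times is None:
        n_ep = raw.data.shape[1] // n_samp
        if n_ep == 0:
            raise ValueError(
                f"recording ({raw.duration:.2f} s) shorter than epoch length {length} s")
        cut = raw.data[:, : n_ep * n_samp]
        data = cut.reshape(raw.n_channels, n_ep, n_samp).transpose(1, 0, 2)
    else:
        if abs((window[1] - window[0]) - length) > 1e-9:
            raise ValueError("pre-stimulus window must span the epoch length")
        segs = []
        for t in np.asarray(stimulus_times, dtype=float):
            a = int(round((t + window[0]) * raw.rate))
            b = a + n_samp
            if a < 0 or b > raw.data.shape[1]:
                logger.warning("stimulus at %.2f s: window out of range, skipped", t)
                continue
            segs.append(raw.data[:, a:b])
        if not segs:
            raise ValueError("no valid pre-stimulus windows")
        data = np.stack(segs, axis=0)
    return EEGEpochs(data=data, rate=raw.rate, channel_labels=list(raw.channel_labels),
                     condition=raw.condition,
                     provenance={"epoch_length_s": length,
                                 "stimulus_locked": stimulus_times is not None})


def subsample(epochs: EEGEpochs, n_channels: int, n_epochs: int,
              rng: np.random.Generator | int | None = None) -> EEGEpochs:
    """Uniformly subsample channels and epochs without replacement (seeded)."""
    rng = np.random.default_rng(rng)
    if n_channels > epochs.n_channels or n_epochs > epochs.n_epochs:
        raise ValueError("requested more channels/epochs than available")
    ch = np.sort(rng.choice(epochs.n_channels, size=n_channels, replace=False))
    ep = np.sort(rng.choice(epochs.n_epochs, size=n_epochs, replace=False))
    prov = dict(epochs.provenance)
    prov["subsample"] = {"channels": ch.tolist(), "epochs": ep.tolist()}
    return EEGEpochs(data=epochs.data[np.ix_(ep, np.arange(epochs.n_channels))][:, ch],
                     rate=epochs.rate,
                     channel_labels=[epochs.channel_labels[i] for i in ch],
                     condition=epochs.condition, provenance=prov)


def flag_bad_channels(raw: Recording, amplitude_uv: float = 1000.0) -> list[str]:
    """Amplitude-threshold helper for bad-channel screening (manual use).

    Returns labels whose peak absolute amplitude exceeds the threshold. Not
    applied automatically anywhere; channel rejection is a manual-list affair.
    """
    peak = np.max(np.abs(raw.data), axis=1)
    return [raw.channel_labels[i] for i in np.nonzero(peak > amplitude_uv)[0]]


def preprocess_pipeline(raw: Recording, anode: str | None = None,
                        cathode: str | None = None, target_rate: float = 500.0,
                        band: tuple[float, float] = (0.5, 45.0),
                        epoch_length: float = 4.0,
                        stimulus_times: np.ndarray | None = None,
                        n_channels: int | None = 14, n_epochs: int | None = 80,
                        rng=None) -> EEGEpochs:
    """Run the full documented chain on a continuous recording."""
    if anode is not None and cathode is not None:
        raw = rereference(raw, anode, cathode)
    raw = downsample(raw, target_rate)
    raw = bandpass(raw, band[0], band[1], order=4)
    eps = epoch(raw, epoch_length, stimulus_times=stimulus_times)
    if n_channels is not None and n_epochs is not None:
        n_channels = min(n_channels, eps.n_channels)
        n_epochs = min(n_epochs, eps.n_epochs)
        eps = subsample(eps, n_channels, n_epochs, rng)
    return eps


# ---------------------------------------------------------------------------
# I/O: delimited text, EDF (read-only, via mne when present), epoch bundles
# ---------------------------------------------------------------------------

def read_delimited(path, rate: float, delimiter: str = ",",
                   condition: str | None = None) -> Recording:
    """Read a channels x samples delimited-text matrix."""
    data = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    return Recording(data=data, rate=rate, condition=condition)


def write_delimited(raw: Recording, path, delimiter: str = ",") -> None:
    np.savetxt(path, raw.data, delimiter=delimiter)


def read_edf(path, condition: str | None = None) -> Recording:
    """Read an EDF recording (requires the optional ``mne`` dependency)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF reading requires mne (pip install spontphi[edf])") from exc
    edf = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return Recording(data=edf.get_data() * 1e6, rate=float(edf.info["sfreq"]),
                     channel_labels=list(edf.ch_names), condition=condition)


def save_epochs(epochs: EEGEpochs, directory) -> None:
    """Write an epoch bundle: one CSV of stacked epochs plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n_ep, n_ch, n_s = epochs.data.shape
    np.savetxt(directory / "data.csv", epochs.data.reshape(n_ep * n_ch, n_s),
               delimiter=",")
    manifest = {
        "n_epochs": n_ep, "n_channels": n_ch, "n_samples": n_s,
        "rate": epochs.rate, "channel_labels": epochs.channel_labels,
        "condition": epochs.condition, "provenance": epochs.provenance,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_epochs(directory) -> EEGEpochs:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    flat = np.loadtxt(directory / "data.csv", delimiter=",", ndmin=2)
    data = flat.reshape(manifest["n_epochs"], manifest["n_channels"],
                        manifest["n_samples"])
    return EEGEpochs(data=data, rate=manifest["rate"],
                     channel_labels=manifest["channel_labels"],
                     condition=manifest["condition"],
                     provenance=manifest.get("provenance", {}))
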