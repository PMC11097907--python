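"""Seeded rat-like synthetic EEG for end-to-end testing without any download.

Channels are spectrally shaped Gaussian noise (power spectral density
proportional to 1/f^gamma above 0.5 Hz) passed through a channel mixing
matrix, plus an optional shared broadband driver (raising zero-lag
correlations) and an optional slow (< 4 Hz) rhythmic admixture emulating the
bistable slow-wave activity of deep anesthesia. Profiles for wakefulness and
the three anesthetics differ only in those knobs: deep anesthesia steepens
the spectrum (larger gamma), adds slow-wave fraction, and strengthens the
common driver; the dissociative profile stays close to wakefulness.

These fixtures emulate the spectral and correlation structure that the
spontaneous measures respond to; they are not biophysical simulations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .preprocess import EEGEpochs

__all__ = ["EEGProfile", "condition_profile", "generate_recording", "write_fixture"]


@dataclass
class EEGProfile:
    """Generator knobs for one synthetic recording."""

    n_channels: int = 16
    rate: float = 500.0
    n_epochs: int = 80
    epoch_len: float = 4.0
    spectral_gamma: float = 1.3       # 1/f^gamma exponent of each channel
    slow_osc_fraction: float = 0.0    # in [0, 1]: < 4 Hz rhythmic admixture
    common_driver_gain: float = 0.0   # >= 0: shared-source coupling
    mixing: np.ndarray | None = None  # (n_channels, n_channels) coupling
    slow_freq: float = 1.5            # Hz, slow-wave carrier
    seed: int = 0
    condition: str = "synthetic"

    def __post_init__(self) -> None:
        if not 0.0 <= self.slow_osc_fraction <= 1.0:
            raise ValueError("slow_osc_fraction must be in [0, 1]")
        if self.common_driver_gain < 0:
            raise ValueError("common_driver_gain must be >= 0")
        if self.rate <= 2 * max(self.slow_freq, 45.0):
            raise ValueError("rate must exceed twice the highest generated frequency")
        n_samp = self.epoch_len * self.rate
        if abs(n_samp - round(n_samp)) > 1e-9:
            raise ValueError("epoch sample count must be integral")


# Condition profiles: gamma magnitudes follow the wake (~ -1.3) vs deep
# anesthesia (~ -3) aperiodic slopes typical of rodent epidural EEG; the
# dissociative (ketamine-like) state is spectrally close to wakefulness.
_CONDITIONS = {
    "wake": dict(spectral_gamma=1.3, slow_osc_fraction=0.0, common_driver_gain=0.3),
    "ketamine": dict(spectral_gamma=1.5, slow_osc_fraction=0.05, common_driver_gain=0.35),
    "propofol": dict(spectral_gamma=3.0, slow_osc_fraction=0.4, common_driver_gain=0.6),
    "sevoflurane": dict(spectral_gamma=2.8, slow_osc_fraction=0.35, common_driver_gain=0.6),
}


def condition_profile(condition: str, seed: int = 0, **overrides) -> EEGProfile:
    """Named profile (wake / ketamine / propofol / sevoflurane)."""
    try:
        params = dict(_CONDITIONS[condition])
    except KeyError:
        raise ValueError(f"unknown condition {condition!r}; choose from {sorted(_CONDITIONS)}")
    params.update(overrides)
    return EEGProfile(seed=seed, condition=condition, **params)


def _shaped_noise(n_sig: int, n_samples: int, gamma: float, rate: float,
                  rng: np.random.Generator, f_floor: float = 0.5) -> np.ndarray:
    """Gaussian noise with PSD proportional to 1/f^gamma above ``f_floor``."""
    white = rng.standard_normal((n_sig, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n_samples, d=1.0 / rate)
    f_eff = np.maximum(f, f_floor)        # flatten below f_floor: finite variance
    scale = f_eff ** (-gamma / 2.0)
    scale[0] = 0.0                        # no DC
    x = np.fft.irfft(spec * scale, n=n_samples, axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def generate_recording(profile: EEGProfile) -> EEGEpochs:
    """Generate one epoched synthetic recording from a profile (seeded)."""
    rng = np.random.default_rng(profile.seed)
    n_samp_ep = int(round(profile.epoch_len * profile.rate))
    n_total = n_samp_ep * profile.n_epochs
    n_ch = profile.n_channels

    base = _shaped_noise(n_ch, n_total, profile.spectral_gamma, profile.rate, rng)
    if profile.mixing is not None:
        mixing = np.asarray(profile.mixing, dtype=float)
        if mixing.shape != (n_ch, n_ch):
            raise ValueError("mixing must be n_channels x n_channels")
        base = mixing @ base
        base = base / base.std(axis=-1, keepdims=True)
    if profile.common_driver_gain > 0:
        driver = _shaped_noise(1, n_total, profile.spectral_gamma, profile.rate, rng)
        base = base + profile.common_driver_gain * driver
        base = base / base.std(axis=-1, keepdims=True)
    if profile.slow_osc_fraction > 0:
        # shared slow wave: amplitude-modulated carrier below 4 Hz
        t = np.arange(n_total) / profile.rate
        envelope = 1.0 + 0.5 * np.sin(2 * np.pi * 0.25 * t + rng.uniform(0, 2 * np.pi))
        carrier = np.sin(2 * np.pi * profile.slow_freq * t + rng.uniform(0, 2 * np.pi))
        slow = envelope * carrier
        slow = slow / slow.std()
        frac = profile.slow_osc_fraction
        base = (1 - frac) * base + frac * slow[None, :]
        base = base / base.std(axis=-1, keepdims=True)

    data = 50.0 * base  # ~50 uV RMS, epidural scale
    epochs = data.reshape(n_ch, profile.n_epochs, n_samp_ep).transpose(1, 0, 2)
    return EEGEpochs(data=epochs, rate=profile.rate,
                     channel_labels=[f"ch{i}" for i in range(n_ch)],
                     condition=profile.condition,
                     provenance={"generator": "synthetic_eeg",
                                 "profile": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                                             for k, v in asdict(profile).items()}})


def write_fixture(epochs: EEGEpochs, directory) -> None:
    """Write the fixture as delimited text plus a JSON manifest of its profile."""
    from .preprocess import save_epochs

    directory = Path(directory)
    save_epochs(epochs, directory)
    (directory / "fixture.json").write_text(
        json.dumps(epochs.provenance, indent=2, default=str))
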