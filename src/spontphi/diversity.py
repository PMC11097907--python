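"""Signal-diversity and spectral measures of spontaneous EEG.

Implements single-channel Lempel-Ziv complexity (LZs, from the 1976
exhaustive-history parse), amplitude coalition entropy (ACE), synchrony
coalition entropy (SCE), Welch power spectral density, and the aperiodic
spectral exponent (log-log slope of the PSD, conventionally fit on 20-40 Hz).

All binarizations threshold the analytic-signal (Hilbert) amplitude of each
channel at its own epoch mean. Normalizations divide by the mean value of the
same statistic after within-channel time shuffling (k surrogates), which maps
the measures to an approximately [0, 1] scale where 1 means
"indistinguishable from temporally unstructured data".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.signal import hilbert, welch

logger = logging.getLogger(__name__)

__all__ = [
    "BinaryRaster",
    "SpectrumSet",
    "binarize_hilbert",
    "lz76",
    "lz76_normalized",
    "lzs",
    "ace",
    "coalition_entropy",
    "sce",
    "welch_psd",
    "spectral_exponent",
]

N_SHUFFLES = 10  # surrogate count for every shuffle normalization


@dataclass
class BinaryRaster:
    """Binary activity raster (channels x samples) for one epoch."""

    bits: np.ndarray
    constant_channels: np.ndarray  # bool flags: channel had zero variance

    def __post_init__(self) -> None:
        self.bits = np.ascontiguousarray(self.bits, dtype=np.uint8)
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("raster must be binary")


@dataclass
class SpectrumSet:
    """Welch power spectral density per channel."""

    freqs: np.ndarray  # Hz, strictly ascending
    power: np.ndarray  # channels x freqs, uV^2/Hz

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly ascending")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")


def binarize_hilbert(epoch: np.ndarray) -> BinaryRaster:
    """Threshold each channel's Hilbert amplitude at its own epoch mean.

    ``epoch`` is (channels x samples). Constant channels produce an all-zero
    row and are flagged.
    """
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    if epoch.shape[1] < 2:
        raise ValueError("epoch needs at least 2 samples")
    env = np.abs(hilbert(epoch, axis=-1))
    mean = env.mean(axis=-1, keepdims=True)
    constant = epoch.std(axis=-1) == 0
    bits = (env > mean).astype(np.uint8)
    bits[constant] = 0
    if constant.any():
        logger.warning("binarize_hilbert: %d constant channel(s) set to all-zero",
                       int(constant.sum()))
    return BinaryRaster(bits=bits, constant_channels=constant)


@njit(cache=True)
def _lz76_count(s):  # pragma: no cover - jitted
    n = s.size
    if n == 0:
        return 0
    if n == 1:
        return 1
    c = 1
    l = 1
    i = 0
    k = 1
    kmax = 1
    while True:
        if s[i + k - 1] == s[l + k - 1]:
            k += 1
            if l + k > n:
                c += 1
                break
        else:
            if k > kmax:
                kmax = k
            i += 1
            if i == l:
                c += 1
                l += kmax
                if l + 1 > n:
                    break
                i = 0
                k = 1
                kmax = 1
            else:
                k = 1
    return c


def lz76(bits) -> int:
    """Number of phrases in the LZ76 exhaustive-history parse of a binary string.

    Phrase boundaries follow Lempel & Ziv's production parse: each phrase is
    the shortest extension of the history that cannot be copied from it
    (self-referential copying allowed); a trailing reproducible remainder
    counts as one final phrase.
    """
    arr = np.ascontiguousarray(bits, dtype=np.uint8)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("need a non-empty 1-D sequence")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("sequence must be binary")
    return int(_lz76_count(arr))


# Shuffle normalization depends only on (length, #ones); keyed cache keeps the
# per-channel surrogate cost amortized across calls. Seeding by the key makes
# the value independent of call order.
_NORM_CACHE: dict[tuple[int, int, int, int], float] = {}


def _shuffled_mean_count(n: int, ones: int, n_shuffles: int, seed: int) -> float:
    key = (n, ones, n_shuffles, seed)
    val = _NORM_CACHE.get(key)
    if val is None:
        rng = np.random.default_rng(np.random.SeedSequence([n, ones, n_shuffles, seed]))
        base = np.zeros(n, dtype=np.uint8)
        base[:ones] = 1
        total = 0
        for _ in range(n_shuffles):
            total += _lz76_count(rng.permutation(base))
        val = total / n_shuffles
        if len(_NORM_CACHE) > 100_000:
            _NORM_CACHE.clear()
        _NORM_CACHE[key] = val
    return val


def lz76_normalized(bits, n_shuffles: int = N_SHUFFLES, seed: int = 0,
                    method: str = "shuffle") -> float:
    """LZ76 parse count normalized to ~[0, 1].

    ``method='shuffle'`` divides by the mean parse count of ``n_shuffles``
    within-sequence shuffles (surrogates preserve the symbol composition);
    ``method='asymptotic'`` divides by the n/log2(n) upper bound instead.
    """
    arr = np.ascontiguousarray(bits, dtype=np.uint8)
    c = lz76(arr)
    if method == "asymptotic":
        n = arr.size
        return c * np.log2(n) / n
    if method != "shuffle":
        raise ValueError(f"unknown normalization {method!r}")
    denom = _shuffled_mean_count(arr.size, int(arr.sum()), n_shuffles, seed)
    return c / denom


def _as_epoch_array(epochs) -> np.ndarray:
    """Coerce EEGEpochs / 3-D / 2-D input to (epochs, channels, samples)."""
    data = getattr(epochs, "data", epochs)
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError("expected (epochs x) channels x samples data")
    return data


def lzs(epochs, n_shuffles: int = N_SHUFFLES, seed: int = 0,
        method: str = "shuffle") -> float:
    """Mean single-channel normalized LZ76 complexity.

    Per epoch and channel, the Hilbert-binarized signal is parsed and
    normalized; values are averaged over channels, then epochs. Constant
    (all-zero raster) channels are excluded with a log entry.
    """
    data = _as_epoch_array(epochs)
    per_epoch = []
    for ep in data:
        raster = binarize_hilbert(ep)
        vals = [lz76_normalized(row, n_shuffles, seed, method)
                for row, const in zip(raster.bits, raster.constant_channels)
                if not const]
        if not vals:
            logger.warning("lzs: epoch with all-constant channels excluded")
            continue
        per_epoch.append(float(np.mean(vals)))
    if not per_epoch:
        raise ValueError("no valid epochs for LZs")
    return float(np.mean(per_epoch))


def _coalition_ids(bits: np.ndarray) -> np.ndarray:
    """Encode each binary column (a coalition) as an integer id."""
    n_ch = bits.shape[0]
    if n_ch > 62:
        raise ValueError("too many channels to encode coalitions")
    weights = (1 << np.arange(n_ch, dtype=np.int64))
    return weights @ bits.astype(np.int64)


def coalition_entropy(bits: np.ndarray) -> float:
    """Shannon entropy (bits) of the distribution of binary column patterns."""
    _, counts = np.unique(_coalition_ids(np.asarray(bits, dtype=np.uint8)),
                          return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _shuffle_rows(bits: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = np.empty_like(bits)
    for i, row in enumerate(bits):
        out[i] = rng.permutation(row)
    return out


def ace(epochs, n_shuffles: int = N_SHUFFLES, seed: int = 0) -> float:
    """Amplitude coalition entropy.

    Entropy of the per-sample coalition (which channels are jointly above
    their mean Hilbert amplitude), normalized by the mean coalition entropy
    after independent within-channel time shuffling.
    """
    data = _as_epoch_array(epochs)
    if data.shape[1] < 2:
        raise ValueError("ACE needs at least 2 channels")
    rng = np.random.default_rng(np.random.SeedSequence([seed, data.shape[1], data.shape[2]]))
    vals = []
    for ep in data:
        bits = binarize_hilbert(ep).bits
        h = coalition_entropy(bits)
        h_sh = np.mean([coalition_entropy(_shuffle_rows(bits, rng))
                        for _ in range(n_shuffles)])
        vals.append(h / h_sh if h_sh > 0 else 0.0)
    return float(np.mean(vals))


def _phase_coalitions(phases: np.ndarray, channel: int, threshold: float) -> np.ndarray:
    """Binary synchrony raster of ``channel`` with every other channel."""
    diff = phases - phases[channel]
    diff = np.angle(np.exp(1j * diff))  # wrap to (-pi, pi]
    sync = (np.abs(diff) < threshold).astype(np.uint8)
    return np.delete(sync, channel, axis=0)


def sce(epochs, threshold: float = 0.8, n_shuffles: int = N_SHUFFLES,
        seed: int = 0) -> float:
    """Synchrony coalition entropy.

    For each channel, the coalition at each sample is the set of partner
    channels whose instantaneous (Hilbert) phase lies within ``threshold``
    radians. The entropy of that coalition sequence is normalized by the mean
    entropy after shuffling each channel's phase series in time, then averaged
    over channels and epochs.
    """
    data = _as_epoch_array(epochs)
    if data.shape[1] < 2:
        raise ValueError("SCE needs at least 2 channels")
    rng = np.random.default_rng(np.random.SeedSequence([seed + 1, data.shape[1], data.shape[2]]))
    vals = []
    for ep in data:
        phases = np.angle(hilbert(ep, axis=-1))
        surrogates = [_shuffle_rows(phases, rng) for _ in range(n_shuffles)]
        per_channel = []
        for ch in range(ep.shape[0]):
            h = coalition_entropy(_phase_coalitions(phases, ch, threshold))
            denom = float(np.mean([
                coalition_entropy(_phase_coalitions(s, ch, threshold))
                for s in surrogates]))
            per_channel.append(h / denom if denom > 0 else 0.0)
        vals.append(float(np.mean(per_channel)))
    return float(np.mean(vals))


def welch_psd(epochs, rate: float | None = None, window: float = 1.0,
              overlap: float = 0.5) -> SpectrumSet:
    """Hann-windowed averaged periodogram per channel, averaged over epochs."""
    data = _as_epoch_array(epochs)
    if rate is None:
        rate = getattr(epochs, "rate", None)
        if rate is None:
            raise ValueError("rate required for plain-array input")
    nper = int(round(window * rate))
    if nper > data.shape[2]:
        raise ValueError("window longer than epoch")
    freqs, power = welch(data, fs=rate, window="hann", nperseg=nper,
                         noverlap=int(round(nper * overlap)), axis=-1)
    return SpectrumSet(freqs=freqs, power=power.mean(axis=0))


def spectral_exponent(spec: SpectrumSet, band: tuple[float, float] = (20.0, 40.0)) -> float:
    """OLS slope of log10 power vs log10 frequency in ``band``, channel-averaged."""
    sel = (spec.freqs >= band[0]) & (spec.freqs <= band[1])
    if sel.sum() < 3:
        raise ValueError("need at least 3 frequency bins in band")
    pw = spec.power[:, sel]
    if np.any(pw <= 0):
        raise ValueError("zero power bin inside band")
    logf = np.log10(spec.freqs[sel])
    design = np.column_stack([logf, np.ones_like(logf)])
    slopes, _ = np.linalg.lstsq(design, np.log10(pw).T, rcond=None)[0]
    return float(np.mean(slopes))
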