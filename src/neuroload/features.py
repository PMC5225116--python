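"""Spectral feature extraction: Welch PSD -> log band power -> z-scoring.

Each 3-s, 250-Hz epoch is transformed channel-wise with the Welch method
(Hamming windows of 500 samples, 250-sample overlap, 512-point FFT; a
750-sample epoch yields exactly two full segments).  PSD bins are then
averaged within six canonical bands (delta 1-3, theta 4-7, low alpha
8-10, high alpha 11-12, beta 13-25, gamma 26-40 Hz), converted to the
natural logarithm, and — downstream of extraction — z-scored per feature
against training-set statistics only.

Conventions pinned here: density PSD scaling with window power
correction and one-sided doubling (DC/Nyquist undoubled); band
membership by bin-centre inclusion in the closed interval, so bins
falling between the gapped band edges (e.g. 3.4 Hz) belong to no band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

log = logging.getLogger(__name__)

DEFAULT_FS = 250.0
WELCH_WINDOW_LEN = 500
WELCH_OVERLAP = 250
WELCH_NFFT = 512

LABEL_COLUMNS = ("participant", "mode", "level", "block", "trial", "subjective")


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if self.low_hz > self.high_hz:
            raise ValueError(f"band {self.name}: low > high")


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 3.0),
    BandDefinition("theta", 4.0, 7.0),
    BandDefinition("low_alpha", 8.0, 10.0),
    BandDefinition("high_alpha", 11.0, 12.0),
    BandDefinition("beta", 13.0, 25.0),
    BandDefinition("gamma", 26.0, 40.0),
)

BAND_NAMES = tuple(b.name for b in DEFAULT_BANDS)


def welch_psd(
    x: np.ndarray,
    fs: float = DEFAULT_FS,
    window_len: int = WELCH_WINDOW_LEN,
    overlap: int = WELCH_OVERLAP,
    nfft: int = WELCH_NFFT,
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch power spectral density along the last axis.

    Averages modified periodograms of Hamming-windowed segments; only
    full segments are used.  Returns ``(freqs, psd)`` with bin spacing
    ``fs / nfft``.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < window_len:
        raise ValueError(
            f"signal length {x.shape[-1]} shorter than one window ({window_len})"
        )
    freqs, psd = sps.welch(
        x, fs=fs, window="hamming", nperseg=window_len, noverlap=overlap,
        nfft=nfft, detrend=False, scaling="density", axis=-1,
    )
    return freqs, psd


def band_bins(freqs: np.ndarray, band: BandDefinition) -> np.ndarray:
    """Indices of PSD bins whose centre lies in ``[low_hz, high_hz]``."""
    mask = (freqs >= band.low_hz) & (freqs <= band.high_hz)
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        raise ValueError(f"band {band.name} [{band.low_hz}, {band.high_hz}] "
                         "contains no PSD bins")
    return idx


def band_power(
    freqs: np.ndarray, psd: np.ndarray,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
) -> np.ndarray:
    """Mean PSD over the bins of each band, stacked on a new last axis."""
    powers = [psd[..., band_bins(freqs, b)].mean(axis=-1) for b in bands]
    return np.stack(powers, axis=-1)


def feature_name(channel: str, band: str) -> str:
    return f"{channel}_{band}"


def split_feature_name(name: str) -> tuple[str, str]:
    """Split ``<channel>_<band>`` robustly (band names contain '_')."""
    for band in BAND_NAMES:
        suffix = f"_{band}"
        if name.endswith(suffix):
            return name[: -len(suffix)], band
    channel, _, band = name.rpartition("_")
    return channel, band


def feature_names_for(channels, bands=DEFAULT_BANDS) -> list[str]:
    """Channel-major feature ordering: all bands of channel 1, then 2, ..."""
    return [feature_name(ch, b.name) for ch in channels for b in bands]


@dataclass
class FeatureMatrix:
    """Trials x features log band-power matrix with per-trial labels.

    ``labels`` has columns participant, mode, level, block, trial,
    subjective, row-aligned with ``values``.
    """

    values: np.ndarray
    feature_names: list[str]
    labels: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (trials x features)")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length mismatch")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("labels row count mismatch")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def channels(self) -> list[str]:
        seen: list[str] = []
        for name in self.feature_names:
            ch = split_feature_name(name)[0]
            if ch not in seen:
                seen.append(ch)
        return seen

    def feature_indices_for_channels(self, channels) -> np.ndarray:
        channels = list(channels)
        unknown = [c for c in channels if c not in self.channels]
        if unknown:
            raise ValueError(f"unknown channels: {unknown}")
        idx = [i for i, name in enumerate(self.feature_names)
               if split_feature_name(name)[0] in channels]
        return np.asarray(idx, dtype=int)

    def to_frame(self) -> pd.DataFrame:
        feat = pd.DataFrame(self.values, columns=self.feature_names)
        return pd.concat(
            [self.labels.reset_index(drop=True)[list(LABEL_COLUMNS)], feat], axis=1
        )

    def to_csv(self, path) -> None:
        # %.17g preserves doubles bit-exactly through a text round-trip.
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        frame = pd.read_csv(path, float_precision="round_trip")
        names = [c for c in frame.columns if c not in LABEL_COLUMNS]
        return cls(
            values=frame[names].to_numpy(dtype=float),
            feature_names=names,
            labels=frame[list(LABEL_COLUMNS)].copy(),
        )


def extract_features(epoched_session, bands=DEFAULT_BANDS) -> FeatureMatrix:
    """Unnormalized log band-power features for every epoch and channel.

    Output columns follow channel-major ordering (all bands of the first
    channel, then the second, ...).  Nonpositive band power — possible
    only for degenerate all-zero signals — is flagged as NaN.
    """
    data = np.asarray(epoched_session.data, dtype=float)
    if data.ndim != 3:
        raise ValueError("epoch data must be trials x channels x samples")
    freqs, psd = welch_psd(data, fs=epoched_session.fs)
    powers = band_power(freqs, psd, bands)  # (trials, channels, bands)
    n, c, b = powers.shape
    flat = powers.reshape(n, c * b)
    nonpos = flat <= 0
    if nonpos.any():
        log.warning("%d nonpositive band powers flagged as missing",
                    int(nonpos.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(nonpos, np.nan, np.log(np.where(nonpos, 1.0, flat)))
    names = feature_names_for(epoched_session.channel_names, bands)
    return FeatureMatrix(values=values, feature_names=names,
                         labels=epoched_session.labels.copy())


@dataclass(frozen=True)
class NormalizationStats:
    """Per-feature training mean/sd; zero-variance features are zeroed."""

    mean: np.ndarray
    sd: np.ndarray
    zero_variance: np.ndarray

    @property
    def n_features(self) -> int:
        return len(self.mean)


def fit_normalizer(train_values: np.ndarray) -> NormalizationStats:
    """Training-set z-scoring statistics (population sd).

    Statistics must come from training rows only; apply the same stats
    to test rows so that genuine train/test shifts survive scaling.
    """
    train_values = np.asarray(train_values, dtype=float)
    if train_values.ndim != 2 or train_values.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 training rows")
    mean = train_values.mean(axis=0)
    sd = train_values.std(axis=0)
    zero = sd == 0
    if zero.any():
        log.warning("%d zero-variance features will be set to 0",
                    int(zero.sum()))
    return NormalizationStats(mean=mean, sd=sd, zero_variance=zero)


def apply_normalizer(values: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.shape[1] != stats.n_features:
        raise ValueError("feature count mismatch with normalization stats")
    safe_sd = np.where(stats.zero_variance, 1.0, stats.sd)
    out = (values - stats.mean) / safe_sd
    out[:, stats.zero_variance] = 0.0
    return out
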